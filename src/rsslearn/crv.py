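"""Second-order interaction analysis via cooperative relationship vectors.

For every ordered pair of binary nucleotide:position features, the joint
scatter of their per-sample attributions is multimodal: the modes coincide
with the four binary-encoding combinations (0,0), (0,1), (1,0), (1,1) of
the pair.  Each mode forms a half-line-like cloud anchored near the
origin; a cooperative relationship vector (CRV) summarizes it:

* slope — direction of the first principal component of the mean-centred
  mode points;
* length — sqrt(X99^2 + Y99^2) where X99 and Y99 are the 99th percentiles
  of the |attribution| of each feature within the mode (robust to
  outliers);
* angle — four-quadrant inverse tangent of the components.  The printed
  percentile components are nonnegative, so the quadrant is recovered by
  giving each component the sign of the mode's centroid coordinate (zero
  treated as positive) before taking atan2.  This reproduces the quadrant
  semantics: Q1 (0-90 deg) positive cooperativity, Q3 (180-270 deg)
  negative cooperativity, Q2/Q4 antagonism, angles near an axis mark one
  feature dominating the pair.

Grouped CRVs are summarized by cumulative length-angle curves (running
total of lengths as the angle sweeps counterclockwise from 225 deg), and
nucleotides whose curves covary are merged into reduced IUPAC categories.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .explain import AttributionMatrix
from .sequences import IUPAC_FROM_BASES

QUADRANT_MEANING = {
    "Q1": "Model has a POSITIVE response to BOTH features",
    "Q2": "Model only has a NEGATIVE response to feature 1",
    "Q3": "Model has a NEGATIVE response to BOTH features",
    "Q4": "Model only has a NEGATIVE response to feature 2",
    "axis": "One feature's attributions dominate the pair",
}

COMBOS = ((0, 0), (0, 1), (1, 0), (1, 1))

#: sweep origin for cumulative curves, in degrees
SWEEP_START = 225.0


@dataclass(frozen=True)
class CRVRecord:
    feature1: str
    feature2: str
    combo: tuple[int, int]
    n_points: int
    slope: float
    centroid_x: float
    centroid_y: float
    x99: float
    y99: float
    length: float
    angle_deg: float
    quadrant: str
    axis_dominated: bool
    degenerate: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["combo"] = f"{self.combo[0]},{self.combo[1]}"
        return d


def _quadrant(angle: float) -> str:
    a = angle % 360.0
    if a % 90.0 == 0.0:
        return "axis"
    if a < 90.0:
        return "Q1"
    if a < 180.0:
        return "Q2"
    if a < 270.0:
        return "Q3"
    return "Q4"


def _position(feature: str) -> str:
    return feature.rsplit("_", 1)[0]


def partition_modes(
    matrix: AttributionMatrix,
    encoding: pd.DataFrame,
    f1: str,
    f2: str,
) -> dict[tuple[int, int], np.ndarray]:
    """Split the pairwise attribution scatter by binary-encoding combo.

    Returns, per combo, an (n, 2) array of (feature1, feature2)
    attributions.  The four sets are disjoint and their union covers all
    samples.
    """
    if f1 == f2:
        raise ValueError("feature pair must be distinct")
    for f in (f1, f2):
        if f not in matrix.values.columns:
            raise KeyError(f"feature {f!r} not in attribution matrix")
        if f not in encoding.columns:
            raise KeyError(f"feature {f!r} not in encoding")
    enc = encoding.loc[matrix.values.index]
    b1 = enc[f1].to_numpy(dtype=int)
    b2 = enc[f2].to_numpy(dtype=int)
    x = matrix.values[f1].to_numpy(dtype=float)
    y = matrix.values[f2].to_numpy(dtype=float)
    out = {}
    for combo in COMBOS:
        mask = (b1 == combo[0]) & (b2 == combo[1])
        out[combo] = np.column_stack([x[mask], y[mask]])
    return out


def _pc1_slope(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, int(np.argmax(eigvals))]  # PC1 direction
    if abs(v[0]) < 1e-300:
        return float(np.inf) if v[1] >= 0 else float(-np.inf)
    return float(v[1] / v[0])


def fit_crv(
    points: np.ndarray,
    combo: tuple[int, int],
    f1: str,
    f2: str,
    axis_tolerance_deg: float = 10.0,
) -> CRVRecord:
    """Fit one cooperative relationship vector to a mode's point cloud."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    degenerate = n < 2 or bool(np.allclose(points, points[0]))
    if n == 0:
        cx = cy = x99 = y99 = 0.0
        slope = float("nan")
    else:
        cx, cy = points.mean(axis=0)
        if degenerate:
            slope = float("nan")
            x99 = y99 = 0.0
        else:
            slope = _pc1_slope(points)
            # linear interpolation between order statistics
            x99 = float(np.percentile(np.abs(points[:, 0]), 99))
            y99 = float(np.percentile(np.abs(points[:, 1]), 99))
    length = float(np.hypot(x99, y99))
    sx = 1.0 if cx >= 0 else -1.0
    sy = 1.0 if cy >= 0 else -1.0
    if length == 0.0:
        angle = 0.0
        quadrant = "axis"
    else:
        angle = float(np.degrees(np.arctan2(sy * y99, sx * x99)) % 360.0)
        quadrant = _quadrant(angle)
    dist_to_axis = min(angle % 90.0, 90.0 - angle % 90.0)
    return CRVRecord(
        feature1=f1, feature2=f2, combo=tuple(combo), n_points=n,
        slope=slope, centroid_x=float(cx), centroid_y=float(cy),
        x99=x99, y99=y99, length=length, angle_deg=angle,
        quadrant=quadrant,
        axis_dominated=bool(dist_to_axis <= axis_tolerance_deg),
        degenerate=degenerate,
    )


def all_crvs(
    matrix: AttributionMatrix,
    encoding: pd.DataFrame,
    features: Sequence[str] | None = None,
    axis_tolerance_deg: float = 10.0,
) -> pd.DataFrame:
    """CRVs for every ordered feature pair and every encoding combo.

    Same-position (1,1) combos are structurally empty under one-hot
    encoding and are never emitted; other degenerate modes are retained
    with length 0 so the combinatorial bookkeeping stays exact.
    """
    if features is None:
        features = list(matrix.values.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    records = []
    for f1 in features:
        for f2 in features:
            if f1 == f2:
                continue
            modes = partition_modes(matrix, encoding, f1, f2)
            same_position = _position(f1) == _position(f2)
            for combo in COMBOS:
                if same_position and combo == (1, 1):
                    continue
                records.append(
                    fit_crv(modes[combo], combo, f1, f2,
                            axis_tolerance_deg=axis_tolerance_deg).to_dict()
                )
    return pd.DataFrame(records)


def sweep_offset(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Counterclockwise angular offset from the 225-degree sweep origin."""
    return (np.asarray(angle_deg, dtype=float) - SWEEP_START) % 360.0


def cumulative_curve(
    crvs: pd.DataFrame,
    group_by: str = "feature1",
) -> pd.DataFrame:
    """Cumulative CRV length as the angle sweeps counterclockwise from 225 deg.

    ``group_by`` is ``feature1`` (one curve per feature) or ``position``
    (one curve per position of feature1).  Long-format output columns:
    group, sweep_angle, angle_deg, cumulative_length.  Each curve is
    nondecreasing and ends at the total CRV length of its group.
    """
    if crvs.empty:
        raise ValueError("no CRVs given")
    df = crvs.copy()
    if group_by == "feature1":
        df["group"] = df["feature1"]
    elif group_by == "position":
        df["group"] = df["feature1"].map(_position)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    df["sweep_angle"] = sweep_offset(df["angle_deg"].to_numpy())
    parts = []
    for group, sub in df.groupby("group", sort=True):
        sub = sub.sort_values(["sweep_angle", "length"], kind="mergesort")
        parts.append(pd.DataFrame({
            "group": group,
            "sweep_angle": sub["sweep_angle"].to_numpy(),
            "angle_deg": sub["angle_deg"].to_numpy(),
            "cumulative_length": sub["length"].cumsum().to_numpy(),
        }))
    return pd.concat(parts, ignore_index=True)


def _step_values(curve: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Evaluate a cumulative (step) curve on a sweep-angle grid."""
    angles = curve["sweep_angle"].to_numpy()
    heights = curve["cumulative_length"].to_numpy()
    idx = np.searchsorted(angles, grid, side="right") - 1
    out = np.where(idx >= 0, heights[np.clip(idx, 0, len(heights) - 1)], 0.0)
    return out


def covariation_distance(curve_a: pd.DataFrame, curve_b: pd.DataFrame) -> float:
    """Max absolute difference between two final-value-normalized curves."""
    grid = np.unique(np.concatenate([
        curve_a["sweep_angle"].to_numpy(), curve_b["sweep_angle"].to_numpy(),
        [0.0, 360.0 - 1e-9],
    ]))
    va = _step_values(curve_a, grid)
    vb = _step_values(curve_b, grid)
    fa = va[-1] if va[-1] > 0 else 1.0
    fb = vb[-1] if vb[-1] > 0 else 1.0
    return float(np.max(np.abs(va / fa - vb / fb)))


def covariation_groups(
    curves: pd.DataFrame,
    threshold: float = 0.15,
) -> list[str]:
    """Group the four nucleotides of one position by curve covariation.

    ``curves`` must hold the cumulative curves of exactly four features of
    one position (groups named ``<pos>_<base>``).  Bases whose normalized
    curves stay within ``threshold`` (max absolute difference) are merged
    by single linkage, and each group is reported as its IUPAC code.
    Groups are sorted by descending size, ties alphabetically.
    """
    names = sorted(curves["group"].unique())
    if len(names) != 4:
        raise ValueError("expected curves for exactly 4 features of one position")
    bases = [name.rsplit("_", 1)[1] for name in names]
    sub = {name: curves[curves["group"] == name] for name in names}
    # single linkage over the 4 items
    clusters = [{i} for i in range(4)]
    dist = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            dist[i, j] = dist[j, i] = covariation_distance(sub[names[i]],
                                                           sub[names[j]])
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if d <= threshold:
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    codes = [
        IUPAC_FROM_BASES[frozenset(bases[i] for i in cl)] for cl in clusters
    ]
    return sorted(codes, key=lambda c: (-len(_iupac_bases(c)), c))


def _iupac_bases(code: str) -> frozenset[str]:
    from .sequences import IUPAC_CODES
    return IUPAC_CODES[code]


#: reduced nucleotide categories per position reported by the source study
#: (reference constants for comparison, not computed here)
REFERENCE_CRV_GROUPINGS = {
    "H4": ("D", "C"), "H5": ("R", "Y"), "H6": ("R", "T", "C"),
    "H7": ("R", "Y"), "S1": ("W", "S"), "S2": ("M", "T", "G"),
}


def quadrant_census(crvs: pd.DataFrame) -> pd.DataFrame:
    """Count CRVs per quadrant per combo (plot-ready summary table)."""
    return (crvs.groupby(["combo", "quadrant"]).size()
            .rename("n_crvs").reset_index())
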