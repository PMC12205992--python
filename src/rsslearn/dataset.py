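"""Read-count table ingest, completion, normalization, and stratification.

A SARP-seq dataset maps each RSS variant sequence to an NGS read count,
an indirect measure of V(D)J recombination efficiency.  Variants that
never recombined are absent from the raw table and are reintroduced with
zero counts so the full library is represented.  Targets for regression
are min-max normalized read counts, either dataset-wide or within each
nonamer group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .sequences import DNA, RSSVariant

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence", "count")
OPTIONAL_COLUMNS = ("replicate", "nonamer")


def load_read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Load a read-count table from TSV or CSV.

    The file must have a header with at least ``sequence`` and ``count``
    columns; ``replicate`` and ``nonamer`` columns are preserved if present.
    """
    path = Path(path)
    if fmt is None:
        fmt = "CSV" if path.suffix.lower() == ".csv" else "TSV"
    sep = "," if fmt.upper() == "CSV" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    for i, seq in enumerate(df["sequence"]):
        if not isinstance(seq, str) or not seq or any(b not in DNA for b in seq.upper()):
            raise ValueError(f"malformed sequence at line {i + 2}: {seq!r}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"count must be a nonnegative integer (first offense at line {line})"
        )
    df = df.copy()
    df["sequence"] = df["sequence"].str.upper()
    df["count"] = counts.astype(np.int64)
    keep = [c for c in df.columns if c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    return df[keep]


def save_read_counts(table: pd.DataFrame, path) -> None:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=False)


def complete_with_zeros(
    table: pd.DataFrame, library: Sequence[RSSVariant | str]
) -> pd.DataFrame:
    """Reintroduce library variants absent from the table with zero counts.

    Output has exactly one row per library variant (per replicate, if the
    table carries a ``replicate`` column).  Idempotent.
    """
    lib_seqs = [v.sequence if isinstance(v, RSSVariant) else str(v).upper()
                for v in library]
    lib_set = set(lib_seqs)
    outside = sorted(set(table["sequence"]) - lib_set)
    if outside:
        shown = ", ".join(outside[:10])
        raise ValueError(
            f"{len(outside)} observed sequence(s) outside the library: {shown}"
        )
    extra = [c for c in ("nonamer",) if c in table.columns]

    def _complete(sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.set_index("sequence")
        if sub.index.duplicated().any():
            dup = sub.index[sub.index.duplicated()][0]
            raise ValueError(f"duplicate row for variant {dup!r}")
        out = sub.reindex(lib_seqs)
        out["count"] = out["count"].fillna(0).astype(table["count"].dtype)
        for c in extra:
            nonnull = sub[c].dropna().unique()
            out[c] = nonnull[0] if len(nonnull) == 1 else out[c]
        return out.reset_index()

    if "replicate" in table.columns:
        parts = []
        for rep, sub in table.groupby("replicate", sort=True):
            comp = _complete(sub.drop(columns=["replicate"]))
            comp["replicate"] = rep
            parts.append(comp)
        return pd.concat(parts, ignore_index=True)
    return _complete(table)


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average read counts across replicate tables, per variant.

    Tables must cover identical variant sets.  The result's ``count`` is the
    arithmetic mean (real-valued).
    """
    if not tables:
        raise ValueError("no tables given")
    base = tables[0].sort_values("sequence").reset_index(drop=True)
    seqs = set(base["sequence"])
    stacked = [base["count"].to_numpy(dtype=float)]
    for t in tables[1:]:
        if set(t["sequence"]) != seqs:
            raise ValueError("replicate tables cover different variant sets")
        t = t.sort_values("sequence").reset_index(drop=True)
        stacked.append(t["count"].to_numpy(dtype=float))
    out = base.copy()
    out["count"] = np.mean(stacked, axis=0)
    if "replicate" in out.columns:
        out = out.drop(columns=["replicate"])
    return out


def minmax_normalize(table: pd.DataFrame, mode: str = "dataset-wide") -> pd.DataFrame:
    """Rescale counts to [0, 1] by min-max, dataset-wide or per nonamer group.

    A constant group (max == min) gets all targets set to 0 with a logged
    warning, matching the "no detectable recombination" reading of a flat
    group.
    """
    if table.empty:
        raise ValueError("table is empty")
    if mode not in ("dataset-wide", "nonamer-wise"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = table.copy()
    counts = out["count"].to_numpy(dtype=float)

    def _norm(values: np.ndarray, label: str) -> np.ndarray:
        lo, hi = values.min(), values.max()
        if hi == lo:
            logger.warning("constant normalization group %s; targets set to 0", label)
            return np.zeros_like(values)
        return (values - lo) / (hi - lo)

    if mode == "dataset-wide":
        out["target"] = _norm(counts, "dataset")
    else:
        if "nonamer" not in out.columns:
            raise ValueError("nonamer-wise normalization needs a 'nonamer' column")
        grouped = out.groupby("nonamer")["count"]
        lo = grouped.transform("min").to_numpy(dtype=float)
        hi = grouped.transform("max").to_numpy(dtype=float)
        span = hi - lo
        if (span == 0).any():
            flat = out.loc[span == 0, "nonamer"].unique()
            logger.warning("constant normalization group(s) %s; targets set to 0",
                           list(flat))
        out["target"] = np.where(span > 0, (counts - lo) / np.where(span > 0, span, 1.0),
                                 0.0)
    out.attrs["normalization_mode"] = mode
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_distribution(table: pd.DataFrame, threshold: int = 10) -> dict:
    """Composition of a complete count table, to the nearest percent.

    Returns percentages of variants with count >= threshold, 0 < count <
    threshold, and count == 0 (rounded half away from zero).
    """
    if table.empty:
        raise ValueError("table is empty")
    counts = table["count"].to_numpy(dtype=float)
    n = len(counts)
    high = (counts >= threshold).sum()
    zero = (counts == 0).sum()
    low = n - high - zero
    return {
        "pct_at_or_above_threshold": _round_half_away(100.0 * high / n),
        "pct_below_threshold": _round_half_away(100.0 * low / n),
        "pct_zero": _round_half_away(100.0 * zero / n),
        "n": int(n),
        "threshold": int(threshold),
    }


@dataclass(frozen=True)
class FoldRotation:
    """One rotation of fold roles in the k-fold rotation scheme.

    ``folds`` maps each variant sequence to its fold index (shared across
    rotations); in rotation ``r`` fold ``test_fold`` is the test set, fold
    ``validation_fold`` the validation set, and the remaining k-2 folds
    train.
    """

    rotation: int
    k: int
    folds: pd.Series
    validation_fold: int
    test_fold: int

    def role_masks(self) -> dict[str, pd.Series]:
        f = self.folds
        val = f == self.validation_fold
        test = f == self.test_fold
        return {"train": ~(val | test), "validation": val, "test": test}

    def sequences(self, role: str) -> pd.Index:
        return self.folds.index[self.role_masks()[role]]


def assign_bins(targets: pd.Series, n_bins: int = 10, min_bin_size: int = 1) -> pd.Series:
    """Bin targets for stratification: a dedicated zero bin plus quantile
    bins over the nonzero values.  Bins smaller than ``min_bin_size`` are
    merged with their lower neighbor."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t = targets.to_numpy(dtype=float)
    labels = np.zeros(len(t), dtype=int)
    nz = t > 0
    if nz.any():
        q = pd.qcut(t[nz], q=min(n_bins, nz.sum()), labels=False, duplicates="drop")
        labels[nz] = np.asarray(q, dtype=int) + 1
    binned = pd.Series(labels, index=targets.index, name="bin")
    # merge undersized bins downward so every stratum supports k-fold splitting
    sizes = binned.value_counts().sort_index()
    for b in sizes.index[::-1]:
        if sizes[b] < min_bin_size and b > 0:
            logger.warning("merging undersized bin %d (%d rows)", b, sizes[b])
            binned[binned == b] = b - 1
            sizes = binned.value_counts().sort_index()
    return binned


def stratified_rotations(
    table: pd.DataFrame,
    k: int = 20,
    n_bins: int = 10,
    seed: int = 0,
) -> list[FoldRotation]:
    """Stratified k-fold rotation scheme over a normalized table.

    Variants are binned by target value (zero bin + quantile bins) and split
    into k folds stratified across bins.  Rotation r uses fold r as test and
    fold (r+1) mod k as validation, so across the k rotations every fold
    serves exactly once as validation and once as test.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    targets = table.set_index("sequence")["target"]
    bins = assign_bins(targets, n_bins=n_bins, min_bin_size=k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = pd.Series(-1, index=targets.index, name="fold")
    for fold_idx, (_, test_idx) in enumerate(
        skf.split(np.zeros(len(targets)), bins.to_numpy())
    ):
        folds.iloc[test_idx] = fold_idx
    return [
        FoldRotation(rotation=r, k=k, folds=folds,
                     validation_fold=(r + 1) % k, test_fold=r)
        for r in range(k)
    ]


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def rotations_to_tsv(rotations: Sequence[FoldRotation], path) -> None:
    folds = rotations[0].folds
    pd.DataFrame({"sequence": folds.index, "fold_index": folds.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
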