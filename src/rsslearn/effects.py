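"""Point-mutation effect maps and external-score comparisons.

The effect of a single point mutation at one position is estimated over a
complete library as the difference between the mean score of all
sequences carrying the mutated base and the mean score of all sequences
carrying the original base at that position (each set marginalizes the
other positions uniformly).  The same machinery runs on model
predictions or on any external per-variant score table, e.g. RIC scores
(a mutual-information statistic of RSS functionality consumed here as a
precomputed two-column table; -38.81 to 0 is the established threshold
range for functional 12-RSSs).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import BASE_ORDER, DNA, IUPAC_CODES, IUPAC_FROM_BASES

#: established functional threshold range for 12-RSS RIC scores
RIC_FUNCTIONAL_RANGE = (-38.81, 0.0)


def load_score_table(path, score_name: str = "score") -> pd.Series:
    """Read a two-column (sequence, score) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    seq_col, score_col = df.columns[:2]
    s = pd.Series(df[score_col].to_numpy(dtype=float),
                  index=df[seq_col].str.upper(), name=score_name)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("score table contains non-finite values")
    return s


def _position_index(scores: pd.Series, positions: Sequence[str], position: str) -> int:
    try:
        return list(positions).index(position)
    except ValueError:
        raise KeyError(f"unknown position {position!r}") from None


def _check_complete(scores: pd.Series, positions: Sequence[str]) -> None:
    n_pos = len(positions)
    expected = 4 ** n_pos
    seqs = set(scores.index)
    if len(scores) != expected or len(seqs) != expected:
        missing = expected - len(seqs)
        raise ValueError(
            f"scores must cover the complete {expected}-variant library "
            f"({missing} variants unaccounted for)"
        )


def point_mutation_effect(
    scores: pd.Series,
    positions: Sequence[str],
    position: str,
    from_base: str,
    to_base: str,
) -> dict:
    """Mean score change of mutating ``from_base`` to ``to_base`` at one
    position, marginalizing all other positions over the complete library."""
    _check_complete(scores, positions)
    j = _position_index(scores, positions, position)
    chars = scores.index.str[j]
    orig = scores[chars == from_base.upper()]
    mut = scores[chars == to_base.upper()]
    return {
        "position": position, "from": from_base.upper(), "to": to_base.upper(),
        "mean_change": float(mut.mean() - orig.mean()),
        "n_from": int(len(orig)), "n_to": int(len(mut)),
    }


def _category_sets(scheme) -> dict[str, frozenset[str]]:
    """Normalize a per-position category scheme to {label: base set}."""
    if scheme == "bases":
        return {b: frozenset(b) for b in BASE_ORDER}
    out = {}
    for item in scheme:
        bases = IUPAC_CODES[item] if item in IUPAC_CODES else frozenset(item)
        out[item] = bases
    covered = frozenset().union(*out.values())
    if covered != frozenset(DNA) or sum(len(b) for b in out.values()) != 4:
        raise ValueError(f"category scheme {scheme!r} does not partition A,T,G,C")
    return out


def effect_heatmaps(
    scores: pd.Series,
    positions: Sequence[str],
    category_scheme: str | Mapping[str, Sequence[str]] = "bases",
) -> dict[str, pd.DataFrame]:
    """Per-position from x to matrices of mean score change.

    ``category_scheme`` is ``"bases"`` for the full 4x4 maps, or a mapping
    position -> IUPAC categories (e.g. the reduced CRV groupings) that
    partition {A,T,G,C}.  Category scores pool all member sequences
    (pooled means, weighting every sequence equally), so the matrices are
    antisymmetric with a zero diagonal.
    """
    _check_complete(scores, positions)
    out = {}
    for j, position in enumerate(positions):
        scheme = category_scheme if isinstance(category_scheme, str) \
            else category_scheme[position]
        cats = _category_sets(scheme)
        chars = scores.index.str[j]
        means = {
            label: float(scores[chars.isin(list(bases))].mean())
            for label, bases in cats.items()
        }
        labels = list(cats)
        mat = pd.DataFrame(
            [[means[to] - means[frm] for to in labels] for frm in labels],
            index=pd.Index(labels, name="from"),
            columns=pd.Index(labels, name="to"),
        )
        out[position] = mat
    return out


def heatmaps_to_long(heatmaps: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for position, mat in heatmaps.items():
        for frm in mat.index:
            for to in mat.columns:
                rows.append({"position": position, "from": frm, "to": to,
                             "mean_change": float(mat.at[frm, to])})
    return pd.DataFrame(rows)


def correlate_scores(
    a: pd.Series, b: pd.Series, transform: str = "none"
) -> dict:
    """Spearman and Pearson correlation of two score tables over their
    shared variants; ``transform='log10_on_a'`` log-transforms table a
    (nonpositive values excluded, count reported)."""
    if transform not in ("none", "log10_on_a"):
        raise ValueError(f"unknown transform {transform!r}")
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared variants")
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    excluded = 0
    if transform == "log10_on_a":
        pos = av > 0
        excluded = int((~pos).sum())
        av, bv = np.log10(av[pos]), bv[pos]
    return {
        "spearman_rho": float(stats.spearmanr(av, bv).statistic),
        "pearson_r": float(stats.pearsonr(av, bv).statistic),
        "n": int(len(av)), "n_excluded": excluded,
    }


def position_frequency_matrix(
    sequences: Sequence[str], positions: Sequence[str]
) -> pd.DataFrame:
    """Base counts per position (logo-ready); column sums equal the number
    of sequences at every position."""
    n_pos = len(positions)
    counts = np.zeros((n_pos, 4), dtype=int)
    base_idx = {b: i for i, b in enumerate(BASE_ORDER)}
    for seq in sequences:
        if len(seq) != n_pos:
            raise ValueError(f"sequence {seq!r} does not share the positions")
        for j, b in enumerate(seq.upper()):
            counts[j, base_idx[b]] += 1
    return pd.DataFrame(counts, index=pd.Index(positions, name="position"),
                        columns=list(BASE_ORDER))


def striation_sample(
    a: pd.Series,
    b: pd.Series,
    centers: Sequence[float] = (-17.0, -20.0, -26.0, -32.0),
    half_width: float = 0.25,
    positions: Sequence[str] | None = None,
) -> list[dict]:
    """Sample vertical striations of the (a, b) score scatter.

    For each center c, variants with |a - c| <= half_width form one
    striation; the report gives the top and bottom b-scored sequences,
    the b and a ranges, and a position-frequency matrix of the sampled
    sequences.  Empty striations are flagged, not fatal.
    """
    common = a.index.intersection(b.index)
    av, bv = a.loc[common], b.loc[common]
    lo, hi = av.min(), av.max()
    reports = []
    for center in centers:
        if not (lo <= center <= hi):
            raise ValueError(f"center {center} outside observed x range [{lo}, {hi}]")
        mask = (av - center).abs() <= half_width
        seqs = common[mask]
        rep = {"center": float(center), "half_width": float(half_width),
               "n": int(mask.sum()), "empty": bool(mask.sum() == 0)}
        if rep["n"] > 0:
            sub_b = bv[mask]
            rep.update({
                "top_sequence": str(sub_b.idxmax()),
                "bottom_sequence": str(sub_b.idxmin()),
                "y_range": (float(sub_b.min()), float(sub_b.max())),
                "x_range": (float(av[mask].min()), float(av[mask].max())),
                "pfm": position_frequency_matrix(
                    list(seqs),
                    positions if positions is not None
                    else [f"p{i}" for i in range(len(seqs[0]))],
                ),
            })
        reports.append(rep)
    return reports
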