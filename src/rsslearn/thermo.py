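"""Melting-temperature analysis of the H4-S2 duplex window.

The duplex melting temperature (Tm) of the 6-bp randomized window is
computed with the nearest-neighbor thermodynamic model (stacked
dinucleotide enthalpies/entropies), and related to model predictions:
globally (rank and linear correlation on log-predictions) and per 4-mer
alignment motif.  For each of the 256 possible 4-mers placed at offsets
-1 (H4-H7), 0 (H5-S1) and +1 (H6-S2), an ordinary least squares
regression of log10(prediction) on Tm is fit over the 16 sequences
matching the motif.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp
from scipy import stats

from .sequences import DNA, kmer_alignments

#: offset of position H6 inside the 4-mer, per alignment
_H6_INDEX_IN_KMER = {-1: 2, 0: 1, 1: 0}


def duplex_tm(sequence: str, expected_length: int | None = 6, **nn_kwargs) -> float:
    """Nearest-neighbor melting temperature (deg C) of a duplex window.

    Uses the unified nearest-neighbor DNA parameter set and the salt and
    strand-concentration defaults of Biopython's MeltingTemp module.
    """
    seq = sequence.upper()
    if expected_length is not None and len(seq) != expected_length:
        raise ValueError(f"expected a {expected_length}-base window, got {len(seq)}")
    for b in seq:
        if b not in DNA:
            raise ValueError(f"invalid base {b!r} in {sequence!r}")
    return float(MeltingTemp.Tm_NN(seq, **nn_kwargs))


def library_tms(sequences, **nn_kwargs) -> pd.Series:
    return pd.Series({s: duplex_tm(s, **nn_kwargs) for s in sequences}, name="tm")


def tm_prediction_correlation(
    predictions: pd.Series, tms: pd.Series
) -> dict:
    """Spearman rho of (Tm, prediction) and Pearson r of (Tm, log10 prediction).

    Variants with nonpositive predictions are excluded from the Pearson
    (log) correlation; the exclusion count is reported.
    """
    common = predictions.index.intersection(tms.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared variants")
    p = predictions.loc[common].to_numpy(dtype=float)
    t = tms.loc[common].to_numpy(dtype=float)
    rho = float(stats.spearmanr(t, p).statistic)
    pos = p > 0
    if pos.sum() < 3:
        raise ValueError("fewer than 3 positive predictions; log correlation undefined")
    r = float(stats.pearsonr(t[pos], np.log10(p[pos])).statistic)
    return {"spearman_rho": rho, "pearson_r_log": r,
            "n": int(len(common)), "n_excluded_nonpositive": int((~pos).sum())}


@dataclass
class RegressionSummary:
    kmer: str
    alignment: int
    n_used: int
    slope: float
    intercept: float
    r_squared: float
    centroid_tm: float
    centroid_log_pred: float
    has_G_at_H6_aligned: bool

    def to_dict(self) -> dict:
        return asdict(self)


def alignment_regression(
    kmer: str,
    alignment: int,
    predictions: pd.Series,
    tms: pd.Series | None = None,
) -> RegressionSummary:
    """OLS of log10(prediction) on Tm over the 16 variants matching one
    4-mer alignment motif."""
    motif = kmer_alignments(kmer)[alignment]
    sets = [s for s in predictions.index if _matches(s, motif)]
    preds = predictions.loc[sets]
    usable = preds[preds > 0]
    if len(usable) < 2:
        raise ValueError(
            f"all predictions nonpositive for motif {motif}; regression undefined"
        )
    if tms is None:
        t = np.array([duplex_tm(s) for s in usable.index])
    else:
        t = tms.loc[usable.index].to_numpy(dtype=float)
    if np.allclose(t, t[0]):
        raise ValueError(f"constant Tm within motif {motif}; slope undefined")
    y = np.log10(usable.to_numpy(dtype=float))
    if np.allclose(y, y[0]):
        slope, intercept, r_squared = 0.0, float(y[0]), 0.0
    else:
        res = stats.linregress(t, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r_squared = float(res.rvalue**2)
    return RegressionSummary(
        kmer=kmer.upper(), alignment=alignment, n_used=len(usable),
        slope=slope, intercept=intercept,
        r_squared=r_squared,
        centroid_tm=float(t.mean()), centroid_log_pred=float(y.mean()),
        has_G_at_H6_aligned=kmer.upper()[_H6_INDEX_IN_KMER[alignment]] == "G",
    )


def _matches(seq: str, motif: str) -> bool:
    from .sequences import IUPAC_CODES
    return len(seq) == len(motif) and all(
        b in IUPAC_CODES[c] for b, c in zip(seq, motif)
    )


def sweep_kmer_regressions(predictions: pd.Series, tms: pd.Series | None = None
                           ) -> pd.DataFrame:
    """Alignment regressions for all 256 4-mers x 3 alignments (768 rows)."""
    if len(predictions) != 4096:
        raise ValueError("predictions must cover the full 4096-variant library")
    if tms is None:
        tms = library_tms(predictions.index)
    rows = []
    for combo in product(DNA, repeat=4):
        kmer = "".join(combo)
        for alignment in (-1, 0, 1):
            rows.append(alignment_regression(kmer, alignment, predictions,
                                             tms).to_dict())
    return pd.DataFrame(rows)


def sweep_aggregates(sweep: pd.DataFrame) -> dict:
    """Per-alignment slope/R^2 aggregates of a regression sweep."""
    out = {"n_regressions": int(len(sweep)),
           "negative_slope_fraction": float((sweep["slope"] < 0).mean())}
    for alignment, sub in sweep.groupby("alignment"):
        key = {-1: "minus1", 0: "zero", 1: "plus1"}[alignment]
        out[f"mean_slope_{key}"] = float(sub["slope"].mean())
        out[f"mean_r_squared_{key}"] = float(sub["r_squared"].mean())
    return out
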