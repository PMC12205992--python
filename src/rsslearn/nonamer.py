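"""Nonamer-informed dataset assembly and cross-nonamer attribution analysis.

Three plasmid libraries (CF1, Pax3, LMO2) share a randomized N(H4-H7)K(S2)
window (H4-H7 fully randomized, S2 restricted to T or G, S1 constant) but
differ in their nonamer sequence.  The nonamer acts mostly as a global
multiplicative scale on recombination efficiency; to look past that scale,
per-nonamer attribution matrices are rescaled by each group's global mean
|attribution| (turning values into fold changes from the group mean), and
two-sample Kolmogorov-Smirnov statistics between the rescaled per-feature
distributions flag candidate long-distance heptamer-nonamer interactions.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .explain import AttributionMatrix
from .sequences import (
    H4S2_POSITIONS,
    NONAMER_POSITIONS,
    RSSOneHotEncoder,
    enumerate_library,
    feature_names,
)

CNON_POSITIONS: tuple[str, ...] = H4S2_POSITIONS + NONAMER_POSITIONS

#: the N(H4-H7)K(S2) library design: H4-H7 free, S1 constant, S2 in {T, G}
def cnon_library_alphabets(s1_base: str = "A") -> dict[str, str]:
    return {"S1": s1_base, "S2": "TG"}


def build_cnon_dataset(
    tables: Mapping[str, pd.DataFrame],
    nonamer_sequences: Mapping[str, str],
    s1_base: str = "A",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the combined nonamer-informed training table and encoding.

    ``tables`` maps nonamer group -> read-count table (optionally with a
    ``replicate`` column; replicates are averaged first).  Each group's
    table is zero-completed over the N(H4-H7)K(S2) library, then the
    combined table is dataset-wide min-max normalized.
    ``nonamer_sequences`` maps group -> 5 bases at N1,N2,N3,N8,N9.

    Returns (table, encoding): the table has columns sequence, nonamer,
    count, target; the encoding is the 24-bit H4-S2 block (the constant S1
    block included, carrying no information) plus the 20-bit nonamer
    block, 44 features total, indexed like the table.
    """
    library = enumerate_library(H4S2_POSITIONS, cnon_library_alphabets(s1_base))
    parts = []
    for group, table in tables.items():
        if group not in nonamer_sequences:
            raise ValueError(f"missing nonamer sequence for group {group!r}")
        if "replicate" in table.columns:
            reps = [sub.drop(columns="replicate")
                    for _, sub in table.groupby("replicate")]
            reps = [ds.complete_with_zeros(r, library) for r in reps]
            table = ds.average_replicates(reps)
        else:
            table = ds.complete_with_zeros(table, library)
        table = table.copy()
        table["nonamer"] = group
        parts.append(table[["sequence", "count", "nonamer"]])
    combined = pd.concat(parts, ignore_index=True)
    combined = ds.minmax_normalize(combined, mode="dataset-wide")

    h4s2_enc = RSSOneHotEncoder(H4S2_POSITIONS).fit().transform(
        combined["sequence"].tolist()
    )
    non_enc = RSSOneHotEncoder(NONAMER_POSITIONS).fit().transform(
        [nonamer_sequences[g] for g in combined["nonamer"]]
    )
    encoding = pd.DataFrame(
        np.hstack([h4s2_enc.to_numpy(), non_enc.to_numpy()]),
        columns=feature_names(CNON_POSITIONS),
        index=pd.MultiIndex.from_frame(combined[["sequence", "nonamer"]]),
    )
    combined.index = encoding.index
    return combined, encoding


def per_group_attributions(
    model,
    encoding: pd.DataFrame,
    groups: pd.Series,
    background_size: int = 64,
    n_permutations: int = 2,
    seed: int = 0,
) -> AttributionMatrix:
    """Attributions computed per nonamer group with a paired design.

    Each group's samples are explained against a background drawn from the
    group's own rows, but the background draws use the *same* H4-S2
    variant positions in every group (with that group's nonamer bits) and
    the same permutation sequence.  Groups that differ only by a
    multiplicative scale then receive exactly proportional attributions,
    so the downstream KS comparison of rescaled distributions reflects
    genuine shape differences, not background sampling noise.

    Requires every group to cover the same H4-S2 library in the same
    order (as produced by :func:`build_cnon_dataset`).
    """
    from .explain import PermutationExplainer

    groups = groups.loc[encoding.index]
    rng = np.random.default_rng(seed)
    sizes = groups.value_counts()
    if sizes.nunique() != 1:
        raise ValueError("groups must cover identical libraries (equal sizes)")
    n_per_group = int(sizes.iloc[0])
    bg_positions = rng.choice(n_per_group, size=min(background_size, n_per_group),
                              replace=False)
    parts = []
    base = None
    for group in pd.unique(groups):
        sub = encoding.loc[(groups == group).to_numpy()]
        background = sub.iloc[bg_positions]
        attr = PermutationExplainer(
            model, background, n_permutations=n_permutations, random_state=seed
        ).attributions(sub)
        parts.append(attr.values)
        base = attr.base_prediction if base is None else base
    values = pd.concat(parts)
    return AttributionMatrix(values=values.loc[encoding.index],
                             base_prediction=float(base))


def rescale_by_global_mean(
    matrix: AttributionMatrix,
    groups: pd.Series,
    features: Sequence[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, float]]:
    """Divide each group's attributions by the group's global mean
    |attribution| over the selected features (default: H4-S2 features).

    After rescaling each group's global mean |value| is exactly 1; values
    read as fold changes from that group's mean.  Returns (per-group
    rescaled frames, per-group divisors).
    """
    if features is None:
        features = [c for c in matrix.values.columns
                    if c.rsplit("_", 1)[0] in H4S2_POSITIONS]
    groups = groups.loc[matrix.values.index]
    rescaled, divisors = {}, {}
    for group in pd.unique(groups):
        sub = matrix.values.loc[groups == group, list(features)]
        divisor = float(sub.abs().to_numpy().mean())
        if divisor == 0:
            raise ValueError(f"group {group!r} has zero global mean |attribution|")
        rescaled[group] = sub / divisor
        divisors[group] = divisor
    return rescaled, divisors


def nonamer_ks_matrix(rescaled: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Two-sample KS statistics per feature for every unordered group pair."""
    groups = list(rescaled)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, df in rescaled.items():
        if len(df) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    features = list(next(iter(rescaled.values())).columns)
    rows = []
    for ga, gb in combinations(groups, 2):
        for feat in features:
            stat, p = ds.ks_two_sample(rescaled[ga][feat], rescaled[gb][feat])
            rows.append({"feature": feat, "pair": f"{ga}-vs-{gb}",
                         "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def flag_long_distance_candidates(
    ks_matrix: pd.DataFrame, threshold: float = 0.20
) -> pd.DataFrame:
    """Features whose KS statistic reaches the threshold for any group
    pair, annotated with every pair that exceeds it."""
    hits = ks_matrix[ks_matrix["statistic"] >= threshold]
    rows = []
    for feat, sub in hits.groupby("feature"):
        rows.append({
            "feature": feat,
            "pairs": ";".join(sorted(sub["pair"])),
            "max_statistic": float(sub["statistic"].max()),
        })
    return pd.DataFrame(rows, columns=["feature", "pairs", "max_statistic"])
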