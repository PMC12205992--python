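"""Sequence data model for the randomized window of a 12-RSS.

The recombination signal sequence (RSS) positions handled here are the 3'
heptamer positions H4-H7, the first two spacer positions S1-S2, and the
variable nonamer positions N1-N3, N8, N9.  A library is the Cartesian
product of per-position alphabets; variants are one-hot encoded into
binary nucleotide:position features named ``<position>_<base>``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DNA = "ACGT"

#: order of bases inside each one-hot block (matches the H4_A/H4_T/H4_G/H4_C
#: feature naming order used throughout the analyses)
BASE_ORDER = "ATGC"

H4S2_POSITIONS: tuple[str, ...] = ("H4", "H5", "H6", "H7", "S1", "S2")
NONAMER_POSITIONS: tuple[str, ...] = ("N1", "N2", "N3", "N8", "N9")

#: full 15-code IUPAC ambiguity table (the reduced-category analyses need
#: more than the N and K codes used in the library designs)
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: reverse lookup: base set -> IUPAC code
IUPAC_FROM_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}


@dataclass(frozen=True)
class RSSVariant:
    """One variant sequence over named RSS positions.

    ``positions`` and ``bases`` are parallel; every base must be one of
    A, C, G, T.  ``nonamer_group`` optionally labels which nonamer library
    (e.g. CF1, Pax3, LMO2) the variant belongs to.
    """

    positions: tuple[str, ...]
    bases: str
    nonamer_group: str | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.bases):
            raise ValueError(
                f"{len(self.positions)} positions but {len(self.bases)} bases"
            )
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("position labels must be unique")
        for pos, base in zip(self.positions, self.bases):
            if base not in DNA:
                raise ValueError(f"invalid base {base!r} at position {pos}")

    @property
    def sequence(self) -> str:
        return self.bases

    def base_at(self, position: str) -> str:
        try:
            return self.bases[self.positions.index(position)]
        except ValueError:
            raise KeyError(f"variant has no position {position}") from None


def feature_names(positions: Sequence[str]) -> list[str]:
    """Binary feature names in position-major, A/T/G/C order."""
    return [f"{pos}_{b}" for pos in positions for b in BASE_ORDER]


def enumerate_library(
    positions: Sequence[str],
    per_position_alphabets: Mapping[str, Iterable[str]] | None = None,
) -> list[RSSVariant]:
    """Enumerate the full Cartesian product of per-position alphabets.

    Ordering is deterministic: lexicographic by position order with bases
    ordered A < C < G < T.
    """
    if not positions:
        raise ValueError("position list is empty")
    positions = tuple(positions)
    alphabets: list[str] = []
    for pos in positions:
        if per_position_alphabets is None or pos not in per_position_alphabets:
            alpha = DNA
        else:
            alpha = "".join(per_position_alphabets[pos])
        if not alpha:
            raise ValueError(f"empty alphabet for position {pos}")
        for b in alpha:
            if b not in DNA:
                raise ValueError(f"invalid base {b!r} in alphabet of position {pos}")
        alphabets.append("".join(sorted(set(alpha))))
    return [
        RSSVariant(positions, "".join(combo))
        for combo in itertools.product(*alphabets)
    ]


def match_motif(library: Sequence[RSSVariant], motif: str) -> list[RSSVariant]:
    """Return library variants matching an IUPAC motif, order preserved."""
    if not library:
        return []
    n_pos = len(library[0].positions)
    if len(motif) != n_pos:
        raise ValueError(f"motif length {len(motif)} != position count {n_pos}")
    sets = []
    for code in motif.upper():
        if code not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {code!r}")
        sets.append(IUPAC_CODES[code])
    return [
        v for v in library
        if all(b in s for b, s in zip(v.bases, sets))
    ]


def kmer_alignments(kmer: str) -> dict[int, str]:
    """Place a 4-mer at the three possible offsets in the 6-position window.

    Returns motifs keyed by alignment: -1 -> (kmer)NN at H4-H7,
    0 -> N(kmer)N at H5-S1, +1 -> NN(kmer) at H6-S2.
    """
    kmer = kmer.upper()
    if len(kmer) != 4:
        raise ValueError(f"kmer must have length 4, got {len(kmer)}")
    for b in kmer:
        if b not in DNA:
            raise ValueError(f"invalid base {b!r} in kmer")
    return {-1: kmer + "NN", 0: "N" + kmer + "N", 1: "NN" + kmer}


class RSSOneHotEncoder(BaseEstimator, TransformerMixin):
    """One-hot encoder mapping variants to binary nucleotide:position features.

    Each position expands to a 4-column block (order A, T, G, C) with exactly
    one bit set per row.  ``transform`` accepts a list of :class:`RSSVariant`
    or of plain sequence strings and returns a DataFrame whose columns are
    the feature names and whose index is the sequence strings.
    """

    def __init__(self, positions: Sequence[str] = H4S2_POSITIONS):
        self.positions = tuple(positions)

    def fit(self, X=None, y=None) -> "RSSOneHotEncoder":
        self.feature_names_out_ = feature_names(self.positions)
        return self

    def _sequences(self, X) -> list[str]:
        seqs = []
        for item in X:
            if isinstance(item, RSSVariant):
                if item.positions != self.positions:
                    missing = set(self.positions) - set(item.positions)
                    if missing:
                        raise ValueError(
                            f"variant missing positions {sorted(missing)}"
                        )
                    seqs.append("".join(item.base_at(p) for p in self.positions))
                else:
                    seqs.append(item.bases)
            else:
                seq = str(item).upper()
                if len(seq) != len(self.positions):
                    raise ValueError(
                        f"sequence {seq!r} has length {len(seq)}, expected "
                        f"{len(self.positions)}"
                    )
                for pos, b in zip(self.positions, seq):
                    if b not in DNA:
                        raise ValueError(f"invalid base {b!r} at position {pos}")
                seqs.append(seq)
        return seqs

    def transform(self, X) -> pd.DataFrame:
        self.fit()
        seqs = self._sequences(X)
        n = len(seqs)
        arr = np.zeros((n, 4 * len(self.positions)), dtype=np.int8)
        base_idx = {b: i for i, b in enumerate(BASE_ORDER)}
        for row, seq in enumerate(seqs):
            for j, b in enumerate(seq):
                arr[row, 4 * j + base_idx[b]] = 1
        return pd.DataFrame(arr, index=pd.Index(seqs, name="sequence"),
                            columns=self.feature_names_out_)

    def inverse_transform(self, encoded: pd.DataFrame) -> list[str]:
        arr = np.asarray(encoded, dtype=float)
        if arr.shape[1] != 4 * len(self.positions):
            raise ValueError("column count does not match position count")
        seqs = []
        for row in arr:
            bases = []
            for j in range(len(self.positions)):
                block = row[4 * j: 4 * j + 4]
                if block.sum() != 1:
                    raise ValueError("row is not a valid one-hot block pattern")
                bases.append(BASE_ORDER[int(np.argmax(block))])
            seqs.append("".join(bases))
        return seqs

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.positions), dtype=object)


def one_hot_encode(
    variants: Sequence[RSSVariant | str],
    positions: Sequence[str] = H4S2_POSITIONS,
) -> pd.DataFrame:
    return RSSOneHotEncoder(positions).fit().transform(variants)


def decode_one_hot(
    encoded: pd.DataFrame, positions: Sequence[str] = H4S2_POSITIONS
) -> list[str]:
    return RSSOneHotEncoder(positions).fit().inverse_transform(encoded)


# -- serialization ---------------------------------------------------------

def variants_to_tsv(variants: Sequence[RSSVariant], path) -> None:
    df = pd.DataFrame(
        {"id": [f"v{i}" for i in range(len(variants))],
         "sequence": [v.sequence for v in variants]}
    )
    df.to_csv(path, sep="\t", index=False)


def variants_from_tsv(path, positions: Sequence[str] = H4S2_POSITIONS) -> list[RSSVariant]:
    df = pd.read_csv(path, sep="\t")
    return [RSSVariant(tuple(positions), s.upper()) for s in df["sequence"]]


def variants_to_fasta(variants: Sequence[RSSVariant], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(v.sequence), id=f"v{i}", description="")
        for i, v in enumerate(variants)
    ]
    SeqIO.write(records, path, "fasta")


def variants_from_fasta(path, positions: Sequence[str] = H4S2_POSITIONS) -> list[RSSVariant]:
    from Bio import SeqIO

    return [
        RSSVariant(tuple(positions), str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
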