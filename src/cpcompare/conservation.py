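"""Pairwise sequence-identity matrices and column conservation over MSAs.

The identity score between two aligned rows follows the convention used for
family-wide identity matrices: alignment positions gapped in *both* sequences
are removed first, identities are counted over the remaining columns, and the
denominator is the ungapped length of the *longer* of the two sequences.  This
penalises insertions present in only one family member instead of quietly
ignoring them.

Column conservation is the classic sequence-logo quantity: information content
IC = log2(20) - H(column), with per-column letter frequencies scaled by the
column's non-gap fraction so heavily gapped columns carry less stack height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: letters that may appear but never count as identities or logo mass
AMBIGUOUS = set("BZXJUO")
GAP = "-"
MAX_IC = math.log2(20.0)


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise MSAError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise MSAError("sequence ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            ragged = [self.ids[i] for i, r in enumerate(self.rows)
                      if len(r) != len(self.rows[0])]
            raise MSAError(f"ragged alignment; offending ids: {ragged}")
        self.rows = [r.upper().replace(".", GAP) for r in self.rows]

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise MSAError(f"no sequences in {path}")
        return cls(ids=[r.id for r in records], rows=[str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Identity fraction with gap-gap columns removed and the longer ungapped
    length as denominator.  Case-insensitive; ambiguity codes never count as
    identities."""
    if len(row_a) != len(row_b):
        raise MSAError(f"aligned rows differ in length: {len(row_a)} vs {len(row_b)}")
    a, b = row_a.upper(), row_b.upper()
    ident = 0
    len_a = 0
    len_b = 0
    for ca, cb in zip(a, b):
        ga, gb = ca == GAP, cb == GAP
        if ga and gb:
            continue  # gap-gap columns are removed before scoring
        if not ga:
            len_a += 1
        if not gb:
            len_b += 1
        if not ga and not gb and ca == cb and ca not in AMBIGUOUS:
            ident += 1
    denom = max(len_a, len_b)
    if denom == 0:
        raise MSAError("both rows are all-gap")
    return ident / denom


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal exactly 1, fractions in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MSAError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise MSAError("identity matrix is not symmetric")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def identity_matrix(msa: MSA) -> IdentityMatrix:
    """All-pairs identity over the MSA (vectorised over columns)."""
    if msa.n_seqs < 2:
        raise MSAError("need at least 2 sequences")
    enc = np.frombuffer("".join(msa.rows).encode("ascii"), dtype=np.uint8)
    enc = enc.reshape(msa.n_seqs, msa.length)
    is_gap = enc == ord(GAP)
    is_amb = np.isin(enc, np.frombuffer("".join(sorted(AMBIGUOUS)).encode(), dtype=np.uint8))
    ungapped = (~is_gap).sum(axis=1)

    n = msa.n_seqs
    values = np.eye(n)
    for i in range(n):
        # identities: equal, both non-gap, not an ambiguity code
        eq = (enc[i] == enc[i + 1:]) & ~is_gap[i] & ~is_gap[i + 1:] & ~is_amb[i]
        ident = eq.sum(axis=1)
        denom = np.maximum(ungapped[i], ungapped[i + 1:])
        vals = ident / denom
        values[i, i + 1:] = vals
        values[i + 1:, i] = vals
    return IdentityMatrix(ids=list(msa.ids), values=values)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


@dataclass
class DistributionSummary:
    histogram: dict[int, float]  # integer identity percent -> percentage of pairs
    five_number: tuple[float, float, float, float, float]  # min, Q1, median, Q3, max
    n_pairs: int

    @property
    def median(self) -> float:
        return self.five_number[2]


def distribution_summary(m: IdentityMatrix) -> DistributionSummary:
    """Histogram over rounded integer percents plus a five-number summary of
    the unrounded off-diagonal identities (upper triangle, each pair once)."""
    vals = m.off_diagonal()
    if vals.size == 0:
        raise MSAError("matrix has no off-diagonal pairs")
    bins = _round_half_up(vals * 100.0)
    counts: dict[int, int] = {}
    for b in bins:
        counts[int(b)] = counts.get(int(b), 0) + 1
    hist = {b: 100.0 * c / vals.size for b, c in sorted(counts.items())}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    five = (float(vals.min()), float(q1), float(med), float(q3), float(vals.max()))
    return DistributionSummary(histogram=hist, five_number=five, n_pairs=int(vals.size))


def filter_columns(msa: MSA, max_gap_fraction: float = 0.5) -> tuple[MSA, list[int]]:
    """Keep columns whose gap fraction is <= threshold; returns the filtered
    MSA plus the kept-column indices into the original alignment, so logo
    positions remain traceable to the full alignment numbering."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise MSAError("max_gap_fraction must be in [0, 1]")
    n = msa.n_seqs
    kept = [
        j for j in range(msa.length)
        if sum(1 for row in msa.rows if row[j] == GAP) / n <= max_gap_fraction
    ]
    rows = ["".join(row[j] for j in kept) for row in msa.rows]
    return MSA(ids=list(msa.ids), rows=rows), kept


@dataclass
class LogoColumn:
    index: int  # position in the (possibly filtered) alignment, 0-based
    frequencies: dict[str, float]  # letter -> frequency; sums to the non-gap fraction
    information: float  # bits, in [0, log2 20]


def column_conservation(msa: MSA) -> list[LogoColumn]:
    """Per-column letter frequencies and information content (bits).

    Frequencies are computed over the 20 standard letters among non-gap rows
    and then scaled by the column's non-gap fraction (gap mass excluded from
    the stack); the entropy is taken over the renormalised (non-gap)
    distribution, with no small-sample correction.  All-gap columns report
    zero information and empty frequencies.
    """
    if msa.n_seqs == 0:
        raise MSAError("empty MSA")
    columns: list[LogoColumn] = []
    n = msa.n_seqs
    for j in range(msa.length):
        col = [row[j] for row in msa.rows]
        letters = [c for c in col if c in STANDARD_AA]
        if not letters:
            columns.append(LogoColumn(index=j, frequencies={}, information=0.0))
            continue
        counts: dict[str, int] = {}
        for c in letters:
            counts[c] = counts.get(c, 0) + 1
        total = len(letters)
        probs = {c: k / total for c, k in counts.items()}
        entropy = -sum(p * math.log2(p) for p in probs.values())
        ic = max(0.0, MAX_IC - entropy)
        nongap_fraction = total / n
        freqs = {c: p * nongap_fraction for c, p in sorted(probs.items())}
        columns.append(LogoColumn(index=j, frequencies=freqs, information=ic))
    return columns
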