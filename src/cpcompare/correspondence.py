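"""Equivalent-residue maps between homologous chains.

Before any "equivalent C-alpha atoms" superposition the two chains must be put
in register.  Here the register comes from a global pairwise sequence alignment
of the sequences extracted from the modeled residues (the structures themselves
are never consulted), so missing segments on either side simply drop out of the
map and the mapped numbering stays collinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

from .structure import Chain, StructureError

AMINO_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


class CorrespondenceError(ValueError):
    pass


def _one_letter(resname: str) -> str:
    """Three-letter to one-letter code; modified residues map to their parent
    (MSE -> M), anything unknown to 'X'."""
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def extract_sequence(chain: Chain) -> tuple[str, list[int]]:
    """One-letter sequence over the CA-bearing residues, with a parallel list
    of author residue numbers.  Waters and CA-free het groups contribute
    nothing."""
    letters: list[str] = []
    numbers: list[int] = []
    for res in sorted(chain.residues, key=lambda r: (r.number, r.icode)):
        if res.is_water or res.atom("CA") is None:
            continue
        letters.append(_one_letter(res.name))
        numbers.append(res.number)
    return "".join(letters), numbers


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring.  matrix is "blosum62" (default; affine gaps in matrix
    units) or "identity" (match 1 / mismatch 0 / linear gap -1, for toy
    examples)."""

    matrix: str = "blosum62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: leave terminal gaps unpenalised (semi-global).  The right choice when
    #: aligning sequences extracted from modeled residues, which are fragments
    #: of the full proteins with unrelated overhangs.
    end_gaps_free: bool = False


@dataclass
class AlignedPair:
    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise CorrespondenceError("aligned sequences must have equal length")
        for ca, cb in zip(self.seq_a, self.seq_b):
            if ca == "-" and cb == "-":
                raise CorrespondenceError("pairwise alignment may not contain gap-gap columns")

    @property
    def identity(self) -> float:
        """Fraction of identical columns over the longer ungapped length."""
        ident = sum(1 for a, b in zip(self.seq_a, self.seq_b) if a == b and a != "-")
        la = sum(1 for a in self.seq_a if a != "-")
        lb = sum(1 for b in self.seq_b if b != "-")
        return ident / max(la, lb)


def _validate_sequence(seq: str, label: str) -> None:
    if not seq:
        raise CorrespondenceError(f"sequence {label} is empty")
    bad = set(seq.upper()) - AMINO_LETTERS - {"X"}
    if bad:
        raise CorrespondenceError(f"sequence {label} contains invalid characters {sorted(bad)}")


def align_global(a: str, b: str, params: ScoringConfig | None = None) -> AlignedPair:
    """Optimal global (end-to-end) pairwise alignment.

    Uses BLOSUM62 with affine gap penalties by default; ties are broken
    deterministically by taking the first optimal traceback (match/mismatch
    preferred over gaps).
    """
    params = params or ScoringConfig()
    a, b = a.upper(), b.upper()
    _validate_sequence(a, "a")
    _validate_sequence(b, "b")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix == "blosum62":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -abs(params.gap_open)
        aligner.extend_gap_score = -abs(params.gap_extend)
    elif params.matrix == "identity":
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -1.0
    else:
        raise CorrespondenceError(f"unknown scoring matrix {params.matrix!r}")
    if params.end_gaps_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # biopython < 1.86 attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0

    alignment = aligner.align(a, b)[0]
    return AlignedPair(seq_a=str(alignment[0]), seq_b=str(alignment[1]),
                       score=float(alignment.score))


@dataclass
class ResidueMap:
    """Ordered equivalences ((chain_a, number_a), (chain_b, number_b));
    strictly increasing in both coordinates."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums_a = [p[0][1] for p in self.pairs]
        nums_b = [p[1][1] for p in self.pairs]
        if sorted(nums_a) != nums_a or len(set(nums_a)) != len(nums_a):
            raise CorrespondenceError("residue map not strictly increasing on side a")
        if sorted(nums_b) != nums_b or len(set(nums_b)) != len(nums_b):
            raise CorrespondenceError("residue map not strictly increasing on side b")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "ResidueMap":
        return ResidueMap(pairs=[(b, a) for a, b in self.pairs])

    def numbers_a(self) -> list[int]:
        return [p[0][1] for p in self.pairs]

    def numbers_b(self) -> list[int]:
        return [p[1][1] for p in self.pairs]


def build_residue_map(chain_a: Chain, chain_b: Chain, aln: AlignedPair) -> ResidueMap:
    """One equivalence per alignment column where both sides are non-gap and
    both residues carry a CA atom.  Mismatched columns still map (superposition
    compares positions, not identities)."""
    seq_a, numbers_a = extract_sequence(chain_a)
    seq_b, numbers_b = extract_sequence(chain_b)
    if aln.seq_a.replace("-", "") != seq_a or aln.seq_b.replace("-", "") != seq_b:
        raise CorrespondenceError(
            "alignment is not consistent with the sequences extracted from these chains")
    pairs = []
    ia = ib = 0
    for ca, cb in zip(aln.seq_a, aln.seq_b):
        if ca != "-" and cb != "-":
            pairs.append(((chain_a.id, numbers_a[ia]), (chain_b.id, numbers_b[ib])))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return ResidueMap(pairs=pairs)


def map_chains(chain_a: Chain, chain_b: Chain,
               params: ScoringConfig | None = None) -> ResidueMap:
    """Convenience: extract, align and map two chains in one call.

    Defaults to semi-global scoring (end gaps free), since modeled-residue
    sequences are fragments whose overhangs have no homologous partner.
    """
    params = params or ScoringConfig(end_gaps_free=True)
    seq_a, _ = extract_sequence(chain_a)
    seq_b, _ = extract_sequence(chain_b)
    aln = align_global(seq_a, seq_b, params)
    return build_residue_map(chain_a, chain_b, aln)
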