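"""B-factor flexibility profiling and disordered-segment detection.

Crystallographic B-factors (isotropic temperature factors, A^2) measure the
positional spread of each atom; regions whose mean B stands far above the
chain's distribution are flexible in the crystal.  Residues entirely absent
from the deposited model ("no interpretable electron density") are the extreme
case; they are recovered here by comparing the modeled author numbers against
the expected sequence range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correspondence import ResidueMap
from .structure import Chain, Selection, Structure, StructureError, select_atoms
from .superposition import superpose_mapped


class FlexibilityError(ValueError):
    pass


@dataclass
class RegionStats:
    label: str
    n_residues: int
    n_atoms: int
    mean_b: float  # A^2
    sd_b: float  # sample sd, A^2
    mean_b_normalized: float  # z-score of the region mean vs the reference atom distribution
    all_equal_reference: bool = False  # z forced to 0: reference B spread was zero


def region_b_stats(
    s: Structure,
    sel: Selection,
    whole_chain_ref: Selection | None = None,
    label: str = "region",
) -> RegionStats:
    """Mean/sd of B over the selected atoms (CA-only under the default
    selection), plus the region mean's z-score against the reference
    distribution (default: the whole chain with the same atom names).

    Waters never enter the reference distribution.
    """
    picked = select_atoms(s, sel)
    picked.pairs = [(r, a) for r, a in picked.pairs if not r.is_water]
    if len(picked) == 0:
        raise FlexibilityError(f"selection on chain {sel.chain_id} matched no atoms")
    bs = picked.b_factors()
    mean_b = float(np.mean(bs))
    sd_b = float(np.std(bs, ddof=1)) if len(bs) > 1 else 0.0

    ref_sel = whole_chain_ref or Selection(chain_id=sel.chain_id, atom_names=sel.atom_names)
    ref = select_atoms(s, ref_sel)
    ref_b = np.array([a.b_factor for r, a in ref.pairs if not r.is_water])
    ref_mean = float(np.mean(ref_b))
    ref_sd = float(np.std(ref_b, ddof=1)) if len(ref_b) > 1 else 0.0
    if ref_sd == 0.0:
        z, flat = 0.0, True
    else:
        z, flat = (mean_b - ref_mean) / ref_sd, False

    n_residues = len({(r.number, r.icode) for r, _ in picked.pairs})
    return RegionStats(label=label, n_residues=n_residues, n_atoms=len(bs),
                       mean_b=mean_b, sd_b=sd_b, mean_b_normalized=z,
                       all_equal_reference=flat)


@dataclass
class RegionComparison:
    """Paired flexibility report for one region of two homologous structures."""

    mean_b_a: float
    mean_b_b: float
    delta_mean_b: float  # b minus a
    rmsd: float  # region r.m.s.d. in the global-fit frame, Angstrom
    n_atoms: int


def compare_regions(
    s_a: Structure,
    s_b: Structure,
    rmap: ResidueMap,
    region_a: Selection,
    region_b: Selection,
    fit_sel: tuple[Selection, Selection] | None = None,
) -> RegionComparison:
    """Mean-B on each side plus the region r.m.s.d. after a global fit.

    The fit defaults to the whole mapped chains; the region deviation is then
    measured in that frame, so a rigid sub-region shift shows up at full size.
    """
    if fit_sel is None:
        fit_sel = (Selection(chain_id=region_a.chain_id, atom_names=region_a.atom_names),
                   Selection(chain_id=region_b.chain_id, atom_names=region_b.atom_names))
    ms = superpose_mapped(s_a, s_b, rmap, fit_sel, {"region": (region_a, region_b)})
    reg = ms.regions["region"]
    stats_a = region_b_stats(s_a, region_a, label="a")
    stats_b = region_b_stats(s_b, region_b, label="b")
    return RegionComparison(
        mean_b_a=stats_a.mean_b,
        mean_b_b=stats_b.mean_b,
        delta_mean_b=stats_b.mean_b - stats_a.mean_b,
        rmsd=reg.rmsd,
        n_atoms=reg.n_atoms,
    )


@dataclass
class DisorderReport:
    chain_id: str
    expected_range: tuple[int, int]
    missing_segments: list[tuple[int, int]] = field(default_factory=list)
    n_modeled: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        span = self.expected_range[1] - self.expected_range[0] + 1
        if self.n_modeled + self.n_missing != span:
            raise FlexibilityError("modeled + missing does not cover the expected span")


def detect_disorder(chain: Chain, expected_range: tuple[int, int]) -> DisorderReport:
    """Maximal runs of expected author numbers absent from the chain.

    Only CA-bearing residues count as modeled — a residue reduced to a stray
    side-chain fragment without a CA is treated as missing, matching how
    deposited models describe unassigned density.
    """
    first, last = int(expected_range[0]), int(expected_range[1])
    if first > last:
        raise FlexibilityError(f"invalid expected range [{first}, {last}]")
    present = {r.number for r in chain.residues if not r.is_water and r.atom("CA") is not None}
    segments: list[tuple[int, int]] = []
    run_start: int | None = None
    for num in range(first, last + 1):
        if num not in present:
            if run_start is None:
                run_start = num
        elif run_start is not None:
            segments.append((run_start, num - 1))
            run_start = None
    if run_start is not None:
        segments.append((run_start, last))
    n_missing = sum(e - s + 1 for s, e in segments)
    span = last - first + 1
    return DisorderReport(chain_id=chain.id, expected_range=(first, last),
                          missing_segments=segments, n_modeled=span - n_missing,
                          n_missing=n_missing)


def model_mean_b(s: Structure, chains: list[str] | None = None) -> tuple[float, int]:
    """Model-wide mean B over all protein atoms of the named chains (default:
    all chains), waters excluded, altlocs already resolved at read time,
    occupancy-unweighted.  Returns (mean_b, n_atoms)."""
    chain_ids = chains or [c.id for c in s.chains]
    bs: list[float] = []
    for cid in chain_ids:
        for res in s.chain(cid).residues:
            if res.is_water:
                continue
            bs.extend(a.b_factor for a in res.atoms)
    if not bs:
        raise FlexibilityError("no protein atoms found")
    return float(np.mean(bs)), len(bs)
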