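"""Unit-cell volume, Matthews coefficient and solvent-content calculations.

The Matthews coefficient V_M is the crystal volume per Dalton of protein
(A^3/Da); fractional solvent content follows from V_M and the protein's
partial specific volume v-bar (0.74 cm^3/g for an average protein):

    solvent = 1 - (1.660 * v_bar) / V_M

where 1.660 = 10^24 / N_A folds the Dalton-to-gram and A^3-to-cm^3
conversions into a single factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import gemmi

from .structure import StructureError, UnitCell

#: 10^24 / Avogadro's number: converts (cm^3/g) * (Da) into A^3.
INV_AVOGADRO_FACTOR = 1.0e24 / 6.02214076e23  # = 1.66054...


@dataclass(frozen=True)
class CrystalContents:
    """What sits in the asymmetric unit and how many AUs tile the cell."""

    n_molecules_per_au: int
    mass_per_molecule: float  # Da
    au_per_cell: int  # space-group multiplicity

    def __post_init__(self) -> None:
        if self.n_molecules_per_au <= 0 or self.mass_per_molecule <= 0 or self.au_per_cell <= 0:
            raise StructureError("crystal contents must all be strictly positive")


def cell_volume(cell: UnitCell) -> float:
    """Triclinic unit-cell volume in A^3 (closed form; exact for all settings)."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise StructureError(f"invalid cell: metric discriminant {disc:.3g} <= 0")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def spacegroup_multiplicity(name: str) -> int:
    """Asymmetric units per cell for a space group given by its symbol.

    Accepts Hermann-Mauguin symbols with or without spaces ("P41", "P 41",
    "P 21 21 21").  Backed by gemmi's space-group tables.
    """
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        raise StructureError(f"unknown space group {name!r}")
    return len(sg.operations())


def matthews(cell: UnitCell, contents: CrystalContents) -> float:
    """Matthews coefficient V_M in A^3/Da."""
    mass_in_cell = contents.au_per_cell * contents.n_molecules_per_au * contents.mass_per_molecule
    return cell_volume(cell) / mass_in_cell


def solvent_content(v_m: float, partial_specific_volume: float = 0.74) -> float:
    """Fractional solvent content from V_M (Matthews' relation).

    Non-physical inputs (V_M at or below the protein-only limit) are clamped
    to 0 with a warning rather than raised, mirroring how crystallography
    suites report them.
    """
    if v_m <= 0:
        raise StructureError("V_M must be positive")
    protein_fraction = INV_AVOGADRO_FACTOR * partial_specific_volume / v_m
    frac = 1.0 - protein_fraction
    if frac < 0:
        warnings.warn(f"V_M {v_m:.3g} below the protein-only limit; solvent content clamped to 0")
        return 0.0
    return frac
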