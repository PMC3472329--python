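"""Hierarchical crystal-structure model, residue-range selections and PDB/mmCIF I/O.

The model intentionally exposes only author residue numbering (the numbering
printed in structure papers, e.g. "residues 2-272"); ranges are 1-based and
inclusive at both ends.  File parsing and writing are delegated to gemmi; the
in-memory types here are plain dataclasses so the analysis modules stay free of
parser details.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for unreadable files, unknown formats or invalid selections."""


@dataclass
class Atom:
    """A single atom site.

    position is Cartesian, in Angstrom; b_factor is the isotropic temperature
    factor in A^2; altloc is the alternate-location indicator ('' if none).
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise StructureError(f"negative B-factor {self.b_factor}")


@dataclass
class Residue:
    number: int
    icode: str = ""
    name: str = "ALA"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            key = (r.number, r.icode)
            if key in seen:
                raise StructureError(f"duplicate residue {key} in chain {self.id}")
            seen.add(key)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]


@dataclass
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise StructureError(f"cell angle {ang} outside (0, 180)")


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    cell: UnitCell | None = None
    spacegroup_name: str | None = None
    spacegroup_multiplicity: int | None = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in structure {self.id}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(f"no chain {chain_id!r} in structure {self.id} "
                             f"(have {[c.id for c in self.chains]})")


@dataclass(frozen=True)
class Selection:
    """A residue-range / atom-name selection on one chain.

    include_ranges/exclude_ranges are inclusive [start, end] pairs in author
    numbering; an empty include list means the whole chain.  A residue is
    selected iff it falls in some include range (or include is empty) and in no
    exclude range.  An empty atom_names set selects all atoms (all-atom mode).
    """

    chain_id: str
    include_ranges: tuple[tuple[int, int], ...] = ()
    exclude_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] = frozenset({"CA"})

    def __post_init__(self) -> None:
        for start, end in tuple(self.include_ranges) + tuple(self.exclude_ranges):
            if start > end:
                raise StructureError(f"range [{start}, {end}] has start > end")
        # normalise possibly-list inputs to tuples (frozen dataclass workaround)
        object.__setattr__(self, "include_ranges",
                           tuple((int(s), int(e)) for s, e in self.include_ranges))
        object.__setattr__(self, "exclude_ranges",
                           tuple((int(s), int(e)) for s, e in self.exclude_ranges))
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def covers(self, number: int) -> bool:
        if self.include_ranges:
            if not any(s <= number <= e for s, e in self.include_ranges):
                return False
        return not any(s <= number <= e for s, e in self.exclude_ranges)

    def restricted_to(self, subrange: tuple[int, int]) -> "Selection":
        """Selection further limited to one inclusive range (used by region reports)."""
        lo, hi = int(subrange[0]), int(subrange[1])
        if not self.include_ranges:
            inc: tuple[tuple[int, int], ...] = ((lo, hi),)
        else:
            inc = tuple(
                (max(s, lo), min(e, hi))
                for s, e in self.include_ranges
                if max(s, lo) <= min(e, hi)
            )
            if not inc:
                # empty intersection: excluding the whole subrange selects nothing
                return replace(self, include_ranges=((lo, hi),),
                               exclude_ranges=self.exclude_ranges + ((lo, hi),))
        return replace(self, include_ranges=inc)


@dataclass
class AtomSelection:
    """Result of select_atoms: ordered (residue, atom) pairs plus bookkeeping."""

    pairs: list[tuple[Residue, Atom]]
    n_residues_selected: int
    n_residues_skipped: int  # selected residues lacking any requested atom

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for _, a in self.pairs], dtype=float).reshape(-1, 3)

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for _, a in self.pairs], dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: Iterable[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the Structure hierarchy.

    Only the first model is taken.  Alternate locations are resolved to the
    highest-occupancy conformer (ties: first in file).  Waters and heteroatoms
    are retained; they can be recognised by residue name.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureError(f"unknown format {format!r} (pdb, mmcif, auto)")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with record context
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    model = st[0]

    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=max(ga.b_iso, 0.0),
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    name=gres.name,
                    atoms=_resolve_altlocs(atoms),
                )
            )
        chains.append(Chain(id=gch.name, residues=residues))

    cell = None
    if st.cell and st.cell.a > 0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_name = st.spacegroup_hm or None
    mult = None
    if sg_name:
        sg = gemmi.find_spacegroup_by_name(sg_name)
        if sg is not None:
            mult = len(sg.operations())
    return Structure(id=st.name or path.stem, chains=chains, cell=cell,
                     spacegroup_name=sg_name, spacegroup_multiplicity=mult)


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write the structure as a standard PDB file (CRYST1 when a cell is set)."""
    if format.lower() != "pdb":
        raise StructureError(f"unsupported output format {format!r} (only pdb)")
    st = gemmi.Structure()
    st.name = s.id
    if s.cell is not None:
        st.cell = gemmi.UnitCell(s.cell.a, s.cell.b, s.cell.c,
                                 s.cell.alpha, s.cell.beta, s.cell.gamma)
    if s.spacegroup_name:
        st.spacegroup_hm = s.spacegroup_name
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "A" if res.name in _STANDARD_AA else "H"
            for atom in res.atoms:
                if not np.all(np.isfinite(atom.position)):
                    raise StructureError(f"non-finite coordinates on {ch.id}/{res.number}")
                if np.any(np.abs(atom.position) >= 10000):
                    raise StructureError(
                        f"coordinate overflow of fixed-width PDB field on {ch.id}/{res.number}")
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or atom.name[:1])
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def select_atoms(s: Structure, sel: Selection) -> AtomSelection:
    """Apply a Selection; returns atoms ordered by residue number then icode.

    Residues matched by the ranges but lacking any of the requested atom names
    are skipped silently; their count is reported in the result metadata.
    Waters are never returned unless their residue name is explicitly allowed
    by being inside an include range *and* carrying a requested atom name
    (in practice waters have no CA, so the default selection excludes them).
    """
    chain = s.chain(sel.chain_id)
    pairs: list[tuple[Residue, Atom]] = []
    n_selected = 0
    n_skipped = 0
    ordered = sorted(chain.residues, key=lambda r: (r.number, r.icode))
    for res in ordered:
        if not sel.covers(res.number):
            continue
        n_selected += 1
        got = False
        for atom in res.atoms:
            if not sel.atom_names or atom.name in sel.atom_names:
                pairs.append((res, atom))
                got = True
        if not got:
            n_skipped += 1
    return AtomSelection(pairs=pairs, n_residues_selected=n_selected,
                         n_residues_skipped=n_skipped)
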