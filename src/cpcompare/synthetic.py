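"""Synthetic fixtures with known ground truth.

Every generator here exists so that the analysis stages can be validated
end-to-end without any external coordinate or sequence data: chains with
controllable geometry, structure pairs related by a known rigid transform plus
region-localised perturbations, painted B-factor profiles, deliberately
deleted residue segments, star-evolved MSAs with a target pairwise identity,
and a tetragonal crystal fixture.

Randomness: each generator takes an explicit seed and builds its own
numpy Generator, so adding one generator call never shifts another's stream.
Coordinate noise is applied to only one member of a pair, keeping the expected
r.m.s.d. of a noisy pair at sigma * sqrt(3) analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conservation import MSA, STANDARD_AA
from .crystal import CrystalContents
from .structure import Atom, Chain, Residue, Selection, Structure, StructureError, UnitCell

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

CA_CA_DISTANCE = 3.8  # Angstrom, trans peptide


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def _helix_coords(n: int) -> np.ndarray:
    """Ideal alpha-helical CA trace: rise 1.5 A/residue, radius 2.3 A,
    100 degrees of twist per residue."""
    i = np.arange(n)
    theta = np.radians(100.0 * i)
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _extended_coords(n: int) -> np.ndarray:
    """Beta-strand-like zigzag with exact 3.8 A CA-CA steps (non-collinear)."""
    dx = 3.3
    dy = math.sqrt(CA_CA_DISTANCE ** 2 - dx ** 2)
    i = np.arange(n)
    return np.column_stack([dx * i, dy * (i % 2), np.zeros(n)])


def _random_walk_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-step random walk; directions biased to avoid immediate backtracking
    so the trace stays loosely compact rather than self-retracing."""
    coords = np.zeros((n, 3))
    prev = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        step = rng.normal(size=3) + 0.5 * prev
        step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + CA_CA_DISTANCE * step
        prev = step
    return coords


def make_chain(
    n: int,
    geometry: str = "helix",
    seed: int = 0,
    chain_id: str = "A",
    start_number: int = 1,
    sequence: str | None = None,
    b_factor: float = 20.0,
) -> Chain:
    """CA-only chain of n residues; deterministic under seed.

    sequence (one-letter) sets the residue names; default poly-alanine.
    """
    if n < 1:
        raise SyntheticError(f"need at least 1 residue, got {n}")
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        coords = _helix_coords(n)
    elif geometry == "extended":
        coords = _extended_coords(n)
    elif geometry == "random-walk":
        coords = _random_walk_coords(n, rng)
    else:
        raise SyntheticError(f"unknown geometry {geometry!r}")
    if sequence is not None and len(sequence) != n:
        raise SyntheticError("sequence length does not match residue count")
    residues = []
    for i in range(n):
        letter = sequence[i] if sequence else "A"
        residues.append(
            Residue(
                number=start_number + i,
                name=ONE_TO_THREE.get(letter.upper(), "ALA"),
                atoms=[Atom(name="CA", element="C", position=coords[i],
                            b_factor=b_factor)],
            )
        )
    return Chain(id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# rigid transforms and perturbation
# ---------------------------------------------------------------------------

def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


@dataclass(frozen=True)
class PerturbationSpec:
    """Recipe for deriving a perturbed homolog from a template structure.

    Applied in order: global rigid transform, per-region rigid displacements,
    i.i.d. Gaussian coordinate noise, B-factor painting, deletion of missing
    ranges.  Ranges are (chain_id, start, end), author numbering, inclusive.
    coordinate_noise_sd may be a single sigma or a {chain_id: sigma} mapping.
    """

    global_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    global_rotation_deg: float = 0.0
    global_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_displacements: tuple[tuple[str, int, int, tuple[float, float, float]], ...] = ()
    chain_offsets: tuple[tuple[str, tuple[float, float, float]], ...] = ()
    coordinate_noise_sd: float | tuple[tuple[str, float], ...] = 0.0
    bfactor_profile: tuple[tuple[str, int, int, float], ...] = ()
    bfactor_noise_sd: float = 0.0
    missing_ranges: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    rotation: np.ndarray
    translation: np.ndarray
    region_displacement_magnitudes: dict[tuple[str, int, int], float]
    chain_offsets: dict[str, np.ndarray]
    noise_sd_by_chain: dict[str, float]
    expected_pair_rmsd_by_chain: dict[str, float]  # sigma*sqrt(3) per chain
    painted_b: dict[tuple[str, int, int], float]
    missing_segments: dict[str, list[tuple[int, int]]]


def _noise_sd_for(spec: PerturbationSpec, chain_id: str) -> float:
    if isinstance(spec.coordinate_noise_sd, (int, float)):
        return float(spec.coordinate_noise_sd)
    return dict(spec.coordinate_noise_sd).get(chain_id, 0.0)


def perturb(s: Structure, spec: PerturbationSpec) -> tuple[Structure, GroundTruth]:
    """Derive a perturbed copy of s with a full ground-truth record."""
    for (cid1, s1, e1, _), (cid2, s2, e2, _) in zip(spec.region_displacements,
                                                    spec.region_displacements[1:]):
        if cid1 == cid2 and max(s1, s2) <= min(e1, e2):
            raise SyntheticError("overlapping region displacements")
    rng = np.random.default_rng(spec.seed)
    rot = rotation_matrix(np.array(spec.global_rotation_axis), spec.global_rotation_deg)
    trans = np.asarray(spec.global_translation, dtype=float)
    offsets = {cid: np.asarray(v, dtype=float) for cid, v in spec.chain_offsets}

    truth = GroundTruth(
        rotation=rot,
        translation=trans,
        region_displacement_magnitudes={
            (cid, a, b): float(np.linalg.norm(d))
            for cid, a, b, d in spec.region_displacements
        },
        chain_offsets=offsets,
        noise_sd_by_chain={c.id: _noise_sd_for(spec, c.id) for c in s.chains},
        expected_pair_rmsd_by_chain={
            c.id: _noise_sd_for(spec, c.id) * math.sqrt(3.0) for c in s.chains
        },
        painted_b={(cid, a, b): v for cid, a, b, v in spec.bfactor_profile},
        missing_segments={},
    )

    new_chains: list[Chain] = []
    for chain in s.chains:
        sigma = _noise_sd_for(spec, chain.id)
        displacements = [(a, b, np.asarray(d, dtype=float))
                         for cid, a, b, d in spec.region_displacements if cid == chain.id]
        paint = [(a, b, v) for cid, a, b, v in spec.bfactor_profile if cid == chain.id]
        missing = [(a, b) for cid, a, b in spec.missing_ranges if cid == chain.id]
        truth.missing_segments[chain.id] = sorted(missing)
        offset = offsets.get(chain.id, np.zeros(3))

        residues: list[Residue] = []
        for res in chain.residues:
            if any(a <= res.number <= b for a, b in missing):
                continue
            atoms: list[Atom] = []
            for atom in res.atoms:
                pos = rot @ atom.position + trans
                for a, b, d in displacements:
                    if a <= res.number <= b:
                        pos = pos + d
                pos = pos + offset
                if sigma > 0:
                    pos = pos + rng.normal(scale=sigma, size=3)
                bval = atom.b_factor
                for a, b, v in paint:
                    if a <= res.number <= b:
                        bval = v
                if spec.bfactor_noise_sd > 0:
                    bval = max(0.0, bval + rng.normal(scale=spec.bfactor_noise_sd))
                atoms.append(Atom(name=atom.name, element=atom.element, position=pos,
                                  occupancy=atom.occupancy, b_factor=bval,
                                  altloc=atom.altloc))
            residues.append(Residue(number=res.number, icode=res.icode,
                                    name=res.name, atoms=atoms))
        new_chains.append(Chain(id=chain.id, residues=residues))

    out = Structure(id=s.id + "_perturbed", chains=new_chains, cell=s.cell,
                    spacegroup_name=s.spacegroup_name,
                    spacegroup_multiplicity=s.spacegroup_multiplicity)
    return out, truth


def delete_ranges(chain: Chain, ranges: list[tuple[int, int]]) -> Chain:
    """Copy of the chain without the residues in the given inclusive ranges."""
    kept = [r for r in chain.residues
            if not any(a <= r.number <= b for a, b in ranges)]
    return Chain(id=chain.id, residues=kept)


# ---------------------------------------------------------------------------
# MSAs: star-topology evolution
# ---------------------------------------------------------------------------

def _substitution_rate_for_identity(target_identity: float) -> float:
    """Per-site, per-branch substitution probability s for a star tree such
    that the expected pairwise identity between two leaves equals the target.

    Substitution replaces a letter by a uniform choice among the other 19, so
    two leaves agree with probability (1-s)^2 + s^2/19.  Solving the quadratic
    (k = 20/19):  s = (1 - sqrt(1 - k (1 - t))) / k.
    """
    k = 20.0 / 19.0
    disc = 1.0 - k * (1.0 - target_identity)
    if disc < 0:
        raise SyntheticError(
            f"target identity {target_identity} below the star-model floor (0.05)")
    return (1.0 - math.sqrt(disc)) / k


def evolve_msa(
    length: int,
    n_seqs: int,
    target_identity: float,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> tuple[MSA, float]:
    """Star-topology family: one random ancestor, each leaf mutated
    independently so the expected leaf-leaf identity is the target.

    Gaps model deletions: starting at each position with probability gap_rate,
    a run of geometric length (mean 3) is replaced by '-'.  Deletions remove
    the same columns from numerator and denominator on the deleted side only,
    so for small gap_rate the expected identity stays close to the target.

    Returns (msa, expected_pairwise_identity).
    """
    if not 0.0 < target_identity <= 1.0:
        raise SyntheticError("target identity must be in (0, 1]")
    if not 0.0 <= gap_rate < 1.0:
        raise SyntheticError("gap rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
    ancestor = rng.choice(letters, size=length)
    s = _substitution_rate_for_identity(target_identity)

    rows: list[str] = []
    for _ in range(n_seqs):
        seq = ancestor.copy()
        hit = rng.random(length) < s
        if hit.any():
            # uniform among the other 19 letters
            repl = rng.choice(letters, size=int(hit.sum()))
            same = repl == seq[hit]
            while same.any():
                repl[same] = rng.choice(letters, size=int(same.sum()))
                same = repl == seq[hit]
            seq[hit] = repl
        row = bytearray(seq.tobytes())
        if gap_rate > 0:
            j = 0
            while j < length:
                if rng.random() < gap_rate:
                    run = int(rng.geometric(1.0 / 3.0))
                    for jj in range(j, min(j + run, length)):
                        row[jj] = ord("-")
                    j += run
                j += 1
        rows.append(row.decode("ascii"))
    ids = [f"seq{i:04d}" for i in range(n_seqs)]
    return MSA(ids=ids, rows=rows), target_identity


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def mutate_sequence(seq: str, substitution_rate: float, seed: int = 0,
                    protected: set[int] | None = None) -> str:
    """Point-mutate a sequence (uniform among the other 19 letters); the
    expected identity to the input is 1 - substitution_rate.

    protected: 0-based positions never mutated — models structurally
    constrained anchor residues (e.g. the conserved strands flanking a
    flexible loop), which keep homolog alignments in register there.
    """
    rng = np.random.default_rng(seed)
    protected = protected or set()
    out = list(seq)
    for i, c in enumerate(out):
        if i not in protected and rng.random() < substitution_rate:
            choices = [x for x in STANDARD_AA if x != c]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# crystal fixture
# ---------------------------------------------------------------------------

def make_crystal_fixture(
    cell: UnitCell | None = None,
    spacegroup: str = "P 41",
    au_per_cell: int = 4,
    n_molecules_per_au: int = 2,
    mass_per_molecule: float = 66000.0,
) -> tuple[UnitCell, CrystalContents]:
    """Tetragonal crystal-form fixture.

    Defaults describe the crystal form of the Dictyostelium capping-protein
    heterodimer: P4_1 (4 AU per cell), a = b = 124.5 A, c = 77.5 A, two
    heterodimers of ~66 kDa (32 + 34 kDa subunits) per asymmetric unit.
    """
    cell = cell or UnitCell(124.5, 124.5, 77.5, 90.0, 90.0, 90.0)
    contents = CrystalContents(n_molecules_per_au=n_molecules_per_au,
                               mass_per_molecule=mass_per_molecule,
                               au_per_cell=au_per_cell)
    return cell, contents
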