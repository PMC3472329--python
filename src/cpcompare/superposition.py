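"""Least-squares rigid-body superposition over mapped atom sets.

The solver is the Kabsch/SVD construction: given paired coordinate sets it
returns the proper rotation R and translation t minimising
sum_i ||R a_i + t - b_i||^2.  The reflection branch of the SVD is corrected by
the sign of det(V U^T), so the result is always a pure rotation, also for
planar point clouds where the smallest singular value is zero.

Fit and report selections are deliberately separate: a fit computed on one set
of residues (e.g. "everything except a flexible region") can be *reported* on
any other region, so a region's deviation is measured in the global frame —
the way regional differences between homologous structures are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correspondence import CorrespondenceError, ResidueMap
from .structure import Selection, Structure, StructureError


class SuperpositionError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # Angstrom
    n_atoms: int
    per_pair_deviation: np.ndarray  # Angstrom, aligned with the input pairs

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.per_pair_deviation = np.asarray(self.per_pair_deviation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise SuperpositionError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise SuperpositionError("rotation is improper (reflection)")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply R x + t to an (n, 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of a onto b.

    Requires at least 3 non-collinear points; collinear/degenerate input (the
    covariance has rank < 2) raises, since the rotation about the line would be
    undetermined.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise SuperpositionError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 points, got {n}")

    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    ac = a - cen_a
    bc = b - cen_b

    h = ac.T @ bc  # 3x3 covariance
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise SuperpositionError("degenerate geometry: points are (near-)collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cen_b - rot @ cen_a

    dev = np.linalg.norm(a @ rot.T + trans - b, axis=1)
    rmsd = float(np.sqrt(np.mean(dev ** 2)))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms=n, per_pair_deviation=dev)


@dataclass
class RegionRmsd:
    """Deviation of one mapped region measured in an externally fitted frame."""

    name: str
    n_atoms: int
    rmsd: float
    per_pair_deviation: np.ndarray


@dataclass
class MappedSuperposition:
    """Fit over the fit selection plus per-region reports in the fitted frame."""

    fit: SuperpositionResult
    fit_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    regions: dict[str, RegionRmsd] = field(default_factory=dict)


def _mapped_coordinates(
    s_a: Structure, s_b: Structure, rmap: ResidueMap,
    sel_a: Selection, sel_b: Selection,
) -> tuple[np.ndarray, np.ndarray, list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Coordinates for map pairs surviving both selections; atoms paired by
    name within each residue (CA-only under the default selections)."""
    chain_a = s_a.chain(sel_a.chain_id)
    chain_b = s_b.chain(sel_b.chain_id)
    names = sorted(sel_a.atom_names & sel_b.atom_names)
    if not names:
        raise SuperpositionError("fit/report selections share no atom names")
    xa, xb, kept = [], [], []
    for (cid_a, num_a), (cid_b, num_b) in rmap.pairs:
        if cid_a != sel_a.chain_id or cid_b != sel_b.chain_id:
            continue
        if not (sel_a.covers(num_a) and sel_b.covers(num_b)):
            continue
        res_a = chain_a.residue(num_a)
        res_b = chain_b.residue(num_b)
        if res_a is None or res_b is None:
            continue
        added = False
        for name in names:
            at_a = res_a.atom(name)
            at_b = res_b.atom(name)
            if at_a is not None and at_b is not None:
                xa.append(at_a.position)
                xb.append(at_b.position)
                added = True
        if added:
            kept.append(((cid_a, num_a), (cid_b, num_b)))
    return (np.array(xa, dtype=float).reshape(-1, 3),
            np.array(xb, dtype=float).reshape(-1, 3), kept)


def superpose_mapped(
    s_a: Structure,
    s_b: Structure,
    rmap: ResidueMap,
    fit_sel: tuple[Selection, Selection],
    report_sels: dict[str, tuple[Selection, Selection]] | None = None,
) -> MappedSuperposition:
    """Fit on fit_sel ∩ map, then report per-region r.m.s.d. in that frame.

    The transform superposes structure a onto structure b.  Every report region
    must intersect the map, otherwise the request is an error (a silent zero
    would masquerade as a perfect fit).
    """
    xa, xb, kept = _mapped_coordinates(s_a, s_b, rmap, *fit_sel)
    if len(kept) == 0:
        raise SuperpositionError("fit selection does not intersect the residue map")
    fit = kabsch(xa, xb)

    regions: dict[str, RegionRmsd] = {}
    for name, (ra, rb) in (report_sels or {}).items():
        ya, yb, rkept = _mapped_coordinates(s_a, s_b, rmap, ra, rb)
        if len(rkept) == 0:
            raise SuperpositionError(f"report selection {name!r} has no mapped residues")
        dev = np.linalg.norm(fit.transform(ya) - yb, axis=1)
        regions[name] = RegionRmsd(name=name, n_atoms=ya.shape[0],
                                   rmsd=float(np.sqrt(np.mean(dev ** 2))),
                                   per_pair_deviation=dev)
    return MappedSuperposition(fit=fit, fit_pairs=kept, regions=regions)


def per_residue_profile(result: MappedSuperposition) -> pd.DataFrame:
    """Per-mapped-pair deviation table (number_a, number_b, deviation_A) for the
    fit set; sqrt(mean(deviation^2)) equals the reported rmsd by construction."""
    if len(result.fit_pairs) != len(result.fit.per_pair_deviation):
        raise CorrespondenceError("pair list and deviation vector lengths differ")
    return pd.DataFrame(
        {
            "number_a": [p[0][1] for p in result.fit_pairs],
            "number_b": [p[1][1] for p in result.fit_pairs],
            "deviation_A": result.fit.per_pair_deviation,
        }
    )


def region_table(ms: MappedSuperposition) -> pd.DataFrame:
    """Region report as a tidy table (region, n_atoms, rmsd_A)."""
    rows = [{"region": "fit", "n_atoms": ms.fit.n_atoms, "rmsd_A": ms.fit.rmsd}]
    rows += [{"region": r.name, "n_atoms": r.n_atoms, "rmsd_A": r.rmsd}
             for r in ms.regions.values()]
    return pd.DataFrame(rows)
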