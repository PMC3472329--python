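"""Kabsch superposition: exactness, optimality, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import special_ortho_group

from cpcompare.structure import Selection, Structure
from cpcompare.superposition import (
    SuperpositionError, kabsch, per_residue_profile, superpose_mapped,
)
from cpcompare.correspondence import map_chains
from cpcompare.synthetic import make_chain, perturb, PerturbationSpec, rotation_matrix


def cloud(n, rng, scale=10.0):
    return rng.normal(scale=scale, size=(n, 3))


def test_identity_superposition(rng):
    a = cloud(10, rng)
    res = kabsch(a, a)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(res.translation, 0.0, atol=1e-10)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)


def test_pure_translation_recovered(rng):
    a = cloud(10, rng)
    res = kabsch(a, a + np.array([5.0, 0.0, 0.0]))
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(res.translation, [5.0, 0.0, 0.0], atol=1e-10)
    assert res.rmsd == pytest.approx(0.0, abs=1e-10)


def test_known_rotation_recovered(rng):
    a = cloud(10, rng)
    r90z = rotation_matrix(np.array([0.0, 0.0, 1.0]), 90.0)
    res = kabsch(a, a @ r90z.T)
    np.testing.assert_allclose(res.rotation, r90z, atol=1e-8)
    assert res.rmsd <= 1e-8


def test_rmsd_of_isotropic_noise_is_sigma_root3(rng):
    """E[rmsd] for per-coordinate Gaussian noise sigma is sigma*sqrt(3)."""
    sigma, n = 0.5, 1000
    a = cloud(n, rng, scale=20.0)
    b = a + rng.normal(scale=sigma, size=a.shape)
    res = kabsch(a, b)
    assert res.rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)


def test_optimality_against_rotation_sampling_oracle(rng):
    """On small clouds the Kabsch r.m.s.d. beats 10,000 random proper
    rotations each given its own optimal translation."""
    rotations = special_ortho_group.rvs(3, size=10000, random_state=12345)
    for n in (4, 5, 6):
        a = cloud(n, rng, scale=5.0)
        b = cloud(n, rng, scale=5.0)
        best = kabsch(a, b).rmsd
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rotated = np.einsum("kij,nj->kni", rotations, ac)  # optimal t = centroid match
        rmsds = np.sqrt(np.mean(np.sum((rotated - bc) ** 2, axis=2), axis=1))
        assert best <= rmsds.min() + 1e-12


def test_rmsd_invariant_under_common_rigid_transform(rng):
    a, b = cloud(30, rng), cloud(30, rng)
    base = kabsch(a, b).rmsd
    r = rotation_matrix(np.array([1.0, 2.0, 0.5]), 37.0)
    t = np.array([3.0, -4.0, 5.0])
    assert kabsch(a @ r.T + t, b @ r.T + t).rmsd == pytest.approx(base, abs=1e-9)


def test_rmsd_symmetric(rng):
    a, b = cloud(25, rng), cloud(25, rng)
    assert kabsch(a, b).rmsd == pytest.approx(kabsch(b, a).rmsd, abs=1e-9)


def test_rotation_always_proper_on_planar_clouds(rng):
    """Planar clouds exercise the zero-singular-value branch; the returned
    rotation must still be proper (det +1), never a reflection."""
    for _ in range(20):
        a = np.column_stack([rng.normal(size=(8, 2)) * 5, np.zeros(8)])
        r = special_ortho_group.rvs(3, random_state=rng.integers(2**31))
        res = kabsch(a, a @ r.T)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd <= 1e-8


def test_agrees_with_scipy_align_vectors(rng):
    """Independent oracle: scipy's Wahba solver gives the same optimum."""
    a, b = cloud(40, rng), cloud(40, rng, scale=8.0)
    res = kabsch(a, b)
    rot, rssd = Rotation.align_vectors(b - b.mean(axis=0), a - a.mean(axis=0))
    assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-6)
    np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-6)


@pytest.mark.parametrize("bad", [
    np.zeros((2, 3)),
    np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0])),  # collinear
])
def test_degenerate_geometry_rejected(bad):
    with pytest.raises(SuperpositionError):
        kabsch(bad, bad + 1.0)


def test_transform_recovery_improves_with_less_noise(rng):
    """Recovered rotation angle error decreases monotonically as sigma -> 0."""
    a = cloud(100, rng, scale=15.0)
    true_rot = rotation_matrix(np.array([1.0, -1.0, 2.0]), 55.0)
    errors = []
    for sigma in (1.0, 0.3, 0.1, 0.0):
        b = a @ true_rot.T + rng.normal(scale=sigma, size=a.shape) if sigma else a @ true_rot.T
        rec = kabsch(a, b).rotation
        errors.append(np.degrees(np.arccos(
            np.clip((np.trace(rec @ true_rot.T) - 1) / 2, -1, 1))))
    assert errors == sorted(errors, reverse=True)
    assert errors[-1] <= 1e-7


# --- mapped superposition ---------------------------------------------------

def _pair_with_displaced_region(seed=9, displacement=3.0):
    chain_a = make_chain(200, "random-walk", seed=seed, chain_id="A")
    s_a = Structure(id="a", chains=[chain_a])
    s_b, truth = perturb(s_a, PerturbationSpec(
        global_rotation_axis=(0, 1, 0), global_rotation_deg=30.0,
        global_translation=(5.0, 6.0, 7.0),
        region_displacements=(("A", 101, 117, (0.0, 0.0, displacement)),),
        seed=seed,
    ))
    return s_a, s_b, map_chains(s_a.chain("A"), s_b.chain("A"))


def test_fit_and_report_on_rigid_copy_is_zero():
    chain_a = make_chain(50, "random-walk", seed=4, chain_id="A")
    s_a = Structure(id="a", chains=[chain_a])
    s_b, _ = perturb(s_a, PerturbationSpec(global_rotation_deg=120.0,
                                           global_translation=(1, 2, 3)))
    rmap = map_chains(s_a.chain("A"), s_b.chain("A"))
    sel = (Selection(chain_id="A"), Selection(chain_id="A"))
    ms = superpose_mapped(s_a, s_b, rmap, sel, {"all": sel})
    assert ms.fit.rmsd == pytest.approx(0.0, abs=1e-8)
    assert ms.regions["all"].rmsd == pytest.approx(0.0, abs=1e-8)


def test_displaced_region_reported_at_full_size():
    """Fit on everything minus a displaced region, report the region: the
    region's r.m.s.d. equals the displacement; the rest stays at zero."""
    s_a, s_b, rmap = _pair_with_displaced_region()
    fit = (Selection(chain_id="A", exclude_ranges=((101, 117),)),
           Selection(chain_id="A", exclude_ranges=((101, 117),)))
    region = (Selection(chain_id="A", include_ranges=((101, 117),)),
              Selection(chain_id="A", include_ranges=((101, 117),)))
    ms = superpose_mapped(s_a, s_b, rmap, fit, {"region": region, "rest": fit})
    assert ms.regions["region"].rmsd == pytest.approx(3.0, abs=1e-6)
    assert ms.regions["region"].n_atoms == 17
    assert ms.regions["rest"].rmsd == pytest.approx(0.0, abs=1e-8)


def test_empty_report_selection_raises():
    s_a, s_b, rmap = _pair_with_displaced_region()
    fit = (Selection(chain_id="A"), Selection(chain_id="A"))
    empty = (Selection(chain_id="A", include_ranges=((500, 600),)),
             Selection(chain_id="A", include_ranges=((500, 600),)))
    with pytest.raises(SuperpositionError, match="no mapped residues"):
        superpose_mapped(s_a, s_b, rmap, fit, {"empty": empty})


def test_per_residue_profile_mean_square_identity(rng):
    s_a, s_b, rmap = _pair_with_displaced_region(seed=13, displacement=2.0)
    sel = (Selection(chain_id="A"), Selection(chain_id="A"))
    ms = superpose_mapped(s_a, s_b, rmap, sel)
    prof = per_residue_profile(ms)
    assert len(prof) == ms.fit.n_atoms
    assert np.sqrt(np.mean(prof["deviation_A"] ** 2)) == pytest.approx(ms.fit.rmsd,
                                                                       abs=1e-12)
    # the displaced residues carry the largest deviations
    top = prof.nlargest(17, "deviation_A")["number_a"]
    assert set(top).issubset(set(range(95, 124)))
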