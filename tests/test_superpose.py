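import numpy as np
import pytest

from _oracles import quaternion_rmsd
from phnmr.exceptions import (
    ConditioningError,
    CoverageError,
    DimensionError,
    PrecisionUndefinedError,
)
from phnmr.structure_io import Selection, StructureEnsemble
from phnmr.superpose import (
    RegionCorrespondence,
    ensemble_precision,
    kabsch,
    region_rmsd,
)
from phnmr.synthetic import ideal_backbone, make_ensemble


def _rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestKabsch:
    def test_identity_gives_zero_rmsd(self, rng):
        a = rng.normal(size=(6, 3))
        sup = kabsch(a, a)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self, rng):
        a = rng.normal(size=(8, 3))
        rot = _rotation([0, 0, 1], np.pi / 2)
        t = np.array([5.0, 0.0, 0.0])
        b = a @ rot.T + t
        sup = kabsch(a, b)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(sup.apply(a), b, atol=1e-9)

    def test_unit_square_with_displaced_corner_matches_quaternion_oracle(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        b = a.copy()
        b[2, 0] += 0.5
        assert kabsch(a, b).rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-12)

    def test_agrees_with_quaternion_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 11))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            assert kabsch(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-7)

    def test_rotation_is_proper_orthonormal(self, rng):
        # include a near-reflection case: b is a mirrored a
        a = rng.normal(size=(7, 3))
        b = a * np.array([1, 1, -1])
        sup = kabsch(a, b)
        np.testing.assert_allclose(sup.rotation.T @ sup.rotation, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        base = kabsch(a, b).rmsd
        for _ in range(10):
            rot = _rotation(rng.normal(size=3), rng.uniform(0, np.pi))
            t = rng.normal(size=3) * 10
            assert kabsch(a @ rot.T + t, b @ rot.T + t).rmsd == pytest.approx(
                base, abs=1e-7)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(DimensionError):
            kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_collinear_points_raise_conditioning_error(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ConditioningError):
            kabsch(a, a + 1.0)

    def test_weighted_superposition_prioritizes_heavy_points(self, rng):
        a = rng.normal(size=(5, 3))
        b = a.copy()
        b[0] += 3.0  # outlier
        w = np.array([0.0001, 1, 1, 1, 1])
        assert kabsch(a, b, w).rmsd < kabsch(a, b).rmsd


class TestRegionRmsd:
    def test_structure_against_itself_is_zero(self, small_ensemble):
        ens, _ = small_ensemble
        corr = RegionCorrespondence(tuple((i, i) for i in range(3, 15)))
        assert region_rmsd(ens, ens, corr) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_inputs(self):
        ens_a, _ = make_ensemble(20, 5, 0.4, seed=11)
        ens_b, _ = make_ensemble(20, 5, 0.4, seed=12)
        corr = RegionCorrespondence(tuple((i, i) for i in range(2, 18)))
        ab = region_rmsd(ens_a, ens_b, corr)
        ba = region_rmsd(ens_b, ens_a, corr.swapped())
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_jittered_pair_concentrates_near_monte_carlo_expectation(self):
        # two independently jittered copies of one template, sigma per coord:
        # compare the analysis-path RMSD with a direct brute-force average
        # over replicate pairs of the same generator settings
        sigma = 0.5
        corr = RegionCorrespondence(tuple((i, i) for i in range(1, 21)))
        direct = []
        for seed in range(100):
            a, _ = make_ensemble(20, 1, sigma, seed=1000 + seed)
            b, _ = make_ensemble(20, 1, sigma, seed=2000 + seed)
            direct.append(region_rmsd(a, b, corr, representative=1))
        direct = np.asarray(direct)
        # closed form: coordinate differences are N(0, 2 sigma^2); the rigid
        # fit removes 6 of the 3N dof, so E[RMSD] ~ sigma sqrt(6 (1 - 2/N))
        n_atoms = 20 * 4
        expected = sigma * np.sqrt(6.0 * (1 - 2 / n_atoms))
        assert direct.mean() == pytest.approx(expected, rel=0.05)

    def test_missing_residue_raises_coverage_error(self, small_ensemble):
        ens, _ = small_ensemble
        corr = RegionCorrespondence(((1, 1), (2, 99)))
        with pytest.raises(CoverageError):
            region_rmsd(ens, ens, corr)

    def test_correspondence_rejects_repeats(self):
        with pytest.raises(ValueError):
            RegionCorrespondence(((1, 1), (1, 2)))


class TestEnsemblePrecision:
    def test_identical_models_give_zero(self):
        template = ideal_backbone(10)
        roster = [("A", i, "ALA", a)
                  for i in range(1, 11) for a in ("N", "CA", "C", "O")]
        ens = StructureEnsemble(roster, np.stack([template] * 5))
        prec = ensemble_precision(ens, Selection.of(None, "backbone"))
        assert prec.mean_rmsd == pytest.approx(0.0, abs=1e-9)
        assert prec.sd_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_rotated_models_give_zero(self):
        template = ideal_backbone(10)
        rot = _rotation([1, 2, 3], 1.1)
        roster = [("A", i, "ALA", a)
                  for i in range(1, 11) for a in ("N", "CA", "C", "O")]
        ens = StructureEnsemble(
            roster, np.stack([template, template @ rot.T + np.array([3, 1, 0])]))
        prec = ensemble_precision(ens, Selection.of(None, "backbone"))
        assert prec.mean_rmsd == pytest.approx(0.0, abs=1e-7)

    def test_single_model_refuses(self):
        ens, _ = make_ensemble(10, 1, 0.3, seed=3)
        with pytest.raises(PrecisionUndefinedError):
            ensemble_precision(ens, Selection.of(None, "backbone"))

    def test_model_order_independent(self, small_ensemble, rng):
        ens, _ = small_ensemble
        sel = Selection.of(None, "backbone")
        base = ensemble_precision(ens, sel)
        perm = rng.permutation(ens.n_models)
        shuffled = StructureEnsemble(ens.roster, ens.coords[perm])
        other = ensemble_precision(shuffled, sel)
        assert other.mean_rmsd == pytest.approx(base.mean_rmsd, abs=1e-7)
        np.testing.assert_allclose(sorted(other.per_model_rmsd),
                                   sorted(base.per_model_rmsd), atol=1e-7)

    def test_jittered_ensemble_precision_tracks_generator_sigma(self, small_ensemble):
        # mean RMSD to the mean structure ~ sqrt(3)*sigma*sqrt(1-1/n) per atom
        ens, _ = small_ensemble
        prec = ensemble_precision(ens, Selection.of(None, "backbone"))
        expected = np.sqrt(3) * 0.5 * np.sqrt(1 - 1 / 20)
        assert prec.mean_rmsd == pytest.approx(expected, rel=0.10)
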