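"""Procrustes, bending energy, sliding, shape PCA."""

import numpy as np
import pytest

from island_ark import morpho as mo
from island_ark import synthdata as sd
from island_ark.io_formats import LandmarkDataset


def rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


SQUARE = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
L_SHAPE = np.array([[0.0, 0], [2, 0], [2, 0.5], [0.5, 0.5], [0.5, 2],
                    [0, 2]])


class TestCentroidSize:
    def test_unit_square(self):
        assert mo.centroid_size(SQUARE) == pytest.approx(np.sqrt(2))

    def test_homogeneous_in_scale(self):
        assert mo.centroid_size(3.7 * SQUARE) == \
            pytest.approx(3.7 * mo.centroid_size(SQUARE))

    def test_translation_invariant(self):
        assert mo.centroid_size(SQUARE + [5, -3]) == \
            pytest.approx(mo.centroid_size(SQUARE))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            mo.centroid_size(SQUARE[:2])


def unitize(cfg):
    c = cfg - cfg.mean(axis=0)
    return c / np.linalg.norm(c)


class TestAlignPair:
    def test_self_alignment_identity(self):
        ref = unitize(L_SHAPE)
        aligned, d = mo.align_pair(ref, ref)
        assert d == pytest.approx(0, abs=1e-12)
        assert np.allclose(aligned, ref)

    def test_rotation_recovered(self):
        ref = unitize(L_SHAPE)
        rotated = ref @ rot(np.pi / 6).T
        aligned, d = mo.align_pair(rotated, ref)
        assert d == pytest.approx(0, abs=1e-10)

    def test_reflection_not_removed(self):
        ref = unitize(L_SHAPE)
        mirrored = unitize(L_SHAPE * [-1, 1])
        _, d = mo.align_pair(mirrored, ref)
        assert d > 0.1


class TestGpa:
    def test_same_shape_under_similarity_transforms(self, rng):
        base = L_SHAPE
        coords = []
        for _ in range(6):
            c = 0.5 + 2 * rng.random()
            cfg = c * base @ rot(rng.uniform(0, 2 * np.pi)).T \
                + rng.uniform(-10, 10, 2)
            coords.append(cfg)
        ds = LandmarkDataset([f"s{i}" for i in range(6)], np.array(coords),
                             np.zeros(6, dtype=bool), [])
        fit = mo.gpa(ds)
        assert fit.converged
        spread = fit.aligned - fit.aligned.mean(axis=0)
        assert np.abs(spread).max() < 1e-7

    def test_unit_centroid_size_and_centering(self, rng):
        study = sd.synth_landmarks(n_per_group=4, seed=1)
        fit = mo.gpa(study.data)
        for cfg in fit.aligned:
            assert np.allclose(cfg.mean(axis=0), 0, atol=1e-9)
            assert np.linalg.norm(cfg) == pytest.approx(1.0)

    def test_two_specimen_mean_equidistant(self, rng):
        a = unitize(L_SHAPE)
        b = unitize(L_SHAPE + rng.normal(0, 0.05, L_SHAPE.shape))
        ds = LandmarkDataset(["a", "b"], np.array([a, b]),
                             np.zeros(6, dtype=bool), [])
        fit = mo.gpa(ds)
        d = [np.linalg.norm(cfg - fit.mean_shape) for cfg in fit.aligned]
        assert d[0] == pytest.approx(d[1], rel=1e-5)

    def test_specimen_order_irrelevant(self, rng):
        study = sd.synth_landmarks(n_per_group=4, seed=2)
        ds = study.data
        fit1 = mo.gpa(ds)
        perm = list(reversed(range(ds.n)))
        ds2 = LandmarkDataset([ds.specimens[i] for i in perm],
                              ds.coords[perm], ds.semi_flags,
                              list(ds.curve_order), dict(ds.groups))
        fit2 = mo.gpa(ds2)
        assert np.allclose(fit2.mean_shape, fit1.mean_shape, atol=1e-8)


class TestBendingEnergy:
    def test_affine_null_space(self, rng):
        ref = rng.normal(size=(9, 2))
        Be = mo.bending_energy(ref)
        for field in (np.ones(9), ref[:, 0], ref[:, 1]):
            assert np.abs(Be @ field).max() < 1e-8

    def test_symmetric_psd(self, rng):
        ref = rng.normal(size=(8, 2))
        Be = mo.bending_energy(ref)
        assert np.allclose(Be, Be.T)
        assert np.linalg.eigvalsh(Be).min() > -1e-9

    def test_energy_matches_tps_interpolation_oracle(self):
        """Quadratic form equals the analytic TPS energy of the fitted
        spline for a single displaced interior point on a 3x3 grid."""
        gx, gy = np.meshgrid([0.0, 1, 2], [0.0, 1, 2])
        ref = np.column_stack([gx.ravel(), gy.ravel()])
        Be = mo.bending_energy(ref)
        dz = np.zeros(9)
        dz[4] = 1.0                          # displace the centre point
        quad = float(dz @ Be @ dz)
        # independent oracle: solve the full bordered system for the spline
        # coefficients and evaluate the energy as w^T K w
        k = 9
        d2 = ((ref[:, None] - ref[None, :]) ** 2).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(d2 > 0, d2 * np.log(np.where(d2 > 0, d2, 1.0)), 0.0)
        P = np.column_stack([np.ones(k), ref])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.concatenate([dz, np.zeros(3)])
        w = np.linalg.solve(L, rhs)[:k]
        assert quad == pytest.approx(float(w @ K @ w), abs=1e-10)

    def test_coincident_points_error(self):
        ref = np.array([[0.0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="coincident"):
            mo.bending_energy(ref)


def small_curve_dataset(perturb=None):
    """One fixed triangle plus a 4-point semi-landmark curve."""
    fixed = np.array([[0.0, 0], [4, 0], [2, 3]])
    curve = np.column_stack([np.linspace(0.5, 3.5, 4), np.full(4, -1.0)])
    ref = np.vstack([fixed, curve])
    spec = ref.copy()
    if perturb is not None:
        spec = spec + perturb
    ds = LandmarkDataset(["x"], spec[None, :, :],
                         np.array([False] * 3 + [True] * 4), [3, 4, 5, 6])
    return ds, ref


class TestSliding:
    def test_identical_to_reference_no_motion(self):
        ds, ref = small_curve_dataset()
        out = mo.slide_semilandmarks(ds, mo.SlidingSpec(), ref)
        assert np.allclose(out.coords[0], ref)

    def test_fixed_landmarks_never_move(self, rng):
        pert = np.zeros((7, 2))
        pert[3:] = rng.normal(0, 0.1, (4, 2))
        ds, ref = small_curve_dataset(pert)
        out = mo.slide_semilandmarks(ds, mo.SlidingSpec(), ref)
        assert np.allclose(out.coords[0, :3], ds.coords[0, :3])

    def test_pure_tangent_displacement_restored(self):
        # move one interior semi-landmark along its own chord tangent
        pert = np.zeros((7, 2))
        pert[4] = [0.3, 0.0]                 # chord direction is +x
        ds, ref = small_curve_dataset(pert)
        out = mo.slide_semilandmarks(ds, mo.SlidingSpec(), ref)
        assert np.allclose(out.coords[0, 4], ref[4], atol=1e-6)

    def test_energy_never_increases(self, rng):
        pert = np.zeros((7, 2))
        pert[3:] = rng.normal(0, 0.2, (4, 2))
        ds, ref = small_curve_dataset(pert)
        Be = mo.bending_energy(ref)
        before = np.trace((ds.coords[0] - ref).T @ Be @ (ds.coords[0] - ref))
        out = mo.slide_semilandmarks(ds, mo.SlidingSpec(), ref)
        after = np.trace((out.coords[0] - ref).T @ Be @ (out.coords[0] - ref))
        assert after <= before + 1e-12


class TestGpaWithSliding:
    def test_no_semis_equals_plain_gpa(self, rng):
        study = sd.synth_landmarks(n_per_group=4, k_semi=0, seed=3)
        fit_a = mo.gpa(study.data)
        fit_b = mo.gpa_with_sliding(study.data)
        assert np.allclose(fit_a.mean_shape, fit_b.mean_shape)

    def test_energy_trace_monotone(self):
        study = sd.synth_landmarks(n_per_group=6, seed=4)
        fit = mo.gpa_with_sliding(study.data)
        trace = fit.energy_trace
        assert len(trace) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_group_separation_survives_sliding(self):
        study = sd.synth_landmarks(n_per_group=8, effect_size=0.15,
                                   noise_sd=0.003, seed=5)
        fit = mo.gpa_with_sliding(study.data)
        pca = mo.shape_pca(fit)
        grp = np.array([study.data.groups[s] for s in fit.specimens])
        a = pca.scores[grp == "island", 0]
        b = pca.scores[grp == "continental", 0]
        assert a.min() > b.max() or a.max() < b.min()


class TestShapePca:
    def test_identical_specimens_zero_variance(self):
        base = unitize(L_SHAPE)
        ds = LandmarkDataset([f"s{i}" for i in range(4)],
                             np.array([L_SHAPE * (i + 1) for i in range(4)]),
                             np.zeros(6, dtype=bool), [])
        fit = mo.gpa(ds)
        pca = mo.shape_pca(fit)
        assert pca.variance_explained.size == 0 or \
            pca.variance_explained.max() < 1e-16

    def test_variance_sums_to_total(self):
        study = sd.synth_landmarks(n_per_group=5, seed=6)
        fit = mo.gpa(study.data)
        pca = mo.shape_pca(fit)
        flat = fit.aligned.reshape(fit.aligned.shape[0], -1)
        total = ((flat - flat.mean(0)) ** 2).sum() / (flat.shape[0] - 1)
        assert pca.variance_explained.sum() == pytest.approx(total)

    def test_reconstruction_from_all_scores(self):
        study = sd.synth_landmarks(n_per_group=5, seed=7)
        fit = mo.gpa(study.data)
        pca = mo.shape_pca(fit)
        flat = fit.aligned.reshape(fit.aligned.shape[0], -1)
        recon = flat.mean(axis=0) + pca.scores @ pca.loadings
        assert np.allclose(recon, flat, atol=1e-8)

    def test_loadings_orthonormal_with_sign_convention(self):
        study = sd.synth_landmarks(n_per_group=5, seed=8)
        pca = mo.shape_pca(mo.gpa(study.data))
        G = pca.loadings @ pca.loadings.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-10)
        for row in pca.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestPcDeformation:
    def test_zero_score_is_mean(self):
        study = sd.synth_landmarks(n_per_group=4, seed=9)
        pca = mo.shape_pca(mo.gpa(study.data))
        assert np.allclose(mo.pc_deformation(pca, 0, 0.0), pca.mean_shape)

    def test_symmetric_displacement(self):
        study = sd.synth_landmarks(n_per_group=4, seed=10)
        pca = mo.shape_pca(mo.gpa(study.data))
        plus = mo.pc_deformation(pca, 0, 0.1) - pca.mean_shape
        minus = mo.pc_deformation(pca, 0, -0.1) - pca.mean_shape
        assert np.allclose(plus, -minus)

    def test_direct_arithmetic(self):
        study = sd.synth_landmarks(n_per_group=4, seed=11)
        pca = mo.shape_pca(mo.gpa(study.data))
        expect = pca.mean_shape.reshape(-1) + 0.1 * pca.loadings[0]
        assert np.allclose(mo.pc_deformation(pca, 0, 0.1).reshape(-1), expect)

    def test_bad_component_errors(self):
        study = sd.synth_landmarks(n_per_group=4, seed=12)
        pca = mo.shape_pca(mo.gpa(study.data))
        with pytest.raises(ValueError):
            mo.pc_deformation(pca, 999, 0.1)


def test_full_pipeline_similarity_invariance(rng):
    """Scores and variances unchanged when every specimen is independently
    rotated, translated and scaled."""
    study = sd.synth_landmarks(n_per_group=5, seed=13)
    ds = study.data
    fit1 = mo.gpa_with_sliding(ds)
    pca1 = mo.shape_pca(fit1)
    coords = []
    for cfg in ds.coords:
        c = 0.5 + rng.random()
        coords.append(c * cfg @ rot(rng.uniform(0, 2 * np.pi)).T
                      + rng.uniform(-3, 3, 2))
    ds2 = LandmarkDataset(list(ds.specimens), np.array(coords),
                          ds.semi_flags, list(ds.curve_order),
                          dict(ds.groups))
    pca2 = mo.shape_pca(mo.gpa_with_sliding(ds2))
    assert np.allclose(pca2.variance_explained, pca1.variance_explained,
                       atol=1e-8)
    k = min(pca1.scores.shape[1], 3)
    for j in range(k):
        assert np.allclose(np.abs(pca2.scores[:, j]),
                           np.abs(pca1.scores[:, j]), atol=1e-6)
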