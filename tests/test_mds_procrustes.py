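import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group

from gdmfuse import (
    ClassicalMDS,
    LabeledDistanceMatrix,
    MdsConfiguration,
    ProcrustesAlignment,
    alignment_diagnostics,
    apply_procrustes,
    classical_mds,
    distances_from_config,
    fit_procrustes,
    shared_dimension,
)


def config_from_points(pts, labels=None):
    """Build an MdsConfiguration directly from known coordinates."""
    pts = np.asarray(pts, dtype=float)
    labels = labels or [f"p{i}" for i in range(len(pts))]
    m = pts.shape[1]
    ones = np.ones(m)
    return MdsConfiguration(labels, pts, ones, np.cumsum(ones) / m,
                            np.cumsum(ones) / m)


class TestClassicalMds:
    def test_two_points_hand_eigendecomposition(self):
        # distance d: single axis, coords +-d/2, eigenvalue d^2/2
        D = LabeledDistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        cfg = classical_mds(D)
        assert cfg.n_axes == 1
        assert cfg.eigenvalues[0] == pytest.approx(4.5, abs=1e-12)
        np.testing.assert_allclose(sorted(cfg.coords.ravel()), [-1.5, 1.5],
                                   atol=1e-12)

    def test_unit_square_two_axes_and_reconstruction(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = LabeledDistanceMatrix(list("abcd"), squareform(pdist(pts)))
        cfg = classical_mds(D)
        assert cfg.n_axes == 2
        np.testing.assert_allclose(distances_from_config(cfg).d, D.d, atol=1e-9)

    def test_round_trip_on_euclidean_embeddable_matrix(self, square5):
        cfg = classical_mds(square5)
        np.testing.assert_allclose(distances_from_config(cfg).d, square5.d,
                                   atol=1e-8)

    def test_coincident_points_degenerate(self):
        D = LabeledDistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            classical_mds(D)

    def test_missing_entries_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="impute"):
            classical_mds(LabeledDistanceMatrix(["a", "b"], d))

    def test_eigenvalues_nonincreasing_and_explained_monotone(self, square5):
        cfg = classical_mds(square5)
        assert np.all(np.diff(cfg.eigenvalues) <= 1e-12)
        assert np.all(np.diff(cfg.cumulative_explained) >= 0)
        assert cfg.cumulative_explained_abs[-1] <= cfg.cumulative_explained[-1] + 1e-12

    def test_estimator_api(self, square5):
        est = ClassicalMDS(eig_rel_tol=1e-6)
        assert est.get_params()["eig_rel_tol"] == 1e-6
        coords = est.fit_transform(square5)
        assert coords.shape[0] == square5.n
        assert est.n_axes_ == coords.shape[1]


class TestSharedDimension:
    @pytest.mark.parametrize("na, nb, expected", [(59, 33, 33), (5, 5, 5), (1, 7, 1)])
    def test_min_of_retained_counts(self, na, nb, expected):
        rng = np.random.default_rng(0)
        cfgA = config_from_points(rng.normal(size=(na + 1, na)))
        cfgB = config_from_points(rng.normal(size=(nb + 1, nb)),
                                  labels=[f"q{i}" for i in range(nb + 1)])
        assert shared_dimension(cfgA, cfgB) == expected


class TestProcrustes:
    def test_identity_when_configs_equal(self):
        rng = np.random.default_rng(1)
        cfg = config_from_points(rng.normal(size=(6, 3)))
        T = fit_procrustes(cfg, cfg, zeta=3)
        assert T.scale_s == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation_R @ T.rotation_R.T, np.eye(3),
                                   atol=1e-10)
        np.testing.assert_allclose(T.translation_tau, 0.0, atol=1e-12)
        assert T.ssd_after == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_similarity_transform(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4))
        s_true = 2.5
        R_true = ortho_group.rvs(4, random_state=rng)
        tau_true = rng.normal(size=4)
        # construct Y so that s*Y*R + tau recovers X exactly
        Y = (X - tau_true) @ R_true.T / s_true
        cfgX = config_from_points(X)
        cfgY = config_from_points(Y)
        al = ProcrustesAlignment(zeta=4).fit(cfgX, cfgY)
        assert al.scale_ == pytest.approx(s_true, abs=1e-8)
        assert al.ssd_after_ < 1e-16
        np.testing.assert_allclose(al.transform(cfgY).coords, X, atol=1e-8)

    def test_two_anchor_exact_alignment(self):
        # a 2-point similarity always has an exact solution
        cfgX = config_from_points(np.array([[0.0, 0.0], [1.0, 0.0]]))
        cfgY = config_from_points(np.array([[2.0, 1.0], [2.0, 3.0]]))
        al = ProcrustesAlignment(zeta=2).fit(cfgX, cfgY)
        assert al.ssd_after_ == pytest.approx(0.0, abs=1e-20)

    def test_ssd_never_increased_by_calibration(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = rng.normal(size=(7, 3))
            Y = rng.normal(size=(7, 3))
            al = ProcrustesAlignment(zeta=3).fit(config_from_points(X),
                                                 config_from_points(Y))
            assert al.ssd_after_ <= al.ssd_before_ + 1e-12

    def test_insufficient_anchors(self):
        cfgX = config_from_points(np.zeros((2, 2)), labels=["a", "b"])
        cfgY = config_from_points(np.zeros((2, 2)), labels=["b", "c"])
        with pytest.raises(ValueError, match="anchor"):
            ProcrustesAlignment(zeta=2).fit(cfgX, cfgY)

    def test_apply_identity_and_translation(self):
        cfg = config_from_points(np.array([[0.0, 0.0], [1.0, 1.0]]))
        T = fit_procrustes(cfg, cfg, zeta=2)
        np.testing.assert_allclose(apply_procrustes(cfg, T).coords, cfg.coords,
                                   atol=1e-12)
        T.translation_tau = np.array([1.0, 0.0])
        T.rotation_R = np.eye(2)
        T.scale_s = 1.0
        shifted = apply_procrustes(cfg, T)
        np.testing.assert_allclose(shifted.coords[:, 0], cfg.coords[:, 0] + 1.0)

    def test_apply_then_inverse_restores(self):
        rng = np.random.default_rng(5)
        cfg = config_from_points(rng.normal(size=(5, 3)))
        s = 1.7
        R = ortho_group.rvs(3, random_state=rng)
        tau = rng.normal(size=3)
        from gdmfuse.procrustes import ProcrustesTransform

        T = ProcrustesTransform(s, R, tau, [], 0, 0, 0, 0)
        Tinv = ProcrustesTransform(1.0 / s, R.T, -(tau @ R.T) / s, [], 0, 0, 0, 0)
        back = apply_procrustes(apply_procrustes(cfg, T), Tinv)
        np.testing.assert_allclose(back.coords, cfg.coords, atol=1e-10)

    def test_distances_invariant_to_rigid_motion_scale_exact(self):
        rng = np.random.default_rng(6)
        cfg = config_from_points(rng.normal(size=(6, 3)))
        from gdmfuse.procrustes import ProcrustesTransform

        R = ortho_group.rvs(3, random_state=rng)
        T = ProcrustesTransform(2.0, R, rng.normal(size=3), [], 0, 0, 0, 0)
        d0 = distances_from_config(cfg).d
        d1 = distances_from_config(apply_procrustes(cfg, T)).d
        np.testing.assert_allclose(d1, 2.0 * d0, atol=1e-10)

    def test_transform_serialisation_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        cfgX = config_from_points(rng.normal(size=(5, 2)))
        cfgY = config_from_points(rng.normal(size=(5, 2)))
        T = fit_procrustes(cfgX, cfgY, zeta=2)
        path = tmp_path / "t.txt"
        T.save(path)
        from gdmfuse.procrustes import ProcrustesTransform

        back = ProcrustesTransform.load(path)
        assert back.scale_s == pytest.approx(T.scale_s, rel=1e-15)
        np.testing.assert_allclose(back.rotation_R, T.rotation_R, atol=1e-15)
        np.testing.assert_allclose(back.translation_tau, T.translation_tau,
                                   atol=1e-15)
        assert back.shared_labels == T.shared_labels


class TestAlignmentDiagnostics:
    def test_identical_matrices_zero(self, square5):
        d = alignment_diagnostics(square5, square5)
        assert d["bias_mean"] == 0.0 and d["ssd"] == 0.0

    def test_hand_computed_bias_and_ssd(self):
        # 3 shared labels; A pairs (0.1, 0.2, 0.3), Bx (0.2, 0.2, 0.3)
        A = LabeledDistanceMatrix(
            list("abc"),
            np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]),
        )
        Bx = LabeledDistanceMatrix(
            list("abc"),
            np.array([[0, 0.2, 0.2], [0.2, 0, 0.3], [0.2, 0.3, 0]]),
        )
        d = alignment_diagnostics(A, Bx)
        assert d["bias_mean"] == pytest.approx(0.1 / 3)
        assert d["ssd"] == pytest.approx(0.01)
        assert d["bias_relative"] == pytest.approx((0.1 / 3) / 0.2)

    def test_constant_offset_detected(self, square5):
        shifted = LabeledDistanceMatrix(
            list(square5.labels),
            np.where(np.eye(5, dtype=bool), 0.0, square5.d + 0.01),
        )
        d = alignment_diagnostics(square5, shifted)
        assert d["bias_mean"] == pytest.approx(0.01, abs=1e-12)


class TestCalibrationPipeline:
    def test_exact_scale_distortion_recovered(self):
        """A scale-2 platform distortion yields bias_relative near 1 before
        calibration and near-zero SSD after."""
        from gdmfuse import calibrate_and_merge, synth

        coords, _ = synth.simulate_latent_coords(20, dim=2, seed=8)
        distortion = synth.Distortion(scale=2.0)
        A, B, truth = synth.simulate_study_pair(coords, 12, 12, 4, distortion,
                                                seed=8)
        res = calibrate_and_merge(A, B)
        assert res.diagnostics_before["bias_relative"] == pytest.approx(1.0, abs=1e-9)
        assert res.aligner.ssd_after_ < 1e-12
        assert res.diagnostics_after["ssd"] < 1e-12

    def test_noisy_distortion_ssd_reduction_bounded(self):
        from gdmfuse import calibrate_and_merge, synth

        coords, _ = synth.simulate_latent_coords(20, dim=2, seed=9)
        distortion = synth.Distortion.random(2, scale=1.5, coord_noise_sd=0.1,
                                             seed=9)
        A, B, truth = synth.simulate_study_pair(coords, 12, 12, 4, distortion,
                                                seed=9)
        res = calibrate_and_merge(A, B)
        assert 0.0 < res.ssd_reduction_percent < 100.0

    def test_noise_monotonically_degrades_alignment(self):
        """Increasing platform noise increases the residual anchor SSD."""
        from gdmfuse import calibrate_and_merge, synth

        coords, _ = synth.simulate_latent_coords(20, dim=2, seed=10)
        ssds = []
        for sd in [0.0, 0.05, 0.2, 0.8]:
            acc = 0.0
            for seed in range(3):
                distortion = synth.Distortion.random(2, scale=1.5,
                                                     coord_noise_sd=sd, seed=seed)
                A, B, _ = synth.simulate_study_pair(coords, 12, 12, 4,
                                                    distortion, seed=seed)
                acc += calibrate_and_merge(A, B).aligner.ssd_after_
            ssds.append(acc / 3)
        assert ssds == sorted(ssds)
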