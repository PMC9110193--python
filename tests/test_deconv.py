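"""Solver tests: bSVD oracle equivalence, ADMM step algebra, PnP reduction,
dispatch provenance, and denoiser training basics."""

import numpy as np
import pytest

from ctpdeconv.core import (
    AIFCurve,
    CTPSeries,
    TimeGrid,
    build_operator,
    estimate_baseline,
)
from ctpdeconv.deconv import (
    ADMMConfig,
    ADMMState,
    BSVDConfig,
    DenoiserSpec,
    RegularizerSpec,
    admm_step_classic,
    admm_step_pnp,
    bsvd_deconvolve,
    deconvolve,
    train_denoiser,
)
from ctpdeconv.denoise import ZeroDenoiser
from ctpdeconv.errors import (
    ConfigurationError,
    DivergenceError,
    SingularOperatorError,
    UsageError,
)
from ctpdeconv.phantom import make_training_pairs

from conftest import random_aif


def series_from_curve(curve, grid):
    vox = np.asarray(curve, dtype=float).reshape(1, 1, 1, -1)
    return CTPSeries(voxels=vox, grid=grid, voxel_size=(1, 1, 1))


class TestBSVD:
    def test_impulse_aif_exact_recovery(self, grid8):
        aif = AIFCurve(values=np.eye(8)[0], grid=grid8)
        rng = np.random.default_rng(1)
        k_true = rng.uniform(0, 1, 8)
        data = k_true.copy()  # impulse AIF, dt 1: data == k
        res = bsvd_deconvolve(
            series_from_curve(data, grid8), aif, BSVDConfig(truncation_fraction=0.0)
        )
        assert np.allclose(res.values.ravel(), k_true, rtol=1e-8, atol=1e-10)

    def test_known_four_frame_example(self):
        grid = TimeGrid(dt=1.0, n_frames=4)
        aif = AIFCurve(values=[0, 2, 1, 0], grid=grid)
        res = bsvd_deconvolve(
            series_from_curve([0, 6, 5, 1], grid), aif, BSVDConfig(truncation_fraction=0.0)
        )
        assert np.allclose(res.values.ravel(), [3, 1, 0, 0], atol=1e-9)

    def test_zero_tissue_curve_gives_zero_residue(self, grid8):
        res = bsvd_deconvolve(
            series_from_curve(np.zeros(8), grid8), random_aif(grid8), BSVDConfig()
        )
        assert np.allclose(res.values, 0.0)

    def test_all_zero_aif_raises(self, grid8):
        aif = AIFCurve(values=np.zeros(8), grid=grid8)
        with pytest.raises(SingularOperatorError):
            bsvd_deconvolve(series_from_curve(np.ones(8), grid8), aif)

    @pytest.mark.parametrize("n_frames", [8, 12, 16])
    def test_matches_dense_pseudo_inverse(self, n_frames):
        # independent oracle: lstsq on the padded dense operator
        grid = TimeGrid(dt=1.0, n_frames=n_frames)
        rng = np.random.default_rng(n_frames)
        # bolus and residue each supported on the first half of the window,
        # so the full linear convolution fits inside the acquisition
        aif_vals = np.zeros(n_frames)
        aif_vals[: n_frames // 2] = rng.uniform(0.1, 1.0, n_frames // 2)
        aif = AIFCurve(values=aif_vals, grid=grid)
        k_true = np.zeros(n_frames)
        k_true[: n_frames // 2] = rng.uniform(0, 1, n_frames // 2)
        op = build_operator(aif, 2)
        data = op.apply(op.pad(k_true))[:n_frames]
        res = bsvd_deconvolve(
            series_from_curve(data, grid), aif, BSVDConfig(truncation_fraction=0.0)
        )
        k_oracle = np.linalg.lstsq(op.matrix, op.pad(data), rcond=None)[0][:n_frames]
        assert np.linalg.norm(res.values.ravel() - k_oracle) <= 1e-6 * np.linalg.norm(k_oracle)
        # forward re-convolution consistency
        recon = op.apply(op.pad(res.values.ravel()))[:n_frames]
        assert np.linalg.norm(recon - data) <= 1e-6 * np.linalg.norm(data)


def toy_problem():
    grid = TimeGrid(dt=1.0, n_frames=3)
    aif = AIFCurve(values=[1.0, 0.5, 0.2], grid=grid)
    op = build_operator(aif, pad_factor=1)
    rng = np.random.default_rng(0)
    d = rng.normal(size=3)
    state = ADMMState(
        u=rng.normal(size=3), z=rng.normal(size=3), lam=rng.normal(size=3)
    )
    return op, d, state


class TestClassicStep:
    def test_zero_kappa_leaves_multiplier_unchanged(self):
        op, d, state = toy_problem()
        cfg = ADMMConfig(n_iter=3, chi_tilde=0.25, b_su_tilde=0.5, kappa=0.0)
        reg = RegularizerSpec(kind="tikhonov", weight=0.1)
        lam0 = state.lam.copy()
        for _ in range(3):
            state = admm_step_classic(state, op, d, cfg, reg)
        assert np.array_equal(state.lam, lam0)

    def test_consistent_state_is_fixed_point(self):
        op, _, _ = toy_problem()
        k = np.array([0.4, 0.1, 0.05])
        d = op.apply(k)
        state = ADMMState(u=k.copy(), z=k.copy(), lam=np.zeros(3))
        cfg = ADMMConfig(n_iter=1, chi_tilde=0.25, b_su_tilde=0.5, kappa=0.5)
        reg = RegularizerSpec(kind="tikhonov", weight=0.0)
        out = admm_step_classic(state, op, d, cfg, reg)
        assert np.allclose(out.u, k, atol=1e-12)
        assert np.allclose(out.z, k, atol=1e-12)
        assert np.allclose(out.lam, 0.0, atol=1e-12)

    def test_single_step_matches_hand_evaluated_formulas(self):
        # all step parameters 0.5 (so chi_tilde = b_su*chi = 0.25), Tikhonov
        op, d, state = toy_problem()
        b_su = b_sz = chi = kappa = alpha = 0.5
        cfg = ADMMConfig(
            n_iter=1, chi_tilde=b_su * chi, b_su_tilde=b_su, b_sz=b_sz, kappa=kappa
        )
        reg = RegularizerSpec(kind="tikhonov", weight=alpha)
        u, z, lam = state.u.copy(), state.z.copy(), state.lam.copy()
        N = op.matrix
        u1 = (1 - b_su * chi) * u + b_su * chi * (z - lam) - b_su * (N.T @ (N @ u - d))
        z1 = (1 - b_su * chi) * z + b_sz * chi * (u1 + lam) - alpha * z
        lam1 = lam + kappa * (u1 - z1)
        out = admm_step_classic(state, op, d, cfg, reg)
        assert np.allclose(out.u, u1, atol=1e-12)
        assert np.allclose(out.z, z1, atol=1e-12)
        assert np.allclose(out.lam, lam1, atol=1e-12)

    def test_divergent_iterate_reported_with_index(self):
        op, d, state = toy_problem()
        cfg = ADMMConfig(n_iter=2, chi_tilde=0.25, b_su_tilde=0.5)
        reg = RegularizerSpec(kind="tikhonov", weight=0.0)
        with pytest.raises(DivergenceError) as err:
            admm_step_classic(state, op, d * np.nan, cfg, reg)
        assert err.value.iteration == 1


class TestPnPStep:
    def test_zero_denoiser_reduces_to_classic_exactly(self):
        # binary-exact parameters so both parameterisations round identically
        op, d, state = toy_problem()
        cfg = ADMMConfig(
            n_iter=12, chi_tilde=0.125, b_su_tilde=0.25, b_sz=0.25, kappa=0.5,
            alpha_tilde=0.75,
        )
        reg0 = RegularizerSpec(kind="tikhonov", weight=0.0)
        sp = ADMMState(u=state.u.copy(), z=state.z.copy(), lam=state.lam.copy())
        sc = ADMMState(u=state.u.copy(), z=state.z.copy(), lam=state.lam.copy())
        zero = ZeroDenoiser()
        for _ in range(12):
            sp = admm_step_pnp(sp, op, d, cfg, zero)
            sc = admm_step_classic(sc, op, d, cfg, reg0)
            assert np.array_equal(sp.u, sc.u)
            assert np.array_equal(sp.z, sc.z)
            assert np.array_equal(sp.lam, sc.lam)

    def test_chi_one_data_consistent_u_copies_z(self):
        op, _, _ = toy_problem()
        k = np.array([0.4, 0.1, 0.05])
        d = op.apply(k)
        state = ADMMState(u=k.copy(), z=np.array([1.0, 2.0, 3.0]), lam=np.zeros(3))
        cfg = ADMMConfig(n_iter=1, chi_tilde=1.0, b_su_tilde=0.5)
        out = admm_step_pnp(state, op, d, cfg, ZeroDenoiser())
        assert np.allclose(out.u, state.z, atol=1e-12)

    def test_schedule_exhaustion_raises(self):
        op, d, state = toy_problem()
        cfg = ADMMConfig(n_iter=1, chi_tilde=0.25, b_su_tilde=0.1)
        state = admm_step_pnp(state, op, d, cfg, ZeroDenoiser())
        with pytest.raises(ConfigurationError):
            admm_step_pnp(state, op, d, cfg, ZeroDenoiser())

    def test_gap_norm_decreases_on_noiseless_phantom(self, small_noiseless):
        series, aif, _ = small_noiseless
        sub = estimate_baseline(series)
        result = deconvolve(sub, aif, method="admm_tv")
        gaps = np.asarray(result.diagnostics["gap_norms"])
        assert gaps[-1] < gaps[0]
        assert np.all(np.diff(gaps[-5:]) <= 1e-9 * gaps.max())


class TestADMMConfig:
    def test_schedule_length_must_match(self):
        with pytest.raises(ConfigurationError):
            ADMMConfig(n_iter=3, chi_tilde=[0.2, 0.2])

    def test_chi_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            ADMMConfig(n_iter=2, chi_tilde=1.5)

    def test_for_operator_scales_fidelity_step(self, grid8):
        op = build_operator(random_aif(grid8), 2)
        cfg = ADMMConfig.for_operator(op)
        smax = np.linalg.norm(op.matrix, 2)
        assert cfg.b_su_tilde[0] == pytest.approx(0.9 / smax**2)


class TestDispatch:
    def test_bsvd_dispatch_matches_direct_call(self, small_noiseless):
        series, aif, _ = small_noiseless
        sub = estimate_baseline(series)
        direct = bsvd_deconvolve(sub, aif, BSVDConfig())
        via = deconvolve(sub, aif, method="bsvd")
        assert np.array_equal(direct.values, via.residue.values)
        assert via.provenance["method"] == "bsvd"

    def test_default_adcnn_reports_twelve_iterations(self, small_noiseless):
        series, aif, _ = small_noiseless
        sub = estimate_baseline(series)
        with pytest.warns(UserWarning, match="falling back"):
            result = deconvolve(sub, aif, method="adcnn")
        assert result.provenance["iterations"] == 12

    def test_default_denoiser_architecture(self):
        spec = DenoiserSpec(kind="residual_cnn")
        assert spec.n_residual_blocks == 7
        assert spec.n_filters == 15
        assert spec.kernel_size == 3

    def test_unknown_method_rejected(self, small_noiseless):
        series, aif, _ = small_noiseless
        with pytest.raises(UsageError):
            deconvolve(estimate_baseline(series), aif, method="wiener")


class TestTrainDenoiser:
    @pytest.fixture()
    def tiny_spec(self):
        return DenoiserSpec(kind="residual_cnn", n_residual_blocks=2, n_filters=4)

    def test_degenerate_clean_pairs_drive_residual_to_zero(self):
        # start from a perturbed net (non-zero residual prediction); training
        # on identical (clean, clean) pairs must push the residual toward 0
        from ctpdeconv.nn import ResidualCNN, train

        rng = np.random.default_rng(0)
        clean = rng.normal(size=(8, 16, 16))
        net = ResidualCNN(n_residual_blocks=2, n_filters=4, seed=1)
        net.params[-1][0] += rng.normal(0, 0.2, net.params[-1][0].shape).astype(
            np.float32
        )
        result = train(clean, clean, net, epochs=3, seed=1)
        assert result.loss_trace[-1] < result.loss_trace[0]

    def test_weights_round_trip(self, tmp_path, tiny_spec, small_spec):
        noisy, clean = make_training_pairs(
            small_spec, 8, seed=4, patch_size=16, mode="additive", sigma=0.001
        )
        den, _ = train_denoiser((noisy, clean), tiny_spec, epochs=2, seed=2)
        path = tmp_path / "weights.json"
        den.save(path)
        from ctpdeconv.denoise import CNNDenoiser

        loaded = CNNDenoiser.load(path)
        x = np.random.default_rng(5).normal(size=(16, 16))
        assert np.allclose(den.residual(x), loaded.residual(x), atol=1e-7)

    def test_empty_pairs_rejected(self, tiny_spec):
        with pytest.raises(UsageError):
            train_denoiser((np.empty((0, 8, 8)), np.empty((0, 8, 8))), tiny_spec)

    def test_training_deterministic_under_seed(self, tiny_spec):
        rng = np.random.default_rng(3)
        noisy = rng.normal(size=(6, 16, 16))
        clean = noisy + rng.normal(size=(6, 16, 16)) * 0.1
        _, t1 = train_denoiser((noisy, clean), tiny_spec, epochs=2, seed=9)
        _, t2 = train_denoiser((noisy, clean), tiny_spec, epochs=2, seed=9)
        assert t1 == t2
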