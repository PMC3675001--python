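"""M-step and EM-driver contracts for both models."""

import numpy as np
import pytest
from scipy.special import logsumexp

from maxcauses import (
    ModelParams,
    TruncationParams,
    bsc_update_W,
    evidence_rate,
    initialize,
    mca_responsibility,
    mca_update_W,
    run_em,
    sample_dataset,
    sparsity_terms,
    update_pi,
    update_sigma,
)
from maxcauses.inference import e_step
from maxcauses.models import log_joint
from maxcauses.synthetic import generate_bars_dataset, make_bars_params

from conftest import all_states


class TestSparsityTerms:
    def test_hand_computed_H2_gamma1(self):
        pi = 0.3
        t = sparsity_terms(pi, 2, 1)
        assert t.B_pi == pytest.approx((1 - pi) ** 2 + 2 * pi * (1 - pi))
        assert t.A_pi == pytest.approx(2 * pi * (1 - pi))

    def test_gamma_H_limits(self):
        t = sparsity_terms(0.2, 10, 10)
        assert t.B_pi == pytest.approx(1.0)
        assert t.A_pi == pytest.approx(2.0)

    def test_bounds(self):
        for pi in (0.05, 0.3, 0.7):
            for gamma in (1, 3, 5):
                t = sparsity_terms(pi, 8, gamma)
                assert 0 < t.B_pi <= 1
                assert 0 <= t.A_pi <= gamma * t.B_pi + 1e-12


class TestEvidenceRate:
    def test_anchor_values(self):
        assert evidence_rate(2.0) == pytest.approx(0.5)
        assert evidence_rate(10.0) >= 0.95

    def test_monotone_on_grid(self):
        e = np.linspace(0, 50, 200)
        lam = evidence_rate(e)
        assert np.all(np.diff(lam) >= 0)
        assert np.all((lam >= 0) & (lam < 1))


class TestMcaResponsibility:
    def test_single_active_unit_identity(self, rng):
        W = rng.standard_normal((5, 3)) + 3.0  # keep entries away from 0
        R = mca_responsibility(np.array([0, 1, 0]), W, 25)
        np.testing.assert_allclose(R[:, 1], 1.0, atol=1e-12)
        assert np.all(R[:, [0, 2]] == 0)

    def test_high_rho_concentrates_on_winner(self):
        W = np.array([[3.0, -2.0]])
        R = mca_responsibility(np.ones(2), W, 101)
        assert abs(R[0, 0] - 1.0) < 1e-6
        assert abs(R[0, 1]) < 1e-6

    def test_inactive_units_zero(self, rng):
        W = rng.standard_normal((4, 4))
        R = mca_responsibility(np.array([1, 0, 1, 0]), W, 11)
        assert np.all(R[:, [1, 3]] == 0)


class TestWUpdates:
    def test_mca_single_patch_point_posterior(self, rng):
        # posterior mass all on the singleton state of unit 0
        W = np.abs(rng.standard_normal((4, 2))) + 5.0
        params = ModelParams(W=W, sigma=0.05, pi=0.5, model_kind="MCA")
        y = W[:, 0] + 0.01
        stats = e_step(y[None, :], params, TruncationParams(2, 2))
        Wn = mca_update_W(y[None, :], stats, params, np.array([0]), rho=25,
                          learning_rate=False)
        np.testing.assert_allclose(Wn[:, 0], y, atol=1e-6)

    def test_mca_two_patches_weighted_mean(self):
        W = np.array([[5.0]])
        params = ModelParams(W=W, sigma=0.5, pi=0.5, model_kind="MCA")
        Y = np.array([[4.0], [6.0]])
        stats = e_step(Y, params, TruncationParams(1, 1))
        # force all mass on the singleton state for both patches
        stats.Pt[:, 0] = 0.0
        stats.Pt[:, 1] = 1.0
        stats.Pout[:] = 0.0
        Wn = mca_update_W(Y, stats, params, np.array([0, 1]), rho=25,
                          learning_rate=False)
        assert Wn[0, 0] == pytest.approx(5.0)

    def test_mca_generating_bars_are_fixed_point(self):
        # noiseless data with exact point posteriors on the true states
        params, gt = make_bars_params(seed=3, sigma=1e-9, model_kind="MCA")
        patches, S = generate_bars_dataset(gt, 400, seed=4)
        p = ModelParams(W=gt.W, sigma=1e-9, pi=gt.pi, model_kind="MCA")
        stats = e_step(patches.Y, p, TruncationParams(6, 4))
        keep = []
        for n in range(patches.N):
            active = set(np.flatnonzero(S[n]).tolist())
            if len(active) <= 4 and active <= set(stats.I[n].tolist()):
                # overwrite with the exact posterior: all mass on the truth
                template = np.zeros(stats.Z.shape[1], dtype=np.int8)
                for j, unit in enumerate(stats.I[n]):
                    template[j] = S[n, unit]
                k = np.flatnonzero((stats.Z == template).all(axis=1))[0]
                stats.Pt[n] = 0.0
                stats.Pt[n, k] = 1.0
                stats.Pout[n] = 0.0
                keep.append(n)
        keep = np.array(keep)
        Wn = mca_update_W(patches.Y, stats, p, keep, rho=25,
                          learning_rate=False)
        assert np.abs(Wn - gt.W).max() < 1e-6

    def test_bsc_single_unit_mean_patch(self, rng):
        Y = rng.standard_normal((20, 3)) + 4.0
        params = ModelParams(W=np.full((3, 1), 4.0), sigma=0.5, pi=0.999999,
                             model_kind="BSC")
        stats = e_step(Y, params, TruncationParams(1, 1))
        # pi ~ 1 puts essentially all mass on the active singleton
        Wn = bsc_update_W(Y, stats, params, np.arange(20))
        np.testing.assert_allclose(Wn[:, 0], Y.mean(axis=0), atol=1e-4)

    def test_bsc_noiseless_recovery(self, rng):
        D, H, N = 6, 3, 60
        Wt = rng.standard_normal((D, H)) * 3
        gen = ModelParams(W=Wt, sigma=1e-9, pi=0.4, model_kind="BSC")
        patches, S = sample_dataset(gen, N, seed=9)
        stats = e_step(patches.Y, gen, TruncationParams(H, H))
        Wn = bsc_update_W(patches.Y, stats, gen, np.arange(N))
        np.testing.assert_allclose(Wn, Wt, atol=1e-6)

    def test_bsc_update_invariant_to_patch_order(self, rng):
        D, H, N = 5, 3, 30
        params = ModelParams(W=rng.standard_normal((D, H)), sigma=0.7, pi=0.3,
                             model_kind="BSC")
        Y = rng.standard_normal((N, D))
        stats = e_step(Y, params, TruncationParams(H, H))
        W1 = bsc_update_W(Y, stats, params, np.arange(N))
        perm = rng.permutation(N)
        stats2 = e_step(Y[perm], params, TruncationParams(H, H))
        W2 = bsc_update_W(Y[perm], stats2, params, np.arange(N))
        np.testing.assert_allclose(W1, W2, atol=1e-9)


class TestSigmaUpdate:
    def test_recovers_generating_noise(self, rng):
        D, H, N = 8, 3, 600
        Wt = rng.standard_normal((D, H)) * 4
        gen = ModelParams(W=Wt, sigma=2.0, pi=0.3, model_kind="BSC")
        patches, _ = sample_dataset(gen, N, seed=11)
        stats = e_step(patches.Y, gen, TruncationParams(H, H))
        sig = update_sigma(patches.Y, stats, gen, np.arange(N))
        se = 2.0 / np.sqrt(2 * N * D)  # chi-square std error of sigma-hat
        assert abs(sig - 2.0) < 3 * se + 0.05

    def test_zero_residual_floors(self, rng):
        D, H = 4, 2
        Wt = np.abs(rng.standard_normal((D, H))) + 2
        gen = ModelParams(W=Wt, sigma=1e-9, pi=0.4, model_kind="MCA")
        patches, _ = sample_dataset(gen, 30, seed=2)
        stats = e_step(patches.Y, gen, TruncationParams(H, H))
        sig = update_sigma(patches.Y, stats, gen, np.arange(30))
        scale = np.sqrt(np.mean(patches.Y**2))
        assert sig <= 2e-4 * scale


class TestPiUpdate:
    def test_gamma_H_closed_form(self):
        assert update_pi(2.0, 10, 10) == pytest.approx(0.2)

    def test_hand_case_H2_gamma1(self):
        s_bar = 0.6
        pi = update_pi(s_bar, 2, 1)
        t = sparsity_terms(pi, 2, 1)
        assert abs(t.A_pi / t.B_pi - s_bar) < 1e-8

    @pytest.mark.parametrize("H,gamma,s_bar", [
        (10, 4, 1.5), (10, 4, 2.0), (8, 3, 0.7), (6, 2, 1.2), (12, 5, 3.0),
    ])
    def test_stationarity_residual_on_grid(self, H, gamma, s_bar):
        pi = update_pi(s_bar, H, gamma)
        t = sparsity_terms(pi, H, gamma)
        assert abs(t.A_pi / t.B_pi - s_bar) < 1e-8


class TestInitialize:
    def test_one_active_component_on_average(self, rng):
        Y = rng.standard_normal((40, 6))
        assert initialize(Y, 10, seed=0).pi == pytest.approx(0.1)

    def test_sigma_is_mean_pixel_variance(self, rng):
        Y = rng.standard_normal((50, 7)) * 3
        p = initialize(Y, 4, seed=0)
        assert p.sigma**2 == pytest.approx(np.mean(Y.var(axis=0)))

    def test_columns_are_mean_plus_seeded_noise(self, rng):
        Y = np.full((20, 5), 2.5)
        a = initialize(Y, 3, seed=4)
        b = initialize(Y, 4, seed=4)
        np.testing.assert_array_equal(a.W, b.W[:, :3] * 0 + a.W)  # determinism
        np.testing.assert_allclose(a.W.mean(axis=1), 2.5, atol=1.5)


class TestRunEM:
    def test_zero_iterations_returns_initialization(self, rng):
        Y = rng.standard_normal((20, 4))
        params, trace = run_em(Y, "BSC", 3, TruncationParams(3, 3), 0, seed=1)
        expected = initialize(Y, 3, seed=1, model_kind="BSC")
        np.testing.assert_array_equal(params.W, expected.W)
        assert len(trace) == 0

    def test_deterministic_given_seed(self, rng):
        params, gt = make_bars_params(b=3, seed=0, model_kind="BSC")
        Y, _ = generate_bars_dataset(gt, 100, seed=1)
        a, _ = run_em(Y, "BSC", 6, TruncationParams(4, 3), 5, seed=2)
        b, _ = run_em(Y, "BSC", 6, TruncationParams(4, 3), 5, seed=2)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.pi == b.pi and a.sigma == b.sigma

    def test_resume_matches_uninterrupted(self, rng):
        params, gt = make_bars_params(b=3, seed=5, model_kind="BSC")
        Y, _ = generate_bars_dataset(gt, 100, seed=6)
        trunc = TruncationParams(4, 3)
        checkpoints = {}
        full, _ = run_em(
            Y, "BSC", 6, trunc, 9, seed=3,
            on_iteration=lambda t, p, tr: checkpoints.__setitem__(t, p),
        )
        resumed, _ = run_em(Y, "BSC", 6, trunc, 9, seed=3,
                            init_params=checkpoints[6], start_iteration=7)
        np.testing.assert_array_equal(full.W, resumed.W)

    def test_bsc_exact_em_monotone(self, rng):
        # no truncation: the recorded free energy is the exact likelihood
        D, H, N = 6, 3, 40
        Wt = rng.standard_normal((D, H)) * 2
        gen = ModelParams(W=Wt, sigma=1.0, pi=0.3, model_kind="BSC")
        patches, _ = sample_dataset(gen, N, seed=8)
        _, trace = run_em(patches, "BSC", H, TruncationParams(H, H), 30, seed=9)
        F = np.array(trace.free_energy)
        assert np.all(np.diff(F) >= -1e-9)

    def test_mca_em_improves_likelihood_run_level(self, rng):
        # MCA's W step is a fixed-point update, so only run-level
        # improvement of the exact likelihood is guaranteed in practice
        D, H, N = 4, 3, 60
        Wt = np.abs(rng.standard_normal((D, H))) * 3 + 1
        gen = ModelParams(W=Wt, sigma=0.5, pi=0.3, model_kind="MCA")
        patches, _ = sample_dataset(gen, N, seed=13)

        def loglik(p):
            return float(sum(
                logsumexp([log_joint(y, s, p) for s in all_states(H)])
                for y in patches.Y
            ))

        init = initialize(patches.Y, H, seed=14, model_kind="MCA")
        learned, trace = run_em(patches, "MCA", H, TruncationParams(H, H),
                                25, seed=14)
        assert np.all(np.isfinite(trace.free_energy))
        assert loglik(learned) > loglik(init)
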