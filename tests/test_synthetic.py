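"""Ground-truth generators: OU weights, rectified GP, toy model, RNN."""

import numpy as np
import pytest

from slicerank.core import UsageError
from slicerank.synthetic import (
    FeedforwardParams,
    RNNParams,
    build_rnn_connectivity,
    desk_rnn_params,
    generate_toy_feedforward,
    kappa_and_zeta,
    sample_rectified_gp,
    sigma3_for_zeta,
    simulate_ou_weights,
    simulate_rnn,
    squared_exponential_kernel,
)


class TestOUWeights:
    def test_zero_noise_at_target_is_constant(self):
        p = FeedforwardParams(N=5, K=20, sigma_ou=0.0, mu_go=1.0)
        w = simulate_ou_weights(p, "go")
        assert np.allclose(w, 1.0)

    def test_zero_noise_matches_exponential_relaxation(self):
        p = FeedforwardParams(N=4, K=30, sigma_ou=0.0, clamp=(-10, 10))
        rng = np.random.default_rng(0)
        alphas = np.array([0.3, 0.5, 0.6, 0.8])
        w = simulate_ou_weights(p, "go", rng, alphas)
        grid = p.trial_grid()
        expected = p.mu_go + (1.0 - p.mu_go) * np.exp(-np.outer(alphas, grid))
        assert np.allclose(w, expected, atol=1e-12)

    def test_defaults_clamped_to_saturation(self):
        w = simulate_ou_weights(FeedforwardParams(seed=3), "go")
        assert w.min() >= 0.0 and w.max() <= 2.0

    def test_deterministic_under_seed(self):
        p = FeedforwardParams(seed=9)
        assert np.array_equal(simulate_ou_weights(p, "no"), simulate_ou_weights(p, "no"))


class TestRectifiedGP:
    def test_kernel_unit_diagonal(self):
        t = np.linspace(0, 10, 7)
        k = squared_exponential_kernel(t, 0.7)
        assert np.allclose(np.diag(k), 1.0)

    def test_outputs_nonnegative(self):
        x = sample_rectified_gp(FeedforwardParams(T=30, K=50, seed=2))
        assert (x >= 0).all()

    def test_unrectified_covariance_matches_kernel(self):
        """Monte-Carlo check of the pre-rectification covariance at two
        fixed times against the squared-exponential kernel."""
        p = FeedforwardParams(T=10, K=1, seed=4)
        t = p.time_grid()
        cov = squared_exponential_kernel(t, p.gp_lengthscale)
        cov[np.diag_indices_from(cov)] += 1e-8
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(11)
        n = 10_000
        draws = L @ rng.standard_normal((10, n))
        i, j = 2, 3
        est = np.mean(draws[i] * draws[j])
        se = np.std(draws[i] * draws[j]) / np.sqrt(n)
        assert abs(est - cov[i, j]) < 3 * se


class TestToyFeedforward:
    def test_sources_sum_exactly(self):
        b = generate_toy_feedforward(FeedforwardParams(N=10, T=20, K=15, seed=1))
        assert np.array_equal(b.noiseless, b.sources["sensory"] + b.sources["topdown"])

    def test_sources_are_slice_rank_one(self):
        b = generate_toy_feedforward(FeedforwardParams(N=10, T=20, K=15, seed=1))
        # sensory is time-slicing: its time unfolding is rank 1
        s_unfold = b.sources["sensory"].transpose(1, 0, 2).reshape(20, -1)
        sv = np.linalg.svd(s_unfold, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]
        td_unfold = b.sources["topdown"].reshape(10, -1)
        sv = np.linalg.svd(td_unfold, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]

    def test_default_dims(self):
        p = FeedforwardParams()
        assert (p.N, p.T, p.K) == (80, 90, 100)

    def test_observation_noise_raises_zero_rank_loss_by_variance(self):
        p = FeedforwardParams(N=20, T=30, K=40, seed=5, noise_std=0.5)
        b = generate_toy_feedforward(p)
        noise = b.tensor.values - b.noiseless
        assert np.var(noise) == pytest.approx(0.25, rel=0.05)

    def test_reproducible(self):
        a = generate_toy_feedforward(FeedforwardParams(N=8, T=10, K=12, seed=7))
        b = generate_toy_feedforward(FeedforwardParams(N=8, T=10, K=12, seed=7))
        assert np.array_equal(a.tensor.values, b.tensor.values)
        assert np.array_equal(a.trial_labels, b.trial_labels)


class TestRNN:
    def test_connectivity_schur_structure(self):
        p = desk_rnn_params(seed=0)
        rng = np.random.default_rng(0)
        W, U, B = build_rnn_connectivity(p, rng)
        assert np.allclose(U.T @ U, np.eye(p.N), atol=1e-10)
        S = U.T @ W @ U
        h = p.N // 2
        assert np.allclose(np.diag(S), -p.lam, atol=1e-10)
        assert np.allclose(np.diag(S[:h, :h], k=-1), p.lam + p.eps, atol=1e-10)
        assert np.allclose(S[:h, h:], 0.0, atol=1e-10)

    def test_sequential_propagation(self):
        """Noiseless mode amplitudes peak later and later along the chain."""
        b = simulate_rnn(desk_rnn_params(seed=5))
        rng = np.random.default_rng(5)
        _, U, _ = build_rnn_connectivity(desk_rnn_params(seed=5), rng)
        modes = U.T @ b.sources["sequence"][:, :, 0]
        peaks = modes[:25].argmax(axis=1)
        assert (np.diff(peaks) >= 0).all()

    def test_noiseless_trials_with_equal_theta_share_sequences(self):
        p = desk_rnn_params(seed=2, K=6)
        b = simulate_rnn(p)
        assert np.array_equal(b.tensor.values, b.noiseless)
        seq = b.sources["sequence"]
        # conditions alternate 0, pi/2 -> same-condition sequence parts equal
        assert np.allclose(seq[:, :, 0], seq[:, :, 2], atol=1e-12)
        assert np.allclose(seq[:, :, 1], seq[:, :, 3], atol=1e-12)

    def test_noisy_mean_converges_to_noiseless(self):
        """E[Y] = X for the identity readout: averaging noisy repetitions
        of one trial (same connectivity/inputs, fresh intrinsic-noise
        streams) approaches the deterministic trial."""
        base = RNNParams(N=20, T=30, K=1, lam=3.0, eps=1.0, horizon=5.0, seed=3)
        clean = simulate_rnn(base).noiseless[:, :, 0]
        n_rep = 200
        acc = np.zeros_like(clean)
        for s in range(n_rep):
            p = RNNParams(N=20, T=30, K=1, lam=3.0, eps=1.0, horizon=5.0,
                          seed=3, sigma1=0.3, noise_seed=1000 + s)
            acc += simulate_rnn(p).tensor.values[:, :, 0]
        mean = acc / n_rep
        spread = np.abs(mean - clean).max()
        # intrinsic noise integrates over the trial; allow a generous
        # Monte-Carlo band around the diffusion scale
        mc_scale = 0.3 * np.sqrt(base.horizon) / np.sqrt(n_rep)
        assert spread < 6 * mc_scale

    def test_blowup_detected(self):
        # dt * (1 + lam) > 2 makes the Euler step unstable
        with pytest.raises(Exception):
            simulate_rnn(RNNParams(N=20, T=30, K=2, lam=3.0, eps=1.0, horizon=30.0))

    def test_odd_n_rejected(self):
        with pytest.raises(UsageError):
            RNNParams(N=21)


class TestKappaZeta:
    def test_perfect_reconstruction(self, rng):
        y = rng.normal(size=(4, 5, 6))
        x = y - 0.1
        k, z = kappa_and_zeta(y, y, x)
        assert k == pytest.approx(1.0)

    def test_grand_mean_reconstruction_scores_zero(self, rng):
        y = rng.normal(size=(4, 5, 6))
        k, _ = kappa_and_zeta(y, np.full_like(y, y.mean()), y)
        assert k == pytest.approx(0.0)

    def test_noiseless_data_has_zero_zeta(self, rng):
        y = rng.normal(size=(4, 5, 6))
        _, z = kappa_and_zeta(y, y, y)
        assert z == 0.0

    def test_zero_variance_rejected(self):
        y = np.ones((2, 2, 2))
        with pytest.raises(UsageError):
            kappa_and_zeta(y, y, y)

    def test_sigma3_calibration(self, rng):
        x = rng.normal(size=(20, 20, 20))
        s3 = sigma3_for_zeta(x, 0.3)
        y = x + s3 * rng.standard_normal(x.shape)
        _, z = kappa_and_zeta(y, y, x)
        assert z == pytest.approx(0.3, abs=0.03)
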