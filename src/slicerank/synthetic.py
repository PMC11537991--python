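"""Ground-truth simulators used to validate the decomposition.

Two generative models are provided:

* A **feedforward go/no-go model of perceptual learning**: linear neurons
  summing (i) a stimulus-locked sensory input with a Gaussian-bump
  temporal profile whose per-neuron weights potentiate/depress over
  trials via a clamped Ornstein-Uhlenbeck process, and (ii) a top-down
  modulatory input drawn as a rectified Gaussian process over time with
  fixed uniform neural weights.  The resulting tensor is the exact sum of
  a time-slicing source (sensory) and a neuron-slicing source (top-down),
  hence has slice rank 2.

* A **linear RNN generating condition-dependent sequences**: connectivity
  built from a Schur parameterization ``W = U S U^T`` with two
  block-diagonal shift chains, so that an initial state at the head of a
  chain propagates as a stereotyped sequence, while a 2-D input enters at
  the chain tails.  Noiseless activity decomposes exactly into two
  trial-slicing components (one per sequence, loadings cos/sin of the
  condition angle) plus two neuron-slicing components (the input modes).
  Intrinsic, input, and observation noise can be injected independently;
  with the identity readout the noisy observations have mean equal to
  the noiseless tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataTensor, SliceRankError, UsageError


class SimulationError(SliceRankError, RuntimeError):
    pass


@dataclass
class GroundTruthBundle:
    """A synthetic tensor together with its generating sources."""

    tensor: DataTensor  # observed (noise included if any)
    noiseless: np.ndarray  # exact sum of the sources
    sources: dict[str, np.ndarray]
    params: dict
    trial_labels: np.ndarray


# ---------------------------------------------------------------------------
# Feedforward go/no-go toy model


@dataclass
class FeedforwardParams:
    N: int = 80
    T: int = 90
    K: int = 100
    mu_go: float = 2.0
    mu_no: float = 0.0
    sigma_ou: float = 1.3
    alpha_range: tuple[float, float] = (0.2, 0.8)
    clamp: tuple[float, float] = (0.0, 2.0)
    gp_lengthscale: float = float(np.sqrt(0.5))
    same_stimulus_prob: float = 0.5
    time_span: tuple[float, float] = (0.0, 10.0)
    trial_span: tuple[float, float] = (0.0, 10.0)
    stimulus_center: float = 4.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.same_stimulus_prob <= 1):
            raise UsageError("same_stimulus_prob must lie in [0, 1]")
        if self.gp_lengthscale <= 0:
            raise UsageError("gp_lengthscale must be positive")
        if self.alpha_range[0] <= 0 or self.alpha_range[1] < self.alpha_range[0]:
            raise UsageError("alpha_range must be a positive increasing interval")

    def time_grid(self) -> np.ndarray:
        return np.linspace(*self.time_span, self.T)

    def trial_grid(self) -> np.ndarray:
        return np.linspace(*self.trial_span, self.K)


def simulate_ou_weights(
    params: FeedforwardParams,
    stimulus: str,
    rng: np.random.Generator | None = None,
    alphas: np.ndarray | None = None,
) -> np.ndarray:
    """Clamped Ornstein-Uhlenbeck weight trajectories, shape (N, K).

    Each neuron relaxes from 1 toward the stimulus target (potentiation
    to ``mu_go`` or depression to ``mu_no``) at its own rate
    ``alpha_n ~ U(alpha_range)``, with diffusion ``sigma_ou``; each exact
    OU step is followed by clamping to the saturation interval.
    """
    if stimulus not in ("go", "no"):
        raise UsageError("stimulus must be 'go' or 'no'")
    rng = rng or np.random.default_rng(params.seed)
    if alphas is None:
        alphas = rng.uniform(*params.alpha_range, size=params.N)
    mu = params.mu_go if stimulus == "go" else params.mu_no
    grid = params.trial_grid()
    w = np.ones(params.N)
    out = np.empty((params.N, params.K))
    lo, hi = params.clamp
    out[:, 0] = np.clip(w, lo, hi)
    w = out[:, 0].copy()
    for k in range(1, params.K):
        dk = grid[k] - grid[k - 1]
        decay = np.exp(-alphas * dk)
        if params.sigma_ou > 0:
            step_sd = params.sigma_ou * np.sqrt(
                (1 - np.exp(-2 * alphas * dk)) / (2 * alphas)
            )
            noise = step_sd * rng.standard_normal(params.N)
        else:
            noise = 0.0
        w = mu + (w - mu) * decay + noise
        np.clip(w, lo, hi, out=w)
        out[:, k] = w
    return out


def squared_exponential_kernel(t: np.ndarray, lengthscale: float) -> np.ndarray:
    d = t[:, None] - t[None, :]
    return np.exp(-(d**2) / (2 * lengthscale**2))


def sample_rectified_gp(
    params: FeedforwardParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rectified zero-mean GP draws over the time grid, one per trial;
    shape (T, K)."""
    rng = rng or np.random.default_rng(params.seed)
    t = params.time_grid()
    cov = squared_exponential_kernel(t, params.gp_lengthscale)
    cov[np.diag_indices_from(cov)] += 1e-8
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise SimulationError(f"GP covariance not positive definite: {err}") from err
    draws = L @ rng.standard_normal((params.T, params.K))
    return np.maximum(0.0, draws)


def generate_toy_feedforward(params: FeedforwardParams | None = None) -> GroundTruthBundle:
    """The go/no-go simulation: X = I^S + I^TD, exact slice rank 2."""
    params = params or FeedforwardParams()
    rng = np.random.default_rng(params.seed)
    # trial labels: 1 = go; stays equal to the previous trial with prob P
    labels = np.empty(params.K, dtype=int)
    labels[0] = int(rng.random() < 0.5)
    for k in range(1, params.K):
        same = rng.random() < params.same_stimulus_prob
        labels[k] = labels[k - 1] if same else 1 - labels[k - 1]
    alphas = rng.uniform(*params.alpha_range, size=params.N)
    w_go = simulate_ou_weights(params, "go", rng, alphas)
    w_no = simulate_ou_weights(params, "no", rng, alphas)
    w_sens = np.where(labels[None, :] == 1, w_go, w_no)  # (N, K)
    t = params.time_grid()
    s = np.exp(-((t - params.stimulus_center) ** 2))  # bell-shaped activation
    x_td = sample_rectified_gp(params, rng)  # (T, K)
    w_td = rng.uniform(0.0, 1.0, size=params.N)
    sensory = s[None, :, None] * w_sens[:, None, :]  # time-slicing source
    topdown = w_td[:, None, None] * x_td[None, :, :]  # neuron-slicing source
    clean = sensory + topdown
    observed = clean
    if params.noise_std > 0:
        observed = clean + params.noise_std * rng.standard_normal(clean.shape)
    return GroundTruthBundle(
        tensor=DataTensor(observed),
        noiseless=clean,
        sources={"sensory": sensory, "topdown": topdown},
        params={"model": "feedforward", **params.__dict__},
        trial_labels=labels,
    )


# ---------------------------------------------------------------------------
# Linear RNN with embedded sequences


@dataclass
class RNNParams:
    N: int = 200
    T: int = 200
    K: int = 200
    lam: float = 24.0  # leak of the Schur chain modes
    eps: float = 1.0  # feedforward gain surplus along the chain
    sigma1: float = 0.0  # intrinsic noise
    sigma2: float = 0.0  # input noise
    sigma3: float = 0.0  # observation noise
    horizon: float = 5.0  # trial length in units of the membrane time constant
    condition_angles: np.ndarray | None = None  # per-trial theta
    continuous_conditions: bool = False
    seed: int = 0
    # optional separate stream for the Wiener increments and observation
    # noise, so noisy repetitions of identical trials can be generated
    noise_seed: int | None = None

    def __post_init__(self):
        if self.N % 2:
            raise UsageError("N must be even (two Schur blocks)")
        if min(self.sigma1, self.sigma2, self.sigma3) < 0:
            raise UsageError("noise scales must be >= 0")
        if self.horizon <= 0 or self.T < 2:
            raise UsageError("positive horizon and T >= 2 required")

    @property
    def dt(self) -> float:
        return self.horizon / self.T


def desk_rnn_params(**overrides) -> RNNParams:
    """Small-scale preset (N = T = K = 60) with chain gains re-tuned so
    both sequences complete within the trial."""
    base = dict(N=60, T=60, K=60, lam=6.5, eps=1.0)
    base.update(overrides)
    return RNNParams(**base)


def build_rnn_connectivity(params: RNNParams, rng: np.random.Generator | None = None):
    """Schur-parameterized connectivity: W = U S U^T with two shift-chain
    blocks; the input matrix reads into the chain tails.

    Returns (W, U, B).  Sequence heads are columns 0 and N/2 of U; input
    modes are columns N/2 - 1 and N - 1.
    """
    rng = rng or np.random.default_rng(params.seed)
    N = params.N
    h = N // 2
    G = rng.standard_normal((N, N))
    U, _, _ = np.linalg.svd(G)
    block = (params.lam + params.eps) * np.eye(h, k=-1) - params.lam * np.eye(h)
    S = np.zeros((N, N))
    S[:h, :h] = block
    S[h:, h:] = block
    W = U @ S @ U.T
    B = np.stack([U[:, h - 1], U[:, N - 1]], axis=1)
    return W, U, B


def simulate_rnn(params: RNNParams | None = None) -> GroundTruthBundle:
    """Euler-Maruyama simulation of the coupled activity/input SDEs.

    Per trial, activity starts at ``cos(theta) U_1 + sin(theta) U_{N/2+1}``
    and evolves under leak, Schur-chain recurrence, and the 2-D input
    (whose own linear dynamics matrix is redrawn per trial, entries
    ``N(0, 1/2)``).  Returns the observed tensor Y (all noise applied),
    the noiseless tensor X (same per-trial parameters, all noise off),
    and the exact source split of X into the recurrent-sequence part and
    the input-driven part.
    """
    params = params or RNNParams()
    rng = np.random.default_rng(params.seed)
    N, T, K = params.N, params.T, params.K
    h = N // 2
    W, U, B = build_rnn_connectivity(params, rng)
    dt = params.dt
    if params.condition_angles is not None:
        thetas = np.asarray(params.condition_angles, dtype=np.float64)
        if thetas.shape != (K,):
            raise UsageError("condition_angles must have one angle per trial")
    elif params.continuous_conditions:
        thetas = rng.uniform(0.0, np.pi / 2, size=K)
    else:
        thetas = np.where(np.arange(K) % 2 == 0, 0.0, np.pi / 2)
    A_trial = rng.normal(0.0, np.sqrt(0.5), size=(K, 2, 2))
    u0_trial = rng.standard_normal((K, 2))
    noise_rng = rng if params.noise_seed is None else np.random.default_rng(params.noise_seed)

    X = np.empty((N, T, K))
    X_seq = np.empty((N, T, K))
    Y = np.empty((N, T, K))
    sq = np.sqrt(dt)
    limit = 1e6
    for k in range(K):
        c1, c2 = np.cos(thetas[k]), np.sin(thetas[k])
        x0 = c1 * U[:, 0] + c2 * U[:, h]
        # deterministic pass (noiseless X) and its recurrent-only twin
        x = x0.copy()
        xs = x0.copy()
        u = u0_trial[k].copy()
        A = A_trial[k]
        xn = x0.copy()
        un = u0_trial[k].copy()
        noisy = params.sigma1 > 0 or params.sigma2 > 0
        for t in range(T):
            X[:, t, k] = x
            X_seq[:, t, k] = xs
            Y[:, t, k] = xn
            dx = (-x + W @ x + B @ u) * dt
            dxs = (-xs + W @ xs) * dt
            du = (A @ u) * dt
            x = x + dx
            xs = xs + dxs
            u = u + du
            if noisy:
                dxn = (-xn + W @ xn + B @ un) * dt
                dun = (A @ un) * dt
                xn = xn + dxn + params.sigma1 * sq * noise_rng.standard_normal(N)
                un = un + dun + params.sigma2 * sq * noise_rng.standard_normal(2)
            else:
                xn = x
                un = u
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > limit:
            raise SimulationError(
                f"RNN trajectory blew up (lam={params.lam}, eps={params.eps}, "
                f"dt={dt:.4g}); reduce the chain gain or the step"
            )
    if not noisy:
        Y = X.copy()
    if params.sigma3 > 0:
        Y = Y + params.sigma3 * noise_rng.standard_normal(Y.shape)
    return GroundTruthBundle(
        tensor=DataTensor(Y),
        noiseless=X,
        sources={"sequence": X_seq, "input": X - X_seq},
        params={
            "model": "rnn", "N": N, "T": T, "K": K, "lam": params.lam,
            "eps": params.eps, "sigma1": params.sigma1, "sigma2": params.sigma2,
            "sigma3": params.sigma3, "horizon": params.horizon, "seed": params.seed,
        },
        trial_labels=thetas,
    )


def sigma3_for_zeta(x_noiseless: np.ndarray, zeta: float) -> float:
    """Observation-noise scale that yields an expected noise fraction
    ``zeta`` of the total centered variance."""
    if not (0 < zeta < 1):
        raise UsageError("zeta must lie in (0, 1)")
    var_x = float(np.var(x_noiseless))
    return float(np.sqrt(zeta / (1.0 - zeta) * var_x))


def kappa_and_zeta(y, yhat, x_noiseless) -> tuple[float, float]:
    """Variance explained by a reconstruction and the data's noise
    fraction: ``kappa = 1 - ||Yhat - Y||^2 / ||Y - ybar||^2`` and
    ``zeta = ||Y - X||^2 / ||Y - ybar||^2`` with ``ybar`` the grand mean
    of Y.  An optimal denoiser (Yhat = X) satisfies kappa = 1 - zeta."""
    yv = np.asarray(y, dtype=np.float64)
    yh = np.asarray(yhat, dtype=np.float64)
    xv = np.asarray(x_noiseless, dtype=np.float64)
    if not (yv.shape == yh.shape == xv.shape):
        raise UsageError("y, yhat and x_noiseless must share a shape")
    denom = float(np.sum((yv - yv.mean()) ** 2))
    if denom == 0:
        raise UsageError("y has zero variance")
    kappa = 1.0 - float(np.sum((yh - yv) ** 2)) / denom
    zeta = float(np.sum((yv - xv) ** 2)) / denom
    return kappa, zeta
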