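"""Masked stochastic-gradient fitting of slice-rank models at fixed rank.

The loss is the mean squared error over *unmasked* entries.  Two masks
combine multiplicatively: a fixed train mask (held-out entries never enter
the loss, used for cross-validation) and a stochastic mask that hides a
scheduled fraction of the trainable entries to inject gradient noise and
escape local minima.  The stochastic fraction starts high (default 80%)
and decays geometrically over blocks of iterations; within a block the
hidden subset is redrawn every ``mask_reinit_every`` iterations.

Parameters are optimized with Adam.  Non-negativity, when requested, is
enforced by projection (clamping at zero after every step), which pairs
naturally with the uniform [0, 1] initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._adam import Adam
from .core import (
    SLICE_TYPES,
    DataTensor,
    FitError,
    RankTuple,
    SliceTCAModel,
    UsageError,
    as_values,
    masked_mse,
    slice_dims,
)


@dataclass
class FitConfig:
    """Hyperparameters of the masked-SGD fit.

    ``learning_rate`` applies throughout unless ``lr_final`` is set, in
    which case the rate interpolates geometrically from ``learning_rate``
    to ``lr_final`` across blocks.  The stochastic-mask fraction follows
    ``mask_start_fraction * mask_decay**block`` unless
    ``mask_final_fraction`` is set (endpoint mode), in which case it
    interpolates geometrically between the stated start and end values.
    """

    learning_rate: float = 0.02
    lr_final: float | None = None
    n_blocks: int = 5
    iters_per_block: int = 200
    mask_start_fraction: float = 0.80
    mask_decay: float = 0.5
    mask_final_fraction: float | None = None
    mask_reinit_every: int = 20
    nonnegative: bool = False
    init_low: float | None = None
    init_high: float | None = None
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if not (0 <= self.mask_start_fraction < 1):
            raise UsageError("mask_start_fraction must lie in [0, 1)")
        if self.mask_decay <= 0:
            raise UsageError("mask_decay must be positive")
        if self.n_blocks < 1 or self.iters_per_block < 1:
            raise UsageError("n_blocks and iters_per_block must be >= 1")
        for b in range(self.n_blocks):
            if not (0 <= mask_schedule(b, self) < 1):
                raise UsageError(f"mask fraction at block {b} leaves [0, 1)")

    def init_interval(self) -> tuple[float, float]:
        if self.init_low is not None and self.init_high is not None:
            return (self.init_low, self.init_high)
        return (0.0, 1.0) if self.nonnegative else (-1.0, 1.0)


def toy_config(seed: int = 0, nonnegative: bool = True) -> FitConfig:
    """Endpoint-mode preset used for the feedforward toy simulation:
    five blocks of 200 iterations, learning rate 0.2 -> 0.0125, stochastic
    mask 0.8 -> 0.05 redrawn every iteration."""
    return FitConfig(
        learning_rate=0.2,
        lr_final=0.0125,
        n_blocks=5,
        iters_per_block=200,
        mask_start_fraction=0.8,
        mask_final_fraction=0.05,
        mask_reinit_every=1,
        nonnegative=nonnegative,
        seed=seed,
    )


def mask_schedule(block_index: int, config: FitConfig) -> float:
    """Stochastic-mask fraction for a given block of iterations."""
    if block_index >= config.n_blocks:
        raise UsageError(
            f"block index {block_index} out of range for {config.n_blocks} blocks"
        )
    start = config.mask_start_fraction
    if config.mask_final_fraction is not None:
        if config.n_blocks == 1:
            return start
        ratio = config.mask_final_fraction / start
        return start * ratio ** (block_index / (config.n_blocks - 1))
    return start * config.mask_decay**block_index


def _lr_schedule(block_index: int, config: FitConfig) -> float:
    if config.lr_final is None or config.n_blocks == 1:
        return config.learning_rate
    ratio = config.lr_final / config.learning_rate
    return config.learning_rate * ratio ** (block_index / (config.n_blocks - 1))


@dataclass
class FitResult:
    """A fitted model plus bookkeeping for reproducibility."""

    model: SliceTCAModel
    final_loss: float
    loss_trace: np.ndarray
    block_losses: np.ndarray
    seed: int
    config: FitConfig = field(repr=False, default=None)


def _init_params(
    rank: RankTuple, dims, rng: np.random.Generator, lo: float, hi: float
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for st in SLICE_TYPES:
        R = rank[st]
        if R == 0:
            continue
        L, (a, b) = slice_dims(st, dims)
        params[f"{st}_loading"] = rng.uniform(lo, hi, size=(L, R))
        params[f"{st}_slice"] = rng.uniform(lo, hi, size=(R, a, b))
    return params


def _assemble(params: dict[str, np.ndarray], dims) -> np.ndarray:
    """Reconstruction from raw parameter stacks."""
    N, T, K = dims
    out = np.zeros((N, T, K))
    if "neuron_loading" in params:
        U = params["neuron_loading"]
        A = params["neuron_slice"]
        out += (U @ A.reshape(A.shape[0], -1)).reshape(N, T, K)
    if "time_loading" in params:
        V = params["time_loading"]
        B = params["time_slice"]
        out += np.moveaxis((V @ B.reshape(B.shape[0], -1)).reshape(T, N, K), 0, 1)
    if "trial_loading" in params:
        W = params["trial_loading"]
        C = params["trial_slice"]
        out += np.moveaxis((W @ C.reshape(C.shape[0], -1)).reshape(K, N, T), 0, 2)
    return out


def _grads(params: dict[str, np.ndarray], G: np.ndarray, dims) -> dict[str, np.ndarray]:
    """Gradients of the masked MSE; G = d(loss)/d(Xhat)."""
    N, T, K = dims
    grads: dict[str, np.ndarray] = {}
    if "neuron_loading" in params:
        U = params["neuron_loading"]
        A = params["neuron_slice"]
        Gf = G.reshape(N, T * K)
        Af = A.reshape(A.shape[0], -1)
        grads["neuron_loading"] = Gf @ Af.T
        grads["neuron_slice"] = (U.T @ Gf).reshape(A.shape)
    if "time_loading" in params:
        V = params["time_loading"]
        B = params["time_slice"]
        Gf = G.transpose(1, 0, 2).reshape(T, N * K)
        Bf = B.reshape(B.shape[0], -1)
        grads["time_loading"] = Gf @ Bf.T
        grads["time_slice"] = (V.T @ Gf).reshape(B.shape)
    if "trial_loading" in params:
        W = params["trial_loading"]
        C = params["trial_slice"]
        Gf = G.transpose(2, 0, 1).reshape(K, N * T)
        Cf = C.reshape(C.shape[0], -1)
        grads["trial_loading"] = Gf @ Cf.T
        grads["trial_slice"] = (W.T @ Gf).reshape(C.shape)
    return grads


def _model_from_params(
    params: dict[str, np.ndarray], rank: RankTuple, dims, nonnegative: bool
) -> SliceTCAModel:
    arrays = {}
    for st in SLICE_TYPES:
        if rank[st] > 0:
            arrays[st] = (params[f"{st}_loading"], params[f"{st}_slice"])
    return SliceTCAModel.from_arrays(dims, arrays, nonnegative=nonnegative)


def fit(
    x,
    rank,
    train_mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a slice-rank model of fixed rank by masked stochastic gradients.

    ``train_mask`` marks entries allowed to enter the loss (None = all).
    Returns the model together with its loss on the train mask.
    """
    config = config or FitConfig()
    xv = as_values(x)
    dims = xv.shape
    rank = RankTuple.coerce(rank)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.init_interval()
    params = _init_params(rank, dims, rng, lo, hi)

    if train_mask is None:
        train_f = None
        train_idx = None
        n_train = xv.size
    else:
        train_mask = np.asarray(train_mask, dtype=bool)
        if train_mask.shape != dims:
            raise UsageError(f"train mask shape {train_mask.shape} != {dims}")
        n_train = int(train_mask.sum())
        if n_train == 0:
            raise UsageError("train mask selects no entries")
        train_f = train_mask.astype(np.float64)
        train_idx = np.flatnonzero(train_mask.ravel())

    loss_trace: list[float] = []
    block_losses: list[float] = []

    if rank.total == 0:
        final = masked_mse(xv, np.zeros(dims), train_mask)
        return FitResult(
            model=SliceTCAModel([], dims, nonnegative=config.nonnegative),
            final_loss=final,
            loss_trace=np.array([final]),
            block_losses=np.array([final]),
            seed=config.seed,
            config=config,
        )

    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, eps=config.eps)

    eff = np.empty(dims)
    for b in range(config.n_blocks):
        opt.lr = _lr_schedule(b, config)
        frac = mask_schedule(b, config)
        n_drop = int(round(frac * n_train))
        n_keep = n_train - n_drop
        if n_keep <= 0:
            raise UsageError("stochastic mask leaves no trainable entries")
        for it in range(config.iters_per_block):
            if it % config.mask_reinit_every == 0:
                if train_f is None:
                    eff.fill(1.0)
                    if n_drop:
                        drop = rng.choice(xv.size, size=n_drop, replace=False)
                        eff.ravel()[drop] = 0.0
                else:
                    eff[:] = train_f
                    if n_drop:
                        drop = train_idx[
                            rng.choice(n_train, size=n_drop, replace=False)
                        ]
                        eff.ravel()[drop] = 0.0
            D = _assemble(params, dims)
            D -= xv
            D *= eff
            loss = float(np.vdot(D, D)) / n_keep
            loss_trace.append(loss)
            if not np.isfinite(loss):
                raise FitError(
                    f"loss diverged at block {b}, iteration {it}",
                    loss_trace=np.array(loss_trace),
                )
            opt.step(_grads(params, (2.0 / n_keep) * D, dims))
            if config.nonnegative:
                for v in params.values():
                    np.maximum(v, 0.0, out=v)
        block_losses.append(masked_mse(xv, _assemble(params, dims), train_mask))

    model = _model_from_params(params, rank, dims, config.nonnegative)
    final = block_losses[-1]
    return FitResult(
        model=model,
        final_loss=final,
        loss_trace=np.asarray(loss_trace),
        block_losses=np.asarray(block_losses),
        seed=config.seed,
        config=config,
    )


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-restart substreams from one base seed (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def multi_seed_fit(
    x,
    rank,
    train_mask: np.ndarray | None = None,
    config: FitConfig | None = None,
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
) -> FitResult:
    """Repeat ``fit`` with different random seeds; keep the lowest-loss model."""
    if n_seeds < 1:
        raise UsageError("n_seeds must be >= 1")
    config = config or FitConfig()
    if seeds is None:
        seeds = derive_seeds(config.seed, n_seeds)
    best: FitResult | None = None
    last_err: FitError | None = None
    for s in seeds:
        try:
            res = fit(x, rank, train_mask, replace(config, seed=int(s)))
        except FitError as err:
            last_err = err
            continue
        if best is None or res.final_loss < best.final_loss:
            best = res
    if best is None:
        raise FitError("all restarts diverged") from last_err
    return best


# ---------------------------------------------------------------------------
# CP/TCA gradient engine (shared schedule and optimizer)


def fit_tca_factors(
    x,
    r: int,
    train_mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Fit CP factors (U, V, W) of rank ``r`` with the same masked-SGD
    engine; returns the factors and the final train loss."""
    config = config or FitConfig()
    xv = as_values(x)
    N, T, K = xv.shape
    rng = np.random.default_rng(config.seed)
    lo, hi = config.init_interval()
    if r == 0:
        return (
            np.zeros((N, 0)), np.zeros((T, 0)), np.zeros((K, 0)),
            masked_mse(xv, np.zeros_like(xv), train_mask),
        )
    params = {
        "U": rng.uniform(lo, hi, size=(N, r)),
        "V": rng.uniform(lo, hi, size=(T, r)),
        "W": rng.uniform(lo, hi, size=(K, r)),
    }
    if train_mask is None:
        train_f = None
        train_idx = None
        n_train = xv.size
    else:
        train_mask = np.asarray(train_mask, dtype=bool)
        train_f = train_mask.astype(np.float64)
        train_idx = np.flatnonzero(train_mask.ravel())
        n_train = len(train_idx)
        if n_train == 0:
            raise UsageError("train mask selects no entries")
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2, eps=config.eps)
    eff = np.empty_like(xv)
    trace: list[float] = []
    for b in range(config.n_blocks):
        opt.lr = _lr_schedule(b, config)
        frac = mask_schedule(b, config)
        n_drop = int(round(frac * n_train))
        n_keep = n_train - n_drop
        for it in range(config.iters_per_block):
            if it % config.mask_reinit_every == 0:
                if train_f is None:
                    eff.fill(1.0)
                    if n_drop:
                        eff.ravel()[rng.choice(xv.size, n_drop, replace=False)] = 0.0
                else:
                    eff[:] = train_f
                    if n_drop:
                        eff.ravel()[
                            train_idx[rng.choice(n_train, n_drop, replace=False)]
                        ] = 0.0
            U, V, W = params["U"], params["V"], params["W"]
            D = np.einsum("nr,tr,kr->ntk", U, V, W, optimize=True)
            D -= xv
            D *= eff
            loss = float(np.vdot(D, D)) / n_keep
            trace.append(loss)
            if not np.isfinite(loss):
                raise FitError(
                    f"TCA loss diverged at block {b}, iteration {it}",
                    loss_trace=np.array(trace),
                )
            G = (2.0 / n_keep) * D
            grads = {
                "U": np.einsum("ntk,tr,kr->nr", G, V, W, optimize=True),
                "V": np.einsum("ntk,nr,kr->tr", G, U, W, optimize=True),
                "W": np.einsum("ntk,nr,tr->kr", G, U, V, optimize=True),
            }
            opt.step(grads)
            if config.nonnegative:
                for v in params.values():
                    np.maximum(v, 0.0, out=v)
    U, V, W = params["U"], params["V"], params["W"]
    xhat = np.einsum("nr,tr,kr->ntk", U, V, W, optimize=True)
    return U, V, W, masked_mse(xv, xhat, train_mask)
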