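"""Invariance classes of the slice-rank decomposition and the hierarchical
three-stage optimization that resolves them.

Two families of parameter changes leave the fit quality untouched:

* **within-slice-type**: mixing the R components of one slice type by any
  invertible matrix F (loadings by F, slices by F^-1) preserves that
  type's partial reconstruction — the invariance every matrix
  factorization inherits;
* **between-slice-type**: a rank-1 tensor built from one loading of each
  of two types and an arbitrary vector along the third axis can be moved
  from one type's slices to the other's, changing both partial
  reconstructions but not their sum.

The hierarchy resolves them in order: stage 1 fits the reconstruction
(masked SGD), stage 2 picks the member of the between-type orbit whose
partial reconstructions have minimal total energy (a convex quadratic in
the transfer parameters, minimized by Adam), and stage 3 canonicalizes
each slice type by a truncated SVD of its partial reconstruction —
orthonormal loadings ordered by captured variance, with a deterministic
sign convention.  Stage 2 never changes the full reconstruction; stage 3
never changes any partial reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    SLICE_TYPES,
    RankTuple,
    SliceComponent,
    SliceTCAModel,
    UsageError,
    partial_reconstruct,
    reconstruct,
)
from ._adam import Adam
from .fitting import FitConfig, FitResult, multi_seed_fit


@dataclass
class WithinTransform:
    """Invertible mixing of the components of one slice type."""

    slice_type: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise UsageError("within-type transform must be a square matrix")


def apply_within_transform(model: SliceTCAModel, wt: WithinTransform) -> SliceTCAModel:
    """Mix loadings by F and slices by F^-1; the slice type's partial
    reconstruction is unchanged."""
    comps = model.components_of(wt.slice_type)
    R = len(comps)
    if wt.matrix.shape != (R, R):
        raise UsageError(
            f"transform is {wt.matrix.shape} but type {wt.slice_type!r} has {R} components"
        )
    if R == 0:
        return model.copy()
    cond = np.linalg.cond(wt.matrix)
    if not np.isfinite(cond) or cond > 1e12:
        raise UsageError(f"transform matrix is singular (cond={cond:.3g})")
    Finv = np.linalg.inv(wt.matrix)
    loadings = model.loadings(wt.slice_type) @ wt.matrix
    slices = np.einsum("rq,qab->rab", Finv, model.slices(wt.slice_type))
    out = model.copy()
    comps_out = [c for c in out.components if c.slice_type == wt.slice_type]
    for r, c in enumerate(comps_out):
        c.loading = loadings[:, r]
        c.slice = slices[r]
    return out


@dataclass
class BetweenTransferParams:
    """Rank-1 transfer tensors moving energy between slice types.

    Shapes are bound to the model's rank tuple and dims:
    ``x``: (R_time, R_trial, N), ``y``: (R_neuron, R_trial, T),
    ``z``: (R_neuron, R_time, K).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @classmethod
    def zeros(cls, rank: RankTuple, dims) -> "BetweenTransferParams":
        N, T, K = dims
        return cls(
            x=np.zeros((rank.time, rank.trial, N)),
            y=np.zeros((rank.neuron, rank.trial, T)),
            z=np.zeros((rank.neuron, rank.time, K)),
        )


def _transfer_deltas(model: SliceTCAModel, p: BetweenTransferParams):
    """Per-type slice increments implied by the transfer parameters."""
    U = model.loadings("neuron")
    V = model.loadings("time")
    W = model.loadings("trial")
    dA = np.einsum("rst,ks->rtk", p.y, W, optimize=True) + np.einsum(
        "ts,rsk->rtk", V, p.z, optimize=True
    )
    dB = np.einsum("srn,kr->snk", p.x, W, optimize=True) - np.einsum(
        "nr,rsk->snk", U, p.z, optimize=True
    )
    dC = -np.einsum("scn,ts->cnt", p.x, V, optimize=True) - np.einsum(
        "nr,rct->cnt", U, p.y, optimize=True
    )
    return dA, dB, dC


def apply_transfer_params(
    model: SliceTCAModel, p: BetweenTransferParams
) -> SliceTCAModel:
    """Apply a full set of between-type transfers to the slices.  The full
    reconstruction is exactly preserved."""
    rank = model.rank
    dims = model.dims
    N, T, K = dims
    expected = {
        "x": (rank.time, rank.trial, N),
        "y": (rank.neuron, rank.trial, T),
        "z": (rank.neuron, rank.time, K),
    }
    for name, shape in expected.items():
        arr = getattr(p, name)
        if arr.shape != shape:
            raise UsageError(f"transfer {name} has shape {arr.shape}, expected {shape}")
    dA, dB, dC = _transfer_deltas(model, p)
    out = model.copy()
    for st, delta in (("neuron", dA), ("time", dB), ("trial", dC)):
        for r, c in enumerate(c for c in out.components if c.slice_type == st):
            c.slice = c.slice + delta[r]
    return out


def apply_between_transform(
    model: SliceTCAModel,
    pair: tuple[str, str],
    transfer: np.ndarray,
    i: int = 0,
    j: int = 0,
) -> SliceTCAModel:
    """Pass a single rank-1 tensor between component ``i`` of ``pair[0]``
    and component ``j`` of ``pair[1]`` using the vector ``transfer`` along
    the remaining axis."""
    a, b = pair
    if a not in SLICE_TYPES or b not in SLICE_TYPES or a == b:
        raise UsageError(f"pair must be two distinct slice types; got {pair}")
    rank = model.rank
    if rank[a] == 0 or rank[b] == 0:
        raise UsageError(f"both slice types in {pair} need at least one component")
    p = BetweenTransferParams.zeros(rank, model.dims)
    transfer = np.asarray(transfer, dtype=np.float64)
    key = frozenset(pair)
    if key == frozenset(("neuron", "time")):
        r, s = (i, j) if a == "neuron" else (j, i)
        p.z[r, s] = transfer
    elif key == frozenset(("neuron", "trial")):
        r, s = (i, j) if a == "neuron" else (j, i)
        p.y[r, s] = transfer
    else:  # time & trial
        s, r = (i, j) if a == "time" else (j, i)
        p.x[s, r] = transfer
    return apply_transfer_params(model, p)


def partial_energy(model: SliceTCAModel) -> float:
    """Sum of squared entries of the three partial reconstructions —
    the stage-2 objective."""
    return float(
        sum(np.vdot(P := partial_reconstruct(model, st), P) for st in SLICE_TYPES)
    )


@dataclass
class BetweenConfig:
    learning_rate: float = 0.02
    max_iter: int = 3000
    grad_tol: float = 1e-8
    # supplementary plateau rule: stop when the objective's relative
    # decrease over `check_every` iterations falls below `rel_tol`
    rel_tol: float = 1e-12
    check_every: int = 50


@dataclass
class OptimizedModel:
    """Result of the hierarchical pipeline with per-stage provenance."""

    model: SliceTCAModel
    l1: float
    l2: float
    provenance: dict = field(default_factory=dict)


def optimize_between(
    model: SliceTCAModel, config: BetweenConfig | None = None
) -> OptimizedModel:
    """Minimize the total energy of the three partial reconstructions over
    the between-slice-type transfer orbit (full reconstruction fixed)."""
    config = config or BetweenConfig()
    rank = model.rank
    dims = model.dims
    n_active = sum(1 for st in SLICE_TYPES if rank[st] > 0)
    l2_init = partial_energy(model)
    if n_active < 2:
        return OptimizedModel(
            model=model.copy(), l1=np.nan, l2=l2_init,
            provenance={"stage2": "skipped: fewer than two active slice types"},
        )
    U = model.loadings("neuron")
    V = model.loadings("time")
    W = model.loadings("trial")
    P_n0 = partial_reconstruct(model, "neuron")
    P_t0 = partial_reconstruct(model, "time")
    P_k0 = partial_reconstruct(model, "trial")
    p = BetweenTransferParams.zeros(rank, dims)
    params = {"x": p.x, "y": p.y, "z": p.z}
    opt = Adam(params, lr=config.learning_rate)
    n_param = sum(v.size for v in params.values())
    l2 = l2_init
    iters_used = config.max_iter
    l2_checkpoint = np.inf
    converged = False
    best_l2 = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    for it in range(config.max_iter):
        Tx = np.einsum("srn,ts,kr->ntk", params["x"], V, W, optimize=True)
        Ty = np.einsum("rst,nr,ks->ntk", params["y"], U, W, optimize=True)
        Tz = np.einsum("rsk,nr,ts->ntk", params["z"], U, V, optimize=True)
        P_trial = P_k0 - Tx - Ty
        P_time = P_t0 + Tx - Tz
        P_neuron = P_n0 + Ty + Tz
        l2 = float(np.vdot(P_trial, P_trial) + np.vdot(P_time, P_time)
                   + np.vdot(P_neuron, P_neuron))
        if l2 < best_l2:
            best_l2 = l2
            best_params = {k: v.copy() for k, v in params.items()}
        gx = 2.0 * np.einsum("ntk,ts,kr->srn", P_time - P_trial, V, W, optimize=True)
        gy = 2.0 * np.einsum("ntk,nr,ks->rst", P_neuron - P_trial, U, W, optimize=True)
        gz = 2.0 * np.einsum("ntk,nr,ts->rsk", P_neuron - P_time, U, V, optimize=True)
        gnorm = float(np.sqrt(
            (np.vdot(gx, gx) + np.vdot(gy, gy) + np.vdot(gz, gz)) / max(n_param, 1)
        ))
        if gnorm < config.grad_tol:
            iters_used = it
            converged = True
            break
        if it % config.check_every == 0:
            if (l2_checkpoint - best_l2) < config.rel_tol * max(best_l2, 1e-300):
                iters_used = it
                converged = True
                break
            l2_checkpoint = best_l2
        opt.step({"x": gx, "y": gy, "z": gz})
    if not converged:
        warnings.warn(
            f"stage-2 transfer optimization stopped at iteration budget with "
            f"RMS gradient {gnorm:.3g}", RuntimeWarning,
        )
    # the zero transfer is always a member of the orbit, so best_l2 <= l2_init
    best_l2 = min(best_l2, l2_init)
    out = apply_transfer_params(model, BetweenTransferParams(**best_params))
    return OptimizedModel(
        model=out, l1=np.nan, l2=best_l2,
        provenance={"stage2": {"l2_init": l2_init, "l2_final": best_l2,
                               "iterations": iters_used, "grad_rms": gnorm}},
    )


def canonicalize_within(model: SliceTCAModel) -> SliceTCAModel:
    """Stage 3: per slice type, recompute components from the truncated SVD
    of the partial reconstruction unfolded along the loading axis.

    Loadings become orthonormal, slices mutually orthogonal, components
    ordered by non-increasing captured variance; each loading is oriented
    so its largest-magnitude entry is positive.  Partial reconstructions
    are unchanged (the unfolding has rank <= R by construction)."""
    N, T, K = model.dims
    arrays = {}
    for st in SLICE_TYPES:
        R = model.rank[st]
        if R == 0:
            continue
        P = partial_reconstruct(model, st)
        if st == "neuron":
            M = P.reshape(N, T * K)
            sl_shape = (T, K)
        elif st == "time":
            M = P.transpose(1, 0, 2).reshape(T, N * K)
            sl_shape = (N, K)
        else:
            M = P.transpose(2, 0, 1).reshape(K, N * T)
            sl_shape = (N, T)
        Um, S, Vt = np.linalg.svd(M, full_matrices=False)
        if R < len(S) and S[R - 1] > 0 and np.isclose(S[R - 1], S[R], rtol=1e-10):
            warnings.warn(
                f"degenerate singular values in {st!r} partial; ordering uses "
                "a stable tie-break", RuntimeWarning,
            )
        loadings = Um[:, :R].copy()
        slices = (S[:R, None] * Vt[:R]).reshape(R, *sl_shape)
        for r in range(R):
            imax = int(np.argmax(np.abs(loadings[:, r])))
            if loadings[imax, r] < 0:
                loadings[:, r] *= -1
                slices[r] *= -1
        arrays[st] = (loadings, slices)
    return SliceTCAModel.from_arrays(model.dims, arrays, nonnegative=False)


def hierarchical_optimize(
    x,
    rank,
    fit_config: FitConfig | None = None,
    train_mask: np.ndarray | None = None,
    n_seeds: int = 10,
    between_config: BetweenConfig | None = None,
) -> OptimizedModel:
    """Full pipeline: multi-seed masked-SGD fit (stage 1), between-type
    transfer optimization (stage 2), within-type SVD canonicalization
    (stage 3).  Non-negative fits skip stages 2-3, which are only valid
    for unconstrained models."""
    fit_config = fit_config or FitConfig()
    rank = RankTuple.coerce(rank)
    res: FitResult = multi_seed_fit(x, rank, train_mask, fit_config, n_seeds=n_seeds)
    prov = {
        "stage1": {
            "l1": res.final_loss,
            "seed": res.seed,
            "n_seeds": n_seeds,
            "rank": rank.as_tuple(),
        }
    }
    if fit_config.nonnegative:
        prov["stage2"] = prov["stage3"] = (
            "skipped: hierarchical gauge fixing applies to unconstrained models only"
        )
        return OptimizedModel(model=res.model, l1=res.final_loss,
                              l2=partial_energy(res.model), provenance=prov)
    stage2 = optimize_between(res.model, between_config)
    prov.update(stage2.provenance)
    final = canonicalize_within(stage2.model)
    prov["stage3"] = "svd canonicalization"
    return OptimizedModel(model=final, l1=res.final_loss, l2=stage2.l2,
                          provenance=prov)
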