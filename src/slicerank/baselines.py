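"""Unfoldings, matrix-factorization and CP/TCA baselines, and
error-versus-components comparison curves.

A slice-rank model restricted to a single slice type is exactly a matrix
factorization of the corresponding tensor unfolding (neuron-unfolded
``N x TK``, time-unfolded ``T x NK``, trial-unfolded ``K x NT``), so
truncated SVD on an unfolding is both a baseline method and an oracle for
the single-type special case.  The CP/TCA baseline shares the masked-SGD
engine; a CP component is a slicing component with a rank-1 slice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    SLICE_TYPES,
    TCAComponent,
    UsageError,
    as_values,
    masked_mse,
    tca_reconstruct,
)
from .fitting import FitConfig, fit, fit_tca_factors, multi_seed_fit, derive_seeds


@dataclass
class UnfoldedMatrix:
    """A tensor unfolding that remembers how to fold itself back."""

    values: np.ndarray
    kept_axis: str
    folded_dims: tuple[int, int, int]

    def refold(self) -> np.ndarray:
        N, T, K = self.folded_dims
        if self.kept_axis == "neuron":
            return self.values.reshape(N, T, K)
        if self.kept_axis == "time":
            return self.values.reshape(T, N, K).transpose(1, 0, 2)
        return self.values.reshape(K, N, T).transpose(1, 2, 0)


def unfold(x, kept_axis: str) -> UnfoldedMatrix:
    """Unfold keeping one axis as rows; column order is row-major over the
    remaining axes in (N, T, K) order."""
    xv = as_values(x)
    N, T, K = xv.shape
    if kept_axis == "neuron":
        m = xv.reshape(N, T * K)
    elif kept_axis == "time":
        m = xv.transpose(1, 0, 2).reshape(T, N * K)
    elif kept_axis == "trial":
        m = xv.transpose(2, 0, 1).reshape(K, N * T)
    else:
        raise UsageError(f"kept_axis must be one of {SLICE_TYPES}; got {kept_axis!r}")
    return UnfoldedMatrix(values=m, kept_axis=kept_axis, folded_dims=(N, T, K))


def svd_truncation_error(m: np.ndarray, r: int) -> float:
    """MSE of the best rank-r approximation (Eckart-Young)."""
    if r == 0:
        return float(np.mean(m**2))
    s = np.linalg.svd(m, compute_uv=False)
    return float(np.sum(s[r:] ** 2) / m.size)


def fit_matrix_factorization(
    m: UnfoldedMatrix | np.ndarray,
    r: int,
    nonnegative: bool = False,
    config: FitConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-r factor pair (W, H) with ``W @ H`` approximating the matrix.

    Unconstrained and unmasked: closed-form truncated SVD.  Non-negative
    or masked: the shared masked-SGD engine with clamping, run on the
    matrix viewed as a single-trial tensor."""
    mat = m.values if isinstance(m, UnfoldedMatrix) else np.asarray(m, dtype=np.float64)
    if r > min(mat.shape):
        raise UsageError(f"rank {r} exceeds matrix dims {mat.shape}")
    if r == 0:
        return np.zeros((mat.shape[0], 0)), np.zeros((0, mat.shape[1]))
    if not nonnegative and mask is None:
        U, S, Vt = np.linalg.svd(mat, full_matrices=False)
        return U[:, :r] * S[:r], Vt[:r]
    config = config or FitConfig(nonnegative=nonnegative)
    if config.nonnegative != nonnegative:
        config = replace(config, nonnegative=nonnegative)
    tensor = mat[:, :, None]
    m3 = None if mask is None else np.asarray(mask, dtype=bool)[:, :, None]
    res = fit(tensor, (r, 0, 0), m3, config)
    W = res.model.loadings("neuron")
    H = res.model.slices("neuron")[:, :, 0]
    return W, H


def fit_tca(
    x,
    r: int,
    nonnegative: bool = False,
    config: FitConfig | None = None,
    train_mask: np.ndarray | None = None,
    n_seeds: int = 1,
) -> list[TCAComponent]:
    """CP/TCA fit via the shared masked-SGD engine."""
    config = config or FitConfig(nonnegative=nonnegative)
    if config.nonnegative != nonnegative:
        config = replace(config, nonnegative=nonnegative)
    xv = as_values(x)
    best = None
    for s in derive_seeds(config.seed, n_seeds):
        U, V, W, loss = fit_tca_factors(xv, r, train_mask, replace(config, seed=s))
        if best is None or loss < best[-1]:
            best = (U, V, W, loss)
    U, V, W, _ = best
    return [TCAComponent(U[:, i], V[:, i], W[:, i]) for i in range(r)]


@dataclass
class ComparisonCurve:
    """Training error as a function of the number of components."""

    method: str
    counts: list[int]
    train_errors: list[float]
    details: list[dict] | None = None


def _compositions(total: int):
    for a in range(total + 1):
        for b in range(total - a + 1):
            yield (a, b, total - a - b)


def error_vs_components(
    x,
    method: str,
    max_components: int,
    config: FitConfig | None = None,
    n_seeds: int = 1,
    composition_cap: int = 6,
) -> ComparisonCurve:
    """Error-vs-components curve for one method.

    ``method`` is one of ``slicetca``, ``tca``, ``pca-neuron``,
    ``pca-time``, ``pca-trial``, ``nmf-neuron``, ``nmf-time``,
    ``nmf-trial``.  For ``slicetca`` each total rank reports the best
    training error over all rank-tuple compositions of that total
    (exhaustive up to ``composition_cap``, then a greedy increment from
    the best composition found so far).
    """
    xv = as_values(x)
    config = config or FitConfig()
    counts = list(range(max_components + 1))
    errors: list[float] = []
    details: list[dict] = []

    if method.startswith("pca-") or method.startswith("nmf-"):
        kind, axis = method.split("-", 1)
        if axis not in SLICE_TYPES:
            raise UsageError(f"unknown unfolding {axis!r} in method {method!r}")
        m = unfold(xv, axis)
        for r in counts:
            if kind == "pca":
                errors.append(svd_truncation_error(m.values, r))
            else:
                W, H = fit_matrix_factorization(m, r, nonnegative=True, config=config)
                errors.append(float(np.mean((m.values - W @ H) ** 2)))
            details.append({"rank": r})
    elif method == "tca":
        for r in counts:
            comps = fit_tca(xv, r, nonnegative=config.nonnegative, config=config,
                            n_seeds=n_seeds)
            errors.append(float(np.mean((xv - tca_reconstruct(comps, xv.shape)) ** 2)))
            details.append({"rank": r})
    elif method == "slicetca":
        best_comp = (0, 0, 0)
        for total in counts:
            if total == 0:
                errors.append(float(np.mean(xv**2)))
                details.append({"rank": (0, 0, 0)})
                continue
            if total <= composition_cap:
                cands = list(_compositions(total))
            else:
                cands = [
                    tuple(np.add(best_comp, e))
                    for e in ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                ]
            best = None
            for cand in cands:
                res = multi_seed_fit(xv, cand, None, config, n_seeds=n_seeds)
                if best is None or res.final_loss < best[1]:
                    best = (cand, res.final_loss)
            best_comp = best[0]
            errors.append(best[1])
            details.append({"rank": best[0]})
    else:
        raise UsageError(f"unknown method {method!r}")
    return ComparisonCurve(method=method, counts=counts, train_errors=errors,
                           details=details)
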