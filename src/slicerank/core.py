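"""Core data model: tensors, slice-rank-1 components, models, and losses.

A trial-structured population recording is stored as a dense third-order
tensor ``X`` of shape ``(N, T, K)`` — neurons x time x trials.  A
slice-rank-1 component is the outer product of a *loading* vector along one
axis and a *slice* (matrix) over the remaining two axes.  Depending on
which axis carries the loading, a component captures one of three
covariability classes:

* ``neuron``-slicing: loading over neurons, ``T x K`` slice — a fixed
  neural pattern whose activation varies freely over time and trials.
* ``time``-slicing: loading over time, ``N x K`` slice — a stereotyped
  temporal profile whose neural encoding changes from trial to trial.
* ``trial``-slicing: loading over trials, ``N x T`` slice — a stereotyped
  spatiotemporal pattern (e.g. a sequence) scaled per trial.

A model is a list of such components, described by the rank tuple
``(R_neuron, R_time, R_trial)``.  A canonical-polyadic (CP/TCA) component
is the special case of a slicing component whose slice is itself rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

SLICE_TYPES = ("neuron", "time", "trial")

#: index of the loading axis in the (N, T, K) layout, per slice type
LOADING_AXIS = {"neuron": 0, "time": 1, "trial": 2}


class SliceRankError(Exception):
    """Base class for errors raised by this package."""


class UsageError(SliceRankError, ValueError):
    """The caller asked for something invalid (bad flag, empty mask, ...)."""


class StructuralError(SliceRankError, ValueError):
    """Shapes or component structure are inconsistent."""


class FitError(SliceRankError, RuntimeError):
    """Optimization diverged; carries the loss trace for post-mortem."""

    def __init__(self, message: str, loss_trace=None):
        super().__init__(message)
        self.loss_trace = loss_trace


def _check_slice_type(slice_type: str) -> str:
    if slice_type not in SLICE_TYPES:
        raise UsageError(
            f"unknown slice type {slice_type!r}; expected one of {SLICE_TYPES}"
        )
    return slice_type


def slice_dims(slice_type: str, dims: Sequence[int]) -> tuple[int, tuple[int, int]]:
    """Return (loading length, slice shape) for a slice type at given dims."""
    N, T, K = dims
    _check_slice_type(slice_type)
    if slice_type == "neuron":
        return N, (T, K)
    if slice_type == "time":
        return T, (N, K)
    return K, (N, T)


@dataclass
class DataTensor:
    """Dense ``neurons x time x trials`` tensor with fixed axis semantics."""

    values: np.ndarray
    axis_names: tuple[str, str, str] = SLICE_TYPES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise StructuralError(
                f"expected a 3-array (neuron, time, trial); got ndim={self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise StructuralError(f"all dims must be >= 1; got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("tensor entries must all be finite")
        if tuple(self.axis_names) != SLICE_TYPES:
            raise StructuralError(f"axis names must be {SLICE_TYPES}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        return self.values.shape[2]


def as_values(x) -> np.ndarray:
    """Accept a DataTensor or a raw 3-array and return the float64 array."""
    if isinstance(x, DataTensor):
        return x.values
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 3:
        raise StructuralError(f"expected a 3-array; got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class RankTuple:
    """Number of components per slice type: (R_neuron, R_time, R_trial)."""

    neuron: int = 0
    time: int = 0
    trial: int = 0

    def __post_init__(self):
        for st in SLICE_TYPES:
            r = getattr(self, st)
            if not (isinstance(r, (int, np.integer)) and r >= 0):
                raise UsageError(f"rank for {st!r} must be a non-negative int; got {r}")

    @property
    def total(self) -> int:
        return self.neuron + self.time + self.trial

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.neuron, self.time, self.trial)

    def __getitem__(self, slice_type: str) -> int:
        return getattr(self, _check_slice_type(slice_type))

    @classmethod
    def coerce(cls, rank) -> "RankTuple":
        if isinstance(rank, cls):
            return rank
        return cls(*(int(r) for r in rank))


@dataclass
class SliceComponent:
    """One slice-rank-1 term: a loading vector and its slice matrix."""

    slice_type: str
    loading: np.ndarray
    slice: np.ndarray

    def __post_init__(self):
        _check_slice_type(self.slice_type)
        self.loading = np.asarray(self.loading, dtype=np.float64)
        self.slice = np.asarray(self.slice, dtype=np.float64)
        if self.loading.ndim != 1 or self.slice.ndim != 2:
            raise StructuralError(
                "loading must be a vector and slice a matrix; got "
                f"ndim {self.loading.ndim} and {self.slice.ndim}"
            )

    def dims(self) -> tuple[int, int, int]:
        """Infer (N, T, K) implied by this component."""
        L = self.loading.shape[0]
        a, b = self.slice.shape
        if self.slice_type == "neuron":
            return (L, a, b)
        if self.slice_type == "time":
            return (a, L, b)
        return (a, b, L)

    def tensor(self) -> np.ndarray:
        """Dense (N, T, K) tensor of this single component."""
        out = np.multiply.outer(self.loading, self.slice)
        if self.slice_type == "neuron":
            return out
        if self.slice_type == "time":
            return np.moveaxis(out, 0, 1)
        return np.moveaxis(out, 0, 2)


@dataclass
class TCAComponent:
    """A CP/TCA term: outer product of neuron, time and trial factors."""

    neuron_factor: np.ndarray
    time_factor: np.ndarray
    trial_factor: np.ndarray

    def __post_init__(self):
        for name in ("neuron_factor", "time_factor", "trial_factor"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.ndim != 1:
                raise StructuralError(f"{name} must be a vector")
            setattr(self, name, v)

    def as_slice_component(self, slice_type: str = "neuron") -> SliceComponent:
        """Equivalent slicing component: the slice is the rank-1 outer
        product of the two non-loading factors."""
        _check_slice_type(slice_type)
        if slice_type == "neuron":
            return SliceComponent(
                "neuron", self.neuron_factor, np.outer(self.time_factor, self.trial_factor)
            )
        if slice_type == "time":
            return SliceComponent(
                "time", self.time_factor, np.outer(self.neuron_factor, self.trial_factor)
            )
        return SliceComponent(
            "trial", self.trial_factor, np.outer(self.neuron_factor, self.time_factor)
        )


@dataclass
class SliceTCAModel:
    """A slice-rank decomposition: components grouped by slice type.

    Zero-rank models are legal and reconstruct to the all-zeros tensor.
    """

    components: list[SliceComponent]
    dims: tuple[int, int, int]
    nonnegative: bool = False

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise StructuralError(f"bad dims {self.dims}")
        for c in self.components:
            exp_len, exp_shape = slice_dims(c.slice_type, self.dims)
            if c.loading.shape != (exp_len,) or c.slice.shape != exp_shape:
                raise StructuralError(
                    f"component of type {c.slice_type!r} has loading "
                    f"{c.loading.shape} / slice {c.slice.shape}, expected "
                    f"({exp_len},) / {exp_shape} for dims {self.dims}"
                )
        if self.nonnegative:
            for c in self.components:
                if (c.loading < 0).any() or (c.slice < 0).any():
                    raise StructuralError(
                        "non-negative model contains negative entries"
                    )

    @property
    def rank(self) -> RankTuple:
        counts = {st: 0 for st in SLICE_TYPES}
        for c in self.components:
            counts[c.slice_type] += 1
        return RankTuple(counts["neuron"], counts["time"], counts["trial"])

    def components_of(self, slice_type: str) -> list[SliceComponent]:
        _check_slice_type(slice_type)
        return [c for c in self.components if c.slice_type == slice_type]

    def loadings(self, slice_type: str) -> np.ndarray:
        """Stacked loadings, shape (loading length, R_type)."""
        comps = self.components_of(slice_type)
        L, _ = slice_dims(slice_type, self.dims)
        if not comps:
            return np.zeros((L, 0))
        return np.stack([c.loading for c in comps], axis=1)

    def slices(self, slice_type: str) -> np.ndarray:
        """Stacked slices, shape (R_type, a, b)."""
        comps = self.components_of(slice_type)
        _, (a, b) = slice_dims(slice_type, self.dims)
        if not comps:
            return np.zeros((0, a, b))
        return np.stack([c.slice for c in comps], axis=0)

    @classmethod
    def from_arrays(
        cls,
        dims: Sequence[int],
        arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
        nonnegative: bool = False,
    ) -> "SliceTCAModel":
        """Build from per-type (loadings (L, R), slices (R, a, b)) pairs."""
        comps: list[SliceComponent] = []
        for st in SLICE_TYPES:
            if st not in arrays:
                continue
            loadings, slices = arrays[st]
            loadings = np.asarray(loadings, dtype=np.float64)
            slices = np.asarray(slices, dtype=np.float64)
            if loadings.ndim != 2 or slices.ndim != 3 or loadings.shape[1] != slices.shape[0]:
                raise StructuralError(
                    f"bad stacked arrays for {st!r}: {loadings.shape}, {slices.shape}"
                )
            for r in range(loadings.shape[1]):
                comps.append(SliceComponent(st, loadings[:, r], slices[r]))
        return cls(comps, tuple(dims), nonnegative=nonnegative)

    def copy(self) -> "SliceTCAModel":
        return SliceTCAModel(
            [SliceComponent(c.slice_type, c.loading.copy(), c.slice.copy())
             for c in self.components],
            self.dims,
            nonnegative=self.nonnegative,
        )


def _partial_from_stacks(
    slice_type: str, loadings: np.ndarray, slices: np.ndarray, dims: Sequence[int]
) -> np.ndarray:
    """Sum of outer products for one slice type, via a single BLAS call."""
    N, T, K = dims
    R = loadings.shape[1]
    if R == 0:
        return np.zeros((N, T, K))
    flat = loadings @ slices.reshape(R, -1)
    if slice_type == "neuron":
        return flat.reshape(N, T, K)
    if slice_type == "time":
        return np.ascontiguousarray(np.moveaxis(flat.reshape(T, N, K), 0, 1))
    return np.ascontiguousarray(np.moveaxis(flat.reshape(K, N, T), 0, 2))


def partial_reconstruct(model: SliceTCAModel, slice_type: str) -> np.ndarray:
    """Sum of the components of a single slice type, as an (N, T, K) array."""
    _check_slice_type(slice_type)
    return _partial_from_stacks(
        slice_type, model.loadings(slice_type), model.slices(slice_type), model.dims
    )


def reconstruct(model: SliceTCAModel) -> np.ndarray:
    """Full low-slice-rank reconstruction: the sum of the three partials."""
    out = np.zeros(model.dims)
    for st in SLICE_TYPES:
        out += partial_reconstruct(model, st)
    return out


def masked_mse(x, xhat, mask: np.ndarray | None = None) -> float:
    """Mean squared error over selected entries.

    Without a mask this is ``||X - Xhat||_F^2 / (N*T*K)``; with a boolean
    mask only the selected entries enter both the sum and the denominator.
    """
    xv = as_values(x)
    xh = as_values(xhat)
    if xv.shape != xh.shape:
        raise StructuralError(f"shape mismatch: {xv.shape} vs {xh.shape}")
    d = xv - xh
    if mask is None:
        return float(np.mean(d * d))
    mask = np.asarray(mask)
    if mask.shape != xv.shape:
        raise StructuralError(f"mask shape {mask.shape} != data shape {xv.shape}")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise UsageError("mask selects no entries")
    dm = d[mask]
    return float(np.dot(dm, dm) / n_sel)


def tca_reconstruct(components: Iterable[TCAComponent], dims: Sequence[int]) -> np.ndarray:
    """CP reconstruction: entry (n,t,k) = sum_r u_n v_t w_k."""
    N, T, K = dims
    comps = list(components)
    if not comps:
        return np.zeros((N, T, K))
    U = np.stack([c.neuron_factor for c in comps], axis=1)
    V = np.stack([c.time_factor for c in comps], axis=1)
    W = np.stack([c.trial_factor for c in comps], axis=1)
    if U.shape[0] != N or V.shape[0] != T or W.shape[0] != K:
        raise StructuralError(
            f"factor lengths {(U.shape[0], V.shape[0], W.shape[0])} do not "
            f"match dims {(N, T, K)}"
        )
    return np.einsum("nr,tr,kr->ntk", U, V, W, optimize=True)


def relative_error(x, xhat) -> float:
    """Relative Frobenius error ||X - Xhat||_F / ||X||_F (any shape)."""
    xv = x.values if isinstance(x, DataTensor) else np.asarray(x, dtype=np.float64)
    xh = xhat.values if isinstance(xhat, DataTensor) else np.asarray(xhat, dtype=np.float64)
    denom = np.linalg.norm(xv)
    if denom == 0:
        return float(np.linalg.norm(xh) > 0)
    return float(np.linalg.norm(xv - xh) / denom)
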