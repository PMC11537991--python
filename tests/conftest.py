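import numpy as np
import pytest

from slicerank.core import SLICE_TYPES, SliceTCAModel, slice_dims


def random_model(rng, dims, rank, nonnegative=False):
    """Random dense model with the given (R_neuron, R_time, R_trial)."""
    arrays = {}
    for st, R in zip(SLICE_TYPES, rank):
        if R:
            L, (a, b) = slice_dims(st, dims)
            if nonnegative:
                arrays[st] = (rng.uniform(0, 1, (L, R)), rng.uniform(0, 1, (R, a, b)))
            else:
                arrays[st] = (rng.normal(size=(L, R)), rng.normal(size=(R, a, b)))
    return SliceTCAModel.from_arrays(dims, arrays, nonnegative=nonnegative)


def loop_reconstruct(model):
    """Brute-force triple-loop evaluation of the slice-rank model."""
    N, T, K = model.dims
    out = np.zeros((N, T, K))
    for n in range(N):
        for t in range(T):
            for k in range(K):
                for c in model.components:
                    if c.slice_type == "neuron":
                        out[n, t, k] += c.loading[n] * c.slice[t, k]
                    elif c.slice_type == "time":
                        out[n, t, k] += c.loading[t] * c.slice[n, k]
                    else:
                        out[n, t, k] += c.loading[k] * c.slice[n, t]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dims():
    return (3, 4, 2)


@pytest.fixture
def small_model(rng, small_dims):
    return random_model(rng, small_dims, (2, 1, 1))
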