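"""Per-neuron fit quality, per-slice-type contribution ratios, and slice
singular-value spectra."""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    SLICE_TYPES,
    SliceTCAModel,
    StructuralError,
    as_values,
    partial_reconstruct,
    reconstruct,
)


def neuron_goodness_of_fit(x, xhat) -> np.ndarray:
    """Per-neuron 1 - sum_{t,k}(X - Xhat)^2 / sum_{t,k} X^2.

    Neurons with zero raw energy are reported as NaN (undefined).
    """
    xv = as_values(x)
    xh = as_values(xhat)
    if xv.shape != xh.shape:
        raise StructuralError(f"shape mismatch: {xv.shape} vs {xh.shape}")
    num = np.sum((xv - xh) ** 2, axis=(1, 2))
    den = np.sum(xv**2, axis=(1, 2))
    out = np.full(xv.shape[0], np.nan)
    nz = den > 0
    out[nz] = 1.0 - num[nz] / den[nz]
    return out


def component_contributions(model: SliceTCAModel) -> dict[str, np.ndarray]:
    """Per-neuron fraction of the reconstruction owed to each slice type:
    ``f_n^type = sum_{t,k} Xhat^type / sum_{t,k} Xhat`` (raw, unsquared
    sums).  For non-negative models the three fractions lie in [0, 1] and
    sum to one; for sign-unconstrained models cancellation can push them
    outside [0, 1] — they are reported as computed.  Neurons whose total
    reconstructed sum is zero get NaN."""
    total = np.sum(reconstruct(model), axis=(1, 2))
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} neuron(s) have zero reconstructed sum; "
            "their contributions are undefined", RuntimeWarning,
        )
    out: dict[str, np.ndarray] = {}
    for st in SLICE_TYPES:
        part = np.sum(partial_reconstruct(model, st), axis=(1, 2))
        frac = np.full(model.dims[0], np.nan)
        frac[~zero] = part[~zero] / total[~zero]
        out[st] = frac
    return out


def slice_spectra(model: SliceTCAModel, center_axis: int = 1) -> list[dict]:
    """Singular values of each component's slice after centering.

    Centering removes the mean over the slice's second axis by default
    (``center_axis=1``), matching covariance-eigenspectrum usage; pass 0
    to center over rows instead.  Returns one record per component with
    the slice type and the non-increasing singular values."""
    records = []
    for idx, c in enumerate(model.components):
        centered = c.slice - c.slice.mean(axis=center_axis, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        records.append(
            {"component": idx, "slice_type": c.slice_type, "singular_values": s}
        )
    return records
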