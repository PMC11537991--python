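"""Trial-structured preprocessing: piecewise linear time warping to shared
event anchors, Gaussian temporal smoothing, and per-neuron scaling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import UsageError, as_values


@dataclass
class EventAlignment:
    """Per-trial event times and the shared target times to warp onto."""

    trial_anchors: np.ndarray  # (K, n_anchors), strictly increasing per trial
    target_anchors: np.ndarray  # (n_anchors,), strictly increasing

    def __post_init__(self):
        self.trial_anchors = np.asarray(self.trial_anchors, dtype=np.float64)
        self.target_anchors = np.asarray(self.target_anchors, dtype=np.float64)
        if self.trial_anchors.ndim != 2:
            raise UsageError("trial_anchors must be (n_trials, n_anchors)")
        if self.trial_anchors.shape[1] != self.target_anchors.shape[0]:
            raise UsageError("anchor counts must match targets")
        if np.any(np.diff(self.trial_anchors, axis=1) <= 0):
            raise UsageError("anchors must be strictly increasing within each trial")
        if np.any(np.diff(self.target_anchors) <= 0):
            raise UsageError("target anchors must be strictly increasing")


def median_anchor_targets(trial_anchors: np.ndarray) -> np.ndarray:
    """Target anchors whose inter-anchor intervals are the medians of the
    per-trial interval lengths (first anchor at the median start time)."""
    trial_anchors = np.asarray(trial_anchors, dtype=np.float64)
    start = np.median(trial_anchors[:, 0])
    intervals = np.median(np.diff(trial_anchors, axis=1), axis=0)
    return np.concatenate([[start], start + np.cumsum(intervals)])


def piecewise_linear_warp(
    series: np.ndarray,
    sample_times: np.ndarray,
    trial_anchors: np.ndarray,
    target_anchors: np.ndarray,
    out_len: int,
) -> np.ndarray:
    """Warp one trial's series so its anchors land on the targets.

    The output is sampled on ``out_len`` points spanning the target
    anchors; each inter-anchor segment is linearly rescaled, and values
    are linearly interpolated from the recorded samples.
    """
    series = np.asarray(series, dtype=np.float64)
    sample_times = np.asarray(sample_times, dtype=np.float64)
    trial_anchors = np.asarray(trial_anchors, dtype=np.float64)
    target_anchors = np.asarray(target_anchors, dtype=np.float64)
    if np.any(np.diff(trial_anchors) <= 0):
        raise UsageError("trial anchors must be strictly increasing")
    if trial_anchors[0] < sample_times[0] or trial_anchors[-1] > sample_times[-1]:
        raise UsageError("anchors fall outside the recorded span")
    out_grid = np.linspace(target_anchors[0], target_anchors[-1], out_len)
    # map each output time back to source time, piecewise linearly
    src_times = np.interp(out_grid, target_anchors, trial_anchors)
    return np.interp(src_times, sample_times, series)


def warp_trials(
    trials: list[np.ndarray],
    sample_times: list[np.ndarray],
    alignment: EventAlignment,
    out_len: int,
) -> np.ndarray:
    """Warp a list of (N, T_k) trial matrices to a common (K, N, out_len)
    stack; transpose/stack downstream to build the data tensor."""
    K = len(trials)
    if alignment.trial_anchors.shape[0] != K:
        raise UsageError("one anchor row per trial required")
    out = []
    for k in range(K):
        mat = np.asarray(trials[k], dtype=np.float64)
        warped = np.stack(
            [
                piecewise_linear_warp(
                    row, sample_times[k], alignment.trial_anchors[k],
                    alignment.target_anchors, out_len,
                )
                for row in mat
            ]
        )
        out.append(warped)
    return np.stack(out)


def smooth_and_scale(
    x,
    smoothing_width: float = 0.0,
    mode: str | None = None,
) -> np.ndarray:
    """Gaussian smoothing along time (reflect padding) followed by
    per-neuron scaling.

    ``smoothing_width`` is the Gaussian sigma in time bins (0 = none).
    ``mode`` is ``'minmax'`` (per-neuron min 0, max 1 over the whole
    experiment), ``'zscore'``, or None.
    """
    xv = as_values(x).copy()
    if smoothing_width < 0:
        raise UsageError("smoothing_width must be >= 0")
    if smoothing_width > 0:
        xv = gaussian_filter1d(xv, sigma=smoothing_width, axis=1, mode="reflect")
    if mode is None:
        return xv
    if mode == "minmax":
        lo = xv.min(axis=(1, 2), keepdims=True)
        hi = xv.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        flat = span[:, 0, 0] == 0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} constant neuron(s) mapped to 0 under min-max",
                RuntimeWarning,
            )
        span[span == 0] = 1.0
        return (xv - lo) / span
    if mode == "zscore":
        mu = xv.mean(axis=(1, 2), keepdims=True)
        sd = xv.std(axis=(1, 2), keepdims=True)
        sd[sd == 0] = 1.0
        return (xv - mu) / sd
    raise UsageError(f"unknown scaling mode {mode!r}")
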