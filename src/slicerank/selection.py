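"""Blocked held-out masking, cross-validated rank grid search, selection.

Held-out entries are contiguous blocks of time samples on randomly chosen
(neuron, trial) fibers, rather than salt-and-pepper entries, so that
temporal autocorrelation (indicator dynamics, smoothing) cannot leak
information from train to test.  A margin is trimmed from both ends of
each block: margins belong to neither the train nor the test set, and
only block interiors are scored.

The grid search fits every rank tuple under the same per-seed train/test
split and reports per-seed train and test losses.  Model selection uses a
scale-free performance score, ``perf = 1 - RMSE_test / RMS(data)``: all
ranks whose performance reaches a threshold fraction of the best
performance are admissible, and the admissible rank with the smallest
total rank wins (80% threshold for unconstrained models, 95% under
non-negativity, which tolerates less slack because its solution space is
already restricted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .core import RankTuple, UsageError, as_values, masked_mse, reconstruct
from .fitting import FitConfig, FitError, derive_seeds, fit


@dataclass
class HoldoutSpec:
    """Geometry of the blocked holdout mask."""

    fraction: float = 0.20
    block_length: int = 10
    trim_length: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fraction < 1):
            raise UsageError("holdout fraction must lie in (0, 1)")
        if self.block_length < 1 or self.trim_length < 0:
            raise UsageError("block_length >= 1 and trim_length >= 0 required")
        if 2 * self.trim_length >= self.block_length:
            raise UsageError("trim must leave a non-empty block interior")


@dataclass
class MaskSet:
    """Disjoint boolean train/test masks; trimmed margins are in neither."""

    train_mask: np.ndarray
    test_mask: np.ndarray

    def __post_init__(self):
        if self.train_mask.shape != self.test_mask.shape:
            raise UsageError("train and test masks must share a shape")
        if np.any(self.train_mask & self.test_mask):
            raise UsageError("train and test masks overlap")


def make_holdout_mask(dims, spec: HoldoutSpec) -> MaskSet:
    """Place random non-overlapping time blocks on (neuron, trial) fibers
    until ~``fraction`` of all entries is held out (counted before
    trimming).  Blocks never wrap around the time boundary."""
    N, T, K = dims
    B = spec.block_length
    if B > T:
        raise UsageError(f"block_length {B} exceeds T={T}")
    total = N * T * K
    target_blocks = int(round(spec.fraction * total / B))
    capacity = N * K * (T // B)
    if target_blocks > capacity:
        raise UsageError(
            f"cannot place {target_blocks} blocks of length {B}: capacity {capacity}"
        )
    rng = np.random.default_rng(spec.seed)
    held = np.zeros((N, T, K), dtype=bool)
    test = np.zeros((N, T, K), dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = 200 * max(target_blocks, 1)
    while placed < target_blocks:
        attempts += 1
        if attempts > max_attempts:
            raise UsageError(
                "holdout geometry infeasible: rejection sampling exceeded budget"
            )
        n = int(rng.integers(N))
        k = int(rng.integers(K))
        t0 = int(rng.integers(T - B + 1))
        if held[n, t0 : t0 + B, k].any():
            continue
        held[n, t0 : t0 + B, k] = True
        lo = t0 + spec.trim_length
        hi = t0 + B - spec.trim_length
        test[n, lo:hi, k] = True
        placed += 1
    return MaskSet(train_mask=~held, test_mask=test)


@dataclass
class CVResult:
    """Per-rank, per-seed train/test losses from the grid search."""

    grid: dict[RankTuple, dict[str, np.ndarray]]
    n_seeds: int
    holdout: HoldoutSpec
    data_rms: float
    failures: dict[RankTuple, list[str]] = field(default_factory=dict)

    def mean_test_loss(self, rank: RankTuple) -> float:
        return float(np.nanmean(self.grid[rank]["test"]))

    def mean_train_loss(self, rank: RankTuple) -> float:
        return float(np.nanmean(self.grid[rank]["train"]))

    def to_records(self) -> list[dict]:
        rows = []
        for rank, losses in self.grid.items():
            for s in range(len(losses["test"])):
                rows.append(
                    {
                        "R_neuron": rank.neuron,
                        "R_time": rank.time,
                        "R_trial": rank.trial,
                        "seed_index": s,
                        "train_loss": losses["train"][s],
                        "test_loss": losses["test"][s],
                    }
                )
        return rows


def default_grid(max_rank: int = 4) -> list[RankTuple]:
    """Full {0..max_rank}^3 grid, ordered by increasing total rank."""
    grid = [
        RankTuple(a, b, c)
        for a, b, c in itertools.product(range(max_rank + 1), repeat=3)
    ]
    grid.sort(key=lambda r: (r.total, r.as_tuple()))
    return grid


def grid_search(
    x,
    rank_grid,
    spec: HoldoutSpec | None = None,
    fit_config: FitConfig | None = None,
    n_seeds: int = 10,
) -> CVResult:
    """Cross-validated 3D grid search over rank tuples.

    For each repetition a fresh blocked train/test split and a fresh
    parameter-initialization seed are drawn; the same split/seed pair is
    reused for every rank so that grid points are directly comparable.
    """
    spec = spec or HoldoutSpec()
    fit_config = fit_config or FitConfig()
    grid = [RankTuple.coerce(r) for r in rank_grid]
    if not grid:
        raise UsageError("rank grid is empty")
    xv = as_values(x)
    seeds = derive_seeds(spec.seed, 2 * n_seeds)
    mask_seeds, init_seeds = seeds[:n_seeds], seeds[n_seeds:]
    results = {r: {"train": np.full(n_seeds, np.nan), "test": np.full(n_seeds, np.nan)}
               for r in grid}
    failures: dict[RankTuple, list[str]] = {}
    for s in range(n_seeds):
        masks = make_holdout_mask(xv.shape, replace(spec, seed=mask_seeds[s]))
        for rank in grid:
            cfg = replace(fit_config, seed=init_seeds[s])
            try:
                res = fit(xv, rank, masks.train_mask, cfg)
            except FitError as err:
                failures.setdefault(rank, []).append(f"seed {s}: {err}")
                continue
            results[rank]["train"][s] = res.final_loss
            results[rank]["test"][s] = masked_mse(
                xv, reconstruct(res.model), masks.test_mask
            )
    return CVResult(
        grid=results,
        n_seeds=n_seeds,
        holdout=spec,
        data_rms=float(np.sqrt(np.mean(xv**2))),
        failures=failures,
    )


def performance(cv: CVResult, rank: RankTuple) -> float:
    """Scale-free skill score 1 - RMSE_test / RMS(data)."""
    return 1.0 - float(np.sqrt(cv.mean_test_loss(rank))) / cv.data_rms


def select_model(
    cv: CVResult,
    nonnegative: bool = False,
    theta: float | None = None,
) -> RankTuple:
    """Smallest-total-rank model within the admissible performance band.

    ``theta`` overrides the default threshold (0.80 unconstrained, 0.95
    non-negative); pass an explicit value for elbow-style near-optimal
    selection.  Ties in total rank break lexicographically on
    (R_neuron, R_time, R_trial).
    """
    if theta is None:
        theta = 0.95 if nonnegative else 0.80
    scored = [
        (rank, performance(cv, rank))
        for rank in cv.grid
        if np.isfinite(cv.mean_test_loss(rank))
    ]
    if not scored:
        raise UsageError("no successful grid points to select from")
    best_perf = max(p for _, p in scored)
    # guard the degenerate case best_perf <= 0, where the band is empty
    admissible = [
        rank for rank, p in scored if p >= theta * best_perf or p >= best_perf
    ]
    admissible.sort(key=lambda r: (r.total, r.as_tuple()))
    return admissible[0]
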