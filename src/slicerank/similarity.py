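"""Agreement between two fitted decompositions, with a shuffle baseline.

Components are compared per slice type: each pair gets a score in [0, 1]
equal to the mean of the |cosine| between the loading vectors and the
|cosine| between the vectorized slices (the absolute value absorbs the
sign ambiguity of unconstrained factorizations).  Components are matched
by the Hungarian algorithm maximizing the summed score; the overall
similarity is the mean of the matched per-component scores.  The chance
baseline permutes the entries within each weight vector of one model
before rescoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SLICE_TYPES, SliceTCAModel, UsageError


def _abs_cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero weight vector in similarity; scoring 0", RuntimeWarning)
        return 0.0
    return float(abs(np.dot(a.ravel(), b.ravel())) / (na * nb))


@dataclass
class SimilarityReport:
    overall: float
    per_slice_type: dict[str, float]
    per_component: dict[str, list[dict]] = field(default_factory=dict)
    matching: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "per_slice_type": self.per_slice_type,
            "per_component": self.per_component,
            "matching": {k: [list(p) for p in v] for k, v in self.matching.items()},
        }


def _score_matrix(a: SliceTCAModel, b: SliceTCAModel, st: str):
    ca = a.components_of(st)
    cb = b.components_of(st)
    R = len(ca)
    load = np.zeros((R, R))
    slc = np.zeros((R, R))
    for i, ci in enumerate(ca):
        for j, cj in enumerate(cb):
            load[i, j] = _abs_cosine(ci.loading, cj.loading)
            slc[i, j] = _abs_cosine(ci.slice, cj.slice)
    return load, slc


def model_similarity(a: SliceTCAModel, b: SliceTCAModel) -> SimilarityReport:
    """Matched-component agreement score between two models of equal rank."""
    if a.rank != b.rank or a.dims != b.dims:
        raise UsageError(
            f"models must share rank and dims; got {a.rank}/{a.dims} vs "
            f"{b.rank}/{b.dims}"
        )
    per_type: dict[str, float] = {}
    per_comp: dict[str, list[dict]] = {}
    matching: dict[str, list[tuple[int, int]]] = {}
    all_scores: list[float] = []
    for st in SLICE_TYPES:
        R = a.rank[st]
        if R == 0:
            continue
        load, slc = _score_matrix(a, b, st)
        combined = 0.5 * (load + slc)
        rows, cols = linear_sum_assignment(-combined)
        matching[st] = list(zip(rows.tolist(), cols.tolist()))
        pairs = []
        scores = []
        for i, j in matching[st]:
            pairs.append(
                {"a": int(i), "b": int(j),
                 "loading_score": load[i, j], "slice_score": slc[i, j],
                 "score": combined[i, j]}
            )
            scores.append(combined[i, j])
        per_comp[st] = pairs
        per_type[st] = float(np.mean(scores))
        all_scores.extend(scores)
    overall = float(np.mean(all_scores)) if all_scores else 1.0
    return SimilarityReport(overall=overall, per_slice_type=per_type,
                            per_component=per_comp, matching=matching)


def _shuffle_model(model: SliceTCAModel, rng: np.random.Generator) -> SliceTCAModel:
    out = model.copy()
    for c in out.components:
        c.loading = rng.permutation(c.loading)
        flat = rng.permutation(c.slice.ravel())
        c.slice = flat.reshape(c.slice.shape)
    return out


def shuffled_similarity(
    a: SliceTCAModel,
    b: SliceTCAModel,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Mean per-slice-type similarity after permuting the entries within
    each weight vector of ``b`` — the chance level against which the true
    similarity should be judged."""
    rng = np.random.default_rng(seed)
    sums: dict[str, float] = {}
    overall_sum = 0.0
    for _ in range(n_shuffles):
        rep = model_similarity(a, _shuffle_model(b, rng))
        for st, v in rep.per_slice_type.items():
            sums[st] = sums.get(st, 0.0) + v
        overall_sum += rep.overall
    out = {st: v / n_shuffles for st, v in sums.items()}
    out["overall"] = overall_sum / n_shuffles
    return out
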