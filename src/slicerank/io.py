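"""Serialization: HDF5/NPZ tensors, HDF5 models, CSV/JSON exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    SLICE_TYPES,
    DataTensor,
    SliceTCAModel,
    StructuralError,
    UsageError,
)
from .selection import CVResult
from .synthetic import GroundTruthBundle


def save_tensor(path, tensor: DataTensor) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, tensor=tensor.values, axis_names=np.array(tensor.axis_names))
        return
    with h5py.File(path, "w") as f:
        d = f.create_dataset("tensor", data=tensor.values, track_times=False)
        d.attrs["axis_names"] = [s.encode() for s in tensor.axis_names]
        d.attrs["dims"] = tensor.dims


def load_tensor(path) -> DataTensor:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            return DataTensor(f["tensor"])
    with h5py.File(path, "r") as f:
        if "tensor" not in f:
            raise StructuralError(f"{path} has no 'tensor' dataset")
        return DataTensor(f["tensor"][()])


def save_model(path, model: SliceTCAModel, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dims"] = model.dims
        f.attrs["nonnegative"] = model.nonnegative
        for st in SLICE_TYPES:
            g = f.create_group(st)
            g.create_dataset("loadings", data=model.loadings(st), track_times=False)
            g.create_dataset("slices", data=model.slices(st), track_times=False)
        if attrs:
            f.attrs["meta"] = json.dumps(attrs)


def load_model(path) -> SliceTCAModel:
    with h5py.File(path, "r") as f:
        dims = tuple(int(d) for d in f.attrs["dims"])
        nonneg = bool(f.attrs["nonnegative"])
        arrays = {}
        for st in SLICE_TYPES:
            loadings = f[st]["loadings"][()]
            slices = f[st]["slices"][()]
            if loadings.shape[1] > 0:
                arrays[st] = (loadings, slices)
        return SliceTCAModel.from_arrays(dims, arrays, nonnegative=nonneg)


def model_to_csv(path, model: SliceTCAModel) -> None:
    """Tidy long-format export: one row per weight."""
    rows = []
    for cid, c in enumerate(model.components):
        for i, w in enumerate(c.loading):
            rows.append((cid, c.slice_type, "loading", i, -1, w))
        for (i, j), w in np.ndenumerate(c.slice):
            rows.append((cid, c.slice_type, "slice", i, j, w))
    pd.DataFrame(
        rows, columns=["component", "slice_type", "part", "index0", "index1", "weight"]
    ).to_csv(path, index=False)


def save_bundle(path, bundle: GroundTruthBundle) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=bundle.tensor.values, track_times=False)
        f.create_dataset("noiseless", data=bundle.noiseless, track_times=False)
        f.create_dataset("trial_labels", data=np.asarray(bundle.trial_labels, dtype=float), track_times=False)
        g = f.create_group("sources")
        for name, arr in bundle.sources.items():
            g.create_dataset(name, data=arr, track_times=False)
        f.attrs["params"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in bundle.params.items()}
        )


def load_bundle(path) -> GroundTruthBundle:
    with h5py.File(path, "r") as f:
        return GroundTruthBundle(
            tensor=DataTensor(f["tensor"][()]),
            noiseless=f["noiseless"][()],
            sources={k: v[()] for k, v in f["sources"].items()},
            params=json.loads(f.attrs["params"]),
            trial_labels=f["trial_labels"][()],
        )


def cv_to_csv(path, cv: CVResult) -> None:
    pd.DataFrame(cv.to_records()).to_csv(path, index=False)


def cv_summary(cv: CVResult) -> dict:
    from .selection import performance

    return {
        "n_seeds": cv.n_seeds,
        "holdout": {
            "fraction": cv.holdout.fraction,
            "block_length": cv.holdout.block_length,
            "trim_length": cv.holdout.trim_length,
            "seed": cv.holdout.seed,
        },
        "grid": [
            {
                "rank": list(rank.as_tuple()),
                "mean_train_loss": cv.mean_train_loss(rank),
                "mean_test_loss": cv.mean_test_loss(rank),
                "performance": performance(cv, rank),
            }
            for rank in cv.grid
        ],
    }
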