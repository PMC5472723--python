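"""HDF5/NPZ containers for datasets, fitted models, features and Gabors.

A dataset container holds ``stimulus`` (T x H x W), ``spikes`` (T),
``bin_ms`` and optionally ``repeats`` (n_trials x T).  Model containers
store the QCParams blocks together with the geometry and model-structure
flags, plus a JSON echo of the configuration that produced them, so
every output is self-describing.  Files ending in ``.npz`` use a plain
NumPy archive with the same keys as a fallback to HDF5.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .eigenfeatures import EigenFeature
from .gaborfit import GaborParams
from .model import ModelSpec, QCParams
from .stimuli import PatchConfig, StimulusMovie

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_model",
    "read_model",
    "write_features",
    "read_features",
    "write_gabors",
    "read_gabors",
]


def _is_npz(path: str) -> bool:
    return str(path).endswith(".npz")


def write_dataset(path, movie: StimulusMovie, spikes, repeats=None) -> None:
    spikes = np.asarray(spikes)
    if spikes.shape[0] != movie.n_frames:
        raise ValueError("spikes length does not match stimulus frames")
    data = {"stimulus": movie.frames, "spikes": spikes, "bin_ms": movie.bin_ms}
    if repeats is not None:
        data["repeats"] = np.asarray(repeats)
    if _is_npz(path):
        np.savez(path, **data)
        return
    with h5py.File(path, "w") as f:
        for k, v in data.items():
            f.create_dataset(k, data=v)


def read_dataset(path):
    """Load a dataset container -> (StimulusMovie, spikes, repeats | None).

    The stimulus is validated and mean-centered on load; spikes must be
    nonnegative integers aligned to the frames.
    """
    if _is_npz(path):
        with np.load(path) as f:
            data = {k: f[k] for k in f.files}
    else:
        with h5py.File(path, "r") as f:
            data = {k: f[k][()] for k in f.keys()}
    for key in ("stimulus", "spikes", "bin_ms"):
        if key not in data:
            raise KeyError(f"dataset file {path} is missing required key {key!r}")
    movie = StimulusMovie(frames=data["stimulus"], bin_ms=float(np.asarray(data["bin_ms"]).item()))
    spikes = np.asarray(data["spikes"])
    if spikes.ndim != 1 or spikes.shape[0] != movie.n_frames:
        raise ValueError(
            f"key 'spikes' must be a vector of length {movie.n_frames}, got shape {spikes.shape}"
        )
    if np.any(spikes < 0) or not np.allclose(spikes, np.round(spikes)):
        raise ValueError("key 'spikes' must hold nonnegative integer counts")
    spikes = spikes.astype(np.int64)
    repeats = data.get("repeats")
    if repeats is not None:
        repeats = np.asarray(repeats)
        if repeats.ndim != 2 or repeats.shape[1] != movie.n_frames:
            raise ValueError(
                f"key 'repeats' must be n_trials x {movie.n_frames}, got shape {repeats.shape}"
            )
    return movie, spikes, repeats


def _config_json(**kwargs) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    return json.dumps(kwargs, default=default, sort_keys=True)


def write_model(path, params: QCParams, cfg: PatchConfig, spec: ModelSpec,
                frame_shape, extra_config=None) -> None:
    blocks = {
        "a1": params.a1,
        "v1": params.v1,
        "J": params.J,
        "v2": params.v2,
        "a2": params.a2,
        "d": params.d,
    }
    meta = _config_json(
        patch_config=cfg,
        model_spec=spec,
        frame_shape=list(frame_shape),
        extra=extra_config or {},
    )
    if _is_npz(path):
        np.savez(path, config_json=np.bytes_(meta.encode()), **blocks)
        return
    with h5py.File(path, "w") as f:
        for k, v in blocks.items():
            f.create_dataset(k, data=v)
        f.attrs["config_json"] = meta


def read_model(path):
    """-> (QCParams, PatchConfig, ModelSpec, frame_shape)."""
    if _is_npz(path):
        with np.load(path) as f:
            data = {k: f[k] for k in f.files}
            meta = json.loads(bytes(data.pop("config_json")).decode())
    else:
        with h5py.File(path, "r") as f:
            data = {k: f[k][()] for k in f.keys()}
            meta = json.loads(f.attrs["config_json"])
    params = QCParams(
        a1=float(data["a1"]),
        v1=data["v1"],
        J=data["J"],
        v2=data["v2"],
        a2=float(data["a2"]),
        d=float(data["d"]),
    )
    pc = meta["patch_config"]
    cfg = PatchConfig(
        patch_h=int(pc["patch_h"]),
        patch_w=int(pc["patch_w"]),
        stride=int(pc["stride"]),
        n_lags=int(pc["n_lags"]),
    )
    ms = meta["model_spec"]
    spec = ModelSpec(
        quadratic=bool(ms["quadratic"]),
        convolutional=bool(ms["convolutional"]),
        final_nonlinearity=str(ms["final_nonlinearity"]),
    )
    return params, cfg, spec, tuple(meta["frame_shape"])


def write_features(path, features: list, extra_config=None) -> None:
    vecs = np.stack([f.vector for f in features]) if features else np.zeros((0, 0))
    evals = np.array([f.eigenvalue for f in features])
    pvals = np.array([f.p_value for f in features])
    meta = _config_json(extra=extra_config or {})
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=vecs)
        f.create_dataset("eigenvalues", data=evals)
        f.create_dataset("p_values", data=pvals)
        f.attrs["config_json"] = meta


def read_features(path) -> list:
    with h5py.File(path, "r") as f:
        vecs = f["vectors"][()]
        evals = f["eigenvalues"][()]
        pvals = f["p_values"][()]
    return [
        EigenFeature(vector=vecs[i], eigenvalue=float(evals[i]), p_value=float(pvals[i]))
        for i in range(len(evals))
    ]


_GABOR_FIELDS = ("x0", "y0", "theta", "gamma", "sigma", "lam", "phi", "A", "w")


def write_gabors(path, gabors: list, shape, extra_config=None) -> None:
    arr = np.array([[getattr(g, k) for k in _GABOR_FIELDS] for g in gabors])
    meta = _config_json(shape=list(shape), extra=extra_config or {})
    with h5py.File(path, "w") as f:
        f.create_dataset("gabors", data=arr)
        f.attrs["config_json"] = meta


def read_gabors(path):
    with h5py.File(path, "r") as f:
        arr = f["gabors"][()]
        meta = json.loads(f.attrs["config_json"])
    gabors = [GaborParams(**dict(zip(_GABOR_FIELDS, row))) for row in arr]
    return gabors, tuple(meta["shape"])
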