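"""Serialization: HDF5 containers for weights/models/traces, CSV for series.

A trained model reloads bit-exactly: weight matrices, readouts, selected
nodes, filter state and the carried-over reservoir states are all stored in
one HDF5 file, with configs serialized as JSON attributes.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import PredictionTrace, TrainedModel, TrainingConfig
from .readout import Readout
from .reservoir import (
    FastReservoirConfig,
    ReservoirWeights,
    SDPConfig,
    SlowReservoirConfig,
)
from .slow_feature import SlowNodeSet
from .systems import ObservationSeries

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "save_trajectory",
    "write_slow_feature",
    "save_weights",
    "load_weights",
    "save_model",
    "load_model",
    "save_prediction",
]


def write_series_csv(path, values, column: str = "y") -> None:
    """Two-column CSV (n, value) for observation or parameter series."""
    values = np.asarray(values)
    pd.DataFrame({"n": np.arange(len(values)), column: values}).to_csv(
        path, index=False)


def read_series_csv(path, column: str | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if column is None:
        column = [c for c in df.columns if c != "n"][0]
    return df[column].to_numpy(dtype=float)


def write_slow_feature(csv_path, json_path, u_tilde, h, scores, indices,
                       n_window: int, tau_f: float, seed: int) -> None:
    """Slow-feature series as CSV (n, u_tilde, h) with a JSON sidecar."""
    u_tilde = np.asarray(u_tilde)
    pd.DataFrame({"n": np.arange(len(u_tilde)), "u_tilde": u_tilde,
                  "h": np.asarray(h)}).to_csv(csv_path, index=False)
    sidecar = {
        "scores": np.asarray(scores).tolist(),
        "selected_indices": np.asarray(indices).tolist(),
        "n_window": int(n_window),
        "tau_f": float(tau_f),
        "seed": int(seed),
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh)


def save_trajectory(path, traj, seed: int | None = None) -> None:
    """Single HDF5 container: dense trajectory, lambda series, metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.t)
        f.create_dataset("x", data=traj.x)
        f.create_dataset("lambda", data=traj.lam)
        f.attrs["spec"] = _cfg_json(traj.spec)
        if traj.schedule is not None:
            f.attrs["schedule_kind"] = traj.schedule.kind
            f.attrs["schedule"] = _cfg_json(traj.schedule)
        f.attrs["dt_int"] = traj.spec.dt_int
        if seed is not None:
            f.attrs["seed"] = seed


def _write_matrix(grp: h5py.Group, name: str, M) -> None:
    if sp.issparse(M):
        M = sp.csr_array(M)
        g = grp.create_group(name)
        g.attrs["format"] = "csr"
        g.create_dataset("data", data=M.data)
        g.create_dataset("indices", data=M.indices)
        g.create_dataset("indptr", data=M.indptr)
        g.attrs["shape"] = M.shape
    else:
        d = grp.create_dataset(name, data=np.asarray(M))
        d.attrs["format"] = "dense"


def _read_matrix(grp: h5py.Group, name: str):
    obj = grp[name]
    if isinstance(obj, h5py.Group):
        return sp.csr_array(
            (obj["data"][:], obj["indices"][:], obj["indptr"][:]),
            shape=tuple(obj.attrs["shape"]))
    return obj[:]


def _weights_to_group(g: h5py.Group, w: ReservoirWeights) -> None:
    g.attrs["kind"] = w.kind
    g.attrs["activation"] = w.activation
    g.attrs["seed"] = w.seed
    g.attrs["leak_rate"] = np.nan if w.leak_rate is None else w.leak_rate
    _write_matrix(g, "W", w.W)
    for name, vec in (("w_in", w.w_in), ("w_param", w.w_param), ("b", w.b)):
        if vec is not None:
            g.create_dataset(name, data=vec)


def _weights_from_group(g: h5py.Group) -> ReservoirWeights:
    leak = float(g.attrs["leak_rate"])
    return ReservoirWeights(
        kind=str(g.attrs["kind"]),
        W=_read_matrix(g, "W"),
        w_in=g["w_in"][:] if "w_in" in g else None,
        w_param=g["w_param"][:] if "w_param" in g else None,
        b=g["b"][:],
        leak_rate=None if np.isnan(leak) else leak,
        activation=str(g.attrs["activation"]),
        seed=int(g.attrs["seed"]),
    )


def save_weights(path, w: ReservoirWeights) -> None:
    with h5py.File(path, "w") as f:
        _weights_to_group(f.create_group("weights"), w)


def load_weights(path) -> ReservoirWeights:
    with h5py.File(path, "r") as f:
        return _weights_from_group(f["weights"])


def _cfg_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg))


def save_model(path, model: TrainedModel, include_traces: bool = False) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["slow_cfg"] = _cfg_json(model.slow_cfg)
        f.attrs["fast_cfg"] = _cfg_json(model.fast_cfg)
        f.attrs["sdp_cfg"] = _cfg_json(model.sdp_cfg)
        f.attrs["train_cfg"] = _cfg_json(model.train_cfg)
        f.attrs["beta"] = model.beta
        f.attrs["y_train_ptp"] = model.y_train_ptp
        f.attrs["train_rmse"] = model.train_rmse
        f.attrs["node_fraction"] = model.slow_nodes.fraction
        for name, w in (("slow", model.slow_weights),
                        ("fast", model.fast_weights),
                        ("sdp", model.sdp_weights)):
            _weights_to_group(f.create_group(name), w)
        f.create_dataset("slow_nodes", data=model.slow_nodes.indices)
        f.create_dataset("scores", data=model.scores)
        f.create_dataset("u_tilde", data=model.u_tilde)
        f.create_dataset("h", data=model.h)
        f.create_dataset("u_fast_end", data=model.u_fast_end)
        f.create_dataset("u_sdp_end", data=model.u_sdp_end)
        for name, r in (("fast_readout", model.fast_readout),
                        ("sdp_readout", model.sdp_readout)):
            g = f.create_group(name)
            g.create_dataset("w_out", data=r.w_out)
            g.attrs["b_out"] = r.b_out
            g.attrs["beta"] = r.beta
        if include_traces and model.fast_trace is not None:
            f.create_dataset("fast_trace", data=model.fast_trace)
            f.create_dataset("sdp_trace", data=model.sdp_trace)
            f.create_dataset("slow_trace", data=model.slow_trace)


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        def readout(name):
            g = f[name]
            return Readout(w_out=g["w_out"][:], b_out=float(g.attrs["b_out"]),
                           beta=float(g.attrs["beta"]))

        return TrainedModel(
            slow_cfg=SlowReservoirConfig(**json.loads(f.attrs["slow_cfg"])),
            fast_cfg=FastReservoirConfig(**json.loads(f.attrs["fast_cfg"])),
            sdp_cfg=SDPConfig(**json.loads(f.attrs["sdp_cfg"])),
            train_cfg=TrainingConfig(**json.loads(f.attrs["train_cfg"])),
            slow_weights=_weights_from_group(f["slow"]),
            fast_weights=_weights_from_group(f["fast"]),
            sdp_weights=_weights_from_group(f["sdp"]),
            slow_nodes=SlowNodeSet(indices=f["slow_nodes"][:],
                                   fraction=float(f.attrs["node_fraction"])),
            scores=f["scores"][:],
            u_tilde=f["u_tilde"][:],
            h=f["h"][:],
            fast_readout=readout("fast_readout"),
            sdp_readout=readout("sdp_readout"),
            u_fast_end=f["u_fast_end"][:],
            u_sdp_end=f["u_sdp_end"][:],
            beta=float(f.attrs["beta"]),
            y_train_ptp=float(f.attrs["y_train_ptp"]),
            train_rmse=float(f.attrs.get("train_rmse", np.nan)),
            fast_trace=f["fast_trace"][:] if "fast_trace" in f else None,
            sdp_trace=f["sdp_trace"][:] if "sdp_trace" in f else None,
            slow_trace=f["slow_trace"][:] if "slow_trace" in f else None,
        )


def save_prediction(h5_path, csv_path, pred: PredictionTrace) -> None:
    """Prediction trace as HDF5 (with states) plus CSV (n, y_pred, h_pred)."""
    with h5py.File(h5_path, "w") as f:
        f.attrs["n0"] = pred.n0
        f.attrs["diverged_at"] = -1 if pred.diverged_at is None else pred.diverged_at
        f.create_dataset("y_pred", data=pred.y_pred)
        f.create_dataset("h_pred", data=pred.h_pred)
        if pred.fast_states is not None:
            f.create_dataset("fast_states", data=pred.fast_states)
        if pred.sdp_states is not None:
            f.create_dataset("sdp_states", data=pred.sdp_states)
    pd.DataFrame({"n": pred.steps, "y_pred": pred.y_pred,
                  "h_pred": pred.h_pred}).to_csv(csv_path, index=False)
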