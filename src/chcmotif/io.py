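"""File-format adapters: behavior CSV, trace HDF5, stack TIFF, config YAML."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import BehaviorTrace


def write_behavior_csv(path, trace: BehaviorTrace, states=None, md=None) -> None:
    trace.to_frame(states=states, md=md).to_csv(path, index=False)


def read_behavior_csv(path, sample_rate: float = 100.0) -> BehaviorTrace:
    df = pd.read_csv(path)
    if df.isna().all(axis=1).any():
        raise ValueError("all-NaN frames in behavior CSV")
    return BehaviorTrace(
        time_s=df["time_s"].to_numpy(),
        fb_speed=df["fb_speed"].to_numpy(),
        rl_speed=df["rl_speed"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        sample_rate=sample_rate,
    )


def write_traces_h5(path, dff_set=None, events=None, frame_rate=None, **extra) -> None:
    with h5py.File(path, "w") as f:
        if dff_set is not None:
            for name in ("F", "F0", "dff", "background_dff"):
                f.create_dataset(name, data=getattr(dff_set, name))
            f.attrs["frame_rate"] = dff_set.frame_rate
        if events is not None:
            f.create_dataset("events", data=np.asarray(events, dtype=np.int8))
        if frame_rate is not None:
            f.attrs["frame_rate"] = frame_rate
        for k, v in extra.items():
            f.create_dataset(k, data=v)


def read_traces_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for k in f.keys():
            out[k] = f[k][()]
        out.update({f"attr_{k}": v for k, v in f.attrs.items()})
    return out


def write_stack_tiff(path, stack) -> None:
    """3-channel stack as a (z, c, y, x) multi-page TIFF."""
    order = ("gephyrin", "chc", "ais")
    arr = np.stack([stack.channels[c] for c in order], axis=1).astype(np.float32)
    tifffile.imwrite(path, arr, metadata={"axes": "ZCYX", "channels": ",".join(order)})


def read_stack_tiff(path, voxel_size_um=(1.0, 0.15, 0.15)):
    from .synthetic.stack import ImageStack

    arr = tifffile.imread(path)
    if arr.ndim != 4:
        raise ValueError("expected a (z, c, y, x) stack")
    order = ("gephyrin", "chc", "ais")
    return ImageStack(
        channels={c: arr[:, i] for i, c in enumerate(order)}, voxel_size_um=voxel_size_um
    )


def load_config(path, cls):
    """Instantiate a simulation config dataclass from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return cls(**data)


def write_ground_truth_json(path, truth) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(truth.__dict__, default=default, indent=1))
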