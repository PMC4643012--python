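"""Movie, event-table, property-map and config round-trips.

Movies travel as multi-page 32-bit float TIFF (one page per frame, metadata
in the ImageDescription tag) or as compressed ``.npz`` containers; event
plots as tidy CSV with columns kind, chirality, x, y, t; property maps as
CSV grids or float TIFF; run configuration as flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .events import EventPlot, PatternEvent
from .numerics import SpaceTimeCube

__all__ = [
    "save_movie", "load_movie",
    "save_events", "load_events",
    "save_property_map", "load_property_map",
    "save_config", "load_config",
]

_EVENT_KINDS = {"target_origin", "spiral_tip"}
_CHIRALITIES = {"left", "right", "none"}


def save_movie(cube: SpaceTimeCube, path: str | Path) -> Path:
    path = Path(path)
    meta = {"dt_record": cube.dt_record, "dx": cube.dx, **cube.meta}
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, cube.data.astype(np.float32),
                         description=json.dumps(meta))
    elif path.suffix == ".npz":
        np.savez_compressed(path, data=cube.data.astype(np.float32),
                            meta=json.dumps(meta))
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")
    return path


def load_movie(path: str | Path) -> SpaceTimeCube:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]
            meta = json.loads(str(z["meta"]))
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")
    if data.ndim == 2:
        data = data[None]
    dt_record = float(meta.pop("dt_record", 1.0))
    dx = float(meta.pop("dx", 1.0))
    cube = SpaceTimeCube(np.asarray(data, dtype=float), dt_record=dt_record, dx=dx)
    cube.meta.update(meta)
    return cube


def save_events(ep: EventPlot, path: str | Path) -> Path:
    path = Path(path)
    df = ep.to_dataframe()
    df.attrs["shape"] = ep.shape
    header = f"# shape={ep.shape[0]}x{ep.shape[1]} n_frames={ep.n_frames}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def load_events(path: str | Path) -> EventPlot:
    path = Path(path)
    shape = (0, 0)
    n_frames = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if key == "shape":
                    a, _, b = val.partition("x")
                    shape = (int(a), int(b))
                elif key == "n_frames":
                    n_frames = int(val)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    events = []
    for idx, row in df.iterrows():
        if row["kind"] not in _EVENT_KINDS:
            raise ValueError(f"row {idx}: unknown event kind {row['kind']!r}")
        if row["chirality"] not in _CHIRALITIES:
            raise ValueError(f"row {idx}: unknown chirality {row['chirality']!r}")
        events.append(PatternEvent(row["kind"], row["chirality"],
                                   float(row["x"]), float(row["y"]), int(row["t"])))
    return EventPlot(events, shape=shape, n_frames=n_frames)


def save_property_map(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, values.astype(np.float32))
    elif path.suffix == ".csv":
        np.savetxt(path, values, delimiter=",")
    else:
        raise ValueError(f"unsupported property-map format {path.suffix!r}")
    return path


def load_property_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    if path.suffix == ".csv":
        return np.loadtxt(path, delimiter=",", ndmin=2)
    raise ValueError(f"unsupported property-map format {path.suffix!r}")


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError("config file must contain a mapping")
    return out
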