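"""File formats: TIFF stacks with JSON sidecars, CSV traces and tables.

Hyper-temporal stacks are stored as multi-page 32-bit float TIFF (page order
= ascending gate time) with a sidecar metadata file ``<path>.json`` carrying
``gate_times_s``, ``gate_width_s``, ``pixel_size_m`` and ``seed``; a
write-read round trip reproduces the frame payload bit-exactly.  Temperature
movies use the same layout with ``frame_times_s``.  Traces are CSV with the
header ``time_s,value_mV``; numbers are written in shortest round-trip
decimal form (Python repr).
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .detection import HyperStack, TimeTrace
from .phantom import TemperatureMovie, ThermalPhantom

__all__ = [
    "write_stack", "read_stack",
    "write_movie",
    "write_trace", "read_trace",
    "write_map_csv", "write_linescan_csv",
    "config_hash",
]


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _utc_now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%SZ")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Stacks
# --------------------------------------------------------------------------

def write_stack(stack: HyperStack, path, seed: int | None = None,
                extra_metadata: dict | None = None) -> Path:
    """Write a stack as float32 multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "gate_times_s": [float(t) for t in stack.gate_times],
        "gate_width_s": float(stack.gate_width),
        "pixel_size_m": float(stack.pixel_size),
        "seed": seed if seed is not None else stack.metadata.get("seed"),
        "created_utc": _utc_now(),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path) -> HyperStack:
    """Read a stack written by :func:`write_stack`, validating the sidecar.

    Rejects a missing sidecar, a page count that does not match
    ``gate_times_s``, and non-monotone gate times.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {side}")
    meta = json.loads(side.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    gate_times = np.asarray(meta.get("gate_times_s", []), dtype=float)
    if frames.shape[0] != len(gate_times):
        raise ValueError(
            f"TIFF has {frames.shape[0]} pages but sidecar lists "
            f"{len(gate_times)} gate times")
    if len(gate_times) > 1 and np.any(np.diff(gate_times) <= 0):
        raise ValueError("sidecar gate times are not strictly increasing")
    return HyperStack(frames=frames.astype(np.float32),
                      gate_times=gate_times,
                      pixel_size=float(meta["pixel_size_m"]),
                      gate_width=float(meta["gate_width_s"]),
                      metadata=meta)


def write_movie(movie: TemperatureMovie, path, seed: int | None = None) -> Path:
    """Write a temperature movie as float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "frame_times_s": [float(t) for t in movie.frame_times],
        "pixel_size_m": float(movie.pixel_size),
        "seed": seed,
        "created_utc": _utc_now(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Traces and tables
# --------------------------------------------------------------------------

def write_trace(trace: TimeTrace, path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value_mV"])
        for t, v in zip(trace.times, trace.values):
            w.writerow([repr(float(t)), repr(float(v))])
    return path


def read_trace(path) -> TimeTrace:
    path = Path(path)
    times, values = [], []
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["time_s", "value_mV"]:
            raise ValueError(f"unexpected trace CSV header {header!r}")
        for row in reader:
            times.append(float(row[0]))
            values.append(float(row[1]))
    return TimeTrace(times=np.array(times), values=np.array(values))


def write_map_csv(values: np.ndarray, valid: np.ndarray, path) -> Path:
    """Per-pixel map as ``x_px,y_px,value,valid`` rows."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_px", "y_px", "value", "valid"])
        ny, nx = values.shape
        for r in range(ny):
            for c in range(nx):
                w.writerow([c, r, repr(float(values[r, c])), int(valid[r, c])])
    return path


def write_linescan_csv(positions: np.ndarray, values: np.ndarray, path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position_m", "value_mV"])
        for p, v in zip(positions, values):
            w.writerow([repr(float(p)), repr(float(v))])
    return path
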