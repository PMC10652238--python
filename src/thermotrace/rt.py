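"""Rate-of-transfer (RT) estimation from hyper-temporal stacks.

By analogy with the heat equation dT/dt = alpha * laplacian(T), the rate of
transfer at a location is

    RT = (dBC/dt) / laplacian(BC)        [m^2/s]

the ratio of the boxcar signal's temporal derivative (central differences
across adjacent gate times) to its two-dimensional spatial Laplacian (5-point
stencil).  On frames that evolve by pure diffusion with diffusivity alpha,
RT equals alpha identically; RT therefore quantifies the local speed toward
thermal equilibrium, and is invariant to any positive rescaling of the
signal (gain, units).  The sign convention makes a decaying local maximum
(dBC/dt < 0, laplacian < 0) yield RT > 0.

Estimates where |laplacian| falls below a configurable quantile floor are
flagged invalid: near inflection lines the ratio is ill-conditioned, and the
measured quantity is meaningful only at pronounced curvature extrema (the
Laplacian peaks flanking an interface).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import HyperStack

__all__ = [
    "RTEstimate",
    "RTBoxStats",
    "laplacian2d",
    "temporal_derivative",
    "compute_rt",
    "find_laplacian_peaks",
    "aggregate_rt",
]


@dataclass
class RTEstimate:
    """Rate-of-transfer estimate at one pixel and gate time."""

    location: tuple[int, int]
    gate_time: float
    dbc_dt: float          # mV/s
    laplacian: float       # mV/m^2
    rt: float              # m^2/s
    valid: bool
    region: str = ""


@dataclass
class RTBoxStats:
    """Mean and 25-75% margins of valid RT estimates for one region."""

    region: str
    mean: float
    q25: float
    q75: float
    n_points: int
    gate_times: tuple[float, ...] = ()


# --------------------------------------------------------------------------
# Differential operators
# --------------------------------------------------------------------------

def laplacian2d(frame: np.ndarray, pixel_size: float,
                stencil: str = "5-point") -> np.ndarray:
    """Finite-difference Laplacian of a frame, border ring NaN-masked.

    ``5-point`` is the standard cross stencil (d2/dx2 + d2/dy2); ``9-point``
    is the isotropic variant.  Values are scaled by 1/pixel_size^2.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be 2-D and at least 3x3")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    out = np.full(frame.shape, np.nan)
    c = frame[1:-1, 1:-1]
    n, s = frame[:-2, 1:-1], frame[2:, 1:-1]
    w, e = frame[1:-1, :-2], frame[1:-1, 2:]
    if stencil == "5-point":
        lap = n + s + w + e - 4.0 * c
    elif stencil == "9-point":
        nw, ne = frame[:-2, :-2], frame[:-2, 2:]
        sw, se = frame[2:, :-2], frame[2:, 2:]
        lap = (4.0 * (n + s + w + e) + nw + ne + sw + se - 20.0 * c) / 6.0
    else:
        raise ValueError("stencil must be '5-point' or '9-point'")
    out[1:-1, 1:-1] = lap / pixel_size ** 2
    return out


def temporal_derivative(stack: HyperStack, gate_time: float) -> np.ndarray:
    """Per-pixel dBC/dt at a gate time (mV/s).

    Central difference across the adjacent frames; one-sided forward/backward
    differences at the first/last gate time.
    """
    if stack.frames.shape[0] < 2:
        raise ValueError("temporal derivative requires >= 2 frames")
    i = int(np.argmin(np.abs(stack.gate_times - gate_time)))
    if abs(stack.gate_times[i] - gate_time) > 1e-12 + 1e-6 * stack.gate_width:
        raise ValueError(f"gate_time {gate_time:g} not in the stack")
    t = stack.gate_times
    f = stack.frames
    if i == 0:
        return (f[1] - f[0]) / (t[1] - t[0])
    if i == len(t) - 1:
        return (f[-1] - f[-2]) / (t[-1] - t[-2])
    return (f[i + 1] - f[i - 1]) / (t[i + 1] - t[i - 1])


# --------------------------------------------------------------------------
# RT estimation
# --------------------------------------------------------------------------

def compute_rt(stack: HyperStack, gate_time: float,
               locations: Sequence[tuple[int, int]],
               floor_quantile: float = 0.80,
               regions: Sequence[str] | None = None,
               stencil: str = "5-point") -> list[RTEstimate]:
    """RT = (dBC/dt) / laplacian(BC) at selected pixels of one gate time.

    The Laplacian floor is the ``floor_quantile`` quantile of |laplacian|
    over the frame's interior: estimates below it are returned flagged
    invalid rather than dropped.  An all-invalid result set triggers a
    warning, not an exception.
    """
    i = int(np.argmin(np.abs(stack.gate_times - gate_time)))
    frame = stack.frames[i]
    lap = laplacian2d(frame, stack.pixel_size, stencil=stencil)
    ddt = temporal_derivative(stack, stack.gate_times[i])
    interior = np.abs(lap[np.isfinite(lap)])
    floor = float(np.quantile(interior, floor_quantile)) if interior.size else math.inf

    if regions is None:
        regions = [""] * len(locations)
    out: list[RTEstimate] = []
    ny, nx = frame.shape
    for (r, c), reg in zip(locations, regions):
        if not (0 <= r < ny and 0 <= c < nx):
            raise ValueError(f"location {(r, c)} outside the {ny}x{nx} field")
        l = lap[r, c]
        d = ddt[r, c]
        ok = bool(np.isfinite(l) and abs(l) >= floor)
        rt = float(d / l) if ok else math.nan
        out.append(RTEstimate(location=(r, c), gate_time=float(stack.gate_times[i]),
                              dbc_dt=float(d), laplacian=float(l), rt=rt,
                              valid=ok, region=reg))
    if out and not any(e.valid for e in out):
        warnings.warn("all RT estimates below the Laplacian floor", stacklevel=2)
    return out


def find_laplacian_peaks(frame_laplacian: np.ndarray, min_separation: int = 3,
                         threshold_quantile: float = 0.90) -> list[tuple[int, int]]:
    """Local extrema of |laplacian|, strongest first, pruned by separation.

    Candidate pixels are local maxima of the absolute Laplacian above the
    given quantile of finite |values|; candidates closer (Euclidean) than
    ``min_separation`` pixels to an already accepted, stronger peak are
    dropped.  Ordering is deterministic: by descending strength, then by
    (row, col).
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1 px")
    a = np.abs(np.asarray(frame_laplacian, dtype=float))
    finite = np.isfinite(a)
    if not finite.any():
        return []
    vals = a[finite]
    thr = float(np.quantile(vals, threshold_quantile))
    if vals.max() <= vals.min():        # flat frame
        return []

    from scipy import ndimage
    filled = np.where(finite, a, -np.inf)
    local_max = ndimage.maximum_filter(filled, size=3, mode="constant",
                                       cval=-np.inf) == filled
    cand = np.argwhere(local_max & finite & (a >= thr) & (a > vals.min()))
    order = sorted((( -a[r, c], r, c) for r, c in cand))
    peaks: list[tuple[int, int]] = []
    for negs, r, c in order:
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation ** 2
               for pr, pc in peaks):
            peaks.append((int(r), int(c)))
    return peaks


def aggregate_rt(estimates: Sequence[RTEstimate],
                 gate_times: Sequence[float] | None = None) -> list[RTBoxStats]:
    """Mean / 25-75% box statistics of valid RT estimates per region.

    Percentiles use linear interpolation between order statistics.  Regions
    with no valid estimate are omitted with a warning.  Returns stats sorted
    by region name.
    """
    groups: dict[str, list[RTEstimate]] = {}
    for e in estimates:
        groups.setdefault(e.region, []).append(e)
    out: list[RTBoxStats] = []
    for region in sorted(groups):
        vals = np.array([e.rt for e in groups[region] if e.valid])
        times = tuple(sorted({e.gate_time for e in groups[region] if e.valid}))
        if vals.size == 0:
            warnings.warn(f"region {region!r}: no valid RT estimates; omitted",
                          stacklevel=2)
            continue
        q25, q75 = np.percentile(vals, [25.0, 75.0], method="linear")
        out.append(RTBoxStats(region=region, mean=float(vals.mean()),
                              q25=float(q25), q75=float(q75),
                              n_points=int(vals.size), gate_times=times))
    return out
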