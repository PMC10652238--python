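"""Detection model: probe sampling, boxcar gating, noise, lock-in, stacks.

Converts temperature movies into probe time traces (a 2-D Gaussian probe
kernel sampling the temperature field, scaled by a mV/K gain), applies boxcar
gating — the mean of the signal over a short gate window minus the mean over a
baseline window, optionally in absolute value — and assembles hyper-temporal
stacks: one boxcar image per gate start time t_g.

Noise is injected post-averaging: accumulating N pump periods reduces the
single-period noise standard deviation by sqrt(N), so a single draw at
``noise_std_single / sqrt(n_periods)`` is statistically identical to averaging
N noisy periods and 2040x cheaper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .phantom import TemperatureMovie

__all__ = [
    "ProbeModel",
    "TimeTrace",
    "BoxcarConfig",
    "HyperStack",
    "movie_to_trace",
    "gate_signal",
    "build_stack",
    "add_noise",
    "lockin_demodulate",
    "snr_linescan",
]

TRACE_DT = 10e-9  # default trace resolution, s


@dataclass(frozen=True)
class ProbeModel:
    """Probe beam and averaging model.

    spot_fwhm : probe focal spot FWHM (m), default 1 um.
    gain : detector signal in mV per kelvin of probe-sampled temperature rise.
    noise_std_single : single-period noise std (mV); the effective noise after
        period averaging is ``noise_std_single / sqrt(n_periods)``.
    n_periods : number of averaged pump periods (default 2040).
    """

    spot_fwhm: float = 1e-6
    gain: float = 1.0
    noise_std_single: float = 0.0
    n_periods: int = 2040

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if not self.spot_fwhm > 0:
            raise ValueError("spot_fwhm must be > 0")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.noise_std_single < 0:
            raise ValueError("noise_std_single must be >= 0")

    @property
    def effective_noise_std(self) -> float:
        return self.noise_std_single / math.sqrt(self.n_periods)


@dataclass
class TimeTrace:
    """Single-location signal versus time (uniform sampling)."""

    times: np.ndarray
    values: np.ndarray
    location: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        d = np.diff(self.times)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class BoxcarConfig:
    """Boxcar gate/baseline windows.

    Windows are half-open ``[start, start + width)`` on sample timestamps.
    ``baseline_window=None`` uses a zero baseline, appropriate for simulated
    single-period traces whose pre-pulse signal is identically zero; on a full
    10 us period the recommended baseline is the signal-free last microsecond,
    e.g. ``(9e-6, 1e-6)``.
    """

    gate_start: float = 0.0
    gate_width: float = 250e-9
    baseline_window: tuple[float, float] | None = None
    take_absolute: bool = True

    def __post_init__(self) -> None:
        if not self.gate_width > 0:
            raise ValueError("gate_width must be > 0")
        if self.baseline_window is not None:
            b0, bw = self.baseline_window
            if not bw > 0:
                raise ValueError("baseline width must be > 0")
            g0, g1 = self.gate_start, self.gate_start + self.gate_width
            if b0 < g1 and g0 < b0 + bw:
                raise ValueError("gate and baseline windows overlap")

    def with_gate(self, gate_start: float) -> "BoxcarConfig":
        return BoxcarConfig(gate_start=gate_start, gate_width=self.gate_width,
                            baseline_window=self.baseline_window,
                            take_absolute=self.take_absolute)


@dataclass
class HyperStack:
    """Ordered boxcar frames, one per gate start time.

    frames : (n_gates, ny, nx) boxcar output in mV.
    """

    frames: np.ndarray
    gate_times: np.ndarray
    pixel_size: float
    gate_width: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.gate_times = np.asarray(self.gate_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_gates, ny, nx) array")
        if len(self.gate_times) != self.frames.shape[0]:
            raise ValueError("one gate time per frame required")
        if np.any(np.diff(self.gate_times) <= 0):
            raise ValueError("gate_times must be strictly increasing")
        if not (self.pixel_size > 0 and self.gate_width > 0):
            raise ValueError("pixel_size and gate_width must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def window(self, t_min: float, t_max: float) -> "HyperStack":
        """Sub-stack of frames with ``t_min <= gate_time <= t_max``."""
        sel = (self.gate_times >= t_min - 1e-15) & (self.gate_times <= t_max + 1e-15)
        if not np.any(sel):
            raise ValueError("window selects no frames")
        return HyperStack(self.frames[sel], self.gate_times[sel],
                          self.pixel_size, self.gate_width, dict(self.metadata))

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        return self.frames[:, row, col]


# --------------------------------------------------------------------------
# Probe sampling
# --------------------------------------------------------------------------

def _probe_sigma_px(spot_fwhm: float, pixel_size: float) -> float:
    return spot_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / pixel_size


def probe_kernel(spot_fwhm: float, pixel_size: float, shape: tuple[int, int],
                 location: tuple[int, int]) -> np.ndarray:
    """Normalised Gaussian probe weights centered on ``location`` (row, col)."""
    sigma = _probe_sigma_px(spot_fwhm, pixel_size)
    rows = np.arange(shape[0])[:, None] - location[0]
    cols = np.arange(shape[1])[None, :] - location[1]
    w = np.exp(-(rows ** 2 + cols ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def movie_to_trace(movie: TemperatureMovie, probe: ProbeModel,
                   location: tuple[int, int],
                   times: np.ndarray | None = None) -> TimeTrace:
    """Probe time trace at a pixel: gain x (Gaussian-probe-sampled dT).

    The temperature field is weighted by a normalised 2-D Gaussian kernel of
    the probe FWHM centered on ``location``, then linearly interpolated to a
    uniform 10 ns time axis (or ``times``).
    """
    ny, nx = movie.frames.shape[1:]
    r, c = location
    if not (0 <= r < ny and 0 <= c < nx):
        raise ValueError(f"location {location} outside the {ny}x{nx} field")
    if times is None:
        times = np.arange(movie.frame_times[0], movie.frame_times[-1] + TRACE_DT / 2,
                          TRACE_DT)
    times = np.asarray(times, dtype=float)
    if times[0] < movie.frame_times[0] - 1e-15 or times[-1] > movie.frame_times[-1] + 1e-15:
        raise ValueError("requested trace times not covered by the movie")

    sigma = _probe_sigma_px(probe.spot_fwhm, movie.pixel_size)
    sampled = np.array([
        ndimage.gaussian_filter(f, sigma=sigma, mode="nearest")[r, c]
        for f in movie.frames
    ])
    values = probe.gain * np.interp(times, movie.frame_times, sampled)
    return TimeTrace(times=times, values=values, location=(r, c),
                     metadata={"gain_mV_per_K": probe.gain,
                               "spot_fwhm_m": probe.spot_fwhm})


# --------------------------------------------------------------------------
# Boxcar gating
# --------------------------------------------------------------------------

def _window_mean(times: np.ndarray, values: np.ndarray, start: float,
                 width: float):
    """Mean of samples whose timestamps fall in half-open [start, start+width).

    ``values`` may be (n,) or (n, ...); averaging is over the time axis.
    A small symmetric tolerance absorbs floating-point jitter on the ends.
    """
    eps = 1e-15 + 1e-9 * width
    sel = (times >= start - eps) & (times < start + width - eps)
    if not np.any(sel):
        raise ValueError(
            f"window [{start:g}, {start + width:g}) contains no samples")
    return values[sel].mean(axis=0)


def gate_signal(trace: TimeTrace, cfg: BoxcarConfig) -> float:
    """Boxcar output BC for one trace.

    BC = | mean over gate window - mean over baseline window |, the absolute
    value applied only when ``cfg.take_absolute`` is set.
    """
    t0, t1 = trace.times[0], trace.times[-1]
    if cfg.gate_start < t0 - 1e-15 or cfg.gate_start + cfg.gate_width > t1 + trace.dt:
        raise ValueError("gate window outside trace support")
    gate = _window_mean(trace.times, trace.values, cfg.gate_start, cfg.gate_width)
    base = 0.0
    if cfg.baseline_window is not None:
        b0, bw = cfg.baseline_window
        if b0 < t0 - 1e-15 or b0 + bw > t1 + trace.dt:
            raise ValueError("baseline window outside trace support")
        base = _window_mean(trace.times, trace.values, b0, bw)
    bc = gate - base
    return float(abs(bc)) if cfg.take_absolute else float(bc)


def build_stack(movie: TemperatureMovie, probe: ProbeModel,
                gate_times: Sequence[float], cfg: BoxcarConfig) -> HyperStack:
    """Hyper-temporal stack: per-pixel boxcar output at each gate start time.

    Equivalent to running :func:`movie_to_trace` + :func:`gate_signal` pixel
    by pixel (same 10 ns trace grid and half-open window semantics), but
    vectorised: each movie frame is convolved with the Gaussian probe kernel
    once, then gated across all pixels simultaneously.
    """
    gate_times = np.asarray(list(gate_times), dtype=float)
    if gate_times.ndim != 1 or len(gate_times) == 0:
        raise ValueError("gate_times must be a non-empty 1-D sequence")
    if np.any(np.diff(gate_times) <= 0):
        raise ValueError("gate_times must be strictly increasing")

    sigma = _probe_sigma_px(probe.spot_fwhm, movie.pixel_size)
    blurred = np.stack([
        ndimage.gaussian_filter(f, sigma=sigma, mode="nearest")
        for f in movie.frames
    ])

    times = np.arange(movie.frame_times[0], movie.frame_times[-1] + TRACE_DT / 2,
                      TRACE_DT)
    # time-interpolate to the trace grid: (n_times, ny, nx)
    idx = np.searchsorted(movie.frame_times, times, side="right") - 1
    idx = np.clip(idx, 0, len(movie.frame_times) - 2)
    t_lo = movie.frame_times[idx]
    t_hi = movie.frame_times[idx + 1]
    frac = np.clip((times - t_lo) / (t_hi - t_lo), 0.0, 1.0)
    dense = (1 - frac)[:, None, None] * blurred[idx] + frac[:, None, None] * blurred[idx + 1]
    dense *= probe.gain

    base = 0.0
    if cfg.baseline_window is not None:
        b0, bw = cfg.baseline_window
        base = _window_mean(times, dense, b0, bw)

    frames = []
    for tg in gate_times:
        if tg < times[0] - 1e-15 or tg + cfg.gate_width > times[-1] + TRACE_DT:
            raise ValueError(f"gate window at t_g={tg:g} outside trace support")
        bc = _window_mean(times, dense, tg, cfg.gate_width) - base
        frames.append(np.abs(bc) if cfg.take_absolute else bc)

    return HyperStack(frames=np.stack(frames), gate_times=gate_times,
                      pixel_size=movie.pixel_size, gate_width=cfg.gate_width,
                      metadata={"gain_mV_per_K": probe.gain,
                                "spot_fwhm_m": probe.spot_fwhm,
                                "take_absolute": cfg.take_absolute})


# --------------------------------------------------------------------------
# Noise and demodulation
# --------------------------------------------------------------------------

def add_noise(obj, probe: ProbeModel, seed: int):
    """Add period-averaged Gaussian noise to a trace or stack.

    Zero-mean Gaussian noise with std ``noise_std_single / sqrt(n_periods)``
    is added elementwise; deterministic for a fixed seed.  Returns a new
    object of the same type; with zero noise amplitude the values are
    returned unchanged.
    """
    std = probe.effective_noise_std
    rng = np.random.default_rng(seed)
    if isinstance(obj, TimeTrace):
        noise = rng.normal(0.0, std, size=obj.values.shape) if std > 0 else 0.0
        return TimeTrace(times=obj.times.copy(), values=obj.values + noise,
                         location=obj.location,
                         metadata={**obj.metadata, "noise_std_mV": std,
                                   "seed": seed})
    if isinstance(obj, HyperStack):
        noise = rng.normal(0.0, std, size=obj.frames.shape) if std > 0 else 0.0
        return HyperStack(frames=obj.frames + noise,
                          gate_times=obj.gate_times.copy(),
                          pixel_size=obj.pixel_size, gate_width=obj.gate_width,
                          metadata={**obj.metadata, "noise_std_mV": std,
                                    "seed": seed})
    raise TypeError(f"cannot add noise to {type(obj).__name__}")


def lockin_demodulate(trace: TimeTrace, frequency: float = 1e5):
    """First-harmonic amplitude (mV) and phase (rad) of a trace.

    Convention: a pure ``A*sin(2*pi*f*t)`` returns amplitude ``A`` (peak, not
    RMS) and phase 0; generally ``v ~ amp*sin(2*pi*f*t + phase)``.  The trace
    must span an integer number of periods of ``frequency``.
    """
    if not frequency > 0:
        raise ValueError("frequency must be > 0")
    times, values = trace.times, trace.values
    n = len(times)
    cycles = n * trace.dt * frequency
    if abs(cycles - round(cycles)) > 1e-6:
        # tolerate a duplicated endpoint sample (t[-1] lands exactly on the
        # period boundary): drop it and re-check
        cycles_wo = (n - 1) * trace.dt * frequency
        if abs(cycles_wo - round(cycles_wo)) <= 1e-6 and round(cycles_wo) >= 1:
            times, values = times[:-1], values[:-1]
            n -= 1
            cycles = cycles_wo
        else:
            raise ValueError(
                f"trace spans {cycles:g} periods of {frequency:g} Hz; an "
                "integer number of periods is required")
    if round(cycles) < 1:
        raise ValueError("trace must span at least one full period")
    theta = 2.0 * math.pi * frequency * times
    x = 2.0 / n * float(np.sum(values * np.sin(theta)))
    y = 2.0 / n * float(np.sum(values * np.cos(theta)))
    return math.hypot(x, y), math.atan2(y, x)


def snr_linescan(values: np.ndarray, signal_region, noise_region) -> float:
    """SNR = (max over signal region - mean over noise region) / noise std.

    Regions may be slices, index arrays or boolean masks over ``values``.
    The noise std uses the sample convention (ddof=1) and must be computed
    from at least 8 samples.
    """
    values = np.asarray(values, dtype=float)
    sig = values[signal_region]
    noi = values[noise_region]
    if noi.size < 8:
        raise ValueError("noise region must contain >= 8 samples")
    std = float(np.std(noi, ddof=1))
    if std == 0.0:
        raise ValueError("zero noise standard deviation: SNR undefined")
    return (float(np.max(sig)) - float(np.mean(noi))) / std
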