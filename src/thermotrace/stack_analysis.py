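"""Per-pixel statistics on traces and hyper-temporal stacks.

The central quantities:

* **CV image** — per-pixel coefficient of variance sigma/|m| across the
  frames of a gate-time window.  Fast-decaying pixels vary strongly across
  the diffusion window and light up; slowly decaying water is a homogeneous
  low-CV background.
* **Decay time tau_d** — time for the post-peak signal to fall by a 1/e
  margin of the peak-to-minimum span.  A fit-free per-location decay
  constant; mapped per pixel it is the reference the CV image approximates.
* **Double-exponential fits** — least-squares a*exp(-t/tau_fast) +
  b*exp(-t/tau_slow) + c for interface traces showing an initial fast decay
  (small features, interfacial thermal resistance) followed by slow bulk
  relaxation.
* **FWHM linescans** — diffusive broadening of a peak across gate times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .detection import HyperStack, TimeTrace

__all__ = [
    "CVImage",
    "DecayFit",
    "TauMap",
    "Linescan",
    "DispersionSummary",
    "compute_cv_image",
    "extract_tau",
    "fit_double_exponential",
    "map_tau",
    "fwhm_linescan",
    "background_subtract_median",
    "dispersion_summary",
]


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------

@dataclass
class CVImage:
    """Per-pixel coefficient of variance over a gate-time window.

    ``values`` is NaN where ``valid`` is False (|mean| below the floor).
    ``convention`` records the standard-deviation convention used
    (population, divide by n).
    """

    values: np.ndarray
    valid: np.ndarray
    window: tuple[float, float]
    convention: str = "population"
    metadata: dict = field(default_factory=dict)


@dataclass
class DecayFit:
    """Single- or double-exponential decay characterisation of one trace."""

    model: str                      # "single" | "double"
    tau_d: float = math.nan         # 1/e decay time (single model)
    tau_fast: float = math.nan
    tau_slow: float = math.nan
    amp_fast: float = math.nan
    amp_slow: float = math.nan
    offset: float = math.nan
    peak_time: float = math.nan
    peak_value: float = math.nan
    min_value: float = math.nan
    residual_norm: float = 0.0
    valid: bool = True
    preferred_model: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable one-block summary of the fit."""
        lines = [f"DecayFit ({self.model}); valid={self.valid}"]
        if self.model == "single":
            lines.append(f"  tau_d      = {self.tau_d * 1e6:.4g} us")
        else:
            lines.append(f"  tau_fast   = {self.tau_fast * 1e9:.4g} ns "
                         f"(amp {self.amp_fast:.4g})")
            lines.append(f"  tau_slow   = {self.tau_slow * 1e6:.4g} us "
                         f"(amp {self.amp_slow:.4g})")
            lines.append(f"  offset     = {self.offset:.4g} mV")
            lines.append(f"  preferred  = {self.preferred_model}")
        lines.append(f"  peak {self.peak_value:.4g} mV at {self.peak_time * 1e6:.4g} us; "
                     f"min {self.min_value:.4g} mV; residual {self.residual_norm:.3g}")
        return "\n".join(lines)


@dataclass
class TauMap:
    """Per-pixel 1/e decay times; NaN where invalid."""

    tau: np.ndarray
    valid: np.ndarray
    window: tuple[float, float]
    metadata: dict = field(default_factory=dict)


@dataclass
class Linescan:
    """Signal along a spatial cross-section at one gate time."""

    positions: np.ndarray
    values: np.ndarray
    gate_time: float = math.nan
    fwhm: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must match")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class DispersionSummary:
    """Shortest interval holding a probability mass, plus the symmetric-
    percentile alternative."""

    lower: float
    upper: float
    width: float
    mass: float
    central_lower: float
    central_upper: float
    central_width: float
    n: int


# --------------------------------------------------------------------------
# CV image
# --------------------------------------------------------------------------

def compute_cv_image(stack: HyperStack, window: tuple[float, float],
                     mean_floor_frac: float = 0.01) -> CVImage:
    """Coefficient-of-variance image over a gate-time window.

    Per pixel, CV = population standard deviation / |mean| across the frames
    whose gate times fall in ``[window[0], window[1]]`` (inclusive; must
    select at least 3 frames).  Pixels whose |mean| is below
    ``mean_floor_frac`` times the selected frames' global maximum are masked
    rather than divided, to keep near-zero-signal pixels from blowing up.
    """
    sub = stack.window(*window)
    if sub.frames.shape[0] < 3:
        raise ValueError(
            f"window {window} selects {sub.frames.shape[0]} frames; >= 3 required")
    m = sub.frames.mean(axis=0)
    sigma = sub.frames.std(axis=0, ddof=0)
    floor = mean_floor_frac * float(np.max(np.abs(sub.frames)))
    valid = np.abs(m) >= floor
    values = np.full(m.shape, np.nan)
    np.divide(sigma, np.abs(m), out=values, where=valid)
    return CVImage(values=values, valid=valid, window=tuple(window),
                   convention="population",
                   metadata={"mean_floor": floor,
                             "n_frames": int(sub.frames.shape[0]),
                             "gate_times_s": sub.gate_times.tolist()})


# --------------------------------------------------------------------------
# 1/e decay-time extraction
# --------------------------------------------------------------------------

def _as_series(trace_or_values, time_axis):
    if isinstance(trace_or_values, TimeTrace):
        return trace_or_values.times, trace_or_values.values
    values = np.asarray(trace_or_values, dtype=float)
    if time_axis is None:
        raise ValueError("time_axis required when passing a bare value series")
    times = np.asarray(time_axis, dtype=float)
    if times.shape != values.shape:
        raise ValueError("time_axis and values must match")
    return times, values


def _cross_time(t: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """First time the decaying series v(t) falls to ``level`` (linear interp)."""
    below = v <= level
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    frac = (v[k - 1] - level) / (v[k - 1] - v[k])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def extract_tau(trace_or_values, time_axis=None,
                truncation_correction: bool = True,
                max_iter: int = 200, rtol: float = 1e-6) -> DecayFit:
    """1/e peak-to-minimum decay time of a series.

    The decay time tau_d is the interval from the signal peak to the first
    post-peak time at which the signal falls to
    ``floor + (peak - floor)/e``, with the crossing located by linear
    interpolation between bracketing samples.  ``floor`` starts as the
    minimum over the post-peak window.

    When the trace is cut off before it reaches its asymptote, the window
    minimum overestimates the floor and the plain rule biases tau_d low.
    With ``truncation_correction`` (default) the floor is re-estimated
    self-consistently: assuming the decay approaches an asymptote b
    exponentially, the window minimum m at the window end T satisfies
    ``m = b + (peak - b) * exp(-T/tau)``; solving for b under the current tau
    estimate and re-locating the 1/e crossing converges, for any single
    exponential with any additive baseline and window length, to the exact
    time constant.  For traces that do reach their asymptote inside the
    window the correction is a no-op.  ``truncation_correction=False`` keeps
    the plain window-minimum rule.

    A trace that never reaches the 1/e level inside the window is flagged
    ``valid=False`` (never extrapolated).
    """
    t, v = _as_series(trace_or_values, time_axis)
    ipk = int(np.argmax(v))
    post_t = t[ipk:]
    post_v = v[ipk:]
    if len(post_v) < 4:
        raise ValueError("need an identifiable maximum followed by >= 3 samples")
    peak = float(post_v[0])
    m = float(post_v.min())
    peak_time = float(t[ipk])
    span_T = float(post_t[-1] - post_t[0])

    def solve(floor: float) -> float | None:
        level = floor + (peak - floor) / math.e
        tc = _cross_time(post_t - peak_time, post_v, level)
        return tc

    if peak == m:
        return DecayFit(model="single", tau_d=math.nan, peak_time=peak_time,
                        peak_value=peak, min_value=m, valid=False,
                        diagnostics={"reason": "flat series"})

    tau = solve(m)
    if tau is None or tau <= 0:
        return DecayFit(model="single", tau_d=math.nan, peak_time=peak_time,
                        peak_value=peak, min_value=m, valid=False,
                        diagnostics={"reason": "no 1/e crossing in window"})

    n_iter = 0
    if truncation_correction:
        for n_iter in range(1, max_iter + 1):
            decay = math.exp(-span_T / tau)
            floor = (m - peak * decay) / (1.0 - decay)
            # the asymptote cannot exceed the observed minimum
            floor = min(floor, m)
            new_tau = solve(floor)
            if new_tau is None or new_tau <= 0:
                break
            if abs(new_tau - tau) <= rtol * tau:
                tau = new_tau
                break
            tau = new_tau

    # A corrected crossing pinned to the window end is the boundary fixed
    # point of the floor iteration: the decay is slower than the window can
    # resolve.  Flag rather than report the window span as a decay time.
    dt_last = float(post_t[-1] - post_t[-2])
    if truncation_correction and tau >= span_T - 0.5 * dt_last:
        return DecayFit(model="single", tau_d=math.nan, peak_time=peak_time,
                        peak_value=peak, min_value=m, valid=False,
                        diagnostics={"reason": "decay slower than analysis window",
                                     "iterations": n_iter})

    return DecayFit(model="single", tau_d=float(tau), peak_time=peak_time,
                    peak_value=peak, min_value=m, residual_norm=0.0,
                    valid=True,
                    diagnostics={"iterations": n_iter,
                                 "truncation_correction": truncation_correction})


# --------------------------------------------------------------------------
# Double-exponential fitting
# --------------------------------------------------------------------------

def _double_model(t, a, tau_f, b, tau_s, c):
    return a * np.exp(-t / tau_f) + b * np.exp(-t / tau_s) + c


def fit_double_exponential(trace_or_values, time_axis=None,
                           degeneracy_ratio: float = 0.5) -> DecayFit:
    """Least-squares two-term exponential fit of the post-peak decay.

    Fits ``a*exp(-t'/tau_fast) + b*exp(-t'/tau_slow) + c`` (t' measured from
    the peak) with multi-start initialisation; the two time constants are
    ordered ``tau_fast < tau_slow`` after the fit.  Fits whose constants are
    not separated (``tau_fast/tau_slow > degeneracy_ratio``) or whose second
    amplitude is negligible are reported with ``preferred_model='single'``:
    the data do not support two distinct decay processes.

    Requires >= 8 post-peak samples; non-convergence of every start is
    flagged ``valid=False`` with diagnostics.
    """
    t, v = _as_series(trace_or_values, time_axis)
    ipk = int(np.argmax(v))
    tt = t[ipk:] - t[ipk]
    vv = v[ipk:]
    if len(vv) < 8:
        raise ValueError("need >= 8 post-peak samples for a double-exponential fit")

    peak = float(vv[0])
    mn = float(vv.min())
    scale = peak - mn if peak > mn else (abs(peak) or 1.0)
    span = float(tt[-1]) if tt[-1] > 0 else 1.0

    naive = extract_tau(vv, tt, truncation_correction=True)
    tau0 = naive.tau_d if naive.valid and np.isfinite(naive.tau_d) else span / 3.0

    starts = []
    for ff in (0.1, 0.25, 0.5):
        for fs in (1.0, 2.0, 4.0):
            starts.append((0.5 * scale, ff * tau0, 0.5 * scale, fs * tau0, mn))
    dtmin = float(np.min(np.diff(tt))) if len(tt) > 1 else span
    lo = [0.0, dtmin / 4, 0.0, dtmin / 4, -np.inf]
    hi = [np.inf, 100 * span, np.inf, 100 * span, np.inf]

    best = None
    failures = []
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(_double_model, tt, vv, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            failures.append(str(exc))
            continue
        resid = float(np.linalg.norm(_double_model(tt, *popt) - vv))
        if best is None or resid < best[0]:
            best = (resid, popt)

    if best is None:
        return DecayFit(model="double", peak_time=float(t[ipk]), peak_value=peak,
                        min_value=mn, residual_norm=math.inf, valid=False,
                        diagnostics={"failures": failures})

    resid, (a, tau_f, b, tau_s, c) = best
    if tau_f > tau_s:
        a, b = b, a
        tau_f, tau_s = tau_s, tau_f

    preferred = "double"
    total_amp = abs(a) + abs(b)
    if tau_s <= 0 or tau_f / tau_s > degeneracy_ratio:
        preferred = "single"
    elif total_amp > 0 and min(abs(a), abs(b)) / total_amp < 1e-3:
        preferred = "single"

    return DecayFit(model="double", tau_fast=float(tau_f), tau_slow=float(tau_s),
                    amp_fast=float(a), amp_slow=float(b), offset=float(c),
                    peak_time=float(t[ipk]), peak_value=peak, min_value=mn,
                    residual_norm=resid, valid=True, preferred_model=preferred,
                    diagnostics={"n_starts": len(starts),
                                 "n_failed_starts": len(failures)})


# --------------------------------------------------------------------------
# Per-pixel decay-time map
# --------------------------------------------------------------------------

def map_tau(stack: HyperStack, window: tuple[float, float],
            truncation_correction: bool = True) -> TauMap:
    """Per-pixel 1/e decay time over a gate-time window.

    Runs :func:`extract_tau` on every pixel's frame series inside the window;
    pixels without a valid crossing are masked.  This is the pixel-by-pixel
    reference that the (much cheaper) CV image approximates.
    """
    sub = stack.window(*window)
    if sub.frames.shape[0] < 4:
        raise ValueError("window must cover >= 4 frames of the decay regime")
    ny, nx = sub.shape
    tau = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    times = sub.gate_times
    for r in range(ny):
        for c in range(nx):
            fitted = extract_tau(sub.frames[:, r, c], times,
                                 truncation_correction=truncation_correction)
            if fitted.valid and np.isfinite(fitted.tau_d) and fitted.tau_d > 0:
                tau[r, c] = fitted.tau_d
                valid[r, c] = True
    return TauMap(tau=tau, valid=valid, window=tuple(window),
                  metadata={"n_frames": int(sub.frames.shape[0]),
                            "truncation_correction": truncation_correction})


def cv_tau_rank_correlation(cv: CVImage, taumap: TauMap) -> float:
    """Spearman rank correlation between CV and tau_d over jointly valid pixels.

    Fast decays (small tau) vary strongly across the diffusion window (large
    CV), so the expected correlation on monotone-decay stacks is negative —
    the mirrored evolution of the two maps.
    """
    both = cv.valid & taumap.valid
    if both.sum() < 3:
        raise ValueError("need >= 3 jointly valid pixels")
    rho = stats.spearmanr(cv.values[both].ravel(), taumap.tau[both].ravel())
    return float(rho.statistic)


# --------------------------------------------------------------------------
# Linescan width
# --------------------------------------------------------------------------

def fwhm_linescan(linescan: Linescan, peak_index: int | None = None) -> float:
    """Full width at half maximum of a linescan peak, in meters.

    The half-maximum level is referenced to the local baseline — the mean of
    the two flanking minima — and each crossing is located by linear
    interpolation, taking the outermost crossing on either flank (ties broken
    toward the wider width).
    """
    x, v = linescan.positions, linescan.values
    ipk = int(np.argmax(v)) if peak_index is None else int(peak_index)
    if ipk == 0 or ipk == len(v) - 1:
        raise ValueError("peak lies on the linescan border; no flanking minima")
    left_min = float(v[:ipk].min())
    right_min = float(v[ipk + 1:].min())
    peak = float(v[ipk])
    baseline = 0.5 * (left_min + right_min)
    if peak <= max(left_min, right_min):
        raise ValueError("no local maximum above its flanking minima")
    level = baseline + 0.5 * (peak - baseline)

    def flank_crossing(indices) -> float:
        """Outermost crossing of ``level`` walking outward from the peak."""
        crossing = None
        for i in range(len(indices) - 1):
            a, b = indices[i], indices[i + 1]
            va, vb = v[a], v[b]
            if va >= level and vb < level:
                frac = (va - level) / (va - vb)
                crossing = float(x[a] + frac * (x[b] - x[a]))
        if crossing is None:
            raise ValueError("half-maximum level not crossed on a flank")
        return crossing

    left = flank_crossing(list(range(ipk, -1, -1)))
    right = flank_crossing(list(range(ipk, len(v))))
    width = abs(right - left)
    linescan.fwhm = width
    return width


# --------------------------------------------------------------------------
# Background subtraction and dispersion
# --------------------------------------------------------------------------

def background_subtract_median(image: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    """Subtract the median of the masked region from the whole image.

    After subtraction the masked region's median is 0; applying the operation
    twice is idempotent.  NaN pixels inside the mask are ignored.
    """
    image = np.asarray(image, dtype=float)
    region_mask = np.asarray(region_mask, dtype=bool)
    if image.shape != region_mask.shape:
        raise ValueError("image and mask shapes differ")
    sel = image[region_mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("empty (or all-NaN) background region")
    return image - float(np.median(sel))


def dispersion_summary(values, probability_mass: float = 0.75) -> DispersionSummary:
    """Shortest interval containing a probability mass of the sample.

    Returns the minimum-width interval over consecutive order statistics that
    contains ``probability_mass`` of the values (default 75%), together with
    the symmetric-percentile alternative (e.g. the central 12.5–87.5%
    interval), since "75% of the values fall between a and b" admits both
    conventions.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    x = x[np.isfinite(x)]
    n = x.size
    if n < 8:
        raise ValueError("need >= 8 values")
    if not 0 < probability_mass <= 1:
        raise ValueError("probability_mass must be in (0, 1]")
    k = max(2, int(math.ceil(probability_mass * n)))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    lower, upper = float(x[i]), float(x[i + k - 1])
    tail = 100.0 * (1.0 - probability_mass) / 2.0
    c_lo, c_hi = np.percentile(x, [tail, 100.0 - tail])
    return DispersionSummary(lower=lower, upper=upper, width=upper - lower,
                             mass=probability_mass,
                             central_lower=float(c_lo), central_upper=float(c_hi),
                             central_width=float(c_hi - c_lo), n=n)
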