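"""Synthetic thermal phantoms and pulsed-heating / 2-D heat-diffusion simulation.

This module stands in for the microscope's sample chamber: it builds 2-D
material maps (absorption, thermal diffusivity, volumetric heat capacity) for
an absorber/water interface with optional disc-shaped features, and integrates
the heat equation

    dT/dt = (1/C_V) div( k grad T ) + S/C_V - loss * T,      k = alpha * C_V

on the imaging plane with an explicit forward-time centered-space scheme in
flux-conservative form, so that total heat ``sum(C_V * T * dx^2)`` is conserved
under insulated boundaries with the source off.  The source term
``S = peak_heating_rate * absorption_map * profile`` is active for the pump
pulse duration and zero afterwards.  A first-order ``loss * T`` term emulates
heat escaping normal to the imaging plane (finite water-layer thickness); it
defaults to zero.

Temperature movies produced here are converted into detector traces and
boxcar-gated hyper-temporal stacks by :mod:`thermotrace.detection`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RegionProps",
    "WATER",
    "AXON_BUNDLE",
    "SURROUNDING_TISSUE",
    "FEATURE",
    "ThermalPhantom",
    "PumpPulse",
    "SimConfig",
    "TemperatureMovie",
    "build_interface_phantom",
    "simulate_temperature_field",
    "predict_feature_tau",
    "synthetic_exponential_trace",
    "synthetic_double_exponential_trace",
]


# --------------------------------------------------------------------------
# Region material properties
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionProps:
    """Material properties of one homogeneous phantom region.

    Parameters
    ----------
    absorption : float
        Mid-IR absorption coefficient mu_abs in 1/m.
    diffusivity : float
        Thermal diffusivity alpha in m^2/s.
    heat_capacity : float
        Volumetric heat capacity C_V in J/(m^3 K).
    label : str
        Region tag; one of ``water``, ``axon_bundle``, ``surrounding_tissue``,
        ``feature``, ``background``.
    """

    absorption: float
    diffusivity: float
    heat_capacity: float
    label: str = "background"
    #: optional per-region out-of-plane loss rate (1/s); None falls back to
    #: the phantom-level scalar.  Emulates region-dependent water-layer
    #: thickness above/below the imaging plane.
    loss: float | None = None

    def __post_init__(self) -> None:
        for name in ("diffusivity", "heat_capacity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RegionProps.{name} must be > 0")
        if self.absorption < 0:
            raise ValueError("RegionProps.absorption must be >= 0")


#: Physiological-saline / water bath.  Literature bulk values.
WATER = RegionProps(absorption=1.0e5, diffusivity=1.43e-7,
                    heat_capacity=4.18e6, label="water")
#: Soft-tissue-like absorber (axon bundle); absorption ~2.2x water,
#: consistent with the observed amplitude contrast at amide-band pumping.
AXON_BUNDLE = RegionProps(absorption=2.2e5, diffusivity=1.1e-7,
                          heat_capacity=3.7e6, label="axon_bundle")
#: Heterogeneous connective tissue around the bundle.
SURROUNDING_TISSUE = RegionProps(absorption=1.5e5, diffusivity=1.1e-7,
                                 heat_capacity=3.7e6, label="surrounding_tissue")
#: Small (~1 um) strongly absorbing feature with reduced diffusivity.
FEATURE = RegionProps(absorption=2.6e5, diffusivity=0.8e-7,
                      heat_capacity=3.6e6, label="feature")

_VALID_LABELS = ("water", "axon_bundle", "surrounding_tissue", "feature",
                 "background")
_LABEL_DTYPE = "<U18"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ThermalPhantom:
    """2-D material maps describing the simulated sample.

    All maps share one shape ``(ny, nx)``; rows are y, columns are x.
    """

    pixel_size: float
    absorption_map: np.ndarray
    diffusivity_map: np.ndarray
    heat_capacity_map: np.ndarray
    label_map: np.ndarray
    #: first-order heat-loss rate normal to the imaging plane, 1/s; a scalar
    #: or a per-pixel map (region-dependent water-layer thickness)
    out_of_plane_loss: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(np.asarray(self.out_of_plane_loss) < 0):
            raise ValueError("out_of_plane_loss must be >= 0")
        shapes = {self.absorption_map.shape, self.diffusivity_map.shape,
                  self.heat_capacity_map.shape, self.label_map.shape}
        if len(shapes) != 1:
            raise ValueError("all phantom maps must share one shape")
        for name in ("diffusivity_map", "heat_capacity_map"):
            arr = getattr(self, name)
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive")
        if not np.all(self.absorption_map >= 0):
            raise ValueError("absorption_map must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorption_map.shape

    def region_mask(self, label: str) -> np.ndarray:
        """Boolean mask of pixels tagged ``label``."""
        return self.label_map == label

    def mirrored(self, axis: int = 1) -> "ThermalPhantom":
        """Phantom reflected along ``axis`` (1 = left/right)."""
        loss = self.out_of_plane_loss
        if isinstance(loss, np.ndarray):
            loss = np.flip(loss, axis).copy()
        return ThermalPhantom(
            pixel_size=self.pixel_size,
            absorption_map=np.flip(self.absorption_map, axis).copy(),
            diffusivity_map=np.flip(self.diffusivity_map, axis).copy(),
            heat_capacity_map=np.flip(self.heat_capacity_map, axis).copy(),
            label_map=np.flip(self.label_map, axis).copy(),
            out_of_plane_loss=loss,
        )


@dataclass(frozen=True)
class PumpPulse:
    """Pulsed mid-IR pump.

    ``peak_heating_rate`` is the pump intensity scale I0 (W/m^2): the volumetric
    source is ``S = absorption_map * I0 * profile`` while the pulse is on, and
    the temperature source rate is ``S / C_V`` (K/s).  The default gives a
    few-kelvin rise in water over one 500 ns pulse.
    """

    duration: float = 500e-9
    repetition_period: float = 10e-6
    spot_fwhm: float = 6e-6
    peak_heating_rate: float = 2e8

    def __post_init__(self) -> None:
        if not 0 < self.duration < self.repetition_period:
            raise ValueError("need 0 < duration < repetition_period")
        if not self.spot_fwhm > 0:
            raise ValueError("spot_fwhm must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Explicit-scheme integration settings.

    ``time_step`` must satisfy the FTCS stability bound
    ``time_step <= pixel_size^2 / (4 * max(diffusivity))``; this is validated
    against the phantom before stepping.  ``padding`` (meters) extends the
    domain by edge replication before simulating with ``fixed_ambient``
    boundaries, so the clamped ring sits well outside the analysed field.
    """

    time_step: float = 10e-9
    total_time: float = 2.5e-6
    boundary_condition: str = "fixed_ambient"
    pump_mode: str = "uniform"
    seed: int = 0
    padding: float = 5e-6

    def __post_init__(self) -> None:
        if not self.time_step > 0:
            raise ValueError("time_step must be > 0")
        if self.total_time < self.time_step:
            raise ValueError("total_time must cover at least one step")
        if self.boundary_condition not in ("insulated", "fixed_ambient"):
            raise ValueError("boundary_condition must be 'insulated' or "
                             "'fixed_ambient'")
        if self.pump_mode not in ("uniform", "co_scanned"):
            raise ValueError("pump_mode must be 'uniform' or 'co_scanned'")

    def validate_stability(self, phantom: ThermalPhantom) -> None:
        limit = phantom.pixel_size ** 2 / (4.0 * float(phantom.diffusivity_map.max()))
        if self.time_step > limit * (1 + 1e-12):
            raise ValueError(
                f"explicit-scheme stability violated: time_step={self.time_step:g} s "
                f"exceeds pixel_size^2/(4 max alpha) = {limit:g} s")


@dataclass
class TemperatureMovie:
    """Ordered 2-D temperature-rise frames with their times.

    ``frames`` has shape ``(n_times, ny, nx)`` in kelvin above ambient.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    phantom: ThermalPhantom

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frames must be (n_times, ny, nx) aligned with frame_times")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def pixel_size(self) -> float:
        return self.phantom.pixel_size


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------

def _props_to_maps(shape, props: RegionProps):
    return (np.full(shape, props.absorption, dtype=float),
            np.full(shape, props.diffusivity, dtype=float),
            np.full(shape, props.heat_capacity, dtype=float))


def build_interface_phantom(
    field_size: tuple[float, float] = (15e-6, 15e-6),
    interface_position: float = 7.5e-6,
    side_a_props: RegionProps = AXON_BUNDLE,
    side_b_props: RegionProps = WATER,
    features: Sequence[tuple[tuple[float, float], float, RegionProps]] = (),
    pixel_size: float = 200e-9,
    out_of_plane_loss: float = 0.0,
) -> ThermalPhantom:
    """Two homogeneous regions split by a straight vertical interface.

    Parameters
    ----------
    field_size : (width, height) in meters (x, y).
    interface_position : x position of the interface in meters; pixels whose
        center lies at x < interface_position get ``side_a_props``.
    features : sequence of ``((cx, cy), radius, props)`` discs (meters) stamped
        on top of the two-region background.  Overlapping or non-positive-radius
        discs are rejected, as are discs extending outside the field.

    Returns
    -------
    ThermalPhantom with ``label_map`` recording region identity per pixel.
    """
    width, height = field_size
    nx = int(round(width / pixel_size))
    ny = int(round(height / pixel_size))
    if nx < 32 or ny < 32:
        raise ValueError(f"field must span >= 32x32 pixels, got {ny}x{nx}")

    # pixel-center coordinates
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    xx, yy = np.meshgrid(x, y)

    absorption, diffusivity, heat_capacity = _props_to_maps((ny, nx), side_a_props)
    label = np.full((ny, nx), side_a_props.label, dtype=_LABEL_DTYPE)

    def region_loss(props: RegionProps) -> float:
        return out_of_plane_loss if props.loss is None else props.loss

    loss_map = np.full((ny, nx), region_loss(side_a_props), dtype=float)

    right = xx >= interface_position
    absorption[right] = side_b_props.absorption
    diffusivity[right] = side_b_props.diffusivity
    heat_capacity[right] = side_b_props.heat_capacity
    label[right] = side_b_props.label
    loss_map[right] = region_loss(side_b_props)

    feats = list(features)
    for (_, radius, _) in feats:
        if not radius > 0:
            raise ValueError("feature radius must be > 0")
    for i in range(len(feats)):
        (cxi, cyi), ri, _ = feats[i]
        if not (ri <= cxi <= width - ri and ri <= cyi <= height - ri):
            raise ValueError(f"feature {i} extends outside the field")
        for j in range(i + 1, len(feats)):
            (cxj, cyj), rj, _ = feats[j]
            if math.hypot(cxi - cxj, cyi - cyj) < ri + rj:
                raise ValueError(f"features {i} and {j} overlap")

    for (cx, cy), radius, props in feats:
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        absorption[disc] = props.absorption
        diffusivity[disc] = props.diffusivity
        heat_capacity[disc] = props.heat_capacity
        label[disc] = props.label
        loss_map[disc] = region_loss(props)

    loss: float | np.ndarray = loss_map
    if np.all(loss_map == loss_map.flat[0]):
        loss = float(loss_map.flat[0])
    return ThermalPhantom(pixel_size=pixel_size, absorption_map=absorption,
                          diffusivity_map=diffusivity,
                          heat_capacity_map=heat_capacity, label_map=label,
                          out_of_plane_loss=loss)


# --------------------------------------------------------------------------
# Forward simulation
# --------------------------------------------------------------------------

def _pump_profile(phantom: ThermalPhantom, pulse: PumpPulse, mode: str,
                  center: tuple[int, int] | None) -> np.ndarray:
    ny, nx = phantom.shape
    if mode == "uniform":
        return np.ones((ny, nx))
    # co_scanned: Gaussian pump re-centered on the scanned pixel
    if center is None:
        center = (ny // 2, nx // 2)
    sigma_px = pulse.spot_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / phantom.pixel_size
    rows = np.arange(ny)[:, None] - center[0]
    cols = np.arange(nx)[None, :] - center[1]
    return np.exp(-(rows ** 2 + cols ** 2) / (2.0 * sigma_px ** 2))


def simulate_temperature_field(
    phantom: ThermalPhantom,
    pulse: PumpPulse,
    config: SimConfig,
    frame_times: np.ndarray | None = None,
    pump_center: tuple[int, int] | None = None,
    initial_temperature: np.ndarray | None = None,
) -> TemperatureMovie:
    """Integrate one pump period of heating and diffusion.

    A single pulse is simulated per call (full relaxation between pulses is
    assumed: decay constants <= 2 us are much shorter than the 10 us period).
    Frames are captured at ``frame_times`` (default: every time step), snapped
    to the nearest integration step.  For ``fixed_ambient`` boundaries the
    domain is padded by edge replication (``config.padding``) before stepping
    and frames are cropped back to the phantom field.

    Raises
    ------
    ValueError
        If the stability bound is violated, or if NaN/overflow appears during
        stepping.
    """
    config.validate_stability(phantom)
    dt = config.time_step
    n_steps = int(round(config.total_time / dt))

    if frame_times is None:
        frame_times = np.arange(n_steps + 1) * dt
    frame_times = np.asarray(frame_times, dtype=float)
    frame_steps = np.round(frame_times / dt).astype(int)
    if np.any(frame_steps < 0) or np.any(frame_steps > n_steps):
        raise ValueError("frame_times must lie within [0, total_time]")
    snapped = frame_steps * dt

    pad = 0
    if config.boundary_condition == "fixed_ambient":
        pad = max(1, int(math.ceil(config.padding / phantom.pixel_size)))

    def padded(arr):
        return np.pad(arr, pad, mode="edge") if pad else arr

    alpha = padded(phantom.diffusivity_map)
    cv = padded(phantom.heat_capacity_map)
    absorb = padded(phantom.absorption_map)
    dx = phantom.pixel_size
    k = alpha * cv  # conductivity, W/(m K)

    profile = _pump_profile(phantom, pulse, config.pump_mode, pump_center)
    profile = padded(profile)
    # temperature source rate while the pulse is on, K/s
    source_rate = pulse.peak_heating_rate * absorb * profile / cv
    loss = phantom.out_of_plane_loss
    if isinstance(loss, np.ndarray):
        loss = padded(loss)
    has_loss = bool(np.any(np.asarray(loss) > 0))

    # face conductivities (arithmetic mean)
    kx = 0.5 * (k[:, 1:] + k[:, :-1])   # faces between column j and j+1
    ky = 0.5 * (k[1:, :] + k[:-1, :])
    coeff = dt / (dx * dx)

    if initial_temperature is None:
        T = np.zeros_like(alpha)
    else:
        initial_temperature = np.asarray(initial_temperature, dtype=float)
        if initial_temperature.shape != phantom.shape:
            raise ValueError("initial_temperature must match the phantom shape")
        # ambient (zero) beyond the field, not edge-replicated
        T = np.pad(initial_temperature, pad) if pad else initial_temperature.copy()
    frames_by_step: dict[int, np.ndarray] = {}

    def capture(step):
        if step in wanted:
            view = T[pad:T.shape[0] - pad, pad:T.shape[1] - pad] if pad else T
            frames_by_step[step] = view.copy()

    wanted = set(frame_steps.tolist())
    capture(0)

    for step in range(1, n_steps + 1):
        t_start = (step - 1) * dt
        flux_x = kx * (T[:, 1:] - T[:, :-1])     # conductive flux * dx
        flux_y = ky * (T[1:, :] - T[:-1, :])
        div = np.zeros_like(T)
        div[:, :-1] += flux_x
        div[:, 1:] -= flux_x
        div[:-1, :] += flux_y
        div[1:, :] -= flux_y
        T = T + coeff * div / cv
        # source active over steps fully inside the pulse window
        if t_start < pulse.duration - 1e-15:
            on = min(dt, pulse.duration - t_start)
            T = T + source_rate * on
        if has_loss:
            T = T - dt * loss * T
        if config.boundary_condition == "fixed_ambient":
            T[0, :] = 0.0
            T[-1, :] = 0.0
            T[:, 0] = 0.0
            T[:, -1] = 0.0
        if step % 64 == 0 or step == n_steps:
            m = float(T.max(initial=0.0))
            if not np.isfinite(m) or m > 1e9:
                raise FloatingPointError(
                    f"temperature field diverged at step {step} (max {m})")
        capture(step)

    frames = np.stack([frames_by_step[s] for s in frame_steps])
    return TemperatureMovie(frames=frames, frame_times=snapped, phantom=phantom)


def total_heat(movie: TemperatureMovie) -> np.ndarray:
    """``sum(C_V * dT * dx^2)`` per frame (J/m, per unit depth)."""
    cv = movie.phantom.heat_capacity_map
    dx = movie.phantom.pixel_size
    return np.array([float(np.sum(cv * f)) * dx * dx for f in movie.frames])


# --------------------------------------------------------------------------
# Lumped decay-time prediction (Fourier's law scaling)
# --------------------------------------------------------------------------

def predict_feature_tau(c_v: float, volume: float, h: float, area: float) -> float:
    """Characteristic decay time C_V*V/(h*A) of a lumped absorber.

    Fourier's-law scaling for a feature of volumetric heat capacity ``c_v``,
    volume ``V`` and surface area ``A`` coupled to its environment with heat
    transfer coefficient ``h``.  For a sphere of radius r this reduces to
    ``c_v * r / (3 h)``: smaller features (smaller volume-to-surface ratio)
    decay faster.
    """
    for name, val in (("c_v", c_v), ("volume", volume), ("h", h), ("area", area)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    return c_v * volume / (h * area)


# --------------------------------------------------------------------------
# Closed-form synthetic traces (study-condition generators)
# --------------------------------------------------------------------------

def _time_axis(t_end: float, dt: float) -> np.ndarray:
    return np.arange(0.0, t_end + dt / 2, dt)


def synthetic_exponential_trace(tau: float, t_end: float = 5e-6,
                                dt: float = 10e-9, amplitude: float = 1.0,
                                baseline: float = 0.0):
    """``baseline + amplitude * exp(-t/tau)`` sampled at ``dt`` over [0, t_end].

    Returns ``(times, values)``.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    t = _time_axis(t_end, dt)
    return t, baseline + amplitude * np.exp(-t / tau)


def synthetic_double_exponential_trace(tau_fast: float, tau_slow: float,
                                       t_end: float = 5e-6, dt: float = 10e-9,
                                       amp_fast: float = 0.5,
                                       amp_slow: float = 0.5,
                                       baseline: float = 0.0):
    """Two-term exponential decay sampled at ``dt``; returns ``(times, values)``."""
    if not (tau_fast > 0 and tau_slow > 0):
        raise ValueError("time constants must be > 0")
    t = _time_axis(t_end, dt)
    v = (baseline + amp_fast * np.exp(-t / tau_fast)
         + amp_slow * np.exp(-t / tau_slow))
    return t, v
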