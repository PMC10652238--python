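"""Run configuration: YAML with nested sections, validated into objects.

A run config has ``phantom``, ``pulse``, ``sim``, ``detection`` and
``analysis`` sections plus a top-level ``seed``.  The same dictionary is
hashed (:func:`thermotrace.io.config_hash`) into every output's provenance
metadata, so identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import phantom as ph
from .detection import BoxcarConfig, ProbeModel

__all__ = ["RunConfig", "load_config"]

_REGION_PRESETS = {
    "water": ph.WATER,
    "axon_bundle": ph.AXON_BUNDLE,
    "surrounding_tissue": ph.SURROUNDING_TISSUE,
    "feature": ph.FEATURE,
}


def _region(spec) -> ph.RegionProps:
    if isinstance(spec, str):
        try:
            return _REGION_PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown region preset {spec!r}") from None
    base = _REGION_PRESETS.get(spec.get("preset", ""), None)
    def pick(key, default=None):
        if key in spec:
            return spec[key]
        if base is not None:
            return getattr(base, key)
        if default is not None:
            return default
        raise ValueError(f"region spec missing {key!r}")
    loss = spec.get("loss", base.loss if base is not None else None)
    return ph.RegionProps(absorption=float(pick("absorption")),
                          diffusivity=float(pick("diffusivity")),
                          heat_capacity=float(pick("heat_capacity")),
                          label=str(pick("label", "background")),
                          loss=float(loss) if loss is not None else None)


@dataclass
class RunConfig:
    """Validated run configuration with constructors for each stage."""

    raw: dict
    seed: int = 0
    output_dir: Path = Path(".")

    @property
    def analysis(self) -> dict:
        return self.raw.get("analysis", {})

    def build_phantom(self) -> ph.ThermalPhantom:
        p = self.raw.get("phantom", {})
        features = [((float(f["center"][0]), float(f["center"][1])),
                     float(f["radius"]), _region(f.get("props", "feature")))
                    for f in p.get("features", [])]
        return ph.build_interface_phantom(
            field_size=tuple(float(v) for v in p.get("field_size", (15e-6, 15e-6))),
            interface_position=float(p.get("interface_position", 7.5e-6)),
            side_a_props=_region(p.get("side_a", "axon_bundle")),
            side_b_props=_region(p.get("side_b", "water")),
            features=features,
            pixel_size=float(p.get("pixel_size", 200e-9)),
            out_of_plane_loss=float(p.get("out_of_plane_loss", 0.0)),
        )

    def build_pulse(self) -> ph.PumpPulse:
        p = self.raw.get("pulse", {})
        return ph.PumpPulse(
            duration=float(p.get("duration", 500e-9)),
            repetition_period=float(p.get("repetition_period", 10e-6)),
            spot_fwhm=float(p.get("spot_fwhm", 6e-6)),
            peak_heating_rate=float(p.get("peak_heating_rate", 2e8)),
        )

    def build_sim(self) -> ph.SimConfig:
        s = self.raw.get("sim", {})
        return ph.SimConfig(
            time_step=float(s.get("time_step", 10e-9)),
            total_time=float(s.get("total_time", 2.5e-6)),
            boundary_condition=s.get("boundary_condition", "fixed_ambient"),
            pump_mode=s.get("pump_mode", "uniform"),
            seed=self.seed,
            padding=float(s.get("padding", 5e-6)),
        )

    def build_probe(self) -> ProbeModel:
        d = self.raw.get("detection", {})
        return ProbeModel(
            spot_fwhm=float(d.get("spot_fwhm", 1e-6)),
            gain=float(d.get("gain", 1.0)),
            noise_std_single=float(d.get("noise_std_single", 0.0)),
            n_periods=int(d.get("n_periods", 2040)),
        )

    def build_boxcar(self) -> BoxcarConfig:
        d = self.raw.get("detection", {})
        baseline = d.get("baseline_window")
        return BoxcarConfig(
            gate_width=float(d.get("gate_width", 250e-9)),
            baseline_window=tuple(float(v) for v in baseline) if baseline else None,
            take_absolute=bool(d.get("take_absolute", True)),
        )

    def gate_times(self):
        d = self.raw.get("detection", {})
        import numpy as np
        if "gate_times" in d:
            return np.asarray([float(t) for t in d["gate_times"]])
        start = float(d.get("gate_start", 0.0))
        stop = float(d.get("gate_stop", 2e-6))
        step = float(d.get("gate_step", d.get("gate_width", 250e-9)))
        return np.arange(start, stop + step / 2, step)


def load_config(path_or_name, seed: int | None = None,
                output_dir=None) -> RunConfig:
    """Load a YAML run config; the name ``demo`` resolves to the packaged
    two-region interface demo."""
    if str(path_or_name) in ("demo", "demo_interface"):
        text = resources.files("thermotrace.data").joinpath(
            "demo_interface.yaml").read_text()
    else:
        p = Path(path_or_name)
        if not p.exists():
            raise FileNotFoundError(f"config file {p} not found")
        text = p.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    out = Path(output_dir) if output_dir else Path(raw.get("output_dir", "."))
    return RunConfig(raw=raw, seed=cfg_seed, output_dir=out)
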