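"""Shared fixtures: simulated phantoms and stacks reused across test modules.

Simulations are session-scoped; everything is generated at test time from the
package's own synthetic-data module under its default study conditions
(15 x 15 um field, 200 nm pixels, 500 ns pump pulse, 250 ns boxcar gates).
"""

import numpy as np
import pytest

from thermotrace import phantom as ph
from thermotrace.config import load_config
from thermotrace.detection import BoxcarConfig, ProbeModel, build_stack

GATE_TIMES_2US = np.arange(0.0, 2.01e-6, 0.25e-6)
RT_GATE_TIMES = [0.75e-6, 1.0e-6, 1.25e-6, 1.5e-6, 1.75e-6]

#: water point 1 um into the cold side of the default interface (x = 8.5 um)
COLD_SIDE_PIXEL = (32, 43)

#: disc features lined up along the interface on the absorber side
INTERFACE_FEATURES = [((7.0e-6, y * 1e-6), 0.5e-6, ph.FEATURE)
                      for y in (3.5, 5.0, 6.5, 8.0, 9.5, 11.0)]


def make_stack(phantom, total_time=2.5e-6, gate_times=GATE_TIMES_2US,
               probe=None, boxcar=None):
    movie = ph.simulate_temperature_field(
        phantom, ph.PumpPulse(), ph.SimConfig(total_time=total_time))
    return movie, build_stack(movie, probe or ProbeModel(), gate_times,
                              boxcar or BoxcarConfig())


@pytest.fixture(scope="session")
def demo_run():
    """Full demo-config pipeline: phantom, movie, stack."""
    cfg = load_config("demo")
    phantom = cfg.build_phantom()
    movie = ph.simulate_temperature_field(phantom, cfg.build_pulse(),
                                          cfg.build_sim())
    stack = build_stack(movie, cfg.build_probe(), cfg.gate_times(),
                        cfg.build_boxcar())
    return cfg, phantom, movie, stack


@pytest.fixture(scope="session")
def plain_interface_run():
    """Loss-free absorber/water interface (pure in-plane diffusion)."""
    phantom = ph.build_interface_phantom()
    movie, stack = make_stack(phantom)
    return phantom, movie, stack


@pytest.fixture(scope="session")
def featured_interface_run():
    """Loss-free interface with ~1 um disc features hugging the boundary."""
    phantom = ph.build_interface_phantom(features=INTERFACE_FEATURES)
    movie, stack = make_stack(phantom)
    return phantom, movie, stack


@pytest.fixture(scope="session")
def featured_lossy_movie():
    """Interface with disc features plus uniform out-of-plane loss, so the
    cold side genuinely decays (finite water layer) while the small features
    contribute a fast transient."""
    phantom = ph.build_interface_phantom(features=INTERFACE_FEATURES,
                                         out_of_plane_loss=4e5)
    return ph.simulate_temperature_field(
        phantom, ph.PumpPulse(), ph.SimConfig(total_time=3.0e-6))


@pytest.fixture(scope="session")
def gaussian_spot_movie():
    """Free diffusion of an initial 1 um-sigma Gaussian hot spot in a
    homogeneous non-absorbing medium (closed-form reference case)."""
    alpha = 1.4e-7
    dx = 100e-9
    n = 161
    props = ph.RegionProps(absorption=0.0, diffusivity=alpha,
                           heat_capacity=4.18e6, label="water")
    phantom = ph.build_interface_phantom(
        field_size=(n * dx, n * dx), interface_position=0.0,
        side_a_props=props, side_b_props=props, pixel_size=dx)
    x = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(x, x)
    sigma0 = 1e-6
    t0_field = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma0 ** 2))
    movie = ph.simulate_temperature_field(
        phantom, ph.PumpPulse(peak_heating_rate=0.0),
        ph.SimConfig(total_time=2.0e-6, padding=3e-6),
        frame_times=np.array([0.0, 0.75e-6, 2.0e-6]),
        initial_temperature=t0_field)
    return movie, alpha, sigma0
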