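# Two-region absorber/water interface demo: 15 x 15 um field at 200 nm pixels,
# vertical interface at x = 7.5 um, one small low-diffusivity disc feature on
# the absorber side near the interface.  Heating: 500 ns pump pulse at 100 kHz;
# detection: 1 um probe, boxcar gate width 250 ns.
#
# Per-region out-of-plane loss rates emulate the region decay constants the
# generator is meant to reproduce (bulk water ~1.5 us, bulk absorber ~1.9 us,
# small features ~0.9 us); lateral diffusion across the interface then speeds
# up the near-interface absorber pixels relative to the bulk.
seed: 0
phantom:
  field_size: [15.0e-6, 15.0e-6]
  interface_position: 7.5e-6
  pixel_size: 200.0e-9
  side_a:
    preset: axon_bundle
    loss: 5.263e5          # 1/s  -> bulk decay ~1.9 us
  side_b:
    preset: water
    loss: 6.667e5          # 1/s  -> bulk decay ~1.5 us
  features:
    - center: [6.8e-6, 4.0e-6]  # x, y in meters; hugs the interface
      radius: 0.5e-6
      props:
        preset: feature
        loss: 1.111e6      # 1/s  -> ~0.9 us
pulse:
  duration: 500.0e-9
  repetition_period: 10.0e-6
  spot_fwhm: 6.0e-6
  peak_heating_rate: 2.0e8
sim:
  time_step: 10.0e-9
  total_time: 3.0e-6
  boundary_condition: fixed_ambient
  pump_mode: uniform
  padding: 5.0e-6
detection:
  spot_fwhm: 1.0e-6
  gain: 1.0
  noise_std_single: 0.0
  n_periods: 2040
  gate_width: 250.0e-9
  gate_start: 0.0
  gate_stop: 2.75e-6
analysis:
  cv_window: [0.75e-6, 2.0e-6]
  tau_window: [0.5e-6, 2.75e-6]
  rt_gate_times: [0.75e-6, 1.0e-6, 1.25e-6, 1.5e-6, 1.75e-6]
  laplacian_floor_quantile: 0.8
  peak_min_separation: 5
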