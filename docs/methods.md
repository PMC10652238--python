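# Methods

## Signal model

A pump pulse of duration `t_p = 500 ns` at a 100 kHz repetition rate heats a
2-D sample plane; a continuous probe samples the local temperature rise ΔT
through a Gaussian focal spot, and the detector signal is `gain · ⟨ΔT⟩_probe`
(mV per K).  The boxcar output at gate start time `t_g` is

    BC(t_g) = | mean(v, [t_g, t_g + w)) − mean(v, baseline) |,   w = 250 ns

with half-open windows evaluated on the 10 ns sample timestamps (bit-
reproducible gating; ties are resolved by timestamp membership, never by
interpolation).  The absolute value is applied after baseline subtraction.
A hyper-temporal stack is one BC image per gate time, default spacing equal
to the gate width.

Because averaging N pump periods reduces white noise by √N, noise is
injected once, post-averaging, at `noise_std_single/√N` (default N = 2040)
rather than simulating thousands of raw periods — statistically identical
and three orders of magnitude cheaper.

The lock-in amplitude convention is *peak* (a pure `A·sin(2πft)` demodulates
to amplitude `A`, phase 0).  The convention matters when comparing mV
levels between instruments and is recorded here because amplitude values are
otherwise ambiguous by a factor of √2.

## Forward simulation

The phantom is a set of per-pixel maps — absorption μ_abs (1/m), thermal
diffusivity α (m²/s), volumetric heat capacity C_V (J·m⁻³·K⁻¹), region
labels — on a 200 nm grid (15 × 15 μm default field).  Temperature evolves
by

    ∂T/∂t = (1/C_V) ∇·(k ∇T) + μ_abs·I₀·p(x)/C_V − loss·T,    k = α·C_V

integrated with explicit forward-time stepping in **flux-conservative
form**: face conductivities are arithmetic means of the neighbouring `k`,
so with insulated boundaries and zero loss the total heat `Σ C_V·T·dx²` is
conserved to round-off (the suite asserts < 10⁻⁶ relative drift per step).
For homogeneous media this is exactly the familiar `α∇²T` form; for
heterogeneous phantoms the conservative form is the physically correct
generalisation.  The stability bound `dt ≤ dx²/(4·max α)` is validated
before stepping (default `dt = 10 ns` is ~7× below the bound at 200 nm
pixels).

Boundaries: `fixed_ambient` (default) pads the domain by ≥ 5 μm of
edge-replicated material and clamps the outer ring to ΔT = 0, so the clamp
never touches the analysed field within one period; `insulated` uses
zero-flux faces and exists mainly for the conservation tests.  One pump
period is simulated per call — with decay constants ≤ 2 μs and a 10 μs
period, the sample relaxes essentially completely between pulses, so
steady-state accumulation is neglected.

The pump spatial profile defaults to `uniform`: the pump spot (6 μm FWHM)
is much larger than the probe spot (1 μm FWHM), so over the neighbourhood
that determines any one trace the heating is effectively flat.  A
`co_scanned` mode re-centres a Gaussian pump profile for small phantoms
where the 6 μm envelope matters.

**Out-of-plane loss.**  The imaging plane sits in a water layer of finite,
unknown thickness; heat escaping normal to the plane is modelled as a
first-order `−loss·T` term.  The default is zero (pure in-plane diffusion).
The loss rate may be a per-region value: this is how the generator realises
the study conditions of distinct single-exponential bulk decays — water
1/loss = 1.5 μs, bulk absorber 1.9 μs, small features ~1 μs — which pure
2-D diffusion cannot produce for spatially uniform regions (a uniformly
heated half-plane does not decay laterally).  Lateral diffusion then adds
the interface physics on top: near-boundary absorber pixels decay faster
than their bulk, and ~1 μm discs decay fastest of all.

Material defaults are literature-scale: water α = 1.43·10⁻⁷ m²/s,
C_V = 4.18·10⁶ J·m⁻³·K⁻¹; tissue-like absorber α = 1.1·10⁻⁷,
C_V = 3.7·10⁶, absorption 2.2× water (matching the observed amplitude
contrast at amide-band pumping).  The pump intensity scale I₀ = 2·10⁸ W/m²
gives a few-kelvin rise in water over one pulse.

## Decay-time extraction (τ_d)

τ_d is the interval from the signal peak to the first post-peak time the
signal falls to `floor + (peak − floor)/e`, the crossing located by linear
interpolation.  The floor starts as the post-peak window minimum.  When the
trace is cut off before reaching its asymptote, the window minimum
overestimates the floor and biases τ_d low (an exponential with τ = 1.5 μs
observed for 5 μs would read ~1.41 μs).  The extractor therefore
re-estimates the floor self-consistently: modelling the decay as
approaching an asymptote `b` exponentially, the window-end minimum `m`
satisfies `m = b + (peak − b)·e^(−T/τ)`; solving for `b` under the current
τ estimate and re-locating the 1/e crossing converges to the exact constant
for any single exponential with any additive baseline.  Two guards apply:
the floor never exceeds the observed minimum, and a converged crossing
pinned to the window end (the boundary fixed point, reached whenever the
true decay is slower than the window span) is flagged invalid rather than
reported.  Traces that never reach the 1/e level are likewise flagged, not
extrapolated.  `truncation_correction=False` restores the plain
window-minimum rule.

Double-exponential fits use `scipy.optimize.curve_fit` with nine
multi-starts seeded from the 1/e estimate, non-negative amplitude bounds,
and τ ordering applied after the fit.  Fits with `τ_fast/τ_slow > 0.5` or a
negligible second amplitude are reported with `preferred_model = "single"`:
the data do not support two distinct processes.

## CV images

`CV = σ/|m|` per pixel with the **population** σ convention (divide by n);
the sample convention shifts the water value from ≈ 0.28 to ≈ 0.31, both
rounding to ≈ 0.3, and the convention is recorded in the result metadata.
The gate-time window is a required argument — computing CV over heating
frames versus diffusion-only frames are both legitimate and give different
images, so neither is silently defaulted; the diffusion window
(t_g ≥ 0.75 μs) is the documented recommendation.  Pixels whose |mean| is
below 1 % of the window's global maximum are masked rather than divided, to
keep near-zero-signal pixels from dominating the image.

On any stack of monotone decays, smaller τ ⇒ larger CV over a fixed
window, which is why the CV image is a cheap surrogate for the per-pixel
τ map; the suite asserts the negative rank correlation on simulated
phantoms.

## Rate of transfer

    RT = (∂BC/∂t) / ∇²BC        [m²/s]

with central differences across adjacent gate frames (one-sided at the
ends, no temporal smoothing by default) and a 5-point Laplacian stencil
(9-point optional), border ring masked.  The sign is chosen so a decaying
local maximum (both derivatives negative) yields RT > 0.  On exact 2-D
heat-kernel stacks RT recovers the generator diffusivity within 2 % (the
residual is the O(Δt²) central-difference error at 250 ns spacing; the
suite pins this with an analytic-stack oracle).  RT is invariant under any
positive rescaling of the signal — gain and units cancel in the ratio.

The ratio is ill-conditioned near inflection lines, so estimates where
|∇²BC| falls below a quantile floor (default the 80th percentile of the
frame's interior |∇²|) are flagged invalid; in practice RT is evaluated at
Laplacian peaks, which is where the quantity is meaningful.  Box statistics
(mean, 25th/75th percentiles with linear order-statistic interpolation) are
aggregated per region over the diffusion-window gate times (default five,
0.75–1.75 μs).

Interpretation caveats: with out-of-plane loss active, RT measures
`α − loss·T/∇²T`, not a diffusivity — on loss-dominated, low-curvature
regions it can be large or negative.  The clean RT orderings (cold side vs
hotspot, feature-throttled inflow) are therefore asserted on loss-free
phantoms, where they emerge from the diffusivity contrast alone: heat
flowing from the absorber (α = 1.1·10⁻⁷) into water (1.43·10⁻⁷) gives the
water-side point a higher RT than the absorber hotspots, and low-α discs at
the interface reduce the cold-side RT below the plain-interface value.

## What the generator does and does not emulate

It emulates: the field/pixel geometry, pulse and gate timing, probe blur,
√N period averaging, region-wise single-exponential decays at the study
constants, interface broadening (FWHM growth follows
`FWHM²(t) = FWHM²(0) + 16·ln2·α·t` within 3 %), CV contrast and dispersion,
and the qualitative interface orderings above.  It does not emulate: 3-D
heat flow (the per-region loss term is a first-order surrogate), optics
beyond a Gaussian probe kernel (no depth sectioning, no scattering),
detector electronics (AC coupling, preamp transfer functions), multi-pulse
steady state, or molecular-scale interfacial conductance.  Passing tests
demonstrate the estimators are correct on data obeying this model; on real
recordings the absolute τ and RT values additionally reflect water-layer
thickness and 3-D geometry, so relative contrasts are the robust readout.
The double-exponential cold-side signature emerges in 2-D with a realistic
~160–220 ns fast constant but a small fast-component amplitude (< 5 % of
the slow term); its form and time scale, not its amplitude, are the tested
claim.

## Numerical and convention choices

* Window semantics: half-open `[start, start + width)`, timestamps only.
* Baseline default: none for single-period simulated traces (their
  pre-pulse signal is identically zero); on full 10 μs periods use the
  signal-free last microsecond, e.g. `(9e-6, 1e-6)`.
* SNR: `(max_signal − mean_noise)/std_noise` with sample (ddof = 1) noise
  std over ≥ 8 samples.  The peak-gated-boxcar ≥ whole-trace-mean SNR
  ordering is a low-duty-cycle property (fast decays, as for sub-μm beads);
  for decays filling a large fraction of the period, the whole-period mean
  approaches a matched filter and the ordering can invert.
* Percentile conventions: RT boxes use linear interpolation between order
  statistics; "x % of values fall between a and b" is reported both as the
  shortest interval containing the mass (default) and as the symmetric
  percentile interval, labelled.
* FWHM: half-maximum referenced to the mean of the flanking minima;
  crossings by linear interpolation, ties broken toward the wider width.
* Determinism: one integer seed controls every stochastic draw; zero noise
  amplitude means bitwise-noiseless operation.  Identical config + seed
  give byte-identical TIFF payloads and CSVs.
* Stacks are float32 multi-page TIFF with a JSON sidecar (`gate_times_s`,
  `gate_width_s`, `pixel_size_m`, `seed`); CSV numbers use shortest
  round-trip decimals.

## Problem sizes

Defaults used throughout the tests and examples: 75 × 75 pixel fields
(15 × 15 μm at 200 nm), 10 ns integration steps over 2.5–4 μs (250–400
steps), 9–12 gate frames.  The heat-kernel and diffusion-law oracles use
refined 161 × 161 grids at 100 nm.  These sizes resolve all asserted
effects; larger fields change nothing structurally.

## Known limitations

* The floor-corrected 1/e rule assumes the tail approaches its asymptote
  exponentially; on strongly non-exponential tails (e.g. the dip transients
  near feature-laden interfaces) it is a controlled heuristic and the
  double-exponential fit is the better tool.
* Region labels are nearest-pixel rasterisations; feature pixel counts are
  exact for pixel centers but boundary pixels are all-or-nothing.
* `co_scanned` pump mode re-simulates per probe position only through the
  explicit `pump_center` argument; full per-pixel rescanned stacks are
  O(pixels) simulations and are left to the caller.
* RT under active out-of-plane loss mixes loss and diffusion (see above);
  comparisons across regions should fix the loss model.
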