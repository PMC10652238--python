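# thermotrace

Time-resolved photothermal image-stack analysis for mid-infrared photothermal
microscopy, together with a physics-based synthetic-data generator (pulsed
heating + 2-D heat diffusion + boxcar detection) that stands in for the
microscope.

## The problem

Mid-IR photothermal microscopy images biological samples by the transient
temperature rise a pulsed infrared pump induces in absorbing structures.  In
water-rich samples the water background absorbs almost as strongly as the
features of interest, so amplitude contrast alone cannot separate them.  The
*transient dynamics* can: after each pump pulse the signal decays at a rate
set by the local thermal environment, and gating the detected signal with a
boxcar window at successive delays `t_g` yields a **hyper-temporal stack** —
one image per gate time — that samples the heating/diffusion transient with
~10 ns resolution.

`thermotrace` implements the statistics this modality needs, for people
building or analysing such measurements:

* **Boxcar signal** `BC = |⟨v⟩_gate − ⟨v⟩_baseline|`, gated over half-open
  windows on the sample timestamps, assembled into stacks frame by frame.
* **Coefficient of variance** `CV = σ/|m|` per pixel across the stack:
  fast-decaying regions vary strongly over the diffusion window and light up,
  while slowly decaying water forms a homogeneous background — water
  suppression without pixel-by-pixel fitting.
* **Decay time** `τ_d`: the time for the post-peak signal to fall by a 1/e
  margin of the peak-to-minimum span (fit-free, with a truncation-corrected
  floor estimate), plus least-squares double-exponential fits
  `a·e^(−t/τ_fast) + b·e^(−t/τ_slow) + c` for interface traces where small
  features add a fast component.
* **Rate of transfer** `RT = (∂BC/∂t) / ∇²BC` in m²/s, by analogy with the
  heat equation `∂T/∂t = α∇²T`: on purely diffusing fields RT equals the
  thermal diffusivity, and in general it quantifies the local speed toward
  thermal equilibrium.  Estimates are taken at peaks of the spatial
  Laplacian and summarised by mean and 25–75 % box statistics.
* A **forward simulator**: 2-D material phantoms (absorption, diffusivity α,
  volumetric heat capacity C_V, region labels), a flux-conservative explicit
  solver for `∂T/∂t = (1/C_V)∇·(αC_V∇T) + S/C_V − loss·T` with a 500 ns
  pump pulse source, Gaussian-probe sampling, period-averaged noise
  (std/√N), and first-harmonic lock-in demodulation.

## Worked example

The packaged demo config simulates a 15 × 15 μm absorber/water interface at
200 nm pixels with one ~1 μm disc feature near the boundary, builds the
boxcar stack (250 ns gates), and maps CV, τ_d and RT per region:

```bash
thermotrace report --config demo --out-dir out
```

```text
thermotrace report  (config=e4ea63e610945630 seed=0)
stack: 12 frames, (75, 75) px, gate width 250 ns

              region  median CV  median tau_d (us)   n_px
         axon_bundle      0.224              1.931   2834
             feature      0.298              1.267     16
               water      0.283              1.496   2775
```

The generator's per-region decay constants (bulk absorber 1.9 μs, water
1.5 μs, feature ~1 μs) are recovered by the per-pixel 1/e mapping, the
water CV sits near 0.28, and CV and τ_d are anticorrelated: the fast-decaying
feature has the highest CV, the slow bulk absorber the lowest.  The report
also prints per-region RT box statistics evaluated at Laplacian peaks over
the diffusion window.  Individual steps are available as
`thermotrace simulate | trace | cv | tau | rt | snr`, all reading/writing
multi-page float32 TIFF stacks with JSON sidecar metadata and CSV tables;
identical config + seed reproduce byte-identical outputs.

The same operations are importable as a library:

```python
import thermotrace as tt

times, values = tt.synthetic_exponential_trace(tau=1.5e-6, t_end=5e-6)
fit = tt.extract_tau(values, times)
print(fit.tau_d)          # 1.4999996689587552e-06
```

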