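# Methods

## Scope and data model

The package analyzes TCSPC FLIM stacks: per-pixel histograms of photon
arrival times relative to the excitation pulse. The default acquisition
geometry is 256 time bins over a 12.5 ns window at an 80 MHz laser
repetition rate, so the window equals one excitation period. Time bin *i*
spans `[i·Δt, (i+1)·Δt)` with `Δt = window/n_bins`; its representative time
is the bin center. Angular frequency is always derived as `ω = k·2π·f` for
harmonic `k ≥ 1` and never stored. Stacks are multi-page TIFF with a JSON
metadata sidecar; measurement features are CSV with header
`condition,animal_id,location_id,n_valid_pixels,delta_I,g1,s1,g2,s2,...`.

## Synthetic forward model

Every pixel decay is a multi-exponential mixture whose weights are
*fractional fluorescence* (intensity shares — the weights of the phasor
vector sum), not pre-exponential amplitudes. The noise-free histogram is
built in closed form:

1. **Periodic folding.** At 80 MHz with nanosecond lifetimes, decay tails
   wrap into subsequent excitation periods; the expected profile is the
   periodic summation of the decay over the window, carried until terms fall
   below double precision.
2. **Instrument response.** A Gaussian IRF with configurable FWHM (default
   0.2 ns) and offset (default 0.5 ns) is convolved in. The convolution of
   an exponential with a Gaussian is the exponentially-modified Gaussian;
   bin masses are differences of its antiderivative
   `H(t) = τ[Φ((t−μ)/σ) − h(t)]`, evaluated with `erfcx` to avoid overflow.
   An adaptive-quadrature oracle in the test suite pins the closed form to
   1e−9 relative tolerance.
3. **TAC truncation.** The earliest bins (default 5) are zeroed on the
   expected histogram, emulating timing-electronics blanking; those photons
   are lost, not redistributed.
4. **Poisson noise.** Sampled mode draws independent Poisson counts per bin.

### Condition presets

All presets share the lifetime grid (0.3, 0.8, 2.0, 4.0) ns — two short
"free NADH" components and two long "enzyme-bound" components. The numeric
fractions and intensity ratios are package configuration chosen to emulate
the qualitative structure of pharmacological NADH studies; they are not
fitted values from any dataset:

| preset | free-pool fraction | intensity ratio |
|---|---|---|
| baseline | 0.30 | 1.00 |
| glycolysis_inhibition | 0.3005 | 1.00 |
| tca_inhibition | 0.40 | 1.15 |
| etc_inhibition | 0.50 | 1.45 |
| oxphos_uncoupling | 0.37 | 0.75 |
| seizure_like | 0.48 | 1.35 |

Mitochondrial manipulations shift the phasor toward the free-NADH side of
the plot, with the electron-transport-chain block also brightening the NADH
pool; uncoupling oxidizes NADH and dims it. Glycolysis inhibition is
deliberately perturbed far below the between-replicate dispersion so that,
like in real cortical measurements, it cannot be separated from baseline.
The seizure-like preset mimics the ETC preset, providing the held-out test
condition for classification.

### Replicate structure

A study comprises `n_animals × n_locations` paired scenes per condition
(default 3 × 3 = 9). Each location draws multiplicative log-normal
perturbations (sd = `dispersion`, default 0.05) of the mixture fractions
(renormalized), brightness, and treated/baseline intensity ratio; each
animal contributes a smaller shared effect (0.1 × `dispersion`). The
location level dominates by design: the downstream two-sample Hotelling
test pools measurements as exchangeable replicates, and a dominant
animal-level effect would make its nominal 5 % level badly anti-conservative
at 9 measurements from 3 animals. The residual animal effect (intra-class
correlation ≈ 0.01) keeps the hierarchy present without invalidating the
pooled-covariance assumption. Default brightness is 1200 expected
photons/pixel, so 3×3 binning clears the 5000-photon validity floor with
margin; default scene size is 24×24 pixels with a vessel stripe covering
~1/8 of the field (scene geometry is free metadata — the analysis is
per-pixel and does not depend on the field size, so tests and the default
study use compact fields to keep simulation cheap).

## Preprocessing

Fixed order, logged per stage: 3×3 median filter applied independently to
each time-bin count plane (border replication) → manual vessel-mask
exclusion → 3×3 sliding-window decay binning (each pixel becomes the sum of
its neighborhood; dimensions preserved, borders replicated — neighborhood
aggregation, not block downsampling) → validity floor flagging binned
pixels under 5000 photons. The alternative of median-filtering phasor
images after computation is exposed in principle via the modular API (run
`phasor_image` first, filter its planes); the shipped pipeline filters
counts, preserving the stated order. For a measurement pair the valid mask
is the intersection of both acquisitions' floors, so the phasor average and
ΔI = (ΣI_treated − ΣI_baseline)/ΣI_baseline use the same pixels.

## Phasor computation and calibration

Discrete Fourier sums use bin centers and include all bins, truncated
region included; no background subtraction is performed. At 256 bins the
discretization error against the closed-form circle point is ~1e−4.

The calibration is the standard phasor-referencing construction: treat
phasors as complex `z = g + i·s`; measure the reference standard (free NADH
in buffer) through the same instrument and multiply every pixel by
`z_theory / z_measured`, where `z_theory` is the vector-sum phasor of the
configurable reference model. The default reference model is a single
effective 0.4 ns lifetime for free NADH in aqueous buffer
(literature-informed; a bi-exponential model can be substituted as a
`LifetimeMixture`). Both phase+modulation (default) and phase-only
corrections are supported. The IRF delay and Gaussian width are exactly
multiplicative in the Fourier domain and are removed perfectly; early-bin
truncation is not exactly multiplicative, but with ~2 % of the period
truncated the residual after calibration is below 0.01 in phasor distance
at 1e6 photons (verified in the acceptance tests over lifetimes 1–3 ns at
both harmonics).

Per-measurement aggregation is the unweighted pixel mean of g and s over
valid pixels (a photon-weighted mean would differ only through the
linearity identity; the unweighted mean matches the convention of averaging
per-pixel phasor estimates over the field of view).

## Statistics

**Standard deviational ellipses** summarize cluster dispersion: center at
the bivariate mean, orientation from the rotation extremizing the standard
deviation of projected deviations, semi-axes equal to those extremal
standard deviations. Implemented as the eigen-decomposition of the
deviation covariance with 1/(n−1) normalization — algebraically equivalent
to the classical `tan 2θ` rotation criterion up to that normalization
choice, which the test suite pins against the rotation formula directly.
The normalization is irrelevant to the ellipses' purpose (relative visual
dispersion); axes scale by a common factor under 1/n instead.

**Two-sample Hotelling T²** with pooled covariance tests each condition's
mean (g, s) against baseline per harmonic:
`F = T²(n_a+n_b−p−1)/((n_a+n_b−2)p)` with `p = 2`, p-value from
`F(p, n_a+n_b−p−1)`. No multiple-testing correction is applied across
conditions; significance is α = 0.05. A singular pooled covariance raises
unless an explicit pseudo-inverse flag is passed. Validity is established
two ways in the tests: the type-I error at the minimum cohort size (9 vs 9)
sits within 0.05 ± 0.015 over 2000 null replicates, and the parametric
p-value tracks a 10,000-draw permutation reference within Monte-Carlo error.

## Classification

Feature rows are (g, s, ΔI) per measurement at one harmonic; per-harmonic
models are trained separately, never concatenated. Baseline and glycolysis
measurements are excluded from training by the default class map (the
latter carries no class signal by construction), as is the held-out
seizure-like condition. The three families:

* **LDA** — shared pooled covariance, empirical class priors.
* **KNN** — default k = 3 on z-scored features (ΔI and phasor coordinates
  differ in scale by an order of magnitude); ties break toward the
  lexicographically smallest class label.
* **Gaussian naive Bayes** — per-class independent feature Gaussians,
  variance floor 1e−12 (relative to the largest feature variance) against
  degenerate inputs.

Cross-validation is stratified K-fold (default K = 5, seeded, logged);
`K = n` switches to the deterministic leave-one-out loop, cheap at n ≈ 27.
Held-out prediction reports per-measurement labels plus the fraction of the
test set assigned to each class.

## Determinism and problem sizes

All randomness flows from one integer seed through `numpy` `SeedSequence`
spawning; repeat runs write byte-identical tables and reports. The default
synthetic study (5 conditions × 9 pairs of 24×24×256 stacks, plus the
seizure-like test group) runs in a few seconds; the test suite's
20-replicate pattern checks use that same default configuration.

## Limitations

* The generator emulates condition structure, photon statistics, IRF, and
  TAC truncation, but not optical blur, scattering or depth effects, motion,
  detector afterpulsing, or spectral channels. Passing tests demonstrate the
  correctness of the analysis chain and the resolvability of the configured
  effect sizes — not the effect sizes of any real tissue preparation.
* Preset lifetimes/fractions are qualitative configuration; recovering a
  specific laboratory's values would require its calibration data.
* The Hotelling test treats measurements as exchangeable; strong
  animal-level effects would require a mixed-model or cluster-robust
  extension that is out of scope here (and the generator's defaults keep
  that effect small by design).
* Vessel masks are inputs (manual masking in practice); no automated vessel
  detection or image registration is provided.
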