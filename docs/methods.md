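# Methods

## Model

The predicted BOLD response of a region is

```
β_S · { [ (stimulus ⊗ IRF_S) · e^(−t/α) ] ⊗ HRF }  +  β_T · { σ(stimulus ⊗ IRF_T) ⊗ HRF }
```

computed per stimulus category, where the stimulus is a binary step
function on a 1-ms grid, `⊗` is causal convolution, and `t` is time since
the most recent stimulus onset.  The asymmetric sigmoid is

```
σ(x) = 1 − exp(−( x/λ)^k_on)   for x ≥ 0   (onset lobe)
σ(x) = 1 − exp(−(−x/λ)^k_off)  for x < 0   (offset lobe)
```

so both lobes of the biphasic transient drive map to non-negative
responses in [0, 1).  Lower shape values `k` produce heavier sigmoid
tails and therefore elongate the corresponding transient response; the
onset/offset balance `k_on/(k_on + k_off)` summarizes the asymmetry
(0.5 = symmetric, above 0.5 = offset-dominant).

### Neural IRFs

Both channel IRFs are cascades of leaky integrators (gamma densities).
The sustained IRF is a gamma density with shape `n1 = 9` and time constant
τ; the transient IRF is the difference between that density and a slower
one with shape `n2 = 10` and time constant `κτ`, `κ = 1.33`.  `n1`, `n2`
and `κ` are fixed; τ is optimized.  Kernels are sampled on the working
grid and truncated where the remaining tail mass falls below 1e-6.

Normalization: the sustained kernel has unit (discrete) area, so a long
stimulus drives it to a plateau of exactly 1.  The transient kernel is
rescaled so that its positive lobe has unit area; because the kernel's
running integral peaks exactly at the lobe crossing, this simultaneously
makes the response to an isolated onset of a long stimulus peak at 1.
The two stated conventions (unit positive lobe, unit onset peak) are
therefore one and the same, and λ's bounds [0.01, 0.5] read directly as
fractions of peak drive.  The net kernel area is 0 to float rounding.

### Nonlinearities

- **Adaptation** (A): the convolved sustained drive is multiplied by
  `exp(-(t - t_on)/α)` with `t_on` the latest onset at or before `t`; the
  multiplier is 1 before the first onset, runs through inter-stimulus gaps,
  resets at every onset, and persists to the end of the run after the last
  stimulus (where the drive is zero anyway beyond the IRF tail).
- **CTS** (C): pointwise power law `drive^ε` on the non-negative sustained
  drive.
- **Sigmoid** (S) and **quadratic** (Q): pointwise on the transient drive.

### Variants

GLM (stimulus boxcar ⊗ HRF, no neural stage), L, CTS, A (sustained-only),
S (transient-only; the sustained channel is absent, mirroring regions with
no sustained response), and the dual-channel L+Q, C+Q, A+Q, A+S.  A
nonlinear hemodynamic (balloon-type) comparator is out of scope: its
parameter set lives outside this package's sources.

## Hemodynamics and design matrices

The HRF is a double-gamma kernel: response peak at 5 s, undershoot peak at
15 s with ratio 1/6, unit peak, truncated at 32 s; it is configurable so an
external kernel can be swapped in.  Neural responses are convolved with the
HRF at the working resolution and sampled at TR onsets (TR = 1 s by
default); window-averaged downsampling is intentionally not the default
since the HRF's low-pass character makes point sampling essentially
lossless for grid-aligned designs.  Predictors (channel × category) are
assembled per run with one intercept column per run and no drift
regressors; each channel block is divided by its maximal height so the two
channels' β weights share a scale.  Held-out data reuse the training
split's normalization record.

## Fitting

β weights are ordinary least squares.  The free parameters of a variant
(subset of τ, α, ε, λ, k_on, k_off) are optimized by L-BFGS-B within
bounds τ ∈ [4, 20] ms, α ∈ [10, 40] s, ε ∈ [0.01, 1], λ ∈ [0.01, 0.5],
k_on, k_off ∈ [0.1, 6], starting from τ = 4.93 ms, α = 20 s, ε = 0.1,
λ = 0.1, k_on = k_off = 3.  The objective is the residual sum of squares,
after the nested OLS fit, over training runs concatenated across all three
experiments (concatenated RSS, not mean per-run RSS).  Parameters are
rescaled to the unit box so the finite-difference gradient treats ms-, s-
and unitless-scale parameters equally; during optimization the IRF grid
length is fixed from the τ upper bound so the objective is smooth in τ.
A seeded multi-start option (`n_starts`) restarts from uniform draws
within the bounds; the default is a single start.  The sigmoid landscape
has genuine local basins (see Limitations), so the multi-start flag is
recommended whenever the shape parameters themselves are of interest.

Cross-validation is split-half by default: runs 1–2 vs 3–4 within each
experiment (or a seeded random assignment), parameters and β estimated on
one half, x-R² computed on the other, averaged over both directions.
x-R² = 1 − SS_res/SS_tot on the concatenated held-out series per
experiment, after removing per-run means from both data and prediction
(intercepts are excluded from the variance accounting); it is negative
whenever the model's residual variance exceeds the data variance.

### Fast forward path

Runs are permutations of 12 trial types separated by 12-s baselines, and
every neural nonlinearity is pointwise or onset-resetting, so a run's
neural response is an exact sum of per-trial snippets with disjoint
support; by linearity of convolution the TR-sampled BOLD predictor is the
same scatter-add of per-(experiment, duration) BOLD snippets.  The
optimizer evaluates this cached path (~20 ms per design-matrix build);
a dense reference implementation exists alongside it and the two are
equality-tested (≤1e-9 for linear/adaptation/quadratic variants; ≤1e-6
for compressive variants, whose sub-unity exponents amplify float rounding
near zero).

## Synthetic data

The generator emulates the study layout: per experiment (1: one continuous
image per trial; 2: thirty 33-ms flashed images; 3: thirty semi-continuous
images with 33-ms gaps), four 270-s runs of the full 3-category ×
{3, 5, 10, 20}-s permutation with 12-s baselines, TR = 1 s, seeded trial
order.  Sub-millisecond cycle remainders (e.g. the 666.67-ms cycle of 20-s
trials) are floored to whole milliseconds with the remainder appended as
trial-end baseline, reproducing the 633-ms printed spacings on an integer
grid.  Series are forward-model predictions plus additive white Gaussian
noise (AR(1), ρ = 0.3 optional); the default noise SD of 0.2 corresponds
to roughly SNR 10 against a ~2 percent-signal-change peak, and
`noise_sd_for_snr` sets the SD for an exact peak-signal-to-noise target.
Two illustrative presets bracket the regimes of interest: "ventral-like"
(both channels, α = 15 s, offset-dominant sigmoid k_on = 1, k_off = 0.3,
balance ≈ 0.77) and "lateral-like" (transient-only, k_on = k_off = 3).
Preset values are round illustrative choices within the fitting bounds,
not fits to any dataset.

The generator does **not** emulate voxel-level spatial structure,
participant hierarchies, scanner drift, physiological noise, or
hemodynamic variability across regions — so passing tests demonstrate
correctness and identifiability of the computational pipeline under its
own assumptions, not performance on real recordings.

## Problem sizes used in the test suite

Simulation-based tests use 2 runs per experiment (the minimum supporting
split-half cross-validation) and a reduced optimizer budget (maxiter
10–15, single start) where only model ranking or qualitative recovery is
asserted; the generative-identity check uses the full budget (maxiter 100,
9 seeded starts — even without noise the sigmoid objective has shallow
local basins, so broad multi-start coverage is needed to pin the onset
shape parameter).  The model-selection check uses 50 seeded replicates at
SNR 5.  The test configuration pins BLAS to one thread so optimizer
trajectories are bit-reproducible.

## Numerical choices

- Time is 0-based with half-open [onset, offset) ms intervals; step
  functions are rendered by sample-start membership, exact at 1 ms.
- Working resolutions must divide 1000 ms; a resolution leaving fewer than
  5 samples before the sustained IRF peak is rejected.
- After IRF convolution, values below 1e-13 of the peak are snapped to
  zero: outside the kernel support the true convolution is exactly zero,
  and FFT rounding noise there would otherwise be amplified by the
  compressive nonlinearities.
- `σ(x)` saturates to exactly 1.0 in float64 once the Weibull exponent
  exceeds ~37, although the mathematical range is [0, 1).
- The optimizer safeguard returns the initial point if no better point is
  found, so the final objective never exceeds the initial one.
- A zero transient β makes |β_S/β_T| undefined; it is reported as NaN
  (missing), never infinity.
- The noise ceiling is the squared Spearman–Brown-corrected split-half
  correlation of condition-mean time courses, averaged over seeded random
  splits; this choice is configurable since several conventions exist.
- The contrast effect size is β(preferred) − mean β(nonpreferred) within a
  channel.

## Limitations

- **Sigmoid identifiability at low SNR.**  At SNR 5 (peak signal /
  noise SD) with two runs per experiment, many (λ, k_on, k_off)
  configurations produce near-identical predictors once β_T rescales:
  the RSS difference between the generating shapes and a maximally
  different configuration is ~2e-4 of the total.  Onset/offset balance
  recovery is therefore only reliable in low-noise regimes (it is clean at
  SNR 50); channel contributions (β, |β_S/β_T|) and model ranking remain
  robust at SNR 5.  Real studies mitigate this by averaging fits across
  participants.
- Model selection among nested/similar variants (e.g. L+Q vs A+S) has
  modest margins at SNR 5; the ranking statistics in the tests hold in
  aggregate, not in every single replicate.
- No adaptation is modeled in the transient channel, no contrast
  dependence of IRF latency, and no spatial (receptive-field) component.
- The GLM benchmark deliberately has no neural stage; its known failure
  modes (overestimating responses to continuous images, underestimating
  flashed ones) are reproduced by construction.
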