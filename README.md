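# temporal-channels

Encoding models that predict fMRI responses in visual cortex from the
**millisecond-resolution timing** of visual stimulation, for researchers
studying temporal processing with BOLD imaging.

fMRI samples the brain on a seconds timescale, yet neural temporal
nonlinearities play out over tens of milliseconds: brief flashes evoke
far larger responses than their duration predicts, and prolonged images
adapt.  This package implements a two-temporal-channel encoding framework
that bridges the gap.  A stimulus sequence is coded as a millisecond step
function and passed through two neural channels:

- a **sustained** channel — a monophasic impulse response function (IRF,
  a gamma cascade with optimizable time constant τ) whose output is
  multiplied by an exponential fMRI-adaptation decay `exp(-t/α)` restarting
  at each stimulus onset;
- a **transient** channel — a biphasic IRF responding at stimulus onsets
  and offsets, compressed by separate cumulative-Weibull sigmoids
  `σ(x) = 1 − exp(−(x/λ)^k_on)` for onsets (`x ≥ 0`) and
  `1 − exp(−(−x/λ)^k_off)` for offsets (`x < 0`).

Channel outputs are convolved with a canonical HRF, sampled at the TR, and
combined as `β_S`- and `β_T`-weighted predictors in a GLM.  This is the A+S
model; the package also implements the comparison architectures (GLM, L,
CTS, A, S, L+Q, C+Q, A+Q), bounded nonlinear optimization of
(τ, α, ε, λ, k_on, k_off), split-half cross-validated variance explained
(x-R², which can be negative), and derived metrics such as the onset/offset
balance `k_on/(k_on + k_off)` and the channel ratio `|β_S/β_T|`.

A synthetic-data module generates ground-truth region-of-interest time
series with the study's run structure (270-s runs, 12-s baselines, 3
categories × trial durations of 3/5/10/20 s, three timing experiments), so
the whole pipeline is testable without any scanner data.

## Worked example

```python
from temporal_channels.synthetic import ventral_like, generate_dataset, default_designs
from temporal_channels.fitting import compare_models, cross_validate
from temporal_channels.metrics import balance_metric, channel_ratio

# simulate a "ventral-like" region: both channels active, strong adaptation
truth = ventral_like(noise_sd=0.35, seed=7)
runs, sidecar = generate_dataset(truth, default_designs(2, seed=7))

table = compare_models(["GLM", "CTS", "L+Q", "A+S"], runs, maxiter=10)
print(table.round(3))

fit = cross_validate("A+S", runs, maxiter=10)
print("balance:", round(balance_metric(fit.params.k_on, fit.params.k_off), 2))
print("body |bS/bT|:", round(channel_ratio(fit.betas["sustained"]["body"],
                                           fit.betas["transient"]["body"]), 2))
```

prints

```
      exp1   exp2   exp3   mean
GLM  0.065  0.107  0.504  0.225
CTS  0.065  0.375  0.550  0.330
L+Q  0.229  0.422  0.643  0.431
A+S  0.283  0.427  0.648  0.453
balance: 0.5
body |bS/bT|: 0.7
```

Rows are cross-validated R² per timing experiment (exp1: one continuous
image per trial; exp2: 30 flashed 33-ms images; exp3: 30 semi-continuous
images) plus their mean.  The generating A+S architecture predicts held-out
runs best, the standard GLM fails most severely on the flashed-image
experiment, and the fitted channel weights show both sustained and
transient contributions — the signature this model family was built to
capture.

A thin CLI wraps the same functions:

```bash
tcm simulate design -e 2 --seed 3 --out design.json
tcm simulate dataset --preset ventral-like --seed 7 --out-dir ds/
tcm fit --variant A+S --data ds/ --out fit.json
tcm compare --variants GLM,CTS,L+Q,A+S --data ds/ --out table.tsv
```

## Documentation

`docs/methods.md` describes the model equations, parameter bounds and
defaults, the synthetic-data generator and what it does (and does not)
emulate, numerical choices, and known limitations.
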