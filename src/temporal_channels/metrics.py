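"""Derived summary quantities for fitted temporal-channel models.

* onset/offset balance of the transient sigmoid shapes,
* sustained-to-transient channel contribution ratio |beta_S / beta_T|,
* contrast effect size (category selectivity within a channel),
* model-free peak trial amplitudes,
* split-half noise ceiling on cross-validated variance explained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class ChannelWeights:
    """Fitted response amplitudes per category for both channels."""

    beta_s: Mapping[str, float]
    beta_t: Mapping[str, float]
    preferred_category: str

    def __post_init__(self) -> None:
        if set(self.beta_s) != set(self.beta_t):
            raise ValueError("categories must be identical across channels")
        if self.preferred_category not in self.beta_s:
            raise ValueError(f"preferred category {self.preferred_category!r} missing from weights")

    def channel(self, name: str) -> Mapping[str, float]:
        if name == "sustained":
            return self.beta_s
        if name == "transient":
            return self.beta_t
        raise ValueError(f"unknown channel {name!r}")


def balance_metric(k_on: float, k_off: float) -> float:
    """Onset/offset balance k_on / (k_on + k_off).

    Because smaller shape parameters elongate transient responses, values
    above 0.5 indicate offset-dominant transients (the offset sigmoid is
    more compressive/elongating than the onset one); 0.5 means the onset
    and offset of a stimulus contribute equally.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("shape parameters must be positive")
    return k_on / (k_on + k_off)


def channel_ratio(beta_s: float, beta_t: float) -> float:
    """|beta_S / beta_T|; NaN (missing) when the transient weight is zero."""
    if beta_t == 0:
        return math.nan
    return abs(beta_s / beta_t)


def contrast_effect_size(weights: ChannelWeights, channel: str) -> float:
    """Category selectivity of one channel: beta(preferred) minus the mean
    beta over nonpreferred categories."""
    betas = weights.channel(channel)
    preferred = weights.preferred_category
    others = [b for cat, b in betas.items() if cat != preferred]
    if not others:
        raise ValueError("need at least two categories")
    return float(betas[preferred] - np.mean(others))


def peak_trial_amplitude(
    series: np.ndarray,
    trial_windows: Mapping[str, Sequence[tuple[float, float]]],
    lag_s: float = 6.0,
    tr_s: float = 1.0,
) -> dict[str, float]:
    """Model-free peak response per condition.

    Each trial window ``(start_s, end_s)`` is extended by a hemodynamic lag
    (default 6 s) and the series maximum within it taken; per-condition
    values are means over that condition's trials.
    """
    series = np.asarray(series, dtype=np.float64)
    out: dict[str, float] = {}
    for cond, windows in trial_windows.items():
        peaks = []
        for start_s, end_s in windows:
            i0 = int(np.floor(start_s / tr_s))
            i1 = int(np.ceil((end_s + lag_s) / tr_s))
            if i0 < 0 or i0 >= series.size:
                raise ValueError(f"trial window ({start_s}, {end_s}) outside the series")
            peaks.append(series[i0 : min(i1, series.size)].max())
        out[cond] = float(np.mean(peaks))
    return out


def noise_ceiling(
    trials_by_condition: Mapping[str, np.ndarray],
    n_splits: int = 50,
    seed: int = 0,
) -> float:
    """Upper bound on attainable x-R^2 from inter-trial variability.

    Trials of each condition are split in half; condition-mean time courses
    of the two halves (concatenated across conditions) are correlated, the
    correlation is Spearman-Brown corrected to full length and squared.  The
    result is averaged over ``n_splits`` random splits and is invariant to
    overall scaling of the data.
    """
    arrays = {}
    for cond, trials in trials_by_condition.items():
        trials = np.asarray(trials, dtype=np.float64)
        if trials.ndim != 2 or trials.shape[0] < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 trials (rows)")
        arrays[cond] = trials
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_splits):
        half_a, half_b = [], []
        for trials in arrays.values():
            n = trials.shape[0]
            perm = rng.permutation(n)
            half_a.append(trials[perm[: n // 2]].mean(axis=0))
            half_b.append(trials[perm[n // 2 :]].mean(axis=0))
        a = np.concatenate(half_a)
        b = np.concatenate(half_b)
        sa, sb = a.std(), b.std()
        if sa == 0 and sb == 0:
            r = 1.0  # identical constant halves
        elif sa == 0 or sb == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        sb_corrected = 2 * r / (1 + r) if r > -1 else -1.0
        vals.append(sb_corrected**2 if sb_corrected > 0 else 0.0)
    return float(np.mean(vals))


def metrics_table(
    roi: str,
    weights: ChannelWeights,
    k_on: float | None = None,
    k_off: float | None = None,
    path: str | Path | None = None,
):
    """Tidy long-format table (roi, metric, channel, category, value)."""
    import pandas as pd

    rows = []
    for chan in ("sustained", "transient"):
        betas = weights.channel(chan)
        for cat, b in betas.items():
            rows.append((roi, "beta", chan, cat, b))
        rows.append((roi, "contrast_effect_size", chan, "", contrast_effect_size(weights, chan)))
    for cat in weights.beta_s:
        rows.append(
            (roi, "channel_ratio", "", cat, channel_ratio(weights.beta_s[cat], weights.beta_t[cat]))
        )
    if k_on is not None and k_off is not None:
        rows.append((roi, "balance", "transient", "", balance_metric(k_on, k_off)))
    frame = pd.DataFrame(rows, columns=["roi", "metric", "channel", "category", "value"])
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
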