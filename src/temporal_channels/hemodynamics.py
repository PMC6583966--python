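"""Hemodynamic stage: neural responses -> TR-resolution BOLD predictors.

Neural channel outputs are convolved with a canonical hemodynamic response
function (HRF) at the working (millisecond) resolution and sampled at TR
onsets.  Because the HRF is a strong low-pass filter, this downsampling
loses essentially nothing.  Predictors for all channel x category pairs are
assembled into a design matrix whose channel blocks are max-height
normalized so that the fitted beta weights of the sustained and transient
channels are on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import oaconvolve
from scipy.stats import gamma as _gamma

from . import channels as ch
from .design import StepFunction, rising_edges
from .variants import ModelVariant, get_variant

HRF_DURATION_S = 32.0
HRF_PEAK_S = 5.0
HRF_UNDERSHOOT_S = 15.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(resolution_ms: int = 1) -> np.ndarray:
    """Double-gamma canonical HRF: peak at 5 s, undershoot at 15 s with 1/6
    amplitude, truncated at 32 s and scaled to unit peak."""
    if 1000 % resolution_ms != 0:
        raise ValueError(f"resolution_ms={resolution_ms} must divide 1000")
    t = np.arange(int(HRF_DURATION_S * 1000) // resolution_ms) * (resolution_ms / 1000.0)
    # gamma density with scale 1 peaks at shape-1
    peak = _gamma.pdf(t, HRF_PEAK_S + 1.0)
    under = _gamma.pdf(t, HRF_UNDERSHOOT_S + 1.0)
    h = peak - HRF_UNDERSHOOT_RATIO * under
    return h / h.max()


@dataclass(frozen=True)
class HemodynamicModel:
    """HRF kernel at working resolution plus the fMRI sampling interval."""

    kernel: np.ndarray
    resolution_ms: int = 1
    tr_s: float = 1.0

    @classmethod
    def canonical(cls, resolution_ms: int = 1, tr_s: float = 1.0) -> "HemodynamicModel":
        return cls(kernel=canonical_hrf(resolution_ms), resolution_ms=resolution_ms, tr_s=tr_s)

    @property
    def samples_per_tr(self) -> int:
        step = self.tr_s * 1000.0 / self.resolution_ms
        if abs(step - round(step)) > 1e-9:
            raise ValueError("TR must be an integer number of working-resolution samples")
        return int(round(step))


def predict_bold(neural: np.ndarray, hemo: HemodynamicModel) -> np.ndarray:
    """Convolve a neural response with the HRF at working resolution and
    sample at TR onsets (t = 0, TR, 2 TR, ...)."""
    neural = np.asarray(neural, dtype=np.float64)
    step = hemo.samples_per_tr
    if neural.size % step != 0:
        raise ValueError(
            f"run length of {neural.size} samples is not an integer multiple of "
            f"TR={hemo.tr_s} s at {hemo.resolution_ms}-ms resolution"
        )
    dense = oaconvolve(neural, hemo.kernel)[: neural.size]
    return dense[::step]


@dataclass
class DesignMatrix:
    """Stacked TR-resolution predictors (channel x category) plus per-run intercepts."""

    X: np.ndarray
    columns: list[str]
    n_predictors: int
    run_slices: list[slice]
    channel_blocks: dict[str, slice]
    normalization: dict[str, float]
    variant: ModelVariant
    tr_s: float = 1.0

    @property
    def predictors(self) -> np.ndarray:
        return self.X[:, : self.n_predictors]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.X, columns=self.columns).to_csv(path, sep="\t", index=False)


def _neural_responses(
    step: StepFunction, variant: ModelVariant, params: ch.ModelParams
) -> dict[str, np.ndarray]:
    """Per-channel neural response matrices (n_categories, n_samples)."""
    res = step.resolution_ms
    out: dict[str, np.ndarray] = {}
    if variant.has_irf:
        h_s, h_t = ch.make_irfs(params.irf, resolution_ms=res)
    if variant.sustained == "boxcar":
        out["sustained"] = step.values.astype(np.float64)
    elif variant.sustained != "absent":
        rows = []
        for i, cat in enumerate(step.categories):
            drive = ch.convolve_channel(step.values[i], h_s)
            if variant.sustained == "adaptation":
                onsets_ms = rising_edges(step, cat) * float(res)
                drive = ch.apply_adaptation(drive, onsets_ms, params.alpha_s, resolution_ms=res)
            elif variant.sustained == "cts":
                drive = ch.apply_cts(drive, params.epsilon)
            rows.append(drive)
        out["sustained"] = np.vstack(rows)
    if variant.transient != "absent":
        rows = []
        for i in range(len(step.categories)):
            drive = ch.convolve_channel(step.values[i], h_t)
            if variant.transient == "sigmoid":
                drive = ch.sigmoid_rectifier(drive, params.transient)
            else:
                drive = ch.quadratic_rectifier(drive)
            rows.append(drive)
        out["transient"] = np.vstack(rows)
    return out


def neural_responses_to_tsv(
    step: StepFunction,
    variant: ModelVariant | str,
    params: ch.ModelParams | None = None,
    path: str | Path | None = None,
):
    """Long-format table (time_ms, channel, category, value) of the
    millisecond-resolution neural responses, for inspection and plotting."""
    import pandas as pd

    variant = get_variant(variant)
    neural = _neural_responses(step, variant, params or ch.ModelParams())
    t_ms = np.arange(step.n_samples) * step.resolution_ms
    parts = []
    for chan, rows in neural.items():
        for i, cat in enumerate(step.categories):
            parts.append(
                pd.DataFrame(
                    {"time_ms": t_ms, "channel": chan, "category": cat, "value": rows[i]}
                )
            )
    frame = pd.concat(parts, ignore_index=True)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def build_design_matrix(
    runs: Sequence[StepFunction],
    variant: ModelVariant | str,
    params: ch.ModelParams | None = None,
    hemo: HemodynamicModel | None = None,
    normalization: dict[str, float] | None = None,
) -> DesignMatrix:
    """Assemble the full design matrix for a set of runs (reference path).

    This computes every predictor densely at the runs' working resolution.
    Channel blocks are scaled to a common maximal height unless an explicit
    ``normalization`` record (e.g. from a training split) is supplied.
    """
    variant = get_variant(variant)
    params = params or ch.ModelParams()
    if not runs:
        raise ValueError("need at least one run")
    res = runs[0].resolution_ms
    cats = runs[0].categories
    if any(r.resolution_ms != res or r.categories != cats for r in runs):
        raise ValueError("runs must share resolution and categories")
    hemo = hemo or HemodynamicModel.canonical(resolution_ms=res)
    if hemo.resolution_ms != res:
        raise ValueError("hemodynamic model resolution must match the step functions")

    chans = variant.channels
    per_run_blocks: list[np.ndarray] = []
    for step in runs:
        neural = _neural_responses(step, variant, params)
        cols = []
        for chan in chans:
            for i in range(len(cats)):
                cols.append(predict_bold(neural[chan][i], hemo))
        per_run_blocks.append(np.column_stack(cols))

    n_pred = len(chans) * len(cats)
    n_rows = sum(b.shape[0] for b in per_run_blocks)
    X = np.zeros((n_rows, n_pred + len(runs)))
    run_slices = []
    r0 = 0
    for j, block in enumerate(per_run_blocks):
        r1 = r0 + block.shape[0]
        X[r0:r1, :n_pred] = block
        X[r0:r1, n_pred + j] = 1.0
        run_slices.append(slice(r0, r1))
        r0 = r1

    channel_blocks = {
        chan: slice(k * len(cats), (k + 1) * len(cats)) for k, chan in enumerate(chans)
    }
    norm: dict[str, float] = {}
    for chan, sl in channel_blocks.items():
        scale = (
            normalization[chan]
            if normalization is not None
            else float(np.abs(X[:, sl]).max())
        )
        if scale > 0:
            X[:, sl] /= scale
        norm[chan] = scale

    columns = [f"{chan}.{cat}" for chan in chans for cat in cats]
    columns += [f"intercept.run{j}" for j in range(len(runs))]
    return DesignMatrix(
        X=X,
        columns=columns,
        n_predictors=n_pred,
        run_slices=run_slices,
        channel_blocks=channel_blocks,
        normalization=norm,
        variant=variant,
        tr_s=hemo.tr_s,
    )
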