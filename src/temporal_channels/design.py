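"""Experiment timing structures and millisecond-resolution stimulus step functions.

Three related experimental designs are supported, all built from trials of
3, 5, 10, or 20 s separated by 12-s blank baselines:

* experiment 1 — one continuous image spanning the whole trial,
* experiment 2 — 30 flashed 33-ms images whose interstimulus interval (ISI)
  grows with trial duration (67/133/300/633 ms),
* experiment 3 — 30 semi-continuous images with a constant 33-ms ISI whose
  image duration grows with trial duration (67/133/300/633 ms).

A run is rendered as a per-category binary step function on a millisecond
grid; this vector is the input signal of the neural channel models.

Time convention: 0-based, half-open intervals ``[onset, offset)`` in ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

CATEGORIES = ("face", "body", "word")
TRIAL_DURATIONS_S = (3, 5, 10, 20)
IMAGES_PER_TRIAL = 30
FLASH_MS = 33  # image duration in experiment 2; ISI in experiment 3
DEFAULT_BASELINE_S = 12.0


@dataclass(frozen=True)
class TrialSpec:
    """One trial: an ordered set of image on/off intervals within the trial.

    ``events`` are half-open ``(onset_ms, offset_ms)`` intervals relative to
    trial start; any sub-millisecond cycle remainder is absorbed as extra
    blank time at the end of the trial.
    """

    experiment: int
    duration_s: float
    category: str
    events: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError(f"unknown experiment id {self.experiment!r}; expected 1, 2 or 3")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        dur_ms = self.duration_ms
        prev_off = 0
        for on, off in self.events:
            if not (0 <= on < off <= dur_ms):
                raise ValueError(f"event ({on}, {off}) outside trial [0, {dur_ms}) ms")
            if on < prev_off:
                raise ValueError("events overlap or are not strictly increasing")
            prev_off = off

    @property
    def duration_ms(self) -> int:
        return int(round(self.duration_s * 1000))

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class RunDesign:
    """Ordered trials separated by shared baselines.

    A baseline precedes and follows every trial, and the baseline between two
    consecutive trials is counted once, so
    ``total = sum(durations) + (n_trials + 1) * baseline``.
    """

    trials: tuple[TrialSpec, ...]
    baseline_s: float = DEFAULT_BASELINE_S

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a run needs at least one trial")
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be positive")

    @property
    def total_duration_s(self) -> float:
        return sum(t.duration_s for t in self.trials) + (len(self.trials) + 1) * self.baseline_s

    @property
    def trial_onsets_s(self) -> tuple[float, ...]:
        """Onset time of each trial, computed by accumulation."""
        onsets = []
        t = self.baseline_s
        for trial in self.trials:
            onsets.append(t)
            t += trial.duration_s + self.baseline_s
        return tuple(onsets)

    def stimulus_onsets_ms(self, category: str | None = None) -> np.ndarray:
        """Absolute onset times (ms) of every image event, optionally per category."""
        out = []
        for onset_s, trial in zip(self.trial_onsets_s, self.trials):
            if category is not None and trial.category != category:
                continue
            base = int(round(onset_s * 1000))
            out.extend(base + on for on, _ in trial.events)
        return np.asarray(out, dtype=np.int64)


@dataclass
class StepFunction:
    """Per-category binary stimulus vector over run time.

    ``values`` has shape ``(n_categories, n_samples)``; at most one category
    is on at any sample.
    """

    resolution_ms: int
    categories: tuple[str, ...]
    values: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.resolution_ms / 1000.0

    def channel(self, category: str) -> np.ndarray:
        return self.values[self.categories.index(category)]


def build_trial(
    experiment: int, duration_s: float, category: str, *, freeform: bool = False
) -> TrialSpec:
    """Construct the image event layout of a single trial.

    Experiment 1 shows one image for the whole trial.  Experiments 2 and 3
    tile the trial with 30 image+gap cycles of length ``duration_ms / 30``,
    floored to the millisecond grid; experiment 2 fixes the image at 33 ms
    and experiment 3 fixes the gap at 33 ms.

    Arbitrary durations are rejected unless ``freeform=True``, since only
    the 3/5/10/20-s trials are part of the standard designs.
    """
    if experiment not in (1, 2, 3):
        raise ValueError(f"unknown experiment id {experiment!r}; expected 1, 2 or 3")
    if not freeform and duration_s not in TRIAL_DURATIONS_S:
        raise ValueError(
            f"duration {duration_s!r} s is not one of the standard trial durations "
            f"{TRIAL_DURATIONS_S}; pass freeform=True to allow it"
        )
    dur_ms = int(round(duration_s * 1000))
    if dur_ms <= 0:
        raise ValueError("trial duration must be positive")

    if experiment == 1:
        events: tuple[tuple[int, int], ...] = ((0, dur_ms),)
    else:
        cycle_ms = dur_ms // IMAGES_PER_TRIAL
        if cycle_ms <= FLASH_MS:
            raise ValueError(
                f"trial of {duration_s} s too short for {IMAGES_PER_TRIAL} cycles "
                f"with a {FLASH_MS}-ms component"
            )
        image_ms = FLASH_MS if experiment == 2 else cycle_ms - FLASH_MS
        events = tuple(
            (i * cycle_ms, i * cycle_ms + image_ms) for i in range(IMAGES_PER_TRIAL)
        )
    return TrialSpec(experiment=experiment, duration_s=duration_s, category=category, events=events)


def trial_gap_ms(trial: TrialSpec) -> int:
    """Blank gap between consecutive images within a trial (0 for experiment 1)."""
    if trial.n_events < 2:
        return 0
    (on0, off0), (on1, _) = trial.events[0], trial.events[1]
    return on1 - off0


def build_run(trials: Sequence[TrialSpec], baseline_s: float = DEFAULT_BASELINE_S) -> RunDesign:
    """Assemble an ordered list of trials into a run with shared baselines."""
    return RunDesign(trials=tuple(trials), baseline_s=baseline_s)


def standard_run(
    experiment: int,
    categories: Sequence[str] = CATEGORIES,
    durations_s: Sequence[float] = TRIAL_DURATIONS_S,
    baseline_s: float = DEFAULT_BASELINE_S,
    seed: int | None = None,
) -> RunDesign:
    """One instance of every category x duration permutation (12 trials, 270 s).

    With ``seed`` given, trial order is shuffled reproducibly, mirroring the
    random presentation order used in the scanner; the default order is
    deterministic for testability.
    """
    trials = [
        build_trial(experiment, d, c) for c in categories for d in durations_s
    ]
    if seed is not None:
        rng = np.random.default_rng(seed)
        trials = [trials[i] for i in rng.permutation(len(trials))]
    return build_run(trials, baseline_s=baseline_s)


def render_step_function(run: RunDesign, resolution_ms: int = 1) -> StepFunction:
    """Render a run as a per-category binary step function.

    A sample is on when its start time falls inside an image interval; at
    1-ms resolution this reproduces the event intervals exactly.
    """
    if resolution_ms < 1 or 1000 % resolution_ms != 0:
        raise ValueError(f"resolution_ms={resolution_ms} must divide 1000")
    total_ms = int(round(run.total_duration_s * 1000))
    n = total_ms // resolution_ms
    values = np.zeros((len(CATEGORIES), n), dtype=np.float64)
    for onset_s, trial in zip(run.trial_onsets_s, run.trials):
        row = CATEGORIES.index(trial.category)
        base = int(round(onset_s * 1000))
        for on, off in trial.events:
            i0 = -((base + on) // -resolution_ms)  # ceil
            i1 = -((base + off) // -resolution_ms)
            if values[:, i0:i1].any():
                raise ValueError("overlapping trials in run design")
            values[row, i0:i1] = 1.0
    return StepFunction(resolution_ms=resolution_ms, categories=CATEGORIES, values=values)


def segments_from_step(step: StepFunction, category: str) -> list[tuple[int, int]]:
    """Recover half-open (onset_ms, offset_ms) intervals from a step function."""
    x = step.channel(category)
    edges = np.flatnonzero(np.diff(np.concatenate(([0.0], x, [0.0]))))
    res = step.resolution_ms
    return [
        (int(edges[i] * res), int(edges[i + 1] * res)) for i in range(0, len(edges), 2)
    ]


def rising_edges(step: StepFunction, category: str) -> np.ndarray:
    """Sample indices at which the given category switches off -> on."""
    x = step.channel(category)
    return np.flatnonzero(np.diff(np.concatenate(([0.0], x))) > 0)


# ---------------------------------------------------------------------------
# serialization

def run_to_json(run: RunDesign, path: str | Path | None = None) -> str:
    payload = {
        "baseline_s": run.baseline_s,
        "trials": [
            {
                "experiment": t.experiment,
                "duration_s": t.duration_s,
                "category": t.category,
                "events": [list(e) for e in t.events],
            }
            for t in run.trials
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def run_from_json(source: str | Path | dict) -> RunDesign:
    if isinstance(source, dict):
        payload = source
    else:
        path = Path(source)
        payload = json.loads(path.read_text() if path.is_file() else str(source))
    trials = tuple(
        TrialSpec(
            experiment=t["experiment"],
            duration_s=t["duration_s"],
            category=t["category"],
            events=tuple(tuple(e) for e in t["events"]),
        )
        for t in payload["trials"]
    )
    return RunDesign(trials=trials, baseline_s=payload["baseline_s"])


def step_to_tsv(step: StepFunction, path: str | Path) -> None:
    import pandas as pd

    t_ms = np.arange(step.n_samples) * step.resolution_ms
    frame = pd.DataFrame({"time_ms": t_ms})
    for i, cat in enumerate(step.categories):
        frame[cat] = step.values[i].astype(int)
    frame.to_csv(path, sep="\t", index=False)
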