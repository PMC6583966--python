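"""Millisecond-resolution neural response models for the two temporal channels.

The sustained channel is a monophasic impulse response function (IRF) —
a cascade of leaky integrators, i.e. a gamma density with shape ``n1`` and
time constant ``tau`` — optionally followed by an exponential-decay
adaptation nonlinearity or a compressive static power law (CTS).

The transient channel is a biphasic IRF, the difference of two gamma
densities (shapes ``n1`` and ``n2``, time constants ``tau`` and
``kappa * tau``), followed by a compressive sigmoid built from cumulative
Weibull functions applied separately to positive (stimulus-onset) and
negative (stimulus-offset) lobes of the convolved drive::

    sigma(x) = 1 - exp(-( x / lam) ** k_on ),  x >= 0
    sigma(x) = 1 - exp(-(-x / lam) ** k_off),  x <  0

Shape constants ``kappa = 1.33``, ``n1 = 9``, ``n2 = 10`` are fixed; the
time constant tau and the nonlinearity parameters are optimizable within
the bounds in :data:`PARAM_BOUNDS`.

Normalization conventions: the sustained kernel has unit area, so a long
stimulus drives it to a plateau of 1; the transient kernel's positive lobe
has unit area, which makes its response to an isolated onset of a long
stimulus peak at exactly 1, so the sigmoid scale ``lam`` is interpretable
as a fraction of peak drive.  The biphasic kernel is balanced to net area 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve
from scipy.stats import gamma as _gamma

#: optimization bounds for every tunable parameter (lower, upper)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_ms": (4.0, 20.0),
    "alpha_s": (10.0, 40.0),
    "epsilon": (0.01, 1.0),
    "lam": (0.01, 0.5),
    "k_on": (0.1, 6.0),
    "k_off": (0.1, 6.0),
}

#: initial values passed to the optimizer
PARAM_INITIAL: dict[str, float] = {
    "tau_ms": 4.93,
    "alpha_s": 20.0,
    "epsilon": 0.1,
    "lam": 0.1,
    "k_on": 3.0,
    "k_off": 3.0,
}

KAPPA = 1.33
N1 = 9
N2 = 10

#: modeling conventions recorded in serialized outputs, since alternative
#: choices exist in the literature
CONVENTIONS: dict[str, str] = {
    "sustained_irf_normalization": "unit area (long stimulus plateaus at 1)",
    "transient_irf_normalization": (
        "unit positive-lobe area, equivalently unit peak response to an "
        "isolated onset of a long stimulus"
    ),
    "adaptation_clock": "resets at each stimulus onset; runs through gaps and to run end",
    "contrast_effect_size": "beta(preferred) minus mean beta(nonpreferred) within channel",
}

_TRUNC_MASS = 1e-6  # kernels are truncated once the remaining tail mass is below this


@dataclass(frozen=True)
class IRFParams:
    """Timing constants of the channel IRFs; only ``tau_ms`` is optimized."""

    tau_ms: float = PARAM_INITIAL["tau_ms"]
    kappa: float = KAPPA
    n1: int = N1
    n2: int = N2

    def __post_init__(self) -> None:
        lo, hi = PARAM_BOUNDS["tau_ms"]
        if not (lo <= self.tau_ms <= hi):
            raise ValueError(f"tau_ms={self.tau_ms} outside bounds [{lo}, {hi}]")
        if self.kappa <= 1:
            raise ValueError("kappa must exceed 1")
        if not (self.n2 > self.n1 >= 1):
            raise ValueError("need n2 > n1 >= 1")


@dataclass(frozen=True)
class SustainedNonlinParams:
    """Adaptation decay constant and/or CTS exponent, as the variant requires."""

    alpha_s: float | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        for name, value in (("alpha_s", self.alpha_s), ("epsilon", self.epsilon)):
            if value is None:
                continue
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class TransientNonlinParams:
    """Sigmoid scale and onset/offset shape parameters."""

    lam: float = PARAM_INITIAL["lam"]
    k_on: float = PARAM_INITIAL["k_on"]
    k_off: float = PARAM_INITIAL["k_off"]

    def __post_init__(self) -> None:
        for name in ("lam", "k_on", "k_off"):
            value = getattr(self, name)
            lo, hi = PARAM_BOUNDS[name]
            if not (0 < value and lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class ModelParams:
    """Flat record of every tunable parameter; variants read the subset they use.

    Values are not bounds-checked here so that limit constructions (e.g.
    ``alpha_s=inf`` to reduce the adaptation model to the linear one) stay
    expressible; the optimizer enforces bounds on its free parameters.
    """

    tau_ms: float = PARAM_INITIAL["tau_ms"]
    alpha_s: float = PARAM_INITIAL["alpha_s"]
    epsilon: float = PARAM_INITIAL["epsilon"]
    lam: float = PARAM_INITIAL["lam"]
    k_on: float = PARAM_INITIAL["k_on"]
    k_off: float = PARAM_INITIAL["k_off"]

    def replace(self, **updates: float) -> "ModelParams":
        from dataclasses import replace as _replace

        return _replace(self, **updates)

    def as_dict(self) -> dict[str, float]:
        from dataclasses import asdict

        return asdict(self)

    @property
    def irf(self) -> IRFParams:
        return IRFParams(tau_ms=self.tau_ms)

    @property
    def transient(self) -> TransientNonlinParams:
        return TransientNonlinParams(lam=self.lam, k_on=self.k_on, k_off=self.k_off)


def irf_support_ms(params: IRFParams, resolution_ms: int = 1) -> int:
    """Grid length (ms) holding all but ``1e-6`` of the slower gamma's mass."""
    tail = _gamma.ppf(1.0 - _TRUNC_MASS, params.n2, scale=params.kappa * params.tau_ms)
    n = int(np.ceil(tail / resolution_ms)) + 1
    return n * resolution_ms


def make_irfs(
    params: IRFParams, resolution_ms: int = 1, support_ms: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled sustained (monophasic) and transient (biphasic) IRF kernels.

    Returns ``(h_sustained, h_transient)`` on a common grid.  ``h_sustained``
    is non-negative with unit sum; ``h_transient`` has a unit-area positive
    lobe and net area ~0.  ``support_ms`` may be given to fix the grid length
    (e.g. across an optimizer's tau sweep); otherwise the grid is sized so the
    truncated tail mass is below 1e-6.
    """
    n_before_peak = (params.n1 - 1) * params.tau_ms / resolution_ms
    if n_before_peak < 5:
        raise ValueError(
            f"resolution {resolution_ms} ms too coarse: only {n_before_peak:.1f} samples "
            f"before the sustained IRF peak at {(params.n1 - 1) * params.tau_ms:.1f} ms"
        )
    if support_ms is None:
        support_ms = irf_support_ms(params, resolution_ms)
    t = np.arange(support_ms // resolution_ms) * float(resolution_ms)
    g1 = _gamma.pdf(t, params.n1, scale=params.tau_ms)
    g1 /= g1.sum()
    g2 = _gamma.pdf(t, params.n2, scale=params.kappa * params.tau_ms)
    g2 /= g2.sum()
    h_t = g1 - g2
    h_t /= h_t[h_t > 0].sum()
    return g1, h_t


def convolve_channel(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal linear convolution of a stimulus vector with an IRF, truncated
    to the signal length (zero signal assumed before run start)."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        return signal.copy()
    out = oaconvolve(signal, kernel)[: signal.size]
    # outside the kernel support the true convolution is exactly zero; FFT
    # rounding noise there would otherwise be amplified by the compressive
    # (power < 1) nonlinearities downstream
    peak = np.abs(out).max()
    if peak > 0:
        out[np.abs(out) < 1e-13 * peak] = 0.0
    return out


def apply_adaptation(
    drive: np.ndarray,
    stimulus_onsets_ms: np.ndarray,
    alpha_s: float,
    resolution_ms: int = 1,
) -> np.ndarray:
    """Multiply a sustained drive by an exponential decay restarting at each onset.

    The multiplier is ``exp(-(t - t_on) / alpha)`` with ``t_on`` the most
    recent stimulus onset at or before ``t``; before the first onset it is 1.
    The decay clock keeps running through inter-stimulus gaps (and to run
    end), resetting only at the next onset.
    """
    if alpha_s <= 0:
        raise ValueError("alpha_s must be positive")
    onsets = np.asarray(stimulus_onsets_ms, dtype=np.float64)
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("stimulus onsets must be sorted")
    drive = np.asarray(drive, dtype=np.float64)
    t_ms = np.arange(drive.size) * float(resolution_ms)
    idx = np.searchsorted(onsets, t_ms, side="right") - 1
    mult = np.ones_like(drive)
    seen = idx >= 0
    alpha_ms = alpha_s * 1000.0
    mult[seen] = np.exp(-(t_ms[seen] - onsets[idx[seen]]) / alpha_ms)
    return drive * mult


def apply_cts(drive: np.ndarray, epsilon: float) -> np.ndarray:
    """Compressive static power law (drive ** epsilon) on the sustained channel."""
    lo, hi = PARAM_BOUNDS["epsilon"]
    if not (lo <= epsilon <= hi):
        raise ValueError(f"epsilon={epsilon} outside bounds [{lo}, {hi}]")
    drive = np.asarray(drive, dtype=np.float64)
    # tolerate convolution rounding noise but reject genuinely signed input
    tol = 1e-9 * max(1.0, float(np.abs(drive).max(initial=0.0)))
    if np.any(drive < -tol):
        raise ValueError("CTS applies to the non-negative sustained drive only")
    return np.power(np.maximum(drive, 0.0), epsilon)


def sigmoid_rectifier(x: np.ndarray | float, params: TransientNonlinParams) -> np.ndarray:
    """Asymmetric compressive sigmoid mapping both lobes of the transient
    drive to non-negative responses in [0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 - np.exp(-((x[pos] / params.lam) ** params.k_on))
    out[~pos] = 1.0 - np.exp(-((-x[~pos] / params.lam) ** params.k_off))
    return out


def quadratic_rectifier(x: np.ndarray | float) -> np.ndarray:
    """Pointwise squaring, the transient nonlinearity of the +Q model family."""
    x = np.asarray(x, dtype=np.float64)
    return np.square(x)
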