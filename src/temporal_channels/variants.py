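"""Model variant registry.

Each variant names which nonlinearity (if any) sits in each channel:

========  ==================  ====================
name      sustained channel   transient channel
========  ==================  ====================
GLM       stimulus boxcar     absent
L         linear IRF          absent
CTS       IRF + power law     absent
A         IRF + adaptation    absent
S         absent              IRF + sigmoid
L+Q       linear IRF          IRF + squaring
C+Q       IRF + power law     IRF + squaring
A+Q       IRF + adaptation    IRF + squaring
A+S       IRF + adaptation    IRF + sigmoid
========  ==================  ====================

The GLM benchmark has no neural IRF stage at all: its predictor is a single
convolution of the stimulus boxcar with the HRF.
"""

from __future__ import annotations

from dataclasses import dataclass

SUSTAINED_KINDS = ("absent", "boxcar", "linear", "cts", "adaptation")
TRANSIENT_KINDS = ("absent", "quadratic", "sigmoid")


@dataclass(frozen=True)
class ModelVariant:
    name: str
    sustained: str
    transient: str

    def __post_init__(self) -> None:
        if self.sustained not in SUSTAINED_KINDS:
            raise ValueError(f"unknown sustained kind {self.sustained!r}")
        if self.transient not in TRANSIENT_KINDS:
            raise ValueError(f"unknown transient kind {self.transient!r}")

    @property
    def channels(self) -> tuple[str, ...]:
        out = []
        if self.sustained != "absent":
            out.append("sustained")
        if self.transient != "absent":
            out.append("transient")
        return tuple(out)

    @property
    def has_irf(self) -> bool:
        return self.sustained not in ("absent", "boxcar") or self.transient != "absent"

    @property
    def free_params(self) -> tuple[str, ...]:
        """Optimizable parameter names, in canonical order."""
        names: list[str] = []
        if self.has_irf:
            names.append("tau_ms")
        if self.sustained == "adaptation":
            names.append("alpha_s")
        elif self.sustained == "cts":
            names.append("epsilon")
        if self.transient == "sigmoid":
            names.extend(["lam", "k_on", "k_off"])
        return tuple(names)


VARIANTS: dict[str, ModelVariant] = {
    "GLM": ModelVariant("GLM", "boxcar", "absent"),
    "L": ModelVariant("L", "linear", "absent"),
    "CTS": ModelVariant("CTS", "cts", "absent"),
    "A": ModelVariant("A", "adaptation", "absent"),
    "S": ModelVariant("S", "absent", "sigmoid"),
    "L+Q": ModelVariant("L+Q", "linear", "quadratic"),
    "C+Q": ModelVariant("C+Q", "cts", "quadratic"),
    "A+Q": ModelVariant("A+Q", "adaptation", "quadratic"),
    "A+S": ModelVariant("A+S", "adaptation", "sigmoid"),
}


def get_variant(name: str | ModelVariant) -> ModelVariant:
    if isinstance(name, ModelVariant):
        return name
    key = name.upper()
    if key not in VARIANTS:
        raise ValueError(f"unknown model variant {name!r}; expected one of {sorted(VARIANTS)}")
    return VARIANTS[key]
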