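"""Proton-motive force from the Goldman equation plus a fixed pH term.

The PMF is the electrochemical proton gradient across the inner
membrane: PMF = V_m + (2.303 RT/F) * delta_pH, with the membrane
potential V_m from the Goldman-Hodgkin-Katz equation over K+, Na+ and
Cl- at cytoplasmic/periplasmic concentrations. Default concentrations
and permeabilities are packaged calibration constants chosen to give an
initial PMF of -134 mV at 310 K; flagellar rotation moves 1200 protons
per revolution, and the gradient is treated as instantly restored by
proton pumps (the PMF is bookkept, not depleted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
PROTONS_PER_REVOLUTION = 1200
ROTATION_HZ = 100.0  # flagellar rotation rate


class PMFError(Exception):
    pass


@dataclass
class PMFState:
    """Ion concentrations (mM), relative permeabilities, and pH term."""

    cations_in: dict[str, float] = field(
        default_factory=lambda: {"K": 300.0, "Na": 10.0}
    )
    cations_out: dict[str, float] = field(
        default_factory=lambda: {"K": 5.0, "Na": 145.0}
    )
    anions_in: dict[str, float] = field(default_factory=lambda: {"Cl": 6.0})
    anions_out: dict[str, float] = field(default_factory=lambda: {"Cl": 110.0})
    permeabilities: dict[str, float] = field(
        default_factory=lambda: {"K": 1.0, "Na": 0.02, "Cl": 0.01}
    )
    temperature: float = 310.0  # K
    delta_pH: float = 0.6  # pH_in - pH_out (alkaline inside)

    def __post_init__(self):
        for pool in (self.cations_in, self.cations_out,
                     self.anions_in, self.anions_out):
            for ion, conc in pool.items():
                if conc <= 0:
                    raise PMFError(f"non-positive concentration for {ion!r}")


def goldman_pmf(state: PMFState) -> tuple[float, float]:
    """(membrane potential, PMF) in mV.

    V_m = (RT/F) ln[(sum P_cat C_out + sum P_an C_in) /
                    (sum P_cat C_in + sum P_an C_out)];
    the pH difference contributes -(2.303 RT/F) * delta_pH.
    """
    rt_f = R_GAS * state.temperature / FARADAY * 1000.0  # mV
    p = state.permeabilities
    numerator = sum(p[i] * c for i, c in state.cations_out.items()) + sum(
        p[i] * c for i, c in state.anions_in.items()
    )
    denominator = sum(p[i] * c for i, c in state.cations_in.items()) + sum(
        p[i] * c for i, c in state.anions_out.items()
    )
    if denominator <= 0 or numerator <= 0:
        raise PMFError("Goldman equation requires positive ion terms")
    v_m = rt_f * math.log(numerator / denominator)
    ph_term = -math.log(10.0) * rt_f * state.delta_pH
    return v_m, v_m + ph_term


def proton_accounting(revolutions: float, dt: float = 0.0) -> float:
    """Protons moved across the membrane for ``revolutions`` turns."""
    return PROTONS_PER_REVOLUTION * revolutions
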