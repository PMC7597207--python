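"""CheY-P transduction, flagellar switching, and motile force output.

Receptor-cluster activity sets the CheA autophosphorylation rate; with
first-order CheZ dephosphorylation the steady-state CheY-P level is a
Michaelis-type monotone map of activity, normalized so baseline
activity gives the baseline CheY-P concentration. CheY-P tilts the free
energy barrier of each flagellar motor's bistable CCW/CW switch:

    dG(Y) = g0/4 - (g1/2) * Y / (Y + Kd)        [kT]
    k(CCW->CW) = omega * exp(-dG),  k(CW->CCW) = omega * exp(+dG)

Motile state follows a veto rule: a single CW flagellum puts the cell
in a tumble; all-CCW is a run. Thrust is linear in the PMF and
logarithmic in the number of bundled flagella, L(n) = 1 + log10(n),
calibrated so one flagellum at 140 mV yields 0.31 pN and four yield
~0.5 pN. A run applies the thrust along the body axis at the rear; a
tumble applies it at a random angle, producing torque about the body
center.

The switch parameters (omega, Kd and the baseline CheY-P) are
calibration constants: at baseline they give k+ = 0.25/s and
k- = 1.765/s, which under the veto rule over four flagella yield mean
run durations near 1.0 s and mean tumble durations near 0.7 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

BASELINE_PMF_MV = 140.0
SINGLE_FLAGELLUM_THRUST_PN = 0.31

CCW = "CCW"
CW = "CW"


@dataclass
class CheYState:
    baseline_activity: float = 1.0 / 3.0
    baseline_cheY_P: float = 2.59  # uM, relative scale
    # Michaelis half-saturation of the activity -> CheY-P map; equal to
    # the baseline activity so that baseline maps to baseline
    activity_half: float = 1.0 / 3.0

    @property
    def cheY_P_max(self) -> float:
        a0 = self.baseline_activity
        return self.baseline_cheY_P * (a0 + self.activity_half) / a0


@dataclass
class SwitchParams:
    omega: float = 0.6643  # 1/s, barrier crossing attempt rate
    g0: float = 40.0  # kT
    g1: float = 40.0  # kT
    kd: float = 3.1504  # uM, FliM binding scale


@dataclass
class FlagellumState:
    rotation: str = CCW

    def __post_init__(self):
        if self.rotation not in (CCW, CW):
            raise ValueError(f"rotation must be CCW or CW, got {self.rotation!r}")


@dataclass
class MotileOutput:
    state: str  # run | tumble | nonmotile
    thrust: float  # pN
    torque: float  # pN um
    force_angle: float  # radians relative to the body axis


def cheY_P_level(activity: float, params: Optional[CheYState] = None) -> float:
    """Steady-state CheY-P from cluster activity (monotone increasing)."""
    if not 0.0 <= activity <= 1.0:
        raise ValueError("activity must be in [0, 1]")
    params = params or CheYState()
    return params.cheY_P_max * activity / (activity + params.activity_half)


def switch_rates(
    cheY_P: float, params: Optional[SwitchParams] = None
) -> tuple[float, float]:
    """(k_CCW->CW, k_CW->CCW) in 1/s at CheY-P concentration ``cheY_P``."""
    params = params or SwitchParams()
    dg = params.g0 / 4.0 - params.g1 / 2.0 * cheY_P / (cheY_P + params.kd)
    return params.omega * math.exp(-dg), params.omega * math.exp(dg)


def flagellum_switch_step(
    flagellum: FlagellumState,
    cheY_P: float,
    dt: float,
    rng,
    params: Optional[SwitchParams] = None,
) -> FlagellumState:
    """One Markov step of the bistable CCW/CW switch (dt <= 0.01 s)."""
    if dt > 0.01 + 1e-12:
        raise ValueError("flagellar switching requires dt <= 0.01 s")
    k_plus, k_minus = switch_rates(cheY_P, params)
    if flagellum.rotation == CCW:
        if rng.random() < k_plus * dt:
            flagellum.rotation = CW
    else:
        if rng.random() < k_minus * dt:
            flagellum.rotation = CCW
    return flagellum


def bundling_factor(n_flagella: int) -> float:
    """L(n) = 1 + log10(n): marginal thrust falls as the bundle grows."""
    if n_flagella < 1:
        return 0.0
    return 1.0 + math.log10(n_flagella)


def motile_output(
    flagella: list[FlagellumState],
    pmf: float,
    rng,
    lever_arm: float = 1.0,  # um, half body length
    tumble_angle: Optional[float] = None,
) -> MotileOutput:
    """Aggregate flagellar states into a motile force (veto rule).

    ``pmf`` may be signed (the physiological PMF is negative); thrust
    scales with its magnitude. During a tumble the thrust of the still-
    coherent CCW flagella is applied at ``tumble_angle`` (drawn
    uniformly if not supplied), generating reorienting torque.
    """
    if not flagella:
        return MotileOutput(state="nonmotile", thrust=0.0, torque=0.0,
                            force_angle=0.0)
    if not math.isfinite(pmf):
        raise ValueError("PMF must be finite")
    n_ccw = sum(1 for f in flagella if f.rotation == CCW)
    scale = abs(pmf) / BASELINE_PMF_MV
    if n_ccw == len(flagella):
        thrust = SINGLE_FLAGELLUM_THRUST_PN * scale * bundling_factor(n_ccw)
        return MotileOutput(state="run", thrust=thrust, torque=0.0,
                            force_angle=0.0)
    angle = (
        tumble_angle
        if tumble_angle is not None
        else rng.uniform(-math.pi, math.pi)
    )
    thrust = SINGLE_FLAGELLUM_THRUST_PN * scale * bundling_factor(max(n_ccw, 1))
    torque = thrust * lever_arm * math.sin(angle)
    return MotileOutput(state="tumble", thrust=thrust, torque=torque,
                        force_angle=angle)
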