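"""Engine processes for the sensory-motor chain.

The chemoreceptor and flagellar processes run at 0.01 s — the cell-
environment coupling timescale chemotaxis requires — while the PMF
process, whose ion gradients are quasi-static, runs at 1.0 s.
"""

from __future__ import annotations

import math

from colisim.engine import Process, VariableSchema
from colisim.chemotaxis.motor import (
    CCW,
    CW,
    CheYState,
    FlagellumState,
    SwitchParams,
    cheY_P_level,
    flagellum_switch_step,
    motile_output,
)
from colisim.chemotaxis.pmf import (
    PMFState,
    PROTONS_PER_REVOLUTION,
    ROTATION_HZ,
    goldman_pmf,
)
from colisim.chemotaxis.receptor import ReceptorCluster, receptor_update


def _set_schema(default, units, emit=False, divider="copy"):
    return VariableSchema(
        default=default, units=units, updater="set", divider=divider, emit=emit
    )


class ProtonMotiveForce(Process):
    """Goldman membrane potential + pH term; instant proton restoration."""

    defaults = {"time_step": 1.0, "state": None}

    def __init__(self, parameters=None):
        super().__init__(parameters)
        overrides = self.parameters["state"] or {}
        self.state = PMFState(**overrides) if isinstance(overrides, dict) else overrides

    def ports_schema(self):
        v_m, pmf = goldman_pmf(self.state)
        return {
            "membrane": {
                "membrane_potential": _set_schema(v_m, "mV"),
                "PMF": _set_schema(pmf, "mV", emit=True),
            }
        }

    def next_update(self, states, timestep):
        v_m, pmf = goldman_pmf(self.state)
        return {"membrane": {"membrane_potential": v_m, "PMF": pmf}}


class Chemoreceptor(Process):
    """MWC Tar/Tsr cluster activity with methylation adaptation."""

    defaults = {
        "time_step": 0.01,
        "ligand": "MeAsp",
        "cluster": None,  # ReceptorCluster overrides
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        overrides = self.parameters["cluster"] or {}
        self.cluster = (
            ReceptorCluster(**overrides) if isinstance(overrides, dict) else overrides
        )

    def ports_schema(self):
        return {
            "internal": {
                "chemoreceptor_activity": _set_schema(
                    self.cluster.baseline_activity, "dimensionless", emit=True
                ),
                "methylation": _set_schema(
                    self.cluster.methylation, "dimensionless", emit=True
                ),
            },
            "boundary": {
                "external": {
                    "*": VariableSchema(
                        default=0.0, units="mM", updater="set", divider="copy"
                    )
                }
            },
        }

    def next_update(self, states, timestep):
        ligand = states["boundary"]["external"].get(self.parameters["ligand"], 0.0)
        self.cluster.methylation = states["internal"]["methylation"]
        activity, methylation = receptor_update(
            self.cluster, max(ligand, 0.0), timestep
        )
        return {
            "internal": {
                "chemoreceptor_activity": activity,
                "methylation": methylation,
            }
        }


class FlagellarActivity(Process):
    """CheY-P transduction, per-flagellum switching, thrust/torque output.

    Flagella are sub-compartments of the cell; their CCW/CW rotation
    states are stepped here and aggregated by the veto rule into the
    cell's motile state. The tumble force angle is drawn once per tumble
    episode and held until the next run. With defunct receptors
    (``receptors_active`` False) CheY-P stays at baseline, producing
    baseline run/tumble motility.
    """

    defaults = {
        "time_step": 0.01,
        "lever_arm": 1.0,  # um
        "cheY": None,
        "switch": None,
        "receptors_active": True,
    }

    def __init__(self, parameters=None):
        super().__init__(parameters)
        cheY = self.parameters["cheY"] or {}
        switch = self.parameters["switch"] or {}
        self.cheY = CheYState(**cheY) if isinstance(cheY, dict) else cheY
        self.switch = SwitchParams(**switch) if isinstance(switch, dict) else switch
        self._tumble_angle = None

    def ports_schema(self):
        return {
            "internal": {
                "chemoreceptor_activity": _set_schema(
                    self.cheY.baseline_activity, "dimensionless"
                ),
                "CheY_P": _set_schema(self.cheY.baseline_cheY_P, "uM", emit=True),
                "protons_pumped": VariableSchema(
                    default=0.0, units="counts", updater="accumulate",
                    divider="halve",
                ),
            },
            "flagella": {
                "_divider": "split_list",
                "*": {
                    "rotation": _set_schema(CCW, "dimensionless"),
                },
            },
            "membrane": {
                "PMF": _set_schema(-134.0, "mV"),
            },
            "boundary": {
                "thrust": _set_schema(0.0, "pN"),
                "torque": _set_schema(0.0, "pN um"),
                "force_angle": _set_schema(0.0, "radians"),
                "motile_state": _set_schema("nonmotile", "dimensionless", emit=True),
            },
        }

    def next_update(self, states, timestep):
        if self.parameters["receptors_active"]:
            activity = states["internal"]["chemoreceptor_activity"]
        else:
            activity = self.cheY.baseline_activity
        cheY_P = cheY_P_level(min(max(activity, 0.0), 1.0), self.cheY)

        names = sorted(states["flagella"])
        flagella = [
            FlagellumState(rotation=states["flagella"][name]["rotation"])
            for name in names
        ]
        for flagellum in flagella:
            flagellum_switch_step(flagellum, cheY_P, timestep, self.rng, self.switch)

        n_cw = sum(1 for f in flagella if f.rotation == CW)
        if n_cw > 0 and self._tumble_angle is None:
            self._tumble_angle = self.rng.uniform(-math.pi, math.pi)
        elif n_cw == 0:
            self._tumble_angle = None
        output = motile_output(
            flagella,
            states["membrane"]["PMF"],
            self.rng,
            lever_arm=self.parameters["lever_arm"],
            tumble_angle=self._tumble_angle,
        )
        revolutions = ROTATION_HZ * len(flagella) * timestep
        return {
            "internal": {
                "CheY_P": cheY_P,
                "protons_pumped": PROTONS_PER_REVOLUTION * revolutions,
            },
            "flagella": {
                name: {"rotation": flagellum.rotation}
                for name, flagellum in zip(names, flagella)
            },
            "boundary": {
                "thrust": output.thrust,
                "torque": output.torque,
                "force_angle": output.force_angle,
                "motile_state": output.state,
            },
        }
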