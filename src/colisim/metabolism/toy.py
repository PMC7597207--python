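"""Packaged toy glucose/lactose network and calibrated kinetic defaults.

The network is a mass-consistent miniature of central carbon
metabolism: glucose (180 fg/count) splits into two 90 fg precursor
units; lactose (342 fg/count) is cleaved into glucose plus galactose
(162 fg/count), and galactose feeds the precursor pool at 1.8 units.
Biomass is the precursor itself, so one unit of biomass flux deposits
90 fg into the internal pools and every internal reaction conserves
mass exactly.

Kinetic defaults are calibrated so a 1000 fg cell in ~1 mM glucose
grows with a doubling time near 40 min, lactose growth (once LacY is
expressed) is comparable, and the depleted-glucose lag phase shows low
growth.
"""

from __future__ import annotations

from colisim.metabolism.kinetics import KineticReaction
from colisim.metabolism.network import MetabolicNetwork

# fg per count == g/mol at the 1e-12 mmol/count lumping
TOY_WEIGHTS = {
    "glc": 180.0,
    "lac": 342.0,
    "gal": 162.0,
    "pre": 90.0,
}


def toy_network() -> MetabolicNetwork:
    """Glucose/lactose toy network with a precursor biomass objective."""
    return MetabolicNetwork(
        reactions={
            "EX_glc": {"glc": 1.0},
            "EX_lac": {"lac": 1.0},
            "GLYC": {"glc": -1.0, "pre": 2.0},
            "LACZ": {"lac": -1.0, "glc": 1.0, "gal": 1.0},
            "GALK": {"gal": -1.0, "pre": 1.8},
        },
        bounds={
            "EX_glc": (0.0, 1000.0),
            "EX_lac": (0.0, 1000.0),
            "GLYC": (0.0, 1000.0),
            "LACZ": (0.0, 1000.0),
            "GALK": (0.0, 1000.0),
        },
        objective={"pre": 1.0},
        exchange_reactions={"EX_glc": "glc", "EX_lac": "lac"},
        molecular_weights=dict(TOY_WEIGHTS),
    )


def toy_transport_reactions() -> list[KineticReaction]:
    """Transport kinetics for the two sugars (counts/s per the network)."""
    return [
        KineticReaction(
            id="EX_glc",
            substrates={"glc": 0.1},  # Km, mM
            enzyme="GalP",
            kcat=6.0e-5,  # per transporter per second, lumped counts
        ),
        KineticReaction(
            id="EX_lac",
            substrates={"lac": 1.0},
            enzyme="LacY",
            kcat=2.0e-5,
        ),
    ]


TOY_INITIAL_POOLS = {"pre": 1000.0 / 90.0}  # 1000 fg of precursor

TOY_PROTEINS = {"GalP": 100.0, "LacY": 0.0}
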