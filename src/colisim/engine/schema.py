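"""Variable schemas: units, updaters, dividers, emission flags.

Every leaf variable in a store tree carries exactly one schema that
declares how process updates are applied to it (its *updater*), how it is
partitioned between daughter cells (its *divider*), whether it is recorded
by the emitter, and bookkeeping properties such as molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

UPDATERS = ("accumulate", "set", "nonnegative_accumulate")
DIVIDERS = ("halve", "binomial", "copy", "split_list")


class SchemaError(Exception):
    """Raised on inconsistent or undefined schema declarations."""


@dataclass
class VariableSchema:
    """Declaration of a single store variable.

    Parameters
    ----------
    default:
        Initial value used when the hierarchy is built and no explicit
        initial state is supplied.
    units:
        Unit tag (``fg``, ``mM``, ``mV``, ``pN``, ``s``, ``counts``,
        ``um``, ``radians``, ``dimensionless`` ...). Updates from a
        process declaring different units for the same variable are
        rejected at wiring time.
    updater:
        How an update entry is applied: ``accumulate`` adds the delta,
        ``set`` replaces the value, ``nonnegative_accumulate`` adds and
        clamps at zero.
    divider:
        How the variable is split between daughters at division:
        ``halve``, ``binomial`` (fair coin per count, exact
        conservation), ``copy``, or ``split_list`` (alternate assignment
        of list elements / sub-compartments).
    emit:
        Whether the emitter records this variable.
    properties:
        Free-form metadata, e.g. ``{"molecular_weight": 1.2e-7}`` in fg
        per count for mass accounting.
    """

    default: Any = 0.0
    units: str = "dimensionless"
    updater: str = "accumulate"
    divider: str = "halve"
    emit: bool = False
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.updater not in UPDATERS:
            raise SchemaError(f"unknown updater {self.updater!r}")
        if self.divider not in DIVIDERS:
            raise SchemaError(f"unknown divider {self.divider!r}")

    def compatible(self, other: "VariableSchema") -> bool:
        return (
            self.units == other.units
            and self.updater == other.updater
            and self.divider == other.divider
        )


def apply_update(value: Any, delta: Any, schema: VariableSchema) -> Any:
    """Apply one update entry to a variable according to its updater."""
    if schema.updater == "accumulate":
        return value + delta
    if schema.updater == "set":
        return delta
    if schema.updater == "nonnegative_accumulate":
        new = value + delta
        return max(0, new) if not hasattr(new, "__len__") else new.clip(0)
    raise SchemaError(f"unknown updater {schema.updater!r}")


def divide_value(value: Any, schema: VariableSchema, rng) -> tuple[Any, Any]:
    """Split one variable between two daughters according to its divider."""
    divider = schema.divider
    if divider == "halve":
        return value / 2, value / 2
    if divider == "binomial":
        n = int(value)
        left = int(rng.binomial(n, 0.5))
        return left, n - left
    if divider == "copy":
        return value, value
    if divider == "split_list":
        seq = list(value)
        return seq[0::2], seq[1::2]
    raise SchemaError(f"divider undefined: {divider!r}")
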