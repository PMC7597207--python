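"""The experiment: wiring, multi-timescale scheduling, update application.

An :class:`Experiment` assembles processes, a topology, and a store
hierarchy, then advances a temporal front. Each process is invoked every
``time_step`` of its own; at each front advance the due processes run in
sorted-name order and their updates are applied in the same order, so a
given configuration and seed replays bit-identically.
"""

from __future__ import annotations

import math
import zlib
from fractions import Fraction
from typing import Any, Callable, Optional

import numpy as np

from colisim.engine.process import Process
from colisim.engine.schema import SchemaError, VariableSchema, apply_update
from colisim.engine.store import (
    HierarchyError,
    Path,
    Store,
    apply_topology_update,
    build_store,
)


class ConfigurationError(Exception):
    """Invalid experiment configuration (e.g. non-commensurate dts)."""


class UpdateLocalityError(Exception):
    """A process attempted to update a variable outside its ports."""


def _named_stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-name child RNG, independent of process count."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _fraction(dt: float) -> Fraction:
    return Fraction(dt).limit_denominator(10**6)


class Experiment:
    """A runnable compartment hierarchy.

    Parameters
    ----------
    processes:
        Map of unique process name -> :class:`Process` instance.
    topology:
        Map of process name -> {port name -> absolute path tuple into the
        hierarchy}. The graph is bipartite: processes only connect to
        stores.
    initial_state:
        Nested dict of initial values, overriding schema defaults.
    emit_interval:
        Simulated seconds between emissions (default 1.0 s).
    seed:
        Global seed; every stochastic process draws from a child stream
        keyed by its name.
    """

    def __init__(
        self,
        processes: dict[str, Process],
        topology: dict[str, dict[str, Path]],
        initial_state: Optional[dict] = None,
        emit_interval: float = 1.0,
        seed: int = 0,
    ):
        self.seed = int(seed)
        self.store = build_store()
        self.processes: dict[str, Process] = {}
        self.topology: dict[str, dict[str, Path]] = {}
        self._port_schemas: dict[str, dict[str, Any]] = {}
        self._next_time: dict[str, Fraction] = {}
        self.emit_interval = _fraction(emit_interval)
        self.emitted: list[dict] = []
        self.time = Fraction(0)
        self._divide_rng = _named_stream(self.seed, "__divide__")
        self._composers: dict[Path, Callable] = {}
        self._agent_processes: dict[Path, list[str]] = {}

        if initial_state:
            from colisim.engine.store import _seed

            _seed(self.store, initial_state)
        for name in sorted(processes):
            self.add_process(name, processes[name], topology[name])
        self._validate_time_steps()

    # -- wiring ------------------------------------------------------------

    def add_process(self, name: str, process: Process, wiring: dict[str, Path]):
        if name in self.processes:
            raise ConfigurationError(f"duplicate process name {name!r}")
        process.name = name
        process.rng = _named_stream(self.seed, name)
        schemas = process.ports_schema()
        for port, schema in schemas.items():
            if port not in wiring:
                raise ConfigurationError(
                    f"process {name!r} port {port!r} missing from topology"
                )
            self._declare(self.store.ensure(tuple(wiring[port])), schema)
        self.processes[name] = process
        self.topology[name] = {p: tuple(path) for p, path in wiring.items()}
        self._port_schemas[name] = schemas
        self._next_time[name] = self.time + _fraction(process.time_step)

    def _declare(self, node: Store, schema: Any) -> None:
        if isinstance(schema, VariableSchema):
            if node.schema is None and not node.children:
                node.schema = schema
                if node.value is None:
                    node.value = schema.default
            elif node.schema is not None and node.provisional:
                node.schema = schema
                node.provisional = False
            elif node.schema is not None and not node.schema.compatible(schema):
                raise SchemaError(
                    f"conflicting schema for store {node.name!r}"
                )
            elif node.schema is not None and schema.emit:
                # any process asking for emission gets it
                node.schema.emit = True
            return
        # nested dict; '*' templates apply to children created later
        for key, sub in schema.items():
            if key == "*":
                for child in node.children.values():
                    self._declare(child, sub)
                continue
            if key == "_divider":
                node.divider = sub
                continue
            self._declare(node.ensure((key,)), sub)

    def register_composer(
        self, agent_path: Path, composer: Callable, process_names: list[str]
    ) -> None:
        """Enable division for the agent compartment at ``agent_path``.

        ``composer(agent_id, agent_path, seed)`` must return
        ``(processes, topology)`` for a daughter agent; ``process_names``
        lists the parent agent's own processes, removed at division.
        """
        self._composers[tuple(agent_path)] = composer
        self._agent_processes[tuple(agent_path)] = list(process_names)

    def _validate_time_steps(self) -> None:
        fracs = [_fraction(p.time_step) for p in self.processes.values()]
        if not fracs:
            return
        base = fracs[0]
        for f in fracs[1:]:
            base = Fraction(math.gcd(base.numerator * f.denominator,
                                     f.numerator * base.denominator),
                            base.denominator * f.denominator)
        cycle = fracs[0]
        for f in fracs[1:]:
            cycle = cycle * f / Fraction(
                math.gcd(cycle.numerator * f.denominator,
                         f.numerator * cycle.denominator),
                cycle.denominator * f.denominator,
            )
        if base <= 0 or cycle / base > 10**7:
            raise ConfigurationError(
                "process time-steps are not commensurate: "
                f"{sorted(float(f) for f in set(fracs))}"
            )

    # -- views and updates -------------------------------------------------

    def _view(self, name: str) -> dict:
        return {
            port: self.store.get(path).view()
            for port, path in self.topology[name].items()
        }

    def _apply(self, name: str, update: dict) -> list[dict]:
        """Apply one process update; returns any topology messages."""
        messages = []
        for port, sub in update.items():
            if port == "_topology":
                messages.append(sub)
                continue
            if port not in self.topology[name]:
                raise UpdateLocalityError(
                    f"process {name!r} updated undeclared port {port!r}"
                )
            node = self.store.get(self.topology[name][port])
            schema = self._port_schemas[name].get(port, {})
            self._apply_node(name, node, sub, schema)
        return messages

    def _apply_node(self, pname: str, node: Store, update: Any, schema: Any):
        if node.is_leaf:
            if not isinstance(schema, VariableSchema):
                raise UpdateLocalityError(
                    f"process {pname!r} updated variable "
                    f"{node.name!r} outside its declared ports"
                )
            node.value = apply_update(node.value, update, node.schema)
            return
        if not isinstance(update, dict):
            raise UpdateLocalityError(
                f"process {pname!r} sent a scalar update to store {node.name!r}"
            )
        template = schema.get("*") if isinstance(schema, dict) else None
        for key, sub in update.items():
            declared = schema.get(key) if isinstance(schema, dict) else None
            if declared is None:
                declared = template
            if declared is None:
                raise UpdateLocalityError(
                    f"process {pname!r} updated {key!r} outside its ports"
                )
            if key not in node.children:
                # auto-create from a wildcard template (e.g. a new
                # transcript species or a newly added agent variable)
                child = node.ensure((key,))
                self._declare(child, declared)
            self._apply_node(pname, node.children[key], sub, declared)

    # -- topology ----------------------------------------------------------

    def _handle_topology(self, message: dict) -> None:
        result = apply_topology_update(self.store, message, self._divide_rng)
        if message["type"] == "divide":
            path = tuple(message["path"])
            composer = self._composers.pop(path, None)
            for pname in self._agent_processes.pop(path, []):
                self.processes.pop(pname, None)
                self.topology.pop(pname, None)
                self._port_schemas.pop(pname, None)
                self._next_time.pop(pname, None)
            if composer is not None:
                parent = result["parent"]
                for did in result["daughters"]:
                    dpath = parent + (did,)
                    procs, topo = composer(did, dpath, self.seed)
                    for pn in sorted(procs):
                        self.add_process(pn, procs[pn], topo[pn])
                    self.register_composer(dpath, composer, sorted(procs))
        elif message["type"] == "delete":
            path = tuple(message["path"])
            self._composers.pop(path, None)
            for pname in self._agent_processes.pop(path, []):
                self.processes.pop(pname, None)
                self.topology.pop(pname, None)
                self._port_schemas.pop(pname, None)
                self._next_time.pop(pname, None)

    # -- emission ----------------------------------------------------------

    def _emit(self) -> None:
        record: dict[str, Any] = {"time": float(self.time)}
        for path, leaf in self.store.leaves():
            if leaf.schema is not None and leaf.schema.emit:
                value = leaf.value
                if isinstance(value, np.ndarray):
                    value = value.copy()
                record["/".join(path)] = value
        self.emitted.append(record)

    # -- main loop ---------------------------------------------------------

    def run(self, total_time: float) -> list[dict]:
        """Advance the temporal front by ``total_time`` seconds."""
        end = self.time + _fraction(total_time)
        if not self.emitted:
            self._emit()
        next_emit = self.time + self.emit_interval
        while self.time < end and self._next_time:
            front = min(self._next_time.values())
            if front > end:
                break
            due = sorted(
                name for name, t in self._next_time.items() if t == front
            )
            updates = []
            for name in due:
                process = self.processes[name]
                dt = float(_fraction(process.time_step))
                updates.append((name, process.next_update(self._view(name), dt)))
            self.time = front
            messages = []
            for name, update in updates:
                messages.extend(
                    (name, m) for m in self._apply(name, update)
                )
            for name in due:
                if name in self._next_time:  # may have divided away
                    self._next_time[name] = front + _fraction(
                        self.processes[name].time_step
                    )
            for _, message in messages:
                self._handle_topology(message)
            if next_emit <= self.time:
                self._emit()
                while next_emit <= self.time:
                    next_emit += self.emit_interval
        return self.emitted


def run_experiment(
    processes: dict[str, Process],
    topology: dict[str, dict[str, Path]],
    initial_state: Optional[dict] = None,
    total_time: float = 10.0,
    emit_interval: float = 1.0,
    seed: int = 0,
) -> list[dict]:
    """Build an :class:`Experiment`, run it, and return the emitted series."""
    experiment = Experiment(
        processes, topology, initial_state, emit_interval=emit_interval, seed=seed
    )
    experiment.run(total_time)
    return experiment.emitted
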