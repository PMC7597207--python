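"""Engine: updaters, dividers, scheduling, locality, topology updates."""

import numpy as np
import pytest

from colisim.engine import (
    ConfigurationError,
    Experiment,
    Process,
    SchemaError,
    UpdateLocalityError,
    VariableSchema,
    apply_topology_update,
    apply_update,
    build_store,
    divide_state,
    run_experiment,
)


def leaf(default=0.0, updater="accumulate", divider="halve", **kw):
    return VariableSchema(default=default, updater=updater, divider=divider, **kw)


class Accumulator(Process):
    """Adds a fixed delta to one variable every time-step."""

    defaults = {"delta": 1.0, "time_step": 1.0, "variable": "x"}

    def ports_schema(self):
        return {"state": {self.parameters["variable"]: leaf(0.0)}}

    def next_update(self, states, timestep):
        return {"state": {self.parameters["variable"]: self.parameters["delta"]}}


class CallCounter(Process):
    defaults = {"time_step": 1.0}

    def ports_schema(self):
        return {"state": {"calls": leaf(0.0)}}

    def next_update(self, states, timestep):
        return {"state": {"calls": 1}}


class Noop(Process):
    def ports_schema(self):
        return {"state": {"x": leaf(5.0)}}

    def next_update(self, states, timestep):
        return {}


class Trespasser(Process):
    """Tries to write a variable it never declared."""

    def ports_schema(self):
        return {"state": {"x": leaf(0.0)}}

    def next_update(self, states, timestep):
        return {"state": {"y": 1.0}}


@pytest.mark.parametrize(
    "value, delta, updater, expected",
    [
        (10, 5, "accumulate", 15),
        (10, 7, "set", 7),
        (3, -5, "nonnegative_accumulate", 0),
        (3, -2, "nonnegative_accumulate", 1),
    ],
)
def test_apply_update_semantics(value, delta, updater, expected):
    schema = VariableSchema(updater=updater)
    assert apply_update(value, delta, schema) == expected


def test_unknown_updater_rejected():
    with pytest.raises(SchemaError):
        VariableSchema(updater="multiply")


def test_multi_timescale_invocation_counts():
    """A 0.01 s process runs 100x per second; a 1.0 s process once."""
    procs = {
        "fast": CallCounter({"time_step": 0.01}),
        "slow": CallCounter({"time_step": 1.0}),
    }
    topo = {
        "fast": {"state": ("fast_counts",)},
        "slow": {"state": ("slow_counts",)},
    }
    exp = Experiment(procs, topo)
    exp.run(2.0)
    assert exp.store.get(("fast_counts", "calls")).value == 200
    assert exp.store.get(("slow_counts", "calls")).value == 2


def test_noop_process_leaves_state_unchanged():
    records = run_experiment(
        {"idle": Noop()}, {"idle": {"state": ("s",)}}, total_time=7.0
    )
    # no emitted variables declared; final state equals default
    exp = Experiment({"idle": Noop()}, {"idle": {"state": ("s",)}})
    exp.run(7.0)
    assert exp.store.get(("s", "x")).value == 5.0
    assert records[0]["time"] == 0.0


def test_accumulate_counting():
    exp = Experiment(
        {"acc": Accumulator({"delta": 1.0})}, {"acc": {"state": ("s",)}}
    )
    exp.run(10.0)
    assert exp.store.get(("s", "x")).value == 10.0


def test_noncommensurate_time_steps_fail_fast():
    procs = {
        "a": CallCounter({"time_step": 1.0}),
        "b": CallCounter({"time_step": np.pi / 3}),
    }
    topo = {"a": {"state": ("sa",)}, "b": {"state": ("sb",)}}
    with pytest.raises(ConfigurationError):
        Experiment(procs, topo)


def test_update_locality_enforced():
    exp = Experiment(
        {"bad": Trespasser()}, {"bad": {"state": ("s",)}}
    )
    with pytest.raises(UpdateLocalityError):
        exp.run(1.0)


def test_scheduler_determinism_bit_identical():
    def build():
        procs = {
            "a": Accumulator({"delta": 0.5, "variable": "x"}),
            "b": Accumulator({"delta": 0.25, "variable": "x", "time_step": 0.5}),
        }
        topo = {"a": {"state": ("s",)}, "b": {"state": ("s",)}}
        exp = Experiment(procs, topo, seed=42)
        exp.store.get(("s", "x")).schema.emit = True
        exp.run(5.0)
        return exp.emitted

    assert build() == build()


def test_halved_timestep_same_accumulate_total():
    """dt and dt/2 with halved deltas agree for deterministic accumulation."""

    def total(dt, delta):
        exp = Experiment(
            {"a": Accumulator({"delta": delta, "time_step": dt})},
            {"a": {"state": ("s",)}},
        )
        exp.run(8.0)
        return exp.store.get(("s", "x")).value

    assert total(1.0, 1.0) == pytest.approx(total(0.5, 0.5))


# -- division --------------------------------------------------------------


def make_agent():
    root = build_store()
    agent = root.ensure(("agents", "a1"))
    agent.declare(("boundary", "mass"), leaf(0.0, divider="halve"), initial=2000.0)
    agent.declare(
        ("proteins", "lacy"),
        leaf(0, updater="accumulate", divider="binomial"),
        initial=10,
    )
    agent.declare(("config", "tau"), leaf(0.0, divider="copy"), initial=2400.0)
    flagella = agent.ensure(("flagella",))
    flagella.divider = "split_list"
    for i in range(5):
        flagella.ensure((f"f{i}",)).declare(
            ("rotation",), leaf("CCW", updater="set", divider="copy")
        )
    return root, agent


def test_divide_state_dividers():
    rng = np.random.default_rng(7)
    _, agent = make_agent()
    left, right = divide_state(agent, rng)
    assert left.get(("boundary", "mass")).value == 1000.0
    assert right.get(("boundary", "mass")).value == 1000.0
    total = (
        left.get(("proteins", "lacy")).value + right.get(("proteins", "lacy")).value
    )
    assert total == 10
    assert left.get(("config", "tau")).value == 2400.0
    assert right.get(("config", "tau")).value == 2400.0
    # 5 flagellum sub-compartments split 3 / 2
    assert len(left.get(("flagella",)).children) == 3
    assert len(right.get(("flagella",)).children) == 2


def test_binomial_divider_conserves_any_count():
    rng = np.random.default_rng(0)
    schema = leaf(0, divider="binomial")
    for n in [0, 1, 2, 17, 1000]:
        root = build_store()
        root.declare(("c",), schema, initial=n)
        l, r = divide_state(root.get(("c",)), rng)
        assert l.value + r.value == n
        assert l.value >= 0 and r.value >= 0


def test_topology_divide_scopes_to_agent():
    root, _ = make_agent()
    root.declare(("fields", "glc"), leaf(1.0), initial=3.5)
    result = apply_topology_update(
        root, {"type": "divide", "path": ("agents", "a1")}, np.random.default_rng(1)
    )
    agents = root.get(("agents",)).children
    assert set(agents) == {"a1.0", "a1.1"}
    assert result["daughters"] == ["a1.0", "a1.1"]
    assert root.get(("fields", "glc")).value == 3.5


def test_topology_add_and_delete_subcompartment():
    root, agent = make_agent()
    apply_topology_update(
        root,
        {
            "type": "add_subcompartment",
            "path": ("agents", "a1", "flagella", "f5"),
            "state": {"rotation": (leaf("CCW", updater="set", divider="copy"), "CCW")},
        },
    )
    assert len(agent.get(("flagella",)).children) == 6
    apply_topology_update(root, {"type": "delete", "path": ("agents", "a1")})
    assert root.get(("agents",)).children == {}


def test_division_rewires_daughter_processes():
    """After an engine-level divide, daughters keep accumulating mass."""

    class Divider(Process):
        defaults = {"time_step": 1.0, "agent_path": ("agents", "a1")}

        def ports_schema(self):
            return {"boundary": {"mass": leaf(0.0, divider="halve")}}

        def next_update(self, states, timestep):
            if states["boundary"]["mass"] >= 2000.0:
                return {
                    "_topology": {
                        "type": "divide",
                        "path": tuple(self.parameters["agent_path"]),
                    }
                }
            return {"boundary": {"mass": 100.0}}

    def composer(agent_id, agent_path, seed):
        name = f"{agent_id}/divider"
        proc = Divider({"agent_path": agent_path})
        return {name: proc}, {name: {"boundary": agent_path + ("boundary",)}}

    procs, topo = composer("a1", ("agents", "a1"), 0)
    exp = Experiment(procs, topo, {"agents": {"a1": {"boundary": {"mass": 1900.0}}}})
    exp.register_composer(("agents", "a1"), composer, sorted(procs))
    exp.run(2.0)  # reaches 2000 then divides
    agents = exp.store.get(("agents",)).children
    assert set(agents) == {"a1.0", "a1.1"}
    masses = {a: agents[a].get(("boundary", "mass")).value for a in agents}
    assert all(m == 1000.0 for m in masses.values())
    exp.run(2.0)  # daughter processes must be live
    masses = [agents[a].get(("boundary", "mass")).value for a in agents]
    assert all(m == 1200.0 for m in masses)
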