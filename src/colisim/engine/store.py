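"""Hierarchical state: store trees, division, and topology updates.

A :class:`Store` is a node in the compartment hierarchy. Internal nodes
hold named children (sub-stores); leaves hold a value plus its
:class:`~colisim.engine.schema.VariableSchema`. Agent compartments are
subtrees whose ``boundary`` store is shared with the enclosing
environment's processes through the topology.
"""

from __future__ import annotations

import copy
from typing import Any, Iterator, Optional

import numpy as np

from colisim.engine.schema import SchemaError, VariableSchema, divide_value


class HierarchyError(Exception):
    """Raised for topology messages referencing nonexistent compartments."""


Path = tuple[str, ...]


class Store:
    """One node of the compartment hierarchy (tree-structured)."""

    def __init__(self, name: str = ""):
        self.name = name
        self.children: dict[str, "Store"] = {}
        self.value: Any = None
        self.schema: Optional[VariableSchema] = None
        # seeded from initial state before any process declared a schema
        self.provisional: bool = False
        # node-level divider (e.g. 'split_list' on a flagella store whose
        # children are sub-compartments); None means recurse into children
        self.divider: Optional[str] = None

    # -- structure ---------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return self.schema is not None

    def get(self, path: Path) -> "Store":
        node = self
        for key in path:
            if key not in node.children:
                raise HierarchyError(f"no store at path {path!r}")
            node = node.children[key]
        return node

    def has(self, path: Path) -> bool:
        node = self
        for key in path:
            if key not in node.children:
                return False
            node = node.children[key]
        return True

    def ensure(self, path: Path) -> "Store":
        """Get the node at ``path``, creating internal nodes as needed."""
        node = self
        for key in path:
            if key not in node.children:
                if node.is_leaf:
                    raise SchemaError(
                        f"cannot add child {key!r} under leaf {node.name!r}"
                    )
                node.children[key] = Store(key)
            node = node.children[key]
        return node

    def declare(self, path: Path, schema: VariableSchema, initial=None) -> None:
        """Declare a leaf variable at ``path`` with ``schema``.

        Re-declaration is allowed only with a compatible schema (same
        units, updater, divider); the first declaration wins otherwise.
        """
        node = self.ensure(path)
        if node.schema is not None and node.provisional:
            node.schema = schema
            node.provisional = False
            if initial is not None:
                node.value = initial
            return
        if node.schema is not None:
            if not node.schema.compatible(schema):
                raise SchemaError(
                    f"conflicting schemas for variable {'/'.join(path)}: "
                    f"{node.schema} vs {schema}"
                )
            if initial is not None:
                node.value = initial
            return
        if node.children:
            raise SchemaError(
                f"variable {'/'.join(path)} already has children; "
                "cannot also be a leaf"
            )
        node.schema = schema
        node.value = initial if initial is not None else copy.deepcopy(schema.default)

    # -- views -------------------------------------------------------------

    def view(self) -> Any:
        """A plain-dict snapshot of this subtree (leaf values copied)."""
        if self.is_leaf:
            v = self.value
            if isinstance(v, np.ndarray):
                return v.copy()
            if isinstance(v, (list, dict)):
                return copy.deepcopy(v)
            return v
        return {name: child.view() for name, child in self.children.items()}

    def set_state(self, state: Any) -> None:
        """Overwrite leaf values from a nested plain dict."""
        if self.is_leaf:
            self.value = state
            return
        for key, sub in state.items():
            if key not in self.children:
                raise HierarchyError(f"no store {key!r} under {self.name!r}")
            self.children[key].set_state(sub)

    def leaves(self, prefix: Path = ()) -> Iterator[tuple[Path, "Store"]]:
        if self.is_leaf:
            yield prefix, self
        else:
            for name, child in self.children.items():
                yield from child.leaves(prefix + (name,))


def build_store(initial_state: Optional[dict] = None) -> Store:
    """Build a root store, optionally seeding plain values (no schema)."""
    root = Store("root")
    if initial_state:
        _seed(root, initial_state)
    return root


def _seed(node: Store, state: dict) -> None:
    for key, sub in state.items():
        child = node.ensure((key,))
        if isinstance(sub, dict):
            _seed(child, sub)
        else:
            # bare value; a process declaring this variable later adopts
            # it (the declared schema replaces this provisional one)
            child.schema = VariableSchema(default=sub)
            child.value = sub
            child.provisional = True


# -- division --------------------------------------------------------------


def divide_state(agent: Store, rng) -> tuple[Store, Store]:
    """Split an agent compartment into two daughter subtrees.

    Leaf variables are partitioned according to their schema dividers;
    a node carrying a ``split_list`` node-divider has its child
    sub-compartments alternately assigned to the daughters.
    """
    left = Store(agent.name)
    right = Store(agent.name)
    left.divider = right.divider = agent.divider
    if agent.is_leaf:
        if agent.schema is None:
            raise SchemaError(f"no divider defined for variable {agent.name!r}")
        left.schema = right.schema = agent.schema
        left.value, right.value = divide_value(agent.value, agent.schema, rng)
        return left, right
    if agent.divider == "split_list":
        names = sorted(agent.children)
        for i, name in enumerate(names):
            target = left if i % 2 == 0 else right
            target.children[name] = copy.deepcopy(agent.children[name])
        return left, right
    for name in sorted(agent.children):
        l_child, r_child = divide_state(agent.children[name], rng)
        left.children[name] = l_child
        right.children[name] = r_child
    return left, right


# -- topology updates ------------------------------------------------------


def apply_topology_update(root: Store, message: dict, rng=None) -> dict:
    """Apply a structural (topology) update message to the hierarchy.

    ``message`` has a ``type`` of ``divide``, ``delete`` or
    ``add_subcompartment`` plus a payload. Returns a dict describing what
    changed (daughter ids for a division), so the caller can re-wire
    processes. All state outside the referenced compartment is untouched.
    """
    kind = message["type"]
    if kind == "divide":
        path = tuple(message["path"])
        if not root.has(path):
            raise HierarchyError(f"divide: no compartment at {path!r}")
        parent = root.get(path[:-1])
        agent_id = path[-1]
        agent = parent.children.pop(agent_id)
        daughter_ids = message.get(
            "daughter_ids", (f"{agent_id}.0", f"{agent_id}.1")
        )
        daughters = divide_state(agent, rng)
        for did, dstore in zip(daughter_ids, daughters):
            dstore.name = did
            parent.children[did] = dstore
        return {"daughters": list(daughter_ids), "parent": path[:-1]}
    if kind == "delete":
        path = tuple(message["path"])
        if not root.has(path):
            raise HierarchyError(f"delete: no compartment at {path!r}")
        parent = root.get(path[:-1])
        del parent.children[path[-1]]
        return {"deleted": path}
    if kind == "add_subcompartment":
        path = tuple(message["path"])  # path of the new compartment
        parent = root.ensure(path[:-1])
        if path[-1] in parent.children:
            raise HierarchyError(f"add: compartment exists at {path!r}")
        node = Store(path[-1])
        for var, spec in message.get("state", {}).items():
            schema, value = spec
            node.declare((var,), schema, initial=value)
        parent.children[path[-1]] = node
        return {"added": path}
    raise HierarchyError(f"unknown topology message type {kind!r}")
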