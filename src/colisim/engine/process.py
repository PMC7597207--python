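"""Process interface: parameterized mechanisms with ports and time-steps."""

from __future__ import annotations

from typing import Optional

import numpy as np


class Process:
    """Base class for all mechanisms.

    A process declares its *ports* (named views into the store hierarchy,
    each with a schema for every variable it reads or writes), a
    ``time_step`` in seconds, and a ``next_update`` method that maps a
    local state view and an interval to an update. The engine enforces
    that updates never reach outside the declared ports.

    Subclasses set ``defaults`` (parameter defaults, may include
    ``time_step``) and implement :meth:`ports_schema` and
    :meth:`next_update`. Stochastic processes draw from ``self.rng``, a
    named child stream assigned by the experiment at wiring time.
    """

    defaults: dict = {}
    time_step: float = 1.0

    def __init__(self, parameters: Optional[dict] = None):
        self.parameters = {**self.defaults, **(parameters or {})}
        self.time_step = float(self.parameters.get("time_step", type(self).time_step))
        if self.time_step <= 0:
            raise ValueError("process time_step must be > 0")
        self.rng: np.random.Generator = np.random.default_rng(0)
        self.name: str = type(self).__name__

    def ports_schema(self) -> dict:
        """Map port name -> (nested) variable schema dict.

        The special key ``"*"`` declares a template schema for arbitrary
        child names (used for per-agent or per-species wildcard ports).
        """
        raise NotImplementedError

    def next_update(self, states: dict, timestep: float) -> dict:
        """Compute an update for ``timestep`` seconds from ``states``.

        The update mirrors the port structure; it may additionally carry
        a ``"_topology"`` message (divide / delete / add_subcompartment).
        """
        raise NotImplementedError
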