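"""Deterministic small fixtures for tests and worked examples."""

from __future__ import annotations

import numpy as np

from .dynamics import EsteemState
from .params import GroupAssignment, ModelParams


def fixture_state(
    kind: str, seed: int = 0, n_agents: int | None = None
) -> tuple[EsteemState, GroupAssignment]:
    """Build a small deterministic esteem state.

    ``zeros``
        The model's initial condition (all esteems 0) at configurable N
        (default 4).
    ``worked_example``
        A 2-agent state with a[1][0] = 0.4 and a[1][1] = -0.2, all else 0:
        agent 0 then has credibility exactly 0.5 for agent 1, so a single
        noise-free Influence(0, 1) lands on hand-computable values
        (a[0][0] = 0.2, a[0][1] = -0.1).
    ``random_small``
        A 6-agent state with seeded uniform entries inside the default
        esteem bounds, for oracle-equivalence runs.
    """
    if kind == "zeros":
        n = n_agents or 4
        state = EsteemState.zeros(n)
    elif kind == "worked_example":
        n = n_agents or 2
        if n < 2:
            raise ValueError("worked_example needs at least 2 agents")
        state = EsteemState.zeros(n)
        state.a[1, 0] = 0.4
        state.a[1, 1] = -0.2
    elif kind == "random_small":
        n = n_agents or 6
        rng = np.random.default_rng(seed)
        state = EsteemState(a=rng.uniform(-1.0, 1.0, size=(n, n)), t=0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    n_small = n // 2
    groups = GroupAssignment.from_params(
        ModelParams(
            n_agents=n,
            n_small=n_small,
            n_large=n - n_small,
            sigma_small=0.1,
            sigma_large=0.15,
            gossip_count=0 if n < 3 else 3,
        )
    )
    return state, groups
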