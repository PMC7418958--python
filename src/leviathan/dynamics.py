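"""Stochastic micro-dynamics: credibility, influence, gossip, iterations.

Every operation here is the plain, loop-based reference implementation of
one micro-step, written to be read next to the model description.  The
production engine used by :func:`run_simulation` is a numba kernel
(:mod:`leviathan._kernel`) that executes the *identical* sequence of draws
from the same ``numpy.random.Generator``, so the two paths are bit-equal
and the reference doubles as the oracle in the test suite.

Draw discipline (shared by both engines):

* every random integer on ``[0, m)`` is ``floor(u * m)`` from a single
  uniform draw ``u`` — never ``Generator.integers`` — so the two engines
  consume the same stream;
* each updated esteem entry receives its own independent uniform noise
  draw on ``(-delta, +delta)``;
* per interaction, in order: focal-agent draw, same-group coin, partner
  draw, Influence(i, j) noise x2, Influence(j, i) noise x2, then for each
  of the two directed Gossip calls k repetitions of (target draw, noise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import GroupAssignment, ModelParams

logger = logging.getLogger(__name__)


@dataclass
class EsteemState:
    """The N x N esteem matrix and the iteration clock.

    ``a[i, j]`` is the esteem agent *i* holds for agent *j*; the diagonal
    ``a[i, i]`` is self-esteem.  All entries start at 0 (neutral esteem).
    """

    a: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n_agents: int) -> "EsteemState":
        return cls(a=np.zeros((n_agents, n_agents), dtype=np.float64), t=0)

    @property
    def n_agents(self) -> int:
        return self.a.shape[0]

    def copy(self) -> "EsteemState":
        return EsteemState(a=self.a.copy(), t=self.t)


@dataclass
class SnapshotSeries:
    """Time-indexed record of esteem matrices for one replica.

    ``snapshots[s]`` is the full esteem matrix at iteration ``times[s]``;
    the series always contains the all-zero initial matrix at t = 0.
    ``stationary_window`` is the trailing fraction of snapshots treated as
    the stable regime by the time-averaged indicators.
    """

    params: ModelParams
    groups: GroupAssignment
    times: np.ndarray
    snapshots: np.ndarray  # shape (n_snapshots, N, N)
    replica_id: int = 0
    stationary_window: float = 0.5

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]

    def stationary_indices(self) -> np.ndarray:
        """Indices of the trailing ``stationary_window`` fraction of snapshots."""
        if not 0.0 < self.stationary_window <= 1.0:
            raise ValueError("stationary_window must lie in (0, 1]")
        start = int(math.floor(self.n_snapshots * (1.0 - self.stationary_window)))
        return np.arange(start, self.n_snapshots)

    def stationary_snapshots(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.stationary_indices()
        return self.times[idx], self.snapshots[idx]


def credibility(esteem_of_speaker: float, self_esteem: float, sigma: float):
    """Logistic credibility a listener gives a speaker.

    ``p = 1 / (1 + exp(-(a_ij - a_ii) / sigma))``: the more the listener
    esteems the speaker above itself, the closer p is to 1.  ``sigma``
    (open-mindedness) sets the slope: large sigma flattens the curve so
    every speaker gets credibility near 0.5 regardless of relative status.

    Accepts scalars or numpy arrays.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    scalars = all(
        np.ndim(x) == 0 for x in (esteem_of_speaker, self_esteem, sigma)
    )
    if scalars:
        # math.exp and the compiled kernel share the same libm call, which
        # keeps the reference and production engines bit-identical
        return 1.0 / (1.0 + math.exp(-(float(esteem_of_speaker) - float(self_esteem)) / float(sigma)))
    d = np.subtract(esteem_of_speaker, self_esteem)
    return 1.0 / (1.0 + np.exp(-d / sigma))


def _clip(value: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return lo if value < lo else hi if value > hi else value


def _noise(rng: np.random.Generator, delta: float) -> float:
    # one dedicated draw per updated entry, uniform on (-delta, +delta)
    return 2.0 * delta * rng.random() - delta


def influence(
    state: EsteemState,
    listener: int,
    speaker: int,
    params: ModelParams,
    groups: GroupAssignment,
    rng: np.random.Generator,
) -> EsteemState:
    """Directed Influence(i, j): the speaker shifts the listener's
    self-esteem and its esteem of the speaker.

    With ``p`` the credibility computed from pre-update values,

        a[i][i] += p * (a[j][i] - a[i][i] + noise)
        a[i][j] += p * (a[j][j] - a[i][j] + noise)

    both clipped to the esteem bounds.  Only row *i*, columns *i* and *j*,
    change.
    """
    i, j = listener, speaker
    if i == j:
        raise ValueError("listener and speaker must differ")
    a = state.a
    delta = params.noise_half_width
    p = credibility(a[i, j], a[i, i], groups.sigma_of(i))
    a[i, i] = _clip(a[i, i] + p * (a[j, i] - a[i, i] + _noise(rng, delta)), params.esteem_bounds)
    a[i, j] = _clip(a[i, j] + p * (a[j, j] - a[i, j] + _noise(rng, delta)), params.esteem_bounds)
    return state


def gossip(
    state: EsteemState,
    listener: int,
    speaker: int,
    params: ModelParams,
    groups: GroupAssignment,
    rng: np.random.Generator,
) -> EsteemState:
    """Directed Gossip(i, j): the speaker relays its esteems about k third
    parties, absorbed by the listener at credibility ``p``.

    ``p`` is computed once per call (it is indexed by the pair, not by the
    gossip target).  Each repetition draws a fresh target z uniformly from
    the agents other than i and j — independently, so targets may repeat —
    and applies ``a[i][z] += p * (a[j][z] - a[i][z] + noise)``.
    """
    i, j = listener, speaker
    if i == j:
        raise ValueError("listener and speaker must differ")
    k = params.gossip_count
    if k == 0:
        return state
    n = state.n_agents
    if n < 3:
        raise ValueError("gossip with k > 0 requires at least 3 agents")
    a = state.a
    delta = params.noise_half_width
    p = credibility(a[i, j], a[i, i], groups.sigma_of(i))
    lo_ex, hi_ex = (i, j) if i < j else (j, i)
    for _ in range(k):
        z = int(rng.random() * (n - 2))
        if z >= lo_ex:
            z += 1
        if z >= hi_ex:
            z += 1
        a[i, z] = _clip(
            a[i, z] + p * (a[j, z] - a[i, z] + _noise(rng, delta)),
            params.esteem_bounds,
        )
    return state


def select_partner(
    i: int,
    groups: GroupAssignment,
    params: ModelParams,
    rng: np.random.Generator,
) -> int:
    """Draw the interaction partner j != i.

    ``pair_selection='group-coin'``: with probability ``same_group_prob``
    the partner comes uniformly from i's own group (excluding i),
    otherwise uniformly from the other group.  Degenerate pools fall back
    to the other one: a same-group draw when i is its group's only member
    uses the other group, and a cross-group draw when the other group is
    empty uses i's own group — so a single-group population reduces to a
    uniform draw over all j != i.

    ``pair_selection='uniform'``: j is drawn uniformly from all agents
    except i (one draw).
    """
    if groups.n_agents < 2:
        raise ValueError("partner selection requires at least 2 agents")
    if params.pair_selection == "uniform":
        j = int(rng.random() * (groups.n_agents - 1))
        return j + 1 if j >= i else j
    own_label = groups.labels[i]
    own = groups.members(own_label)
    other = groups.members("L" if own_label == "S" else "S")
    same = rng.random() < params.same_group_prob
    use_own = (own.size > 1) if same else (other.size == 0)
    if use_own:
        pos_i = int(np.searchsorted(own, i))
        r = int(rng.random() * (own.size - 1))
        if r >= pos_i:
            r += 1
        return int(own[r])
    return int(other[int(rng.random() * other.size)])


def interaction(
    state: EsteemState,
    i: int,
    j: int,
    params: ModelParams,
    groups: GroupAssignment,
    rng: np.random.Generator,
) -> EsteemState:
    """One encounter: Influence(i,j), Influence(j,i), Gossip(i,j), Gossip(j,i).

    The four directed calls are applied sequentially, each reading the
    state already updated by the previous ones; within each call the
    credibility and difference terms use that call's pre-update values.
    """
    influence(state, i, j, params, groups, rng)
    influence(state, j, i, params, groups, rng)
    gossip(state, i, j, params, groups, rng)
    gossip(state, j, i, params, groups, rng)
    return state


def run_iteration(
    state: EsteemState,
    params: ModelParams,
    groups: GroupAssignment,
    rng: np.random.Generator,
) -> EsteemState:
    """One iteration = floor(N/2) random pair interactions.

    Focal agents are drawn uniformly with replacement, so each agent
    interacts once on average per iteration.
    """
    n = state.n_agents
    for _ in range(n // 2):
        i = int(rng.random() * n)
        j = select_partner(i, groups, params, rng)
        interaction(state, i, j, params, groups, rng)
    state.t += 1
    return state


def run_simulation(
    params: ModelParams,
    groups: GroupAssignment | None = None,
    *,
    engine: str = "numba",
    replica_id: int = 0,
    stationary_window: float = 0.5,
) -> SnapshotSeries:
    """Run one replica from the all-zero initial state and record snapshots.

    Snapshots of the full esteem matrix are taken at t = 0 and every
    ``measure_every`` iterations.  ``engine='numba'`` uses the compiled
    kernel; ``engine='python'`` runs the reference loop above.  Both
    engines consume the replica generator identically, so the result is
    bit-identical either way.
    """
    if groups is None:
        groups = GroupAssignment.from_params(params)
    if groups.n_agents != params.n_agents:
        raise ValueError("group assignment size does not match n_agents")
    if engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.default_rng(params.seed)
    state = EsteemState.zeros(params.n_agents)
    n_snap = params.n_iterations // params.measure_every + 1
    times = np.empty(n_snap, dtype=np.int64)
    snapshots = np.empty((n_snap, params.n_agents, params.n_agents), dtype=np.float64)
    times[0] = 0
    snapshots[0] = state.a

    if engine == "numba":
        from ._kernel import run_iterations_kernel

        is_large = groups.is_large
        members_s = groups.members_small.astype(np.int64)
        members_l = groups.members_large.astype(np.int64)
        pos = groups.position_in_group()
        lo, hi = params.esteem_bounds

    s = 1
    remaining = params.n_iterations
    while remaining > 0:
        block = min(params.measure_every, remaining)
        if engine == "numba":
            run_iterations_kernel(
                state.a,
                groups.sigma,
                is_large,
                members_s,
                members_l,
                pos,
                block,
                params.noise_half_width,
                params.gossip_count,
                params.same_group_prob,
                params.pair_selection == "uniform",
                lo,
                hi,
                rng,
            )
            state.t += block
        else:
            for _ in range(block):
                run_iteration(state, params, groups, rng)
        remaining -= block
        if state.t % params.measure_every == 0 and s < n_snap:
            times[s] = state.t
            snapshots[s] = state.a
            logger.debug(
                "replica %d: snapshot %d/%d at t=%d", replica_id, s + 1, n_snap, state.t
            )
            s += 1

    return SnapshotSeries(
        params=params,
        groups=groups,
        times=times,
        snapshots=snapshots,
        replica_id=replica_id,
        stationary_window=stationary_window,
    )
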