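"""Model parameters and group assignment.

The model has four substantive constants — population size ``N``, the
open-mindedness ``sigma`` of each group, the communication-noise half-width
``delta`` and the gossip count ``k`` — plus run-control fields (horizon,
measurement cadence, seed).  The population is partitioned into an S-group
(small sigma: credibility depends sharply on perceived relative status) and
an L-group (large sigma: all interlocutors are nearly equally credible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SMALL = "S"
LARGE = "L"


@dataclass(frozen=True)
class ModelParams:
    """All dynamical constants of one simulation run.

    Parameters
    ----------
    n_agents
        Population size N.
    n_small, n_large
        Sizes of the S-group (small sigma) and L-group (large sigma).
        They must partition ``n_agents``.  A single-group baseline run is
        expressed by setting one of them to 0.
    sigma_small, sigma_large
        Open-mindedness of each group: the slope parameter of the logistic
        credibility function.  Must be positive.
    noise_half_width
        Half-width ``delta`` of the uniform perturbation added to every
        communicated esteem.
    gossip_count
        Number ``k`` of third parties the speaker gossips about per
        directed encounter.
    same_group_prob
        Under ``pair_selection='group-coin'``, the probability that the
        partner is drawn from the focal agent's own group (0.5 in all the
        study designs: contact is group-blind).
    pair_selection
        ``'group-coin'`` (default): flip a same-group coin, then draw
        uniformly inside the chosen group.  ``'uniform'``: draw the
        partner uniformly from all other agents.  The two coincide (up to
        1/N) for equal groups, but for unequal groups the coin rule makes
        minority agents interact more often per capita, which changes the
        emergent hierarchy; the group-size designs therefore use uniform
        pairing (see the methods note).
    esteem_bounds
        Closed interval to which every esteem entry is clipped.
    n_iterations
        Horizon in iterations; one iteration is N/2 pair interactions.
    measure_every
        Snapshot cadence in iterations.
    seed
        Seed of the replica's random generator.
    """

    n_agents: int = 40
    n_small: int = 20
    n_large: int = 20
    sigma_small: float = 0.1
    sigma_large: float = 0.15
    noise_half_width: float = 0.2
    gossip_count: int = 3
    same_group_prob: float = 0.5
    pair_selection: str = "group-coin"
    esteem_bounds: tuple[float, float] = (-1.0, 1.0)
    n_iterations: int = 500_000
    measure_every: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be a positive integer")
        if self.n_small < 0 or self.n_large < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_small + self.n_large != self.n_agents:
            raise ValueError(
                f"n_small + n_large must equal n_agents "
                f"({self.n_small} + {self.n_large} != {self.n_agents})"
            )
        if self.sigma_small <= 0 or self.sigma_large <= 0:
            raise ValueError("sigma_small and sigma_large must be positive")
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be non-negative")
        if self.gossip_count < 0:
            raise ValueError("gossip_count must be non-negative")
        if not 0.0 <= self.same_group_prob <= 1.0:
            raise ValueError("same_group_prob must lie in [0, 1]")
        if self.pair_selection not in ("group-coin", "uniform"):
            raise ValueError("pair_selection must be 'group-coin' or 'uniform'")
        lo, hi = self.esteem_bounds
        if not lo < hi:
            raise ValueError("esteem_bounds must satisfy min < max")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be non-negative")
        if self.measure_every < 1:
            raise ValueError("measure_every must be a positive integer")
        if self.n_agents < 3 and self.gossip_count > 0:
            raise ValueError(
                "gossip requires at least 3 agents (no valid third party)"
            )

    def with_seed(self, seed: int) -> "ModelParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GroupAssignment:
    """Agent -> group labels and the per-agent sigma lookup.

    By convention agents ``0 .. n_small-1`` are the S-group and the rest
    the L-group; the dynamics are exchangeable over agent indices so the
    convention is harmless.
    """

    labels: np.ndarray  # '<U1' array over {"S", "L"}
    sigma: np.ndarray  # per-agent open-mindedness, float64

    @classmethod
    def from_params(cls, params: ModelParams) -> "GroupAssignment":
        labels = np.array(
            [SMALL] * params.n_small + [LARGE] * params.n_large, dtype="<U1"
        )
        sigma = np.where(labels == SMALL, params.sigma_small, params.sigma_large)
        return cls(labels=labels, sigma=sigma.astype(np.float64))

    def __post_init__(self) -> None:
        if self.labels.shape != self.sigma.shape:
            raise ValueError("labels and sigma must have the same length")
        if not np.isin(self.labels, [SMALL, LARGE]).all():
            raise ValueError("labels must be 'S' or 'L'")

    @property
    def n_agents(self) -> int:
        return self.labels.shape[0]

    @property
    def is_large(self) -> np.ndarray:
        return self.labels == LARGE

    @property
    def members_small(self) -> np.ndarray:
        return np.flatnonzero(self.labels == SMALL)

    @property
    def members_large(self) -> np.ndarray:
        return np.flatnonzero(self.labels == LARGE)

    def members(self, which: str) -> np.ndarray:
        if which == SMALL:
            return self.members_small
        if which == LARGE:
            return self.members_large
        raise ValueError(f"unknown group {which!r}; expected 'S' or 'L'")

    def sigma_of(self, i: int) -> float:
        return float(self.sigma[i])

    def position_in_group(self) -> np.ndarray:
        """Index of each agent inside its own group's member array."""
        pos = np.empty(self.n_agents, dtype=np.int64)
        pos[self.members_small] = np.arange(self.members_small.size)
        pos[self.members_large] = np.arange(self.members_large.size)
        return pos
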