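"""Derived indicators of the emergent status hierarchy.

Reputation (consensual status), group aggregates, intra-group variation
coefficients, social ranks, rank-occupancy and advancement probabilities,
the glass-ceiling threshold and extreme-rank Z-scores.

Conventions, applied throughout:

* reputation excludes self-esteem: it is the mean esteem *other* agents
  accord an agent (matrix column mean over off-diagonal entries);
* population (not sample) standard deviations — these are descriptive
  statistics over whole groups of at most a few dozen agents;
* the variation coefficient divides by the *absolute* group mean, because
  mean self-esteem is typically negative in this model and a signed CV
  would invert the group ordering;
* rank 1 is the best (highest) reputation; exact ties — a measure-zero
  event once noise acts — are broken by ascending agent index so the
  noise-free degenerate case stays deterministic;
* pooled indicators use each series' trailing stationary window.
"""

from __future__ import annotations

from collections.abc import Sequence
from typing import Union

import numpy as np
import pandas as pd

from .dynamics import SnapshotSeries
from .params import LARGE, SMALL, GroupAssignment

SeriesLike = Union[SnapshotSeries, Sequence[SnapshotSeries]]


def _as_series_list(series: SeriesLike) -> list[SnapshotSeries]:
    if isinstance(series, SnapshotSeries):
        return [series]
    out = list(series)
    if not out:
        raise ValueError("at least one snapshot series is required")
    return out


def reputation_vector(snapshot: np.ndarray) -> np.ndarray:
    """Per-agent reputation: mean esteem accorded by all *other* agents.

    ``reputation[j] = mean_{i != j} a[i, j]`` — the diagonal (self-esteem)
    is excluded.
    """
    a = np.asarray(snapshot, dtype=np.float64)
    n = a.shape[0]
    if a.ndim != 2 or a.shape[1] != n:
        raise ValueError("snapshot must be a square matrix")
    if n < 2:
        raise ValueError("reputation requires at least 2 agents")
    return (a.sum(axis=0) - np.diag(a)) / (n - 1)


def group_mean(values: np.ndarray, groups: GroupAssignment, which: str) -> float:
    """Arithmetic mean of a per-agent vector over one group."""
    members = groups.members(which)
    if members.size == 0:
        raise ValueError(f"group {which!r} is empty")
    return float(np.mean(np.asarray(values, dtype=np.float64)[members]))


def variation_coefficient(values: np.ndarray) -> float:
    """Population SD of a group's values divided by |group mean|.

    Indexes intra-group stratification on a scale-free footing; undefined
    (raises) when the group mean is zero.
    """
    v = np.asarray(values, dtype=np.float64)
    m = v.mean()
    if m == 0.0:
        raise ValueError("variation coefficient undefined for zero group mean")
    return float(v.std(ddof=0) / abs(m))


def consensual_stratification(
    snapshot: np.ndarray, groups: GroupAssignment, which: str
) -> float:
    """Population SD of one group's reputations: consensual intra-group
    status differentiation."""
    members = groups.members(which)
    if members.size < 2:
        raise ValueError("consensual stratification requires group size >= 2")
    rep = reputation_vector(snapshot)
    return float(rep[members].std(ddof=0))


def rank_vector(snapshot: np.ndarray) -> np.ndarray:
    """Social rank per agent: 1 = best reputation, N = worst.

    Ties broken by ascending agent index.
    """
    rep = reputation_vector(snapshot)
    n = rep.shape[0]
    order = np.lexsort((np.arange(n), -rep))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def ranks_frame(series: SeriesLike, *, stationary_only: bool = True) -> pd.DataFrame:
    """Long-format rank record pooled over series.

    Columns: replica, t, agent, group, rank.  By default only the trailing
    stationary window of each series is included.
    """
    frames = []
    for s in _as_series_list(series):
        idx = s.stationary_indices() if stationary_only else np.arange(s.n_snapshots)
        n = s.params.n_agents
        snaps = s.snapshots[idx]
        # reputations for all snapshots at once: column means without diagonal
        reps = (snaps.sum(axis=1) - np.diagonal(snaps, axis1=1, axis2=2)) / (n - 1)
        agents = np.arange(n)
        ranks = np.empty_like(reps, dtype=np.int64)
        for row, rep in enumerate(reps):
            order = np.lexsort((agents, -rep))
            ranks[row, order] = np.arange(1, n + 1)
        frames.append(
            pd.DataFrame(
                {
                    "replica": s.replica_id,
                    "t": np.repeat(s.times[idx], n),
                    "agent": np.tile(agents, idx.size),
                    "group": np.tile(s.groups.labels, idx.size),
                    "rank": ranks.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def group_summary(series: SeriesLike) -> pd.DataFrame:
    """Per-(replica, time, group) aggregates of reputation and self-esteem.

    Columns: replica, t, group, mean_reputation, mean_self_esteem,
    cv_self_esteem, cv_reputation, sd_reputation.  CV cells are NaN when
    the corresponding group mean is zero (e.g. at t = 0).
    """
    rows = []
    for s in _as_series_list(series):
        for si in range(s.n_snapshots):
            snap = s.snapshots[si]
            rep = reputation_vector(snap)
            self_est = np.diag(snap)
            for which in (SMALL, LARGE):
                members = s.groups.members(which)
                if members.size == 0:
                    continue
                r = rep[members]
                e = self_est[members]
                rows.append(
                    {
                        "replica": s.replica_id,
                        "t": int(s.times[si]),
                        "group": which,
                        "mean_reputation": r.mean(),
                        "mean_self_esteem": e.mean(),
                        "cv_self_esteem": (
                            np.nan if e.mean() == 0 else variation_coefficient(e)
                        ),
                        "cv_reputation": (
                            np.nan if r.mean() == 0 else variation_coefficient(r)
                        ),
                        "sd_reputation": r.std(ddof=0),
                    }
                )
    return pd.DataFrame(rows)


def occupancy_probability(series: SeriesLike) -> pd.DataFrame:
    """Probability that each rank is held by each group.

    Pools (snapshot, replica) observations over the stationary windows.
    Columns: rank, group, probability; for each rank the two group
    probabilities sum to 1.
    """
    ranks = ranks_frame(series, stationary_only=True)
    n_obs = ranks.groupby("rank").size()
    counts = ranks.groupby(["rank", "group"]).size()
    prob = (counts / n_obs).rename("probability").reset_index()
    # ensure both groups appear for every rank, with 0 where never observed
    full = (
        prob.set_index(["rank", "group"])
        .reindex(
            pd.MultiIndex.from_product(
                [sorted(ranks["rank"].unique()), [SMALL, LARGE]],
                names=["rank", "group"],
            ),
            fill_value=0.0,
        )
        .reset_index()
    )
    present = set(ranks["group"].unique())
    return full[full["group"].isin(present)].reset_index(drop=True)


def best_rank_attained(series: SeriesLike, *, group: str = LARGE) -> int:
    """Best (minimum) rank ever held by the queried group, pooled over the
    stationary windows of all series.

    A raw extreme statistic: it is non-increasing as more data are pooled,
    and converges to 1 whenever the group's top-rank occupancy is positive
    at all, so prefer :func:`glass_ceiling_rank` for locating the ceiling.
    """
    ranks = ranks_frame(series, stationary_only=True)
    sub = ranks[ranks["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty; best rank undefined")
    return int(sub["rank"].min())


def glass_ceiling_rank(
    series: SeriesLike, *, group: str = LARGE, method: str = "occupancy"
) -> int:
    """Glass-ceiling threshold for the queried (disfavoured) group.

    ``method='occupancy'`` (default) locates the ceiling on the pooled
    rank-occupancy curve: the best (lowest-numbered) rank at which the
    group's occupancy probability reaches its population share
    q = (group size)/N.  At every better rank the group is
    under-represented, with occupancy declining toward zero at the very
    top — the knee of the occupancy curve.  The share q is fixed by the
    design, so the estimator has no free threshold.

    ``method='min'`` returns :func:`best_rank_attained`, the raw best rank
    ever observed.
    """
    if method == "min":
        return best_rank_attained(series, group=group)
    if method != "occupancy":
        raise ValueError("method must be 'occupancy' or 'min'")
    series_list = _as_series_list(series)
    g = series_list[0].groups
    n = series_list[0].params.n_agents
    q = g.members(group).size / n
    if q == 0.0:
        raise ValueError(f"group {group!r} is empty; glass ceiling undefined")
    occ = occupancy_probability(series_list)
    sub = occ[occ["group"] == group].sort_values("rank")
    at_share = sub[sub["probability"] >= q]
    if at_share.empty:  # degenerate: never at share; report the modal rank
        return int(sub.loc[sub["probability"].idxmax(), "rank"])
    return int(at_share["rank"].iloc[0])


def advancement_probability(series: SeriesLike) -> pd.DataFrame:
    """P(rank at next measurement <= current rank | group, current rank).

    "Next" means the next snapshot in the stationary window, not the next
    micro-iteration.  Columns: group, rank, probability, n_obs; (group,
    rank) cells never observed are absent.
    """
    frames = []
    for s in _as_series_list(series):
        idx = s.stationary_indices()
        if idx.size < 2:
            raise ValueError(
                "advancement probability needs >= 2 snapshots in the stationary window"
            )
        rank_mat = np.stack([rank_vector(s.snapshots[si]) for si in idx])
        cur = rank_mat[:-1].ravel()
        nxt = rank_mat[1:].ravel()
        lab = np.tile(s.groups.labels, rank_mat.shape[0] - 1)
        frames.append(
            pd.DataFrame({"group": lab, "rank": cur, "advanced": nxt <= cur})
        )
    obs = pd.concat(frames, ignore_index=True)
    out = (
        obs.groupby(["group", "rank"])["advanced"]
        .agg(probability="mean", n_obs="size")
        .reset_index()
    )
    return out


def extreme_rank_zscore(
    series: SeriesLike,
    *,
    n_extreme: int = 5,
    side: str = "top",
    group: str = LARGE,
) -> float:
    """Standardised over/under-representation of a group in the extreme ranks.

    Under proportional representation the queried group should hold a
    fraction q = (group size)/N of the ``n_extreme`` best ("top") or worst
    ("bottom") rank slots.  Over all pooled (snapshot, replica)
    observations with n = n_extreme x n_observations slots and X of them
    held by the group, returns the binomial Z-score
    ``(X - n q) / sqrt(n q (1 - q))``.  Negative at the top and positive
    at the bottom signals a glass-ceiling-like exclusion pattern.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    series_list = _as_series_list(series)
    n_agents = series_list[0].params.n_agents
    g = series_list[0].groups
    q = g.members(group).size / n_agents
    if q in (0.0, 1.0):
        raise ValueError("Z-score undefined when one group is empty")
    ranks = ranks_frame(series_list, stationary_only=True)
    if side == "top":
        extreme = ranks[ranks["rank"] <= n_extreme]
    else:
        extreme = ranks[ranks["rank"] > n_agents - n_extreme]
    n_slots = len(extreme)
    x = int((extreme["group"] == group).sum())
    return float((x - n_slots * q) / np.sqrt(n_slots * q * (1.0 - q)))
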