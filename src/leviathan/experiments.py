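"""Seeded batch experiments: the three study designs.

* :func:`baseline_experiment` — a single-group population, all agents at
  the S-group's open-mindedness, as the comparison baseline.
* :func:`two_group_sweep` — equal-size groups over a grid of sigma_S
  values and sigma_L relations; emits group summaries, ranks, occupancy,
  advancement and the glass-ceiling rank per grid cell.
* :func:`group_size_sweep` — varies the group split and the gossip count
  and emits top/bottom extreme-rank Z-scores for the L-group.

Seeding: within a cell, replica r uses ``cell_seed + r``; cells are
offset as ``base_seed + cell_index * replicas`` so every (cell, replica)
seed is distinct and results are independent of execution order.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SnapshotSeries, run_simulation
from .indicators import (
    advancement_probability,
    best_rank_attained,
    extreme_rank_zscore,
    glass_ceiling_rank,
    group_summary,
    occupancy_probability,
    ranks_frame,
)
from .params import SMALL, ModelParams

logger = logging.getLogger(__name__)

#: sigma_S grid of the main design (dense at small values, where the
#: credibility curve is steepest and group differentiation strongest)
SIGMA_SMALL_GRID = (
    0.03, 0.05, 0.07, 0.1, 0.12, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 1.0, 2.0, 3.0,
)


def sigma_relation(sigma_small: float, rule: str) -> float:
    """Map sigma_S to sigma_L: ``f1`` multiplies by 1.5, ``f2`` adds 0.1."""
    if sigma_small <= 0:
        raise ValueError("sigma_small must be positive")
    if rule == "f1":
        return 1.5 * sigma_small
    if rule == "f2":
        return sigma_small + 0.1
    raise ValueError(f"unknown sigma relation {rule!r}; expected 'f1' or 'f2'")


def default_horizon(sigma_small: float) -> int:
    """Horizon in iterations: the smaller sigma_S, the slower the dynamics
    stabilise, so the longer the run (never below 500k at full scale)."""
    return max(500_000, round(50_000 / sigma_small))


@dataclass(frozen=True)
class SweepConfig:
    """Grids, replica counts and scaling for the batch designs."""

    sigma_small_grid: tuple[float, ...] = SIGMA_SMALL_GRID
    sigma_relation: str = "both"  # 'f1', 'f2' or 'both'
    n_small_grid: tuple[int, ...] = tuple(range(0, 45, 5))
    gossip_grid: tuple[int, ...] = (0, 1, 2, 3)
    replicas: int = 50
    base_seed: int = 0
    n_agents: int = 40
    noise_half_width: float = 0.2
    gossip_count: int = 3
    n_iterations: int | None = None  # None -> default_horizon(sigma_small)
    measure_every: int = 10_000
    stationary_window: float = 0.5
    scale_factor: float = 1.0  # multiplies horizon, cadence and replicas

    def __post_init__(self) -> None:
        if not self.sigma_small_grid:
            raise ValueError("sigma_small_grid must be non-empty")
        if any(s <= 0 for s in self.sigma_small_grid):
            raise ValueError("sigma_small_grid values must be positive")
        if self.sigma_relation not in ("f1", "f2", "both"):
            raise ValueError("sigma_relation must be 'f1', 'f2' or 'both'")
        if self.replicas < 1:
            raise ValueError("replicas must be >= 1")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def relations(self) -> tuple[str, ...]:
        return ("f1", "f2") if self.sigma_relation == "both" else (self.sigma_relation,)

    @property
    def effective_replicas(self) -> int:
        return max(1, round(self.replicas * self.scale_factor))

    def effective_horizon(self, sigma_small: float) -> int:
        base = self.n_iterations or default_horizon(sigma_small)
        return max(1, round(base * self.scale_factor))

    def effective_cadence(self, sigma_small: float) -> int:
        # keep roughly the same number of snapshots per run at any scale
        horizon = self.effective_horizon(sigma_small)
        return max(1, min(self.measure_every, horizon // 10))


@dataclass
class SweepResult:
    """Long-format tables produced by a sweep, keyed by the cell columns
    (design, sigma_small, sigma_large, relation, n_small, k, replica)."""

    summary: pd.DataFrame
    ranks: pd.DataFrame = field(default_factory=pd.DataFrame)
    occupancy: pd.DataFrame = field(default_factory=pd.DataFrame)
    advancement: pd.DataFrame = field(default_factory=pd.DataFrame)
    glass_ceiling: pd.DataFrame = field(default_factory=pd.DataFrame)
    zscores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: df
            for name, df in {
                "summary": self.summary,
                "ranks": self.ranks,
                "occupancy": self.occupancy,
                "advancement": self.advancement,
                "glass_ceiling": self.glass_ceiling,
                "zscores": self.zscores,
            }.items()
            if not df.empty
        }


def run_replicas(
    params: ModelParams,
    n_replicas: int,
    base_seed: int,
    *,
    engine: str = "numba",
    stationary_window: float = 0.5,
) -> list[SnapshotSeries]:
    """Run ``n_replicas`` independent replicas, replica r seeded base_seed + r."""
    out = []
    for r in range(n_replicas):
        t0 = time.perf_counter()
        series = run_simulation(
            params.with_seed(base_seed + r),
            engine=engine,
            replica_id=r,
            stationary_window=stationary_window,
        )
        logger.info(
            "replica %d/%d done in %.1fs (N=%d, sigma_S=%g, horizon=%d)",
            r + 1,
            n_replicas,
            time.perf_counter() - t0,
            params.n_agents,
            params.sigma_small,
            params.n_iterations,
        )
        out.append(series)
    return out


def _stationary_group_summary(series: SnapshotSeries) -> list[dict]:
    """Time-averaged group summary over the stationary window, one row per group."""
    gs = group_summary(series)
    idx = series.stationary_indices()
    t_min = series.times[idx[0]]
    stat = gs[gs["t"] >= t_min]
    rows = []
    for which, sub in stat.groupby("group"):
        rows.append(
            {
                "group": which,
                "mean_reputation": sub["mean_reputation"].mean(),
                "mean_self_esteem": sub["mean_self_esteem"].mean(),
                "cv_self_esteem": sub["cv_self_esteem"].mean(),
                "cv_reputation": sub["cv_reputation"].mean(),
                "sd_reputation": sub["sd_reputation"].mean(),
            }
        )
    return rows


def _cell_meta(design, sigma_small, sigma_large, relation, n_small, k, seed):
    return {
        "design": design,
        "sigma_small": sigma_small,
        "sigma_large": sigma_large,
        "relation": relation,
        "n_small": n_small,
        "k": k,
        "seed": seed,
    }


def baseline_experiment(
    sigma_small: float,
    config: SweepConfig,
    *,
    engine: str = "numba",
) -> pd.DataFrame:
    """Single-group run: all N agents share sigma_small.

    Returns one stationary group-summary row per replica, labelled
    ``design='baseline'`` with ``group='S'`` (the whole population).
    """
    params = ModelParams(
        n_agents=config.n_agents,
        n_small=config.n_agents,
        n_large=0,
        sigma_small=sigma_small,
        sigma_large=sigma_small,
        noise_half_width=config.noise_half_width,
        gossip_count=config.gossip_count,
        n_iterations=config.effective_horizon(sigma_small),
        measure_every=config.effective_cadence(sigma_small),
    )
    rows = []
    series_list = run_replicas(
        params,
        config.effective_replicas,
        config.base_seed,
        engine=engine,
        stationary_window=config.stationary_window,
    )
    for series in series_list:
        meta = _cell_meta(
            "baseline", sigma_small, np.nan, "none", config.n_agents,
            config.gossip_count, series.params.seed,
        )
        for row in _stationary_group_summary(series):
            rows.append({**meta, "replica": series.replica_id, **row})
    return pd.DataFrame(rows)


def _two_group_params(
    config: SweepConfig, sigma_small, sigma_large, n_small, k,
    pair_selection: str = "group-coin",
):
    return ModelParams(
        n_agents=config.n_agents,
        n_small=n_small,
        n_large=config.n_agents - n_small,
        sigma_small=sigma_small,
        sigma_large=sigma_large,
        noise_half_width=config.noise_half_width,
        gossip_count=k,
        pair_selection=pair_selection,
        n_iterations=config.effective_horizon(sigma_small),
        measure_every=config.effective_cadence(sigma_small),
    )


def two_group_sweep(config: SweepConfig, *, engine: str = "numba") -> SweepResult:
    """Equal-group sweep over (sigma_small grid) x (sigma_L relations).

    Per cell: stationary group summaries per replica, pooled occupancy and
    advancement tables, and the glass-ceiling rank.  A failed replica is
    recorded as a flagged row, never silently dropped.
    """
    n_small = config.n_agents // 2
    summary_rows, occ_frames, adv_frames, gc_rows, rank_frames = [], [], [], [], []
    cell_index = 0
    for sigma_small in config.sigma_small_grid:
        for relation in config.relations:
            sigma_large = sigma_relation(sigma_small, relation)
            cell_seed = config.base_seed + cell_index * config.effective_replicas
            cell_index += 1
            params = _two_group_params(config, sigma_small, sigma_large, n_small,
                                       config.gossip_count)
            meta = _cell_meta("two_group", sigma_small, sigma_large, relation,
                              n_small, config.gossip_count, cell_seed)
            series_list = []
            for r in range(config.effective_replicas):
                try:
                    series_list.extend(
                        run_replicas(params, 1, cell_seed + r, engine=engine,
                                     stationary_window=config.stationary_window)
                    )
                    series_list[-1].replica_id = r
                except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                    logger.error("replica %d of cell %s failed: %s", r, meta, exc)
                    summary_rows.append(
                        {**meta, "replica": r, "group": "NA", "failed": True}
                    )
            for series in series_list:
                for row in _stationary_group_summary(series):
                    summary_rows.append(
                        {**meta, "replica": series.replica_id, "failed": False, **row}
                    )
            if not series_list:
                continue
            occ = occupancy_probability(series_list)
            adv = advancement_probability(series_list)
            rnk = ranks_frame(series_list)
            for df, acc in ((occ, occ_frames), (adv, adv_frames), (rnk, rank_frames)):
                for key, val in meta.items():
                    df[key] = val
                acc.append(df)
            gc_rows.append(
                {
                    **meta,
                    "glass_ceiling_rank": glass_ceiling_rank(series_list),
                    "best_rank_attained": best_rank_attained(series_list),
                }
            )
    return SweepResult(
        summary=pd.DataFrame(summary_rows),
        ranks=pd.concat(rank_frames, ignore_index=True) if rank_frames else pd.DataFrame(),
        occupancy=pd.concat(occ_frames, ignore_index=True) if occ_frames else pd.DataFrame(),
        advancement=pd.concat(adv_frames, ignore_index=True) if adv_frames else pd.DataFrame(),
        glass_ceiling=pd.DataFrame(gc_rows),
    )


def group_size_sweep(
    config: SweepConfig,
    *,
    engine: str = "numba",
    pair_selection: str = "uniform",
) -> SweepResult:
    """Sweep over group split x sigma grid x gossip count.

    Emits top-5 and bottom-5 extreme-rank Z-scores for the L-group per
    cell.  Cells where one group is empty carry no Z-score rows (the null
    is degenerate there).

    Partners are drawn uniformly from all other agents by default: with
    unequal groups the same-group-coin rule makes minority agents
    interact more often per capita, which distorts the hierarchy the
    sweep measures (see the methods note); pass
    ``pair_selection='group-coin'`` to use the coin rule anyway.
    """
    z_rows, summary_rows = [], []
    cell_index = 0
    for n_small in config.n_small_grid:
        for sigma_small in config.sigma_small_grid:
            for relation in config.relations:
                sigma_large = sigma_relation(sigma_small, relation)
                for k in config.gossip_grid:
                    cell_seed = (
                        config.base_seed + cell_index * config.effective_replicas
                    )
                    cell_index += 1
                    params = _two_group_params(
                        config, sigma_small, sigma_large, n_small, k,
                        pair_selection=pair_selection,
                    )
                    meta = _cell_meta("size_sweep", sigma_small, sigma_large,
                                      relation, n_small, k, cell_seed)
                    series_list = run_replicas(
                        params, config.effective_replicas, cell_seed,
                        engine=engine, stationary_window=config.stationary_window,
                    )
                    for series in series_list:
                        for row in _stationary_group_summary(series):
                            summary_rows.append(
                                {**meta, "replica": series.replica_id, **row}
                            )
                    if n_small in (0, config.n_agents):
                        continue  # Z-score null degenerate: skip, nothing emitted
                    for side in ("top", "bottom"):
                        z_rows.append(
                            {
                                **meta,
                                "side": side,
                                "zscore": extreme_rank_zscore(
                                    series_list, n_extreme=5, side=side
                                ),
                            }
                        )
    return SweepResult(summary=pd.DataFrame(summary_rows), zscores=pd.DataFrame(z_rows))
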