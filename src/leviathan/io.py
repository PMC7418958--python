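"""Serialization: CSV/NPZ outputs and run manifests with content digests.

Floats in CSVs are written at 10 significant digits so that digests are
stable across platforms for a fixed seed while staying well inside test
tolerances.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SnapshotSeries
from .experiments import SweepResult
from .params import ModelParams

FLOAT_FORMAT = "%.10g"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(params: ModelParams) -> dict:
    d = dataclasses.asdict(params)
    d["esteem_bounds"] = list(d["esteem_bounds"])
    return d


@dataclass
class RunManifest:
    """Inventory of one run's outputs: config echo, seeds, digests."""

    config: dict
    seeds: list[int]
    version: str
    started: str
    finished: str
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    def verify(self) -> bool:
        return all(
            Path(p).exists() and _digest(Path(p)) == d for p, d in self.files.items()
        )


def series_to_long_frame(series: SnapshotSeries) -> pd.DataFrame:
    """Esteem matrices as a long table: replica, t, i, j, esteem."""
    n = series.params.n_agents
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    frames = []
    for s in range(series.n_snapshots):
        frames.append(
            pd.DataFrame(
                {
                    "replica": series.replica_id,
                    "t": int(series.times[s]),
                    "i": ii.ravel(),
                    "j": jj.ravel(),
                    "esteem": series.snapshots[s].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def save_series_npz(series: SnapshotSeries, path: str | Path) -> Path:
    """Raw snapshots in a compressed array container."""
    path = Path(path)
    np.savez_compressed(
        path,
        times=series.times,
        snapshots=series.snapshots,
        labels=series.groups.labels,
        replica_id=np.int64(series.replica_id),
        seed=np.int64(series.params.seed),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_series_npz(path: str | Path, params: ModelParams) -> SnapshotSeries:
    from .params import GroupAssignment

    with np.load(path, allow_pickle=False) as data:
        labels = data["labels"].astype("<U1")
        sigma = np.where(labels == "S", params.sigma_small, params.sigma_large)
        return SnapshotSeries(
            params=params.with_seed(int(data["seed"])),
            groups=GroupAssignment(labels=labels, sigma=sigma.astype(np.float64)),
            times=data["times"],
            snapshots=data["snapshots"],
            replica_id=int(data["replica_id"]),
        )


def write_outputs(
    obj: SnapshotSeries | SweepResult | dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: ModelParams | dict | None = None,
    seeds: list[int] | None = None,
    snapshot_format: str = "npz",
) -> RunManifest:
    """Write tables/snapshots under ``out_dir`` and return the manifest.

    SnapshotSeries are written either as a compressed array container
    (``snapshot_format='npz'``) or a long-format CSV (``'csv'``);
    SweepResult tables and plain dicts of DataFrames become one CSV each.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    written: list[Path] = []

    if isinstance(obj, SnapshotSeries):
        if config is None:
            config = obj.params
        if seeds is None:
            seeds = [obj.params.seed]
        if snapshot_format == "npz":
            path = out_dir / f"snapshots_replica{obj.replica_id}.npz"
            save_series_npz(obj, path)
        elif snapshot_format == "csv":
            path = out_dir / f"snapshots_replica{obj.replica_id}.csv"
            series_to_long_frame(obj).to_csv(
                path, index=False, float_format=FLOAT_FORMAT
            )
        else:
            raise ValueError(f"unknown snapshot_format {snapshot_format!r}")
        written.append(path)
    else:
        tables = obj.tables() if isinstance(obj, SweepResult) else obj
        for name, df in tables.items():
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            written.append(path)

    if isinstance(config, ModelParams):
        config = _params_dict(config)
    manifest = RunManifest(
        config=config or {},
        seeds=list(seeds or []),
        version=__version__,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        files={str(p): _digest(p) for p in written},
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
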