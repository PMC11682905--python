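"""Result serialization: trajectory CSVs, trial tables, run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .config import ScenarioConfig, config_hash
from .dynamics import Trajectory


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    return path


def write_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_summary(summary: Mapping, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return path


def write_manifest(out_dir, config: Optional[ScenarioConfig] = None,
                   seed: Optional[int] = None,
                   rtol: float = 1e-6, atol: float = 1e-3,
                   extra: Optional[Mapping] = None) -> Path:
    """JSON run manifest: configuration, its hash, seed, tolerances, version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "rtol": rtol,
        "atol": atol,
    }
    if config is not None:
        manifest["config"] = json.loads(config.model_dump_json())
        manifest["config_sha256"] = config_hash(config)
    if extra:
        manifest.update(dict(extra))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_run(out_dir, trajectories: Mapping[str, Trajectory],
              config: Optional[ScenarioConfig] = None,
              seed: Optional[int] = None) -> Path:
    """Write a full scenario run (one CSV per trajectory plus manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, traj in trajectories.items():
        write_trajectory(traj, out_dir / f"trajectory_{name}.csv")
    write_manifest(out_dir, config=config, seed=seed)
    return out_dir
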