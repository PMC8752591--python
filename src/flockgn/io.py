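"""File formats: run configs (JSON), configuration snapshots (CSV),
metrics tables (CSV), trajectory containers (NPZ), and run records.

Floats are serialized with shortest round-trip representation, so a CSV
written and read back reproduces positions and angles bit for bit.
"""

from __future__ import annotations

import json
import platform
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .vicsek import ParticleConfiguration, SimulationConfig, Trajectory

FORMAT_VERSION = 1

__all__ = [
    "load_config",
    "save_config",
    "read_configuration_csv",
    "write_configuration_csv",
    "write_metrics_csv",
    "save_trajectory",
    "load_trajectory",
    "write_run_record",
]


def save_config(config: SimulationConfig, path):
    d = dict(
        format_version=FORMAT_VERSION,
        n_particles=config.n_particles,
        box_side=config.box_side,
        speed=config.speed,
        radius=config.radius,
        noise=config.noise,
        dt=config.dt,
        n_steps=config.n_steps,
        seed=config.seed,
    )
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_config(path) -> SimulationConfig:
    d = json.loads(Path(path).read_text())
    d.pop("format_version", None)
    return SimulationConfig(**d)


def write_configuration_csv(cfg: ParticleConfiguration, path):
    """Snapshot as `x,y,theta` rows at full float precision."""
    with open(path, "w") as fh:
        fh.write("x,y,theta\n")
        for (x, y), th in zip(cfg.positions, cfg.angles):
            fh.write(f"{float(x)!r},{float(y)!r},{float(th)!r}\n")


def read_configuration_csv(path) -> ParticleConfiguration:
    df = pd.read_csv(path, float_precision="round_trip")
    return ParticleConfiguration(df[["x", "y"]].to_numpy(), df["theta"].to_numpy())


def write_metrics_csv(metrics: pd.DataFrame, path):
    """Per-step metrics table: step, va and optionally k."""
    metrics.to_csv(path, index=False)


def save_trajectory(traj: Trajectory, path):
    """Chunked container: one positions/angles array per recorded snapshot."""
    arrays = {}
    for i, cfg in enumerate(traj.configs):
        arrays[f"positions_{i}"] = cfg.positions
        arrays[f"angles_{i}"] = cfg.angles
    meta = dict(
        format_version=FORMAT_VERSION,
        n_snapshots=len(traj.configs),
        record_every=traj.record_every,
        n_degenerate=traj.n_degenerate,
        config=dict(
            n_particles=traj.config.n_particles,
            box_side=traj.config.box_side,
            speed=traj.config.speed,
            radius=traj.config.radius,
            noise=traj.config.noise,
            dt=traj.config.dt,
            n_steps=traj.config.n_steps,
            seed=traj.config.seed,
        ),
    )
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    arrays["metrics_step"] = traj.metrics["step"].to_numpy()
    arrays["metrics_va"] = traj.metrics["va"].to_numpy()
    np.savez_compressed(path, **arrays)


def load_trajectory(path) -> Trajectory:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        configs = [
            ParticleConfiguration(data[f"positions_{i}"], data[f"angles_{i}"])
            for i in range(meta["n_snapshots"])
        ]
        metrics = pd.DataFrame({"step": data["metrics_step"], "va": data["metrics_va"]})
    return Trajectory(
        configs=configs,
        metrics=metrics,
        config=SimulationConfig(**meta["config"]),
        n_degenerate=meta["n_degenerate"],
        record_every=meta["record_every"],
    )


def write_run_record(out_dir, command: str, config: dict, seed, outputs, status: str = "ok"):
    """Provenance record emitted next to every artifact-producing command."""
    from . import __version__

    rec = dict(
        format_version=FORMAT_VERSION,
        command=command,
        config=config,
        seed=seed,
        outputs=[str(o) for o in outputs],
        status=status,
        version=__version__,
        python=sys.version.split()[0],
        platform=platform.platform(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = Path(out_dir) / "run_record.json"
    path.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    return path
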