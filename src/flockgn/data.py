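"""Dataset construction for order-parameter regression.

Per noise point, independent Vicsek runs from distinct seeds (disjoint
train/test seed pools) are executed to steady state; snapshots along each
run are stored with their step index, total run length, v_a, and (optionally)
the cluster order parameter k with the seed used to compute it.  Every
stored target is recomputable from its stored configuration.

The full-scale protocol is N=4000 at density rho=4 (L=31.6), speed 0.03,
noise grid {0.1, 1.5, 2.5, 3.5, 5}, 100 train + 100 test runs per noise
point; :func:`fixture_manifest` provides a desk-scale variant for tests.

Augmentation is restricted to exact symmetries of the periodic square —
periodic translations, quarter-turn rotations, and reflection — which
preserve v_a, pairwise periodic distances, and hence the cluster structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import cluster
from .graph import GraphSample, configuration_to_graph
from .vicsek import ParticleConfiguration, SimulationConfig, run, wrap_angle

__all__ = [
    "DatasetManifest",
    "Sample",
    "Dataset",
    "paper_manifest",
    "fixture_manifest",
    "build_dataset",
    "translate",
    "rotate90",
    "reflect",
    "augment",
]

FORMAT_VERSION = 1

# seed pools: train seeds are even offsets, test seeds odd — disjoint by parity
_TRAIN_POOL, _TEST_POOL = 0, 1


@dataclass(frozen=True)
class DatasetManifest:
    noise_points: tuple
    n_train: int
    n_test: int
    sim: SimulationConfig  # template; noise and seed overridden per run
    snapshots_per_run: int = 5  # snapshots sampled evenly over each run
    compute_k: bool = False
    n_augment: int = 0  # extra augmented copies per training snapshot
    base_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "noise_points", tuple(float(x) for x in self.noise_points))
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("need n_train >= 1 and n_test >= 0")
        if self.snapshots_per_run < 1:
            raise ValueError("snapshots_per_run must be >= 1")

    def run_seed(self, noise_index: int, rep: int, pool: int) -> int:
        # disjoint by parity between the train and test pools
        return self.base_seed + 2 * (10_000 * noise_index + rep) + pool

    def to_json(self) -> str:
        d = asdict(self)
        d["format_version"] = FORMAT_VERSION
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        d.pop("format_version", None)
        d["sim"] = SimulationConfig(**d["sim"])
        return cls(**d)


@dataclass
class Sample:
    """One supervised example: a configuration plus its order parameters."""

    positions: np.ndarray
    angles: np.ndarray
    noise: float
    step: int
    n_steps_total: int
    va: float
    k: int | None = None
    k_seed: int | None = None
    run_seed: int = 0
    augmented: bool = False

    @property
    def time_frac(self) -> float:
        return self.step / max(self.n_steps_total, 1)

    def configuration(self) -> ParticleConfiguration:
        return ParticleConfiguration(self.positions.copy(), self.angles.copy())

    def to_graph(self, radius: float, box_side: float, mode: str = "va") -> GraphSample:
        target = self.va if mode == "va" else float(self.k)
        return configuration_to_graph(
            self.configuration(), radius, box_side, target=target, time_frac=self.time_frac
        )


@dataclass
class Dataset:
    manifest: DatasetManifest
    train: list = field(default_factory=list)  # of Sample
    test: list = field(default_factory=list)

    def to_graphs(self, split: str = "train", mode: str = "va"):
        sim = self.manifest.sim
        return [
            s.to_graph(sim.radius, sim.box_side, mode=mode)
            for s in getattr(self, split)
        ]

    def save(self, path):
        """Single .npz with stacked per-sample arrays plus the JSON manifest."""
        arrays = {}
        for split in ("train", "test"):
            samples = getattr(self, split)
            for i, s in enumerate(samples):
                arrays[f"{split}.{i}.positions"] = s.positions
                arrays[f"{split}.{i}.angles"] = s.angles
                meta = [s.noise, s.step, s.n_steps_total, s.va,
                        -1 if s.k is None else s.k,
                        -1 if s.k_seed is None else s.k_seed,
                        s.run_seed, int(s.augmented)]
                arrays[f"{split}.{i}.meta"] = np.array(meta, dtype=float)
        arrays["__manifest__"] = np.frombuffer(self.manifest.to_json().encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "Dataset":
        with np.load(path) as data:
            manifest = DatasetManifest.from_json(bytes(data["__manifest__"].tobytes()).decode())
            splits = {"train": {}, "test": {}}
            for key in data.files:
                if key == "__manifest__":
                    continue
                split, idx, kind = key.split(".", 2)
                splits[split].setdefault(int(idx), {})[kind] = data[key]
            ds = cls(manifest=manifest)
            for split, items in splits.items():
                out = getattr(ds, split)
                for idx in sorted(items):
                    rec = items[idx]
                    m = rec["meta"]
                    out.append(
                        Sample(
                            positions=rec["positions"],
                            angles=rec["angles"],
                            noise=float(m[0]),
                            step=int(m[1]),
                            n_steps_total=int(m[2]),
                            va=float(m[3]),
                            k=None if m[4] < 0 else int(m[4]),
                            k_seed=None if m[5] < 0 else int(m[5]),
                            run_seed=int(m[6]),
                            augmented=bool(m[7]),
                        )
                    )
        return ds


def paper_manifest(base_seed: int = 0, compute_k: bool = False) -> DatasetManifest:
    """The full-scale protocol: N=4000, rho=4, five noise points, 100+100 runs."""
    return DatasetManifest(
        noise_points=(0.1, 1.5, 2.5, 3.5, 5.0),
        n_train=100,
        n_test=100,
        sim=SimulationConfig(n_particles=4000, box_side=31.6, speed=0.03, n_steps=3000),
        snapshots_per_run=5,
        compute_k=compute_k,
        base_seed=base_seed,
    )


def fixture_manifest(
    n_particles: int = 100,
    noise_points=(0.1, 3.5),
    n_train: int = 20,
    n_test: int = 10,
    n_steps: int = 400,
    compute_k: bool = False,
    base_seed: int = 0,
    snapshots_per_run: int = 2,
) -> DatasetManifest:
    """Desk-scale dataset at the full protocol's density rho=4."""
    box = float(np.sqrt(n_particles / 4.0))
    return DatasetManifest(
        noise_points=tuple(noise_points),
        n_train=n_train,
        n_test=n_test,
        sim=SimulationConfig(n_particles=n_particles, box_side=box, speed=0.03, n_steps=n_steps),
        snapshots_per_run=snapshots_per_run,
        compute_k=compute_k,
        base_seed=base_seed,
    )


def build_dataset(manifest: DatasetManifest, rng: np.random.Generator | None = None) -> Dataset:
    """Run the simulation protocol and collect supervised samples.

    Runs stop at the steady-state criterion (capped at the template's
    n_steps); ``snapshots_per_run`` snapshots are sampled evenly over each
    run, always including the final step.
    """
    if rng is None:
        rng = np.random.default_rng(manifest.base_seed)
    ds = Dataset(manifest=manifest)
    for ni, eta in enumerate(manifest.noise_points):
        for split, n_runs, pool in (
            ("train", manifest.n_train, _TRAIN_POOL),
            ("test", manifest.n_test, _TEST_POOL),
        ):
            out = getattr(ds, split)
            for rep in range(n_runs):
                seed = manifest.run_seed(ni, rep, pool)
                sim = manifest.sim.replace(noise=eta, seed=seed)
                traj = run(sim, stop_at_steady=True, record_every=1)
                total = int(traj.metrics["step"].iloc[-1])
                snap_steps = np.unique(
                    np.linspace(
                        max(1, total // manifest.snapshots_per_run),
                        total,
                        manifest.snapshots_per_run,
                    ).astype(int)
                )
                for t in snap_steps:
                    cfg = traj.configs[t]
                    va = float(traj.metrics["va"].iloc[t])
                    k = k_seed = None
                    if manifest.compute_k:
                        k_seed = seed + int(t)
                        k = cluster.cluster_order_parameter(cfg, sim.speed, seed=k_seed)
                    sample = Sample(
                        positions=cfg.positions.copy(),
                        angles=cfg.angles.copy(),
                        noise=eta,
                        step=int(t),
                        n_steps_total=total,
                        va=va,
                        k=k,
                        k_seed=k_seed,
                        run_seed=seed,
                    )
                    out.append(sample)
                    if split == "train":
                        for _ in range(manifest.n_augment):
                            out.append(augment(sample, rng, box_side=sim.box_side))
    return ds


# ---------------------------------------------------------------------------
# label-preserving symmetries of the periodic square

def translate(sample: Sample, shift, box_side: float) -> Sample:
    """Periodic translation of all positions; headings unchanged."""
    pos = np.mod(sample.positions + np.asarray(shift, dtype=float), box_side)
    return _derived(sample, pos, sample.angles.copy())


def rotate90(sample: Sample, times: int, box_side: float) -> Sample:
    """Rotate the box content by `times` quarter turns about the box center."""
    pos = sample.positions.copy()
    ang = sample.angles.copy()
    for _ in range(times % 4):
        # (x, y) -> (L - y, x) maps [0, L)^2 onto itself (90 deg CCW)
        pos = np.column_stack([box_side - pos[:, 1], pos[:, 0]])
        pos = np.mod(pos, box_side)
        ang = ang + np.pi / 2.0
    return _derived(sample, pos, wrap_angle(ang))


def reflect(sample: Sample, box_side: float) -> Sample:
    """Mirror about the vertical box axis: x -> L - x, theta -> pi - theta."""
    pos = np.column_stack([np.mod(box_side - sample.positions[:, 0], box_side), sample.positions[:, 1]])
    return _derived(sample, pos, wrap_angle(np.pi - sample.angles))


def augment(sample: Sample, rng: np.random.Generator, box_side: float) -> Sample:
    """Random composition of translation, quarter-turn rotation, reflection."""
    s = translate(sample, rng.uniform(0, box_side, size=2), box_side)
    s = rotate90(s, int(rng.integers(0, 4)), box_side)
    if rng.integers(0, 2):
        s = reflect(s, box_side)
    return s


def _derived(sample: Sample, pos, ang) -> Sample:
    return Sample(
        positions=pos,
        angles=ang,
        noise=sample.noise,
        step=sample.step,
        n_steps_total=sample.n_steps_total,
        va=sample.va,
        k=sample.k,
        k_seed=sample.k_seed,
        run_seed=sample.run_seed,
        augmented=True,
    )
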