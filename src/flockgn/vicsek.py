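"""Vicsek model of self-propelled particles on a two-dimensional periodic box.

Point particles move at a common constant speed ``v``.  At every time step
each particle adopts the mean heading of all particles within a field-of-view
radius ``r`` (itself included) plus an angular perturbation drawn uniformly
from ``[-eta/2, eta/2]``.  The classic order parameter

    v_a = |sum_i v_i| / (N v)

measures global alignment: 1 when every particle moves in the same
direction, ~0 for a disordered collective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ParticleConfiguration",
    "Trajectory",
    "wrap_angle",
    "periodic_displacement",
    "init_configuration",
    "neighbor_pairs",
    "neighbors",
    "mean_direction",
    "order_parameter_va",
    "step",
    "run",
    "sweep_noise",
    "sweep_density",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles to the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Vicsek run.

    ``noise`` is the full width (radians) of the uniform interval from which
    the per-step angular perturbation is drawn.  The particle density
    ``rho = N / L**2`` follows from ``n_particles`` and ``box_side``.
    """

    n_particles: int
    box_side: float
    speed: float = 0.03
    radius: float = 1.0
    noise: float = 0.0
    dt: float = 1.0
    n_steps: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("n_particles must be a positive integer")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        # minimum-image convention is ambiguous for r > L/2
        if self.radius > self.box_side / 2.0:
            raise ValueError(
                f"radius {self.radius} exceeds box_side/2 = {self.box_side / 2.0}"
            )
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    @property
    def density(self) -> float:
        return self.n_particles / self.box_side**2

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class ParticleConfiguration:
    """Snapshot of the collective: positions in [0, L)^2 and headings in [-pi, pi)."""

    positions: np.ndarray  # (N, 2)
    angles: np.ndarray  # (N,)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if self.angles.shape != (self.positions.shape[0],):
            raise ValueError("angles must be a length-N vector")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleConfiguration":
        return ParticleConfiguration(self.positions.copy(), self.angles.copy())


@dataclass
class Trajectory:
    """Recorded output of :func:`run`."""

    configs: list  # ParticleConfiguration snapshots (every `record_every` steps)
    metrics: pd.DataFrame  # one row per step: step, va
    config: SimulationConfig
    n_degenerate: int = 0  # zero-vector neighborhood events encountered
    record_every: int = 1

    @property
    def final(self) -> ParticleConfiguration:
        return self.configs[-1]

    def steady_va(self, window: int = 50) -> float:
        """Mean v_a over the trailing `window` recorded steps."""
        return float(self.metrics["va"].iloc[-window:].mean())


def init_configuration(config: SimulationConfig, rng: np.random.Generator) -> ParticleConfiguration:
    """Positions i.i.d. uniform over the box; headings i.i.d. uniform over [-pi, pi)."""
    pos = rng.uniform(0.0, config.box_side, size=(config.n_particles, 2))
    ang = rng.uniform(-np.pi, np.pi, size=config.n_particles)
    return ParticleConfiguration(pos, ang)


def periodic_displacement(a, b, box_side: float):
    """Minimum-image displacement b - a, each component in [-L/2, L/2)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return np.mod(d + box_side / 2.0, box_side) - box_side / 2.0


def neighbor_pairs(positions: np.ndarray, radius: float, box_side: float) -> np.ndarray:
    """All unordered pairs (i < j) at periodic distance strictly less than `radius`.

    Uses a periodic k-d tree; pairs at distance exactly `radius` are removed
    to keep the strict-inequality convention.
    """
    if radius > box_side / 2.0:
        raise ValueError("radius must not exceed box_side / 2")
    tree = cKDTree(positions, boxsize=box_side)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        d = periodic_displacement(positions[pairs[:, 0]], positions[pairs[:, 1]], box_side)
        dist = np.hypot(d[:, 0], d[:, 1])
        pairs = pairs[dist < radius]
    return pairs.reshape(-1, 2)


def neighbors(cfg: ParticleConfiguration, radius: float, box_side: float) -> list:
    """Per-particle neighbor index lists (periodic distance < radius, self included)."""
    pairs = neighbor_pairs(cfg.positions, radius, box_side)
    out = [[i] for i in range(cfg.n)]
    for i, j in pairs:
        out[i].append(j)
        out[j].append(i)
    return [np.sort(np.array(lst)) for lst in out]


def mean_direction(angles) -> float:
    """Quadrant-correct mean heading of a neighborhood.

    The angle of the summed unit vectors, via the two-argument arctangent of
    (sum sin, sum cos); a naive arctangent of the ratio would lose the
    quadrant.  Returns 0 for the degenerate case of an exactly zero vector sum.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("mean_direction of an empty neighborhood")
    s = np.sin(angles).sum()
    c = np.cos(angles).sum()
    # exact cancellation up to float rounding of the unit-vector sum
    if np.hypot(s, c) <= 1e-9:
        logger.warning("degenerate neighborhood: zero vector sum, returning 0")
        return 0.0
    return float(wrap_angle(np.arctan2(s, c)))


def order_parameter_va(cfg: ParticleConfiguration, speed: float) -> float:
    """Alignment order parameter v_a = |sum_i v_i| / (N v), in [0, 1]."""
    if speed <= 0:
        raise ValueError("speed must be strictly positive for v_a")
    sx = np.cos(cfg.angles).mean()
    sy = np.sin(cfg.angles).mean()
    return float(np.hypot(sx, sy))


def _neighbor_mean_angles(cfg: ParticleConfiguration, radius: float, box_side: float):
    """Vectorized neighborhood mean heading for every particle.

    Returns (mean_angles, n_degenerate).  Each particle is included in its own
    neighborhood, so the vector sum is zero only in contrived cancellations.
    """
    s = np.sin(cfg.angles)
    c = np.cos(cfg.angles)
    S = s.copy()
    C = c.copy()
    pairs = neighbor_pairs(cfg.positions, radius, box_side)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(S, i, s[j])
        np.add.at(S, j, s[i])
        np.add.at(C, i, c[j])
        np.add.at(C, j, c[i])
    degenerate = np.hypot(S, C) <= 1e-9
    n_deg = int(degenerate.sum())
    mean = np.arctan2(S, C)
    mean[degenerate] = 0.0
    return wrap_angle(mean), n_deg


def step(cfg: ParticleConfiguration, config: SimulationConfig, rng: np.random.Generator):
    """One synchronous update of the whole collective.

    Positions advance with the time-t headings (the backward-update variant);
    new headings are the neighborhood mean of the time-t headings plus a
    uniform perturbation from [-eta/2, eta/2].

    Returns (new_configuration, n_degenerate_neighborhoods).
    """
    L = config.box_side
    mean_ang, n_deg = _neighbor_mean_angles(cfg, config.radius, L)
    dtheta = rng.uniform(-config.noise / 2.0, config.noise / 2.0, size=cfg.n)
    new_angles = wrap_angle(mean_ang + dtheta)
    disp = config.speed * config.dt
    new_pos = cfg.positions + disp * np.column_stack([np.cos(cfg.angles), np.sin(cfg.angles)])
    new_pos = np.mod(new_pos, L)
    return ParticleConfiguration(new_pos, new_angles), n_deg


def run(
    config: SimulationConfig,
    *,
    initial: ParticleConfiguration | None = None,
    rng: np.random.Generator | None = None,
    stop_at_steady: bool = False,
    steady_window: int = 50,
    steady_tol: float = 1e-3,
    steady_consecutive: int = 3,
    steady_burn_in: int | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Run the simulation for up to ``config.n_steps`` synchronous steps.

    ``stop_at_steady`` enables an early stop once the running mean of v_a
    over a ``steady_window``-step window has changed by less than
    ``steady_tol`` between ``steady_consecutive`` consecutive window
    comparisons, after a burn-in of ``steady_burn_in`` steps (default: 10
    windows).  Requiring several consecutive flat windows after a burn-in
    avoids stopping inside the early transient plateau, where a single
    window comparison can be flat by chance while v_a is still ordering.
    ``config.n_steps`` is a hard cap either way.  ``record_every=0`` keeps
    only the initial and final snapshots (memory saver for large N); the
    per-step v_a metric is always complete.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = init_configuration(config, rng) if initial is None else initial.copy()
    va = order_parameter_va(cfg, config.speed) if config.speed > 0 else np.nan
    configs = [cfg.copy()]
    steps = [0]
    vas = [va]
    n_deg_total = 0
    prev_window_mean = None
    n_flat = 0
    if steady_burn_in is None:
        steady_burn_in = 10 * steady_window
    for t in range(1, config.n_steps + 1):
        cfg, n_deg = step(cfg, config, rng)
        n_deg_total += n_deg
        vas.append(order_parameter_va(cfg, config.speed) if config.speed > 0 else np.nan)
        steps.append(t)
        if record_every and t % record_every == 0:
            configs.append(cfg.copy())
        if stop_at_steady and t % steady_window == 0:
            window_mean = float(np.mean(vas[-steady_window:]))
            if prev_window_mean is not None and abs(window_mean - prev_window_mean) < steady_tol:
                n_flat += 1
            else:
                n_flat = 0
            prev_window_mean = window_mean
            if t >= steady_burn_in and n_flat >= steady_consecutive:
                break
    if configs[-1] is not cfg and not np.array_equal(configs[-1].positions, cfg.positions):
        configs.append(cfg.copy())
    metrics = pd.DataFrame({"step": steps, "va": vas})
    return Trajectory(
        configs=configs,
        metrics=metrics,
        config=config,
        n_degenerate=n_deg_total,
        record_every=record_every,
    )


def _steady_stats(
    config: SimulationConfig,
    seeds,
    *,
    window: int = 50,
    compute_k: bool = False,
    k_snapshots: int = 1,
    speed_for_k: float | None = None,
):
    """Steady-state v_a (trailing-window mean) and optional k over `seeds` runs.

    When k is requested the run goes to the full step cap: the spatial
    cluster structure coarsens on the box-crossing timescale L/(v dt), which
    the v_a-based steadiness rule does not resolve — v_a can be flat while
    co-moving clusters are still merging.
    """
    from . import cluster  # local import: cluster depends on this module

    va_vals, k_vals = [], []
    for seed in seeds:
        traj = run(
            config.replace(seed=int(seed)),
            stop_at_steady=not compute_k,
            steady_window=window,
            record_every=window if compute_k and k_snapshots > 1 else 0,
        )
        va_vals.append(traj.steady_va(window))
        if compute_k:
            speed = config.speed if speed_for_k is None else speed_for_k
            snaps = traj.configs[1:][-k_snapshots:] or [traj.configs[-1]]
            ks = [
                cluster.cluster_order_parameter(cfg, speed, seed=int(seed) + si)
                for si, cfg in enumerate(snaps)
            ]
            k_vals.append(float(np.mean(ks)))
    return va_vals, k_vals


def sweep_noise(
    template: SimulationConfig,
    noise_values,
    reps: int,
    *,
    base_seed: int = 0,
    compute_k: bool = False,
    window: int = 50,
) -> pd.DataFrame:
    """Steady-state order parameters across a noise grid at fixed density.

    For every noise value, `reps` independent runs from distinct seeds; v_a is
    averaged over the trailing `window` steps of each run, then over runs.
    """
    rows = []
    for gi, eta in enumerate(noise_values):
        seeds = [base_seed + 1000 * gi + r for r in range(reps)]
        va_vals, k_vals = _steady_stats(
            template.replace(noise=float(eta)), seeds, window=window, compute_k=compute_k
        )
        row = {
            "noise": float(eta),
            "va_mean": float(np.mean(va_vals)),
            "va_std": float(np.std(va_vals)),
        }
        if compute_k:
            row["k_mean"] = float(np.mean(k_vals))
            row["k_std"] = float(np.std(k_vals))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_density(
    template: SimulationConfig,
    density_values,
    reps: int,
    *,
    base_seed: int = 0,
    compute_k: bool = False,
    window: int = 50,
) -> pd.DataFrame:
    """Steady-state order parameters across a density grid at fixed box side.

    Density is varied by varying N at the template's box_side.
    """
    rows = []
    for gi, rho in enumerate(density_values):
        n = max(4, int(round(float(rho) * template.box_side**2)))
        seeds = [base_seed + 1000 * gi + r for r in range(reps)]
        va_vals, k_vals = _steady_stats(
            template.replace(n_particles=n), seeds, window=window, compute_k=compute_k
        )
        row = {
            "density": float(rho),
            "n_particles": n,
            "va_mean": float(np.mean(va_vals)),
            "va_std": float(np.std(va_vals)),
        }
        if compute_k:
            row["k_mean"] = float(np.mean(k_vals))
            row["k_std"] = float(np.std(k_vals))
        rows.append(row)
    return pd.DataFrame(rows)
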