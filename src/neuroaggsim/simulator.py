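"""Culture initialization, time stepping and parameter sweeps.

A simulation lives inside a hard confinement: a linear slit (length x width
footprint) or a disk (given diameter), with a floor at z = 0 and no ceiling.
Cells are seeded uniformly at random with a minimum spacing, a fraction are
labeled astrocytes, and fixed surface-adhesion anchor points are scattered
on the floor.  Each step computes net forces, displaces every cell by
``k(t) * F`` (minus gravity on z) and clamps positions back into the
confinement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _engine, model_core
from .model_core import CellType, ForceParameters, StiffnessSchedule

__all__ = [
    "ConfinementKind",
    "Confinement",
    "CellPopulation",
    "AnchorField",
    "SimulationConfig",
    "Trajectory",
    "initialize_culture",
    "step",
    "run",
    "sweep",
]


class ConfinementKind(str, enum.Enum):
    SLIT = "slit"
    DISK = "disk"


@dataclass(frozen=True)
class Confinement:
    """Hard-walled culture region.

    Slit: footprint ``[0, length] x [0, width]``, origin at a slit corner.
    Disk: footprint of the given ``diameter`` centered on the origin.
    ``height`` is only the initial seeding height — there is no ceiling.
    """

    kind: ConfinementKind = ConfinementKind.SLIT
    length: float = 4000.0
    width: float = 200.0
    diameter: float = 400.0
    height: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "kind", ConfinementKind(self.kind))
        dims = (
            (self.length, self.width, self.height)
            if self.kind is ConfinementKind.SLIT
            else (self.diameter, self.height)
        )
        if any(v <= 0 for v in dims):
            raise ValueError("confinement dimensions must be > 0")

    @property
    def floor_area(self) -> float:
        if self.kind is ConfinementKind.SLIT:
            return self.length * self.width
        return math.pi * (self.diameter / 2.0) ** 2

    @property
    def seeding_volume(self) -> float:
        return self.floor_area * self.height

    def contains_xy(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        if self.kind is ConfinementKind.SLIT:
            return (
                (xy[:, 0] >= 0)
                & (xy[:, 0] <= self.length)
                & (xy[:, 1] >= 0)
                & (xy[:, 1] <= self.width)
            )
        return np.hypot(xy[:, 0], xy[:, 1]) <= self.diameter / 2.0

    def sample_xy(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n uniform points on the footprint."""
        if self.kind is ConfinementKind.SLIT:
            return rng.uniform((0, 0), (self.length, self.width), size=(n, 2))
        r = self.diameter / 2.0 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * math.pi, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        """Project positions back inside the walls and above the floor."""
        p = np.array(positions, dtype=float)
        if self.kind is ConfinementKind.SLIT:
            p[:, 0] = np.clip(p[:, 0], 0.0, self.length)
            p[:, 1] = np.clip(p[:, 1], 0.0, self.width)
        else:
            r = np.hypot(p[:, 0], p[:, 1])
            out = r > self.diameter / 2.0
            if out.any():
                scale = (self.diameter / 2.0) / r[out]
                p[out, 0] *= scale
                p[out, 1] *= scale
        p[:, 2] = np.maximum(p[:, 2], 0.0)
        return p

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "length": self.length,
            "width": self.width,
            "diameter": self.diameter,
            "height": self.height,
        }


@dataclass
class CellPopulation:
    """3D positions (um) and type labels of all mobile cells."""

    positions: np.ndarray
    types: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.types = np.asarray(self.types, dtype=int).reshape(-1)
        if len(self.positions) != len(self.types):
            raise ValueError("positions and types length mismatch")

    def __len__(self) -> int:
        return len(self.types)

    @property
    def neuron_mask(self) -> np.ndarray:
        return self.types == CellType.NEURON

    @property
    def astrocyte_mask(self) -> np.ndarray:
        return self.types == CellType.ASTROCYTE

    def copy(self) -> "CellPopulation":
        return CellPopulation(self.positions.copy(), self.types.copy())

    def to_frame(self, step: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.arange(len(self)),
                "type": np.where(self.neuron_mask, "neuron", "astrocyte"),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        )
        if step is not None:
            df.insert(0, "step", step)
        return df


@dataclass
class AnchorField:
    """Immobile surface-adhesion points on the z = 0 substrate plane."""

    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SimulationConfig:
    confinement: Confinement = field(default_factory=Confinement)
    cell_density: float = 1e-4  # cells/um^3
    astrocyte_fraction: float = 0.2
    min_cell_spacing: float = 10.0  # um
    anchor_density: float = 2e-3  # points/um^2
    min_anchor_spacing: float = 10.0  # um
    force_params: ForceParameters = field(default_factory=ForceParameters)
    schedule: StiffnessSchedule = field(default_factory=StiffnessSchedule)
    seed: int = 0
    snapshot_every: int = 0  # 0: first and last state only

    def __post_init__(self):
        if not 0.0 <= self.astrocyte_fraction <= 1.0:
            raise ValueError("astrocyte_fraction must lie in [0, 1]")
        if self.cell_density <= 0 or self.anchor_density <= 0:
            raise ValueError("densities must be > 0")


@dataclass
class Trajectory:
    """Timestamped snapshots of a run plus the anchors and config used."""

    config: SimulationConfig
    anchors: AnchorField
    steps: list[int]
    snapshots: list[CellPopulation]

    @property
    def initial(self) -> CellPopulation:
        return self.snapshots[0]

    @property
    def final(self) -> CellPopulation:
        return self.snapshots[-1]


def _sample_min_spacing(
    n: int,
    spacing: float,
    sampler,
    rng: np.random.Generator,
    max_attempts_per_point: int = 10_000,
) -> np.ndarray:
    """Rejection-sample n points (any dim) with pairwise spacing >= spacing.

    Uses a uniform grid hash of cell size ``spacing`` so each candidate only
    checks its neighborhood.
    """
    pts: list[np.ndarray] = []
    grid: dict[tuple, list[int]] = {}
    inv = 1.0 / spacing
    attempts = 0
    budget = max_attempts_per_point * max(n, 1)
    while len(pts) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"packing infeasible: placed {len(pts)}/{n} points "
                f"({len(pts) / n:.1%}) at spacing {spacing} um"
            )
        cand = sampler(rng)
        attempts += 1
        key = tuple(int(math.floor(c * inv)) for c in cand)
        ok = True
        for nb in _neighbor_keys(key):
            for idx in grid.get(nb, ()):
                if np.linalg.norm(cand - pts[idx]) < spacing:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(key, []).append(len(pts))
            pts.append(cand)
    return np.array(pts)


def _neighbor_keys(key: tuple) -> Iterable[tuple]:
    if len(key) == 2:
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                yield (key[0] + a, key[1] + b)
    else:
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                for c in (-1, 0, 1):
                    yield (key[0] + a, key[1] + b, key[2] + c)


def initialize_culture(config: SimulationConfig) -> tuple[CellPopulation, AnchorField]:
    """Random seeding of cells and anchors per the config densities.

    Cell count = round(density x seeding volume); anchor count =
    round(anchor density x floor area); both placed uniformly at random
    with their minimum pairwise spacings; the astrocyte subset is drawn
    uniformly.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    conf = config.confinement
    n_cells = int(round(config.cell_density * conf.seeding_volume))
    n_astro = int(round(config.astrocyte_fraction * n_cells))
    n_anchors = int(round(config.anchor_density * conf.floor_area))

    def cell_sampler(r: np.random.Generator) -> np.ndarray:
        xy = conf.sample_xy(1, r)[0]
        return np.array([xy[0], xy[1], r.uniform(0.0, conf.height)])

    def anchor_sampler(r: np.random.Generator) -> np.ndarray:
        return conf.sample_xy(1, r)[0]

    positions = _sample_min_spacing(n_cells, config.min_cell_spacing, cell_sampler, rng)
    types = np.full(n_cells, int(CellType.NEURON))
    astro_idx = rng.choice(n_cells, size=n_astro, replace=False)
    types[astro_idx] = int(CellType.ASTROCYTE)
    anchors = _sample_min_spacing(n_anchors, config.min_anchor_spacing, anchor_sampler, rng)
    return CellPopulation(positions, types), AnchorField(anchors)


def step(
    population: CellPopulation,
    anchors: AnchorField,
    params: ForceParameters,
    k: float,
    confinement: Confinement,
) -> CellPopulation:
    """Advance the population by one step and clamp into the confinement."""
    forces = _engine.compute_forces(
        population.positions, population.types, anchors.positions, params
    )
    disp = model_core.displace(forces, k, params.g)
    new_pos = confinement.clamp(population.positions + disp)
    return CellPopulation(new_pos, population.types)


def run(
    config: SimulationConfig,
    initial: tuple[CellPopulation, AnchorField] | None = None,
) -> Trajectory:
    """Execute a full simulation: ``total_time`` steps with k recomputed each step.

    Snapshots are recorded at step 0, every ``snapshot_every`` steps (if
    non-zero) and at the final step.  Bit-reproducible given the seed.
    """
    pop, anchors = initialize_culture(config) if initial is None else initial
    steps = [0]
    snaps = [pop.copy()]
    sched = config.schedule
    for t in range(1, sched.total_time + 1):
        k = model_core.movement_freedom(t, sched)
        pop = step(pop, anchors, config.force_params, k, config.confinement)
        if (config.snapshot_every and t % config.snapshot_every == 0) or t == sched.total_time:
            steps.append(t)
            snaps.append(pop.copy())
    return Trajectory(config, anchors, steps, snaps)


def _apply_overrides(config: SimulationConfig, overrides: dict) -> SimulationConfig:
    """Apply a flat override dict; understands a few convenience keys."""
    cfg = config
    overrides = dict(overrides)
    if "AS" in overrides:
        nn, na, an, aa = overrides.pop("AS")
        cfg = replace(cfg, force_params=cfg.force_params.with_AS(nn, na, an, aa))
    if "R" in overrides:
        cfg = replace(cfg, force_params=replace(cfg.force_params, R=float(overrides.pop("R"))))
    if "equilibrium_point" in overrides:
        target = float(overrides.pop("equilibrium_point"))
        p = cfg.force_params
        R = model_core.repulsion_for_equilibrium(target, p.A * p.AS[("N", "N")], p.tau_a, p.tau_r)
        cfg = replace(cfg, force_params=replace(p, R=R))
    for key, val in overrides.items():
        if key == "confinement":
            val = val if isinstance(val, Confinement) else Confinement(**val)
        cfg = replace(cfg, **{key: val})
    return cfg


def sweep(
    base_config: SimulationConfig,
    variations: Sequence[dict],
    replicates: int = 1,
    metrics=None,
) -> pd.DataFrame:
    """Run every variation x replicate and return a tidy summary table.

    Each variation is a flat override dict (e.g. ``{"R": 3.0}``,
    ``{"equilibrium_point": 70.0}``, ``{"AS": (1, .9, .8, .7)}``,
    ``{"astrocyte_fraction": 0.33}``) optionally carrying an ``"id"``.
    Replicate seeds are ``base seed + 1000 * replicate_index`` so sweeps are
    reproducible.  Per-run morphometrics (contraction %, cluster count,
    mean-CCDP peak, superficial/deep astrocyte ratios) are attached unless a
    custom ``metrics(trajectory) -> dict`` is given.  Individual run
    failures are recorded in the ``error`` column rather than aborting the
    sweep.
    """
    from . import morphometrics

    if not len(variations):
        raise ValueError("sweep requires at least one variation")

    def default_metrics(traj: Trajectory) -> dict:
        out = {
            "contraction_pct": morphometrics.contraction(traj.initial, traj.final),
        }
        try:
            seg = morphometrics.segment_clusters(traj.final)
            out["n_clusters"] = len(seg.cluster_intervals)
            _, mean_profile = morphometrics.cluster_ccdp(traj.final, seg)
            out["ccdp_peak"] = mean_profile.peak
        except ValueError:
            out["n_clusters"] = 0
            out["ccdp_peak"] = np.nan
        prof = morphometrics.depth_profile(traj.final)
        out["superficial_astro_ratio"] = prof.superficial_ratio
        out["deep_max_astro_ratio"] = prof.deep_max_ratio
        return out

    metrics = metrics or default_metrics
    rows = []
    for vi, overrides in enumerate(variations):
        overrides = dict(overrides)
        var_id = overrides.pop("id", f"var{vi}")
        meta = overrides.pop("meta", {})
        for rep in range(replicates):
            seed = base_config.seed + 1000 * rep
            row = {"variation": var_id, "replicate": rep, "seed": seed}
            row.update(meta)
            row.update({k: v for k, v in overrides.items() if np.isscalar(v)})
            try:
                cfg = _apply_overrides(replace(base_config, seed=seed), overrides)
                traj = run(cfg)
                row.update(metrics(traj))
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - per-run fault isolation
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def force_order_configurations() -> list[dict]:
    """The 24 relative-attraction configurations: permutations of
    {1.0, 0.9, 0.8, 0.7} assigned to (N-N, N-A, A-N, A-A)."""
    from itertools import permutations

    values = (1.0, 0.9, 0.8, 0.7)
    out = []
    for perm in permutations(values):
        nn, na, an, aa = perm
        out.append(
            {
                "id": f"NN{nn}_NA{na}_AN{an}_AA{aa}",
                "AS": perm,
                "meta": {"AS_NN": nn, "AS_NA": na, "AS_AN": an, "AS_AA": aa},
            }
        )
    return out


#: Named attraction-order presets for the shell/sorting experiments.
AS_PRESETS = {
    "all_equal": (1.0, 1.0, 1.0, 1.0),
    "neuron_dominant": (1.0, 0.9, 0.9, 0.7),  # N-N > N-A = A-N > A-A
    "astrocyte_dominant": (0.7, 0.9, 0.9, 1.0),  # A-A > A-N = N-A > N-N
}
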