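"""Config parsing, snapshot CSV dialect and run manifests.

Coordinate convention (stated in every file header comment): float um,
origin at the slit corner (slit) or disk center (disk), z = 0 at the
substrate, right-handed axes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_core
from .model_core import ForceParameters, StiffnessSchedule
from .simulator import AnchorField, CellPopulation, Confinement, SimulationConfig

__all__ = [
    "load_config",
    "dump_config",
    "write_snapshot",
    "read_snapshot",
    "write_anchors",
    "read_anchors",
    "RunManifest",
]

_HEADER = (
    "# coordinates: float um; origin at slit corner (slit) / disk center (disk); "
    "z=0 at substrate; right-handed\n"
)

_FORCE_KEYS = {
    "A", "tau_a", "R", "tau_r", "S", "tau_s", "g",
    "AS_NN", "AS_NA", "AS_AN", "AS_AA",
}
_SCHEDULE_KEYS = {"total_time", "stiffening_delay", "stiffening_constant"}
_SIM_KEYS = {
    "confinement", "cell_density", "astrocyte_fraction", "min_cell_spacing",
    "anchor_density", "min_anchor_spacing", "seed", "snapshot_every",
}
_CONF_KEYS = {"kind", "length", "width", "diameter", "height"}


def load_config(path) -> SimulationConfig:
    """Load and validate a simulation config from YAML.

    A ``preset`` key (``initial`` or ``optimized``) fills the force and
    schedule sections; explicit keys override the preset.  Unknown keys are
    rejected with a list of offenders.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(raw, where=str(path))


def config_from_dict(raw: dict, where: str = "config") -> SimulationConfig:
    raw = dict(raw)
    preset = raw.pop("preset", None)
    if preset is not None:
        params, schedule = model_core.get_preset(preset)
    else:
        params, schedule = ForceParameters(), StiffnessSchedule()

    force_d = params.to_dict()
    sched_d = schedule.to_dict()
    sim_d: dict = {}
    unknown = []
    for key, val in raw.items():
        if key in _FORCE_KEYS:
            force_d[key] = val
        elif key in _SCHEDULE_KEYS:
            sched_d[key] = val
        elif key in _SIM_KEYS:
            sim_d[key] = val
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"{where}: unknown config keys {sorted(unknown)}")
    if "confinement" in sim_d:
        conf = sim_d["confinement"]
        if isinstance(conf, dict):
            bad = set(conf) - _CONF_KEYS
            if bad:
                raise ValueError(f"{where}: unknown confinement keys {sorted(bad)}")
            sim_d["confinement"] = Confinement(**conf)
    return SimulationConfig(
        force_params=ForceParameters.from_dict(force_d),
        schedule=StiffnessSchedule.from_dict(sched_d),
        **sim_d,
    )


def dump_config(config: SimulationConfig, path) -> None:
    """Echo a config as flat YAML next to run outputs."""
    doc = {
        **config.force_params.to_dict(),
        **config.schedule.to_dict(),
        "confinement": config.confinement.to_dict(),
        "cell_density": config.cell_density,
        "astrocyte_fraction": config.astrocyte_fraction,
        "min_cell_spacing": config.min_cell_spacing,
        "anchor_density": config.anchor_density,
        "min_anchor_spacing": config.min_anchor_spacing,
        "seed": config.seed,
        "snapshot_every": config.snapshot_every,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_snapshot(path, population: CellPopulation, step: int = 0) -> None:
    """Write a population as CSV: step, cell_id, type, x, y, z (um)."""
    df = population.to_frame(step=step)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_snapshot(path) -> tuple[CellPopulation, int]:
    """Read a snapshot CSV back into a population (+ its step stamp)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["step", "cell_id", "type", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if len(df) == 0:
        return CellPopulation(np.empty((0, 3)), np.empty(0, dtype=int)), 0
    types = np.where(df["type"].to_numpy() == "neuron", 0, 1)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    return CellPopulation(pos, types), int(df["step"].iloc[0])


def write_anchors(path, anchors: AnchorField) -> None:
    df = pd.DataFrame({"x": anchors.positions[:, 0], "y": anchors.positions[:, 1]})
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_anchors(path) -> AnchorField:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return AnchorField(df[["x", "y"]].to_numpy(dtype=float))


@dataclass
class RunManifest:
    """Reproducibility record written at the end of every CLI run."""

    command: str
    config: dict
    seeds: list
    version: str = ""
    wall_times_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path) -> None:
        from . import __version__

        doc = {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "package_version": self.version or __version__,
            "wall_times_s": self.wall_times_s,
            "outputs": self.outputs,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(doc, indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX
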