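"""Shared file formats: trajectory CSV, kymograph matrices, YAML config.

Column units are encoded in the headers (t_s, d_pp_um, ...); time zero is
anaphase onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .kymo import Kymograph
from .params import (
    STAGE_TABLE,
    ChromosomeLaw,
    DragParams,
    MotorParams,
    StageConfig,
)
from .trajectory import Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_kymograph",
    "SimSettings",
    "RunConfig",
    "load_config",
    "default_config_dict",
]

TRAJECTORY_COLUMNS = ["cell_id", "stage", "lineage", "t_s", "d_pp_um", "d_cc_um", "d_pc_um"]


def write_trajectory_csv(trajs: Union[Trajectory, Sequence[Trajectory]], path) -> None:
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    frame = pd.concat([tr.to_frame() for tr in trajs], ignore_index=True)
    frame.to_csv(path, index=False)


def read_trajectory_csv(path) -> list[Trajectory]:
    """Read the shared trajectory schema; malformed rows are reported with
    their 1-based file line numbers."""
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_lines = []
    for col in ("t_s", "d_pp_um", "d_cc_um", "d_pc_um"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        bad_lines.extend((frame.index[bad] + 2).tolist())  # +2: header + 1-based
        frame[col] = coerced
    if bad_lines:
        raise SchemaError(f"{path}: non-numeric values on line(s) {sorted(set(bad_lines))}")
    trajs = []
    for cell_id, group in frame.groupby("cell_id", sort=False):
        group = group.sort_values("t_s")
        stage = group["stage"].iloc[0]
        trajs.append(
            Trajectory(
                times=group["t_s"].to_numpy(),
                d_pp=group["d_pp_um"].to_numpy(),
                d_cc=group["d_cc_um"].to_numpy(),
                d_pc=group["d_pc_um"].to_numpy(),
                cell_id=str(cell_id),
                stage=int(stage) if pd.notna(stage) else None,
                lineage="" if pd.isna(group["lineage"].iloc[0]) else str(group["lineage"].iloc[0]),
            )
        )
    return trajs


def read_kymograph(path, channel: str, pixel_size: float, frame_interval: float) -> Kymograph:
    """Load a kymograph matrix from TIFF or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        matrix = np.asarray(tifffile.imread(path), dtype=float)
    else:
        matrix = np.loadtxt(path, delimiter=",", dtype=float)
    return Kymograph(matrix, channel, pixel_size, frame_interval)


@dataclass(frozen=True)
class SimSettings:
    dt: float = 0.01
    t_end: float = 300.0
    n_patches: int = 2000
    sample_every: float = 10.3
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Parsed YAML configuration shared by the CLI sub-commands."""

    mt_n_per_aster: float
    mt_growth_velocity: float
    motors: MotorParams
    drags: DragParams
    law: ChromosomeLaw
    stages: dict[int, StageConfig]
    sim: SimSettings


def default_config_dict() -> dict:
    """The fixed parameter set plus the per-stage table, as plain YAML data."""
    return {
        "mt_params": {"n_per_aster": 5000, "growth_velocity": 1.0},
        "motor_params": {"density": 0.12, "size": 1.5, "unbinding_rate": 0.05, "force": 5.0},
        "drag_params": {"pole_drag": 450.0, "coupling": 50.0},
        "chromosome_law": {"final_separation": 6.2, "time_constant": 29.0},
        "stages": [
            {
                "stage": cfg.stage,
                "cell_radius": cfg.cell_radius,
                "initial_d_pp": cfg.initial_d_pp,
                "catastrophe_rate": cfg.catastrophe_rate,
            }
            for cfg in STAGE_TABLE.values()
        ],
        "sim": {"dt": 0.01, "t_end": 300.0, "n_patches": 2000, "sample_every": 10.3, "seed": 0},
    }


def load_config(path: Optional[str] = None) -> RunConfig:
    """Parse a YAML config; omitted blocks fall back to the defaults."""
    data = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"{path}: top level must be a mapping")
        for key, val in user.items():
            if key not in data:
                raise SchemaError(f"{path}: unknown config block {key!r}")
            if key == "stages":
                data[key] = val
            else:
                data[key].update(val)
    try:
        stages = {
            int(row["stage"]): StageConfig(
                stage=int(row["stage"]),
                cell_radius=float(row["cell_radius"]),
                initial_d_pp=float(row["initial_d_pp"]),
                catastrophe_rate=(
                    float(row["catastrophe_rate"]) if row.get("catastrophe_rate") is not None else None
                ),
            )
            for row in data["stages"]
        }
        return RunConfig(
            mt_n_per_aster=float(data["mt_params"]["n_per_aster"]),
            mt_growth_velocity=float(data["mt_params"]["growth_velocity"]),
            motors=MotorParams(**data["motor_params"]),
            drags=DragParams(**data["drag_params"]),
            law=ChromosomeLaw(**data["chromosome_law"]),
            stages=stages,
            sim=SimSettings(**data["sim"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"config error: {exc}") from exc
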