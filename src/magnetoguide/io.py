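"""File formats and run configuration.

Fixed CSV dialect throughout: comma separator, dot decimal, header row,
UTF-8.  Field/force grids round-trip either as delimited text
(x, y, Bx, By, Bz, Bnorm) or as a raw float64 payload next to a small JSON
header declaring shape, spacing and units.  Masks round-trip as 0/1 text
grids (and export to PGM for viewers).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import MaskGrid, PatternSpec
from .magnetostatics import FieldGrid

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_mask",
    "read_mask",
    "write_mask_pgm",
    "write_grid",
    "read_grid",
    "write_grid_binary",
    "read_grid_binary",
    "load_pattern_config",
    "RunConfig",
    "load_run_config",
]

_TRACK_COLUMNS = ["object_id", "t_s", "x_um", "y_um"]


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    """One row per frame: object_id, t_s, x_um, y_um."""
    df = tracks.rename(columns={"track_id": "object_id", "cell_id": "object_id"})
    df[_TRACK_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Strict track reader; malformed rows raise with their line number."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header != _TRACK_COLUMNS:
        raise ValueError(f"{path}: line 1: expected header {_TRACK_COLUMNS}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
        try:
            rows.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=_TRACK_COLUMNS)


def write_mask(mask: MaskGrid, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# origin_um {mask.origin[0]:.6f} {mask.origin[1]:.6f}\n")
        fh.write(f"# pixel_um {mask.pixel_um:.6f}\n")
        np.savetxt(fh, mask.mask.astype(np.uint8), fmt="%d")


def read_mask(path: str | Path) -> MaskGrid:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        l1 = fh.readline().split()
        l2 = fh.readline().split()
        if l1[:2] != ["#", "origin_um"] or l2[:2] != ["#", "pixel_um"]:
            raise ValueError(f"{path}: malformed mask header")
        origin = (float(l1[2]), float(l1[3]))
        pixel = float(l2[2])
        arr = np.loadtxt(fh, dtype=int)
    return MaskGrid(origin, pixel, np.atleast_2d(arr).astype(bool))


def write_mask_pgm(mask: MaskGrid, path: str | Path) -> None:
    """Plain-text (P2) PGM export for quick viewing."""
    m = mask.mask
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"P2\n{m.shape[1]} {m.shape[0]}\n1\n")
        for row in m[::-1]:  # image row 0 at top
            fh.write(" ".join("1" if v else "0" for v in row) + "\n")


def _grid_frame(grid: FieldGrid | "object") -> pd.DataFrame:
    vec = getattr(grid, "B", None)
    if vec is None:
        vec = grid.F
        names = ["Fx", "Fy", "Fz", "Fnorm"]
    else:
        names = ["Bx", "By", "Bz", "Bnorm"]
    XX, YY = np.meshgrid(grid.xs, grid.ys, indexing="ij")
    flat = vec.reshape(-1, 3)
    return pd.DataFrame({
        "x_um": XX.ravel(),
        "y_um": YY.ravel(),
        names[0]: flat[:, 0],
        names[1]: flat[:, 1],
        names[2]: flat[:, 2],
        names[3]: np.linalg.norm(flat, axis=1),
    })


def write_grid(grid, path: str | Path) -> None:
    """Delimited-text export of a field or force grid."""
    _grid_frame(grid).to_csv(path, index=False)


def read_grid(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid_binary(grid, path_stem: str | Path) -> None:
    """Raw float64 payload + JSON header (shape, axes, units)."""
    stem = Path(path_stem)
    vec = getattr(grid, "B", None)
    kind = "field_T" if vec is not None else "force_arb"
    if vec is None:
        vec = grid.F
    payload = np.ascontiguousarray(vec, dtype="<f8")
    header = {
        "kind": kind,
        "shape": list(payload.shape),
        "dtype": "<f8",
        "xs_um": [float(grid.xs[0]), float(grid.xs[-1]), len(grid.xs)],
        "ys_um": [float(grid.ys[0]), float(grid.ys[-1]), len(grid.ys)],
        "z_um": grid.z_um,
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2))
    payload.tofile(stem.with_suffix(".bin"))


def read_grid_binary(path_stem: str | Path) -> tuple[dict, np.ndarray]:
    stem = Path(path_stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype=header["dtype"])
    expected = int(np.prod(header["shape"]))
    if data.size != expected:
        raise ValueError(
            f"{stem}: payload has {data.size} values but header declares {expected}"
        )
    return header, data.reshape(header["shape"])


def load_pattern_config(path: str | Path) -> PatternSpec:
    """Pattern from a YAML/JSON file (keys: shapes, unit_cell, thickness_nm,
    magnetization_direction)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return PatternSpec.from_dict(data)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class PhysicsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mu0_M_T: float = 1.0
    magnetization_scale: float = 1.0
    viscosity_pa_s: float = 8.9e-4
    k_lin: float = 1.0
    cell_diameter_um: float = 10.0
    particle_diameter_um: float = 2.8


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    z_um: float = 2.0
    spacing_um: float = 1.0
    step_cap_um: float = 0.5
    capture_radius_um: float = 5.0
    max_time_s: float = 120.0
    target_speed_um_s: float = 10.0


class StatsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    dilation_radius_um: float = 10.0


class GeneratorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = 200
    labeling: str = "MMP-SA"
    speed_um_s: float = 10.0
    duration_s: float = 5.0
    frame_dt_s: float = 1.0
    noise_sigma_um: float = 0.5


class RunConfig(BaseModel):
    """Schema-validated configuration for the command-line pipeline;
    unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    pattern_preset: str = "bars"
    pattern_file: str | None = None
    pattern_kwargs: dict = Field(default_factory=dict)
    physics: PhysicsBlock = Field(default_factory=PhysicsBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)
    generator: GeneratorBlock = Field(default_factory=GeneratorBlock)
    seed: int = 0


def load_run_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig.model_validate(data)
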