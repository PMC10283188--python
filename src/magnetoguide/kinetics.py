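"""Drag-balance magnetophoresis: terminal velocities, speed ratios and
overdamped trajectory integration.

At the micrometre scale the Reynolds number is ≪ 1, so a magnetically pulled
object moves at the speed where Stokes drag balances the magnetic force:

    F_mag = F_drag = 3 π µ D u₀

with µ the medium viscosity and D the diameter of the moving object (the
cell, or a free particle).  The total moment — hence the force in a shared
field — is proportional to the number of conjugated particles, so relative
speeds of objects in the same field gradient reduce to the ratio of
moment/diameter: a cell with two beads moves twice as fast as a cell with
one, and a free 2.8 µm bead moves 10/2.8 ≈ 3.6× faster than a 10 µm cell
carrying one bead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .forces import HotSpot

__all__ = [
    "MagneticParticle",
    "CellBody",
    "Medium",
    "Track",
    "drag_coefficient",
    "terminal_velocity",
    "speed_ratio",
    "calibrate_k_lin",
    "simulate_trajectory",
    "settle_population",
]

WATER_VISCOSITY = 8.9e-4  # Pa·s, water-like culture medium at 25 °C


@dataclass(frozen=True)
class MagneticParticle:
    """Superparamagnetic microbead (2.8 µm streptavidin bead by default).

    ``moment`` is in A·m² when forces are absolute, or arbitrary units tied
    to the force coefficient k_lin otherwise.
    """

    diameter_um: float = 2.8
    moment: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("particle diameter must be > 0")
        if self.moment < 0:
            raise ValueError("particle moment must be >= 0")

    @property
    def magnetic_moment(self) -> float:
        return self.moment


@dataclass(frozen=True)
class CellBody:
    """A cell decorated with ``n_particles`` identical beads.

    The drag diameter is the cell's own (beads are small against the cell
    and wall effects are neglected); the total moment is n × bead moment.
    """

    diameter_um: float = 10.0
    n_particles: int = 1
    particle: MagneticParticle = field(default_factory=MagneticParticle)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("cell diameter must be > 0")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")

    @property
    def magnetic_moment(self) -> float:
        return self.n_particles * self.particle.moment


@dataclass(frozen=True)
class Medium:
    viscosity_pa_s: float = WATER_VISCOSITY

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be > 0")


@dataclass
class Track:
    """Time-stamped planar positions of one object."""

    object_id: str
    data: pd.DataFrame  # columns t_s, x_um, y_um
    status: str = "ok"  # ok | captured | exited | timeout
    capture_label: int | None = None

    def __post_init__(self) -> None:
        t = self.data["t_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("track timestamps must be strictly increasing")


def drag_coefficient(body, medium: Medium) -> float:
    """Stokes drag coefficient 3πµD in N·s/m."""
    return 3.0 * math.pi * medium.viscosity_pa_s * body.diameter_um * 1e-6


def terminal_velocity(
    force_vector_n: Sequence[float], body, medium: Medium = Medium()
) -> np.ndarray:
    """Terminal velocity u = F / (3πµD) in m/s, parallel to the force."""
    F = np.asarray(force_vector_n, dtype=float)
    return F / drag_coefficient(body, medium)


def speed_ratio(body_a, body_b) -> float:
    """Predicted speed ratio of two bodies in the same local field gradient:
    (m_a / D_a) / (m_b / D_b)."""
    if body_b.magnetic_moment == 0:
        raise ZeroDivisionError(
            "reference body has zero magnetic moment; speed ratio undefined"
        )
    mob_a = body_a.magnetic_moment / body_a.diameter_um
    mob_b = body_b.magnetic_moment / body_b.diameter_um
    return mob_a / mob_b


def calibrate_k_lin(
    force_fn: Callable[[np.ndarray], np.ndarray],
    at_point_um: Sequence[float],
    target_speed_um_s: float,
    body=None,
    medium: Medium = Medium(),
) -> float:
    """Scale factor k such that k × force_fn drives ``body`` at the target
    speed at the given point — the bridge from arbitrary force units to
    absolute kinetics when one observed speed is known."""
    body = body if body is not None else CellBody()
    F = np.linalg.norm(force_fn(np.atleast_2d(np.asarray(at_point_um, float)))[0])
    if F == 0:
        raise ValueError("zero force at calibration point")
    u_target = target_speed_um_s * 1e-6
    return u_target * drag_coefficient(body, medium) / F


def simulate_trajectory(
    body,
    force_fn: Callable[[np.ndarray], np.ndarray],
    start_um: Sequence[float],
    medium: Medium = Medium(),
    hot_spots: Sequence[HotSpot] = (),
    capture_radius_um: float = 5.0,
    max_time_s: float = 600.0,
    domain_um: tuple[float, float, float, float] | None = None,
    step_cap_um: float = 0.5,
    report_dt_s: float = 1.0,
    force_scale: float | None = None,
    noise_sigma_um: float = 0.0,
    rng: np.random.Generator | None = None,
    object_id: str = "cell",
) -> Track:
    """Overdamped trajectory of one body over a force landscape.

    The velocity is the instantaneous terminal velocity u = F/(3πµD); the
    integrator takes explicit Euler steps capped at ``step_cap_um``
    displacement and records positions every ``report_dt_s`` (1 s by
    default, the time-lapse frame interval).  The per-particle force from
    ``force_fn`` is multiplied by the body's magnetic moment and by
    ``force_scale`` (a k_lin calibration), so unlabeled cells do not move.

    Terminates on hot-spot capture, domain exit or ``max_time_s``; optional
    Gaussian positional noise (off by default) models thermal jitter.
    """
    if noise_sigma_um > 0 and rng is None:
        raise ValueError("noise requires an explicit rng (reproducibility contract)")
    scale = 1.0 if force_scale is None else force_scale
    moment = getattr(body, "magnetic_moment", 1.0)
    gamma = drag_coefficient(body, medium)
    pos = np.asarray(start_um, dtype=float)[:2].copy()
    t = 0.0
    rows = [(0.0, pos[0], pos[1])]
    status = "timeout"
    capture_label = None
    next_report = report_dt_s

    def captured():
        for hs in hot_spots:
            if np.hypot(pos[0] - hs.x_um, pos[1] - hs.y_um) <= capture_radius_um:
                return hs.label
        return None

    lab = captured()
    if lab is not None:
        status, capture_label = "captured", lab
    while status == "timeout" and t < max_time_s:
        F = np.asarray(force_fn(pos[None, :]), dtype=float)[0][:2] * moment * scale
        if not np.all(np.isfinite(F)):
            raise FloatingPointError(f"non-finite force at {pos} (t={t:.2f}s)")
        u = F / gamma * 1e6  # µm/s
        speed = float(np.linalg.norm(u))
        if speed < 1e-12:
            # nothing moves; fast-forward to the horizon
            t = max_time_s
            break
        dt = min(step_cap_um / speed, next_report - t, max_time_s - t)
        pos = pos + u * dt
        if noise_sigma_um > 0:
            pos = pos + rng.normal(0.0, noise_sigma_um * math.sqrt(dt / report_dt_s), 2)
        t += dt
        if t >= next_report - 1e-12:
            rows.append((round(t, 9), pos[0], pos[1]))
            next_report += report_dt_s
        lab = captured()
        if lab is not None:
            status, capture_label = "captured", lab
        elif domain_um is not None:
            xmin, xmax, ymin, ymax = domain_um
            if not (xmin <= pos[0] <= xmax and ymin <= pos[1] <= ymax):
                status = "exited"
    if rows[-1][0] < t or status != "timeout":
        rows.append((t if t > rows[-1][0] else rows[-1][0] + 1e-9, pos[0], pos[1]))
    df = pd.DataFrame(rows, columns=["t_s", "x_um", "y_um"])
    return Track(object_id, df, status=status, capture_label=capture_label)


def settle_population(
    cells: pd.DataFrame,
    start_positions: pd.DataFrame,
    force_fn: Callable[[np.ndarray], np.ndarray],
    hot_spots: Sequence[HotSpot] = (),
    medium: Medium = Medium(),
    particle: MagneticParticle = MagneticParticle(),
    cell_diameter_um: float = 10.0,
    force_scale: float | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Settle a cell population over a force landscape.

    ``cells`` needs columns ``cell_id`` and ``n_particles``; positions need
    ``cell_id``, ``x_um``, ``y_um`` (one start per cell).  Cells without
    particles experience no magnetic force and stay at their (uniformly
    dispersed) landing site.  Returns per-cell endpoints with capture labels.
    """
    merged = cells.merge(start_positions, on="cell_id", validate="one_to_one")
    out = []
    for row in merged.itertuples(index=False):
        body = CellBody(cell_diameter_um, int(row.n_particles), particle)
        if body.magnetic_moment == 0:
            out.append((row.cell_id, row.x_um, row.y_um, row.x_um, row.y_um,
                        "unlabeled", None))
            continue
        tr = simulate_trajectory(
            body, force_fn, (row.x_um, row.y_um), medium=medium,
            hot_spots=hot_spots, force_scale=force_scale,
            object_id=str(row.cell_id), **sim_kwargs,
        )
        end = tr.data.iloc[-1]
        out.append((row.cell_id, row.x_um, row.y_um, float(end.x_um),
                    float(end.y_um), tr.status, tr.capture_label))
    return pd.DataFrame(
        out,
        columns=["cell_id", "x0_um", "y0_um", "x_um", "y_um", "status", "hotspot_label"],
    )
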