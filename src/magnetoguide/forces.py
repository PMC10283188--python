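"""Attraction-force landscapes for superparamagnetic particles.

Below saturation a superparamagnetic bead's moment is proportional to the
local flux density, m ∝ B, so the force is F = k·(B·∇)B with a lumped
coefficient k (particle volume × susceptibility / µ0).  Outside the magnetic
material B is curl-free, hence (B·∇)B = ∇(|B|²)/2 and the force landscape is
the gradient of a potential — cells ride uphill in |B|².  At saturation the
moment is fixed and F = (m·∇)B.

The absolute force scale is left as the coefficient ``k_lin`` (default 1,
arbitrary units): hot-spot locations, anisotropy ratios and speed ratios are
all scale-free, and an absolute calibration against one observed speed is
provided in :mod:`magnetoguide.kinetics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import PatternSpec
from .magnetostatics import FieldGrid, field_map, height_above_film, pattern_field_function

__all__ = [
    "ForceMap",
    "HotSpot",
    "linear_force",
    "linear_force_at",
    "advective_force_at",
    "saturated_force",
    "find_hot_spots",
    "anisotropy_ratio",
    "edge_attraction_profile",
    "pattern_force_map",
]

# central-difference step for pointwise differentiation of the analytic
# field: far below the µm feature scale, far above fp noise
_DIFF_H_UM = 0.01


@dataclass(frozen=True)
class HotSpot:
    """A strict local maximum of the force-magnitude landscape."""

    x_um: float
    y_um: float
    magnitude: float
    label: int


@dataclass
class ForceMap:
    """Force vectors on a horizontal grid; magnitude is the pointwise norm.

    ``evaluator`` (if present) returns exact force vectors at arbitrary
    (N, 2 or 3) µm points, bypassing grid interpolation.
    """

    xs: np.ndarray
    ys: np.ndarray
    F: np.ndarray  # (nx, ny, 3), newtons × (k_lin units)
    z_um: float | None
    k_lin: float = 1.0
    evaluator: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.F)):
            raise ValueError("force map contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.F, axis=2)

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.xs[1] - self.xs[0]), float(self.ys[1] - self.ys[0])


def _as_points3(points_um: np.ndarray, z_um: float | None) -> np.ndarray:
    p = np.atleast_2d(np.asarray(points_um, dtype=float))
    if p.shape[1] == 2:
        if z_um is None:
            raise ValueError("2-D points require a z height")
        p = np.column_stack([p, np.full(len(p), z_um)])
    return p


def linear_force_at(
    field_fn: Callable[[np.ndarray], np.ndarray],
    points_um: np.ndarray,
    k_lin: float = 1.0,
    h_um: float = _DIFF_H_UM,
) -> np.ndarray:
    """F = k·∇(|B|²)/2 by central differences of the analytic field (newtons
    per unit k; positions in µm, so the 1e-6 converts the step to metres)."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    F = np.zeros_like(pts)
    for ax in range(pts.shape[1]):
        e = np.zeros(pts.shape[1])
        e[ax] = h_um
        b2p = np.sum(field_fn(pts + e) ** 2, axis=1)
        b2m = np.sum(field_fn(pts - e) ** 2, axis=1)
        F[:, ax] = (b2p - b2m) / (4.0 * h_um * 1e-6)
    return k_lin * F


def advective_force_at(
    field_fn: Callable[[np.ndarray], np.ndarray],
    points_um: np.ndarray,
    k_lin: float = 1.0,
    h_um: float = _DIFF_H_UM,
) -> np.ndarray:
    """F = k·(B·∇)B by central differences — the defining form, equal to
    ∇|B|²/2 wherever curl B = 0.  Kept as an independent cross-check."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    B0 = field_fn(pts)
    F = np.zeros_like(pts)
    for ax in range(pts.shape[1]):
        e = np.zeros(pts.shape[1])
        e[ax] = h_um
        dB = (field_fn(pts + e) - field_fn(pts - e)) / (2.0 * h_um * 1e-6)
        F += B0[:, [ax]] * dB
    return k_lin * F


def linear_force(
    field: FieldGrid,
    k_lin: float = 1.0,
    method: str = "pointwise",
) -> ForceMap:
    """Linear-response force map from a field grid.

    ``method='pointwise'`` differentiates the grid's analytic evaluator
    (exact at every node); ``'grid'`` falls back to finite differences of
    the sampled |B|² and warns when the spacing is too coarse to resolve
    the pole-edge structure.
    """
    if k_lin <= 0:
        raise ValueError("k_lin must be > 0")
    if method == "pointwise" and field.evaluator is None:
        method = "grid"
    if method == "pointwise":
        XX, YY = np.meshgrid(field.xs, field.ys, indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        ev = field.evaluator

        def force_eval(points_um: np.ndarray) -> np.ndarray:
            p = np.atleast_2d(np.asarray(points_um, dtype=float))[:, :2]
            return linear_force_at(ev, p, k_lin=k_lin)

        Fxy = force_eval(pts)
        # plane-bound evaluator: in-plane components only (Fz = 0 on the map;
        # full 3-D forces come from pattern_force_map / linear_force_at)
        F = np.column_stack([Fxy, np.zeros(len(Fxy))]).reshape(
            len(field.xs), len(field.ys), 3
        )
        return ForceMap(field.xs, field.ys, F, field.z_um, k_lin, evaluator=force_eval)

    dx, dy = field.spacing
    if min(dx, dy) > 2.0:
        warnings.warn(
            "grid spacing coarser than ~2 µm; finite differences will smear "
            "the pole-edge force peaks",
            stacklevel=2,
        )
    b2 = np.sum(field.B**2, axis=2) / 2.0
    gx, gy = np.gradient(b2, field.xs * 1e-6, field.ys * 1e-6)
    F = np.stack([k_lin * gx, k_lin * gy, np.zeros_like(gx)], axis=2)
    return ForceMap(field.xs, field.ys, F, field.z_um, k_lin)


def pattern_force_map(
    pattern: PatternSpec,
    z_um: float = 2.0,
    spacing_um: float = 1.0,
    mu0_M: float = 1.0,
    k_lin: float = 1.0,
    window_um: tuple[float, float, float, float] | None = None,
    pad_um: float = 40.0,
) -> ForceMap:
    """Field map + linear force in one call, with full 3-D force vectors."""
    fg = field_map(pattern, z_um=z_um, spacing_um=spacing_um, mu0_M=mu0_M,
                   window_um=window_um, pad_um=pad_um)
    base = pattern_field_function(pattern, mu0_M=mu0_M)
    zc = height_above_film(pattern, z_um)

    def force_eval(points_um: np.ndarray) -> np.ndarray:
        p = _as_points3(points_um, zc)
        return linear_force_at(base, p, k_lin=k_lin)

    XX, YY = np.meshgrid(fg.xs, fg.ys, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel(), np.full(XX.size, zc)])
    F = force_eval(pts).reshape(len(fg.xs), len(fg.ys), 3)
    return ForceMap(fg.xs, fg.ys, F, z_um, k_lin, evaluator=force_eval)


def saturated_force(
    m_vector: Sequence[float],
    field_fn: Callable[[np.ndarray], np.ndarray],
    points_um: np.ndarray,
    h_um: float = _DIFF_H_UM,
) -> np.ndarray:
    """Saturated-moment force F = (m·∇)B at the given points (newtons for m
    in A·m² and B in tesla)."""
    m = np.asarray(m_vector, dtype=float)
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if not np.any(m != 0.0):
        return np.zeros_like(pts)
    F = np.zeros_like(pts, dtype=float)
    for ax in range(3):
        if m[ax] == 0.0:
            continue
        e = np.zeros(3)
        e[ax] = h_um
        dB = (field_fn(pts + e) - field_fn(pts - e)) / (2.0 * h_um * 1e-6)
        F += m[ax] * dB
    return F


def find_hot_spots(
    force_map: ForceMap,
    rel_threshold: float = 0.05,
    connectivity: int = 8,
    merge_radius_um: float = 10.0,
) -> list[HotSpot]:
    """Detect magnetic hot spots: strict local maxima of |F| above
    ``rel_threshold`` × global max.

    Plateaus are merged to their centroid; maxima closer than
    ``merge_radius_um`` (default one cell diameter — a cell docks at such a
    cluster as one site) are merged, keeping the magnitude-weighted centroid.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ValueError("rel_threshold must be in (0, 1)")
    mag = force_map.magnitude
    peak = mag.max()
    if peak <= 0.0:
        return []
    footprint = np.ones((3, 3)) if connectivity == 8 else np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
    )
    local_max = (mag == ndimage.maximum_filter(mag, footprint=footprint, mode="nearest"))
    local_max &= mag > rel_threshold * peak
    labels, n = ndimage.label(local_max, structure=np.ones((3, 3)))
    if n == 0:
        return []
    cands = []
    for lab in range(1, n + 1):
        ii, jj = np.nonzero(labels == lab)
        w = mag[ii, jj]
        cands.append((
            float(np.average(force_map.xs[ii], weights=w)),
            float(np.average(force_map.ys[jj], weights=w)),
            float(w.max()),
        ))
    merged = _merge_close(cands, merge_radius_um)
    merged.sort(key=lambda c: -c[2])
    return [HotSpot(x, y, m, i) for i, (x, y, m) in enumerate(merged)]


def _merge_close(cands: list[tuple[float, float, float]], radius: float):
    """Single-linkage clustering of candidate peaks within ``radius`` µm."""
    n = len(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(cands[i][0] - cands[j][0], cands[i][1] - cands[j][1]) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[float, float, float]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(cands[i])
    out = []
    for members in groups.values():
        w = np.array([m[2] for m in members])
        out.append((
            float(np.average([m[0] for m in members], weights=w)),
            float(np.average([m[1] for m in members], weights=w)),
            float(w.max()),
        ))
    return out


def _line_points(force_map: ForceMap, line, n_samples: int) -> np.ndarray:
    """Points along ('x', x0) — fixed x, sweeping y — or ('y', y0)."""
    axis, value = line
    if axis == "x":
        ys = np.linspace(force_map.ys[0], force_map.ys[-1], n_samples)
        return np.column_stack([np.full(n_samples, value), ys])
    if axis == "y":
        xs = np.linspace(force_map.xs[0], force_map.xs[-1], n_samples)
        return np.column_stack([xs, np.full(n_samples, value)])
    raise ValueError("line must be ('x', value) or ('y', value)")


def _line_peak(force_map: ForceMap, line, n_samples: int) -> float:
    if force_map.evaluator is not None:
        pts = _line_points(force_map, line, n_samples)
        return float(np.linalg.norm(force_map.evaluator(pts), axis=1).max())
    axis, value = line
    mag = force_map.magnitude
    if axis == "x":
        i = int(np.argmin(np.abs(force_map.xs - value)))
        return float(mag[i, :].max())
    i = int(np.argmin(np.abs(force_map.ys - value)))
    return float(mag[:, i].max())


def anisotropy_ratio(
    force_map: ForceMap,
    line_a,
    line_b,
    n_samples: int = 2001,
) -> float:
    """log10 of the ratio of peak |F| along two lines of the map plane.

    Lines are given as ``('x', x0)`` (sweep y at fixed x) or ``('y', y0)``.
    A zero peak on ``line_b`` yields ``inf`` with a warning.
    """
    pa = _line_peak(force_map, line_a, n_samples)
    pb = _line_peak(force_map, line_b, n_samples)
    if pb == 0.0:
        warnings.warn("zero peak force on reference line; ratio is infinite", stacklevel=2)
        return float("inf")
    return float(np.log10(pa / pb))


def edge_attraction_profile(
    pattern: PatternSpec,
    magnetization_direction: Sequence[float] | None = None,
    z_um: float = 2.0,
    mu0_M: float = 1.0,
    sample_spacing_um: float = 1.0,
    rel_level: float = 0.5,
) -> float:
    """Fraction of the pattern boundary where |F| exceeds ``rel_level`` × the
    boundary maximum, at ``z_um`` above the film.

    Out-of-plane magnetization charges the whole top face, making every edge
    attractive (fraction ≈ 1); in-plane magnetization localizes attraction to
    the two pole edges (fraction well below 0.5 for elongated bars).
    """
    if magnetization_direction is not None:
        pattern = pattern.with_magnetization(magnetization_direction)
    boundary = pattern.geometry().boundary
    length = boundary.length
    n = max(8, int(np.ceil(length / sample_spacing_um)))
    dists = np.linspace(0.0, length, n, endpoint=False)
    pts2 = np.array([boundary.interpolate(d).coords[0] for d in dists])
    zc = height_above_film(pattern, z_um)
    pts3 = np.column_stack([pts2, np.full(len(pts2), zc)])
    base = pattern_field_function(pattern, mu0_M=mu0_M)
    F = linear_force_at(base, pts3)
    mag = np.linalg.norm(F, axis=1)
    return float(np.mean(mag > rel_level * mag.max()))
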