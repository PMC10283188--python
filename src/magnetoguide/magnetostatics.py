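"""Stray field of uniformly magnetized thin-film prisms and patterned arrays.

The field of a uniformly magnetized rectangular prism has a closed form in
the equivalent surface-magnetic-charge picture: magnetization **M** along one
axis deposits charge ±|M| on the two perpendicular faces, and the resulting
flux density is a signed sum of arctan/log terms over the eight prism
corners.  Arbitrary magnetization directions follow by superposing the three
axis-aligned solutions; rotated (segment) prisms by rotating the evaluation
frame.  Everything is linear in M, so patterned arrays are plain sums over
their constituent prisms.

The model is valid strictly outside the magnetic material.  Above a
patterned film the far field depends only on the sheet moment M·t, which is
why a nanometre film can be represented at true thickness with no rescaling.

Units: SI internally (tesla, A/m, metres).  Public functions accept µm for
in-plane positions and heights and nm for film thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geometry import PatternSpec, Rect, Segment

__all__ = [
    "MU0",
    "Magnet",
    "prism_field",
    "pattern_field",
    "pattern_field_function",
    "field_map",
    "field_slice_yz",
    "FieldGrid",
]

MU0 = 4e-7 * math.pi

# evaluation points landing exactly on a face/edge extension hit log(0) or
# atan singularities; such points are nudged vertically by this amount
_NUDGE_M = 1e-9


@dataclass(frozen=True)
class Magnet:
    """Axis-aligned uniformly magnetized prism.

    bounds: ((x1, x2), (y1, y2), (z1, z2)) in metres; M in A/m.
    """

    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    M: tuple[float, float, float]

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not hi > lo:
                raise ValueError("prism bounds must satisfy hi > lo on every axis")

    def contains(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        (x1, x2), (y1, y2), (z1, z2) = self.bounds
        return (
            (pts[:, 0] > x1 - tol) & (pts[:, 0] < x2 + tol)
            & (pts[:, 1] > y1 - tol) & (pts[:, 1] < y2 + tol)
            & (pts[:, 2] > z1 - tol) & (pts[:, 2] < z2 + tol)
        )


def _corner_sum_z(bounds, pts: np.ndarray) -> np.ndarray:
    """B/(µ0 M /4π) for unit magnetization along +z."""
    (x1, x2), (y1, y2), (z1, z2) = bounds
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    Bx = np.zeros_like(x)
    By = np.zeros_like(x)
    Bz = np.zeros_like(x)
    for i, xi in enumerate((x1, x2)):
        for j, yj in enumerate((y1, y2)):
            for k, zk in enumerate((z1, z2)):
                s = (-1.0) ** (i + j + k)
                X = x - xi
                Y = y - yj
                Z = z - zk
                R = np.sqrt(X * X + Y * Y + Z * Z)
                Bx += s * np.log(Y + R)
                By += s * np.log(X + R)
                Bz -= s * np.arctan2(X * Y, Z * R)
    # sign fixed against a surface-charge quadrature oracle
    return np.column_stack([Bx, By, Bz])


# cyclic permutations taking the magnetization axis onto z
_PERM = {2: (0, 1, 2), 0: (1, 2, 0), 1: (2, 0, 1)}
_INV = {2: (0, 1, 2), 0: (2, 0, 1), 1: (1, 2, 0)}


def _axis_field(bounds, pts: np.ndarray, axis: int) -> np.ndarray:
    """Corner-sum field for unit M along the given axis (0=x, 1=y, 2=z)."""
    p = _PERM[axis]
    pb = (bounds[p[0]], bounds[p[1]], bounds[p[2]])
    out = _corner_sum_z(pb, pts[:, p])
    return out[:, _INV[axis]]


def prism_field(magnet: Magnet, points_m: np.ndarray, check_inside: bool = True) -> np.ndarray:
    """Flux density (tesla) of a uniformly magnetized prism at exterior points.

    Raises ``ValueError`` for points strictly inside the prism, where the
    charge-sheet exterior solution does not apply.
    """
    pts = np.atleast_2d(np.asarray(points_m, dtype=float))
    if check_inside and np.any(magnet.contains(pts, tol=-1e-15)):
        raise ValueError("evaluation point inside the prism volume")
    B = np.zeros_like(pts)
    for axis in range(3):
        Ma = magnet.M[axis]
        if Ma != 0.0:
            B += Ma * _axis_field(magnet.bounds, pts, axis)
    B *= MU0 / (4.0 * math.pi)
    bad = ~np.all(np.isfinite(B), axis=1)
    if np.any(bad):
        nudged = pts[bad].copy()
        nudged[:, 2] += _NUDGE_M
        B[bad] = prism_field(magnet, nudged, check_inside=False)
    return B


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _pattern_prisms(pattern: PatternSpec, M_magnitude: float):
    """Decompose a pattern into (Magnet, rotation | None, centre) prisms."""
    t = pattern.thickness_nm * 1e-9
    m_dir = np.asarray(pattern.magnetization_direction, dtype=float)
    M_vec = M_magnitude * m_dir
    out = []
    for prim in pattern.primitives:
        if isinstance(prim, Rect):
            bounds = (
                (prim.x1 * 1e-6, prim.x2 * 1e-6),
                (prim.y1 * 1e-6, prim.y2 * 1e-6),
                (0.0, t),
            )
            out.append((Magnet(bounds, tuple(M_vec)), None, None))
        elif isinstance(prim, Segment):
            # oriented rectangle: evaluate in the segment frame
            ang = prim.angle
            R = _rotation_z(ang)
            cx = (prim.p0[0] + prim.p1[0]) / 2.0 * 1e-6
            cy = (prim.p0[1] + prim.p1[1]) / 2.0 * 1e-6
            hl = prim.length / 2.0 * 1e-6
            hw = prim.width / 2.0 * 1e-6
            bounds = ((-hl, hl), (-hw, hw), (0.0, t))
            M_local = R.T @ M_vec
            out.append((Magnet(bounds, tuple(M_local)), R, np.array([cx, cy, 0.0])))
        else:  # pragma: no cover - future primitive kinds
            raise ValueError(f"unsupported primitive for field computation: {type(prim).__name__}")
    return out


def pattern_field(
    pattern: PatternSpec,
    points_um: np.ndarray,
    mu0_M: float = 1.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Superposed flux density (tesla) of all pattern shapes.

    Parameters
    ----------
    points_um : (N, 3) array
        Positions in µm; z measured from the film *bottom* (the film occupies
        z in [0, thickness]).  Use :func:`height_above_film` for "height above
        the magnet" semantics.
    mu0_M : float
        µ0 × magnetization magnitude in tesla (default 1.0 T, a
        permalloy-like scale).
    scale : float
        Dimensionless factor for sub-saturation induced magnetization.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float)) * 1e-6
    M_mag = scale * mu0_M / MU0
    B = np.zeros_like(pts)
    for magnet, R, centre in _pattern_prisms(pattern, M_mag):
        if R is None:
            B += prism_field(magnet, pts)
        else:
            local = (pts - centre) @ R  # == R.T @ (p - c)
            B += prism_field(magnet, local) @ R.T
    return B


def height_above_film(pattern: PatternSpec, z_um: float) -> float:
    """z coordinate (µm, from film bottom) of a plane ``z_um`` above the film top."""
    return z_um + pattern.thickness_nm * 1e-3


def pattern_field_function(
    pattern: PatternSpec, mu0_M: float = 1.0, scale: float = 1.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Closure evaluating the pattern field at arbitrary (N, 3) µm points."""

    def f(points_um: np.ndarray) -> np.ndarray:
        return pattern_field(pattern, points_um, mu0_M=mu0_M, scale=scale)

    return f


@dataclass
class FieldGrid:
    """Vector flux density sampled on a plane.

    For horizontal planes ``xs``/``ys`` are in-plane µm coordinates and
    ``z_um`` is the height above the film top; for vertical (y-z) slices the
    two axes are y and z and ``z_um`` is None.  ``B[i, j]`` corresponds to
    ``(xs[i], ys[j])`` (ij indexing).
    """

    xs: np.ndarray
    ys: np.ndarray
    B: np.ndarray  # (nx, ny, 3) tesla
    z_um: float | None
    plane: str = "xy"
    evaluator: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.xs) < 2 or len(self.ys) < 2:
            raise ValueError("grid needs at least 2 points per axis")
        if self.B.shape != (len(self.xs), len(self.ys), 3):
            raise ValueError("B shape does not match grid axes")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.B, axis=2)

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.xs[1] - self.xs[0]), float(self.ys[1] - self.ys[0])


def field_map(
    pattern: PatternSpec,
    z_um: float = 2.0,
    window_um: tuple[float, float, float, float] | None = None,
    spacing_um: float = 1.0,
    mu0_M: float = 1.0,
    scale: float = 1.0,
    pad_um: float = 40.0,
) -> FieldGrid:
    """Dense horizontal field map at ``z_um`` above the film top.

    The default window is the pattern extent padded by ``pad_um`` so the
    region beyond bar ends — where the poles live — is included.
    """
    if z_um <= 0:
        raise ValueError("evaluation plane must lie strictly above the film top")
    if window_um is None:
        xmin, ymin, xmax, ymax = pattern.extent
        window_um = (xmin - pad_um, xmax + pad_um, ymin - pad_um, ymax + pad_um)
    xmin, xmax, ymin, ymax = window_um
    xs = np.arange(xmin, xmax + spacing_um / 2, spacing_um)
    ys = np.arange(ymin, ymax + spacing_um / 2, spacing_um)
    zc = height_above_film(pattern, z_um)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel(), np.full(XX.size, zc)])
    B = pattern_field(pattern, pts, mu0_M=mu0_M, scale=scale).reshape(len(xs), len(ys), 3)

    base = pattern_field_function(pattern, mu0_M=mu0_M, scale=scale)

    def on_plane(points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        if p.shape[1] == 2:
            p = np.column_stack([p, np.full(len(p), zc)])
        return base(p)

    return FieldGrid(xs=xs, ys=ys, B=B, z_um=z_um, plane="xy", evaluator=on_plane)


def field_slice_yz(
    pattern: PatternSpec,
    x_um: float = 0.0,
    y_range_um: tuple[float, float] = (-150.0, 150.0),
    z_range_um: tuple[float, float] = (0.5, 50.0),
    spacing_um: float = 1.0,
    mu0_M: float = 1.0,
) -> FieldGrid:
    """Vertical y-z slice of the field at fixed x (heights above film top)."""
    ys = np.arange(y_range_um[0], y_range_um[1] + spacing_um / 2, spacing_um)
    zs = np.arange(z_range_um[0], z_range_um[1] + spacing_um / 2, spacing_um)
    YY, ZZ = np.meshgrid(ys, zs, indexing="ij")
    zoff = pattern.thickness_nm * 1e-3
    pts = np.column_stack([np.full(YY.size, x_um), YY.ravel(), ZZ.ravel() + zoff])
    B = pattern_field(pattern, pts, mu0_M=mu0_M).reshape(len(ys), len(zs), 3)
    return FieldGrid(xs=ys, ys=zs, B=B, z_um=None, plane="yz")
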