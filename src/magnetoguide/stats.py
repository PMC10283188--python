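"""Estimators and tests for guidance experiments.

Covers the quantitative readouts of a micro-magnet guidance assay: the
speed of a tracked cell (OLS slope of cumulative path distance vs time,
valid in the constant-velocity drag-balance regime), occupancy of magnetic
patterns and hot spots by settled cells, the uniform-landing null fraction,
a one-sample proportion test against that null, and Welch's two-sample
t-test for group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps

from . import geometry
from .forces import HotSpot
from .kinetics import Track

__all__ = [
    "VelocityFit",
    "OccupancyReport",
    "estimate_velocity",
    "occupancy",
    "uniform_null_fraction",
    "proportion_test",
    "two_sample_t",
]


@dataclass(frozen=True)
class VelocityFit:
    slope_um_s: float
    intercept_um: float
    r_squared: float
    n_frames: int
    stderr_um_s: float


@dataclass
class OccupancyReport:
    n_cells: int
    n_touching_pattern: int
    fraction_touching: float
    n_hot_spots: int
    n_hot_spots_occupied: int
    fraction_hot_spots_occupied: float | None
    cells_per_bar_mean: float | None
    cells_per_bar_sd: float | None
    null_fraction_p0: float

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_velocity(track: Track | pd.DataFrame, distance: str = "net") -> VelocityFit:
    """Speed estimate from a time-lapse track.

    Fits distance travelled against time by ordinary least squares; under
    constant-velocity motion the slope is the speed.  ``distance='net'``
    (default) uses displacement from the start — unbiased under localization
    noise; ``'path'`` uses cumulative path length, which reads directly off
    a trajectory overlay but inflates the slope by ~σ²/step per frame when
    the track is noisy.  The two coincide for straight noiseless motion.
    """
    df = track.data if isinstance(track, Track) else track
    t = np.asarray(df["t_s"], dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 frames to fit a velocity")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    xy = np.column_stack([df["x_um"], df["y_um"]]).astype(float)
    if distance == "net":
        dist = np.linalg.norm(xy - xy[0], axis=1)
    elif distance == "path":
        dist = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    else:
        raise ValueError("distance must be 'net' or 'path'")
    res = sps.linregress(t, dist)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return VelocityFit(
        slope_um_s=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_frames=len(t),
        stderr_um_s=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
    )


def uniform_null_fraction(pattern: geometry.PatternSpec, dilation_radius_um: float = 10.0) -> float:
    """Expected fraction of uniformly landing cells that touch the pattern:
    the effective (dilated) area fraction of the unit cell."""
    return geometry.area_fractions(pattern, dilation_radius_um)["effective_fraction"]


def occupancy(
    final_positions: pd.DataFrame,
    pattern: geometry.PatternSpec,
    hot_spots: Sequence[HotSpot] = (),
    touch_radius_um: float = 10.0,
    capture_radius_um: float = 5.0,
) -> OccupancyReport:
    """Occupancy metrics of a settled cell population.

    A cell *touches* the pattern iff its centre lies within the footprint
    dilated by ``touch_radius_um`` (the cell's contact margin).  A hot spot
    is *occupied* iff at least one cell sits within ``capture_radius_um`` of
    it.  Cells-per-bar counts cells inside each bar's dilated footprint,
    assigning ties to the nearest bar centroid.
    """
    if touch_radius_um < 0:
        raise ValueError("touch radius must be >= 0")
    n_cells = len(final_positions)
    xs = final_positions["x_um"].to_numpy(dtype=float)
    ys = final_positions["y_um"].to_numpy(dtype=float)

    geom = geometry._buffered_geometry(pattern, touch_radius_um, "disk")
    if geom.is_empty or n_cells == 0:
        touching = np.zeros(n_cells, dtype=bool)
    else:
        shapely.prepare(geom)
        touching = shapely.contains_xy(geom, xs, ys)
    n_touch = int(touching.sum())

    n_hs = len(hot_spots)
    occ = 0
    if n_hs and n_cells:
        for hs in hot_spots:
            if np.any(np.hypot(xs - hs.x_um, ys - hs.y_um) <= capture_radius_um):
                occ += 1
    frac_occ = occ / n_hs if n_hs else None

    bars = pattern.rectangles()
    per_bar_mean = per_bar_sd = None
    if bars:
        centroids = np.array([((b.x1 + b.x2) / 2, (b.y1 + b.y2) / 2) for b in bars])
        counts = np.zeros(len(bars), dtype=int)
        bar_geoms = [b.polygon().buffer(touch_radius_um, quad_segs=geometry._QUAD_SEGS)
                     for b in bars]
        for x, y in zip(xs, ys):
            inside = [i for i, g in enumerate(bar_geoms) if g.covers(shapely.Point(x, y))]
            if not inside:
                continue
            if len(inside) == 1:
                counts[inside[0]] += 1
            else:  # overlap tie: nearest bar centroid
                d = [np.hypot(x - centroids[i][0], y - centroids[i][1]) for i in inside]
                counts[inside[int(np.argmin(d))]] += 1
        per_bar_mean = float(counts.mean())
        per_bar_sd = float(counts.std(ddof=1)) if len(bars) > 1 else 0.0

    return OccupancyReport(
        n_cells=n_cells,
        n_touching_pattern=n_touch,
        fraction_touching=n_touch / n_cells if n_cells else 0.0,
        n_hot_spots=n_hs,
        n_hot_spots_occupied=occ,
        fraction_hot_spots_occupied=frac_occ,
        cells_per_bar_mean=per_bar_mean,
        cells_per_bar_sd=per_bar_sd,
        null_fraction_p0=uniform_null_fraction(pattern, touch_radius_um),
    )


def proportion_test(
    k_successes: int,
    n_trials: int,
    p0: float,
    method: str = "exact",
    alternative: str = "two-sided",
) -> dict:
    """One-sample proportion test of H0: p = p0.

    ``method='exact'`` (default) uses the exact binomial test, which is
    well calibrated at moderate n; ``'z-cc'`` is the normal approximation
    with continuity correction and ``'z'`` without.  Two-sided by default.
    """
    if not 0 <= k_successes <= n_trials:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly between 0 and 1")
    if method == "exact":
        res = sps.binomtest(k_successes, n_trials, p0, alternative=alternative)
        stat, p = k_successes / n_trials, float(res.pvalue)
    elif method in ("z", "z-cc"):
        se = math.sqrt(n_trials * p0 * (1.0 - p0))
        dev = k_successes - n_trials * p0
        if method == "z-cc":
            dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
        z = dev / se
        if alternative == "two-sided":
            p = 2.0 * sps.norm.sf(abs(z))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        stat = z
    else:
        raise ValueError("method must be 'exact', 'z' or 'z-cc'")
    return {
        "statistic": float(stat),
        "p_value": float(min(p, 1.0)),
        "method": method,
        "n": n_trials,
    }


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> dict:
    """Welch's two-sample t-test (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p_value": 1.0,
                    "method": "welch-t (degenerate: zero variance)", "n": [len(a), len(b)]}
        return {"t": math.inf if a.mean() > b.mean() else -math.inf,
                "df": float(len(a) + len(b) - 2), "p_value": 0.0,
                "method": "welch-t (degenerate: zero variance)", "n": [len(a), len(b)]}
    res = sps.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p_value": float(res.pvalue),
        "method": "welch-t",
        "n": [len(a), len(b)],
    }
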