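"""Weighted mean center and standard deviational ellipse (SDE).

Planar computation on projected coordinates: the mean center is the
weight-weighted centroid; the ellipse axes are the principal directions of
the weighted covariance of deviations about that center, with the azimuth
of the LONG axis reported clockwise from true north in [0, 180).

Conventions for degenerate cases: when the cross-moment vanishes the
azimuth is 0 if the north-south variance is at least the east-west
variance, else 90; a perfectly circular pattern reports 0.  Semi-axes
equal the directional standard deviations by default; an optional sqrt(2)
scale matches the common GIS (1-standard-deviation ellipse) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atan2, cos, degrees, hypot, pi, radians, sin

import numpy as np
import pandas as pd


@dataclass
class WeightedPoints:
    """Planar points with nonnegative weights (projected units)."""

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.x.shape == self.y.shape == self.w.shape):
            raise ValueError("x, y, w must have identical shapes")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        if self.w.sum() <= 0:
            raise ValueError("total weight must be positive")


@dataclass
class EllipseParams:
    """SDE summary: center, axis standard deviations, azimuth, area.

    ``sigma_long``/``sigma_short`` are the directional standard deviations
    along the long/short principal axes; ``azimuth_deg`` is the long-axis
    bearing clockwise from north in [0, 180); semi-axes carry any requested
    scale factor; ``area`` = pi * long_semi * short_semi.
    """

    center_x: float
    center_y: float
    sigma_long: float
    sigma_short: float
    azimuth_deg: float
    long_semi: float
    short_semi: float
    area: float


def mean_center(points: WeightedPoints) -> tuple[float, float]:
    """Weighted centroid (X_w, Y_w)."""
    wsum = points.w.sum()
    return (float((points.w * points.x).sum() / wsum),
            float((points.w * points.y).sum() / wsum))


def directional_std(points: WeightedPoints, azimuth_deg: float) -> float:
    """Weighted standard deviation of deviations projected on a bearing.

    The bearing is measured clockwise from north, so its unit vector is
    (sin a, cos a) in (x=east, y=north) coordinates.
    """
    cx, cy = mean_center(points)
    a = radians(azimuth_deg)
    proj = (points.x - cx) * sin(a) + (points.y - cy) * cos(a)
    return float(np.sqrt((points.w * proj ** 2).sum() / points.w.sum()))


def sde(points: WeightedPoints, arcgis_scale: bool = False) -> EllipseParams:
    """Standard deviational ellipse of a weighted point pattern.

    Requires at least 3 points not all collinear.  The long axis is the
    direction maximizing the weighted directional variance (principal axis
    of the weighted covariance of deviations about the mean center).
    """
    active = points.w > 0
    if active.sum() < 3:
        raise ValueError("SDE needs at least 3 points with positive weight")
    cx, cy = mean_center(points)
    dx = points.x - cx
    dy = points.y - cy
    if _collinear(dx, dy, points.w):
        raise ValueError("points are collinear; ellipse is degenerate")
    wsum = points.w.sum()
    sxx = float((points.w * dx * dx).sum() / wsum)
    syy = float((points.w * dy * dy).sum() / wsum)
    sxy = float((points.w * dx * dy).sum() / wsum)

    # principal directions of [[sxx, sxy], [sxy, syy]]
    half_trace = 0.5 * (sxx + syy)
    half_diff = 0.5 * (sxx - syy)
    root = hypot(half_diff, sxy)
    lam_max = half_trace + root
    lam_min = half_trace - root
    if lam_max <= 0:
        raise ValueError("degenerate point pattern (zero dispersion)")
    if lam_min < 0:  # numerical noise
        lam_min = 0.0

    if sxy == 0.0:
        if syy >= sxx:
            azimuth = 0.0
        else:
            azimuth = 90.0
        sigma_long = float(np.sqrt(max(sxx, syy)))
        sigma_short = float(np.sqrt(min(sxx, syy)))
        if syy == sxx:
            azimuth = 0.0
    else:
        # eigenvector for lam_max: (sxy, lam_max - sxx) in (x, y)
        vx, vy = sxy, lam_max - sxx
        azimuth = degrees(atan2(vx, vy)) % 180.0
        sigma_long = float(np.sqrt(lam_max))
        sigma_short = float(np.sqrt(lam_min))

    scale = np.sqrt(2.0) if arcgis_scale else 1.0
    long_semi = scale * sigma_long
    short_semi = scale * sigma_short
    return EllipseParams(cx, cy, sigma_long, sigma_short, azimuth,
                         long_semi, short_semi,
                         pi * long_semi * short_semi)


def _collinear(dx: np.ndarray, dy: np.ndarray, w: np.ndarray) -> bool:
    pts = np.column_stack([dx[w > 0], dy[w > 0]])
    if len(pts) < 3:
        return True
    return np.linalg.matrix_rank(pts, tol=1e-10 * max(1.0,
                                 np.abs(pts).max())) < 2


def trajectory(yearly_points: dict[int, WeightedPoints]) -> pd.DataFrame:
    """Per-year mean centers plus inter-year displacement summaries.

    Returns one row per year with the center, the displacement distance and
    bearing (degrees clockwise from north) from the previous year, and the
    cumulative path length.
    """
    if len(yearly_points) < 2:
        raise ValueError("trajectory needs at least 2 years")
    rows = []
    prev = None
    cum = 0.0
    for year in sorted(yearly_points):
        cx, cy = mean_center(yearly_points[year])
        dist = bearing = np.nan
        if prev is not None:
            ddx, ddy = cx - prev[0], cy - prev[1]
            dist = hypot(ddx, ddy)
            bearing = degrees(atan2(ddx, ddy)) % 360.0 if dist > 0 else np.nan
            cum += dist
        rows.append({"year": year, "center_x": cx, "center_y": cy,
                     "distance": dist, "bearing_deg": bearing,
                     "cumulative_length": cum})
        prev = (cx, cy)
    return pd.DataFrame(rows)


def yearly_ellipses(scores, coords: pd.DataFrame,
                    arcgis_scale: bool = False) -> pd.DataFrame:
    """SDE parameters per year, weighting provinces by their score."""
    rows = []
    years = np.sort(scores.index.get_level_values("year").unique())
    for year in years:
        s = scores.xs(year, level="year")
        common = [p for p in s.index if p in coords.index]
        pts = WeightedPoints(coords.loc[common, "x"].to_numpy(),
                             coords.loc[common, "y"].to_numpy(),
                             s.loc[common].to_numpy())
        e = sde(pts, arcgis_scale=arcgis_scale)
        rows.append({"year": int(year), "center_x": e.center_x,
                     "center_y": e.center_y, "sigma_long": e.sigma_long,
                     "sigma_short": e.sigma_short,
                     "azimuth_deg": e.azimuth_deg,
                     "long_semi": e.long_semi, "short_semi": e.short_semi,
                     "area": e.area})
    return pd.DataFrame(rows)
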