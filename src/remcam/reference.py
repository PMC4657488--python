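"""Census-based reference densities from kernel home ranges.

The reference density for a habitat is D_ref = sum_i N_i * p_i / A: each
censused pride contributes its known female count N_i weighted by the
proportion p_i of its 75% kernel home range lying in the habitat, and A is
the habitat area effectively sampled by the camera grid — the convex hull of
the camera locations buffered outward by w, half the mean home-range
diameter, intersected with the habitat polygon. Uncertainty in D_ref is
driven by w: the interval endpoints recompute A at the 95% limits of the
mean home-range radius.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.base import BaseGeometry

from .types import (
    BufferWidth,
    HomeRange,
    ReferenceResult,
    UtilizationDistribution,
    ValidationError,
)

_Z95 = 1.959963984540054


def reference_bandwidth(points: np.ndarray) -> float:
    """Silverman-type reference bandwidth for a bivariate kernel.

    One shared isotropic bandwidth, h = sqrt((var(x) + var(y)) / 2) * n^(-1/6).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    sigma = math.sqrt((pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)) / 2.0)
    if sigma <= 0:
        raise ValidationError("all points identical: zero reference bandwidth")
    return sigma * n ** (-1.0 / 6.0)


def fit_ud(
    points: np.ndarray,
    cell: Optional[float] = None,
    pad_bandwidths: float = 3.0,
) -> UtilizationDistribution:
    """Bivariate Gaussian kernel utilization distribution on a regular grid.

    ``cell`` defaults to a quarter of the reference bandwidth; the grid pads
    the point cloud by ``pad_bandwidths`` bandwidths so that effectively all
    kernel mass is captured before normalisation to unit total mass.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of planar km coordinates")
    if pts.shape[0] < 5:
        raise ValidationError(f"need >= 5 points for a UD, got {pts.shape[0]}")
    h = reference_bandwidth(pts)
    if cell is None:
        cell = h / 4.0
    if cell <= 0:
        raise ValidationError("cell size must be positive")
    lo = pts.min(axis=0) - pad_bandwidths * h
    hi = pts.max(axis=0) + pad_bandwidths * h
    nx = max(int(math.ceil((hi[0] - lo[0]) / cell)), 2)
    ny = max(int(math.ceil((hi[1] - lo[1]) / cell)), 2)
    xs = lo[0] + (np.arange(nx) + 0.5) * cell
    ys = lo[1] + (np.arange(ny) + 0.5) * cell
    # Separable Gaussian kernel: outer products accumulated over points.
    dx = xs[None, :] - pts[:, 0:1]  # (n, nx)
    dy = ys[None, :] - pts[:, 1:2]  # (n, ny)
    gx = np.exp(-0.5 * (dx / h) ** 2)
    gy = np.exp(-0.5 * (dy / h) ** 2)
    dens = gx.T @ gy  # (nx, ny)
    total = dens.sum()
    if total <= 0:
        raise ValidationError("degenerate UD: zero total kernel mass on grid")
    return UtilizationDistribution(mass=dens / total, x0=float(lo[0]), y0=float(lo[1]),
                                   cell=float(cell), bandwidth=float(h))


def isopleth(ud: UtilizationDistribution, level: float = 0.75,
             pride_id: str = "") -> HomeRange:
    """Minimum-area region holding ``level`` of the UD's probability mass.

    Grid cells are accumulated in decreasing density order until the
    cumulative mass reaches the level; the region is polygonised from the
    selected cells and its area is the selected-cell count times cell area.
    """
    if not 0 < level < 1:
        raise ValidationError(f"isopleth level must be in (0, 1), got {level}")
    mass = np.asarray(ud.mass, dtype=float)
    flat = mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level)) + 1
    k = min(k, flat.size)
    chosen = order[:k]
    ii, jj = np.unravel_index(chosen, mass.shape)
    x0 = ud.x0 + ii * ud.cell
    y0 = ud.y0 + jj * ud.cell
    boxes = shapely.box(x0, y0, x0 + ud.cell, y0 + ud.cell)
    poly = shapely.union_all(boxes)
    if isinstance(poly, BaseGeometry) and poly.is_empty:
        raise ValidationError("isopleth selected no cells")
    return HomeRange(pride_id=pride_id, level=level, polygon=poly,
                     area=float(k) * ud.cell ** 2)


def overlap_proportion(hr: HomeRange, habitat_polygon: BaseGeometry) -> float:
    """Proportion of a home range's area overlapping a habitat polygon."""
    area = hr.polygon.area
    if area <= 0:
        raise ValidationError("zero-area home range")
    return hr.polygon.intersection(habitat_polygon).area / area


def buffer_width(
    hr_areas_km2: Sequence[float],
    method: str = "radius_of_mean_area",
    quantile: str = "normal",
) -> BufferWidth:
    """Buffer width w (km): half the mean home-range diameter, with 95% limits.

    The per-pride circular-equivalent radius is rho_i = sqrt(a_i / pi). The
    default operationalisation takes w as the circular-equivalent radius of
    the *mean area*, w = sqrt(mean(a) / pi); ``method='mean_of_radii'`` uses
    mean(rho_i) instead. The 95% limits are mean(rho_i) -/+ 1.96 * SE(rho_i)
    (or a t quantile with ``quantile='t'``), the pride radii being the
    sample.
    """
    areas = np.asarray(list(hr_areas_km2), dtype=float)
    if areas.size < 1:
        raise ValidationError("need at least one home-range area")
    if np.any(areas <= 0):
        raise ValidationError("home-range areas must be positive")
    rho = np.sqrt(areas / math.pi)
    if method == "radius_of_mean_area":
        w = math.sqrt(areas.mean() / math.pi)
    elif method == "mean_of_radii":
        w = float(rho.mean())
    else:
        raise ValidationError(f"unknown buffer-width method {method!r}")
    if areas.size >= 2:
        se = float(rho.std(ddof=1) / math.sqrt(rho.size))
        if quantile == "normal":
            q = _Z95
        elif quantile == "t":
            q = float(stats.t.ppf(0.975, rho.size - 1))
        else:
            raise ValidationError(f"unknown quantile rule {quantile!r}")
        lo = max(float(rho.mean()) - q * se, 0.0)
        hi = float(rho.mean()) + q * se
    else:
        lo = hi = w
    return BufferWidth(w=float(w), w_low=lo, w_high=hi, n=int(areas.size))


def effective_area(
    camera_points: np.ndarray,
    w: float,
    habitat_polygon: Optional[BaseGeometry] = None,
) -> float:
    """Habitat area effectively sampled by the grid (km^2).

    Convex hull of the camera locations, Minkowski-buffered outward by w,
    intersected with the habitat polygon when one is given.
    """
    pts = np.asarray(camera_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 camera points (x, y)")
    if w < 0:
        raise ValidationError("buffer width must be >= 0")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValidationError("camera points are collinear; hull has no area")
    # quad_segs=64 keeps the circular-arc approximation error below ~1e-4.
    buffered = hull.buffer(w, quad_segs=64) if w > 0 else hull
    if habitat_polygon is not None:
        buffered = buffered.intersection(habitat_polygon)
    return float(buffered.area)


def effective_area_geometry(camera_points, w, habitat_polygon=None):
    """As :func:`effective_area` but returning (hull, buffered-intersected)."""
    pts = np.asarray(camera_points, dtype=float)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    buffered = hull.buffer(w, quad_segs=64) if w > 0 else hull
    if habitat_polygon is not None:
        buffered = buffered.intersection(habitat_polygon)
    return hull, buffered


def reference_density(
    prides: Sequence[Tuple[float, float]],
    a: float,
    a_low: Optional[float] = None,
    a_high: Optional[float] = None,
    habitat: str = "",
    season: str = "",
    w: Optional[BufferWidth] = None,
) -> ReferenceResult:
    """Reference density sum(N_i * p_i) / A with buffer-driven CI.

    ``prides`` is a sequence of (N_i, p_i). ``a_low``/``a_high`` are the
    areas at the lower/upper buffer-width limits; a larger buffer gives a
    larger area and hence a smaller density, so the CI endpoints swap.
    """
    if a <= 0:
        raise ValidationError("effective area must be positive")
    prides = list(prides)
    if not prides:
        import logging

        logging.getLogger("remcam.reference").warning(
            "no prides overlap habitat %r; reference density is zero", habitat
        )
    for n_i, p_i in prides:
        if not 0.0 <= p_i <= 1.0:
            raise ValidationError(f"overlap proportion must be in [0, 1], got {p_i}")
        if n_i < 0:
            raise ValidationError("pride female counts must be >= 0")
    abundance = float(sum(n_i * p_i for n_i, p_i in prides))
    d = abundance / a
    if a_low is not None and a_high is not None:
        if a_low <= 0 or a_high <= 0:
            raise ValidationError("CI areas must be positive")
        ci = sorted((abundance / a_low, abundance / a_high))
        lo, hi = ci
        lo, hi = min(lo, d), max(hi, d)
    else:
        lo = hi = d
    return ReferenceResult(habitat=habitat, season=season, abundance=abundance,
                           a=a, d_ref=d, ci_low=lo, ci_high=hi, w=w)
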