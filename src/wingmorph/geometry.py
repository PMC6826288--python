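"""Whole-wing geometric traits.

All statistics are computed on area-normalized wings (total area 1), which
removes absolute size: what remains is boundary elongation/complexity
(normalized perimeter ``P``), local contour curvature ``kappa(s)``, and the
density of internal venation (scaled internal length ``L``).

The normalized perimeter is the isoperimetrically anchored statistic

    P = P_tilde / sqrt(A) - 2 * sqrt(pi)

where ``P_tilde`` is the boundary perimeter and ``A`` the wing area: a circle
of unit area scores exactly 0, and the isoperimetric inequality makes P >= 0
for every simple closed contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .wing_model import (
    SegmentedWing,
    WingModelError,
    ring_area,
    ring_perimeter,
)

__all__ = [
    "CurvatureProfile",
    "ShapeStats",
    "normalize_area",
    "orient_contour",
    "resample_contour",
    "curvature_profile",
    "fit_circle_kasa",
    "normalized_perimeter",
    "internal_vein_length",
    "principal_axis_angle",
]


@dataclass(frozen=True)
class CurvatureProfile:
    """Sampled non-negative curvature along the oriented boundary.

    ``s`` is the arc-length fraction in [0, 1) measured clockwise from the
    wing base; ``kappa`` is |1/R| of the local three-point circle fit.  When
    ``scaled`` is true, kappa has been multiplied by the total perimeter and
    is therefore scale invariant (a circle scores 2*pi everywhere).
    """

    s: np.ndarray
    kappa: np.ndarray
    scaled: bool

    def __post_init__(self) -> None:
        if len(self.s) != len(self.kappa):
            raise WingModelError("s and kappa must have equal length")


@dataclass(frozen=True)
class ShapeStats:
    """Dimensionless whole-wing shape statistics."""

    P: float              # normalized perimeter, >= 0
    L: float              # internal vein length scaled by sqrt(area)
    L_over_P: float       # internal length scaled by the actual perimeter
    perimeter: float      # actual boundary perimeter P_tilde
    total_edge_length: float  # sum of all venation-graph edge lengths


def normalize_area(wing: SegmentedWing) -> SegmentedWing:
    """Rescale coordinates uniformly so the boundary encloses area 1."""
    area = wing.area
    if not np.isfinite(area) or area <= 0:
        raise WingModelError("cannot normalize a wing with degenerate area")
    if wing.normalized and abs(area - 1.0) <= 1e-12:
        return wing
    return wing.scaled(1.0 / np.sqrt(area), normalized=True)


def principal_axis_angle(ring: np.ndarray) -> float:
    """Orientation (radians, in (-pi/2, pi/2]) of the long axis of a polygon.

    Computed from the central second moments of area of the region; returns
    0 for (near-)isotropic shapes such as circles and squares.
    """
    pts = np.asarray(ring, dtype=float)
    a = ring_area(pts)
    if a == 0:
        raise WingModelError("degenerate ring")
    if a < 0:
        pts = pts[::-1]
        a = -a
    x, y = pts.T
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    x, y = x - cx, y - cy
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    sxx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    syy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    sxy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    aniso = np.hypot(sxx - syy, 2 * sxy)
    if aniso <= 1e-9 * (sxx + syy):
        return 0.0
    theta = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return float(theta)


def orient_contour(wing_or_ring: SegmentedWing | np.ndarray) -> np.ndarray:
    """Return the boundary as a clockwise open ring starting at the wing base.

    The base (s = 0) is the leftmost boundary point once the wing's long
    (principal) axis is horizontal, ties broken by the lowest y.  Coordinates
    are returned in the original frame; the rotation is used only to choose
    the base point.
    """
    if isinstance(wing_or_ring, SegmentedWing):
        ring = wing_or_ring.boundary
    else:
        ring = np.asarray(wing_or_ring, dtype=float)
        if len(ring) >= 2 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
    if not Polygon(ring).is_valid:
        raise WingModelError("boundary contour is not simple")
    if ring_area(ring) > 0:        # counterclockwise -> reverse to clockwise
        ring = ring[::-1]
    theta = principal_axis_angle(ring)
    c, s = np.cos(theta), np.sin(theta)
    # rotate by -theta so the long axis is horizontal
    rx = ring @ np.array([[c, s], [-s, c]]).T
    base = np.lexsort((rx[:, 1], np.round(rx[:, 0], 9)))[0]
    return np.roll(ring, -base, axis=0)


def resample_contour(ring: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed ring to ``n`` points uniformly spaced in arc length."""
    pts = np.asarray(ring, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise WingModelError("degenerate contour")
    target = np.arange(n) * total / n
    xs = np.interp(target, cum, closed[:, 0])
    ys = np.interp(target, cum, closed[:, 1])
    return np.column_stack([xs, ys])


def fit_circle_kasa(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (cx, cy, R).

    Solves the linear system for x^2 + y^2 = 2 cx x + 2 cy y + c.  With
    exactly three non-collinear points this is the circumscribed circle.
    Collinear input returns an infinite radius.
    """
    pts = np.asarray(points, dtype=float)
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        return float(cx), float(cy), float("inf")
    return float(cx), float(cy), float(np.sqrt(r2))


def curvature_profile(
    contour: np.ndarray,
    window: float = 0.02,
    n_samples: int | None = None,
    scaled: bool = False,
) -> CurvatureProfile:
    """Windowed three-point curvature along a closed contour.

    The contour is resampled uniformly by arc length; for each sample ``p_i``
    the circle through ``p_{i-N}, p_i, p_{i+N}`` (indices cyclic, N the
    sample offset matching an arc distance of ``window`` x perimeter) gives
    ``kappa_i = 1/R``, reported as an absolute value.  Collinear triples give
    kappa = 0.  With ``scaled`` the profile is multiplied by the perimeter.
    """
    if not 0 < window < 0.5:
        raise WingModelError("curvature window must lie in (0, 0.5)")
    m = int(n_samples) if n_samples else max(1000, int(np.ceil(3.0 / window)))
    pts = resample_contour(contour, m)
    perimeter = ring_perimeter(pts)
    n = max(1, int(round(window * m)))
    a = np.roll(pts, n, axis=0)
    b = pts
    c = np.roll(pts, -n, axis=0)
    ab = b - a
    bc = c - b
    ca = a - c
    cross = np.abs(ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0])
    denom = (np.hypot(*ab.T) * np.hypot(*bc.T) * np.hypot(*ca.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    kappa = np.nan_to_num(kappa, nan=0.0, posinf=0.0)
    if scaled:
        kappa = kappa * perimeter
    s = np.arange(m) / m
    return CurvatureProfile(s=s, kappa=kappa, scaled=scaled)


def normalized_perimeter(wing_or_ring: SegmentedWing | np.ndarray) -> float:
    """Isoperimetrically anchored boundary statistic P = P~/sqrt(A) - 2 sqrt(pi)."""
    if isinstance(wing_or_ring, SegmentedWing):
        ring = wing_or_ring.boundary
    else:
        ring = np.asarray(wing_or_ring, dtype=float)
    area = abs(ring_area(ring))
    if area <= 0 or not np.isfinite(area):
        raise WingModelError("degenerate boundary")
    return float(ring_perimeter(ring) / np.sqrt(area) - 2.0 * np.sqrt(np.pi))


def internal_vein_length(wing: SegmentedWing) -> ShapeStats:
    """Total internal venation length and the (P, L) morphospace point.

    Sums the lengths of all venation-graph edges and subtracts the boundary
    perimeter (computed separately), leaving the internal vein length.  The
    wing is area-normalized first if needed, so ``L`` is the internal length
    scaled by sqrt(area); ``L_over_P`` rescales by the actual perimeter
    instead.  A small negative residual is clamped to zero.
    """
    if wing.edges is None or not wing.edges:
        raise WingModelError("wing has no venation graph")
    if not wing.normalized:
        wing = normalize_area(wing)
    total = float(sum(e.length(wing.vertices) for e in wing.edges))
    perimeter = wing.perimeter
    internal = total - perimeter
    if internal < 0:
        if internal < -1e-6 * max(perimeter, 1.0):
            warnings.warn(
                f"internal vein length clamped to 0 (raw value {internal:.3g}); "
                "graph edges cover less than the boundary perimeter",
                stacklevel=2)
        internal = 0.0
    area = wing.area
    return ShapeStats(
        P=normalized_perimeter(wing),
        L=internal / np.sqrt(area),
        L_over_P=internal / perimeter,
        perimeter=perimeter,
        total_edge_length=total,
    )
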