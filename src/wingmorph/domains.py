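"""Per-domain shape statistics and binned proximal-distal (span-wise) profiles.

Each vein-bounded domain is summarized by two dimensionless numbers:

* circularity ``c = 4 * pi * a / p**2`` (isoperimetric quotient), 1 for a
  circle and decreasing toward 0 for elongated shapes; the reciprocal
  phrasing "perimeter over equal-area circumference" equals ``c ** -0.5``
  and is exposed as :attr:`DomainStats.perimeter_ratio`;
* fractional area ``f = a / A_wing``, the share of the wing the domain fills.

The proximal-distal trace slices the wing into equal-width bins along its
long axis (base at 0, tip at 1) and reports, per bin, the area-weighted mean
domain area and mean circularity, each domain weighted by how much of it
overlaps the bin.  A discrete Gaussian smooths the binned series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from shapely import clip_by_rect
from shapely.geometry import Polygon

from .geometry import normalize_area, principal_axis_angle
from .wing_model import SegmentedWing, WingModelError

__all__ = ["DomainStats", "PDTrace", "domain_metrics", "pd_trace"]


@dataclass(frozen=True)
class DomainStats:
    """Shape summary of one vein-bounded domain (wing area normalized to 1)."""

    id: int
    area: float
    perimeter: float
    circularity: float
    fractional_area: float

    @property
    def perimeter_ratio(self) -> float:
        """Domain perimeter over the circumference of the equal-area circle."""
        return float(self.circularity ** -0.5)


@dataclass(frozen=True)
class PDTrace:
    """Binned span-wise profile of domain area and circularity.

    ``mean_area``/``mean_circularity`` are the raw per-bin weighted means
    (NaN in empty bins); the ``smoothed_*`` copies are Gaussian-filtered over
    the non-empty bins.  ``overlap_fractions[j, i]`` is the fraction of
    domain ``j``'s area falling in bin ``i`` (each row sums to 1), and
    ``bin_weights`` the total weighted area per bin.
    """

    n_bins: int
    bin_centers: np.ndarray
    mean_area: np.ndarray
    mean_circularity: np.ndarray
    smoothed_area: np.ndarray
    smoothed_circularity: np.ndarray
    bin_weights: np.ndarray
    overlap_fractions: np.ndarray
    axis_angle: float
    base_flipped: bool


def domain_metrics(wing: SegmentedWing) -> list[DomainStats]:
    """Circularity and fractional area for every domain of a normalized wing.

    Degenerate (zero-area) domains are excluded with a warning.
    """
    if not wing.normalized:
        wing = normalize_area(wing)
    wing_area = wing.area
    out: list[DomainStats] = []
    for d in wing.domains:
        a, p = d.area, d.perimeter
        if a <= 0 or p <= 0:
            warnings.warn(f"domain {d.id} is degenerate and was excluded",
                          stacklevel=2)
            continue
        out.append(DomainStats(
            id=d.id,
            area=a,
            perimeter=p,
            circularity=4.0 * np.pi * a / p ** 2,
            fractional_area=a / wing_area,
        ))
    return out


def _pd_projection(wing: SegmentedWing) -> tuple[float, bool]:
    """Long-axis angle and whether the axis must be flipped so the base is at 0.

    The base end is taken as the half of the span with the sparser vertex
    cluster: cross-venation (and hence junction density) concentrates
    toward the distal end and trailing edge in densely veined wings, so the
    crowded half is read as the tip.  Ties leave the axis unflipped.
    """
    theta = principal_axis_angle(wing.boundary)
    c, s = np.cos(-theta), np.sin(-theta)
    proj = wing.vertices @ np.array([c, -s])
    bproj = wing.boundary @ np.array([c, -s])
    mid = 0.5 * (bproj.min() + bproj.max())
    flipped = int(np.sum(proj < mid)) > int(np.sum(proj > mid))
    return theta, flipped


def pd_trace(
    wing: SegmentedWing,
    n_bins: int = 25,
    sigma: float = 2.0 / 25.0,
    rescale_perimeter: bool = False,
) -> PDTrace:
    """Area-weighted mean domain area and circularity in span-wise bins.

    Parameters
    ----------
    n_bins:
        Number of equal-width slabs perpendicular to the proximal-distal
        axis (default 25).
    sigma:
        Gaussian smoothing width as a fraction of the span (default 2/25,
        i.e. two bins at the default binning).
    rescale_perimeter:
        When set, the mean-area series (raw and smoothed) is multiplied by
        the wing perimeter.
    """
    if n_bins < 2:
        raise WingModelError("n_bins must be at least 2")
    if not wing.normalized:
        wing = normalize_area(wing)
    stats = domain_metrics(wing)
    theta, flipped = _pd_projection(wing)
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    sign = -1.0 if flipped else 1.0

    bx, by = (wing.boundary @ rot.T).T
    bx = sign * bx
    lo, hi = bx.min(), bx.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    # guard: the outermost slabs must cover boundary points exactly on lo/hi
    edges[0] -= 1e-9 * (hi - lo)
    edges[-1] += 1e-9 * (hi - lo)

    stats_by_id = {d.id: d for d in stats}
    polys = []
    for d in wing.domains:
        if d.id not in stats_by_id:
            continue
        rr = d.ring @ rot.T
        ring = np.column_stack([sign * rr[:, 0], rr[:, 1]])
        poly = Polygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append((d.id, poly))

    n_dom = len(polys)
    overlap = np.zeros((n_dom, n_bins))
    ymin, ymax = by.min() - 1.0, by.max() + 1.0
    for j, (_, poly) in enumerate(polys):
        pa = poly.area
        px0, py0, px1, py1 = poly.bounds
        for i in range(n_bins):
            if px1 < edges[i] or px0 > edges[i + 1]:
                continue
            piece = clip_by_rect(poly, edges[i], ymin, edges[i + 1], ymax)
            if not piece.is_empty:
                overlap[j, i] = piece.area / pa

    areas = np.array([stats_by_id[did].area for did, _ in polys])
    circs = np.array([stats_by_id[did].circularity for did, _ in polys])
    w = overlap * areas[:, None]          # w[j, i] = f_ij * a_j
    bin_w = w.sum(axis=0)
    nonempty = bin_w > 1e-12
    mean_area = np.full(n_bins, np.nan)
    mean_circ = np.full(n_bins, np.nan)
    mean_area[nonempty] = (w * areas[:, None]).sum(axis=0)[nonempty] / bin_w[nonempty]
    mean_circ[nonempty] = (w * circs[:, None]).sum(axis=0)[nonempty] / bin_w[nonempty]

    sigma_bins = sigma * n_bins
    smoothed_area = np.full(n_bins, np.nan)
    smoothed_circ = np.full(n_bins, np.nan)
    idx = np.flatnonzero(nonempty)
    if len(idx):
        smoothed_area[idx] = gaussian_filter1d(mean_area[idx], sigma_bins, mode="reflect")
        smoothed_circ[idx] = gaussian_filter1d(mean_circ[idx], sigma_bins, mode="reflect")

    if rescale_perimeter:
        perim = wing.perimeter
        mean_area = mean_area * perim
        smoothed_area = smoothed_area * perim

    centers = (np.arange(n_bins) + 0.5) / n_bins
    return PDTrace(
        n_bins=n_bins,
        bin_centers=centers,
        mean_area=mean_area,
        mean_circularity=mean_circ,
        smoothed_area=smoothed_area,
        smoothed_circularity=smoothed_circ,
        bin_weights=bin_w,
        overlap_fractions=overlap,
        axis_angle=theta,
        base_flipped=flipped,
    )
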