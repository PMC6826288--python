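"""Ground-truthed synthetic wings for testing every stage of the pipeline.

A synthetic wing is a smooth closed boundary (circle, ellipse or teardrop)
tessellated into a target number of vein-bounded domains by a bounded,
Lloyd-relaxed Voronoi partition of seed points.  A span-wise density
gradient concentrates seeds toward the wing tip (and, optionally, the
trailing edge), emulating the asymmetric venation of dragonfly-like wings;
a gradient of 1 gives a uniform, fly-like tessellation.

Wings can also be rasterized: membrane bright, veins and background dark,
with a controllable vein width in pixels, which provides a known ground
truth for the image-segmentation round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import voronoi_diagram

from .wing_model import SegmentedWing, WingImage, WingModelError

__all__ = [
    "SynthSpec",
    "generate_synthetic_wing",
    "rasterize_wing",
    "fixture_battery",
]

_BOUNDARIES = ("circle", "ellipse", "teardrop")


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic wing.

    ``density_gradient`` multiplies the seed density from base (x = -1) to
    tip (x = +1); ``chord_gradient`` does the same from leading to trailing
    edge.  Both default to 1 (uniform).
    """

    n_domains: int = 50
    boundary: str = "ellipse"
    aspect: float = 2.0
    skew: float = 0.4
    density_gradient: float = 1.0
    chord_gradient: float = 1.0
    vein_width_px: float = 3.0
    raster_span_px: int = 1200
    boundary_points: int = 256
    lloyd_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise WingModelError("n_domains must be >= 1")
        if self.boundary not in _BOUNDARIES:
            raise WingModelError(f"boundary must be one of {_BOUNDARIES}")
        if self.aspect <= 0:
            raise WingModelError("aspect must be positive")
        if self.vein_width_px < 1:
            raise WingModelError("vein_width_px must be >= 1")
        if self.density_gradient <= 0 or self.chord_gradient <= 0:
            raise WingModelError("density gradients must be positive")


def boundary_ring(spec: SynthSpec) -> np.ndarray:
    """Open coordinate ring of the wing outline (counterclockwise)."""
    t = np.linspace(0.0, 2 * np.pi, spec.boundary_points, endpoint=False)
    if spec.boundary == "circle":
        x, y = np.cos(t), np.sin(t)
    elif spec.boundary == "ellipse":
        x, y = np.cos(t), np.sin(t) / spec.aspect
    else:  # teardrop: chord narrows toward the base, bulges toward the tip
        x = np.cos(t)
        y = np.sin(t) * (1.0 + spec.skew * x) / spec.aspect
    return np.column_stack([x, y])


def _sample_seeds(spec: SynthSpec, poly: Polygon, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample seed points with exponential span/chord density gradients."""
    minx, miny, maxx, maxy = poly.bounds
    pts: list[np.ndarray] = []
    g, h = spec.density_gradient, spec.chord_gradient
    budget = 0
    while len(pts) < spec.n_domains:
        budget += 1
        if budget > 2000:
            raise WingModelError("could not place the requested seed count")
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(4 * spec.n_domains + 16, 2))
        u = rng.uniform(size=len(cand))
        tx = (cand[:, 0] - minx) / (maxx - minx)
        ty = (maxy - cand[:, 1]) / (maxy - miny)      # leading edge = top
        density = g ** tx * h ** ty / (max(g, 1.0) * max(h, 1.0))
        keep = u < density
        cand = cand[keep]
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        for p in cand[inside]:
            pts.append(p)
            if len(pts) == spec.n_domains:
                break
    return np.array(pts)


def _voronoi_cells(points: np.ndarray, poly: Polygon) -> list[Polygon]:
    """Clipped Voronoi cell per input point, in input order."""
    diagram = voronoi_diagram(MultiPoint(points), envelope=poly.buffer(1.0))
    cells: list[Polygon | None] = [None] * len(points)
    raw = list(diagram.geoms)
    seed_geoms = shapely.points(points)
    for cell in raw:
        for i in np.flatnonzero(shapely.contains(cell, seed_geoms)):
            cells[i] = cell
    for i, c in enumerate(cells):
        if c is None:       # point exactly on a cell edge; take nearest cell
            d = shapely.distance(np.array(raw, dtype=object), seed_geoms[i])
            cells[i] = raw[int(np.argmin(d))]
    out = []
    for i, c in enumerate(cells):
        clipped = c.intersection(poly)
        if clipped.is_empty:
            raise WingModelError("a Voronoi cell fell outside the boundary")
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        out.append(clipped)
    return out


def generate_synthetic_wing(spec: SynthSpec) -> SegmentedWing:
    """Deterministic synthetic wing matching ``spec`` (same seed, same wing)."""
    ring = boundary_ring(spec)
    poly = Polygon(ring)
    if spec.n_domains == 1:
        return SegmentedWing.from_domain_polygons([ring])
    if spec.n_domains > spec.boundary_points ** 2:
        raise WingModelError("n_domains exceeds the boundary resolution")
    rng = np.random.default_rng(spec.seed)
    seeds = _sample_seeds(spec, poly, rng)
    for _ in range(spec.lloyd_iterations):
        cells = _voronoi_cells(seeds, poly)
        seeds = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    cells = _voronoi_cells(seeds, poly)
    rings = [np.asarray(c.exterior.coords)[:-1] for c in cells]
    return SegmentedWing.from_domain_polygons(rings)


def rasterize_wing(
    wing: SegmentedWing,
    vein_width_px: float = 3.0,
    raster_span_px: int = 1200,
    return_transform: bool = False,
):
    """Render a wing as a grayscale raster: membrane 0.95, veins/background 0.05.

    The wing is scaled so its bounding-box width equals ``raster_span_px``
    pixels; vein centrelines (all graph edges, boundary included) are drawn
    ``vein_width_px`` wide with hard (non-anti-aliased) fills.  With
    ``return_transform`` the function also returns ``(scale, offset_xy,
    n_rows)`` mapping wing coordinates to pixel-centre coordinates via
    ``col = x * scale + ox``, ``row = n_rows - (y * scale + oy)``.
    """
    from skimage.draw import polygon as draw_polygon

    if raster_span_px < 8 * vein_width_px:
        raise WingModelError("raster span too small for the vein width")
    pts = wing.vertices
    minx, miny = pts.min(axis=0)
    maxx, maxy = pts.max(axis=0)
    scale = raster_span_px / (maxx - minx)
    margin = int(np.ceil(2 * vein_width_px)) + 4
    ox = margin - minx * scale
    oy = margin - miny * scale
    n_cols = int(np.ceil((maxx - minx) * scale)) + 2 * margin
    n_rows = int(np.ceil((maxy - miny) * scale)) + 2 * margin

    def to_rc(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = coords[:, 0] * scale + ox
        r = n_rows - (coords[:, 1] * scale + oy)
        return r, c

    img = np.full((n_rows, n_cols), 0.05)
    rr, cc = draw_polygon(*to_rc(wing.boundary), shape=img.shape)
    img[rr, cc] = 0.95

    half = vein_width_px / 2.0
    lines = []
    for e in wing.edges:
        coords = (e.polyline if e.polyline is not None
                  else wing.vertices[[e.a, e.b]])
        r, c = to_rc(np.asarray(coords, dtype=float))
        lines.append(shapely.linestrings(np.column_stack([r, c])))
    veins = shapely.unary_union(shapely.buffer(
        np.array(lines, dtype=object), half, quad_segs=4))
    geoms = veins.geoms if veins.geom_type == "MultiPolygon" else [veins]
    for geom in geoms:
        xy = np.asarray(geom.exterior.coords)
        rr, cc = draw_polygon(xy[:, 0], xy[:, 1], shape=img.shape)
        img[rr, cc] = 0.05
        for hole in geom.interiors:
            xy = np.asarray(hole.coords)
            rr, cc = draw_polygon(xy[:, 0], xy[:, 1], shape=img.shape)
            img[rr, cc] = 0.95
    image = WingImage(img)
    if return_transform:
        return image, (scale, (ox, oy), n_rows)
    return image


def fixture_battery() -> list[SynthSpec]:
    """The canonical 12-wing fixture set: 1-500 domains, 3 outline shapes,
    uniform and tip-ward (3x) density gradients, pinned seeds."""
    return [
        SynthSpec(n_domains=1, boundary="circle", seed=101),
        SynthSpec(n_domains=5, boundary="ellipse", aspect=2.0, seed=102),
        SynthSpec(n_domains=10, boundary="teardrop", aspect=2.0, skew=0.3, seed=103),
        SynthSpec(n_domains=25, boundary="ellipse", aspect=3.0, seed=104),
        SynthSpec(n_domains=50, boundary="circle", seed=105),
        SynthSpec(n_domains=50, boundary="ellipse", aspect=2.0,
                  density_gradient=3.0, seed=106),
        SynthSpec(n_domains=100, boundary="teardrop", aspect=2.5, skew=0.4, seed=107),
        SynthSpec(n_domains=100, boundary="ellipse", aspect=2.0,
                  density_gradient=3.0, seed=108),
        SynthSpec(n_domains=200, boundary="ellipse", aspect=2.0, seed=109),
        SynthSpec(n_domains=200, boundary="teardrop", aspect=3.0, skew=0.3,
                  density_gradient=3.0, seed=110),
        SynthSpec(n_domains=350, boundary="ellipse", aspect=2.5,
                  density_gradient=3.0, seed=111),
        SynthSpec(n_domains=500, boundary="ellipse", aspect=3.0,
                  density_gradient=3.0, seed=112),
    ]
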