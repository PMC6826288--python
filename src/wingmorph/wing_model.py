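"""Core data model for segmented insect wings, plus readers and writers.

A segmented wing is a planar tessellation: a closed outer contour, a set of
vein-bounded membrane polygons ("domains") that tile it, and the venation
graph whose nodes are polygon vertices and whose edges are the unique
polygon-boundary segments (vein stretches between junctions and corners).

Conventions
-----------
* Plane coordinates are mathematical (y up).  Image rasters are converted on
  load: row 0 is the top of the image, so ``y = n_rows - (row + 0.5)`` for
  pixel centres.
* Domain rings are stored counterclockwise; the outer boundary clockwise.
* Intensity convention for images: bright = membrane, dark = vein.

The on-disk wing format is a plain-text integer CSV (see
:func:`write_wing_csv` for the dialect).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "WingModelError",
    "WingCSVError",
    "WingImage",
    "Vertex",
    "Edge",
    "DomainPolygon",
    "SegmentedWing",
    "read_wing_csv",
    "write_wing_csv",
    "load_image",
    "ring_area",
    "ring_perimeter",
]


class WingModelError(ValueError):
    """Invalid wing data or parameters."""


class WingCSVError(WingModelError):
    """Malformed wing CSV file."""


def ring_area(ring: np.ndarray) -> float:
    """Signed shoelace area of an open ring (positive = counterclockwise)."""
    x, y = np.asarray(ring, dtype=float).T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ring_perimeter(ring: np.ndarray) -> float:
    """Perimeter of an open ring (closing segment included)."""
    pts = np.asarray(ring, dtype=float)
    return float(np.sum(np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)))


@dataclass(frozen=True)
class WingImage:
    """2-D grayscale raster; intensities in [0, 1], bright = membrane."""

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise WingModelError("image must be a 2-D raster of at least 2x2 pixels")
        if not np.isfinite(px).all() or px.min() < 0.0 or px.max() > 1.0:
            raise WingModelError("image intensities must be finite and within [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Vertex:
    id: int
    x: float
    y: float


@dataclass
class Edge:
    """Vein stretch between two vertices.

    ``polyline``, when present, is an ordered coordinate array running from
    vertex ``a`` to vertex ``b``; otherwise the edge is a straight segment.
    """

    a: int
    b: int
    polyline: np.ndarray | None = None
    radius: float | None = None
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise WingModelError("edge endpoints must be distinct")

    def length(self, vertices: np.ndarray) -> float:
        if self.polyline is not None:
            pts = np.asarray(self.polyline, dtype=float)
            return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
        d = vertices[self.b] - vertices[self.a]
        return float(np.hypot(*d))


@dataclass
class DomainPolygon:
    """A vein-bounded membrane region; ``ring`` is open and counterclockwise."""

    id: int
    ring: np.ndarray

    @property
    def area(self) -> float:
        return abs(ring_area(self.ring))

    @property
    def perimeter(self) -> float:
        return ring_perimeter(self.ring)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.ring)


def _check_ring_indices(indices: np.ndarray, label: str) -> None:
    idx = list(indices)
    if len(idx) >= 2 and idx[0] == idx[-1]:
        idx = idx[:-1]
    if len(idx) < 3:
        raise WingModelError(f"{label}: ring must have at least 3 distinct vertices")
    if len(set(idx)) != len(idx):
        raise WingModelError(f"{label}: ring repeats a non-terminal vertex")


class SegmentedWing:
    """Outer contour + tessellating domains + venation graph.

    Parameters
    ----------
    vertices:
        (N, 2) array, the shared vertex pool; ids are the row indices.
    boundary_ring:
        Vertex indices of the outer contour (open ring, any orientation;
        stored clockwise).
    domain_rings:
        One open index ring per domain (stored counterclockwise).
    edges:
        Optional explicit edge list; derived from the rings when omitted
        (one edge per unique ring segment).
    """

    def __init__(
        self,
        vertices: np.ndarray,
        boundary_ring: np.ndarray,
        domain_rings: list[np.ndarray],
        edges: list[Edge] | None = None,
        normalized: bool = False,
        validate: bool = True,
    ) -> None:
        self.vertices = np.asarray(vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise WingModelError("vertices must be an (N, 2) array")
        if not domain_rings:
            raise WingModelError("a wing must have at least one domain")
        self.boundary_ring = self._oriented(np.asarray(boundary_ring, int), ccw=False, label="boundary")
        self.domain_rings = [
            self._oriented(np.asarray(r, int), ccw=True, label=f"domain {i}")
            for i, r in enumerate(domain_rings)
        ]
        self.normalized = bool(normalized)
        self.edges = edges if edges is not None else self._derive_edges()
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    def _oriented(self, ring: np.ndarray, ccw: bool, label: str) -> np.ndarray:
        _check_ring_indices(ring, label)
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        if ring.min() < 0 or ring.max() >= len(self.vertices):
            raise WingModelError(f"{label}: ring index out of range")
        area = ring_area(self.vertices[ring])
        if area == 0.0:
            raise WingModelError(f"{label}: ring has zero signed area")
        if (area > 0) != ccw:
            ring = ring[::-1].copy()
        return ring

    def _derive_edges(self) -> list[Edge]:
        boundary_segs = set()
        for u, v in zip(self.boundary_ring, np.roll(self.boundary_ring, -1)):
            boundary_segs.add((min(u, v), max(u, v)))
        segs = set(boundary_segs)
        for ring in self.domain_rings:
            for u, v in zip(ring, np.roll(ring, -1)):
                segs.add((int(min(u, v)), int(max(u, v))))
        return [Edge(a=int(a), b=int(b), is_boundary=(a, b) in boundary_segs)
                for a, b in sorted(segs)]

    @classmethod
    def from_domain_polygons(
        cls,
        rings: list[np.ndarray],
        snap_tol: float = 1e-7,
        normalized: bool = False,
        validate: bool = True,
    ) -> "SegmentedWing":
        """Build a wing from coordinate rings of a tessellation.

        Vertices closer than ``snap_tol`` are merged; the outer boundary is
        recovered as the cycle of segments used by exactly one domain ring.
        """
        if not rings:
            raise WingModelError("a wing must have at least one domain")
        coords = np.concatenate([np.asarray(r, dtype=float) for r in rings])
        rep = _snap_indices(coords, snap_tol)
        uniq, inverse = np.unique(rep, return_inverse=True)
        vertices = coords[uniq]
        index_rings: list[np.ndarray] = []
        pos = 0
        for r in rings:
            n = len(r)
            ring = inverse[pos:pos + n]
            pos += n
            # drop consecutive duplicates introduced by snapping
            keep = np.ones(len(ring), bool)
            keep[1:] = ring[1:] != ring[:-1]
            ring = ring[keep]
            if len(ring) > 1 and ring[0] == ring[-1]:
                ring = ring[:-1]
            index_rings.append(ring)
        boundary = _boundary_cycle(index_rings)
        return cls(vertices, boundary, index_rings, normalized=normalized,
                   validate=validate)

    # -- derived views --------------------------------------------------------

    @property
    def boundary(self) -> np.ndarray:
        """Outer contour coordinates (open ring, clockwise)."""
        return self.vertices[self.boundary_ring]

    @property
    def domains(self) -> list[DomainPolygon]:
        return [DomainPolygon(i, self.vertices[r]) for i, r in enumerate(self.domain_rings)]

    @property
    def n_domains(self) -> int:
        return len(self.domain_rings)

    @property
    def area(self) -> float:
        return abs(ring_area(self.boundary))

    @property
    def perimeter(self) -> float:
        return ring_perimeter(self.boundary)

    @property
    def boundary_polygon(self) -> Polygon:
        return Polygon(self.boundary)

    def to_graph(self):
        """Venation graph as a :class:`networkx.Graph` with ``length`` weights."""
        import networkx as nx

        g = nx.Graph()
        for e in self.edges:
            g.add_edge(e.a, e.b, length=e.length(self.vertices),
                       radius=e.radius, is_boundary=e.is_boundary)
        for n in g.nodes:
            g.nodes[n]["pos"] = tuple(self.vertices[n])
        return g

    def junction_graph(self) -> tuple[list[int], list[Edge]]:
        """Collapse degree-2 vertices into polyline edges between junctions.

        Returns the junction vertex ids (degree != 2 in the segment graph)
        and one :class:`Edge` per vein stretch between junctions, with the
        full polyline attached.  Junction-free cycles (e.g. the boundary of
        a single-domain wing) are split at two anchor vertices so that every
        edge has distinct endpoints.  Edge radii are averaged over the
        collapsed segments when all of them carry one.
        """
        deg: dict[int, int] = {}
        incident: dict[int, list[int]] = {}
        for i, e in enumerate(self.edges):
            for v in (e.a, e.b):
                deg[v] = deg.get(v, 0) + 1
                incident.setdefault(v, []).append(i)
        nodes = sorted(v for v, d in deg.items() if d != 2)
        node_set = set(nodes)
        used = [False] * len(self.edges)
        out: list[Edge] = []

        def walk(start: int, first_edge: int, stop_at_nodes: bool):
            path = [start]
            radii: list[float | None] = []
            boundary = True
            cur, ce = start, first_edge
            while True:
                used[ce] = True
                e = self.edges[ce]
                radii.append(e.radius)
                boundary = boundary and e.is_boundary
                cur = e.b if e.a == cur else e.a
                path.append(cur)
                if (stop_at_nodes and cur in node_set) or cur == start:
                    break
                nxt = incident[cur]
                ce = nxt[1] if nxt[0] == ce else nxt[0]
            return path, radii, boundary

        def emit(path, radii, boundary):
            rad = (float(np.mean(radii))
                   if radii and all(r is not None for r in radii) else None)
            out.append(Edge(path[0], path[-1],
                            polyline=self.vertices[path].copy(),
                            radius=rad, is_boundary=boundary))

        for start in nodes:
            for ei in incident[start]:
                if not used[ei]:
                    path, radii, boundary = walk(start, ei, stop_at_nodes=True)
                    emit(path, radii, boundary)
        for ei in range(len(self.edges)):   # junction-free cycles
            if used[ei]:
                continue
            anchor = min(self.edges[ei].a, self.edges[ei].b)
            path, radii, boundary = walk(anchor, incident[anchor][0],
                                         stop_at_nodes=False)
            half = max(1, len(path) // 2)
            mid = path[half]
            for v in (anchor, mid):
                if v not in node_set:
                    node_set.add(v)
                    nodes.append(v)
            emit(path[:half + 1], radii[:half], boundary)
            emit(path[half:], radii[half:], boundary)
        return sorted(nodes), out

    def scaled(self, factor: float, normalized: bool | None = None) -> "SegmentedWing":
        """Uniformly scaled copy (radii scale with coordinates)."""
        wing = SegmentedWing(
            self.vertices * float(factor),
            self.boundary_ring.copy(),
            [r.copy() for r in self.domain_rings],
            edges=[Edge(e.a, e.b,
                        None if e.polyline is None else e.polyline * factor,
                        None if e.radius is None else e.radius * factor,
                        e.is_boundary)
                   for e in self.edges],
            normalized=self.normalized if normalized is None else normalized,
            validate=False,
        )
        return wing

    # -- validation -----------------------------------------------------------

    def validate(self, rel_tol: float = 1e-2) -> None:
        """Check ring simplicity, tiling consistency and the normalization flag."""
        bpoly = Polygon(self.boundary)
        if not bpoly.is_valid or bpoly.area == 0:
            raise WingModelError("boundary ring is not a simple polygon")
        total = 0.0
        for d in self.domains:
            poly = Polygon(d.ring)
            if not poly.is_valid or poly.area == 0:
                raise WingModelError(f"domain {d.id}: ring is not a simple polygon")
            total += poly.area
        if abs(total - bpoly.area) > rel_tol * bpoly.area:
            raise WingModelError(
                f"domain areas sum to {total:.6g} but boundary area is "
                f"{bpoly.area:.6g} (relative mismatch > {rel_tol})")
        pad = rel_tol * np.sqrt(bpoly.area)
        grown = bpoly.buffer(pad)
        for d in self.domains:
            if not grown.contains(Polygon(d.ring)):
                raise WingModelError(f"domain {d.id} extends outside the boundary")
        if self.normalized and abs(bpoly.area - 1.0) > 1e-6:
            raise WingModelError("normalized flag set but boundary area != 1")


def _snap_indices(coords: np.ndarray, tol: float) -> np.ndarray:
    """Union-find merge of coordinates closer than ``tol``; returns representative row ids."""
    n = len(coords)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0 and n > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(tol):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)])


def _boundary_cycle(index_rings: list[np.ndarray]) -> np.ndarray:
    """Cycle of segments used by exactly one ring = the outer boundary."""
    count: dict[tuple[int, int], int] = {}
    for ring in index_rings:
        for u, v in zip(ring, np.roll(ring, -1)):
            key = (int(min(u, v)), int(max(u, v)))
            count[key] = count.get(key, 0) + 1
    once = [k for k, c in count.items() if c == 1]
    if not once:
        raise WingModelError("tessellation has no free boundary segments")
    adj: dict[int, list[int]] = {}
    for u, v in once:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    for node, nbrs in adj.items():
        if len(nbrs) != 2:
            raise WingModelError(
                f"outer boundary is not a single cycle (vertex {node} has "
                f"{len(nbrs)} free segments)")
    start = min(adj)
    cycle = [start, min(adj[start])]
    while True:
        prev, cur = cycle[-2], cycle[-1]
        nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
        if nxt == start:
            break
        cycle.append(nxt)
    if len(cycle) != len(once):
        raise WingModelError("outer boundary segments form more than one cycle")
    return np.asarray(cycle, dtype=int)


# -- integer-CSV wing format --------------------------------------------------
#
# Dialect (one record per line, comma separated):
#   W,1,<grid>,<normalized 0|1>      header: format version, quantization step
#   V,<id>,<x>,<y>                   integer vertex coordinates (x*grid plane units)
#   D,<id>,<i1>,<i2>,...             domain ring as vertex indices (open ring)
#   B,<i1>,<i2>,...                  boundary ring as vertex indices
#   E,<a>,<b>,<radius>               optional per-edge radius annotations
# Lines beginning with '#' are comments.


def write_wing_csv(wing: SegmentedWing, path: str | Path, grid: float = 1.0) -> None:
    """Write a wing in the integer-CSV dialect, quantizing to ``grid`` units."""
    if wing.n_domains < 1:
        raise WingModelError("a wing must have at least one domain")
    if grid <= 0:
        raise WingModelError("grid step must be positive")
    q = np.rint(wing.vertices / grid).astype(np.int64)
    if len(np.unique(q, axis=0)) != len(q):
        raise WingModelError(
            f"quantization to grid {grid} collapses distinct vertices")
    lines = [f"W,1,{grid!r},{int(wing.normalized)}"]
    for i, (x, y) in enumerate(q):
        lines.append(f"V,{i},{x},{y}")
    for i, ring in enumerate(wing.domain_rings):
        lines.append("D,%d,%s" % (i, ",".join(map(str, ring))))
    lines.append("B," + ",".join(map(str, wing.boundary_ring)))
    for e in wing.edges:
        if e.radius is not None:
            lines.append(f"E,{e.a},{e.b},{e.radius!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wing_csv(path: str | Path) -> SegmentedWing:
    """Read a wing written by :func:`write_wing_csv`.

    Coordinates are the stored integers multiplied by the header grid step,
    so integer wings round-trip exactly.  The venation graph is re-derived
    from the rings; ``E`` records only attach radii.
    """
    path = Path(path)
    if not path.exists():
        raise WingCSVError(f"no such wing file: {path}")
    grid = 1.0
    normalized = False
    verts: dict[int, tuple[int, int]] = {}
    domain_rows: list[tuple[int, np.ndarray]] = []
    boundary: np.ndarray | None = None
    radii: dict[tuple[int, int], float] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        tag = parts[0]
        try:
            if tag == "W":
                grid = float(parts[2])
                normalized = bool(int(parts[3]))
            elif tag == "V":
                vid = int(parts[1])
                if vid in verts:
                    raise WingCSVError(f"line {ln}: duplicate vertex id {vid}")
                verts[vid] = (int(parts[2]), int(parts[3]))
            elif tag == "D":
                domain_rows.append((int(parts[1]), np.array(parts[2:], dtype=int)))
            elif tag == "B":
                boundary = np.array(parts[1:], dtype=int)
            elif tag == "E":
                a, b = int(parts[1]), int(parts[2])
                radii[(min(a, b), max(a, b))] = float(parts[3])
            else:
                raise WingCSVError(f"line {ln}: unknown record type {tag!r}")
        except WingCSVError:
            raise
        except (ValueError, IndexError) as exc:
            raise WingCSVError(f"line {ln}: malformed record {raw!r}") from exc
    if not verts:
        raise WingCSVError(f"{path}: no vertex records")
    if boundary is None:
        raise WingCSVError(f"{path}: missing boundary (B) record")
    if not domain_rows:
        raise WingCSVError(f"{path}: no domain (D) records")
    ids = sorted(verts)
    if ids != list(range(len(ids))):
        raise WingCSVError(f"{path}: vertex ids must be contiguous from 0")
    vertices = np.array([verts[i] for i in ids], dtype=float) * grid
    domain_rows.sort(key=lambda t: t[0])
    rings = []
    for did, ring in domain_rows:
        try:
            _check_ring_indices(ring, f"domain record {did}")
        except WingModelError as exc:
            raise WingCSVError(f"{path}: {exc}") from exc
        rings.append(ring)
    try:
        wing = SegmentedWing(vertices, boundary, rings, normalized=normalized)
    except WingModelError as exc:
        raise WingCSVError(f"{path}: {exc}") from exc
    for e in wing.edges:
        key = (min(e.a, e.b), max(e.a, e.b))
        if key in radii:
            e.radius = radii[key]
    return wing


def load_image(path: str | Path) -> WingImage:
    """Load a PNG/TIFF raster as a :class:`WingImage` with intensities in [0, 1].

    RGB(A) images are converted to luminance (ITU-R 601 weights, matching
    scikit-image's ``rgb2gray``); integer images are divided by their dtype
    maximum.  Row 0 of the file remains the top row of ``pixels``.
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(Path(path))
    except Exception as exc:  # imageio raises various types
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"empty image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr @ np.array([0.2125, 0.7154, 0.0721])
    if arr.ndim != 2:
        raise OSError(f"unsupported image layout {arr.shape} in {path}")
    return WingImage(arr)
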