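"""Image segmentation: from a wing raster to a polygonal tessellation.

The approach mirrors front-propagation (fast-marching style) segmentation:

1. threshold the image to find bright membrane components (one per domain);
2. from one seed per component, expand fronts simultaneously over the wing
   silhouette with speed ``eps + (1 - eps) * intensity ** gamma`` -- fast
   across membrane, crawling through dark veins -- and assign every pixel to
   the first-arriving front, so fronts meet along vein midlines;
3. polygonize the resulting label map: trace the lattice boundaries between
   labels, split them into chains at junction corners (where three or more
   regions meet), simplify each chain once (so the two domains sharing a
   vein get identical coordinates), and assemble the tessellation.

First-arrival times are computed with Dijkstra on the 4-connected pixel
grid (:class:`skimage.graph.MCP_Geometric`), which guarantees 4-connected
label regions and deterministic results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Polygon
from skimage.graph import MCP_Geometric
from skimage.measure import label as cc_label

from .wing_model import SegmentedWing, WingImage, WingModelError

__all__ = [
    "LabelMap",
    "threshold_components",
    "wing_silhouette",
    "propagate_fronts",
    "segment_image",
    "polygonize_labels",
    "segment_wing",
]


@dataclass
class LabelMap:
    """Integer label raster (0 = background/vein) with front arrival times.

    ``cost`` optionally carries the per-pixel traversal cost (1 / speed)
    used during propagation; it enables subpixel boundary placement in
    :func:`polygonize_labels`.
    """

    labels: np.ndarray
    arrival: np.ndarray | None = None
    cost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise WingModelError("label map must be 2-D")
        for arr in (self.arrival, self.cost):
            if arr is not None and arr.shape != self.labels.shape:
                raise WingModelError("arrival/cost arrays must match the label shape")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def threshold_components(
    image: WingImage,
    threshold: float = 0.5,
    min_size: int = 25,
) -> LabelMap:
    """4-connected components of above-threshold (membrane) pixels.

    Components smaller than ``min_size`` pixels are discarded (speckle
    suppression); the survivors are relabeled 1..k in scan order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise WingModelError("threshold must lie in [0, 1]")
    bright = image.pixels > threshold
    lab = cc_label(bright, connectivity=1)
    if min_size > 1 and lab.max() > 0:
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_size)
        lab[np.isin(lab, small)] = 0
        # relabel contiguously, preserving scan order
        remap = np.zeros(counts.size, dtype=int)
        kept = np.unique(lab)
        kept = kept[kept > 0]
        remap[kept] = np.arange(1, len(kept) + 1)
        lab = remap[lab]
    return LabelMap(labels=lab)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx * xx + yy * yy <= radius * radius


def wing_silhouette(
    image: WingImage,
    threshold: float = 0.5,
    close_radius: int = 5,
    boundary_pad: float = 1.5,
) -> np.ndarray:
    """Boolean wing mask: bright pixels closed over vein gaps, holes filled.

    ``boundary_pad`` dilates the mask outward to include the outer half of
    the boundary vein (bright membrane stops at the vein's inner edge, but
    the wing outline runs along the vein centreline); set it to about half
    the boundary vein width in pixels.
    """
    bright = image.pixels > threshold
    if close_radius > 0:
        bright = ndimage.binary_closing(bright, structure=_disk(close_radius))
    mask = ndimage.binary_fill_holes(bright)
    if boundary_pad > 0:
        mask = ndimage.distance_transform_edt(~mask) <= boundary_pad
    return mask


def front_speed(intensity: np.ndarray, eps: float = 0.02, gamma: float = 2.0) -> np.ndarray:
    """Front speed law: ``eps + (1 - eps) * intensity ** gamma``.

    ``eps`` keeps fronts crawling (never stalling) through dark veins;
    ``gamma`` sharpens the membrane/vein speed contrast.
    """
    if not 0.0 < eps <= 1.0:
        raise WingModelError("eps must lie in (0, 1]")
    if gamma <= 0:
        raise WingModelError("gamma must be positive")
    return eps + (1.0 - eps) * np.asarray(intensity, float) ** gamma


def propagate_fronts(
    image: WingImage,
    seeds: np.ndarray | list[tuple[int, int]],
    eps: float = 0.02,
    gamma: float = 2.0,
    threshold: float = 0.5,
    mask: np.ndarray | None = None,
    boundary_pad: float = 1.5,
) -> LabelMap:
    """First-arrival labeling of the wing from one seed per membrane region.

    ``seeds`` are (row, col) pixel positions, each in a distinct bright
    component; seed i propagates label i + 1.  ``mask`` restricts the
    propagation domain and defaults to :func:`wing_silhouette`.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=int))
    if seeds.size == 0:
        raise WingModelError("at least one seed is required")
    bright_lab = cc_label(image.pixels > threshold, connectivity=1)
    comp = bright_lab[seeds[:, 0], seeds[:, 1]]
    if np.any(comp == 0):
        bad = seeds[comp == 0][0]
        raise WingModelError(f"seed {tuple(bad)} is not in a bright region")
    if len(np.unique(comp)) != len(comp):
        raise WingModelError("two seeds lie in the same bright component")
    if mask is None:
        mask = wing_silhouette(image, threshold=threshold,
                               boundary_pad=boundary_pad)
    speed = front_speed(image.pixels, eps=eps, gamma=gamma)
    costs = np.where(mask, 1.0 / speed, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=False)
    arrival, tb = mcp.find_costs([tuple(s) for s in seeds])
    offsets = np.asarray(mcp.offsets, dtype=np.int64)
    n_cols = costs.shape[1]
    off_flat = offsets[:, 0] * n_cols + offsets[:, 1]

    labels = np.zeros(costs.shape, dtype=int)
    labels[seeds[:, 0], seeds[:, 1]] = np.arange(1, len(seeds) + 1)
    flat_labels = labels.ravel()
    flat_tb = tb.ravel()
    flat_arrival = arrival.ravel()
    order = np.argsort(flat_arrival, kind="stable")
    off_list = off_flat.tolist()
    tb_list = flat_tb.tolist()
    lab_list = flat_labels.tolist()
    for idx in order.tolist():
        if not np.isfinite(flat_arrival[idx]):
            break
        t = tb_list[idx]
        if t < 0:           # seed (-1) or unreachable (-2)
            continue
        lab_list[idx] = lab_list[idx - off_list[t]]
    labels = np.array(lab_list, dtype=int).reshape(costs.shape)
    labels[~np.isfinite(arrival)] = 0
    return LabelMap(labels=labels, arrival=arrival, cost=costs)


def _auto_seeds(components: LabelMap) -> np.ndarray:
    """Deterministic seed per component: the most interior pixel
    (maximum distance to the component's boundary)."""
    lab = components.labels
    dist = ndimage.distance_transform_edt(lab > 0)
    k = components.n_labels
    pos = ndimage.maximum_position(dist, labels=lab, index=range(1, k + 1))
    return np.asarray(pos, dtype=int)


def segment_image(
    image: WingImage,
    threshold: float = 0.5,
    eps: float = 0.02,
    gamma: float = 2.0,
    min_size: int = 25,
    boundary_pad: float = 1.5,
    seeds: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> LabelMap:
    """Threshold, seed and propagate in one step.

    Default seeding is deterministic (most-interior point of each bright
    component); pass ``rng`` to use a random interior pixel instead, or
    ``seeds`` to supply explicit (row, col) positions.
    """
    comps = threshold_components(image, threshold=threshold, min_size=min_size)
    if comps.n_labels == 0:
        raise WingModelError("no membrane components found above threshold")
    if seeds is None:
        if rng is None:
            seeds = _auto_seeds(comps)
        else:
            seeds = []
            for k in range(1, comps.n_labels + 1):
                rows, cols = np.nonzero(comps.labels == k)
                i = rng.integers(len(rows))
                seeds.append((rows[i], cols[i]))
            seeds = np.asarray(seeds)
    return propagate_fronts(image, seeds, eps=eps, gamma=gamma,
                            threshold=threshold, boundary_pad=boundary_pad)


def _boundary_chains(labels: np.ndarray):
    """Split the lattice boundaries of a label map into junction-to-junction
    chains of corner points; each chain separates one pair of labels."""
    P = np.pad(labels, 1)
    w2 = P.shape[1]
    ncorner_cols = w2 + 1

    segs: list[tuple[int, int]] = []
    # vertical corner segments between horizontally adjacent pixels
    rs, cs = np.nonzero(P[:, :-1] != P[:, 1:])
    for r, c in zip(rs.tolist(), cs.tolist()):
        k1 = r * ncorner_cols + (c + 1)
        segs.append((k1, k1 + ncorner_cols))
    # horizontal corner segments between vertically adjacent pixels
    rs, cs = np.nonzero(P[:-1, :] != P[1:, :])
    for r, c in zip(rs.tolist(), cs.tolist()):
        k1 = (r + 1) * ncorner_cols + c
        segs.append((k1, k1 + 1))

    adj: dict[int, list[int]] = {}
    for si, (a, b) in enumerate(segs):
        adj.setdefault(a, []).append(si)
        adj.setdefault(b, []).append(si)
    nodes = {c for c, inc in adj.items() if len(inc) != 2}
    used = [False] * len(segs)

    def other(si: int, corner: int) -> int:
        a, b = segs[si]
        return b if a == corner else a

    def seg_labels(si: int) -> tuple[int, int]:
        a, b = segs[si]
        r1, c1 = divmod(a, ncorner_cols)
        if segs[si][1] == a + 1:          # horizontal segment
            pair = (P[r1 - 1, c1], P[r1, c1])
        else:                              # vertical segment
            pair = (P[r1, c1 - 1], P[r1, c1])
        return (int(min(pair)), int(max(pair)))

    chains = []
    for start in sorted(nodes):
        for si in sorted(adj[start]):
            if used[si]:
                continue
            corners = [start]
            cur_seg, cur = si, start
            while True:
                used[cur_seg] = True
                cur = other(cur_seg, cur)
                corners.append(cur)
                if cur in nodes:
                    break
                s1, s2 = adj[cur]
                cur_seg = s2 if s1 == cur_seg else s1
            chains.append((corners, seg_labels(si), False))
    # leftover segments form junction-free closed loops
    for si in range(len(segs)):
        if used[si]:
            continue
        start = min(segs[si])
        corners = [start]
        cur_seg = min(sorted(adj[start]))
        cur = start
        while True:
            used[cur_seg] = True
            cur = other(cur_seg, cur)
            corners.append(cur)
            if cur == start:
                break
            s1, s2 = adj[cur]
            cur_seg = s2 if s1 == cur_seg else s1
        chains.append((corners, seg_labels(si), True))
    return chains, ncorner_cols


def _corner_displacements(
    label_map: LabelMap,
    chains,
    ncorner_cols: int,
) -> dict[int, np.ndarray]:
    """Subpixel corner shifts that equalize front arrival times.

    Two fronts meet between the pixel centres they labeled where their
    arrival times coincide; interpolating linearly with the local traversal
    cost places that point at a signed offset ``(t_b - t_a) / (2 c)`` from
    the lattice midline.  Each corner is shifted by the average offset of
    its incident boundary segments (capped below half a pixel), which keeps
    shared chains identical on both sides and leaves the outer contour,
    where one side is background, untouched.
    """
    A = np.pad(label_map.arrival, 1, constant_values=np.inf)
    C = np.pad(label_map.cost, 1, constant_values=np.inf)
    disp: dict[int, np.ndarray] = {}
    count: dict[int, int] = {}
    for corners, _pair, _is_loop in chains:
        for ca, cb in zip(corners[:-1], corners[1:]):
            lo, hi = min(ca, cb), max(ca, cb)
            r, c = divmod(lo, ncorner_cols)
            if hi == lo + 1:        # horizontal segment: pixels above/below
                pa, pb = (r - 1, c), (r, c)
                direction = np.array([0.0, -1.0])   # toward pb = downward = -y
            else:                   # vertical segment: pixels left/right
                pa, pb = (r, c - 1), (r, c)
                direction = np.array([1.0, 0.0])
            ta, tb = A[pa], A[pb]
            cost = 0.5 * (C[pa] + C[pb])
            if np.isfinite(ta) and np.isfinite(tb) and np.isfinite(cost) and cost > 0:
                d = np.clip((tb - ta) / (2.0 * cost), -0.49, 0.49)
                vec = d * direction
                for cn in (ca, cb):
                    disp[cn] = disp.get(cn, 0.0) + vec
                    count[cn] = count.get(cn, 0) + 1
    return {cn: v / count[cn] for cn, v in disp.items()}


def polygonize_labels(
    label_map: LabelMap,
    simplify_tol: float = 0.5,
    subpixel: bool = True,
) -> SegmentedWing:
    """Convert a label map into a :class:`SegmentedWing`.

    Region boundaries are traced on the pixel-corner lattice, cut into
    chains at junctions, and Douglas-Peucker simplified (``simplify_tol``
    pixels, endpoints preserved).  Because each chain is simplified once and
    shared by both adjacent regions, common edges have identical coordinate
    sequences in both rings, and the outer contour is recovered from the
    segments bordering the background.  When the label map carries arrival
    times and costs (and ``subpixel`` is set), internal boundaries are
    refined to the subpixel locus where the two fronts arrive
    simultaneously.
    """
    labels = np.asarray(label_map.labels)
    k = int(labels.max())
    if k < 1:
        raise WingModelError("label map has no labeled regions")
    if simplify_tol > 1.0 + 1e-12:
        raise WingModelError("simplify_tol must be at most 1 pixel")
    n_rows = labels.shape[0]
    chains, ncorner_cols = _boundary_chains(labels)

    shifts: dict[int, np.ndarray] = {}
    if subpixel and label_map.arrival is not None and label_map.cost is not None:
        shifts = _corner_displacements(label_map, chains, ncorner_cols)

    def corner_xy(corner: int) -> np.ndarray:
        r, c = divmod(corner, ncorner_cols)
        xy = np.array([float(c - 1), float(n_rows - (r - 1))])
        shift = shifts.get(corner)
        return xy if shift is None else xy + shift

    per_label: dict[int, list[tuple[np.ndarray, bool]]] = {}
    for corners, (la, lb), is_loop in chains:
        coords = np.array([corner_xy(c) for c in corners])
        if simplify_tol > 0 and len(coords) > 2:
            if is_loop:
                ring = Polygon(coords).simplify(simplify_tol, preserve_topology=True)
                coords = np.asarray(ring.exterior.coords)
            else:
                coords = np.asarray(
                    LineString(coords).simplify(simplify_tol).coords)
        for lab in (la, lb):
            if lab > 0:
                per_label.setdefault(lab, []).append((coords, is_loop))

    rings: list[np.ndarray] = []
    for lab in range(1, k + 1):
        pieces = per_label.get(lab)
        if not pieces:
            raise WingModelError(f"label {lab} produced no boundary")
        rings.append(_assemble_ring(pieces))
    return SegmentedWing.from_domain_polygons(rings, snap_tol=1e-9)


def _assemble_ring(pieces: list[tuple[np.ndarray, bool]]) -> np.ndarray:
    """Link boundary chains of one region into its outer ring."""
    loops = [c for c, is_loop in pieces if is_loop]
    open_chains = [c for c, is_loop in pieces if not is_loop]
    cycles = [c[:-1] for c in loops]
    remaining = list(range(len(open_chains)))
    ends: dict[tuple[float, float], list[int]] = {}
    for i in remaining:
        for pt in (open_chains[i][0], open_chains[i][-1]):
            ends.setdefault(tuple(pt), []).append(i)
    unused = set(remaining)
    while unused:
        i = min(unused)
        unused.discard(i)
        coords = open_chains[i].tolist()
        while tuple(coords[-1]) != tuple(coords[0]):
            candidates = [j for j in ends.get(tuple(coords[-1]), []) if j in unused]
            if not candidates:
                raise WingModelError("region boundary chains do not close")
            j = candidates[0]
            unused.discard(j)
            nxt = open_chains[j]
            if tuple(nxt[0]) != tuple(coords[-1]):
                nxt = nxt[::-1]
            coords.extend(nxt[1:].tolist())
        cycles.append(np.array(coords[:-1]))
    if not cycles:
        raise WingModelError("region has no boundary cycles")
    # outer ring = the largest-area cycle (smaller ones would be holes)
    from .wing_model import ring_area

    return max(cycles, key=lambda c: abs(ring_area(c)))


def segment_wing(
    image: WingImage,
    threshold: float = 0.5,
    eps: float = 0.02,
    gamma: float = 2.0,
    min_size: int = 25,
    simplify_tol: float = 0.5,
    boundary_pad: float = 1.5,
    seeds: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentedWing:
    """Full image-to-wing segmentation: threshold, propagate, polygonize."""
    lm = segment_image(image, threshold=threshold, eps=eps, gamma=gamma,
                       min_size=min_size, boundary_pad=boundary_pad,
                       seeds=seeds, rng=rng)
    return polygonize_labels(lm, simplify_tol=simplify_tol)
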