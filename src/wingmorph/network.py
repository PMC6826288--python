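"""Venation-network analysis: adjacency matrices and modularity communities.

The venation graph (junctions and vein stretches) is turned into a symmetric
adjacency matrix under one of three weighting schemes:

* ``unweighted``      -- M_ij = 1 for connected vertex pairs;
* ``inverse_length``  -- M_ij = 1 / L**n with L the vein length, n in {1, 2};
* ``resistance``      -- Poiseuille-style vein resistance L / r**4, stored as
  the conductance r**4 / L so that short, wide veins couple nodes strongly.

Community structure is scored with Newman modularity

    Q = (1 / 2m) * sum_ij [M_ij - k_i k_j / (2m)] * delta(c_i, c_j)

and maximized either exactly (exhaustive set-partition search, small graphs)
or with a deterministic greedy agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wing_model import Edge, SegmentedWing, WingModelError

__all__ = [
    "AdjacencyMatrix",
    "CommunityPartition",
    "build_adjacency",
    "interpolate_radii",
    "modularity_score",
    "detect_communities",
]

_SCHEMES = ("unweighted", "inverse_length", "resistance")


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric weighted adjacency matrix of the venation graph.

    ``node_ids`` maps matrix rows back to wing vertex ids when the matrix
    was built over a subset (junctions only); ``None`` means row i is
    vertex i.
    """

    matrix: np.ndarray
    scheme: str
    node_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise WingModelError("adjacency matrix must be square")
        if not np.allclose(m, m.T):
            raise WingModelError("adjacency matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise WingModelError("adjacency matrix must have a zero diagonal")
        if np.any(m < 0):
            raise WingModelError("adjacency weights must be nonnegative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_edge_list(self) -> np.ndarray:
        """(i, j, weight) rows for the upper triangle, i < j, weight > 0."""
        iu, ju = np.triu_indices(self.n, k=1)
        w = self.matrix[iu, ju]
        keep = w > 0
        return np.column_stack([iu[keep], ju[keep], w[keep]])


@dataclass(frozen=True)
class CommunityPartition:
    """Node labeling plus the modularity of that labeling."""

    labels: np.ndarray
    n_communities: int
    Q: float
    method: str


def _edge_weight(edge: Edge, length: float, scheme: str, n: int) -> float:
    if scheme == "unweighted":
        return 1.0
    if scheme == "inverse_length":
        if n not in (1, 2):
            raise WingModelError("inverse_length exponent must be 1 or 2")
        if length <= 0:
            raise WingModelError("zero-length edge cannot be length-weighted")
        return 1.0 / length ** n
    if scheme == "resistance":
        if edge.radius is None or edge.radius <= 0:
            raise WingModelError(
                "resistance weighting requires a positive radius on every "
                "edge (interpolate_radii can supply them)")
        return edge.radius ** 4 / length
    raise WingModelError(f"unknown scheme {scheme!r}; use one of {_SCHEMES}")


def build_adjacency(
    wing: SegmentedWing,
    scheme: str = "unweighted",
    n: int = 1,
    radii: np.ndarray | None = None,
    junctions_only: bool = False,
) -> AdjacencyMatrix:
    """Adjacency matrix of the venation graph under the given scheme.

    By default every polygon vertex is a node and every unique ring segment
    an edge.  With ``junctions_only`` the degree-2 vertices are collapsed so
    nodes are vein junctions and edges whole vein stretches (lengths follow
    the collapsed polylines), which is the natural graph for community
    analysis.  ``radii``, when given, overrides per-edge radii (aligned with
    ``wing.edges``); otherwise the stored ``Edge.radius`` values are used.
    """
    if len(wing.vertices) < 2:
        raise WingModelError("graph must have at least 2 vertices")
    if junctions_only:
        if radii is not None:   # attach per-segment radii before collapsing
            wing = SegmentedWing(
                wing.vertices, wing.boundary_ring, wing.domain_rings,
                edges=[Edge(e.a, e.b, e.polyline, float(r), e.is_boundary)
                       for e, r in zip(wing.edges, radii)],
                normalized=wing.normalized, validate=False)
        node_ids, edges = wing.junction_graph()
        index = {v: i for i, v in enumerate(node_ids)}
        size = len(node_ids)
        if size < 2:
            raise WingModelError("graph must have at least 2 junctions")
        m = np.zeros((size, size))
        for e in edges:
            w = _edge_weight(e, e.length(wing.vertices), scheme, n)
            i, j = index[e.a], index[e.b]
            if scheme == "unweighted":
                m[i, j] = m[j, i] = 1.0
            else:       # parallel vein stretches act in parallel: weights add
                m[i, j] += w
                m[j, i] += w
        return AdjacencyMatrix(matrix=m, scheme=scheme,
                               node_ids=tuple(node_ids))
    size = len(wing.vertices)
    m = np.zeros((size, size))
    for k, e in enumerate(wing.edges):
        if radii is not None:
            e = Edge(e.a, e.b, e.polyline, float(radii[k]), e.is_boundary)
        w = _edge_weight(e, e.length(wing.vertices), scheme, n)
        m[e.a, e.b] = w
        m[e.b, e.a] = w
    return AdjacencyMatrix(matrix=m, scheme=scheme)


def interpolate_radii(
    samples: list[tuple[tuple[float, float], float]] | np.ndarray,
    wing: SegmentedWing,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted vein radii at every edge midpoint.

    ``samples`` is a sequence of ((x, y), radius) measurements; a single
    sample yields a constant radius field.  Returns one radius per
    ``wing.edges`` entry.
    """
    pts = np.array([p for p, _ in samples], dtype=float)
    rad = np.array([r for _, r in samples], dtype=float)
    if len(pts) == 0:
        raise WingModelError("at least one radius sample is required")
    if np.any(rad <= 0):
        raise WingModelError("sample radii must be positive")
    mids = np.array([
        (np.asarray(e.polyline)[len(e.polyline) // 2]
         if e.polyline is not None
         else 0.5 * (wing.vertices[e.a] + wing.vertices[e.b]))
        for e in wing.edges])
    d = np.hypot(mids[:, None, 0] - pts[None, :, 0],
                 mids[:, None, 1] - pts[None, :, 1])
    out = np.empty(len(mids))
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    out[has_exact] = rad[np.argmax(exact[has_exact], axis=1)]
    rest = ~has_exact
    with np.errstate(divide="ignore"):
        w = d[rest] ** -power
    out[rest] = (w * rad).sum(axis=1) / w.sum(axis=1)
    return out


def _as_matrix(matrix: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, AdjacencyMatrix):
        return matrix.matrix
    return np.asarray(matrix, dtype=float)


def modularity_score(matrix: AdjacencyMatrix | np.ndarray, labels) -> float:
    """Newman modularity of a node labeling for a (possibly weighted) matrix."""
    m = _as_matrix(matrix)
    labels = np.asarray(labels)
    if len(labels) != m.shape[0]:
        raise WingModelError("labels must cover all nodes")
    two_m = m.sum()
    if two_m <= 0:
        raise WingModelError("graph has no edges")
    k = m.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += m[np.ix_(mask, mask)].sum() - k[mask].sum() ** 2 / two_m
    return float(q / two_m)


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    yield labels.copy()
    while True:
        i = n - 1
        while i > 0 and labels[i] > maxes[i - 1]:
            labels[i] = 0
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxes[i] = max(maxes[i - 1], labels[i])
        for j in range(i + 1, n):
            maxes[j] = maxes[j - 1]
        yield labels.copy()


def _exact_partition(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    two_m = m.sum()
    k = m.sum(axis=1)
    b = m - np.outer(k, k) / two_m
    best_q, best = -np.inf, None
    for labels in _partitions(n):
        q = 0.0
        for c in range(labels.max() + 1):
            mask = labels == c
            q += b[np.ix_(mask, mask)].sum()
        if q > best_q + 1e-15:
            best_q, best = q, labels
    return best


def _greedy_partition(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Deterministic greedy agglomerative modularity maximization (CNM-style).

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain, stopping when no merge improves
    Q.  Ties are broken lexicographically on the community ids, so results
    are reproducible irrespective of the RNG state.
    """
    n = m.shape[0]
    two_m = m.sum()
    a = m.sum(axis=1) / two_m                   # community degree fractions
    e: dict[tuple[int, int], float] = {}        # between-community weight / 2m
    for i, j in zip(*np.nonzero(np.triu(m, k=1))):
        e[(int(i), int(j))] = m[i, j] / two_m
    comm = {i: {i} for i in range(n)}
    a_c = {i: float(a[i]) for i in range(n)}
    while e:
        best_gain, best_pair = 1e-15, None
        # sorted iteration makes the tie-break lexicographic on community ids
        for (ci, cj), eij in sorted(e.items()):
            gain = 2.0 * (eij - a_c[ci] * a_c[cj])
            if gain > best_gain + 1e-15:
                best_gain, best_pair = gain, (ci, cj)
        if best_pair is None:
            break
        ci, cj = best_pair
        comm[ci] |= comm.pop(cj)
        a_c[ci] += a_c.pop(cj)
        new_e: dict[tuple[int, int], float] = {}
        for (u, v), w in e.items():
            if (u, v) == (ci, cj):
                continue
            u2 = ci if u == cj else u
            v2 = ci if v == cj else v
            key = (min(u2, v2), max(u2, v2))
            new_e[key] = new_e.get(key, 0.0) + w
        e = new_e
    labels = np.empty(n, dtype=int)
    for c, members in comm.items():
        for i in members:
            labels[i] = c
    return labels


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities to contiguous ids in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def detect_communities(
    matrix: AdjacencyMatrix | np.ndarray,
    seed: int = 0,
    method: str = "auto",
) -> CommunityPartition:
    """Maximum-modularity community detection.

    ``method`` is ``"exact"`` (exhaustive over set partitions, feasible for
    up to 12 nodes), ``"greedy"``, or ``"auto"`` (exact for <= 10 nodes,
    greedy otherwise).  Deterministic given the seed; the returned Q always
    satisfies Q >= 0, the score of the trivial single-community partition.
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    if n < 2:
        raise WingModelError("community detection needs at least 2 nodes")
    if m.sum() <= 0:
        raise WingModelError("graph has no edges")
    if method == "auto":
        method = "exact" if n <= 10 else "greedy"
    if method == "exact":
        if n > 12:
            raise WingModelError("exact search is limited to 12 nodes")
        labels = _exact_partition(m)
    elif method == "greedy":
        labels = _greedy_partition(m, np.random.default_rng(seed))
    else:
        raise WingModelError(f"unknown method {method!r}")
    q = modularity_score(m, labels)
    if q < 0.0:
        labels = np.zeros(n, dtype=int)
        q = modularity_score(m, labels)
    labels = _canonical(labels)
    return CommunityPartition(
        labels=labels,
        n_communities=int(labels.max()) + 1,
        Q=q,
        method=method,
    )
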