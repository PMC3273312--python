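"""Fixed-radius random geometric graphs on the unit square.

The simulated tissue is an undirected graph G(n, r): ``n`` nodes (cell
bodies) placed uniformly at random in [0, 1] x [0, 1], with an edge (axon)
between every pair of nodes at Euclidean distance <= r.  The graph is static
for the duration of a simulation; the dynamics module mutates per-edge
weights, not the topology.

Region queries (:func:`nodes_in_disk`, :func:`edges_in_disk`) are the
spatial primitives used by the lesion dynamics: the region of infection and
the apoptosis regions are disks, and an edge belongs to a disk iff at least
one of its endpoints does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SpatialGraph",
    "DegreeStats",
    "generate_graph",
    "build_graph",
    "nodes_in_disk",
    "edges_in_disk",
    "degree_stats",
    "write_graphml",
    "read_graphml",
    "write_tsv",
    "read_tsv",
]

_MAX_R = float(np.sqrt(2.0))


@dataclass(frozen=True)
class SpatialGraph:
    """Immutable spatial graph: coordinates plus a fixed-radius edge set.

    Attributes
    ----------
    coords : (n, 2) float array of node positions in the unit square.
    r : connectivity radius used to build the edge set.
    edges : (m, 2) int array, each row (u, v) with u < v, rows sorted
        lexicographically; undirected, no self-loops, no duplicates.
    degree : (n,) int array, number of incident edges per node.
    """

    coords: np.ndarray
    r: float
    edges: np.ndarray
    degree: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(np.asarray(self.coords, dtype=np.float64))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if coords.shape[0] < 1:
            raise ValueError("graph needs at least one node")
        if np.any(coords < 0.0) or np.any(coords > 1.0):
            raise ValueError("coordinates must lie in the unit square")
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if np.any(edges[:, 0] >= edges[:, 1]):
                raise ValueError("edges must be stored as (u, v) with u < v")
            if np.any(edges < 0) or np.any(edges >= coords.shape[0]):
                raise ValueError("edge endpoint out of range")
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            if np.any(np.all(edges[1:] == edges[:-1], axis=1)):
                raise ValueError("duplicate edges")
        deg = np.zeros(coords.shape[0], dtype=np.int64)
        if edges.size:
            np.add.at(deg, edges[:, 0], 1)
            np.add.at(deg, edges[:, 1], 1)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "degree", deg)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.edges.shape[0]


@dataclass(frozen=True)
class DegreeStats:
    mean: float
    sd: float
    min: int
    max: int
    histogram: np.ndarray  # histogram[d] = number of nodes of degree d


def _validate_radius(r: float, name: str = "r") -> float:
    r = float(r)
    if not 0.0 <= r <= _MAX_R:
        raise ValueError(f"{name} must be in [0, sqrt(2)], got {r}")
    return r


def generate_graph(n: int, r: float, seed) -> SpatialGraph:
    """Sample a fixed-radius random graph G(n, r) on the unit square.

    Nodes are drawn i.i.d. uniform in [0,1]^2 and every pair at distance
    <= r (closed ball) is joined.  The same ``seed`` always yields a
    byte-identical graph.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    n = int(n)
    r = _validate_radius(r)
    rng = np.random.default_rng(seed)
    coords = rng.random((n, 2))
    return build_graph(coords, r)


def build_graph(coords: np.ndarray, r: float) -> SpatialGraph:
    """Build the fixed-radius graph over explicitly given coordinates."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    r = _validate_radius(r)
    if coords.shape[0] >= 2 and r > 0.0:
        pairs = cKDTree(coords).query_pairs(r, output_type="ndarray")
        edges = np.sort(pairs, axis=1)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return SpatialGraph(coords=coords, r=r, edges=edges)


def nodes_in_disk(g: SpatialGraph, center, radius: float) -> np.ndarray:
    """Indices of nodes whose coordinate lies within ``radius`` of ``center``."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    center = np.asarray(center, dtype=np.float64)
    d2 = np.sum((g.coords - center) ** 2, axis=1)
    return np.flatnonzero(d2 <= radius * radius)


def edges_in_disk(
    g: SpatialGraph,
    weights: np.ndarray | None,
    center,
    radius: float,
    healthy_only: bool = False,
) -> np.ndarray:
    """Indices of edges with at least one endpoint inside the disk.

    The endpoint convention ties edge membership to cell bodies: an axon is
    affected by a circular region as soon as either of its cells is.  With
    ``healthy_only`` the result is restricted to edges of positive weight.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if g.m == 0:
        return np.empty(0, dtype=np.int64)
    center = np.asarray(center, dtype=np.float64)
    d2 = np.sum((g.coords - center) ** 2, axis=1)
    inside = d2 <= radius * radius
    mask = inside[g.edges[:, 0]] | inside[g.edges[:, 1]]
    if healthy_only:
        if weights is None:
            raise ValueError("healthy_only requires edge weights")
        mask &= np.asarray(weights) > 0
    return np.flatnonzero(mask)


def segment_point_distance(g: SpatialGraph, point) -> np.ndarray:
    """Distance from each edge, treated as a line segment, to ``point``.

    Supports the "segment" region convention in which an axon is affected by
    a circular region as soon as its segment intersects the disk.
    """
    point = np.asarray(point, dtype=np.float64)
    if g.m == 0:
        return np.empty(0, dtype=np.float64)
    a = g.coords[g.edges[:, 0]]
    b = g.coords[g.edges[:, 1]]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", point[None, :] - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.sqrt(np.sum((closest - point) ** 2, axis=1))


def degree_stats(g: SpatialGraph) -> DegreeStats:
    """Summary of the degree distribution (mean, sd, range, histogram)."""
    deg = g.degree
    return DegreeStats(
        mean=float(deg.mean()),
        sd=float(deg.std()),
        min=int(deg.min()),
        max=int(deg.max()),
        histogram=np.bincount(deg),
    )


# ---------------------------------------------------------------------------
# Import / export.  GraphML carries x, y node attributes (and arbitrary
# per-edge attributes, e.g. final weights); the TSV pair is a plain-text
# alternative: <prefix>.nodes.tsv (id, x, y) and <prefix>.edges.tsv (id1, id2).
# Coordinates are written with 17 significant digits so round-trips are
# lossless well past 12 significant digits.
# ---------------------------------------------------------------------------


def _to_networkx(g: SpatialGraph, edge_attrs: dict[str, np.ndarray] | None = None) -> nx.Graph:
    G = nx.Graph()
    G.graph["r"] = float(g.r)
    for i, (x, y) in enumerate(g.coords):
        G.add_node(int(i), x=float(x), y=float(y))
    for j, (u, v) in enumerate(g.edges):
        attrs = {k: vals[j].item() for k, vals in (edge_attrs or {}).items()}
        G.add_edge(int(u), int(v), **attrs)
    return G


def write_graphml(g: SpatialGraph, path, edge_attrs: dict[str, np.ndarray] | None = None) -> None:
    nx.write_graphml(_to_networkx(g, edge_attrs), str(path))


def read_graphml(path) -> SpatialGraph:
    G = nx.read_graphml(str(path))
    nodes = sorted(G.nodes, key=lambda u: int(u))
    index = {u: i for i, u in enumerate(nodes)}
    coords = np.array([[float(G.nodes[u]["x"]), float(G.nodes[u]["y"])] for u in nodes])
    edges = np.array(
        [sorted((index[u], index[v])) for u, v in G.edges], dtype=np.int64
    ).reshape(-1, 2)
    return SpatialGraph(coords=coords, r=float(G.graph.get("r", 0.0)), edges=edges)


def write_tsv(g: SpatialGraph, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    node_path = prefix.with_suffix(".nodes.tsv")
    edge_path = prefix.with_suffix(".edges.tsv")
    with open(node_path, "w") as fh:
        fh.write(f"# lesionnet nodes v1\tr={g.r!r}\n")
        fh.write("id\tx\ty\n")
        for i, (x, y) in enumerate(g.coords):
            fh.write(f"{i}\t{x:.17g}\t{y:.17g}\n")
    with open(edge_path, "w") as fh:
        fh.write("# lesionnet edges v1\n")
        fh.write("id1\tid2\n")
        for u, v in g.edges:
            fh.write(f"{u}\t{v}\n")
    return node_path, edge_path


def read_tsv(prefix) -> SpatialGraph:
    prefix = Path(prefix)
    node_path = prefix.with_suffix(".nodes.tsv")
    edge_path = prefix.with_suffix(".edges.tsv")
    r = 0.0
    with open(node_path) as fh:
        header = fh.readline()
        if "r=" in header:
            r = float(header.split("r=")[1].strip())
    nodes = np.loadtxt(node_path, skiprows=2, ndmin=2)
    order = np.argsort(nodes[:, 0])
    coords = nodes[order, 1:3]
    edges = np.loadtxt(edge_path, skiprows=2, dtype=np.int64, ndmin=2)
    if edges.size:
        edges = np.sort(edges.reshape(-1, 2), axis=1)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return SpatialGraph(coords=coords, r=r, edges=edges)
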