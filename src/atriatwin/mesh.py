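"""Labeled tetrahedral mesh container and basic combinatorial helpers.

The :class:`LabeledMesh` is the anatomical twin passed between every stage of
the pipeline: node coordinates in millimetres, tetrahedral connectivity,
per-element region labels, named node sets (orifice rings, appendage patches,
landmarks) and, once computed, per-element unit fiber vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

# Canonical region labels.  Integer codes are stable across file round-trips.
REGION_CODES = {
    "LA_endo": 1,
    "LA_epi": 2,
    "RA_endo": 3,
    "RA_epi": 4,
    "TC": 5,
    "PM": 6,
    "BB": 7,
    "FO_rim": 8,
    "SAN": 9,
    "LAA": 10,
    "RAA": 11,
    "discard": 12,
}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

LA_REGIONS = ("LA_endo", "LA_epi", "LAA")
RA_REGIONS = ("RA_endo", "RA_epi", "TC", "PM", "BB", "SAN", "RAA")


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with region labels, named node sets and fibers.

    Attributes
    ----------
    points : (n_nodes, 3) float array, mm
    tets : (n_tets, 4) int array, 0-based node indices
    labels : (n_tets,) int array of region codes (see ``REGION_CODES``)
    node_sets : mapping name -> 1-D int array of node indices
    landmarks : mapping name -> 3-vector (mm)
    fibers : optional (n_tets, 3) unit vectors
    """

    points: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    node_sets: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    fibers: np.ndarray | None = None

    # -- cached derived quantities -------------------------------------
    _volumes: np.ndarray | None = field(default=None, repr=False)
    _edges: np.ndarray | None = field(default=None, repr=False)
    _boundary_faces: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def region_names(self) -> np.ndarray:
        return np.array([REGION_NAMES[c] for c in self.labels])

    def label_of(self, name: str) -> int:
        return REGION_CODES[name]

    def elements_in(self, *names: str) -> np.ndarray:
        codes = [REGION_CODES[n] for n in names]
        return np.flatnonzero(np.isin(self.labels, codes))

    def nodes_of_elements(self, elems: np.ndarray) -> np.ndarray:
        return np.unique(self.tets[elems].ravel())

    def validate(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (m, 4)")
        if self.labels.shape != (self.n_tets,):
            raise ValueError("labels must have one entry per tet")
        vols = self.volumes()
        if np.any(vols <= 0):
            bad = np.flatnonzero(vols <= 0)
            raise ValueError(f"non-positive tet volumes at elements {bad[:10].tolist()}")

    # -- geometry ------------------------------------------------------
    def volumes(self) -> np.ndarray:
        """Signed tet volumes (mm^3); positive for correctly oriented tets."""
        if self._volumes is None:
            p = self.points
            t = self.tets
            a = p[t[:, 1]] - p[t[:, 0]]
            b = p[t[:, 2]] - p[t[:, 0]]
            c = p[t[:, 3]] - p[t[:, 0]]
            self._volumes = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
        return self._volumes

    def centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    # -- combinatorics -------------------------------------------------
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) sorted int array."""
        if self._edges is None:
            t = self.tets
            pairs = np.vstack(
                [t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]],
                 t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]]
            )
            pairs.sort(axis=1)
            self._edges = np.unique(pairs, axis=0)
        return self._edges

    def edge_graph(self, weights: np.ndarray | None = None) -> sparse.csr_matrix:
        """Sparse symmetric adjacency over mesh edges (weights default to length)."""
        e = self.edges()
        if weights is None:
            weights = np.linalg.norm(self.points[e[:, 0]] - self.points[e[:, 1]], axis=1)
        n = self.n_nodes
        g = sparse.coo_matrix(
            (np.concatenate([weights, weights]),
             (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return g.tocsr()

    def boundary_faces(self) -> np.ndarray:
        """Faces incident to exactly one tet, as (n_bf, 3) node triples."""
        if self._boundary_faces is None:
            t = self.tets
            faces = np.vstack(
                [t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]]]
            )
            key = np.sort(faces, axis=1)
            _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
            self._boundary_faces = faces[idx[counts == 1]]
        return self._boundary_faces

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces().ravel())

    def node_elements(self) -> sparse.csr_matrix:
        """Node-to-element incidence (n_nodes x n_tets boolean CSR)."""
        m = self.n_tets
        rows = self.tets.ravel()
        cols = np.repeat(np.arange(m), 4)
        return sparse.coo_matrix(
            (np.ones(4 * m, bool), (rows, cols)), shape=(self.n_nodes, m)
        ).tocsr()

    def require_set(self, name: str) -> np.ndarray:
        if name not in self.node_sets:
            raise KeyError(f"unknown node set {name!r}; available: {sorted(self.node_sets)}")
        return np.asarray(self.node_sets[name], dtype=np.int64)


def extract_submesh(mesh: LabeledMesh, elems: np.ndarray):
    """Submesh of the given elements; returns (submesh, original node ids).

    Node sets and integer-node landmarks are restricted to surviving nodes.
    """
    elems = np.asarray(elems, dtype=np.int64)
    node_ids = np.unique(mesh.tets[elems].ravel())
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[node_ids] = np.arange(node_ids.size)
    sub_sets = {}
    for name, nodes in mesh.node_sets.items():
        kept = remap[np.asarray(nodes, dtype=np.int64)]
        kept = kept[kept >= 0]
        if kept.size:
            sub_sets[name] = kept
    sub = LabeledMesh(
        points=mesh.points[node_ids],
        tets=remap[mesh.tets[elems]],
        labels=mesh.labels[elems].copy(),
        node_sets=sub_sets,
        landmarks=dict(mesh.landmarks),
        fibers=None if mesh.fibers is None else mesh.fibers[elems].copy(),
    )
    return sub, node_ids


def geodesic_distances(mesh: LabeledMesh, sources: np.ndarray) -> np.ndarray:
    """Graph geodesic distance (mm) from a node set, via Dijkstra on mesh edges."""
    from scipy.sparse.csgraph import dijkstra

    g = mesh.edge_graph()
    d = dijkstra(g, directed=False, indices=np.asarray(sources, dtype=np.int64))
    return d.min(axis=0) if d.ndim == 2 else d


def shortest_path_nodes(mesh: LabeledMesh, start: int, goal: int) -> np.ndarray:
    """Node index sequence of the shortest edge-graph path from start to goal."""
    from scipy.sparse.csgraph import dijkstra

    g = mesh.edge_graph()
    _, pred = dijkstra(g, directed=False, indices=start, return_predecessors=True)
    if pred[goal] < 0 and goal != start:
        raise ValueError(f"no path between nodes {start} and {goal}")
    path = [goal]
    while path[-1] != start:
        path.append(int(pred[path[-1]]))
    return np.array(path[::-1], dtype=np.int64)
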