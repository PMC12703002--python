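"""Deterministic synthetic biatrial geometry, torso and mesh quality.

The generator stands in for an image-derived anatomical twinning stage: two
thick-walled ellipsoidal atria with endocardial and epicardial layers, nine
labeled orifice rings (MV, LSPV, LIPV, RSPV, RIPV on the left; TV, SVC, IVC,
CS on the right), appendage patches (LAA, RAA), a transmural fossa-ovalis
bridge joining the atria, and a surrounding torso surface carrying the nine
standard ECG electrodes.

Construction: a subdivided icosahedron is mapped onto each atrial ellipsoid,
orifice caps are removed by a cone-angle test, the wall is built as two
inward normal-offset layers, and each surface triangle prism is split into
three tetrahedra with a consistent minimum-index diagonal rule so adjacent
prisms conform.  Both atria reuse the same sphere tessellation (the left
atrium mirrored in x), which yields an exact node correspondence for the
fossa-ovalis bridge prisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import REGION_CODES, LabeledMesh

# ---------------------------------------------------------------------------
# Icosphere
# ---------------------------------------------------------------------------

_ICO_EDGE = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))  # unit icosahedron edge


def icosphere(subdivisions: int):
    """Unit icosphere: (vertices, faces) after ``subdivisions`` 4-way splits."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
         [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
         [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
         [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
         [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
         [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]], dtype=np.int64)
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    return verts, faces


def _subdivide(verts, faces):
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges.sort(axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = verts[uniq[:, 0]] + verts[uniq[:, 1]]
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    new = np.vstack([verts, mid])
    m01 = len(verts) + inv[: len(faces)]
    m12 = len(verts) + inv[len(faces): 2 * len(faces)]
    m20 = len(verts) + inv[2 * len(faces):]
    f = faces
    new_faces = np.vstack([
        np.stack([f[:, 0], m01, m20], axis=1),
        np.stack([f[:, 1], m12, m01], axis=1),
        np.stack([f[:, 2], m20, m12], axis=1),
        np.stack([m01, m12, m20], axis=1),
    ])
    return new, new_faces


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class OrificeSpec:
    """Cone removing a cap from the atrial shell (axis in the atrium-local
    frame where +x points septal, -y anterior, +z superior)."""

    axis: tuple
    half_angle_deg: float


# Ring orifices, appendage patches and the FO patch, per atrium.
DEFAULT_RA_ORIFICES = {
    "tv": OrificeSpec((0.0, 0.0, -1.0), 35.0),
    "svc": OrificeSpec((0.0, 0.34, 0.94), 16.0),
    "ivc": OrificeSpec((0.0, 0.94, -0.34), 18.0),
    "cs": OrificeSpec((0.5, 0.52, -0.66), 7.0),
}
DEFAULT_LA_ORIFICES = {
    "mv": OrificeSpec((0.0, 0.0, -1.0), 38.0),
    "lspv": OrificeSpec((-0.6, 0.5, 0.62), 14.0),
    "lipv": OrificeSpec((-0.55, 0.79, -0.25), 14.0),
    "rspv": OrificeSpec((0.6, 0.5, 0.62), 14.0),
    "ripv": OrificeSpec((0.55, 0.79, -0.25), 14.0),
}
DEFAULT_APPENDAGES = {
    "raa": OrificeSpec((-0.7, -0.2, 0.686), 15.0),
    "laa": OrificeSpec((-0.65, -0.55, 0.52), 15.0),
}
FO_PATCH = OrificeSpec((0.97, 0.2, 0.14), 8.0)

# Landmark directions (atrium-local frame) for the Bachmann-bundle band.
BB_START_RA = (-0.25, -0.5, 0.83)   # anterosuperior lateral RA, near the SVC
BB_MID_LA = (0.35, -0.6, 0.72)      # anterior septal LA wall (local frame)
BB_END_LA = (-0.5, -0.6, 0.62)      # anterior lateral LA, toward the LAA


@dataclass
class GeometryConfig:
    """Parameters of the synthetic biatrial geometry (lengths in mm).

    Wall thicknesses are surrogate a-priori values (total, split evenly
    between the endo and epi layer).  The default target edge length of
    0.9 mm matches the resolution used for eikonal-type activation models;
    0.25 mm would be the reaction--diffusion resolution (not needed here).
    """

    la_semi_axes: tuple = (23.0, 25.0, 22.0)
    ra_semi_axes: tuple = (24.0, 26.0, 25.0)
    la_wall_thickness: float = 2.0
    ra_wall_thickness: float = 2.5
    target_edge_length: float = 0.9
    septal_gap: float = 3.0
    atria: tuple = ("RA", "LA")
    ra_orifices: dict = field(default_factory=lambda: dict(DEFAULT_RA_ORIFICES))
    la_orifices: dict = field(default_factory=lambda: dict(DEFAULT_LA_ORIFICES))
    appendages: dict = field(default_factory=lambda: dict(DEFAULT_APPENDAGES))
    fo_patch: OrificeSpec = field(default_factory=lambda: FO_PATCH)
    include_fo_bridge: bool = True
    seed: int = 0
    jitter: float = 0.0  # fraction of local edge length

    def __post_init__(self):
        if self.la_wall_thickness <= 0 or self.ra_wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if self.target_edge_length <= 0:
            raise ValueError("target edge length must be positive")
        thick = min(
            self.la_wall_thickness if "LA" in self.atria else np.inf,
            self.ra_wall_thickness if "RA" in self.atria else np.inf,
        )
        if self.target_edge_length > thick:
            raise ValueError(
                f"target edge length {self.target_edge_length} mm is coarser than the "
                f"thinnest wall ({thick} mm); the layers would not be resolved")

    def subdivisions(self) -> int:
        rs = []
        if "LA" in self.atria:
            rs.append(np.mean(self.la_semi_axes))
        if "RA" in self.atria:
            rs.append(np.mean(self.ra_semi_axes))
        rmean = max(rs)
        n = int(np.ceil(np.log2(_ICO_EDGE * rmean / self.target_edge_length)))
        return max(n, 1)

    def centers(self) -> dict:
        off = 0.0
        if len(self.atria) == 2:
            off = (self.ra_semi_axes[0] + self.la_semi_axes[0] + self.septal_gap) / 2.0
        return {"RA": np.array([-off, 0.0, 0.0]), "LA": np.array([off, 0.0, 0.0])}


def _check_cone_overlap(cones: dict, margin_deg: float = 2.0) -> None:
    names = list(cones)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ang = np.degrees(np.arccos(np.clip(
                np.dot(_unit(cones[a].axis), _unit(cones[b].axis)), -1, 1)))
            lim = cones[a].half_angle_deg + cones[b].half_angle_deg + margin_deg
            if ang < lim:
                raise ValueError(
                    f"orifice cones {a!r} and {b!r} overlap: axis separation "
                    f"{ang:.1f} deg < {lim:.1f} deg")


# ---------------------------------------------------------------------------
# Single-atrium shell
# ---------------------------------------------------------------------------

def _prism_tets(tri_cols, bottom, top):
    """Split prisms into 3 tets each using the minimum-index diagonal rule.

    ``tri_cols`` (m, 3) are per-prism column keys (consistent across prisms);
    ``bottom``/``top`` (m, 3) the node ids of the two triangles.
    """
    order = np.argsort(tri_cols, axis=1)
    b = np.take_along_axis(bottom, order, axis=1)
    t = np.take_along_axis(top, order, axis=1)
    t1 = np.stack([b[:, 0], b[:, 1], b[:, 2], t[:, 2]], axis=1)
    t2 = np.stack([b[:, 0], b[:, 1], t[:, 2], t[:, 1]], axis=1)
    t3 = np.stack([b[:, 0], t[:, 1], t[:, 2], t[:, 0]], axis=1)
    return np.vstack([t1, t2, t3])


def _fix_orientation(points, tets):
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vols = np.einsum("ij,ij->i", np.cross(a, b), c)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


def _ellipsoid_offset(u, semi_axes, depth, center, mirror_x):
    """Point on/inside the ellipsoid: map unit direction, offset along normal."""
    s = np.array([-1.0, 1.0, 1.0]) if mirror_x else np.array([1.0, 1.0, 1.0])
    p = (u * s) * np.asarray(semi_axes)
    n = p / np.asarray(semi_axes) ** 2
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return center + p - depth * n


class _AtriumShell:
    """Book-keeping for one atrium built over the shared sphere tessellation."""

    def __init__(self, name, sverts, sfaces, cfg: GeometryConfig):
        self.name = name
        semi = cfg.ra_semi_axes if name == "RA" else cfg.la_semi_axes
        thick = cfg.ra_wall_thickness if name == "RA" else cfg.la_wall_thickness
        orifices = cfg.ra_orifices if name == "RA" else cfg.la_orifices
        app_name = "raa" if name == "RA" else "laa"
        cones = dict(orifices)
        _check_cone_overlap(cones)
        self.semi = np.asarray(semi, float)
        self.center = cfg.centers()[name]
        self.mirror = name == "LA"
        self.thick = thick

        fc = sverts[sfaces].mean(axis=1)
        fc /= np.linalg.norm(fc, axis=1, keepdims=True)
        removed = np.zeros(len(sfaces), dtype=bool)
        self.cap_faces = {}
        for oname, spec in orifices.items():
            ax = _unit(spec.axis)
            inside = fc @ ax > np.cos(np.radians(spec.half_angle_deg))
            self.cap_faces[oname] = np.flatnonzero(inside)
            removed |= inside
        self.kept_faces = sfaces[~removed]
        self.removed_mask = removed
        self.sfaces = sfaces
        self.sverts = sverts

        app = cfg.appendages.get(app_name)
        self.app_name = app_name
        self.app_faces = np.flatnonzero(
            (fc @ _unit(app.axis) > np.cos(np.radians(app.half_angle_deg))) & ~removed
        ) if app is not None else np.array([], dtype=np.int64)

        kept_vids = np.unique(self.kept_faces.ravel())
        self.kept_vids = kept_vids
        self.n_shell = kept_vids.size
        self.vid_to_local = -np.ones(len(sverts), dtype=np.int64)
        self.vid_to_local[kept_vids] = np.arange(self.n_shell)

    def build(self, node_offset, rng, jitter):
        """Create nodes (3 shells: endo, mid, epi), tets and labels."""
        depths = np.array([self.thick, self.thick / 2.0, 0.0])  # endo, mid, epi
        u = self.sverts[self.kept_vids]
        shells = [
            _ellipsoid_offset(u, self.semi, d, self.center, self.mirror)
            for d in depths
        ]
        pts = np.vstack(shells)
        if jitter > 0:
            pts = pts + rng.normal(scale=jitter * self.thick / 2.0, size=pts.shape)
        lf = self.vid_to_local[self.kept_faces]  # local shell triangles
        n = self.n_shell
        tets_endo = _prism_tets(lf, node_offset + lf, node_offset + n + lf)
        tets_epi = _prism_tets(lf, node_offset + n + lf, node_offset + 2 * n + lf)
        tets = np.vstack([tets_endo, tets_epi])
        labels = np.concatenate([
            np.full(len(tets_endo), REGION_CODES[f"{self.name}_endo"]),
            np.full(len(tets_epi), REGION_CODES[f"{self.name}_epi"]),
        ])
        # appendage patch elements (both layers): the 3 tets of each prism
        nk = len(self.kept_faces)
        face_rows = -np.ones(len(self.sfaces), dtype=np.int64)
        face_rows[~self.removed_mask] = np.arange(nk)
        app_rows = face_rows[self.app_faces]
        app_elem = np.concatenate([app_rows + k * nk for k in range(3)] +
                                  [app_rows + 3 * nk + k * nk for k in range(3)]) \
            if app_rows.size else np.array([], dtype=np.int64)
        labels[app_elem] = REGION_CODES[self.app_name.upper()]
        self.node_offset = node_offset
        self.points = pts
        return pts, tets, labels, app_elem

    def shell_nodes(self, layer):
        """Global node ids of a shell layer: 0 endo, 1 mid, 2 epi."""
        return self.node_offset + layer * self.n_shell + np.arange(self.n_shell)

    def nodes_for_vids(self, vids, layer):
        loc = self.vid_to_local[vids]
        if np.any(loc < 0):
            raise ValueError("sphere vertex not present in kept shell")
        return self.node_offset + layer * self.n_shell + loc

    def ring_vids(self, oname):
        """Ordered sphere-vertex loop bounding an orifice cap.

        Cones are disjoint, so the boundary of the cap face set (edges used
        exactly once within the cap) is exactly the orifice ring.
        """
        removed_faces = self.sfaces[self.cap_faces[oname]]
        e = np.vstack([removed_faces[:, [0, 1]], removed_faces[:, [1, 2]],
                       removed_faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        loop_edges = [tuple(x) for x in uniq[counts == 1]]
        adj = {}
        for a, b in loop_edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        start = loop_edges[0][0]
        loop = [start]
        prev = None
        while True:
            nxts = [v for v in adj[loop[-1]] if v != prev]
            if not nxts:
                raise ValueError(f"orifice ring {oname!r} is not a closed loop")
            prev = loop[-1]
            loop.append(nxts[0])
            if loop[-1] == start:
                break
        return np.array(loop[:-1], dtype=np.int64)

    def epi_node_near(self, local_dir):
        u = _unit(local_dir)
        tgt = _ellipsoid_offset(u[None, :], self.semi, 0.0, self.center, self.mirror)[0]
        epi = self.shell_nodes(2)
        pts = self.points[2 * self.n_shell: 3 * self.n_shell]
        return int(epi[np.argmin(np.linalg.norm(pts - tgt, axis=1))])


# ---------------------------------------------------------------------------
# Biatrial generator
# ---------------------------------------------------------------------------

def generate_biatrial(config: GeometryConfig | None = None) -> LabeledMesh:
    """Generate the labeled synthetic biatrial tetrahedral mesh.

    Deterministic given the configuration (including its seed).  Node sets:
    ``ring_<name>`` (ordered orifice loops on the mid-wall surface),
    ``<atrium>_endo_surface`` / ``<atrium>_epi_surface``, appendage patches
    ``laa`` / ``raa``, and per-atrium node sets ``ra_nodes`` / ``la_nodes``.
    """
    cfg = config or GeometryConfig()
    rng = np.random.default_rng(cfg.seed)
    sverts, sfaces = icosphere(cfg.subdivisions())

    shells = {}
    all_pts, all_tets, all_labels = [], [], []
    offset = 0
    for name in cfg.atria:
        sh = _AtriumShell(name, sverts, sfaces, cfg)
        pts, tets, labels, _ = sh.build(offset, rng, cfg.jitter)
        shells[name] = sh
        all_pts.append(pts)
        all_tets.append(tets)
        all_labels.append(labels)
        offset += pts.shape[0]

    points = np.vstack(all_pts)
    tets = np.vstack(all_tets)
    labels = np.concatenate(all_labels)

    node_sets, landmarks = {}, {}
    for name in cfg.atria:
        sh = shells[name]
        orifices = cfg.ra_orifices if name == "RA" else cfg.la_orifices
        for oname in orifices:
            vids = sh.ring_vids(oname)
            mid_nodes = sh.nodes_for_vids(vids, 1)
            node_sets[f"ring_{oname}"] = mid_nodes
            for layer, tag in ((0, "endo"), (2, "epi")):
                node_sets[f"ring_{oname}_{tag}"] = sh.nodes_for_vids(vids, layer)
            landmarks[f"{oname}_center"] = points[mid_nodes].mean(axis=0)
        pre = name.lower()
        node_sets[f"{pre}_endo_surface"] = sh.shell_nodes(0)
        node_sets[f"{pre}_epi_surface"] = sh.shell_nodes(2)
        node_sets[f"{pre}_nodes"] = sh.node_offset + np.arange(3 * sh.n_shell)
        landmarks[f"{pre}_center"] = sh.center
        landmarks[f"{pre}_semi_axes"] = sh.semi

    # appendage node sets + centroids
    for name in cfg.atria:
        sh = shells[name]
        if sh.app_faces.size:
            vids = np.unique(sh.sfaces[sh.app_faces].ravel())
            nodes = np.concatenate([sh.nodes_for_vids(vids, k) for k in range(3)])
            node_sets[sh.app_name] = nodes
            landmarks[f"{sh.app_name}_centroid"] = points[nodes].mean(axis=0)

    # split-plane landmarks (normals in the global frame; LA x-mirrored)
    if "RA" in cfg.atria:
        landmarks["ra_split_normal"] = np.array([1.0, 0.0, 0.0])
    if "LA" in cfg.atria:
        ax1 = _unit(cfg.la_orifices["lspv"].axis)
        ax2 = _unit(cfg.la_orifices["rspv"].axis)
        n = np.cross(ax1 * np.array([-1, 1, 1]), ax2 * np.array([-1, 1, 1]))
        n = _unit(n)
        if n[1] > 0:  # orient so positive side is anterior (-y)
            n = -n
        landmarks["la_split_normal"] = n

    # Bachmann-bundle path landmarks
    if "RA" in cfg.atria:
        landmarks["bb_start_node"] = shells["RA"].epi_node_near(BB_START_RA)
    if "LA" in cfg.atria:
        landmarks["bb_mid_node"] = shells["LA"].epi_node_near(BB_MID_LA)
        landmarks["bb_end_node"] = shells["LA"].epi_node_near(BB_END_LA)

    # fossa-ovalis bridge: prisms between corresponding epi patches
    if cfg.include_fo_bridge and len(cfg.atria) == 2:
        fc = sverts[sfaces].mean(axis=1)
        fc /= np.linalg.norm(fc, axis=1, keepdims=True)
        ax = _unit(cfg.fo_patch.axis)
        fo_faces = np.flatnonzero(fc @ ax > np.cos(np.radians(cfg.fo_patch.half_angle_deg)))
        ra, la = shells["RA"], shells["LA"]
        tris = sfaces[fo_faces]
        ra_nodes = ra.nodes_for_vids(tris.ravel(), 2).reshape(tris.shape)
        la_nodes = la.nodes_for_vids(tris.ravel(), 2).reshape(tris.shape)
        bridge = _prism_tets(tris, ra_nodes, la_nodes)
        tets = np.vstack([tets, bridge])
        labels = np.concatenate([labels, np.full(len(bridge), REGION_CODES["FO_rim"])])
        fo_vids = np.unique(tris.ravel())
        node_sets["fo_ra"] = ra.nodes_for_vids(fo_vids, 2)
        node_sets["fo_la"] = la.nodes_for_vids(fo_vids, 2)
        landmarks["fo_center"] = points[np.concatenate(
            [node_sets["fo_ra"], node_sets["fo_la"]])].mean(axis=0)

    tets = _fix_orientation(points, tets)
    mesh = LabeledMesh(points=points, tets=tets, labels=labels,
                       node_sets=node_sets, landmarks=landmarks)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Torso and electrodes
# ---------------------------------------------------------------------------

ELECTRODE_ORDER = ["RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"]
# surface directions: x to the patient's left, -y anterior, +z superior
ELECTRODE_DIRECTIONS = {
    "RA": (-0.80, -0.25, 0.55),
    "LA": (0.80, -0.25, 0.55),
    "LL": (0.45, -0.30, -0.84),
    "V1": (-0.18, -0.97, 0.15),
    "V2": (0.05, -0.99, 0.12),
    "V3": (0.25, -0.96, 0.05),
    "V4": (0.42, -0.90, 0.00),
    "V5": (0.62, -0.78, -0.02),
    "V6": (0.80, -0.60, -0.03),
}


@dataclass
class TorsoModel:
    """Homogeneous torso volume conductor with named surface electrodes."""

    surface_points: np.ndarray
    surface_faces: np.ndarray
    electrodes: dict              # name -> 3-vector (a surface node position)
    electrode_nodes: dict         # name -> surface/volume node index
    conductivity: float = 0.2     # S/m
    volume_points: np.ndarray | None = None
    volume_tets: np.ndarray | None = None
    center: np.ndarray | None = None
    semi_axes: np.ndarray | None = None

    def electrode_positions(self) -> np.ndarray:
        return np.array([self.electrodes[n] for n in ELECTRODE_ORDER])


@dataclass
class TorsoConfig:
    semi_axes: tuple = (170.0, 110.0, 240.0)
    center: tuple = (0.0, 0.0, 0.0)
    subdivisions: int = 3
    n_shells: int = 8
    conductivity: float = 0.2
    build_volume_mesh: bool = False
    sphere: bool = False  # equal semi-axes (validation torso)

    def axes(self):
        if self.sphere:
            r = float(np.mean(self.semi_axes))
            return np.array([r, r, r])
        return np.asarray(self.semi_axes, float)


def generate_torso_with_electrodes(mesh: LabeledMesh,
                                   config: TorsoConfig | None = None) -> TorsoModel:
    """Ellipsoidal torso enclosing the atria, with the 9 standard electrodes.

    Electrodes are snapped to surface mesh nodes (needed for the FEM lead
    field) and returned in the fixed order RA, LA, LL, V1..V6.
    """
    cfg = config or TorsoConfig()
    axes = cfg.axes()
    center = np.asarray(cfg.center, float)
    rel = (mesh.points - center) / axes
    if np.any((rel ** 2).sum(axis=1) >= 1.0):
        raise ValueError("atria are not strictly inside the torso")

    sverts, sfaces = icosphere(cfg.subdivisions)
    surf = center + sverts * axes

    electrodes, enodes = {}, {}
    for name in ELECTRODE_ORDER:
        tgt = center + _unit(ELECTRODE_DIRECTIONS[name]) * axes
        i = int(np.argmin(np.linalg.norm(surf - tgt, axis=1)))
        electrodes[name] = surf[i]
        enodes[name] = i

    torso = TorsoModel(surface_points=surf, surface_faces=sfaces,
                       electrodes=electrodes, electrode_nodes=enodes,
                       conductivity=cfg.conductivity, center=center,
                       semi_axes=axes)
    if cfg.build_volume_mesh:
        _build_torso_volume(torso, sverts, sfaces, cfg)
    return torso


def _build_torso_volume(torso: TorsoModel, sverts, sfaces, cfg: TorsoConfig):
    """Concentric-shell tet mesh of the solid torso ellipsoid.

    The outermost shell reuses the surface tessellation, so electrode node
    indices remain valid in the volume mesh.
    """
    K = cfg.n_shells
    nv = len(sverts)
    # cosine-graded radii: fine near the surface (injected point currents)
    # and near the center (where the field is evaluated), coarser between
    radii = 0.5 * (1.0 - np.cos(np.pi * np.arange(K, 0, -1) / K))
    pts = [torso.center + sverts * (torso.semi_axes * r) for r in radii]
    pts.append(torso.center[None, :])  # center node
    points = np.vstack(pts)
    cols = sfaces
    tets = []
    for k in range(K - 1):
        tets.append(_prism_tets(cols, k * nv + cols, (k + 1) * nv + cols))
    center_id = K * nv
    fan = np.concatenate(
        [(K - 1) * nv + sfaces, np.full((len(sfaces), 1), center_id)], axis=1)
    tets.append(fan)
    tets = _fix_orientation(points, np.vstack(tets))
    torso.volume_points = points
    torso.volume_tets = tets


# ---------------------------------------------------------------------------
# Structured box mesh (benchmark geometry)
# ---------------------------------------------------------------------------

def box_mesh(lengths=(10.0, 10.0, 10.0), divisions=(10, 10, 10),
             region: str = "RA_endo") -> LabeledMesh:
    """Structured tetrahedral box (Kuhn 6-tet split per cell), mm.

    Node sets ``x0, x1, y0, y1, z0, z1`` name the six faces.  Used for slab
    benchmarks (eikonal velocity recovery, FEM exactness on linear fields).
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1)
    corners = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corners[(dx, dy, dz)] = nid(base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz)
    # Kuhn split: one tet per permutation path 000 -> 111
    perms = [((1, 0, 0), (1, 1, 0)), ((1, 0, 0), (1, 0, 1)),
             ((0, 1, 0), (1, 1, 0)), ((0, 1, 0), (0, 1, 1)),
             ((0, 0, 1), (1, 0, 1)), ((0, 0, 1), (0, 1, 1))]
    tets = []
    for mid1, mid2 in perms:
        tets.append(np.stack([corners[(0, 0, 0)], corners[mid1], corners[mid2],
                              corners[(1, 1, 1)]], axis=1))
    tets = _fix_orientation(points, np.vstack(tets))
    labels = np.full(len(tets), REGION_CODES[region])
    node_sets = {
        "x0": np.flatnonzero(points[:, 0] == 0.0),
        "x1": np.flatnonzero(points[:, 0] == lx),
        "y0": np.flatnonzero(points[:, 1] == 0.0),
        "y1": np.flatnonzero(points[:, 1] == ly),
        "z0": np.flatnonzero(points[:, 2] == 0.0),
        "z1": np.flatnonzero(points[:, 2] == lz),
    }
    return LabeledMesh(points=points, tets=tets, labels=labels, node_sets=node_sets)


# ---------------------------------------------------------------------------
# Mesh quality
# ---------------------------------------------------------------------------

def mesh_quality(mesh: LabeledMesh):
    """Per-element quality ``q_e = 1 - V_e / V`` and the global mean.

    ``V`` is the volume of the equilateral tetrahedron whose edge equals the
    element's average edge length; a regular tet scores 0, a degenerate
    sliver approaches 1.  Zero-volume elements score exactly 1 (warning).
    """
    p = mesh.points[mesh.tets]  # (m, 4, 3)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge_len = np.stack(
        [np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in pairs], axis=1)
    avg_edge = edge_len.mean(axis=1)
    v_equil = avg_edge ** 3 / (6.0 * np.sqrt(2.0))
    ve = np.abs(mesh.volumes())
    with np.errstate(divide="ignore", invalid="ignore"):
        qe = 1.0 - ve / v_equil
    degenerate = ve == 0
    if np.any(degenerate):
        warnings.warn(f"{degenerate.sum()} zero-volume element(s): q_e set to 1")
        qe[degenerate] = 1.0
    qe = np.clip(qe, 0.0, 1.0)
    return qe, float(qe.mean())
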