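"""Rule-based anatomical annotation of the biatrial mesh.

Covers orifice-ring detection on the wall surface, pulmonary-vein
disambiguation by the nearest-centroid cascade, the battery of 15
Laplace--Dirichlet (LD) labeling fields, marking of discrete structures
(sino-atrial node, fossa-ovalis annulus, Bachmann-bundle band, terminal
crest, pectinate muscles), and a gradient-based surrogate fiber field.

The LD fields are harmonic "distance orderings" between orifices and
appendages; all structure-marking rules operate on them plus a handful of
metric widths (sphere radius, band widths) that are exposed as
:class:`StructureRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np

from . import fem
from .mesh import (LA_REGIONS, RA_REGIONS, REGION_CODES, LabeledMesh,
                   extract_submesh, shortest_path_nodes)

_ENDO_CODES = (REGION_CODES["LA_endo"], REGION_CODES["RA_endo"])
_EPI_CODES = (REGION_CODES["LA_epi"], REGION_CODES["RA_epi"])


# ---------------------------------------------------------------------------
# Orifice rings
# ---------------------------------------------------------------------------

def detect_orifice_rings(mesh: LabeledMesh) -> dict:
    """Detect orifice rings as ordered closed node loops.

    A ring node is a surface (boundary) node incident to both endo- and
    epi-labeled elements: at an orifice the open rim exposes the mid-wall
    nodes shared by the two layers.  Loops are matched to anatomy through
    the generator's ``<name>_center`` landmarks when present, otherwise
    returned as ``ring_0``, ``ring_1``, ...
    """
    bnodes = mesh.boundary_nodes()
    inc = mesh.node_elements()
    is_endo = np.isin(mesh.labels, _ENDO_CODES)
    is_epi = np.isin(mesh.labels, _EPI_CODES)
    touches_endo = (inc @ is_endo.astype(np.int8)) > 0
    touches_epi = (inc @ is_epi.astype(np.int8)) > 0
    candidate = np.zeros(mesh.n_nodes, dtype=bool)
    candidate[bnodes] = True
    candidate &= touches_endo & touches_epi

    # adjacency restricted to candidate nodes via boundary-face edges
    bf = mesh.boundary_faces()
    e = np.vstack([bf[:, [0, 1]], bf[:, [1, 2]], bf[:, [2, 0]]])
    e.sort(axis=1)
    e = np.unique(e, axis=0)
    e = e[candidate[e[:, 0]] & candidate[e[:, 1]]]
    adj: dict = {}
    for a, b in e:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))

    loops = []
    seen = set()
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        prev = None
        while True:
            nbrs = [v for v in adj[loop[-1]] if v != prev]
            if len(nbrs) == 0:
                raise ValueError(f"open (non-loop) orifice chain starting at node {start}")
            prev = loop[-1]
            loop.append(nbrs[0])
            if loop[-1] == start:
                break
            if len(loop) > len(adj) + 1:
                raise ValueError(f"orifice chain at node {start} does not close")
        loop = loop[:-1]
        seen.update(loop)
        loops.append(np.array(loop, dtype=np.int64))

    named = {}
    centers = {k[:-len("_center")]: v for k, v in mesh.landmarks.items()
               if k.endswith("_center") and np.ndim(v) == 1 and len(v) == 3
               and not k.startswith(("ra_", "la_", "fo_"))}
    if centers:
        for loop in loops:
            c = mesh.points[loop].mean(axis=0)
            name = min(centers, key=lambda k: np.linalg.norm(centers[k] - c))
            named[name] = loop
        if len(named) != len(loops):
            raise ValueError("ring-to-anatomy assignment is ambiguous (duplicate nearest landmark)")
        return named
    return {f"ring_{i}": loop for i, loop in enumerate(loops)}


def classify_pulmonary_veins(rings: dict, laa_centroid: np.ndarray,
                             points: np.ndarray, rtol: float = 1e-6) -> dict:
    """Label four unnamed PV rings via the nearest-centroid cascade.

    LSPV = ring centroid closest to the LAA; LIPV = closest to the LSPV;
    RSPV = of the remaining two, closest to the LAA; RIPV = the remainder.
    Distance ties (within relative tolerance) raise, mirroring an
    interactive fallback rather than choosing silently.
    """
    if len(rings) != 4:
        raise ValueError(f"expected exactly 4 unlabeled PV rings, got {len(rings)}")
    cents = {k: points[v].mean(axis=0) for k, v in rings.items()}
    laa_centroid = np.asarray(laa_centroid, float)

    def nearest(keys, ref):
        d = {k: float(np.linalg.norm(cents[k] - ref)) for k in keys}
        srt = sorted(d, key=d.get)
        if len(srt) > 1 and abs(d[srt[0]] - d[srt[1]]) <= rtol * max(d[srt[0]], 1e-300):
            raise ValueError(
                f"ambiguous PV classification: {srt[0]} and {srt[1]} are equidistant; "
                "manual assignment required")
        return srt[0]

    remaining = list(rings)
    lspv = nearest(remaining, laa_centroid)
    remaining.remove(lspv)
    lipv = nearest(remaining, cents[lspv])
    remaining.remove(lipv)
    rspv = nearest(remaining, laa_centroid)
    remaining.remove(rspv)
    ripv = remaining[0]
    return {"lspv": rings[lspv], "lipv": rings[lipv],
            "rspv": rings[rspv], "ripv": rings[ripv]}


# ---------------------------------------------------------------------------
# Laplace--Dirichlet field battery
# ---------------------------------------------------------------------------

RA_FIELD_NAMES = ("phi_trans", "phi_ab", "phi_v", "phi_v2", "phi_v3",
                  "phi_r", "phi_r2", "phi_w", "phi_w2")
LA_FIELD_NAMES = ("phi_trans", "phi_ab", "phi_ab2", "phi_v", "phi_r", "phi_r2")


@dataclass
class LDFieldSet:
    """The labeling LD fields, stored on the full mesh (NaN outside domain)."""

    fields: dict                  # atrium -> {name -> (n_nodes,) array}
    domains: dict                 # atrium -> element index array

    def __getitem__(self, key):
        atrium, name = key
        return self.fields[atrium][name]


def ring_annulus(mesh: LabeledMesh, name: str, rings: dict) -> np.ndarray:
    """Transmural node set of an orifice rim: detected loop plus the endo/epi
    rim loops when the generator provides them."""
    parts = [np.asarray(rings[name], dtype=np.int64)]
    for tag in ("endo", "epi"):
        key = f"ring_{name}_{tag}"
        if key in mesh.node_sets:
            parts.append(mesh.require_set(key))
    return np.unique(np.concatenate(parts))


def plane_band_nodes(points: np.ndarray, nodes: np.ndarray, normal: np.ndarray,
                     origin: np.ndarray, half_width: float) -> np.ndarray:
    """Nodes of ``nodes`` within ``half_width`` of the plane (n, origin)."""
    d = (points[nodes] - origin) @ (normal / np.linalg.norm(normal))
    return nodes[np.abs(d) <= half_width]


def _tv_split(mesh: LabeledMesh, tv_nodes: np.ndarray):
    """Septal / lateral halves of the tricuspid annulus (split plane sign)."""
    n = mesh.landmarks["ra_split_normal"]
    c = mesh.landmarks["ra_center"]
    d = (mesh.points[tv_nodes] - c) @ n
    return tv_nodes[d >= 0], tv_nodes[d < 0]  # septal, lateral


def _median_edge(mesh: LabeledMesh) -> float:
    e = mesh.edges()
    return float(np.median(np.linalg.norm(mesh.points[e[:, 0]] - mesh.points[e[:, 1]], axis=1)))


def atrium_elements(mesh: LabeledMesh, atrium: str) -> np.ndarray:
    """Elements of one atrial domain Ωmyo.

    Membership is geometric when the generator's per-atrium node sets are
    available (structure labels such as the BB band can span both atria, and
    FO-annulus wall elements stay part of their atrium; only the inter-atrial
    bridge block, whose nodes mix both atria, is excluded).  Falls back to
    region labels for plain single-region meshes.
    """
    key = f"{atrium.lower()}_nodes"
    if key in mesh.node_sets:
        mask = np.zeros(mesh.n_nodes, dtype=bool)
        mask[mesh.require_set(key)] = True
        return np.flatnonzero(mask[mesh.tets].all(axis=1))
    regions = RA_REGIONS if atrium == "RA" else LA_REGIONS
    return mesh.elements_in(*regions)


def solve_labeling_fields(mesh: LabeledMesh, rings: dict) -> LDFieldSet:
    """Solve the full battery of labeling LD problems on both atria.

    Each atrium is a separate harmonic domain; Dirichlet data live on the
    orifice rims, appendage patches, endo/epi surfaces and the RA roof band
    (the intersection of the IVC--SVC--center plane with the RA wall).
    """
    fields: dict = {}
    domains: dict = {}
    for atrium in ("RA", "LA"):
        elems = atrium_elements(mesh, atrium)
        if elems.size == 0:
            continue
        sub, node_ids = extract_submesh(mesh, elems)
        pre = atrium.lower()

        def ann(name):
            loc = -np.ones(mesh.n_nodes, dtype=np.int64)
            loc[node_ids] = np.arange(node_ids.size)
            glob = ring_annulus(mesh, name, rings)
            out = loc[glob]
            out = out[out >= 0]
            if out.size == 0:
                raise ValueError(f"Table ring set {name!r} missing on the {atrium} domain")
            return out

        endo = sub.require_set(f"{pre}_endo_surface")
        epi = sub.require_set(f"{pre}_epi_surface")

        specs: dict = {"phi_trans": [(endo, 0.0), (epi, 1.0)]}
        if atrium == "RA":
            tv, svc, ivc = ann("tv"), ann("svc"), ann("ivc")
            raa = sub.require_set("raa")
            roof = plane_band_nodes(
                sub.points, np.arange(sub.n_nodes),
                mesh.landmarks["ra_split_normal"], mesh.landmarks["ra_center"],
                0.5 * _median_edge(sub))
            tvs_g, tvl_g = _tv_split(mesh, ring_annulus(mesh, "tv", rings))
            loc = -np.ones(mesh.n_nodes, dtype=np.int64)
            loc[node_ids] = np.arange(node_ids.size)
            tvs, tvl = loc[tvs_g], loc[tvl_g]
            tvs, tvl = tvs[tvs >= 0], tvl[tvl >= 0]
            specs.update({
                "phi_ab": [(raa, -1.0), (svc, 0.0), (tv, 1.0), (ivc, 2.0)],
                "phi_v": [(svc, 0.0), (raa, 0.0), (ivc, 1.0)],
                "phi_v2": [(ivc, 0.0), (raa, 1.0)],
                "phi_v3": [(svc, 0.0), (ivc, 1.0)],
                "phi_r": [(roof, 0.0), (tv, 1.0)],
                "phi_r2": [(svc, 0.0), (roof, 0.0), (ivc, 0.0), (tv, 1.0)],
                "phi_w": [(tvl, -1.0), (tvs, 1.0)],
                "phi_w2": [(roof, 0.0), (tvl, -1.0), (tvs, 1.0)],
            })
            names = RA_FIELD_NAMES
        else:
            mv = ann("mv")
            lpv = np.unique(np.concatenate([ann("lspv"), ann("lipv")]))
            rpv = np.unique(np.concatenate([ann("rspv"), ann("ripv")]))
            laa = sub.require_set("laa")
            specs.update({
                "phi_ab": [(laa, -1.0), (lpv, 0.0), (mv, 1.0), (rpv, 2.0)],
                "phi_ab2": [(rpv, 0.0), (laa, 1.0)],
                "phi_v": [(lpv, 0.0), (rpv, 1.0)],
                "phi_r": [(lpv, 0.0), (rpv, 0.0), (laa, 0.0), (mv, 1.0)],
                "phi_r2": [(lpv, 0.0), (rpv, 0.0), (mv, 1.0)],
            })
            names = LA_FIELD_NAMES

        K = fem.stiffness_matrix(sub.points, sub.tets)
        out = {}
        for fname in names:
            dbc = fem.DirichletSpec(specs[fname])
            fixed, vals = dbc.resolve(sub)
            sol = fem.solve_dirichlet(K, fixed, vals)
            full = np.full(mesh.n_nodes, np.nan)
            full[node_ids] = sol
            out[fname] = full
        fields[atrium] = out
        domains[atrium] = elems
    return LDFieldSet(fields=fields, domains=domains)


# ---------------------------------------------------------------------------
# Structure marking
# ---------------------------------------------------------------------------

@dataclass
class StructureRules:
    """Metric widths and thresholds for discrete-structure marking (mm)."""

    san_radius: float = 2.50
    fo_thickness: float = 2.00
    bb_width: float = 2.00
    tc_lo: float = 0.85
    tc_hi: float = 0.95
    pm_count: int = 6
    pm_fill: float = 0.35

    def __post_init__(self):
        for nm in ("san_radius", "fo_thickness", "bb_width"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")


def _elements_all_nodes_in(mesh: LabeledMesh, node_mask: np.ndarray,
                           candidates: np.ndarray) -> np.ndarray:
    inside = node_mask[mesh.tets[candidates]].all(axis=1)
    return candidates[inside]


def polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min perpendicular distance of each point to a polyline (mm)."""
    best = np.full(len(points), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        if L2 == 0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / L2, 0.0, 1.0)
            d = np.linalg.norm(points - (a + t[:, None] * ab), axis=1)
        np.minimum(best, d, out=best)
    return best


def san_center_node(mesh: LabeledMesh, fields: LDFieldSet, rings: dict) -> int:
    """SAN center: the node of the SVC rim with minimal phi_v2."""
    svc = ring_annulus(mesh, "svc", rings)
    v2 = fields["RA", "phi_v2"][svc]
    return int(svc[np.nanargmin(v2)])


def bb_path(mesh: LabeledMesh) -> np.ndarray:
    """Geodesic Bachmann-bundle polyline through the generator landmarks."""
    s = int(mesh.landmarks["bb_start_node"])
    m = int(mesh.landmarks["bb_mid_node"])
    e = int(mesh.landmarks["bb_end_node"])
    p1 = shortest_path_nodes(mesh, s, m)
    p2 = shortest_path_nodes(mesh, m, e)
    return np.concatenate([p1, p2[1:]])


def mark_structures(mesh: LabeledMesh, fields: LDFieldSet,
                    rules: StructureRules | None = None) -> LabeledMesh:
    """Augment element labels with SAN, FO annulus, BB band, TC and PMs.

    Marking is monotone in the metric widths, and overlapping structures
    follow the precedence SAN > BB > TC > PM (applied last wins by writing
    in increasing precedence).  Empty structures warn, they do not raise.
    """
    rules = rules or StructureRules()
    labels = mesh.labels.copy()
    pts = mesh.points
    ra_elems = atrium_elements(mesh, "RA")

    # --- pectinate muscles: periodic bands of phi_v on the RA endo layer
    endo_elems = mesh.elements_in("RA_endo")
    if endo_elems.size and "RA" in fields.fields:
        v = fields["RA", "phi_v"]
        cv = np.nanmean(v[mesh.tets[endo_elems]], axis=1)
        frac = np.mod(rules.pm_count * cv, 1.0)
        pm = endo_elems[frac <= rules.pm_fill]
        if pm.size == 0:
            warn("PM marking produced no elements")
        labels[pm] = REGION_CODES["PM"]

    # --- terminal crest: iso-band of phi_r2 on the RA endo layer
    if endo_elems.size and "RA" in fields.fields:
        r2 = fields["RA", "phi_r2"]
        cr = np.nanmean(r2[mesh.tets[endo_elems]], axis=1)
        tc = endo_elems[(cr >= rules.tc_lo) & (cr <= rules.tc_hi)]
        if tc.size == 0:
            warn("TC marking produced no elements")
        labels[tc] = REGION_CODES["TC"]

    # --- fossa ovalis annulus around the bridge attachment rim
    if "fo_ra" in mesh.node_sets and rules.fo_thickness > 0:
        rim_pts = np.vstack([pts[mesh.require_set("fo_ra")],
                             pts[mesh.require_set("fo_la")]])
        wall = mesh.elements_in("RA_epi", "LA_epi", "RA_endo", "LA_endo")
        cent = pts[mesh.tets[wall]].mean(axis=1)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(rim_pts).query(cent)
        fo = wall[d <= rules.fo_thickness]
        labels[fo] = REGION_CODES["FO_rim"]

    # --- Bachmann-bundle band around the geodesic path
    if "bb_start_node" in mesh.landmarks and rules.bb_width > 0:
        try:
            poly = pts[bb_path(mesh)]
        except ValueError:
            warn("BB path endpoints are disconnected (no FO bridge?); BB not marked")
            poly = None
    else:
        poly = None
    if poly is not None:
        wall = np.concatenate([ra_elems, atrium_elements(mesh, "LA")])
        nodes = mesh.nodes_of_elements(wall)
        near = np.zeros(mesh.n_nodes, dtype=bool)
        d = polyline_distance(pts[nodes], poly)
        near[nodes] = d <= rules.bb_width / 2.0
        mesh.node_sets["bb_band"] = np.flatnonzero(near)
        bb = _elements_all_nodes_in(mesh, near, wall)
        if bb.size == 0:
            warn("BB marking produced no elements (band thinner than the local edge length)")
        labels[bb] = REGION_CODES["BB"]

    # --- sino-atrial node sphere
    if "RA" in fields.fields and rules.san_radius > 0:
        rings = {k[len("ring_"):]: mesh.require_set(k) for k in mesh.node_sets
                 if k.startswith("ring_") and not k.endswith(("_endo", "_epi"))}
        if "svc" in rings:
            c = san_center_node(mesh, fields, rings)
            within = np.linalg.norm(pts - pts[c], axis=1) <= rules.san_radius
            ra_nodes = np.zeros(mesh.n_nodes, dtype=bool)
            ra_nodes[mesh.nodes_of_elements(ra_elems)] = True
            mesh.node_sets["san_nodes"] = np.flatnonzero(within & ra_nodes)
            san = _elements_all_nodes_in(mesh, within, ra_elems)
            if san.size == 0:
                warn("SAN marking produced no elements")
            labels[san] = REGION_CODES["SAN"]
            mesh.landmarks["san_center_node"] = c

    out = LabeledMesh(points=mesh.points, tets=mesh.tets, labels=labels,
                      node_sets=mesh.node_sets, landmarks=mesh.landmarks,
                      fibers=mesh.fibers)
    return out


# ---------------------------------------------------------------------------
# Surrogate fibers
# ---------------------------------------------------------------------------

@dataclass
class FiberRule:
    """Configuration of the gradient-based fiber surrogate.

    Fibers are the wall-tangent projection of the gradient of one labeling
    field per region (the full anatomical rule set of atlas-based methods is
    intentionally out of scope; this surrogate produces a smooth, unit,
    wall-tangent family adequate for anisotropic conduction).
    """

    default_field: str = "phi_ab"
    # appendage patches carry Dirichlet data of phi_ab (constant inside the
    # patch), so they draw from a field that is free there
    region_fields: dict = field(default_factory=lambda: {"RAA": "phi_v3", "LAA": "phi_v"})
    constant: tuple | None = None  # overrides everything when set


def compute_fibers(mesh: LabeledMesh, fields: LDFieldSet,
                   rule: FiberRule | None = None) -> np.ndarray:
    """Per-element unit fiber vectors, tangent to the wall."""
    rule = rule or FiberRule()
    m = mesh.n_tets
    if rule.constant is not None:
        f = np.tile(np.asarray(rule.constant, float) / np.linalg.norm(rule.constant), (m, 1))
        mesh.fibers = f
        return f

    fib = np.zeros((m, 3))
    have = np.zeros(m, dtype=bool)
    for atrium in fields.fields:
        elems = fields.domains[atrium]
        sub, node_ids = extract_submesh(mesh, elems)
        grads_cache = {}

        def grad_of(name):
            if name not in grads_cache:
                grads_cache[name] = fem.element_gradient(sub, fields[atrium, name][node_ids])
            return grads_cache[name]

        normal = grad_of("phi_trans")
        nn = np.linalg.norm(normal, axis=1, keepdims=True)
        normal = np.divide(normal, nn, out=np.zeros_like(normal), where=nn > 0)
        names = mesh.region_names()[elems]
        src_names = np.array([rule.region_fields.get(r, rule.default_field) for r in names])
        for fname in np.unique(src_names):
            sel = src_names == fname
            g = grad_of(fname)[sel]
            n = normal[sel]
            t = g - (np.einsum("ij,ij->i", g, n))[:, None] * n
            norm = np.linalg.norm(t, axis=1, keepdims=True)
            ok = norm[:, 0] > 1e-12
            t = np.divide(t, norm, out=np.zeros_like(t), where=norm > 0)
            idx = elems[sel]
            fib[idx] = t
            have[idx] = ok

    # bridge elements (no LD fields): fiber along the strand (bridge axis)
    bridge = mesh.elements_in("FO_rim")
    bridge = bridge[~have[bridge]] if bridge.size else bridge
    if bridge.size:
        if "fo_ra" in mesh.node_sets and "fo_la" in mesh.node_sets:
            axis = (mesh.points[mesh.require_set("fo_la")].mean(axis=0)
                    - mesh.points[mesh.require_set("fo_ra")].mean(axis=0))
        else:
            axis = np.array([1.0, 0.0, 0.0])
        fib[bridge] = axis / np.linalg.norm(axis)
        have[bridge] = True

    # fallback: average over vertex-neighbors, repeated until the zero-gradient
    # patches are filled from their rim inward
    if not have.all():
        inc = mesh.node_elements()
        while not have.all():
            progress = False
            for e in np.flatnonzero(~have):
                nbrs = np.unique(inc[mesh.tets[e]].indices)
                nbrs = nbrs[have[nbrs]]
                if nbrs.size == 0:
                    continue
                v = fib[nbrs].mean(axis=0)
                nv = np.linalg.norm(v)
                if nv == 0:
                    continue
                fib[e] = v / nv
                have[e] = True
                progress = True
            if not progress:
                bad = int(np.flatnonzero(~have)[0])
                raise ValueError(f"isolated zero-gradient element {bad}: no fiber source")

    mesh.fibers = fib
    return fib
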