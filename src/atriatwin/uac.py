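"""Volumetric Universal Atrial Coordinates (UACs).

Each atrium is mapped to a unit cuboid: α runs between the two valve-to-vein
interfaces (IVC-to-SVC on the right, lateral-to-septal on the left), β runs
from one valve-annulus side through the roof to the other (0 lateral/posterior
valve, 1 septal/anterior valve), and γ is the relative transmural depth
(0 endocardium, 1 epicardium).  A binary side flag says which atrium the
coordinates belong to.

Construction stages:

1. ``build_interfaces`` — split each atrium into two subdomains by a plane
   through the relevant orifice axes and the atrial center; the node bands
   where the two element sides meet form the three transmural interfaces
   per atrium.
2. ``parameterize_ring_bieikonal`` — arc-length (Bi-Eikonal) parameter
   s ∈ [0, 1] along ring arcs and interfaces.
3. ``compute_preliminary_uac`` — per-subdomain Laplace solves with
   circumferential (quarter-circle, radius R) embeddings of the caval/PV
   orifices on the square edges.
4. ``compute_gamma`` — transmural Laplace solve.
5. ``normalize_orifices_elasticity`` — an updated-Lagrangian linear
   elasticity solve in UAC space that repositions the CS, LIPV and RIPV
   rings onto circles of radius r at their standardized centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from . import fem
from .labeling import atrium_elements, ring_annulus
from .mesh import LabeledMesh, extract_submesh

SUBDOMAIN_SIGNS = {"RA": {"sept": 1, "lat": -1}, "LA": {"ant": 1, "post": -1}}
# per atrium: (valve ring, alpha=0 vein, alpha=1 vein)
ATRIUM_RINGS = {"RA": ("tv", "ivc", "svc"), "LA": ("mv", "lspv", "rspv")}
PLUS_SUBDOMAIN = {"RA": "sept", "LA": "ant"}
MINUS_SUBDOMAIN = {"RA": "lat", "LA": "post"}


@dataclass
class UACNormConfig:
    """Standardized orifice targets and elasticity settings in UAC space."""

    R: float = 0.1
    r: float = 0.04
    alpha_cs: float = 0.2
    beta_cs: float = 0.8
    alpha_ipv: float = 0.25
    beta_ipv: float = 0.25
    growth_layers: int = 3
    cuboid_thickness: float = 0.1
    n_load_steps: int = 5
    young: float = 1.0
    poisson: float = 0.3

    def __post_init__(self):
        if not (0 < self.r < self.R < 0.5):
            raise ValueError("require 0 < r < R < 0.5")
        for a, b in ((self.alpha_cs, self.beta_cs), (self.alpha_ipv, self.beta_ipv)):
            if not (self.r < a < 1 - self.r and self.r < b < 1 - self.r):
                raise ValueError("orifice targets must lie inside the unit square with margin r")


@dataclass
class InterfaceSet:
    """Subdomain partition and transmural interfaces of both atria."""

    element_side: dict        # atrium -> (+1/-1) per atrium element (aligned with elems)
    elems: dict               # atrium -> element ids in the full mesh
    interfaces: dict          # (atrium, kind) -> node ids; kind in {valve_v1, valve_v2, roof}
    interface_s: dict         # (atrium, kind) -> s value per node (same order)
    ring_params: dict         # (atrium, ring name) -> RingParam

    def subdomain_elements(self, atrium: str, sub: str) -> np.ndarray:
        sign = SUBDOMAIN_SIGNS[atrium][sub]
        return self.elems[atrium][self.element_side[atrium] == sign]

    def interface_nodes(self, atrium: str) -> np.ndarray:
        return np.unique(np.concatenate(
            [self.interfaces[(atrium, k)] for k in ("valve_v1", "valve_v2", "roof")]))


@dataclass
class RingParam:
    """Bi-Eikonal ring parameterization: s ∈ [0,1] per loop position."""

    loop: np.ndarray      # ordered node ids
    s: np.ndarray         # per position
    arc: np.ndarray       # 0/1 arc membership per position
    split_pos: tuple      # (position of s=0 split, position of s=1 split)


@dataclass
class UACFrame:
    """Per-node (α, β, γ, side) with the per-subdomain solutions retained.

    ``alpha``/``beta`` carry the septal/anterior-side convention on interface
    nodes (the coordinates are discontinuous across the subdomain cut, as in
    any square parameterization of an annular surface).  ``side`` is 0 for
    RA, 1 for LA.  ``sub_values[(atrium, sub)]`` maps the subdomain's node
    ids to their own (α, β) values, which is what the cuboid mapping and the
    elasticity normalization operate on.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    side: np.ndarray
    sub_values: dict = field(default_factory=dict)
    iface_nodes: dict = field(default_factory=dict)  # atrium -> node ids
    cuboid_thickness: float = 0.1

    def coords(self) -> np.ndarray:
        return np.stack([self.alpha, self.beta, self.gamma], axis=1)


# ---------------------------------------------------------------------------
# Interfaces and subdomains
# ---------------------------------------------------------------------------

def _split_plane(mesh: LabeledMesh, atrium: str):
    pre = atrium.lower()
    n = np.asarray(mesh.landmarks[f"{pre}_split_normal"], float)
    c = np.asarray(mesh.landmarks[f"{pre}_center"], float)
    return n / np.linalg.norm(n), c


def build_interfaces(mesh: LabeledMesh, rings: dict) -> InterfaceSet:
    """Partition each atrium into two subdomains and extract the interfaces.

    The partition plane passes through the atrial center and the axes of the
    valve and the two embedded veins (emitted by the generator as landmark
    normals).  Appendages are kept whole: RAA elements go to the lateral RA,
    LAA elements to the anterior LA.  The interface node band is split into
    the three transmural interfaces by which pair of orifice rims each
    connected piece touches.
    """
    element_side, elems_d, interfaces, interface_s, ring_params = {}, {}, {}, {}, {}
    for atrium in ("RA", "LA"):
        elems = atrium_elements(mesh, atrium)
        if elems.size == 0:
            continue
        n, c = _split_plane(mesh, atrium)
        cent = mesh.points[mesh.tets[elems]].mean(axis=1)
        side = np.where((cent - c) @ n >= 0, 1, -1)
        app = "RAA" if atrium == "RA" else "LAA"
        app_mask = mesh.labels[elems] == mesh.label_of(app)
        side[app_mask] = -1 if atrium == "RA" else 1
        element_side[atrium] = side
        elems_d[atrium] = elems

        # interface nodes: shared by elements of both sides
        pos_nodes = np.zeros(mesh.n_nodes, bool)
        neg_nodes = np.zeros(mesh.n_nodes, bool)
        pos_nodes[np.unique(mesh.tets[elems[side > 0]])] = True
        neg_nodes[np.unique(mesh.tets[elems[side < 0]])] = True
        iface = np.flatnonzero(pos_nodes & neg_nodes)

        valve, v1, v2 = ATRIUM_RINGS[atrium]
        ann = {k: ring_annulus(mesh, k, rings) for k in (valve, v1, v2)}

        sub, node_ids = extract_submesh(mesh, elems)
        loc = -np.ones(mesh.n_nodes, dtype=np.int64)
        loc[node_ids] = np.arange(node_ids.size)
        g = sub.edge_graph()

        def dist_from(nodes_global):
            src = loc[nodes_global]
            src = src[src >= 0]
            d = dijkstra(g, directed=False, indices=src)
            return d.min(axis=0)

        d_valve, d_v1, d_v2 = (dist_from(ann[k]) for k in (valve, v1, v2))

        # classify the interface band into 3 strips via connected components
        ann_all = np.zeros(mesh.n_nodes, bool)
        for k in ann:
            ann_all[ann[k]] = True
        iface_mask = np.zeros(mesh.n_nodes, bool)
        iface_mask[iface] = True
        core = iface[~ann_all[iface]]
        core_loc = loc[core]
        gi = g[core_loc][:, core_loc]
        ncomp, comp = connected_components(gi, directed=False)
        # identify components by the two nearest rims of their closest points
        strips = {}
        for ci in range(ncomp):
            members = core[comp == ci]
            ml = loc[members]
            dv, d1, d2 = d_valve[ml].min(), d_v1[ml].min(), d_v2[ml].min()
            pair = sorted(range(3), key=lambda i: (dv, d1, d2)[i])[:2]
            key = tuple(sorted(pair))
            strips.setdefault(key, []).append(members)
        named = {}
        keymap = {(0, 1): "valve_v1", (0, 2): "valve_v2", (1, 2): "roof"}
        for key, chunks in strips.items():
            if key not in keymap:
                raise ValueError(f"interface strip touches an unexpected rim pair {key}")
            named[keymap[key]] = np.concatenate(chunks)
        for kind in ("valve_v1", "valve_v2", "roof"):
            if kind not in named:
                raise ValueError(f"interface {kind} of the {atrium} is empty: "
                                 "the plane does not separate the atrium as expected")

        # rim-touching interface nodes carry ring Dirichlet data and are
        # deliberately excluded from the strips
        for kind, nodes in named.items():
            ml = loc[nodes]
            if kind == "roof":
                s = d_v1[ml] / (d_v1[ml] + d_v2[ml])
            elif kind == "valve_v1":
                s = d_valve[ml] / (d_valve[ml] + d_v1[ml])
            else:
                s = d_valve[ml] / (d_valve[ml] + d_v2[ml])
            interfaces[(atrium, kind)] = nodes
            interface_s[(atrium, kind)] = s

        # verify separation: removing the interface band disconnects the atrium
        keep = ~iface_mask[np.unique(mesh.tets[elems])]
        nodes_keep = np.unique(mesh.tets[elems])[keep]
        kl = loc[nodes_keep]
        gk = g[kl][:, kl]
        nc, lab = connected_components(gk, directed=False)
        big = np.bincount(lab)
        if (big >= max(4, 0.001 * len(lab))).sum() != 2:
            raise ValueError(f"interfaces fail to separate the {atrium} into two subdomains")

        # ring parameterizations with splits where the band meets each ring
        for rname in (v1, v2, valve):
            loop = np.asarray(rings[rname], dtype=np.int64)
            ring_params[(atrium, rname)] = _parameterize_ring_on_band(
                mesh, loop, iface_mask, d_valve, d_v1, d_v2, loc, rname, valve)

    return InterfaceSet(element_side=element_side, elems=elems_d,
                        interfaces=interfaces, interface_s=interface_s,
                        ring_params=ring_params)


def _contiguous_runs(mask: np.ndarray):
    """Index runs of True in a circular boolean array."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    runs, cur = [], []
    start = int(np.flatnonzero(~mask)[0])
    for k in range(1, n + 1):
        i = (start + k) % n
        if mask[i]:
            cur.append(i)
        elif cur:
            runs.append(np.array(cur))
            cur = []
    if cur:
        runs.append(np.array(cur))
    return runs


def _parameterize_ring_on_band(mesh, loop, iface_mask, d_valve, d_v1, d_v2,
                               loc, rname, valve_name):
    """Ring parameterization with split points where the interface band
    crosses the loop.  s = 0 at the valve-side split, s = 1 at the other."""
    on_band = iface_mask[loop]
    runs = _contiguous_runs(on_band)
    if len(runs) != 2:
        raise ValueError(
            f"ring {rname!r} meets the interface band in {len(runs)} places (expected 2)")
    reps = [int(r[len(r) // 2]) for r in runs]
    if rname == valve_name:
        split0, split1 = reps  # arbitrary but fixed orientation for the valve
    else:
        # the split nearer the valve carries s = 0
        dv = [d_valve[loc[loop[p]]] for p in reps]
        split0, split1 = (reps[0], reps[1]) if dv[0] <= dv[1] else (reps[1], reps[0])
    return parameterize_ring_bieikonal(mesh.points, loop, split0, split1)


def parameterize_ring_bieikonal(points: np.ndarray, loop: np.ndarray,
                                split0: int, split1: int) -> RingParam:
    """Arc-length Bi-Eikonal parameterization of a closed ring.

    ``split0``/``split1`` are positions in the loop.  Each of the two arcs
    between them is parameterized independently by
    ``s = d0 / (d0 + d1)`` with d0, d1 the cumulative arc lengths to the two
    splits, so s = 0 and 1 exactly at the splits and s is strictly monotone
    along each arc.
    """
    loop = np.asarray(loop, dtype=np.int64)
    n = len(loop)
    if split0 == split1:
        raise ValueError("ring split points coincide")
    seg = np.linalg.norm(points[loop] - points[np.roll(loop, -1)], axis=1)

    s = np.zeros(n)
    arc = np.zeros(n, dtype=np.int64)

    def walk(a, b, arc_id):
        # positions a -> b moving forward (wrapping); cumulative lengths
        idx = [a]
        while idx[-1] != b:
            idx.append((idx[-1] + 1) % n)
        idx = np.array(idx)
        cum = np.concatenate([[0.0], np.cumsum(seg[idx[:-1]])])
        total = cum[-1]
        if total == 0:
            raise ValueError("zero-length ring arc")
        s[idx] = cum / total
        arc[idx] = arc_id

    walk(split1, split0, 1)   # second arc first so the first overwrites splits
    walk(split0, split1, 0)
    s[split0], s[split1] = 0.0, 1.0
    # the second arc runs backwards from split1 to split0: flip its s
    second = arc == 1
    second[split0] = second[split1] = False
    s[second] = 1.0 - s[second]
    return RingParam(loop=loop, s=s, arc=arc, split_pos=(split0, split1))


# ---------------------------------------------------------------------------
# Preliminary coordinates
# ---------------------------------------------------------------------------

def _ring_bc_values(which: str, s: np.ndarray, R: float, plus: bool):
    """Quarter-circle embeddings of the vein orifices on the square edges.

    ``which`` is 'v1' (α≈0 vein: IVC/LSPV) or 'v2' (α≈1 vein: SVC/RSPV);
    ``plus`` selects the septal/anterior subdomain column.
    """
    if which == "v1":
        alpha = R * np.cos((1 - s) * np.pi / 2)
    else:
        alpha = 1 + R * np.cos((1 + s) * np.pi / 2)
    if plus:
        beta = 0.5 + R * np.sin((1 - s) * np.pi / 2)
    else:
        beta = 0.5 + R * np.sin((3 + s) * np.pi / 2)
    return alpha, beta


def _interface_bc_values(kind: str, s: np.ndarray, R: float, plus: bool):
    if kind == "roof":
        return R + (1 - 2 * R) * s, np.full_like(s, 0.5)
    alpha = np.zeros_like(s) if kind == "valve_v1" else np.ones_like(s)
    if plus:
        beta = 0.5 + R + (1 - s) * (0.5 - R)
    else:
        beta = s * (0.5 - R)
    return alpha, beta


def _annulus_positions(mesh: LabeledMesh, rname: str, rings: dict):
    """Loop node columns across the three wall layers, ordered like the loop.

    Returns (nodes, positions-in-loop): the mid loop plus, when the generator
    emitted them, the endo and epi rim loops in the same column order.
    """
    loops = [np.asarray(rings[rname], dtype=np.int64)]
    for tag in ("endo", "epi"):
        key = f"ring_{rname}_{tag}"
        if key in mesh.node_sets:
            loops.append(mesh.require_set(key))
    nodes = np.concatenate(loops)
    pos = np.concatenate([np.arange(len(loops[0]))] * len(loops))
    return nodes, pos


def compute_preliminary_uac(mesh: LabeledMesh, interfaces: InterfaceSet,
                            rings: dict, R: float = 0.1,
                            gamma: np.ndarray | None = None) -> UACFrame:
    """Solve the per-subdomain Laplace problems for α and β.

    Boundary data follow the circumferential embedding: valve annulus at
    β ∈ {0, 1}, vein orifices as radius-R half-circles centred on (0, ½) and
    (1, ½) (quarter circle per subdomain), interfaces on the square edges
    and the roof interface at β = ½.
    """
    n = mesh.n_nodes
    alpha = np.full(n, np.nan)
    beta = np.full(n, np.nan)
    side = np.zeros(n, dtype=np.int8)
    sub_values = {}

    for atrium in interfaces.elems:
        valve, v1, v2 = ATRIUM_RINGS[atrium]
        for subname in (MINUS_SUBDOMAIN[atrium], PLUS_SUBDOMAIN[atrium]):
            plus = subname == PLUS_SUBDOMAIN[atrium]
            elems = interfaces.subdomain_elements(atrium, subname)
            sub, node_ids = extract_submesh(mesh, elems)
            loc = -np.ones(n, dtype=np.int64)
            loc[node_ids] = np.arange(node_ids.size)

            bc_alpha, bc_beta = [], []
            for kind in ("valve_v1", "valve_v2", "roof"):
                nodes = interfaces.interfaces[(atrium, kind)]
                s = interfaces.interface_s[(atrium, kind)]
                sel = loc[nodes] >= 0
                a, b = _interface_bc_values(kind, s[sel], R, plus)
                bc_alpha.append((loc[nodes[sel]], a))
                bc_beta.append((loc[nodes[sel]], b))

            for which, rname in (("v1", v1), ("v2", v2)):
                rp = interfaces.ring_params[(atrium, rname)]
                ann_nodes, pos = _annulus_positions(mesh, rname, rings)
                sel = loc[ann_nodes] >= 0
                s = rp.s[pos[sel]]
                a, b = _ring_bc_values(which, s, R, plus)
                bc_alpha.append((loc[ann_nodes[sel]], a))
                bc_beta.append((loc[ann_nodes[sel]], b))

            vann, vpos = _annulus_positions(mesh, valve, rings)
            sel = loc[vann] >= 0
            bc_beta.append((loc[vann[sel]], 1.0 if plus else 0.0))

            K = fem.stiffness_matrix(sub.points, sub.tets)
            fa, va = fem.DirichletSpec(bc_alpha).resolve(sub)
            fb, vb = fem.DirichletSpec(bc_beta).resolve(sub)
            a_sol = fem.solve_dirichlet(K, fa, va)
            b_sol = fem.solve_dirichlet(K, fb, vb)
            sub_values[(atrium, subname)] = {
                "node_ids": node_ids, "alpha": a_sol, "beta": b_sol, "elems": elems,
            }
            # fill whole-mesh arrays; the plus (septal/anterior) side is
            # written last and wins on interface nodes by convention
            alpha[node_ids] = a_sol
            beta[node_ids] = b_sol
        side[np.unique(mesh.tets[interfaces.elems[atrium]])] = 0 if atrium == "RA" else 1

    if gamma is None:
        gamma = compute_gamma(mesh)
    iface_nodes = {a: interfaces.interface_nodes(a) for a in interfaces.elems}
    return UACFrame(alpha=alpha, beta=beta, gamma=gamma, side=side,
                    sub_values=sub_values, iface_nodes=iface_nodes)


def compute_gamma(mesh: LabeledMesh) -> np.ndarray:
    """Transmural coordinate: harmonic, 0 on endocardium, 1 on epicardium."""
    n = mesh.n_nodes
    gamma = np.full(n, np.nan)
    for atrium in ("RA", "LA"):
        elems = atrium_elements(mesh, atrium)
        if elems.size == 0:
            continue
        pre = atrium.lower()
        sub, node_ids = extract_submesh(mesh, elems)
        endo = sub.require_set(f"{pre}_endo_surface")
        epi = sub.require_set(f"{pre}_epi_surface")
        both = np.intersect1d(endo, epi)
        if both.size:
            raise ValueError(
                f"degenerate wall: node(s) on both endo and epi surface of the {atrium}")
        sol = fem.solve_laplace(sub, fem.DirichletSpec([(endo, 0.0), (epi, 1.0)]))
        gamma[node_ids] = sol
    # fossa-ovalis bridge nodes are epicardial by construction
    bridge = mesh.elements_in("FO_rim")
    if bridge.size:
        bn = np.unique(mesh.tets[bridge])
        gamma[bn[np.isnan(gamma[bn])]] = 1.0
    return gamma


# ---------------------------------------------------------------------------
# Elasticity-based orifice normalization
# ---------------------------------------------------------------------------

def _orifice_targets(mesh: LabeledMesh, rings: dict, rname: str,
                     frame: UACFrame, center: tuple, r: float):
    """Target (α, β) per annulus node of an orifice ring.

    The loop is split at its extremal-α points; the higher-β arc maps to the
    upper semicircle (angle sπ), the other to the lower (angle (2−s)π), so
    both arcs meet at (α_c ± r, β_c).
    """
    loop = np.asarray(rings[rname], dtype=np.int64)
    a_vals = frame.alpha[loop]
    split0 = int(np.argmax(a_vals))
    split1 = int(np.argmin(a_vals))
    rp = parameterize_ring_bieikonal(mesh.points, loop, split0, split1)
    mean_beta = [np.nanmean(frame.beta[loop[rp.arc == k]]) for k in (0, 1)]
    upper_arc = int(np.argmax(mean_beta))
    ang = np.where(rp.arc == upper_arc, rp.s * np.pi, (2 - rp.s) * np.pi)
    ta = center[0] + r * np.cos(ang)
    tb = center[1] + r * np.sin(ang)
    ann_nodes, pos = _annulus_positions(mesh, rname, rings)
    return ann_nodes, ta[pos], tb[pos]


ORIFICE_TARGETS = {
    # ring -> (atrium, subdomain, center fn)
    "cs": ("RA", "sept", lambda c: (c.alpha_cs, c.beta_cs)),
    "lipv": ("LA", "post", lambda c: (c.alpha_ipv, c.beta_ipv)),
    "ripv": ("LA", "post", lambda c: (1 - c.alpha_ipv, c.beta_ipv)),
}


def normalize_orifices_elasticity(frame: UACFrame, mesh: LabeledMesh, rings: dict,
                                  cfg: UACNormConfig | None = None) -> UACFrame:
    """Reposition the CS, LIPV and RIPV rings in UAC space.

    The subdomains containing those orifices are mapped onto thin cuboids
    (α, β, γ·thickness); the embedded orifice rims and the interfaces are
    held fixed while the target rings are displaced onto their standardized
    circles through an incremental linear elasticity solve.  Coordinates of
    all other nodes follow elastically; the result stays inside the unit
    square and the rings land on the Table of standardized positions
    exactly (they are Dirichlet data).
    """
    cfg = cfg or UACNormConfig()
    alpha = frame.alpha.copy()
    beta = frame.beta.copy()

    by_sub: dict = {}
    for rname, (atrium, subname, cfn) in ORIFICE_TARGETS.items():
        if (atrium, subname) in frame.sub_values and rname in rings:
            by_sub.setdefault((atrium, subname), []).append((rname, cfn))

    new_sub_values = dict(frame.sub_values)
    for (atrium, subname), targets in by_sub.items():
        sv = frame.sub_values[(atrium, subname)]
        node_ids, elems = sv["node_ids"], sv["elems"]
        sub, ids_check = extract_submesh(mesh, elems)
        assert np.array_equal(ids_check, node_ids)
        loc = -np.ones(mesh.n_nodes, dtype=np.int64)
        loc[node_ids] = np.arange(node_ids.size)

        uac_pts = np.stack(
            [sv["alpha"], sv["beta"], frame.gamma[node_ids] * cfg.cuboid_thickness],
            axis=1)

        # fixed boundary: interfaces + the embedded valve/vein annuli
        valve, v1, v2 = ATRIUM_RINGS[atrium]
        fixed_nodes = loc[frame.iface_nodes[atrium]]
        for rn in (valve, v1, v2):
            ann, _ = _annulus_positions(mesh, rn, rings)
            fixed_nodes = np.concatenate([fixed_nodes, loc[ann]])
        fixed_nodes = np.unique(fixed_nodes[fixed_nodes >= 0])

        # tets collapsing to zero volume in UAC space (all nodes on one
        # embedded rim line) carry no information; they may be dropped iff
        # every node is Dirichlet-fixed
        p = uac_pts[sub.tets]
        vol = np.einsum("ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                        p[:, 3] - p[:, 0]) / 6.0
        scale = np.median(np.abs(vol[vol != 0])) if np.any(vol != 0) else 1.0
        degen = np.abs(vol) < 1e-9 * scale
        if np.any(degen):
            fmask = np.zeros(node_ids.size, dtype=bool)
            fmask[fixed_nodes] = True
            if not fmask[sub.tets[degen]].all():
                bad = np.flatnonzero(degen & ~fmask[sub.tets].all(axis=1))
                raise RuntimeError(
                    f"degenerate UAC-space element(s) with free nodes: {bad[:10].tolist()}")
        uac_mesh = LabeledMesh(points=uac_pts, tets=sub.tets[~degen],
                               labels=sub.labels[~degen], node_sets=sub.node_sets)

        dbc = [(fixed_nodes, np.zeros((fixed_nodes.size, 3)))]
        moved_all = []
        for rname, cfn in targets:
            ann_nodes, ta, tb = _orifice_targets(mesh, rings, rname, frame, cfn(cfg), cfg.r)
            sel = loc[ann_nodes] >= 0
            ln = loc[ann_nodes[sel]]
            disp = np.stack([ta[sel] - sv["alpha"][ln], tb[sel] - sv["beta"][ln],
                             np.zeros(sel.sum())], axis=1)
            dbc.append((ln, disp))
            moved_all.append(ln)

        material = fem.ElasticMaterial(young=cfg.young, poisson=cfg.poisson)
        u = fem.solve_linear_elasticity(
            uac_mesh, fem.DirichletSpec(dbc), material=material,
            n_load_steps=cfg.n_load_steps, check_inversion=False)

        a_new = sv["alpha"] + u[:, 0]
        b_new = sv["beta"] + u[:, 1]
        if a_new.min() < -1e-9 or a_new.max() > 1 + 1e-9 or \
           b_new.min() < -1e-9 or b_new.max() > 1 + 1e-9:
            a_new = np.clip(a_new, 0.0, 1.0)
            b_new = np.clip(b_new, 0.0, 1.0)
        new_sub_values[(atrium, subname)] = {**sv, "alpha": a_new, "beta": b_new}
        # whole-frame arrays keep the septal/anterior convention on interface
        # nodes; those are Dirichlet-fixed here, so only non-interface nodes
        # may actually have moved
        write = np.ones(node_ids.size, dtype=bool)
        if subname == MINUS_SUBDOMAIN[atrium]:
            on_iface = np.zeros(mesh.n_nodes, dtype=bool)
            on_iface[frame.iface_nodes[atrium]] = True
            write = ~on_iface[node_ids]
        alpha[node_ids[write]] = a_new[write]
        beta[node_ids[write]] = b_new[write]

    return UACFrame(alpha=alpha, beta=beta, gamma=frame.gamma, side=frame.side,
                    sub_values=new_sub_values, iface_nodes=frame.iface_nodes,
                    cuboid_thickness=cfg.cuboid_thickness)


# ---------------------------------------------------------------------------
# Coordinate lookup
# ---------------------------------------------------------------------------

def uac_to_node(frame: UACFrame, mesh: LabeledMesh, query) -> int:
    """Nearest mesh node to a UAC query (α, β, γ, side).

    Euclidean metric in (α, β, γ) restricted to the requested side; exact
    ties resolve to the lowest node index.
    """
    a, b, g, side = query
    if side in ("RA", 0):
        s = 0
    elif side in ("LA", 1):
        s = 1
    else:
        raise ValueError(f"invalid side flag {side!r}")
    sel = np.flatnonzero((frame.side == s) & ~np.isnan(frame.alpha))
    d2 = ((frame.alpha[sel] - a) ** 2 + (frame.beta[sel] - b) ** 2
          + (frame.gamma[sel] - g) ** 2)
    return int(sel[np.argmin(d2)])


def jacobian_signs(frame: UACFrame, mesh: LabeledMesh) -> dict:
    """Signed tet volumes of each subdomain mapped into UAC cuboid space.

    A bijectivity proxy: after normalization the map should preserve
    orientation (uniform volume sign per subdomain).
    """
    out = {}
    for key, sv in frame.sub_values.items():
        node_ids, elems = sv["node_ids"], sv["elems"]
        loc = -np.ones(mesh.n_nodes, dtype=np.int64)
        loc[node_ids] = np.arange(node_ids.size)
        pts = np.stack([sv["alpha"], sv["beta"],
                        frame.gamma[node_ids] * frame.cuboid_thickness], axis=1)
        tets = loc[mesh.tets[elems]]
        a = pts[tets[:, 1]] - pts[tets[:, 0]]
        b = pts[tets[:, 2]] - pts[tets[:, 0]]
        c = pts[tets[:, 3]] - pts[tets[:, 0]]
        vols = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
        # physical orientation is positive; flip sign where the physical tet
        # was stored with negative parity relative to the submesh extraction
        out[key] = vols
    return out
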