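"""Universal atrial coordinates: interfaces, ring parameterization,
preliminary solves, transmural coordinate, elasticity normalization."""

import numpy as np
import pytest

from atriatwin import labeling, uac as uac_mod
from atriatwin.mesh import LabeledMesh, REGION_CODES
from atriatwin.synthgeo import OrificeSpec, box_mesh, generate_biatrial
from conftest import coarse_config, fit_circle


class TestRingParameterization:
    def _loop(self, edge_lengths):
        """Closed planar loop whose first len(edge_lengths) segments have the
        given lengths; the loop is closed by a generous return arc."""
        xs = np.concatenate([[0.0], np.cumsum(edge_lengths)])
        fwd = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
        back = np.array([[xs[-1] / 2, 3.0, 0.0]])
        pts = np.vstack([fwd, back])
        loop = np.arange(len(pts))
        return pts, loop

    def test_hand_computed_arc_values(self):
        pts, loop = self._loop([1.0, 1.0, 2.0, 1.0])
        rp = uac_mod.parameterize_ring_bieikonal(pts, loop, 0, 4)
        assert np.allclose(rp.s[:5], [0.0, 0.2, 0.4, 0.8, 1.0])

    def test_splits_exact_and_monotone(self, coarse_mesh, coarse_interfaces):
        rp = coarse_interfaces.ring_params[("RA", "ivc")]
        i0, i1 = rp.split_pos
        assert rp.s[i0] == 0.0 and rp.s[i1] == 1.0
        for arc in (0, 1):
            sel = np.flatnonzero(rp.arc == arc)
            # s strictly monotone along each arc when walked in loop order
            sv = rp.s[sel]
            assert len(np.unique(sv)) == len(sv)

    def test_reversal_flips_s(self):
        pts, loop = self._loop([1.0, 2.0, 1.0, 1.0])
        rp = uac_mod.parameterize_ring_bieikonal(pts, loop, 0, 4)
        rev = loop[::-1].copy()
        pos0 = len(loop) - 1 - 4
        pos1 = len(loop) - 1 - 0
        rp_rev = uac_mod.parameterize_ring_bieikonal(pts, rev, pos0, pos1)
        s_by_node = {n: s for n, s in zip(rev, rp_rev.s)}
        for n, s in zip(loop, rp.s):
            assert s_by_node[n] == pytest.approx(1.0 - s, abs=1e-12)

    def test_coincident_splits_raise(self):
        pts, loop = self._loop([1.0, 1.0])
        with pytest.raises(ValueError, match="coincide"):
            uac_mod.parameterize_ring_bieikonal(pts, loop, 1, 1)

    def test_uniform_ring_midpoint_half(self):
        th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        rp = uac_mod.parameterize_ring_bieikonal(pts, np.arange(8), 0, 4)
        assert rp.s[2] == pytest.approx(0.5)
        assert rp.s[6] == pytest.approx(0.5)


class TestInterfaces:
    def test_each_atrium_splits_into_two_components(self, coarse_interfaces):
        for atrium in ("RA", "LA"):
            pos = coarse_interfaces.subdomain_elements(
                atrium, uac_mod.PLUS_SUBDOMAIN[atrium])
            neg = coarse_interfaces.subdomain_elements(
                atrium, uac_mod.MINUS_SUBDOMAIN[atrium])
            assert len(pos) > 0 and len(neg) > 0
            assert len(pos) + len(neg) == len(coarse_interfaces.elems[atrium])

    def test_raa_assigned_lateral_laa_anterior(self, coarse_mesh, coarse_interfaces):
        raa = coarse_mesh.elements_in("RAA")
        ra_elems = coarse_interfaces.elems["RA"]
        side = coarse_interfaces.element_side["RA"]
        lat = set(coarse_interfaces.subdomain_elements("RA", "lat").tolist())
        assert set(raa.tolist()) <= lat
        laa = coarse_mesh.elements_in("LAA")
        ant = set(coarse_interfaces.subdomain_elements("LA", "ant").tolist())
        assert set(laa.tolist()) <= ant

    def test_symmetric_atrium_balanced_subdomains(self):
        # symmetric RA (no CS, no appendage): the split plane is a mirror plane
        cfg = coarse_config(
            atria=("RA",), include_fo_bridge=False, appendages={},
            ra_orifices={"tv": OrificeSpec((0, 0, -1), 35.0),
                         "svc": OrificeSpec((0, 0.34, 0.94), 16.0),
                         "ivc": OrificeSpec((0, 0.94, -0.34), 18.0)})
        m = generate_biatrial(cfg)
        rings = labeling.detect_orifice_rings(m)
        ifs = uac_mod.build_interfaces(m, rings)
        n_sept = len(ifs.subdomain_elements("RA", "sept"))
        n_lat = len(ifs.subdomain_elements("RA", "lat"))
        assert abs(n_sept - n_lat) <= 0.02 * (n_sept + n_lat)


class TestPreliminaryUAC:
    def test_valve_beta_one_septal_zero_lateral(self, coarse_frame, coarse_rings):
        for atrium, sub_plus, sub_minus in (("RA", "sept", "lat"), ("LA", "ant", "post")):
            valve = uac_mod.ATRIUM_RINGS[atrium][0]
            loop = coarse_rings[valve]
            for sub, val in ((sub_plus, 1.0), (sub_minus, 0.0)):
                sv = coarse_frame.sub_values[(atrium, sub)]
                loc = {n: i for i, n in enumerate(sv["node_ids"])}
                got = [sv["beta"][loc[n]] for n in loop if n in loc]
                assert len(got) > 0
                assert np.allclose(got, val)

    def test_roof_interface_alpha_formula(self, coarse_frame, coarse_interfaces):
        R = 0.1
        for atrium in ("RA", "LA"):
            nodes = coarse_interfaces.interfaces[(atrium, "roof")]
            s = coarse_interfaces.interface_s[(atrium, "roof")]
            assert np.allclose(coarse_frame.alpha[nodes], R + (1 - 2 * R) * s)
            assert np.allclose(coarse_frame.beta[nodes], 0.5)

    def test_coordinates_within_unit_square(self, coarse_frame):
        for arr in (coarse_frame.alpha, coarse_frame.beta, coarse_frame.gamma):
            assert np.nanmin(arr) >= -1e-10
            assert np.nanmax(arr) <= 1 + 1e-10

    def test_side_flag(self, coarse_mesh, coarse_frame):
        ra_nodes = coarse_mesh.node_sets["ra_nodes"]
        la_nodes = coarse_mesh.node_sets["la_nodes"]
        assert np.all(coarse_frame.side[ra_nodes] == 0)
        assert np.all(coarse_frame.side[la_nodes] == 1)


class TestGamma:
    def test_surface_dirichlet_exact(self, coarse_mesh, coarse_frame):
        g = coarse_frame.gamma
        for pre in ("ra", "la"):
            assert np.all(g[coarse_mesh.node_sets[f"{pre}_endo_surface"]] == 0.0)
            assert np.all(g[coarse_mesh.node_sets[f"{pre}_epi_surface"]] == 1.0)

    def test_slab_gamma_linear_through_thickness(self):
        m = box_mesh((10, 10, 2), (5, 5, 4), region="RA_endo")
        m.node_sets["ra_endo_surface"] = m.node_sets["z0"]
        m.node_sets["ra_epi_surface"] = m.node_sets["z1"]
        g = uac_mod.compute_gamma(m)
        assert np.allclose(g, m.points[:, 2] / 2.0, atol=1e-9)

    def test_degenerate_wall_raises(self):
        m = box_mesh((2, 2, 1), (2, 2, 1), region="RA_endo")
        m.node_sets["ra_endo_surface"] = m.node_sets["z0"]
        m.node_sets["ra_epi_surface"] = np.concatenate(
            [m.node_sets["z1"], m.node_sets["z0"][:1]])
        with pytest.raises(ValueError, match="degenerate wall"):
            uac_mod.compute_gamma(m)


class TestNormalization:
    def test_cs_circle_at_standard_position(self, normalized_frame, coarse_rings):
        lp = coarse_rings["cs"]
        cx, cy, r = fit_circle(normalized_frame.alpha[lp], normalized_frame.beta[lp])
        assert cx == pytest.approx(0.2, abs=1e-6)
        assert cy == pytest.approx(0.8, abs=1e-6)
        assert r == pytest.approx(0.04, abs=1e-6)

    def test_pv_circles_at_standard_positions(self, normalized_frame, coarse_rings):
        for name, (ca, cb) in (("lipv", (0.25, 0.25)), ("ripv", (0.75, 0.25))):
            lp = coarse_rings[name]
            cx, cy, r = fit_circle(normalized_frame.alpha[lp], normalized_frame.beta[lp])
            assert (cx, cy) == pytest.approx((ca, cb), abs=1e-6)
            assert r == pytest.approx(0.04, abs=1e-6)

    def test_coordinates_remain_in_unit_square(self, normalized_frame):
        assert np.nanmin(normalized_frame.alpha) >= 0.0
        assert np.nanmax(normalized_frame.alpha) <= 1.0
        assert np.nanmin(normalized_frame.beta) >= 0.0
        assert np.nanmax(normalized_frame.beta) <= 1.0

    def test_renormalization_is_near_identity(self, normalized_frame, coarse_mesh,
                                              coarse_rings):
        again = uac_mod.normalize_orifices_elasticity(
            normalized_frame, coarse_mesh, coarse_rings)
        ok = ~np.isnan(normalized_frame.alpha)
        assert np.allclose(again.alpha[ok], normalized_frame.alpha[ok], atol=5e-3)
        assert np.allclose(again.beta[ok], normalized_frame.beta[ok], atol=5e-3)

    def test_interior_orientation_consistent(self, normalized_frame, coarse_mesh,
                                             coarse_rings):
        """Bijectivity proxy: away from the embedded rims the UAC map
        preserves orientation (the rim squeeze inverts a thin boundary
        collar only; see the methods note)."""
        from scipy.spatial import cKDTree
        ringpts = np.vstack([coarse_mesh.points[uac_mod.ring_annulus(coarse_mesh, k,
                                                                     coarse_rings)]
                             for k in coarse_rings])
        tree = cKDTree(ringpts)
        e = coarse_mesh.edges()
        med = np.median(np.linalg.norm(coarse_mesh.points[e[:, 0]]
                                       - coarse_mesh.points[e[:, 1]], axis=1))
        signs = uac_mod.jacobian_signs(normalized_frame, coarse_mesh)
        for key, vols in signs.items():
            atrium = key[0]
            elems = normalized_frame.sub_values[key]["elems"]
            cent = coarse_mesh.points[coarse_mesh.tets[elems]].mean(axis=1)
            d, _ = tree.query(cent)
            # elements entirely inside the subdomain cut map onto the square
            # edges (zero volume by construction); exclude the cut collar too
            dcut, _ = cKDTree(coarse_mesh.points[
                normalized_frame.iface_nodes[atrium]]).query(cent)
            interior = (d > 2 * med) & (dcut > 2 * med)
            assert interior.sum() > 0.4 * len(elems)
            s = np.sign(vols[interior])
            dominant = np.sign(np.median(s))
            assert np.all(s == dominant)


class TestUacToNode:
    def test_round_trip_identity(self, coarse_mesh, normalized_frame):
        rng = np.random.default_rng(2)
        nodes = rng.choice(coarse_mesh.n_nodes, size=50, replace=False)
        f = normalized_frame
        for n in nodes:
            if np.isnan(f.alpha[n]):
                continue
            q = (f.alpha[n], f.beta[n], f.gamma[n], int(f.side[n]))
            got = uac_mod.uac_to_node(f, coarse_mesh, q)
            # identity up to exact coordinate duplicates
            assert (f.alpha[got], f.beta[got], f.gamma[got]) == \
                (f.alpha[n], f.beta[n], f.gamma[n])

    def test_tie_breaks_to_lower_index(self):
        f = uac_mod.UACFrame(alpha=np.array([0.4, 0.6]), beta=np.zeros(2),
                             gamma=np.zeros(2), side=np.zeros(2, np.int8))
        got = uac_mod.uac_to_node(f, None, (0.5, 0.0, 0.0, "RA"))
        assert got == 0

    def test_invalid_side_raises(self, normalized_frame, coarse_mesh):
        with pytest.raises(ValueError, match="side"):
            uac_mod.uac_to_node(normalized_frame, coarse_mesh, (0.5, 0.5, 1.0, "XX"))

    def test_cs_query_lands_near_ring(self, coarse_mesh, normalized_frame, coarse_rings):
        node = uac_mod.uac_to_node(normalized_frame, coarse_mesh, (0.2, 0.8, 0.5, "RA"))
        d = np.linalg.norm(coarse_mesh.points[coarse_rings["cs"]]
                           - coarse_mesh.points[node], axis=1).min()
        e = coarse_mesh.edges()
        med = np.median(np.linalg.norm(coarse_mesh.points[e[:, 0]]
                                       - coarse_mesh.points[e[:, 1]], axis=1))
        assert d <= 4 * med


class TestResolutionRobustness:
    def test_frames_agree_across_resolutions(self):
        """(α, β) computed at two mesh resolutions agree on matched physical
        sample points (nearest-node matching on the epicardium)."""
        frames, meshes = [], []
        for edge in (2.4, 1.7):
            cfg = coarse_config(target_edge_length=edge)
            m = generate_biatrial(cfg)
            rings = labeling.detect_orifice_rings(m)
            ifs = uac_mod.build_interfaces(m, rings)
            frames.append(uac_mod.compute_preliminary_uac(m, ifs, rings))
            meshes.append(m)
        rng = np.random.default_rng(3)
        f0, f1 = frames
        m0, m1 = meshes
        # sample interior RA+LA epi nodes of the coarse mesh, excluding the
        # interface bands where the coordinate is discontinuous by design
        cand = np.concatenate([m0.node_sets["ra_epi_surface"],
                               m0.node_sets["la_epi_surface"]])
        iface = np.concatenate([f0.iface_nodes["RA"], f0.iface_nodes["LA"]])
        from scipy.spatial import cKDTree
        dif, _ = cKDTree(m0.points[iface]).query(m0.points[cand])
        cand = cand[dif > 4.0]
        sample = rng.choice(cand, size=300, replace=False)
        tree = cKDTree(m1.points)
        _, match = tree.query(m0.points[sample])
        da = f0.alpha[sample] - f1.alpha[match]
        db = f0.beta[sample] - f1.beta[match]
        ok = ~(np.isnan(da) | np.isnan(db))
        rms = np.sqrt(np.nanmean(da[ok] ** 2 + db[ok] ** 2))
        assert rms <= 0.02
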