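"""Eikonal solver, Dijkstra oracle, velocity tensors, cables, biatrial coupling."""

import numpy as np
import pytest

from atriatwin import activation as act
from atriatwin.synthgeo import box_mesh, generate_biatrial
from conftest import coarse_config


def slab(lengths=(30, 10, 10), divisions=(30, 10, 10), vl=1.0, vt=1.0,
         fiber=(1.0, 0.0, 0.0)):
    m = box_mesh(lengths, divisions)
    m.fibers = np.tile(np.asarray(fiber, float), (m.n_tets, 1))
    T = act.build_velocity_tensors(m, act.VelocityModel({"RA": (vl, vt)}))
    return m, T


class TestVelocityTensors:
    def test_eigenvalues_and_principal_axis(self):
        m, _ = slab(divisions=(2, 2, 2))
        T = act.build_velocity_tensors(m, act.VelocityModel({"RA": (1.0, 0.5)}))
        assert np.allclose(T[0], np.diag([1.0, 0.25, 0.25]))
        w = np.linalg.eigvalsh(T)
        assert np.allclose(np.sort(w, axis=1), [0.25, 0.25, 1.0])

    def test_isotropic_configuration(self):
        m, _ = slab(divisions=(2, 2, 2))
        T = act.build_velocity_tensors(m, act.VelocityModel({"RA": (0.8, 0.8)}))
        assert np.allclose(T, 0.64 * np.eye(3))

    def test_baseline_table_velocities(self, marked_mesh):
        T = act.build_velocity_tensors(marked_mesh)
        ra = marked_mesh.elements_in("RA_endo")[0]
        w = np.linalg.eigvalsh(T[ra])
        assert np.max(w) == pytest.approx(0.97 ** 2, rel=1e-12)
        assert np.min(w) == pytest.approx(0.74 ** 2, rel=1e-12)

    def test_missing_region_raises(self):
        m, _ = slab(divisions=(2, 2, 2))
        with pytest.raises(KeyError, match="RA"):
            act.build_velocity_tensors(m, act.VelocityModel({"LA": (1.0, 0.9)}))

    def test_transverse_exceeding_longitudinal_raises(self):
        with pytest.raises(ValueError):
            act.VelocityModel({"RA": (0.5, 0.9)})


class TestEikonal:
    def test_bar_arrival_matches_distance_over_speed(self):
        m, T = slab(vl=2.0, vt=2.0)
        am = act.solve_eikonal(m, T, [act.Seed(0, 0.0)])
        far = np.flatnonzero((m.points[:, 0] == 30) & (m.points[:, 1] == 0)
                             & (m.points[:, 2] == 0))[0]
        assert am.tau[far] == pytest.approx(15.0, rel=0.01)

    def test_two_seeds_equal_min_of_shifted_maps(self):
        """Multi-seed = pointwise min of single-seed maps.  Discretely the
        equality is exact away from the front collision; on the watershed
        the Godunov face update may undershoot by at most one cell
        traversal time (it interpolates across the shock)."""
        m, T = slab()
        tol = 1e-6
        a = act.solve_eikonal(m, T, [act.Seed(0, 0.0)], tol=tol)
        far = m.n_nodes - 1
        b = act.solve_eikonal(m, T, [act.Seed(far, 5.0)], tol=tol)
        ab = act.solve_eikonal(m, T, [act.Seed(0, 0.0), act.Seed(far, 5.0)], tol=tol)
        ref = np.minimum(a.tau, b.tau)
        cell_time = 1.0  # 1 mm cell / 1 mm/ms
        assert np.all(ab.tau <= ref + 1e-3)
        assert np.all(ab.tau >= ref - cell_time)
        watershed = np.abs(a.tau - b.tau) < 3.0
        assert np.allclose(ab.tau[~watershed], ref[~watershed], atol=1e-3)

    def test_anisotropy_halves_arrival_along_fiber(self):
        m, T = slab(lengths=(10, 10, 2), divisions=(20, 20, 4), vl=2.0, vt=1.0)
        origin = np.flatnonzero(np.all(m.points == 0, axis=1))[0]
        am = act.solve_eikonal(m, T, [act.Seed(int(origin), 0.0)])
        ix = np.flatnonzero((m.points[:, 0] == 10) & (m.points[:, 1] == 0)
                            & (m.points[:, 2] == 0))[0]
        iy = np.flatnonzero((m.points[:, 1] == 10) & (m.points[:, 0] == 0)
                            & (m.points[:, 2] == 0))[0]
        assert am.tau[ix] == pytest.approx(5.0, rel=0.02)
        assert am.tau[iy] == pytest.approx(10.0, rel=0.02)
        assert am.tau[ix] / am.tau[iy] == pytest.approx(0.5, rel=0.03)

    def test_seed_times_exact_and_causal(self):
        m, T = slab()
        am = act.solve_eikonal(m, T, [act.Seed(0, 3.0)])
        assert am.tau[0] == 3.0
        assert np.all(am.tau >= 3.0)

    def test_velocity_recovery_by_regression(self):
        m, T = slab(lengths=(27, 5.4, 5.4), divisions=(30, 6, 6), vl=0.97, vt=0.74)
        src = np.flatnonzero(m.points[:, 0] == 0)
        am = act.solve_eikonal(m, T, [act.Seed(int(s), 0.0) for s in src])
        x = m.points[:, 0]
        sel = x > 5  # skip the near field of the planar source
        slope = np.polyfit(x[sel], am.tau[sel], 1)[0]
        assert 1.0 / slope == pytest.approx(0.97, rel=0.03)

    def test_no_seed_raises(self):
        m, T = slab(divisions=(2, 2, 2))
        with pytest.raises(ValueError):
            act.solve_eikonal(m, T, [])


class TestDijkstraOracle:
    def test_single_edge_exact(self):
        from atriatwin.mesh import LabeledMesh
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        m = LabeledMesh(points=pts, tets=np.array([[0, 1, 2, 3]]), labels=np.array([3]))
        m.fibers = np.array([[1.0, 0, 0]])
        T = act.build_velocity_tensors(m, act.VelocityModel({"RA": (0.5, 0.5)}))
        am = act.dijkstra_oracle(m, T, [act.Seed(0, 0.0)])
        assert am.tau[1] == pytest.approx(4.0, rel=1e-9)

    def test_oracle_upper_bounds_eikonal(self):
        m, T = slab(lengths=(10, 10, 2), divisions=(10, 10, 2), vl=1.3, vt=0.8)
        seeds = [act.Seed(0, 0.0)]
        eik = act.solve_eikonal(m, T, seeds)
        orc = act.dijkstra_oracle(m, T, seeds)
        assert np.all(orc.tau >= eik.tau - 2e-3)

    def test_oracle_error_bounded_eikonal_converges(self):
        """The graph oracle carries a persistent metrication overestimate on
        a structured grid (it cannot shrink below the stencil anisotropy);
        the eikonal solver is the convergent one."""
        orc_errs, eik_errs = [], []
        for n in (4, 8, 16):
            m, T = slab(lengths=(10, 10, 10), divisions=(n, n, n))
            d = np.linalg.norm(m.points - m.points[0], axis=1)
            far = d > 5
            orc = act.dijkstra_oracle(m, T, [act.Seed(0, 0.0)])
            orc_errs.append(np.max(orc.tau[far] / d[far] - 1.0))
            eik = act.solve_eikonal(m, T, [act.Seed(0, 0.0)], tol=1e-6)
            eik_errs.append(np.max(np.abs(eik.tau[far] / d[far] - 1.0)))
        assert max(orc_errs) < 0.15
        assert abs(orc_errs[-1] - orc_errs[0]) < 0.02
        assert eik_errs[-1] <= eik_errs[0]
        assert eik_errs[-1] < 0.04


class TestCables:
    def test_delay_is_length_over_velocity(self, coarse_mesh):
        ra = coarse_mesh.node_sets["ra_epi_surface"][0]
        la = coarse_mesh.node_sets["la_epi_surface"][0]
        c = act.cable_from_nodes(coarse_mesh, int(ra), int(la), 1.0)
        L = np.linalg.norm(coarse_mesh.points[la] - coarse_mesh.points[ra])
        assert c.delay == pytest.approx(L / 1.0)
        c2 = act.cable_from_nodes(coarse_mesh, int(ra), int(la), 2.0)
        assert c2.delay == pytest.approx(c.delay / 2.0)

    def test_uac_anchored_cable_and_same_atrium_error(self, coarse_mesh, normalized_frame):
        c = act.build_ic_cable(normalized_frame, coarse_mesh,
                               (0.8, 0.8, 1.0, "RA"), (0.6, 0.9, 1.0, "LA"), 1.5)
        assert normalized_frame.side[c.origin] == 0
        assert normalized_frame.side[c.insertions[0]] == 1
        assert c.delay > 0
        with pytest.raises(ValueError, match="same atrium"):
            act.build_ic_cable(normalized_frame, coarse_mesh,
                               (0.2, 0.2, 1.0, "RA"), (0.8, 0.8, 1.0, "RA"), 1.5)

    def test_cs_origin_superior_to_ostium(self, coarse_mesh):
        node = act.cs_cable_origin(coarse_mesh)
        cs = coarse_mesh.landmarks["cs_center"]
        svc = coarse_mesh.landmarks["svc_center"]
        d = np.linalg.norm(coarse_mesh.points[node] - cs)
        assert d == pytest.approx(3.5, abs=2.0)
        # superior: closer to the SVC than the ostium centroid is
        assert np.linalg.norm(coarse_mesh.points[node] - svc) < np.linalg.norm(cs - svc)


@pytest.fixture(scope="module")
def decoupled():
    """Biatrial mesh without the FO bridge: cables are the only link."""
    m = generate_biatrial(coarse_config(include_fo_bridge=False))
    from atriatwin import labeling
    rings = labeling.detect_orifice_rings(m)
    fields = labeling.solve_labeling_fields(m, rings)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = labeling.mark_structures(m, fields)
    labeling.compute_fibers(m, fields)
    T = act.build_velocity_tensors(m)
    return m, T


class TestBiatrial:
    def test_no_cables_leaves_la_unreachable(self, decoupled):
        m, T = decoupled
        san = int(m.landmarks["san_center_node"])
        am = act.solve_biatrial_activation(m, T, [act.Seed(san, 0.0)], [])
        la = m.node_sets["la_nodes"]
        ra = m.node_sets["ra_nodes"]
        assert np.all(am.unreachable[la])
        assert not np.any(am.unreachable[ra])

    def test_single_cable_earliest_la_time(self, decoupled):
        m, T = decoupled
        san = int(m.landmarks["san_center_node"])
        o = int(m.landmarks["bb_start_node"])
        i = int(m.landmarks["bb_mid_node"])
        cable = act.cable_from_nodes(m, o, i, 1.5)
        am = act.solve_biatrial_activation(m, T, [act.Seed(san, 0.0)], [cable])
        la = m.node_sets["la_nodes"]
        t_first = am.tau[la].min()
        base = act.solve_biatrial_activation(m, T, [act.Seed(san, 0.0)], [])
        assert t_first == pytest.approx(base.tau[o] + cable.delay, abs=2e-3)
        assert am.tau[la].argmin() == np.flatnonzero(la == i)[0]

    def test_adding_cable_never_increases_tau(self, decoupled):
        m, T = decoupled
        san = int(m.landmarks["san_center_node"])
        c1 = act.cable_from_nodes(m, int(m.landmarks["bb_start_node"]),
                                  int(m.landmarks["bb_mid_node"]), 1.5)
        c2 = act.cable_from_nodes(m, act.cs_cable_origin(m),
                                  int(m.landmarks["bb_end_node"]), 1.5)
        a1 = act.solve_biatrial_activation(m, T, [act.Seed(san, 0.0)], [c1])
        a2 = act.solve_biatrial_activation(m, T, [act.Seed(san, 0.0)], [c1, c2])
        ok = np.isfinite(a1.tau)
        # slack of a few solver tolerances: the fast-iterative relaxation
        # path differs between the two runs
        assert np.all(a2.tau[ok] <= a1.tau[ok] + 1e-2)

    def test_fo_rim_conducts_without_cables(self, marked_mesh):
        T = act.build_velocity_tensors(marked_mesh)
        san = int(marked_mesh.landmarks["san_center_node"])
        am = act.solve_biatrial_activation(marked_mesh, T, [act.Seed(san, 0.0)], [])
        assert not np.any(am.unreachable)
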