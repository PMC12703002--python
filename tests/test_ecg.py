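"""Lead fields, source integral, 12-lead assembly, filtering."""

import numpy as np
import pytest

from atriatwin import activation as act, ecg as ecg_mod
from atriatwin.activation import ActivationMap
from atriatwin.ecg import (APTemplate, ECG12, assemble_12lead, filter_scale,
                           lead_field_analytic, lead_field_fem, lead_field_sphere,
                           compute_electrode_potentials, simulate_pwave)
from atriatwin.synthgeo import (ELECTRODE_ORDER, TorsoConfig, box_mesh,
                                generate_torso_with_electrodes)


@pytest.fixture(scope="module")
def torso(coarse_mesh):
    return generate_torso_with_electrodes(coarse_mesh)


@pytest.fixture(scope="module")
def sphere_torso(coarse_mesh):
    return generate_torso_with_electrodes(
        coarse_mesh, TorsoConfig(sphere=True, semi_axes=(200.0, 200.0, 200.0),
                                 subdivisions=3, n_shells=24, build_volume_mesh=True))


class TestAnalyticLeadField:
    def test_inverse_square_law(self, coarse_mesh, torso):
        lf = lead_field_analytic(torso, coarse_mesh)
        cent = coarse_mesh.centroids()
        for name in ("V1", "LL"):
            d = np.linalg.norm((cent - torso.electrodes[name]) * 1e-3, axis=1)
            mag = np.linalg.norm(lf.grad_z[name], axis=1)
            expected = 1.0 / (4 * np.pi * lf.sigma * d ** 2)
            assert np.allclose(mag, expected, rtol=1e-9)

    def test_sigma_scaling(self, coarse_mesh, torso):
        import dataclasses
        t2 = dataclasses.replace(torso, conductivity=0.4)
        a = lead_field_analytic(torso, coarse_mesh)
        b = lead_field_fem if False else lead_field_analytic(t2, coarse_mesh)
        assert np.allclose(b.grad_z["V1"], 0.5 * a.grad_z["V1"])

    def test_z_hand_value(self, torso):
        # Z at 0.1 m from the electrode, sigma = 0.2 S/m
        z = ecg_mod.analytic_z(
            torso, torso.electrodes["V1"] + np.array([100.0, 0, 0]), "V1")
        assert z == pytest.approx(1.0 / (4 * np.pi * 0.2 * 0.1), rel=1e-12)


class TestFemLeadField:
    def test_fem_matches_bounded_sphere_closed_form(self, coarse_mesh, sphere_torso):
        """FEM lead field against the exact Neumann-sphere solution, as
        electrode-pair fields (the common reference cancels), within 5% RMS
        at the atrial source locations."""
        fem_lf = lead_field_fem(sphere_torso, coarse_mesh, reference="LL")
        ana_lf = lead_field_sphere(sphere_torso, coarse_mesh)
        for name in ("V2", "RA", "LA"):
            gf = fem_lf.grad_z[name] - fem_lf.grad_z["LL"]
            ga = ana_lf.grad_z[name] - ana_lf.grad_z["LL"]
            rel = np.linalg.norm(gf - ga) / np.linalg.norm(ga)
            assert rel < 0.05

    def test_discrete_reciprocity(self, sphere_torso):
        """Swapping source and measurement preserves Z (symmetry of K)."""
        from atriatwin import fem as fem_mod
        from scipy.sparse.linalg import splu
        t = sphere_torso
        pts = t.volume_points * 1e-3
        K = fem_mod.stiffness_matrix(pts, t.volume_tets) * t.conductivity
        n = len(pts)
        pin = n - 1
        free = np.setdiff1d(np.arange(n), [pin])
        lu = splu(K[free][:, free].tocsc())
        a, b = t.electrode_nodes["V1"], t.electrode_nodes["V6"]
        r = t.electrode_nodes["LL"]

        def solve(src, snk):
            rhs = np.zeros(n)
            rhs[src] += 1
            rhs[snk] -= 1
            z = np.zeros(n)
            z[free] = lu.solve(rhs[free])
            return z

        z1 = solve(a, r)
        z2 = solve(b, r)
        assert z1[b] - z1[r] == pytest.approx(z2[a] - z2[r], rel=1e-8)

    def test_missing_volume_mesh_raises(self, coarse_mesh, torso):
        with pytest.raises(ValueError, match="volume mesh"):
            lead_field_fem(torso, coarse_mesh)


class TestSourceIntegral:
    def test_uniform_activation_gives_zero_trace(self, coarse_mesh, torso):
        lf = lead_field_analytic(torso, coarse_mesh)
        amap = ActivationMap(tau=np.full(coarse_mesh.n_nodes, 10.0),
                             unreachable=np.zeros(coarse_mesh.n_nodes, bool))
        out = compute_electrode_potentials(amap, coarse_mesh, lf, duration=30.0)
        for tr in out["traces"].values():
            assert np.allclose(tr, 0.0, atol=1e-15)

    def test_linearity_in_amplitude_and_gi(self, coarse_mesh, torso):
        lf = lead_field_analytic(torso, coarse_mesh)
        x = coarse_mesh.points[:, 0]
        amap = ActivationMap(tau=(x - x.min()) / 2.0,
                             unreachable=np.zeros(coarse_mesh.n_nodes, bool))
        base = compute_electrode_potentials(amap, coarse_mesh, lf, duration=30.0)
        ap2 = APTemplate(rest=-160.0, peak=40.0)  # doubled amplitude
        doubled = compute_electrode_potentials(amap, coarse_mesh, lf, ap=ap2,
                                               duration=30.0)
        import dataclasses
        lf2 = dataclasses.replace(lf, gi=2 * lf.gi)
        gi2 = compute_electrode_potentials(amap, coarse_mesh, lf2, duration=30.0)
        for e in ("V1", "RA"):
            assert np.allclose(doubled["traces"][e], 2 * base["traces"][e], rtol=1e-9)
            assert np.allclose(gi2["traces"][e], 2 * base["traces"][e], rtol=1e-9)

    def test_single_element_matches_analytic_dipole(self, torso):
        """One activated element acts as a current dipole; the far-field
        potential must match the hand-written dipole formula within 2%."""
        m = box_mesh((1.0, 1.0, 1.0), (1, 1, 1))
        lf = lead_field_analytic(torso, m)
        g = np.array([1.0, 0.0, 0.0])  # ms/mm activation gradient
        tau = m.points[:, 0] * g[0]
        amap = ActivationMap(tau=tau, unreachable=np.zeros(m.n_nodes, bool))
        ap = APTemplate()
        out = compute_electrode_potentials(amap, m, lf, ap=ap, duration=10.0)
        t = 5.0
        it = 5
        vols = np.abs(m.volumes()) * 1e-9
        cents = m.centroids()
        sigma = torso.conductivity
        for e in ("V3", "RA"):
            phi = 0.0
            for el in range(m.n_tets):
                tau_e = tau[m.tets[el]].mean()
                p = -vols[el] * lf.gi * ap.u_prime(t - tau_e) * (g * 1e3)  # A·m
                r = (torso.electrodes[e] - cents[el]) * 1e-3
                phi += p @ r / (4 * np.pi * sigma * np.linalg.norm(r) ** 3)
            assert out["traces"][e][it] == pytest.approx(phi, rel=0.02)

    def test_full_activation_returns_to_baseline(self, coarse_mesh, torso):
        lf = lead_field_analytic(torso, coarse_mesh)
        x = coarse_mesh.points[:, 0]
        amap = ActivationMap(tau=(x - x.min()) / 2.0,
                             unreachable=np.zeros(coarse_mesh.n_nodes, bool))
        out = compute_electrode_potentials(amap, coarse_mesh, lf, duration=120.0)
        tr = out["traces"]["V2"]
        assert np.abs(tr[-1]) < 1e-6 * np.abs(tr).max()


class TestAssemble12Lead:
    def _traces(self, rng=None):
        t = np.arange(0.0, 50.0)
        rng = rng or np.random.default_rng(7)
        return {"times": t,
                "traces": {e: rng.normal(size=len(t)) for e in ELECTRODE_ORDER}}

    def test_einthoven_identity_exact(self):
        ecg = assemble_12lead(self._traces())
        assert np.allclose(ecg.lead("I") + ecg.lead("III") - ecg.lead("II"),
                           0.0, atol=1e-12)

    def test_goldberger_identity(self):
        ecg = assemble_12lead(self._traces())
        assert np.allclose(ecg.lead("aVR"),
                           -(ecg.lead("I") + ecg.lead("II")) / 2.0, atol=1e-12)
        assert np.allclose(ecg.lead("-aVR"), -ecg.lead("aVR"))

    def test_all_zero_electrodes_give_zero_leads(self):
        t = np.arange(0.0, 50.0)
        phi = {"times": t, "traces": {e: np.zeros(len(t)) for e in ELECTRODE_ORDER}}
        ecg = assemble_12lead(phi)
        assert all(np.all(v == 0) for v in ecg.traces.values())

    def test_missing_electrode_raises(self):
        phi = self._traces()
        del phi["traces"]["V6"]
        with pytest.raises(ValueError, match="V6"):
            assemble_12lead(phi)

    def test_panel_order(self):
        ecg = assemble_12lead(self._traces())
        assert ecg_mod.LEAD_ORDER == ["aVL", "I", "-aVR", "II", "aVF", "III",
                                      "V1", "V2", "V3", "V4", "V5", "V6"]
        assert ecg.panel().shape == (50, 12)


class TestFilterScale:
    def _ecg(self, fn):
        t = np.arange(0.0, 151.0)
        return ECG12(times=t, traces={k: fn(t) for k in
                                      ecg_mod.LEAD_ORDER + ["aVR"]})

    def test_zero_in_zero_out(self):
        out = filter_scale(self._ecg(lambda t: np.zeros_like(t)))
        assert all(np.allclose(v, 0.0) for v in out.traces.values())

    def test_dc_removed(self):
        out = filter_scale(self._ecg(lambda t: np.full_like(t, 3.0)))
        assert np.abs(out.lead("I")).max() < 0.05 * 3.0 * 0.2

    def test_300hz_tone_attenuated_20db(self):
        tone = self._ecg(lambda t: np.sin(2 * np.pi * 0.3 * t))  # 300 Hz at 1 kHz fs
        out = filter_scale(tone, scale=1.0)
        mid = slice(30, 120)
        att = np.abs(out.lead("V1")[mid]).max() / 1.0
        assert att < 0.1  # >= 20 dB

    def test_scale_factor_applied(self):
        sig = self._ecg(lambda t: np.sin(2 * np.pi * 0.01 * t))  # 10 Hz passband
        scaled = filter_scale(sig, scale=0.2)
        unscaled = filter_scale(sig, scale=1.0)
        assert np.allclose(scaled.lead("II"), 0.2 * unscaled.lead("II"), rtol=1e-12)

    def test_short_trace_raises(self):
        t = np.arange(0.0, 10.0)
        short = ECG12(times=t, traces={k: np.zeros(10) for k in
                                       ecg_mod.LEAD_ORDER + ["aVR"]})
        with pytest.raises(ValueError, match="warm-up"):
            filter_scale(short)
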