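"""Lead-field P-wave forward model and 12-lead assembly.

The extracellular potential at an electrode is the volume integral of the
electrode's lead field against the intracellular source current,

    φ_e(t) = Σ_elements  V_e · ∇Z(x_e) · ( G_i ∇V_m(x_e, t) ),

with the transmembrane voltage represented as a travelling action-potential
template ``V_m(x, t) = U(t − τ(x))`` so that ``∇V_m = −U′(t − τ) ∇τ``.

Lead fields ∇Z are available in three flavours:

* ``lead_field_analytic`` — infinite homogeneous medium,
  Z = 1/(4πσ|x − x_e|); the default for arbitrary torsos.
* ``lead_field_sphere`` — exact closed form for a homogeneous *bounded*
  sphere with insulated boundary and the electrode on the surface
  (Neumann Green's function; the Legendre series sums in closed form).
* ``lead_field_fem`` — P1 finite elements on the torso volume mesh with
  unit current injection/extraction, interpolated (non-conformally) onto
  the atrial element centroids.

Leads are assembled in the clinical panel order aVL, I, −aVR, II, aVF,
III, V1..V6 (the inverted aVR panel is stored alongside aVR itself), then
band-pass filtered (0.5–150 Hz zero-phase Butterworth) and scaled by 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import fem
from .activation import ActivationMap
from .mesh import LabeledMesh
from .synthgeo import ELECTRODE_ORDER, TorsoModel

MM_TO_M = 1e-3

LEAD_ORDER = ["aVL", "I", "-aVR", "II", "aVF", "III",
              "V1", "V2", "V3", "V4", "V5", "V6"]


@dataclass
class APTemplate:
    """Monotone logistic action-potential upstroke (depolarization only)."""

    rest: float = -80.0      # mV
    peak: float = 20.0       # mV
    tau_up: float = 1.0      # ms
    dt: float = 1.0          # ms

    def u(self, t):
        amp = self.peak - self.rest
        return self.rest + amp / (1.0 + np.exp(-np.asarray(t) / self.tau_up))

    def u_prime(self, t):
        amp = self.peak - self.rest
        z = np.asarray(t) / self.tau_up
        # numerically safe logistic derivative
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return amp * s * (1.0 - s) / self.tau_up


@dataclass
class LeadFieldSet:
    """Per-electrode lead-field gradients at the atrial element centroids."""

    grad_z: dict                 # electrode name -> (n_tets, 3), V/(A·m)
    sigma: float = 0.2           # torso conductivity, S/m
    gi: float = 0.174            # intracellular conductivity (isotropic), S/m

    def electrodes(self):
        return [e for e in ELECTRODE_ORDER if e in self.grad_z]


@dataclass
class ECG12:
    """Assembled 12-lead traces (mV) on a common time axis (ms)."""

    times: np.ndarray
    traces: dict                 # lead name -> (n_t,) mV; includes aVR too
    filtered: bool = False
    scale: float = 1.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def lead(self, name: str) -> np.ndarray:
        return self.traces[name]

    def panel(self) -> np.ndarray:
        return np.stack([self.traces[k] for k in LEAD_ORDER], axis=1)


def _check_electrodes_outside(torso: TorsoModel, mesh: LabeledMesh):
    pts = mesh.points
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    for name, pos in torso.electrodes.items():
        if np.all(pos >= lo) and np.all(pos <= hi):
            d = np.linalg.norm(pts - pos, axis=1).min()
            if d < 1.0:
                raise ValueError(f"electrode {name} lies inside the atrial wall")


def lead_field_analytic(torso: TorsoModel, mesh: LabeledMesh) -> LeadFieldSet:
    """Infinite homogeneous medium lead field: Z = 1/(4πσ|x − x_e|)."""
    _check_electrodes_outside(torso, mesh)
    cent = mesh.centroids() * MM_TO_M
    sigma = torso.conductivity
    grad = {}
    for name, pos in torso.electrodes.items():
        r = cent - pos * MM_TO_M
        d = np.linalg.norm(r, axis=1, keepdims=True)
        # grad_x [1/(4 pi sigma |x - xe|)] = -(x - xe) / (4 pi sigma |x-xe|^3)
        grad[name] = -r / (4 * np.pi * sigma * d ** 3)
    return LeadFieldSet(grad_z=grad, sigma=sigma)


def analytic_z(torso: TorsoModel, points_mm: np.ndarray, electrode: str) -> np.ndarray:
    """Infinite-medium Z values (V/A) at the given points."""
    sigma = torso.conductivity
    d = np.linalg.norm((points_mm - torso.electrodes[electrode]) * MM_TO_M, axis=-1)
    return 1.0 / (4 * np.pi * sigma * d)


# ---------------------------------------------------------------------------
# Bounded sphere closed form
# ---------------------------------------------------------------------------

def _sphere_z_and_grad(x, a, center, radius, sigma):
    """Potential and gradient inside an insulated homogeneous sphere due to a
    unit surface current source at ``a`` (all coordinates in meters).

    From the interior Neumann solution
    ``φ = 1/(4πσR) Σ_{l≥1} (2l+1)/l (r/R)^l P_l(cosθ)`` whose Legendre sums
    close to ``2R/d + ln(2R² / (R² − x·a + R d))`` with ``d = |x − a|``
    (an a-independent constant is dropped; it cancels in electrode pairs).
    """
    R = radius
    xr = x - center
    ar = a - center
    d = np.linalg.norm(xr - ar, axis=-1, keepdims=True)
    dot = (xr * ar).sum(axis=-1, keepdims=True)
    pref = 1.0 / (4 * np.pi * sigma * R)
    dn = d / R
    tmu = dot / R ** 2
    z = pref * (2.0 / dn[..., 0] + np.log(2.0 / (1.0 - tmu[..., 0] + dn[..., 0])))
    grad_dn = (xr - ar) / (R * d)
    grad = pref * (-2.0 / dn ** 2 * grad_dn
                   - (-ar / R ** 2 + grad_dn) / (1.0 - tmu + dn))
    return z, grad


def lead_field_sphere(torso: TorsoModel, mesh: LabeledMesh) -> LeadFieldSet:
    """Exact bounded-sphere lead field (requires a spherical torso)."""
    if not np.allclose(torso.semi_axes, torso.semi_axes[0]):
        raise ValueError("closed-form bounded lead field requires a spherical torso")
    _check_electrodes_outside(torso, mesh)
    R = float(torso.semi_axes[0]) * MM_TO_M
    c = torso.center * MM_TO_M
    cent = mesh.centroids() * MM_TO_M
    grad = {}
    for name, pos in torso.electrodes.items():
        _, g = _sphere_z_and_grad(cent, pos * MM_TO_M, c, R, torso.conductivity)
        grad[name] = g
    return LeadFieldSet(grad_z=grad, sigma=torso.conductivity)


def sphere_z(torso: TorsoModel, points_mm: np.ndarray, electrode: str) -> np.ndarray:
    R = float(torso.semi_axes[0]) * MM_TO_M
    z, _ = _sphere_z_and_grad(points_mm * MM_TO_M,
                              torso.electrodes[electrode] * MM_TO_M,
                              torso.center * MM_TO_M, R, torso.conductivity)
    return z


# ---------------------------------------------------------------------------
# FEM lead field on the torso volume mesh
# ---------------------------------------------------------------------------

def lead_field_fem(torso: TorsoModel, mesh: LabeledMesh,
                   reference: str | int = "LL") -> LeadFieldSet:
    """P1 finite-element lead fields on the torso tet mesh.

    Unit current is injected at each electrode node and extracted at the
    reference electrode node (the common sink cancels in every assembled
    lead).  ∇Z is interpolated at the atrial element centroids from the
    containing torso tet (non-conformal embedding).
    """
    if torso.volume_points is None:
        raise ValueError("torso has no volume mesh; generate with build_volume_mesh=True")
    pts_m = torso.volume_points * MM_TO_M
    tets = torso.volume_tets
    tmesh = LabeledMesh(points=pts_m, tets=tets,
                        labels=np.zeros(len(tets), dtype=np.int64))
    K = fem.stiffness_matrix(pts_m, tets) * torso.conductivity
    ref_node = torso.electrode_nodes[reference] if isinstance(reference, str) else int(reference)

    # pin one vertex to fix the Neumann nullspace (chosen far from sources)
    pin = len(pts_m) - 1  # the center node
    n = len(pts_m)
    free = np.setdiff1d(np.arange(n), [pin])
    from scipy.sparse.linalg import splu
    lu = splu(K[free][:, free].tocsc())

    cent = mesh.centroids() * MM_TO_M
    elem_idx = _locate_points(tmesh, cent)
    grads_basis, vols = fem.shape_gradients(pts_m, tets)
    vols = np.abs(vols)

    # barycentric coordinates of each centroid in its containing torso tet
    tt = tets[elem_idx]
    T = np.stack([pts_m[tt[:, 1]] - pts_m[tt[:, 0]],
                  pts_m[tt[:, 2]] - pts_m[tt[:, 0]],
                  pts_m[tt[:, 3]] - pts_m[tt[:, 0]]], axis=2)
    lam = np.linalg.solve(T, (cent - pts_m[tt[:, 0]])[:, :, None])[:, :, 0]
    lam4 = np.concatenate([1 - lam.sum(axis=1, keepdims=True), lam], axis=1)

    grad = {}
    for name, enode in torso.electrode_nodes.items():
        rhs = np.zeros(n)
        rhs[enode] += 1.0
        rhs[ref_node] -= 1.0
        z = np.zeros(n)
        z[free] = lu.solve(rhs[free])
        ge = np.einsum("mk,mkd->md", z[tets], grads_basis)
        # nodal gradient recovery: volume-weighted patch average, then
        # barycentric interpolation (smoother than the raw P1 gradient)
        gn = np.zeros((n, 3))
        wn = np.zeros(n)
        np.add.at(gn, tets.ravel(), np.repeat(ge * vols[:, None], 4, axis=0))
        np.add.at(wn, tets.ravel(), np.repeat(vols, 4))
        gn /= wn[:, None]
        grad[name] = np.einsum("mk,mkd->md", lam4, gn[tt])
    return LeadFieldSet(grad_z=grad, sigma=torso.conductivity)


def _locate_points(tmesh: LabeledMesh, pts: np.ndarray) -> np.ndarray:
    """Containing-tet lookup via KD-tree candidates + barycentric test."""
    from scipy.spatial import cKDTree

    cent = tmesh.centroids()
    tree = cKDTree(cent)
    k = min(32, tmesh.n_tets)
    _, cand = tree.query(pts, k=k)
    p = tmesh.points
    out = np.empty(len(pts), dtype=np.int64)
    for i, (x, cds) in enumerate(zip(pts, cand)):
        found = -1
        best_viol, best_e = np.inf, int(cds[0])
        for e in np.atleast_1d(cds):
            t = tmesh.tets[e]
            T = np.column_stack([p[t[1]] - p[t[0]], p[t[2]] - p[t[0]], p[t[3]] - p[t[0]]])
            try:
                lam = np.linalg.solve(T, x - p[t[0]])
            except np.linalg.LinAlgError:
                continue
            lam4 = np.concatenate([[1 - lam.sum()], lam])
            viol = -lam4.min()
            if viol < best_viol:
                best_viol, best_e = viol, int(e)
            if viol <= 1e-9:
                found = int(e)
                break
        out[i] = found if found >= 0 else best_e
    return out


# ---------------------------------------------------------------------------
# Source integral and lead assembly
# ---------------------------------------------------------------------------

def compute_electrode_potentials(amap: ActivationMap, mesh: LabeledMesh,
                                 leads: LeadFieldSet, ap: APTemplate | None = None,
                                 duration: float = 150.0) -> dict:
    """Per-electrode extracellular potential traces (mV).

    ``φ_e(t) = −Σ_e V_e G_i (∇Z·∇τ) U′(t − τ_e)``; elements touching
    unreachable nodes contribute zero (with a warning).
    """
    ap = ap or APTemplate()
    times = np.arange(0.0, duration + 0.5 * ap.dt, ap.dt)
    node_tau = amap.tau
    elem_ok = np.isfinite(node_tau[mesh.tets]).all(axis=1)
    if not elem_ok.all():
        warnings.warn(f"{(~elem_ok).sum()} unreachable element(s) contribute no source")
    safe_node_tau = np.where(np.isfinite(node_tau), node_tau, 0.0)
    tau_e = np.where(elem_ok, safe_node_tau[mesh.tets].mean(axis=1), 0.0)

    grad_tau = fem.element_gradient(mesh, safe_node_tau) / MM_TO_M  # ms/m
    vol = np.abs(mesh.volumes()) * MM_TO_M ** 3               # m^3

    traces = {}
    for name in leads.grad_z:
        w = -vol * leads.gi * np.einsum("md,md->m", leads.grad_z[name], grad_tau)
        w = np.where(elem_ok, w, 0.0)
        tr = np.empty(len(times))
        for i, t in enumerate(times):
            tr[i] = w @ ap.u_prime(t - tau_e)
        traces[name] = tr
    return {"times": times, "traces": traces}


def assemble_12lead(electrode_traces: dict) -> ECG12:
    """Standard 12-lead assembly from the 9 electrode potentials.

    I = LA − RA, II = LL − RA, III = LL − LA; augmented leads from the
    Goldberger combinations; chest leads against the Wilson central
    terminal.  The inverted −aVR panel is stored alongside aVR.
    """
    times = np.asarray(electrode_traces["times"], float)
    phi = electrode_traces["traces"]
    missing = [e for e in ELECTRODE_ORDER if e not in phi]
    if missing:
        raise ValueError(f"missing electrode trace(s): {missing}")
    ra, la, ll = phi["RA"], phi["LA"], phi["LL"]
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
    }
    leads["aVR"] = ra - (la + ll) / 2.0
    leads["aVL"] = la - (ra + ll) / 2.0
    leads["aVF"] = ll - (ra + la) / 2.0
    leads["-aVR"] = -leads["aVR"]
    wct = (ra + la + ll) / 3.0
    for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
        leads[v] = phi[v] - wct
    return ECG12(times=times, traces=leads)


def filter_scale(ecg: ECG12, low_pass: float = 150.0, high_pass: float = 0.5,
                 scale: float = 0.2, order: int = 2) -> ECG12:
    """Zero-phase Butterworth band-pass (default 0.5–150 Hz), then scale.

    Matches the production conditioning of simulated P-waves; the
    calibration comparison uses a separate 60 Hz low-pass
    (:func:`lowpass`).
    """
    fs = 1000.0 / ecg.dt  # Hz
    if fs < 2 * low_pass:
        raise ValueError("sampling rate below twice the low-pass corner")
    sos_lp = butter(order, low_pass / (fs / 2), btype="low", output="sos")
    sos_hp = butter(order, high_pass / (fs / 2), btype="high", output="sos")
    n = len(ecg.times)
    padlen = 3 * (2 * order + 1)
    if n <= padlen:
        raise ValueError("trace shorter than the filter warm-up length")
    out = {}
    for k, v in ecg.traces.items():
        y = sosfiltfilt(sos_lp, v, padlen=padlen)
        y = sosfiltfilt(sos_hp, y, padlen=padlen)
        out[k] = scale * y
    return ECG12(times=ecg.times.copy(), traces=out, filtered=True, scale=scale)


def lowpass(ecg: ECG12, corner: float = 60.0, order: int = 2) -> ECG12:
    """Zero-phase low-pass used for calibration comparisons."""
    fs = 1000.0 / ecg.dt
    sos = butter(order, corner / (fs / 2), btype="low", output="sos")
    out = {k: sosfiltfilt(sos, v, padlen=3 * (2 * order + 1)) for k, v in ecg.traces.items()}
    return ECG12(times=ecg.times.copy(), traces=out, filtered=True, scale=ecg.scale)


def simulate_pwave(mesh: LabeledMesh, amap: ActivationMap, leads: LeadFieldSet,
                   ap: APTemplate | None = None, duration: float = 150.0,
                   conditioned: bool = True) -> ECG12:
    """Activation map -> assembled (optionally filtered+scaled) 12-lead P-wave."""
    phi = compute_electrode_potentials(amap, mesh, leads, ap=ap, duration=duration)
    ecg = assemble_12lead(phi)
    return filter_scale(ecg) if conditioned else ecg
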