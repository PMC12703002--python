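"""Quasi-Monte-Carlo calibration of the atrial activation sequence.

The 24-entry parameter vector ω controls the global longitudinal/transverse
velocity ratio, the longitudinal conduction velocity of five regions
(TC, PM, BB, RA, LA), and six activation sites — two sino-atrial exit sites
on the RA, two Bachmann-bundle insertions, the coronary-sinus connection
and one posterior connection on the LA — each parameterized by its UAC
position (α, β) on the epicardium and its onset time t.

ω is sampled with a low-discrepancy Sobol' design (a Saltelli block layout
is available as an option), each sample is run through the eikonal +
lead-field forward model, simulated and reference P-waves are low-pass
filtered at 60 Hz, and the best fit minimizes the lead-averaged ℓ2 misfit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from . import ecg as ecg_mod
from . import metrics as metrics_mod
from .activation import Seed, VelocityModel, build_velocity_tensors, solve_eikonal
from .mesh import LabeledMesh
from .uac import UACFrame, uac_to_node

log = logging.getLogger(__name__)

# Calibration bounds: velocities in m/s, site coordinates in UAC units,
# onset times in ms.
DEFAULT_BOUNDS = {
    "cv_ratio": (1.0, 1.6),
    "cv_tc": (1.0, 2.4),
    "cv_pm": (1.0, 2.4),
    "cv_bb": (1.0, 2.4),
    "cv_ra": (0.8, 1.8),
    "cv_la": (0.8, 1.8),
}
SITE_BOUNDS = {
    "san": {"alpha": (0.20, 0.92), "beta": (0.32, 0.70), "t": (0.0, 50.0)},
    "bb": {"alpha": (0.345, 0.84), "beta": (0.49, 0.97), "t": (30.0, 100.0)},
    "cs": {"alpha": (0.33, 0.82), "beta": (0.70, 0.93), "t": (50.0, 120.0)},
    "pc": {"alpha": (0.58, 0.84), "beta": (0.22, 0.45), "t": (50.0, 100.0)},
}
SITE_ATRIUM = {"san": "RA", "bb": "LA", "cs": "LA", "pc": "LA"}


def parameter_names(n_san: int = 2, n_bb: int = 2, with_pc: bool = True):
    names = list(DEFAULT_BOUNDS)
    for i in range(1, n_san + 1):
        names += [f"san{i}_alpha", f"san{i}_beta", f"san{i}_t"]
    for j in range(1, n_bb + 1):
        names += [f"bb{j}_alpha", f"bb{j}_beta", f"bb{j}_t"]
    names += ["cs_alpha", "cs_beta", "cs_t"]
    if with_pc:
        names += ["pc_alpha", "pc_beta", "pc_t"]
    return names


def parameter_bounds(names=None):
    names = names or parameter_names()
    lo, hi = [], []
    for nm in names:
        if nm in DEFAULT_BOUNDS:
            a, b = DEFAULT_BOUNDS[nm]
        else:
            site, comp = nm.rsplit("_", 1)
            kind = site.rstrip("0123456789")
            a, b = SITE_BOUNDS[kind][comp]
        if a > b:
            raise ValueError(f"lower bound exceeds upper bound for {nm}")
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


@dataclass
class ParamVector:
    """One calibration sample: named values within the bounds."""

    names: list
    values: np.ndarray

    def __getitem__(self, key):
        return float(self.values[self.names.index(key)])

    def as_dict(self):
        return dict(zip(self.names, self.values))

    def sites(self):
        """Site name -> (alpha, beta, t) for every site present in ω."""
        out = {}
        for nm, v in zip(self.names, self.values):
            if "_" in nm and nm.rsplit("_", 1)[1] in ("alpha", "beta", "t"):
                site, comp = nm.rsplit("_", 1)
                out.setdefault(site, {})[comp] = float(v)
        return {k: (d["alpha"], d["beta"], d["t"]) for k, d in out.items()}


def sample_parameters(n: int, seed: int = 0, names=None,
                      scheme: str = "sobol") -> list:
    """Low-discrepancy samples of ω; deterministic and nested in ``n``.

    ``scheme='sobol'`` draws the first n points of a scrambled Sobol'
    sequence (samples for n and 2n share a common prefix).
    ``scheme='saltelli'`` emits the classic A, B and AB_i block design
    built from 2d-dimensional Sobol' points (n must then be the block size;
    the total sample count is n·(d + 2)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = names or parameter_names()
    lo, hi = parameter_bounds(names)
    d = len(names)
    if scheme == "sobol":
        eng = qmc.Sobol(d=d, scramble=True, seed=seed)
        u = eng.random(n)
    elif scheme == "saltelli":
        eng = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
        ab = eng.random(n)
        A, B = ab[:, :d], ab[:, d:]
        blocks = [A, B]
        for i in range(d):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            blocks.append(ABi)
        u = np.vstack(blocks)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    x = lo + u * (hi - lo)
    return [ParamVector(names=names, values=row.copy()) for row in x]


# ---------------------------------------------------------------------------
# Forward model configuration
# ---------------------------------------------------------------------------

@dataclass
class ForwardModel:
    """Everything needed to run one P-wave forward evaluation."""

    mesh: LabeledMesh
    frame: UACFrame
    leads: ecg_mod.LeadFieldSet
    ap: ecg_mod.APTemplate = field(default_factory=ecg_mod.APTemplate)
    duration: float = 150.0
    base_velocities: dict = field(default_factory=dict)


@dataclass
class ConfiguredModel:
    tensors: np.ndarray
    seeds: list
    omega: ParamVector


def apply_params(omega: ParamVector, base: ForwardModel) -> ConfiguredModel:
    """Instantiate velocity tensors and activation seeds from ω.

    The sampled ratio sets v_t = v_l / ratio uniformly in every region;
    sites anchor to the nearest epicardial node (γ = 1) of their atrium.
    """
    ratio = omega["cv_ratio"]
    vl = {
        "TC": omega["cv_tc"], "PM": omega["cv_pm"], "BB": omega["cv_bb"],
        "RA": omega["cv_ra"], "LA": omega["cv_la"],
    }
    vels = {}
    base_v = dict(VelocityModel().velocities)
    base_v.update(base.base_velocities)
    for region, (bvl, _) in base_v.items():
        l = vl.get(region, bvl)
        vels[region] = (l, l / ratio)
    model = VelocityModel(vels)
    tensors = build_velocity_tensors(base.mesh, model)

    seeds = []
    for site, (a, b, t) in omega.sites().items():
        kind = site.rstrip("0123456789")
        atrium = SITE_ATRIUM[kind]
        node = uac_to_node(base.frame, base.mesh, (a, b, 1.0, atrium))
        seeds.append(Seed(node=node, time=t))
    if not seeds:
        raise ValueError("ω contains no activation sites")
    return ConfiguredModel(tensors=tensors, seeds=seeds, omega=omega)


def forward_pwave(model: ConfiguredModel, base: ForwardModel,
                  conditioned: bool = False) -> ecg_mod.ECG12:
    amap = solve_eikonal(base.mesh, model.tensors, model.seeds)
    return ecg_mod.simulate_pwave(base.mesh, amap, base.leads, ap=base.ap,
                                  duration=base.duration, conditioned=conditioned)


# ---------------------------------------------------------------------------
# Site pruning
# ---------------------------------------------------------------------------

def prune_inactive_sites(model: ConfiguredModel, base: ForwardModel,
                         tol: float = 1e-9) -> ConfiguredModel:
    """Drop sites captured by a propagating front before their onset.

    A site whose prescribed onset is not earlier than the wavefront arrival
    at its node (from the remaining sources) never fires; removing it
    leaves the activation map unchanged (asserted by re-simulation).
    """
    amap = solve_eikonal(base.mesh, model.tensors, model.seeds)
    kept = [s for s in model.seeds if not amap.tau[s.node] < s.time - tol]
    if not kept:
        raise ValueError("pruning removed every activation site")
    if len(kept) < len(model.seeds):
        check = solve_eikonal(base.mesh, model.tensors, kept)
        if not np.allclose(check.tau[np.isfinite(amap.tau)],
                           amap.tau[np.isfinite(amap.tau)], atol=1e-2):
            raise RuntimeError("pruning changed the activation map")
    return ConfiguredModel(tensors=model.tensors, seeds=kept, omega=model.omega)


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    samples: list             # ParamVector per sample
    losses: np.ndarray        # mean ℓ2 per sample
    per_lead: list            # dict lead -> ℓ2 per sample
    best_index: int

    @property
    def best(self) -> ParamVector:
        return self.samples[self.best_index]

    @property
    def best_loss(self) -> float:
        return float(self.losses[self.best_index])


def run_sweep(samples: list, base: ForwardModel, ref: ecg_mod.ECG12,
              calibration_lowpass: float = 60.0) -> SweepResult:
    """Evaluate every sample and select the smallest lead-averaged ℓ2.

    Both the reference and each simulated P-wave are low-pass filtered at
    ``calibration_lowpass`` Hz before comparison.  A failed forward run
    scores +inf and the sweep continues.
    """
    ref_f = ecg_mod.lowpass(ref, corner=calibration_lowpass)
    losses = np.full(len(samples), np.inf)
    per_lead = [None] * len(samples)
    for i, omega in enumerate(samples):
        try:
            model = apply_params(omega, base)
            sim = forward_pwave(model, base, conditioned=False)
            sim_f = ecg_mod.lowpass(sim, corner=calibration_lowpass)
            rep = metrics_mod.compute_metrics(sim_f, ref_f)
            losses[i] = rep.l2_mean
            per_lead[i] = {k: v["l2"] for k, v in rep.per_lead.items()}
        except Exception as exc:  # noqa: BLE001 - a sweep must survive bad samples
            log.warning("forward run %d failed: %s", i, exc)
    if not np.isfinite(losses).any():
        raise RuntimeError("every forward run in the sweep failed")
    best = int(np.argmin(losses))
    return SweepResult(samples=samples, losses=losses, per_lead=per_lead,
                       best_index=best)
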