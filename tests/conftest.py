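"""Shared fixtures: a coarse synthetic biatrial model and derived stages.

The coarse configuration (2.4 mm target edge, slightly thickened walls so
the layers stay resolved) keeps the unit-test suite fast; the acceptance
tests rebuild the default 0.9 mm model separately.
"""

import numpy as np
import pytest

from atriatwin import labeling, uac as uac_mod
from atriatwin.synthgeo import GeometryConfig, generate_biatrial


def coarse_config(**kw):
    base = dict(target_edge_length=2.4, la_wall_thickness=2.5, ra_wall_thickness=2.8)
    base.update(kw)
    return GeometryConfig(**base)


@pytest.fixture(scope="session")
def coarse_mesh():
    return generate_biatrial(coarse_config())


@pytest.fixture(scope="session")
def coarse_rings(coarse_mesh):
    return labeling.detect_orifice_rings(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_fields(coarse_mesh, coarse_rings):
    return labeling.solve_labeling_fields(coarse_mesh, coarse_rings)


@pytest.fixture(scope="session")
def marked_mesh(coarse_mesh, coarse_fields):
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = labeling.mark_structures(coarse_mesh, coarse_fields)
    labeling.compute_fibers(m, coarse_fields)
    return m


@pytest.fixture(scope="session")
def coarse_interfaces(coarse_mesh, coarse_rings):
    return uac_mod.build_interfaces(coarse_mesh, coarse_rings)


@pytest.fixture(scope="session")
def coarse_frame(coarse_mesh, coarse_interfaces, coarse_rings):
    return uac_mod.compute_preliminary_uac(coarse_mesh, coarse_interfaces, coarse_rings)


@pytest.fixture(scope="session")
def normalized_frame(coarse_frame, coarse_mesh, coarse_rings):
    return uac_mod.normalize_orifices_elasticity(coarse_frame, coarse_mesh, coarse_rings)


def fit_circle(x, y):
    """Least-squares circle fit; returns (cx, cy, radius)."""
    A = np.stack([x, y, np.ones_like(x)], axis=1)
    b = x ** 2 + y ** 2
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = c[0] / 2, c[1] / 2
    return cx, cy, float(np.sqrt(c[2] + cx ** 2 + cy ** 2))
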