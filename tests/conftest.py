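import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poremri as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: TE grid (ms) and b grid (s/mm^2) of the phantom acquisition blocks.
PHANTOM_TES = np.array([51.0, 75.0, 100.0, 150.0, 200.0, 250.0])
PHANTOM_BS = np.array([5000.0, 6000.0, 7000.0, 8000.0, 10000.0])


@pytest.fixture(scope="session")
def protocol():
    return pm.AcquisitionProtocol(delta=9.0, Delta=35.0)


@pytest.fixture(scope="session")
def diff():
    return pm.DiffusionParams()


@pytest.fixture(scope="session")
def te_grid():
    return PHANTOM_TES.copy()


@pytest.fixture(scope="session")
def b_grid():
    return PHANTOM_BS.copy()


@pytest.fixture(scope="session")
def phantom1_sample():
    """A fixed draw from the phantom1 preset (heavy-tailed, ~1.07 um mean)."""
    return pm.sample_radii(pm.phantom_preset("phantom1"), seed=7)


def spherical_quadrature(n_polar: int = 100, n_azimuth: int = 100):
    """A 10^4-point spherical quadrature rule (directions, weights).

    Gauss-Legendre nodes in the polar cosine crossed with a uniform
    azimuthal grid; integrates smooth functions on the sphere to near
    machine precision.  Used as the independent oracle for powder averages.
    """
    u, w = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * (np.arange(n_azimuth) + 0.5) / n_azimuth
    st = np.sqrt(1.0 - u**2)
    dirs = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.repeat(u, n_azimuth),
        ],
        axis=1,
    )
    weights = np.repeat(w, n_azimuth) / (2.0 * n_azimuth)
    return dirs, weights


def powder_average_oracle(b_s_mm2, D_par, D_perp, dirs, weights, mu=(0.0, 0.0, 1.0)):
    """Quadrature powder average of exp(-b [D_perp + (D_par-D_perp)(g.mu)^2])."""
    b = b_s_mm2 * 1e-3
    u2 = (dirs @ np.asarray(mu)) ** 2
    return float(np.sum(weights * np.exp(-b * (D_perp + (D_par - D_perp) * u2))))
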