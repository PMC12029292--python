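"""Shared fixtures: materials, geometry, and session-scoped Monte Carlo runs.

The heavier simulations (multi-million photon histories) are run once per
session and shared across transport, reduction and acceptance tests.
"""

import numpy as np
import pytest

from phantomwaxs.detector_image import DetectorGeometry
from phantomwaxs.materials import default_adipose
from phantomwaxs.transport import PhantomGeometry, SimulationConfig, run_simulation

THICKNESSES = (2.0, 4.0, 6.0, 8.0, 10.0)


@pytest.fixture(scope="session")
def adipose():
    return default_adipose()


@pytest.fixture(scope="session")
def detector():
    return DetectorGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _run(thickness_cm, n_photons, seed, material=None, **kwargs):
    phantom = PhantomGeometry(thickness_cm=thickness_cm,
                              **({"material": material} if material else {}))
    cfg = SimulationConfig(phantom=phantom, n_photons=n_photons, seed=seed, **kwargs)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def mc_4cm():
    """8×10⁶ photons through the default 4 cm adipose phantom."""
    return _run(4.0, 8_000_000, seed=41)


@pytest.fixture(scope="session")
def mc_10cm():
    """5×10⁷ photons through the default 10 cm adipose phantom.

    The larger run keeps the fat-peak width estimate at 10 cm usable:
    detected-scattered statistics drop steeply with thickness, and the
    width series needs per-point standard errors near 0.015 nm⁻¹.
    """
    return _run(10.0, 50_000_000, seed=101)


@pytest.fixture(scope="session")
def mc_thickness_series(mc_4cm, mc_10cm):
    """One run per thickness in {2,4,6,8,10} cm (full default physics)."""
    runs = {4.0: mc_4cm, 10.0: mc_10cm}
    for t, n in ((2.0, 5_000_000), (6.0, 10_000_000), (8.0, 18_000_000)):
        runs[t] = _run(t, n, seed=int(10 + t))
    return runs


@pytest.fixture(scope="session")
def mc_scatter_off_series():
    """Thickness series with both scatter channels disabled (pure absorption)."""
    mat = default_adipose(mu_rayleigh=0.0, mu_compton=0.0)
    return {t: _run(t, 300_000, seed=int(20 + t), material=mat) for t in THICKNESSES}
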