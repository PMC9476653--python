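import numpy as np
import pytest

from gpwater import electrostatics as es
from gpwater import gpr, md, oracle


@pytest.fixture(scope="session")
def monomer_geoms():
    return oracle.sample_geometries(200, seed=11)


@pytest.fixture(scope="session")
def water_models():
    """Small, well-conditioned model set shared by the MD/dimer tests.

    A tiny noise floor keeps the dual weights moderate so that
    finite-difference force oracles are not drowned in round-off.
    """
    geoms = oracle.sample_geometries(60, seed=4)
    return gpr.WaterModels.train(geoms, gpr.GPConfig(seed=0, noise=1e-8),
                                 n_train=25)


@pytest.fixture(scope="session")
def accurate_energy_models():
    """Energy-only models at full training-set size (for accuracy checks)."""
    geoms = oracle.sample_geometries(120, seed=4)
    return gpr.WaterModels.train(geoms, gpr.GPConfig(seed=0), n_train=100,
                                 with_moments=False)


@pytest.fixture(scope="session")
def small_box(water_models):
    """8 flexible waters in a 9 A periodic box with a 4 A cutoff."""
    def make(seed=1, ensemble="nve", temperature=298.0, dt_fs=1.0,
             precision=1e-6):
        state = md.build_water_box(8, box_length=9.0, temperature=temperature,
                                   seed=seed)
        return md.Simulation(
            state, water_models,
            md.IntegratorConfig(ensemble=ensemble, temperature=temperature,
                                dt_fs=dt_fs),
            es.ElectrostaticsConfig(precision=precision, rcut=4.0))
    return make


def random_multipoles(rng, n, q_scale=0.4, mu_scale=0.2, th_scale=0.1,
                      neutral=True):
    """Random global-frame moments with exact neutrality and tracelessness."""
    q = rng.normal(0, q_scale, n)
    if neutral:
        q -= q.mean()
    mu = rng.normal(0, mu_scale, (n, 3))
    th = rng.normal(0, th_scale, (n, 3, 3))
    th = 0.5 * (th + th.transpose(0, 2, 1))
    th -= np.eye(3)[None] * (np.trace(th, axis1=1, axis2=2) / 3.0)[:, None, None]
    return q, mu, th
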