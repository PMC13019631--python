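import numpy as np
import pytest

from f12quad import fixtures as fixmod
from f12quad.assembly import RunConfig, f12_energy
from f12quad.dense import dense_intermediates
from f12quad.quadrature import build_grid, make_batches
from f12quad.spaces import make_spaces


@pytest.fixture(scope="session")
def he_bundle():
    return fixmod.he()


@pytest.fixture(scope="session")
def h2_bundle():
    return fixmod.h2()


@pytest.fixture(scope="session")
def h2o_bundle():
    return fixmod.h2o()


@pytest.fixture(scope="session")
def he_spaces(he_bundle):
    return make_spaces(he_bundle.molecule, he_bundle.obs, he_bundle.cabs_aux)


@pytest.fixture(scope="session")
def h2_spaces(h2_bundle):
    return make_spaces(h2_bundle.molecule, h2_bundle.obs, h2_bundle.cabs_aux)


@pytest.fixture(scope="session")
def h2o_spaces(h2o_bundle):
    return make_spaces(h2o_bundle.molecule, h2o_bundle.obs,
                       h2o_bundle.cabs_aux)


@pytest.fixture(scope="session")
def he_dense(he_spaces):
    return dense_intermediates(he_spaces)


@pytest.fixture(scope="session")
def h2_dense(h2_spaces):
    return dense_intermediates(h2_spaces)


@pytest.fixture(scope="session")
def he_production_g4(he_bundle, he_spaces):
    grid = build_grid(he_bundle.molecule, "g4", 0.0, he_bundle.obs)
    make_batches(grid, 64)
    from f12quad.intermediates import IntermediateBuilder
    return IntermediateBuilder(he_spaces, grid, he_bundle.df_aux,
                               theta_nq=1e-10).run()


@pytest.fixture(scope="session")
def h2_production_g4(h2_bundle, h2_spaces):
    grid = build_grid(h2_bundle.molecule, "g4", 0.0, h2_bundle.obs)
    make_batches(grid, 64)
    from f12quad.intermediates import IntermediateBuilder
    return IntermediateBuilder(h2_spaces, grid, h2_bundle.df_aux,
                               theta_nq=1e-10).run()


@pytest.fixture(scope="session")
def he_report(he_bundle, he_spaces):
    return f12_energy(he_bundle.molecule, he_bundle.obs, he_bundle.cabs_aux,
                      he_bundle.df_aux, RunConfig(grid_level="g2"),
                      spaces=he_spaces)
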