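import numpy as np
import pytest

from ca1sim.cell import build_cell
from ca1sim.synthetic import generate_ball_and_stick, generate_reduced_ca1


@pytest.fixture(scope="session")
def reduced_morphology():
    return generate_reduced_ca1(seed=1)


@pytest.fixture(scope="session")
def wildtype_cell(reduced_morphology):
    return build_cell(reduced_morphology)


@pytest.fixture(scope="session")
def passive_stick_cell():
    """Ball-and-stick cell with every active mechanism removed."""
    cell = build_cell(generate_ball_and_stick(apical_length=400.0,
                                              apical_diameter=1.0))
    for arr in (cell.gna, cell.gkdr, cell.gka, cell.gcal, cell.gkca,
                cell.ncx_vmax):
        arr[:] = 0.0
    return cell


def make_passive(cell):
    """Zero all active densities on a copy of ``cell``."""
    c = cell.copy()
    for arr in (c.gna, c.gkdr, c.gka, c.gcal, c.gkca, c.ncx_vmax):
        arr[:] = 0.0
    return c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
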