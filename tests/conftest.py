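import numpy as np
import pytest

import ligandcap as lc


@pytest.fixture
def membrane():
    return lc.default_membrane()


@pytest.fixture
def sites():
    return lc.default_sites()


@pytest.fixture
def cocaine():
    return lc.ligand_preset("cocaine")


@pytest.fixture
def ref_outer():
    return lc.solution_preset("reference_outer")


@pytest.fixture
def ref_inner():
    return lc.solution_preset("reference_inner")


@pytest.fixture
def bath():
    return lc.solution_preset("standard_bath")


@pytest.fixture
def pipette():
    return lc.solution_preset("standard_pipette")


def salt_1_1(conc, side="outer"):
    """Symmetric 1:1 electrolyte at ``conc`` mol/m^3."""
    return lc.IonicSolution(
        [lc.IonSpecies("cat", 1, conc), lc.IonSpecies("an", -1, conc)], side=side
    )


@pytest.fixture
def salt150():
    return salt_1_1(150.0)


def conjugate(solution):
    """Flip the valence sign of every ion species."""
    return lc.IonicSolution(
        [lc.IonSpecies(s.name, -s.z, s.c_bulk) for s in solution.species], side=solution.side
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
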