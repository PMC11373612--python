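import numpy as np
import pytest

from ratepaths import ThermoState, TwoStateModel, make_potential

BENCH_KBT = 0.5915  # kcal/mol
BENCH_D = 1.0       # Å²/ps
BENCH_MASS = 20.0   # amu

FAMILIES = ("narrow", "medium", "broad")


@pytest.fixture(scope="session")
def thermo():
    return ThermoState(kBT=BENCH_KBT, D=BENCH_D, mass=BENCH_MASS)


@pytest.fixture(scope="session")
def quad(thermo):
    """Quadrature reference (committor, density, rates) per benchmark family."""
    return {
        fam: TwoStateModel(make_potential(fam), thermo).fit()
        for fam in FAMILIES
    }


@pytest.fixture(scope="session")
def flat_pot():
    return make_potential("flat", domain=(-7.0, 7.0))
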