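import numpy as np
import pytest

from helixfield.dielectric import (ElectrolyteSpec, WaterDielectricParams,
                                   debye_kappa, get_preset)
from helixfield.helix import default_dna_model

# inverse Debye length of 0.154 M 1:1 salt at 300 K with eps=94
KAPPA_PHYS = debye_kappa(ElectrolyteSpec(0.154))


@pytest.fixture(scope="session")
def tip3p() -> WaterDielectricParams:
    return get_preset("tip3p")


@pytest.fixture(scope="session")
def const_eps() -> WaterDielectricParams:
    """A (numerically) k-independent dielectric with ε≈94: classical limit."""
    return WaterDielectricParams(94.0, 94.0 * (1 - 1e-12), 3.67, 1.77,
                                 2 * np.pi / 2.13, 0.05)


@pytest.fixture(scope="session")
def vacuum_eps() -> WaterDielectricParams:
    """ε≈1 everywhere: no medium to polarize."""
    return WaterDielectricParams(1.0 + 2e-12, 1.0 + 1e-12, 3.67, 1.77,
                                 2 * np.pi / 2.13, 0.05)


@pytest.fixture(scope="session")
def kappa_phys() -> float:
    return KAPPA_PHYS


@pytest.fixture(scope="session")
def dna_model():
    return default_dna_model()


@pytest.fixture(scope="session")
def g_dna(dna_model) -> float:
    return dna_model.geometry.g
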