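import numpy as np
import pytest

import repliq as rq
from repliq.alphabet import N_SYMBOLS, WC_INDEX


def _full_table(nn: np.ndarray) -> rq.StackEnergyTable:
    prov = np.full((N_SYMBOLS,) * 4, "measured", dtype=object)
    return rq.StackEnergyTable(nn=nn.astype(float), provenance=prov)


def make_constant_table(c: float) -> rq.StackEnergyTable:
    """All 256 stack energies equal to c kcal/mol (maximum-entropy limit)."""
    return _full_table(np.full((N_SYMBOLS,) * 4, c))


def make_delta_table(wc: float = -50.0, mismatch: float = 50.0) -> rq.StackEnergyTable:
    """Kronecker-delta limit: Watson-Crick current pairs strongly stabilized."""
    nn = np.full((N_SYMBOLS,) * 4, mismatch)
    for cx in range(N_SYMBOLS):
        nn[:, :, cx, WC_INDEX[cx]] = wc
    return _full_table(nn)


def make_random_table(rng: np.random.Generator, scale: float = 2.0) -> rq.StackEnergyTable:
    """Random stack energies ~ N(0, scale), for oracle-equivalence checks."""
    return _full_table(rng.normal(0.0, scale, size=(N_SYMBOLS,) * 4))


@pytest.fixture(scope="session")
def table() -> rq.StackEnergyTable:
    return rq.load_nn_table()


@pytest.fixture(scope="session")
def thermo() -> rq.ThermoConditions:
    return rq.ThermoConditions()


@pytest.fixture(scope="session")
def benchmark_templates() -> list[rq.TemplateSequence]:
    return rq.standard_templates(length=100)
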