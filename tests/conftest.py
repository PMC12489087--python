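import pytest

from vokinetics import (
    PAPER_INITIAL_STATE,
    PAPER_PARAMETERS,
    STANDARD_ORDERS,
    OrderFunction,
    SolverConfig,
    simulate_enzyme,
)


@pytest.fixture(scope="session")
def paper_params():
    return PAPER_PARAMETERS


@pytest.fixture(scope="session")
def paper_y0():
    return PAPER_INITIAL_STATE


@pytest.fixture(scope="session")
def rk4_zero_delay():
    """Classical RK4 reference run, no delays, h=0.01, T=200."""
    cfg = SolverConfig(h=0.01, T=200.0, scheme="classical_rk4_order1")
    return simulate_enzyme(PAPER_PARAMETERS, PAPER_INITIAL_STATE,
                           STANDARD_ORDERS["integer"], config=cfg)


@pytest.fixture(scope="session")
def pece_order1_zero_delay():
    """PECE at constant order 1, no delays, h=0.01, T=200 (the reduction
    cross-check against the classical path)."""
    cfg = SolverConfig(h=0.01, T=200.0, scheme="pece")
    return simulate_enzyme(PAPER_PARAMETERS, PAPER_INITIAL_STATE,
                           OrderFunction("constant", 1.0), config=cfg)


@pytest.fixture(scope="session")
def pece_097_zero_delay():
    """PECE at constant order 0.97, no delays, h=0.05, T=200."""
    cfg = SolverConfig(h=0.05, T=200.0, scheme="pece")
    return simulate_enzyme(PAPER_PARAMETERS, PAPER_INITIAL_STATE,
                           STANDARD_ORDERS["const_0.97"], config=cfg)
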