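import pytest

from edqueue import CostRates, QueueParams, sweep_cost

# Reference staffing table for the worked scenario lam=3.5, mu=1, N=15,
# cost rates (Cq, Cs, CB, CI) = (200, 150, 120, 100): printed (R, cost, AWT)
# rows at 1-dp / 2-dp precision; the R=12 AWT prints as 0 (below 0.01).
TABLE1 = [
    (1, 2990.0, 388.57),
    (2, 2873.9, 333.42),
    (3, 2345.8, 220.77),
    (4, 1530.2, 78.57),
    (5, 1250.7, 22.51),
    (6, 1242.5, 6.84),
    (7, 1309.9, 2.13),
    (8, 1399.5, 0.65),
    (9, 1496.3, 0.19),
    (10, 1595.4, 0.05),
    (11, 1695.1, 0.01),
    (12, 1795.0, 0.0),
]

RATES = CostRates(Cq=200, Cs=150, CB=120, CI=100)


@pytest.fixture(scope="session")
def rates():
    return RATES


@pytest.fixture(scope="session")
def table1_curve():
    """The reference sweep: lam=3.5, mu=1, N=15, R=1..12."""
    return sweep_cost(N=15, lam=3.5, mu=1.0, rates=RATES, R_range=(1, 12))


@pytest.fixture
def ex_small():
    """The small worked example (R, N, lam, mu) = (4, 5, 2, 1)."""
    return QueueParams(R=4, N=5, lam=2.0, mu=1.0)
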