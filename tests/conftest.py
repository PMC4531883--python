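import numpy as np
import pytest

from visioncea import LifeTable, ModelParams, make_gompertz_life_table


@pytest.fixture(scope="session")
def synthetic_lt() -> LifeTable:
    """The packaged synthetic Gompertz-Makeham life table (default constants)."""
    return make_gompertz_life_table()


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    """Deterministic base case: RR 62.5 %, first-year cost 85k, 3 % discounts."""
    return ModelParams()


def constant_q_table(q: float, min_age: int = 50, n_ages: int = 400) -> LifeTable:
    """Life table with constant annual death probability q (terminal qx = 1).

    Long enough that residual survival is far below 1e-9 for q >= 0.05,
    so geometric-series closed forms hold to high accuracy.
    """
    ages = np.arange(min_age, min_age + n_ages)
    qx = np.full(n_ages, q)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


@pytest.fixture
def const_lt():
    return constant_q_table
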