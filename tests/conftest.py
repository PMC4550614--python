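import numpy as np
import pandas as pd
import pytest

from ioimpact.io_core import IOTable
from ioimpact.synthetic_data import ScenarioConfig, build_paper_fixture, generate_scenario


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def toy_scenario():
    """Default 8-sector synthetic scenario (deterministic)."""
    scenario, waves = generate_scenario(ScenarioConfig(seed=11))
    return scenario, waves


@pytest.fixture
def one_sector_table():
    """Hand-balanced single-sector table: Z=2, fd=3, X0=5, VA=3."""
    return IOTable(
        sector_labels=["Only"],
        Z=[[2.0]],
        final_demand=pd.DataFrame({"private_consumption": [3.0]}, index=["Only"]),
        exports=np.array([0.0]),
        imports=np.array([0.0]),
        employee_income=np.array([2.0]),
        other_value_added=np.array([1.0]),
        domestic_production=np.array([5.0]),
    )


def random_viable_system(rng, n=None):
    """A random viable (A, m, Y, E) system with n <= 8 sectors."""
    n = n or int(rng.integers(1, 9))
    A = rng.uniform(0, 1, size=(n, n))
    A = A / A.sum(axis=0, keepdims=True) * rng.uniform(0.2, 0.9, size=n)
    m = rng.uniform(0, 0.5, size=n)
    Y = rng.uniform(0, 100, size=n)
    E = rng.uniform(0, 20, size=n)
    return A, m, Y, E
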