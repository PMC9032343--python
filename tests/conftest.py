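import pandas as pd
import pytest

from fitproxy.pedigree import BreedingTable, CensusSeries, Individual, Pedigree
from fitproxy.simulate import SimConfig, simulate_population


def make_pedigree(rows):
    """rows: (id, sire, dam, sex, birth, death[, origin]) tuples."""
    return Pedigree(Individual(*row) for row in rows)


@pytest.fixture
def trio():
    """Founder pair A x B with one offspring C."""
    return make_pedigree([
        ("A", None, None, "male", 2000, 2003),
        ("B", None, None, "female", 2000, 2003),
        ("C", "A", "B", "male", 2001, 2005),
    ])


@pytest.fixture
def breeding_two_years():
    return BreedingTable(pd.DataFrame({
        "parent_id": ["A", "A"],
        "year": [2001, 2002],
        "eggs": [4, 5],
        "hatchlings": [3, 4],
        "fledglings": [2, 3],
        "recruits": [1, 1],
        "broods": [1, 2],
    }))


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic population, shared across tests."""
    return simulate_population(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A smaller, faster population for gene-drop-heavy tests."""
    cfg = SimConfig(n_founders=40, years=15, carrying_capacity=70,
                    bottleneck=(2007, 0.4), seed=7)
    return simulate_population(cfg)
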