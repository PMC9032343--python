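import numpy as np
import pandas as pd
import pytest

from fitproxy.metrics import (
    annual_delifed_by_age,
    build_transition_matrix,
    delifed_annual,
    delifed_lifetime,
    igr,
    lrs,
)
from fitproxy.pedigree import BreedingTable, CensusSeries

from _oracles import cubic_dominant_root, power_iteration_dominant
from conftest import make_pedigree


class TestLRS:
    def test_sums_stage_over_years(self, breeding_two_years):
        assert lrs(breeding_two_years, "A", "eggs") == 9
        assert lrs(breeding_two_years, "A", "hatchlings") == 7
        assert lrs(breeding_two_years, "A", "broods") == 3

    def test_absent_individual_zero(self, breeding_two_years):
        assert lrs(breeding_two_years, "ZZZ", "recruits") == 0

    def test_unknown_stage_rejected(self, breeding_two_years):
        with pytest.raises(ValueError):
            lrs(breeding_two_years, "A", "juveniles")

    def test_stage_monotonicity_on_synthetic_cohort(self, small_sim):
        bt = small_sim.breeding
        for pid in bt.df["parent_id"].unique()[:50]:
            counts = [lrs(bt, pid, s)
                      for s in ("eggs", "hatchlings", "fledglings", "recruits")]
            assert counts == sorted(counts, reverse=True)


def matrix_for(offspring_by_age, lifespan, stage="recruits"):
    """Build via the library from a minimal pedigree + breeding table."""
    ped = make_pedigree([("A", None, None, "female", 2000, 2000 + lifespan)])
    rows = [{"parent_id": "A", "year": 2000 + age, "eggs": n, "hatchlings": n,
             "fledglings": n, "recruits": n, "broods": 1 if n else 0}
            for age, n in offspring_by_age.items()]
    bt = BreedingTable(pd.DataFrame(rows)) if rows else BreedingTable(
        pd.DataFrame(columns=["parent_id", "year", "eggs", "hatchlings",
                              "fledglings", "recruits", "broods"]))
    return build_transition_matrix(bt, ped, "A", stage)


class TestTransitionMatrix:
    def test_printed_example_1_2_1(self):
        m = matrix_for({1: 1, 2: 2, 3: 1}, lifespan=3)
        expected = np.array([[0.5, 1.0, 0.5], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_allclose(m, expected)

    def test_single_year_single_offspring(self):
        np.testing.assert_allclose(matrix_for({1: 1}, lifespan=1), [[0.5]])

    def test_no_offspring_lifespan_two(self):
        m = matrix_for({}, lifespan=2)
        np.testing.assert_allclose(m, [[0, 0], [1, 0]])

    def test_zero_lifespan_rejected(self):
        with pytest.raises(ValueError, match="lifespan"):
            matrix_for({}, lifespan=0)


class TestIGR:
    def test_printed_matrix_against_characteristic_polynomial(self):
        # det(M - xI) = 0 for the worked 3x3 matrix reduces to
        # x^3 - 0.5 x^2 - x - 0.5 = 0
        m = np.array([[0.5, 1.0, 0.5], [1, 0, 0], [0, 1, 0]])
        root = cubic_dominant_root(-0.5, -1.0, -0.5)
        assert root == pytest.approx(1.4375, abs=1e-3)
        assert igr(m) == pytest.approx(root, abs=1e-9)

    def test_scalar_matrix(self):
        assert igr(np.array([[0.5]])) == pytest.approx(0.5)

    def test_nilpotent_zero(self):
        m = np.zeros((4, 4))
        m[np.arange(1, 4), np.arange(3)] = 1.0
        assert igr(m) == 0.0

    def test_agrees_with_power_iteration_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            dim = rng.integers(1, 9)
            m = np.zeros((dim, dim))
            if dim > 1:
                m[np.arange(1, dim), np.arange(dim - 1)] = 1.0
            m[0] = rng.uniform(0.05, 4.0, size=dim)
            assert igr(m) == pytest.approx(
                power_iteration_dominant(m), abs=1e-9)

    def test_monotone_in_fecundity_row(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            dim = int(rng.integers(1, 7))
            m = np.zeros((dim, dim))
            if dim > 1:
                m[np.arange(1, dim), np.arange(dim - 1)] = 1.0
            m[0] = rng.uniform(0, 3.0, size=dim)
            m2 = m.copy()
            j = int(rng.integers(dim))
            m2[0, j] += rng.uniform(0.1, 2.0)
            assert igr(m2) >= igr(m) - 1e-12

    def test_stage_ordering_eggs_at_least_recruits(self, small_sim):
        ped, bt = small_sim.pedigree, small_sim.breeding
        parents = [p for p in bt.df["parent_id"].unique()[:30]
                   if ped[p].death_year - ped[p].birth_year >= 1]
        for pid in parents:
            m_eggs = build_transition_matrix(bt, ped, pid, "eggs")
            m_rec = build_transition_matrix(bt, ped, pid, "recruits")
            assert igr(m_eggs) >= igr(m_rec) - 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            igr(np.array([[-0.1]]))


def toy_year():
    """Three adults in year 2005, N_t = 3 -> 4 (w_t = 4/3).

    P survives and has 2 surviving offspring, Q survives childless, R dies
    childless.  Hand-computed de-lifed values (weight 1):
      P: (2 + 1 - 4/3)/2 = 5/6,  Q: (1 - 4/3)/2 = -1/6,  R: (0 - 4/3)/2 = -2/3
    """
    ped = make_pedigree([
        ("P", None, None, "female", 2004, 2007),
        ("Q", None, None, "male", 2004, 2007),
        ("R", None, None, "female", 2004, 2005),
        ("c1", None, "P", "male", 2005, 2007),
        ("c2", None, "P", "female", 2005, 2007),
    ])
    bt = BreedingTable(pd.DataFrame({
        "parent_id": ["P"], "year": [2005], "eggs": [2], "hatchlings": [2],
        "fledglings": [2], "recruits": [2], "broods": [1],
    }))
    census = CensusSeries({2005: 3, 2006: 4, 2007: 4})
    return ped, bt, census


class TestDelifing:
    def test_stable_population_survivor_no_offspring_zero(self):
        ped = make_pedigree([
            ("P", None, None, "female", 2004, 2007),
            ("Q", None, None, "male", 2004, 2007),
        ])
        bt = BreedingTable(pd.DataFrame(
            columns=["parent_id", "year", "eggs", "hatchlings", "fledglings",
                     "recruits", "broods"]))
        census = CensusSeries({2005: 2, 2006: 2})
        assert delifed_annual(bt, census, ped, "P", 2005) == pytest.approx(0.0)

    def test_dying_childless_in_stable_population(self):
        # (0 - 1) / (11 - 1) = -0.1
        ped = make_pedigree([("D", None, None, "male", 2004, 2005)])
        bt = BreedingTable(pd.DataFrame(
            columns=["parent_id", "year", "eggs", "hatchlings", "fledglings",
                     "recruits", "broods"]))
        census = CensusSeries({2005: 11, 2006: 11})
        assert delifed_annual(bt, census, ped, "D", 2005) == pytest.approx(-0.1)

    def test_toy_year_hand_values(self):
        ped, bt, census = toy_year()
        assert delifed_annual(bt, census, ped, "P", 2005) == pytest.approx(5 / 6)
        assert delifed_annual(bt, census, ped, "Q", 2005) == pytest.approx(-1 / 6)
        assert delifed_annual(bt, census, ped, "R", 2005) == pytest.approx(-2 / 3)

    def test_toy_year_halved_offspring_weight(self):
        ped, bt, census = toy_year()
        # weight 0.5: P gets (1 + 1 - 4/3)/2 = 1/3
        assert delifed_annual(bt, census, ped, "P", 2005,
                              offspring_weight=0.5) == pytest.approx(1 / 3)

    def test_census_too_small_rejected(self):
        ped = make_pedigree([("P", None, None, "female", 2004, 2007)])
        bt = BreedingTable(pd.DataFrame(
            columns=["parent_id", "year", "eggs", "hatchlings", "fledglings",
                     "recruits", "broods"]))
        census = CensusSeries({2005: 1, 2006: 2})
        with pytest.raises(ValueError, match="N_t"):
            delifed_annual(bt, census, ped, "P", 2005)

    def test_lifetime_is_sum_of_annual(self):
        ped, bt, census = toy_year()
        # P adult in 2005 and 2006 (t+1 = 2007 censused)
        total = delifed_lifetime(bt, census, ped, "P")
        expected = (delifed_annual(bt, census, ped, "P", 2005)
                    + delifed_annual(bt, census, ped, "P", 2006))
        assert total == pytest.approx(expected)

    def test_by_age_keys_cover_adult_ages_only(self):
        ped, bt, census = toy_year()
        by_age = annual_delifed_by_age(bt, census, ped, "P")
        assert set(by_age) == {1, 2}
        by_age_r = annual_delifed_by_age(bt, census, ped, "R")
        assert set(by_age_r) == {1}

    def test_zero_sum_with_halved_offspring_weight(self, small_sim_no_imm):
        ped = small_sim_no_imm.pedigree
        bt = small_sim_no_imm.breeding
        census = small_sim_no_imm.census
        for year in census.years[:-1]:
            total = sum(
                delifed_annual(bt, census, ped, i, year, offspring_weight=0.5)
                for i in ped.adults(year)
            )
            assert abs(total) < 1e-10, year


@pytest.fixture(scope="module")
def small_sim_no_imm():
    from fitproxy.simulate import SimConfig, simulate_population
    cfg = SimConfig(n_founders=30, years=10, carrying_capacity=60,
                    immigration_rate=0.0, bottleneck=None, seed=21)
    return simulate_population(cfg)
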