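"""Cohort construction, Poisson excess-mortality test, and pedigree selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilink.excess import (
    UNASSIGNED,
    assign_cohorts,
    cohort_rates,
    evaluate_pedigrees,
    excess_risk_test,
    expected_ad_deaths,
    observed_ad_deaths,
    poisson_tail,
    select_study_pedigrees,
)
from resilink.pedigree import Individual, Pedigree
from resilink.simulate import PopulationSpec, gen_population


def person(i, year=1900, sex="male", place="in_state", ad=False, **kw):
    return Individual(id=f"i{i}", birth_year=year, sex=sex, birth_place=place,
                      ad_death=ad, **kw)


class TestCohorts:
    def test_block_floor_arithmetic(self):
        labels = assign_cohorts([person(1, 1902)])
        assert labels["i1"] == ((1900, 1904), "male", "in_state")

    def test_block_edges_share_a_cohort(self):
        labels = assign_cohorts([
            person(1, 1900, sex="female", place="out_of_state"),
            person(2, 1904, sex="female", place="out_of_state"),
        ])
        assert labels["i1"] == labels["i2"]

    def test_unknown_birth_year_bucketed(self):
        labels = assign_cohorts([Individual(id="x")])
        assert labels["x"] == UNASSIGNED

    def test_full_grid_stratum_count(self):
        """1850-1959 spans 22 five-year blocks; x2 sexes x2 places = 88 strata."""
        inds = []
        i = 0
        for year in range(1850, 1960):
            for sex in ("male", "female"):
                for place in ("in_state", "out_of_state"):
                    inds.append(person(i, year, sex, place))
                    i += 1
        table = cohort_rates(inds)
        assert len(table.strata) == 22 * 2 * 2


class TestRates:
    def test_rate_is_simple_proportion(self):
        inds = [person(i, ad=(i < 4)) for i in range(200)]
        table = cohort_rates(inds)
        assert table.rate(((1900, 1904), "male", "in_state")) == pytest.approx(0.02)

    def test_no_deaths_gives_zero_rates(self):
        table = cohort_rates([person(i) for i in range(50)])
        assert all(d["rate"] == 0.0 for d in table.strata.values())

    def test_recovers_known_stratum_probabilities(self):
        rng = np.random.default_rng(5)
        truth = {1900: 0.02, 1905: 0.08}
        inds = []
        n = 4000
        for i in range(n):
            year = 1900 if i < n // 2 else 1905
            inds.append(person(i, year, ad=bool(rng.random() < truth[year])))
        table = cohort_rates(inds)
        for year, p in truth.items():
            r = table.rate(((year, year + 4), "male", "in_state"))
            se = np.sqrt(p * (1 - p) / (n // 2))
            assert abs(r - p) < 3 * se

    def test_scale_invariance(self):
        """Doubling members and deaths leaves rates, E and RR unchanged."""
        inds = [person(i, ad=(i < 4)) for i in range(200)]
        doubled = inds + [person(i + 500, ad=(i < 4)) for i in range(200)]
        t1, t2 = cohort_rates(inds), cohort_rates(doubled)
        lab = ((1900, 1904), "male", "in_state")
        assert t1.rate(lab) == t2.rate(lab)


class TestExpected:
    def make_rates(self):
        inds = [person(i, 1900, ad=(i < 4)) for i in range(200)]  # rate 0.02
        inds += [person(i + 300, 1910, ad=(i < 2)) for i in range(200)]  # rate 0.01
        return cohort_rates(inds)

    def test_hand_summed_expectation(self):
        rates = self.make_rates()
        mem = [person(i + 1000, 1900) for i in range(50)]
        mem += [person(i + 2000, 1910) for i in range(100)]
        ped = Pedigree("E", mem)
        assert expected_ad_deaths(ped, rates) == pytest.approx(
            50 * 0.02 + 100 * 0.01
        )

    def test_empty_pedigree_expectation_is_zero(self):
        assert expected_ad_deaths(Pedigree("E0", []), self.make_rates()) == 0.0

    def test_unknown_stratum_raises(self):
        rates = self.make_rates()
        ped = Pedigree("E", [person(1, 1990)])
        with pytest.raises(KeyError):
            expected_ad_deaths(ped, rates)

    def test_marry_ins_excluded_from_counts(self):
        rates = self.make_rates()
        mem = [person(1, 1900), person(2, 1900, ad=True)]
        mem.append(Individual(id="sp", birth_year=1900, sex="female",
                              birth_place="in_state", ad_death=True, is_marry_in=True))
        ped = Pedigree("E", mem)
        assert observed_ad_deaths(ped) == 1
        assert expected_ad_deaths(ped, rates) == pytest.approx(2 * 0.02)


class TestPoissonTest:
    def test_zero_observed_is_certain(self):
        for e in (0.0, 0.5, 7.3):
            assert excess_risk_test(0, e).p_one_sided == 1.0

    def test_rr_is_observed_over_expected(self):
        assert excess_risk_test(3, 3.0).rr == pytest.approx(1.0)

    def test_partial_pmf_sum_example(self):
        # 1 - e^{-1} (1 + 1 + 1/2 + 1/6 + 1/24)
        import math

        expected = 1 - np.exp(-1) * sum(1 / math.factorial(k) for k in range(5))
        assert poisson_tail(5, 1.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.00366, abs=5e-6)

    def test_tail_matches_cumulative_sum_oracle(self):
        """P(X >= O) vs an independent term-by-term pmf accumulation, 1e-12."""
        for e in (0.5, 1.0, 5.0, 20.0, 50.0):
            # high-precision oracle: accumulate pmf terms iteratively
            term = np.exp(-e)
            cum = term
            for o in range(1, 101):
                assert poisson_tail(o, e) == pytest.approx(1 - cum, abs=1e-12)
                term *= e / o
                cum += term

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            excess_risk_test(-1, 1.0)
        with pytest.raises(ValueError):
            excess_risk_test(1, -0.1)

    def test_degenerate_zero_expectation(self):
        res = excess_risk_test(3, 0.0)
        assert res.degenerate and res.p_one_sided == 0.0 and np.isnan(res.rr)

    @given(o=st.integers(0, 60), e=st.floats(0.1, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_monotonicity(self, o, e):
        p = poisson_tail(o, e)
        assert 0.0 < p <= 1.0
        assert poisson_tail(o + 1, e) <= p            # non-increasing in O
        assert poisson_tail(o, e + 0.5) >= p - 1e-15  # non-decreasing in E


class TestSelection:
    def make_ped(self, pid, n_res, n_case):
        mem = [person(i, 1900) for i in range(10)]
        for j in range(n_res):
            mem[j].phenotype = "resilient"
        for j in range(n_res, n_res + n_case):
            mem[j].phenotype = "case"
        for m in mem:
            m.id = f"{pid}_{m.id}"
        return Pedigree(pid, mem)

    def test_threshold_counts(self):
        ok = self.make_ped("OK", 4, 4)
        short = self.make_ped("NO", 3, 7)
        results = [
            excess_risk_test(10, 2.0, pedigree_id="OK"),
            excess_risk_test(12, 2.0, pedigree_id="NO"),
        ]
        chosen = select_study_pedigrees(results, [ok, short])
        assert chosen == ["OK"]

    def test_non_high_risk_excluded(self):
        ped = self.make_ped("P", 5, 5)
        res = excess_risk_test(1, 2.0, pedigree_id="P")  # RR < 1
        assert select_study_pedigrees([res], [ped]) == []

    def test_spiked_pedigree_recovery(self):
        """Spiked high-risk pedigrees are exactly the ones selected."""
        spec = PopulationSpec(
            n_pedigrees=100, generations=6, mean_offspring=2.7,
            base_ad_rate_by_cohort=0.05, spiked_pedigree_rr=5.0, n_spiked=5,
            resilient_rate=0.12, seed=20,
        )
        peds, truth = gen_population(spec)
        pool = [ind for p in peds for ind in p.members.values()]
        rates = cohort_rates(pool)
        results = evaluate_pedigrees(peds, rates, alpha=0.05, bonferroni=True)
        chosen = set(select_study_pedigrees(results, peds, 4, 4))

        def meets_counts(ped):
            n_res = sum(1 for i in ped.members.values() if i.phenotype == "resilient")
            n_case = sum(1 for i in ped.members.values() if i.phenotype == "case")
            return n_res >= 4 and n_case >= 4

        spiked_eligible = {
            p.pedigree_id
            for p in peds
            if p.pedigree_id in set(truth[truth["spiked"]]["pedigree_id"])
            and meets_counts(p)
        }
        assert len(spiked_eligible) >= 4  # truth set must have teeth
        assert chosen == spiked_eligible
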