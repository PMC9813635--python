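"""Event bookkeeping: prevented events, deaths, premature deaths."""

import numpy as np
import pandas as pd
import pytest

from saltimpact import (
    DomainError,
    PopulationTable,
    Scenario,
    cumulate,
    premature_split,
    run_scenario,
    yearly_events,
)


def _single_stratum_pop(population=100_000, incidence=0.002, fatal=0.5):
    frame = pd.DataFrame(
        [
            dict(
                region="north", sex="male", age_band="55-64",
                population=population, salt_mean=11.0, salt_sd=1.6,
                sbp_mean=130.0, sbp_sd=13.0, htn_prev=0.4,
                ihd_incidence=incidence, stroke_incidence=incidence,
                ihd_fatal_frac=fatal, stroke_fatal_frac=fatal,
            )
        ]
    )
    return PopulationTable(frame, baseline_year=2020)


def _rr_table(pop, rr_by_year, diseases=("ihd", "stroke")):
    rows = []
    for key in pop.keys():
        for year, rr in rr_by_year.items():
            for disease in diseases:
                rows.append(
                    dict(
                        region=key[0], sex=key[1], age_band=key[2],
                        year=year, disease=disease, rr=rr,
                    )
                )
    return pd.DataFrame(rows)


class TestYearlyEvents:
    def test_prevented_equals_population_incidence_one_minus_rr(self):
        pop = _single_stratum_pop(population=100_000, incidence=0.002)
        result = yearly_events(pop, _rr_table(pop, {2021: 0.96}))
        per = result.frame[result.frame["disease"] == "ihd"]
        assert per["events_prevented"].iloc[0] == pytest.approx(
            100_000 * 0.002 * 0.04
        )  # 8 events

    def test_rr_one_prevents_nothing(self):
        pop = _single_stratum_pop()
        result = yearly_events(pop, _rr_table(pop, {2021: 1.0}))
        assert (result.frame["events_prevented"] == 0).all()

    def test_half_risk_arithmetic(self):
        pop = _single_stratum_pop(population=10_000, incidence=0.01)
        result = yearly_events(pop, _rr_table(pop, {2021: 0.5}))
        ihd = result.frame[result.frame["disease"] == "ihd"]
        assert ihd["events_prevented"].iloc[0] == pytest.approx(50.0)

    def test_deaths_apply_fatal_fraction(self):
        pop = _single_stratum_pop(fatal=0.25)
        result = yearly_events(pop, _rr_table(pop, {2021: 0.9}))
        frame = result.frame
        np.testing.assert_allclose(
            frame["deaths_prevented"], 0.25 * frame["events_prevented"]
        )

    def test_result_inequalities(self, default_pop):
        run = run_scenario(default_pop, Scenario("fixed_gram", 1.0, 2021, 2030),
                           "population_based")
        frame = run.result.frame
        assert (frame["events_prevented"] >= -1e-12).all()
        assert (
            frame["events_prevented"] <= frame["events_counterfactual"] + 1e-9
        ).all()
        assert (frame["deaths_prevented"] <= frame["events_prevented"] + 1e-9).all()
        assert (
            frame["premature_prevented"] <= frame["deaths_prevented"] + 1e-9
        ).all()


class TestPrematureSplit:
    def test_bands_below_65_count_fully(self):
        assert premature_split({"55-64": 100.0}) == 100.0
        assert premature_split({"35-44": 10.0, "45-54": 20.0}) == 30.0

    def test_oldest_band_excluded(self):
        assert premature_split({"75-84": 100.0}) == 0.0

    def test_straddling_band_default_half(self):
        assert premature_split({"65-74": 100.0}) == 50.0
        assert premature_split({"65-74": 100.0}, frac_65_74=0.3) == 30.0

    def test_unknown_band_rejected(self):
        with pytest.raises(DomainError, match="85-94"):
            premature_split({"85-94": 1.0})


class TestCumulate:
    def test_constant_rate_accumulates_linearly(self):
        pop = _single_stratum_pop(population=100_000, incidence=0.002)
        years = {year: 0.96 for year in range(2021, 2031)}
        years[2020] = 1.0
        result = yearly_events(pop, _rr_table(pop, years, diseases=("ihd",)))
        cum = cumulate(result, 2030)
        assert cum.loc["ihd", "events_prevented"] == pytest.approx(80.0)

    def test_horizon_at_baseline_is_zero(self, default_pop):
        run = run_scenario(default_pop, Scenario("fixed_gram", 1.0, 2021, 2030),
                           "population_based")
        cum = run.result.cumulate(2020)
        assert (cum == 0).all().all()

    def test_later_horizon_dominates(self, default_pop):
        run = run_scenario(default_pop, Scenario("percent_total", 0.3, 2025, 2040),
                           "population_based")
        c30 = run.result.cumulate(2030)
        c40 = run.result.cumulate(2040)
        assert (c40 >= c30 - 1e-9).all().all()

    def test_horizon_beyond_end_rejected(self, default_pop):
        run = run_scenario(default_pop, Scenario("fixed_gram", 1.0, 2021, 2030),
                           "population_based")
        with pytest.raises(DomainError, match="2050"):
            run.result.cumulate(2050)

    def test_combined_cvd_is_sum_of_diseases(self, default_pop):
        run = run_scenario(default_pop, Scenario("fixed_gram", 1.0, 2021, 2030),
                           "population_based")
        cum = run.result.cumulate(2030)
        for col in cum.columns:
            assert cum.loc["cvd", col] == pytest.approx(
                cum.loc["ihd", col] + cum.loc["stroke", col], rel=1e-12
            )


class TestMonotonicity:
    def test_lower_rr_gives_more_prevented(self):
        pop = _single_stratum_pop()
        mild = yearly_events(pop, _rr_table(pop, {2021: 0.95}))
        strong = yearly_events(pop, _rr_table(pop, {2021: 0.90}))
        assert (
            strong.frame["events_prevented"].to_numpy()
            >= mild.frame["events_prevented"].to_numpy()
        ).all()


class TestMicrosimulationOracle:
    def test_expected_prevented_matches_bernoulli_microsimulation(self):
        """Expectation bookkeeping agrees with a per-person Bernoulli
        simulation within 3 binomial standard errors."""
        n, incidence, rr = 50_000, 0.01, 0.9
        pop = _single_stratum_pop(population=n, incidence=incidence)
        result = yearly_events(
            pop, _rr_table(pop, {2021: rr}, diseases=("ihd",))
        )
        expected = result.frame["events_prevented"].sum()

        rng = np.random.default_rng(42)
        cf = rng.binomial(1, incidence, size=n).sum()
        iv = rng.binomial(1, incidence * rr, size=n).sum()
        observed = cf - iv
        se = np.sqrt(
            n * incidence * (1 - incidence)
            + n * incidence * rr * (1 - incidence * rr)
        )
        assert abs(observed - expected) <= 3 * se
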