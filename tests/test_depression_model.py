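"""Annual risk equation and event simulation."""

import numpy as np
import pytest

from depsim.engine import build_panel, prevalence_function, simulate
from depsim.population import generate_cohort
from depsim.risk import (
    annual_prevalence,
    exposure_band_specs,
    linear_predictor,
    onset_probability,
    simulate_individual_year,
)
from depsim.scenarios import SCENARIOS


def _blank_person(cfg, rng, sex="female"):
    quiet = cfg.with_overrides(
        {
            **{f"risk.prev.{f}.{s}": 0.0
               for f in ("parental_psychiatric_history", "physical_abuse",
                          "emotional_abuse", "sexual_abuse", "neglect", "bullying")
               for s in ("female", "male")},
            "risk.baseline.sigma": 0.0,
        }
    )
    people = generate_cohort(2000, 50, quiet, rng)
    return quiet, next(p for p in people if p.sex == sex)


class TestLinearPredictor:
    def test_all_zero_indicators_reduce_to_intercept(self, cfg, rng):
        quiet, person = _blank_person(cfg, rng)
        ref_band = exposure_band_specs(quiet)[0]
        indicators = {f: False for f in
                      ("physical_inactivity", "obesity_overweight",
                       "chronic_condition", "substance_use", "covid_confinement")}
        assert linear_predictor(person, indicators, ref_band, quiet) == pytest.approx(
            -1.80
        )

    def test_single_factor_adds_its_coefficient(self, cfg, rng):
        quiet, person = _blank_person(cfg, rng)
        ref_band = exposure_band_specs(quiet)[0]
        indicators = {"physical_inactivity": True}
        # -1.80 + 0.4780 = -1.3220
        assert linear_predictor(person, indicators, ref_band, quiet) == pytest.approx(
            -1.3220
        )

    def test_linearity_in_coefficients(self, cfg, rng):
        quiet, person = _blank_person(cfg, rng)
        doubled = quiet.with_overrides(
            {"risk.ln_or.physical_inactivity": 2 * quiet.ln_or("physical_inactivity")}
        )
        band = exposure_band_specs(quiet)[0]
        ind = {"physical_inactivity": True}
        base = linear_predictor(person, ind, band, quiet)
        two = linear_predictor(person, ind, band, doubled)
        intercept = person.baseline_risk
        assert (two - intercept) == pytest.approx(2 * (base - intercept))

    def test_unknown_indicator_raises(self, cfg, rng):
        quiet, person = _blank_person(cfg, rng)
        band = exposure_band_specs(quiet)[0]
        with pytest.raises(KeyError, match="mystery"):
            linear_predictor(person, {"mystery": True}, band, quiet)


class TestOnsetProbability:
    def test_logistic_symmetry_and_known_value(self):
        assert onset_probability(0.0) == 0.5
        # 1 / (1 + e^{1.8}) = 0.14185
        assert onset_probability(-1.80) == pytest.approx(0.14185, abs=1e-5)

    def test_limits(self):
        assert onset_probability(-800.0) == pytest.approx(0.0)
        assert onset_probability(800.0) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        etas = np.linspace(-6, 6, 101)
        p = onset_probability(etas)
        assert np.all(np.diff(p) > 0)

    def test_exponential_mode_caps_at_one(self):
        assert onset_probability(2.0, mode="exp") == 1.0
        assert onset_probability(-1.0, mode="exp") == pytest.approx(np.exp(-1))


class TestEventSimulation:
    def test_degenerate_probabilities(self, cfg, rng):
        quiet, person = _blank_person(cfg, rng)
        never = quiet.with_overrides({"risk.baseline.mu": -700.0})
        always = quiet.with_overrides({"risk.baseline.mu": +700.0})
        person_never = generate_cohort(2000, 1, never, rng)[0]
        person_always = generate_cohort(2000, 1, always, rng)[0]
        for age in range(10, 18):
            assert not simulate_individual_year(
                person_never, age, 2000 + age, 0.0, {}, never, rng
            )
            simulate_individual_year(
                person_always, age, 2000 + age, 0.0, {}, always, rng
            )
        assert person_never.onset_year is None
        assert person_always.onset_year == 2010  # first event at age 10

    def test_cumulative_onset_complement_rule(self):
        # constant p=0.05 over 8 ages: P(any) = 1 - 0.95^8 = 0.3366
        rng = np.random.default_rng(17)
        n = 100_000
        events = rng.random((n, 8)) < 0.05
        frac = events.any(axis=1).mean()
        expected = 1 - 0.95**8
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sd

    def test_closed_form_prevalence_with_factors_off(self, cfg):
        """With all indicators off and sigma=0, prevalence -> logistic(mu)."""
        from depsim.config import STATIC_FACTORS, TIME_VARYING_FACTORS

        overrides = {"risk.baseline.sigma": 0.0,
                     "risk.covid_activity_reduction": 0.0}
        for f in STATIC_FACTORS:
            for s in ("female", "male"):
                overrides[f"risk.prev.{f}.{s}"] = 0.0
        for f in TIME_VARYING_FACTORS:
            for s in ("female", "male"):
                for g in ("10_14", "15_17"):
                    overrides[f"risk.prev.{f}.{s}.{g}"] = 0.0
            overrides[f"risk.trend.{f}"] = 0.0
        overrides["risk.ln_or.male"] = 0.0
        overrides["risk.ln_or.covid_confinement"] = 0.0
        for p in ("facebook", "twitter", "whatsapp", "instagram", "snapchat",
                  "tiktok"):
            overrides[f"sm.{p}.sat_female"] = 0.0
            overrides[f"sm.{p}.sat_male"] = 0.0
        from depsim.config import default_config

        quiet = default_config(n_per_cohort=500).with_overrides(overrides)
        res = simulate(build_panel(quiet, 21), quiet)
        expected = 1 / (1 + np.exp(1.80))  # 0.1419
        pooled = np.nanmean(res.prevalence)
        n_total = res.n_at_risk.sum()
        sd = np.sqrt(expected * (1 - expected) / n_total)
        assert pooled == pytest.approx(expected, abs=3 * sd)

    def test_monotone_in_coefficients_under_crn(self, small_truth_cfg, small_panel):
        """Raising a ln(OR) never lowers cumulative onset with shared draws."""
        base = simulate(small_panel, small_truth_cfg)
        raised = small_truth_cfg.with_overrides(
            {"risk.ln_or.physical_inactivity": 1.2}
        )
        more = simulate(small_panel, raised)
        assert more.onset_total >= base.onset_total

    def test_no_sm_scenario_equals_reference_band_forcing(
        self, small_truth_cfg, small_panel
    ):
        """Removing SM is bit-identical to zeroing every band coefficient."""
        no_sm = simulate(small_panel, small_truth_cfg, scenario=SCENARIOS["no_sm"])
        zeroed = small_truth_cfg.with_overrides(
            {f"risk.ln_or.{b}": 0.0
             for b in ("sm_30_60", "sm_60_120", "sm_120_360", "sm_360_plus")}
        )
        forced = simulate(small_panel, zeroed)
        np.testing.assert_array_equal(no_sm.prevalence, forced.prevalence)
        assert no_sm.onset_total == forced.onset_total


class TestAnnualPrevalence:
    def test_counts_and_errors(self, cfg, rng):
        people = generate_cohort(2000, 960, cfg, rng)
        for p in people[:48]:
            p.depression_years.add(2012)
        assert annual_prevalence(people, 2012) == pytest.approx(0.05)
        assert annual_prevalence(people, 2013) == 0.0
        with pytest.raises(ValueError):
            annual_prevalence(people, 1995)  # nobody aged 10-17

    def test_sex_stratification(self, cfg, rng):
        people = generate_cohort(2000, 500, cfg, rng)
        for p in people:
            if p.sex == "female":
                p.depression_years.add(2012)
        assert annual_prevalence(people, 2012, sex="female") == 1.0
        assert annual_prevalence(people, 2012, sex="male") == 0.0
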