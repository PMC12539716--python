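"""Cohort synthesis, risk-factor assignment and survival."""

import numpy as np
import pytest

from depsim.population import (
    LifeTable,
    PrevalenceTable,
    generate_cohort,
    latent_activity_minutes,
    survive_year,
    time_varying_factors,
)
from depsim.config import STATIC_FACTORS


class TestGenerateCohort:
    def test_cohort_size_and_sex_ratio(self, cfg):
        counts = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            people = generate_cohort(2000, 100, cfg, rng)
            assert len(people) == 100
            counts.append(sum(p.sex == "male" for p in people))
        # male share ~ Binomial(100, 0.512) per seed; mean over 100 seeds
        assert np.mean(counts) == pytest.approx(51.2, abs=1.5)

    def test_degenerate_sigma_gives_constant_baseline(self, cfg, rng):
        zero_sd = cfg.with_overrides({"risk.baseline.sigma": 0.0})
        people = generate_cohort(2000, 50, zero_sd, rng)
        assert all(p.baseline_risk == pytest.approx(-1.80) for p in people)

    def test_certain_static_factor(self, cfg, rng):
        certain = cfg.with_overrides(
            {"risk.prev.bullying.female": 1.0, "risk.prev.bullying.male": 1.0}
        )
        people = generate_cohort(2000, 200, certain, rng)
        assert all(p.static_factors["bullying"] for p in people)

    def test_invalid_cohort_arguments(self, cfg, rng):
        with pytest.raises(ValueError):
            generate_cohort(2000, 0, cfg, rng)
        with pytest.raises(ValueError):
            generate_cohort(1888, 10, cfg, rng)

    def test_static_prevalence_recovered(self, cfg):
        rng = np.random.default_rng(0)
        people = generate_cohort(2000, 10_000, cfg, rng)
        for f in STATIC_FACTORS:
            for sex in ("female", "male"):
                p = cfg.static_prevalence(f, sex)
                sub = [x for x in people if x.sex == sex]
                freq = np.mean([x.static_factors[f] for x in sub])
                sd = np.sqrt(p * (1 - p) / len(sub))
                assert abs(freq - p) < 3 * sd + 1e-9

    def test_deterministic_given_seed(self, cfg):
        a = generate_cohort(2000, 50, cfg, np.random.default_rng(5))
        b = generate_cohort(2000, 50, cfg, np.random.default_rng(5))
        assert [(p.sex, p.baseline_risk, p.static_factors) for p in a] == [
            (p.sex, p.baseline_risk, p.static_factors) for p in b
        ]


class TestTimeVaryingFactors:
    def test_covid_indicator_only_in_2020(self, cfg, rng):
        tables = PrevalenceTable.from_config(cfg)
        person = generate_cohort(2008, 1, cfg, rng)[0]
        on = time_varying_factors(person, 12, 2020, tables, rng, cfg)
        off = time_varying_factors(person, 11, 2019, tables, rng, cfg)
        assert on["covid_confinement"] and not off["covid_confinement"]

    def test_zero_prevalence_never_fires(self, cfg, rng):
        zero = cfg.with_overrides(
            {
                f"risk.prev.substance_use.{s}.{g}": 0.0
                for s in ("female", "male")
                for g in ("10_14", "15_17")
            }
        )
        tables = PrevalenceTable.from_config(zero)
        person = generate_cohort(2000, 1, zero, rng)[0]
        assert not any(
            time_varying_factors(person, a, 2012, tables, rng, zero)["substance_use"]
            for a in range(10, 18)
        )

    def test_age_bounds_enforced(self, cfg, rng):
        tables = PrevalenceTable.from_config(cfg)
        person = generate_cohort(2000, 1, cfg, rng)[0]
        with pytest.raises(ValueError):
            time_varying_factors(person, 9, 2009, tables, rng, cfg)

    def test_pandemic_activity_reduction_flips_borderline_to_inactive(self):
        # 70 min/day of activity becomes 70 * (1 - 0.42) = 40.6 < 60
        assert 70 * (1 - 0.42) == pytest.approx(40.6)
        minutes = latent_activity_minutes(0.5, 0.0, active_max=80.0)
        # u=0.5, p_inactive=0 -> active band midpoint of [60, 80) = 70
        assert minutes == pytest.approx(70.0)
        assert minutes * (1 - 0.42) < 60

    def test_latent_minutes_consistent_with_prevalence(self):
        u = np.linspace(0, 0.999, 5000)
        m = latent_activity_minutes(u, 0.3)
        assert np.mean(m < 60) == pytest.approx(0.3, abs=0.01)
        assert m.min() >= 0 and m.max() < 180


class TestPrevalenceTable:
    def test_year_carry_forward_and_backward(self, cfg):
        tables = PrevalenceTable.from_config(cfg)
        early = tables.prob("physical_inactivity", "female", 12, 1900)
        first = tables.prob("physical_inactivity", "female", 12, cfg.first_year)
        late = tables.prob("physical_inactivity", "female", 12, 2100)
        last = tables.prob("physical_inactivity", "female", 12, cfg.last_year)
        assert early == first and late == last

    def test_round_trip_through_frame(self, cfg):
        tables = PrevalenceTable.from_config(cfg)
        again = PrevalenceTable.from_frame(tables.to_frame())
        assert again.prob("bullying", "male", 11, 2010) == tables.prob(
            "bullying", "male", 11, 2010
        )

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            PrevalenceTable({("f", "female", "10_14"): {2010: 1.5}})


class TestSurvival:
    def test_certain_survival_and_death(self, cfg, rng):
        person = generate_cohort(2000, 1, cfg, rng)[0]
        assert survive_year(person, 12, LifeTable({("female", 12): 0.0,
                                                   ("male", 12): 0.0}), rng)
        person.alive = True
        assert not survive_year(person, 12, LifeTable({("female", 12): 1.0,
                                                       ("male", 12): 1.0}), rng)

    def test_dead_individuals_cannot_be_simulated(self, cfg, rng):
        person = generate_cohort(2000, 1, cfg, rng)[0]
        person.alive = False
        with pytest.raises(ValueError):
            survive_year(person, 12, LifeTable({}), rng)

    def test_death_count_matches_binomial_expectation(self, cfg):
        rng = np.random.default_rng(3)
        q = 0.001
        table = LifeTable({(s, 12): q for s in ("female", "male")})
        people = generate_cohort(2000, 10_000, cfg, rng)
        deaths = 0
        for _ in range(10):
            for p in people:
                p.alive = True
                deaths += not survive_year(p, 12, table, rng)
        # 1e5 person-years at q=0.001 -> ~100 deaths, +-3 sd
        assert abs(deaths - 100) <= 3 * np.sqrt(100)
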