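"""Bass adoption, correlated platform use and usage-minute distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from depsim.population import generate_cohort
from depsim.social_media import (
    PlatformSpec,
    bass_fraction,
    draw_daily_minutes,
    exposure_band,
    band_index,
    platform_use,
    propensity_quantile,
)


def _platform(p=0.03, q=0.38, launch=2004):
    return PlatformSpec("test", launch, p, q)


class TestBassFraction:
    def test_zero_at_launch_and_before(self):
        pf = _platform()
        assert bass_fraction(pf, 2004) == 0.0
        assert bass_fraction(pf, 1999) == 0.0

    def test_asymptote_is_one(self):
        assert bass_fraction(_platform(), 2204) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_at_t5(self):
        # F(5) = (1 - e^-2.05) / (1 + (0.38/0.03) e^-2.05) = 0.33120
        assert bass_fraction(_platform(), 2009) == pytest.approx(0.33120, abs=1e-4)
        assert bass_fraction(_platform(), 2009) == pytest.approx(
            (1 - np.exp(-2.05)) / (1 + (0.38 / 0.03) * np.exp(-2.05)), abs=1e-9
        )

    def test_invalid_innovation_coefficient(self):
        with pytest.raises(ValueError):
            bass_fraction(_platform(p=0.0), 2010)

    @given(
        st.floats(min_value=1e-3, max_value=0.5),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adoption_monotone_in_year(self, p, q):
        pf = _platform(p=p, q=q)
        years = np.arange(2000, 2040)
        f = bass_fraction(pf, years)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((0 <= f) & (f <= 1))


class TestPlatformUse:
    def test_never_used_before_launch(self, cfg, rng):
        person = generate_cohort(2000, 1, cfg, rng)[0]
        pf = PlatformSpec.from_config(cfg, "facebook")
        assert not platform_use(person, pf, 2003, cfg)

    def test_full_adoption_means_everyone_uses(self, cfg, rng):
        full = cfg.with_overrides(
            {"sm.facebook.sat_female": 1.0, "sm.facebook.sat_male": 1.0,
             "sm.facebook.bass_p": 5.0}
        )
        from dataclasses import replace

        full = replace(full, sat_age_mult_10_14=1.0)
        pf = PlatformSpec.from_config(full, "facebook")
        people = generate_cohort(2000, 200, full, rng)
        assert all(platform_use(p, pf, 2015, full) for p in people)

    def test_no_churn_under_nondecreasing_adoption(self, cfg, rng):
        pf = PlatformSpec.from_config(cfg, "instagram")
        people = generate_cohort(2004, 500, cfg, rng)
        for year in range(2015, 2021):
            for p in people:
                if platform_use(p, pf, year, cfg):
                    assert platform_use(p, pf, year + 1, cfg)

    def test_cross_platform_latent_correlation(self):
        # one-factor copula at rho=0.10: latent z-scores correlate at ~0.10
        rng = np.random.default_rng(11)
        n = 100_000
        latent = rng.standard_normal(n)
        z1, z2 = rng.standard_normal((2, n))
        rho = 0.10
        q1 = propensity_quantile(latent, z1, rho)
        q2 = propensity_quantile(latent, z2, rho)
        r = np.corrcoef(special.ndtri(q1), special.ndtri(q2))[0, 1]
        assert r == pytest.approx(0.10, abs=0.03)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            propensity_quantile(0.0, 0.0, 1.0)


class TestDailyMinutes:
    def test_no_platforms_no_minutes(self, cfg, rng):
        person = generate_cohort(2000, 1, cfg, rng)[0]
        assert draw_daily_minutes(person, 2015, frozenset(), cfg, rng) == 0.0

    def test_gamma_mean_and_sd_at_cv20(self, cfg):
        # single platform, mean 90 -> gamma(k=25, scale=3.6): sd = 18
        rng = np.random.default_rng(2)
        one = cfg.with_overrides({"sm.facebook.mean_minutes_2022": 90.0})
        from dataclasses import replace

        one = replace(
            one,
            minutes_sex_mult={"female": 1.0, "male": 1.0},
            minutes_age_mult={"10_14": 1.0, "15_17": 1.0},
        )
        person = generate_cohort(2008, 1, one, rng)[0]
        draws = np.array(
            [
                draw_daily_minutes(person, 2022, frozenset({"facebook"}), one, rng)
                for _ in range(100_000)
            ]
        )
        assert draws.mean() == pytest.approx(90.0, abs=0.2)
        assert draws.std() == pytest.approx(18.0, abs=0.3)

    def test_alternative_cv_recovered_empirically(self, cfg):
        rng = np.random.default_rng(3)
        alt = cfg.with_overrides(
            {"sm.usage_cv": 0.30, "sm.facebook.mean_minutes_2022": 60.0}
        )
        person = generate_cohort(2008, 1, alt, rng)[0]
        draws = np.array(
            [
                draw_daily_minutes(person, 2022, frozenset({"facebook"}), alt, rng)
                for _ in range(100_000)
            ]
        )
        assert draws.std() / draws.mean() == pytest.approx(0.30, abs=0.01)


class TestExposureBands:
    @pytest.mark.parametrize(
        "minutes,label",
        [(45, "30-60"), (60, "60-120"), (0, "0-30"), (29.9, "0-30"),
         (360, "360+"), (1000, "360+")],
    )
    def test_band_labels_half_open(self, minutes, label, cfg):
        assert exposure_band(minutes, cfg) == label

    def test_reference_band_contributes_zero(self, cfg):
        lnors = cfg.band_ln_ors()
        assert lnors[band_index(0.0, cfg.band_edges)] == 0.0
        assert lnors[band_index(15.0, cfg.band_edges)] == 0.0

    @given(st.floats(min_value=0, max_value=2000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bands_partition_nonnegative_minutes(self, minutes):
        edges = (0.0, 30.0, 60.0, 120.0, 360.0)
        i = band_index(minutes, edges)
        assert 0 <= i < len(edges)
        assert edges[i] <= minutes
        if i < len(edges) - 1:
            assert minutes < edges[i + 1]


class TestPopulationUsageIdentity:
    def test_mean_minutes_matches_adoption_weighted_platform_means(self):
        """Law of total expectation: population mean = sum adoption x mean."""
        from dataclasses import replace

        from depsim.engine import build_panel, simulate
        from depsim.synthetic import synthetic_truth_config

        cfg = synthetic_truth_config(n_per_cohort=500)
        cfg = replace(
            cfg,
            minutes_sex_mult={"female": 1.0, "male": 1.0},
            minutes_age_mult={"10_14": 1.0, "15_17": 1.0},
        )
        res = simulate(build_panel(cfg, 9), cfg)
        yi = list(res.years).index(2019)
        expected = sum(
            res.adoption[name][yi] * cfg.mean_minutes(name, "female", "10_14", 2019)
            for name in cfg.platforms
        )
        n = res.n_at_risk[yi]
        se = res.mean_minutes[yi] / np.sqrt(n)  # coarse sampling-error scale
        assert res.mean_minutes[yi] == pytest.approx(expected, abs=3 * se + 1.0)
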