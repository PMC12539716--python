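"""Vectorized simulation core.

The per-individual operations in :mod:`population`, :mod:`social_media` and
:mod:`risk` define the model; this module runs the same model over whole
cohorts with numpy arrays so calibration (thousands of objective
evaluations), scenario contrasts and the Monte Carlo ensemble stay fast.

The central object is a :class:`Panel`: every random draw the simulation
will ever need, pre-generated on a person x year grid from named streams of
one root seed.  Scenario transformations and changes to the calibrated
baseline mean reuse the same panel, which implements common random numbers:
two runs differ only through the parameters, never through fresh noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rng as rngmod
from .config import ModelConfig, STATIC_FACTORS, TIME_VARYING_FACTORS
from .population import draw_cohort_arrays, latent_activity_minutes
from .risk import onset_probability
from .scenarios import ScenarioSpec, high_risk_scores, transform_minutes
from .social_media import PlatformSpec, band_index, bass_fraction, gamma_shape, propensity_quantile

__all__ = ["Panel", "SimResult", "build_panel", "simulate", "prevalence_function"]

_TV_DRAWN = ("obesity_overweight", "chronic_condition", "substance_use")


@dataclass
class Panel:
    """Pre-drawn randomness and person attributes for one root seed."""

    seed: int
    years: np.ndarray          # (Y,)
    birth_year: np.ndarray     # (N,)
    male: np.ndarray           # (N,) bool
    z_baseline: np.ndarray     # (N,) standard normal scores for the intercept
    static: np.ndarray         # (N, 6) bool
    platform_z: np.ndarray     # (N, P)
    latent: np.ndarray         # (N,)
    u_tv: np.ndarray           # (N, Y, 3) uniforms for drawn time-varying factors
    u_pers: np.ndarray         # (N, Y, 3) uniforms for the persistence carry-over
    u_act: np.ndarray          # (N, Y) uniforms for latent activity minutes
    gamma_std: np.ndarray      # (N, Y, P) standard gamma draws (mean 1)
    u_onset: np.ndarray        # (N, Y)
    u_mort: np.ndarray         # (N, Y)

    @property
    def n(self) -> int:
        return self.birth_year.shape[0]

    @property
    def age(self) -> np.ndarray:
        return self.years[None, :] - self.birth_year[:, None]

    @property
    def in_age(self) -> np.ndarray:
        a = self.age
        return (a >= 10) & (a <= 17)


def build_panel(config: ModelConfig, seed: int) -> Panel:
    """Generate all cohorts and pre-draw every random stream.

    The standard-gamma usage draws are generated at the config's CV (shape
    1/CV^2) and rescaled to each platform's mean at evaluation time, so mean
    changes (Monte Carlo draws, scenarios) reuse identical noise.
    """
    years = np.arange(config.first_year, config.last_year + 1)
    Y = years.size
    P = len(config.platforms)

    per_cohort = []
    for by in range(config.cohort_start, config.cohort_end + 1):
        r = rngmod.stream(seed, "cohort", by)
        per_cohort.append((by, draw_cohort_arrays(by, config.n_per_cohort, config, r)))
    N = config.n_per_cohort * len(per_cohort)

    birth_year = np.concatenate(
        [np.full(config.n_per_cohort, by) for by, _ in per_cohort]
    )
    male = np.concatenate([a["male"] for _, a in per_cohort])
    z = np.concatenate([a["z"] for _, a in per_cohort])
    static = np.concatenate([a["static"] for _, a in per_cohort])
    platform_z = np.concatenate([a["platform_z"] for _, a in per_cohort])
    latent = np.concatenate([a["latent"] for _, a in per_cohort])

    r_fac = rngmod.stream(seed, "factors")
    u_tv = r_fac.random((N, Y, len(_TV_DRAWN)))
    u_pers = r_fac.random((N, Y, len(_TV_DRAWN)))
    u_act = r_fac.random((N, Y))
    r_use = rngmod.stream(seed, "usage")
    k = gamma_shape(config.usage_cv)
    gamma_std = r_use.gamma(k, 1.0 / k, size=(N, Y, P))
    u_onset = rngmod.stream(seed, "onset").random((N, Y))
    u_mort = rngmod.stream(seed, "mortality").random((N, Y))

    return Panel(
        seed=seed, years=years, birth_year=birth_year, male=male, z_baseline=z,
        static=static, platform_z=platform_z, latent=latent, u_tv=u_tv,
        u_pers=u_pers, u_act=u_act, gamma_std=gamma_std, u_onset=u_onset,
        u_mort=u_mort,
    )


# ---------------------------------------------------------------------------
# evaluation


def _grid_by_sex_age(panel: Panel, f_1014, f_1517, m_1014, m_1517) -> np.ndarray:
    """(N, Y) grid of values that depend on sex and age group only."""
    older = panel.age >= 15
    male = panel.male[:, None]
    return np.where(
        male,
        np.where(older, m_1517, m_1014),
        np.where(older, f_1517, f_1014),
    )


def _exposure_minutes(panel: Panel, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Raw (pre-scenario) daily minutes (N, Y) and used mask (N, P, Y)."""
    rho = config.co_use_correlation
    quantile = propensity_quantile(panel.latent[:, None], panel.platform_z, rho)  # (N,P)
    older = panel.age >= 15  # (N,Y)
    minutes = np.zeros((panel.n, panel.years.size))
    used_all = np.empty((panel.n, len(config.platforms), panel.years.size), dtype=bool)
    for j, name in enumerate(config.platforms):
        spec = PlatformSpec.from_config(config, name)
        f = bass_fraction(spec, panel.years)  # (Y,)
        sat = _grid_by_sex_age(
            panel,
            config.saturation(name, "female", "10_14"),
            config.saturation(name, "female", "15_17"),
            config.saturation(name, "male", "10_14"),
            config.saturation(name, "male", "15_17"),
        )
        used = quantile[:, j, None] <= sat * f[None, :]
        used_all[:, j, :] = used
        mean = np.empty((panel.n, panel.years.size))
        for yi, year in enumerate(panel.years):
            mean[:, yi] = _grid_by_sex_age(
                panel,
                config.mean_minutes(name, "female", "10_14", year),
                config.mean_minutes(name, "female", "15_17", year),
                config.mean_minutes(name, "male", "10_14", year),
                config.mean_minutes(name, "male", "15_17", year),
            )[:, yi]
        minutes += used * panel.gamma_std[:, :, j] * mean
    return minutes, used_all


def _tv_prevalence_grid(panel: Panel, config: ModelConfig, factor: str) -> np.ndarray:
    grid = np.empty((panel.n, panel.years.size))
    for yi, year in enumerate(panel.years):
        grid[:, yi] = _grid_by_sex_age(
            panel,
            config.tv_prevalence(factor, "female", "10_14", year),
            config.tv_prevalence(factor, "female", "15_17", year),
            config.tv_prevalence(factor, "male", "10_14", year),
            config.tv_prevalence(factor, "male", "15_17", year),
        )[:, yi]
    return grid


@dataclass
class SimResult:
    """Aggregate output of one simulated scenario run."""

    years: np.ndarray
    prevalence: np.ndarray          # overall annual prevalence
    prevalence_female: np.ndarray
    prevalence_male: np.ndarray
    n_at_risk: np.ndarray
    onset_female: int               # first-event counts within the window
    onset_male: int
    mean_minutes: np.ndarray        # among alive 10-17-year-olds
    adoption: dict[str, np.ndarray]  # platform -> adoption fraction per year

    @property
    def onset_total(self) -> int:
        return self.onset_female + self.onset_male


def _eta_base(panel: Panel, config: ModelConfig, scenario: ScenarioSpec | None):
    """Linear predictor minus the calibrated mean, plus at-risk mask.

    Includes sigma * z (person intercept spread), all indicator terms and the
    exposure-band term; the population mean mu is added by the caller so
    calibration can sweep it over a fixed panel.
    """
    scenario = scenario or ScenarioSpec("current")
    minutes_raw, used = _exposure_minutes(panel, config)

    # targeted selection (constant-shift invariant: mu does not alter ranking)
    if scenario.kind == "restrict_high_risk":
        baseline = config.mu_baseline + config.sigma_baseline * panel.z_baseline
        scores = high_risk_scores(panel.male, panel.static, baseline, config)
        k = int(np.ceil(scenario.high_risk_fraction * panel.n))
        order = np.lexsort((np.arange(panel.n), -scores))
        selected = np.zeros(panel.n, dtype=bool)
        selected[order[:k]] = True
        selected = selected[:, None]
    else:
        selected = np.ones((panel.n, 1), dtype=bool)

    year_grid = np.broadcast_to(panel.years[None, :], minutes_raw.shape)
    minutes = transform_minutes(minutes_raw, year_grid, scenario, selected)
    swap_received = (
        (minutes_raw >= scenario.swap_eligibility)
        & (year_grid >= scenario.window[0])
        & (year_grid <= scenario.window[1])
        if scenario.kind == "swap_physical_activity"
        else np.zeros_like(minutes_raw, dtype=bool)
    )

    band_lnors = config.band_ln_ors()
    eta = band_lnors[band_index(minutes, config.band_edges)]

    # static factors and sex
    lnor_static = np.array([config.ln_or(f) for f in STATIC_FACTORS])
    eta += (panel.static @ lnor_static)[:, None]
    eta += np.where(panel.male, config.ln_or("male"), 0.0)[:, None]

    # physical inactivity via latent activity minutes
    p_inact = _tv_prevalence_grid(panel, config, "physical_inactivity")
    act = latent_activity_minutes(
        panel.u_act, p_inact, config.active_latent_max, config.inactivity_threshold
    )
    covid_mask = np.isin(panel.years, np.asarray(config.covid_years))[None, :]
    act = np.where(
        covid_mask, act * (1.0 - config.value("risk.covid_activity_reduction")), act
    )
    act = act + np.where(swap_received, scenario.swap, 0.0)
    eta += (act < config.inactivity_threshold) * config.ln_or("physical_inactivity")

    # remaining time-varying factors (independent annual redraws; optional
    # persistence carries last year's state forward)
    for j, f in enumerate(_TV_DRAWN):
        p = _tv_prevalence_grid(panel, config, f)
        fresh = panel.u_tv[:, :, j] < p
        if config.persistence > 0:
            carry = panel.u_pers[:, :, j] < config.persistence
            ind = fresh.copy()
            for yi in range(1, panel.years.size):
                ind[:, yi] = np.where(carry[:, yi], ind[:, yi - 1], fresh[:, yi])
            fresh = ind
        eta += fresh * config.ln_or(f)

    eta += covid_mask * config.ln_or("covid_confinement")
    eta += (config.sigma_baseline * panel.z_baseline)[:, None]

    # mortality: dead individuals stop contributing the year after the draw
    q = config.value("demographics.adolescent_mortality_q")
    death = (panel.u_mort < q) & panel.in_age
    prior_death = (np.cumsum(death, axis=1) - death) > 0
    at_risk = panel.in_age & ~prior_death

    return eta, at_risk, minutes, used


def _events(eta, panel, config, mode):
    p = onset_probability(eta, config.risk_mode)
    if mode == "threshold":
        return p > config.threshold
    return panel.u_onset < p


def simulate(
    panel: Panel,
    config: ModelConfig,
    scenario: ScenarioSpec | None = None,
    mu: float | None = None,
    mode: str | None = None,
) -> SimResult:
    """Run one scenario over the panel and aggregate annual outcomes."""
    mu = config.mu_baseline if mu is None else float(mu)
    mode = mode or config.event_mode
    eta_base, at_risk, minutes, used = _eta_base(panel, config, scenario)
    event = _events(eta_base + mu, panel, config, mode) & at_risk

    def prev(mask):
        n = (at_risk & mask).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (event & mask).sum(axis=0) / np.maximum(n, 1), np.nan)

    all_mask = np.ones_like(at_risk)
    female = ~panel.male[:, None]
    n_at_risk = at_risk.sum(axis=0)
    any_event = event.any(axis=1)
    onset_f = int((any_event & ~panel.male).sum())
    onset_m = int((any_event & panel.male).sum())

    with np.errstate(invalid="ignore"):
        mean_minutes = np.where(
            n_at_risk > 0,
            (minutes * at_risk).sum(axis=0) / np.maximum(n_at_risk, 1),
            np.nan,
        )
    adoption = {
        name: (used[:, j, :] & at_risk).sum(axis=0) / np.maximum(n_at_risk, 1)
        for j, name in enumerate(config.platforms)
    }
    return SimResult(
        years=panel.years.copy(),
        prevalence=prev(all_mask),
        prevalence_female=prev(female),
        prevalence_male=prev(~female),
        n_at_risk=n_at_risk,
        onset_female=onset_f,
        onset_male=onset_m,
        mean_minutes=mean_minutes,
        adoption=adoption,
    )


def prevalence_function(
    panel: Panel,
    config: ModelConfig,
    scenario: ScenarioSpec | None = None,
    mode: str | None = None,
):
    """Closure mu -> (prevalence, prevalence_female, prevalence_male).

    Everything except the calibrated mean is precomputed once, so sweeping mu
    (the Nelder-Mead objective) costs one vectorized comparison per call and
    is a deterministic function of mu for a fixed panel — exact common
    random numbers.
    """
    mode = mode or config.event_mode
    eta_base, at_risk, _, _ = _eta_base(panel, config, scenario)
    female = ~panel.male[:, None]
    n_all = at_risk.sum(axis=0)
    n_f = (at_risk & female).sum(axis=0)
    n_m = n_all - n_f

    def fn(mu: float):
        event = _events(eta_base + mu, panel, config, mode) & at_risk
        with np.errstate(invalid="ignore"):
            p_all = np.where(n_all > 0, event.sum(axis=0) / np.maximum(n_all, 1), np.nan)
            p_f = np.where(
                n_f > 0, (event & female).sum(axis=0) / np.maximum(n_f, 1), np.nan
            )
            p_m = np.where(
                n_m > 0, (event & ~female).sum(axis=0) / np.maximum(n_m, 1), np.nan
            )
        return p_all, p_f, p_m

    return fn
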