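"""Typed parameter registry and model configuration.

The model is driven by 95 scalar parameters organised in four groups
(demographics, social-media platforms, depression risk factors, lifetime
outcomes), exactly one of which — the population mean of the individual
baseline risk — is calibrated rather than taken from the literature.
Each parameter is a :class:`ParameterSpec` carrying its central value,
optional 95% CI, measurement scale and the rule used to resample it during
Monte Carlo uncertainty propagation.

Structural settings that are not uncertain quantities (cohort range, band
edges, platform launch years, simulation mode switches) live directly on
:class:`ModelConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSpec",
    "ModelConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "write_config",
    "sample_parameter",
    "sample_config",
    "STATIC_FACTORS",
    "TIME_VARYING_FACTORS",
    "SEXES",
    "AGE_GROUPS",
]

SCALES = ("log_odds", "probability", "minutes", "fraction", "euros", "years", "count")
SAMPLINGS = ("fixed", "normal_ci", "uniform_pm20")
PROVENANCES = ("literature", "expert", "calibrated", "placeholder")

SEXES = ("female", "male")
AGE_GROUPS = ("10_14", "15_17")

STATIC_FACTORS = (
    "parental_psychiatric_history",
    "physical_abuse",
    "emotional_abuse",
    "sexual_abuse",
    "neglect",
    "bullying",
)
TIME_VARYING_FACTORS = (
    "physical_inactivity",
    "obesity_overweight",
    "chronic_condition",
    "substance_use",
)

#: platform name -> market launch year (structural, not uncertain)
PLATFORM_LAUNCH = {
    "facebook": 2004,
    "twitter": 2006,
    "whatsapp": 2009,
    "instagram": 2010,
    "snapchat": 2011,
    "tiktok": 2016,
}

SM_BANDS = ("sm_30_60", "sm_60_120", "sm_120_360", "sm_360_plus")


class ConfigError(ValueError):
    """Raised when a configuration file or value violates the schema."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter on its natural scale.

    ``normal_ci`` sampling draws from Normal(value, (ci_high-ci_low)/3.92);
    ``uniform_pm20`` from Uniform(0.8*value, 1.2*value).  Draws on the
    probability/fraction scales are clipped to [0, 1].
    """

    name: str
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    scale: str = "count"
    sampling: str = "fixed"
    provenance: str = "literature"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(f"{self.name}: unknown scale {self.scale!r}")
        if self.sampling not in SAMPLINGS:
            raise ConfigError(f"{self.name}: unknown sampling {self.sampling!r}")
        if self.provenance not in PROVENANCES:
            raise ConfigError(f"{self.name}: unknown provenance {self.provenance!r}")
        if self.scale in ("probability", "fraction") and not 0.0 <= self.value <= 1.0:
            raise ConfigError(
                f"{self.name}: {self.scale} value {self.value} outside [0, 1]"
            )
        if self.sampling == "normal_ci":
            if self.ci_low is None or self.ci_high is None:
                raise ConfigError(f"{self.name}: normal_ci sampling requires CI bounds")
            if not self.ci_low < self.ci_high:
                raise ConfigError(f"{self.name}: ci_low must be < ci_high")

    @property
    def sd(self) -> float | None:
        """Implied normal SD from the 95% CI width (width / 3.92)."""
        if self.ci_low is None or self.ci_high is None:
            return None
        return (self.ci_high - self.ci_low) / 3.92


def sample_parameter(
    spec: ParameterSpec, rng: np.random.Generator, ci_uniform: bool = False
) -> float:
    """Draw one Monte Carlo realisation of ``spec`` on its natural scale.

    ``ci_uniform=True`` replaces the normal-on-CI rule with a uniform draw on
    [ci_low, ci_high] (alternative reading of "within a 95% CI").
    """
    if rng is None:
        raise ValueError("sample_parameter requires a random generator")
    if spec.sampling == "fixed":
        return float(spec.value)
    if spec.sampling == "normal_ci":
        if ci_uniform:
            x = rng.uniform(spec.ci_low, spec.ci_high)
        else:
            x = rng.normal(spec.value, spec.sd)
    elif spec.sampling == "uniform_pm20":
        lo, hi = sorted((0.8 * spec.value, 1.2 * spec.value))
        x = rng.uniform(lo, hi)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(f"{spec.name}: unknown sampling {spec.sampling!r}")
    if spec.scale in ("probability", "fraction"):
        x = min(1.0, max(0.0, x))
    return float(x)


# ---------------------------------------------------------------------------
# ModelConfig


@dataclass(frozen=True)
class ModelConfig:
    """Full model configuration: 95-parameter registry plus structural settings.

    ``overrides`` maps parameter names to replacement values (used both for
    Monte Carlo draws and CLI ``--set`` overrides); :meth:`value` resolves it.
    """

    params: Mapping[str, ParameterSpec]
    # demographics / window
    cohort_start: int = 1990
    cohort_end: int = 2012
    n_per_cohort: int = 1000
    first_year: int = 2000
    last_year: int = 2022
    # exposure structure
    band_edges: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 360.0)
    platform_launch: Mapping[str, int] = field(
        default_factory=lambda: dict(PLATFORM_LAUNCH)
    )
    sat_age_mult_10_14: float = 0.80
    minutes_age_mult: Mapping[str, float] = field(
        default_factory=lambda: {"10_14": 0.85, "15_17": 1.15}
    )
    minutes_sex_mult: Mapping[str, float] = field(
        default_factory=lambda: {"female": 1.10, "male": 0.90}
    )
    minutes_ramp_floor: float = 0.30
    gamma_total_mode: bool = False  # gamma on the summed daily total instead of per platform
    # risk-factor structure
    trend_ref_year: int = 2010
    covid_years: tuple[int, ...] = (2020,)
    persistence: float = 0.0  # P(carry last year's time-varying state)
    active_latent_max: float = 180.0  # upper edge of the latent activity-minutes band
    inactivity_threshold: float = 60.0
    # event mechanism
    event_mode: str = "bernoulli"  # or "threshold"
    threshold: float = 0.5
    risk_mode: str = "logistic"  # or "exp" (raw exponential, capped at 1)
    adult_mode: str = "risk_multiplier"  # or "odds"
    ci_uniform: bool = False
    # calibration settings
    calib_max_iter: int = 300
    calib_tol: float = 1e-3
    calib_restarts: int = 30
    calib_start_low: float = -4.0
    calib_start_high: float = 0.0
    # overrides (Monte Carlo draws / CLI --set), name -> value
    overrides: Mapping[str, float] = field(default_factory=dict)

    # -- parameter access ---------------------------------------------------

    def value(self, name: str) -> float:
        """Resolved value of a parameter (override if present, else central)."""
        if name in self.overrides:
            return float(self.overrides[name])
        try:
            return float(self.params[name].value)
        except KeyError:
            raise ConfigError(f"unknown parameter {name!r}") from None

    def with_overrides(self, mapping: Mapping[str, float]) -> "ModelConfig":
        unknown = set(mapping) - set(self.params)
        if unknown:
            raise ConfigError(f"unknown parameters in overrides: {sorted(unknown)}")
        merged = {**self.overrides, **{k: float(v) for k, v in mapping.items()}}
        return replace(self, overrides=merged)

    def placeholders(self) -> list[str]:
        """Names of parameters whose default value is a documented placeholder."""
        return sorted(
            n for n, s in self.params.items() if s.provenance == "placeholder"
        )

    # -- derived views ------------------------------------------------------

    @property
    def platforms(self) -> list[str]:
        return list(self.platform_launch)

    @property
    def mu_baseline(self) -> float:
        return self.value("risk.baseline.mu")

    @property
    def sigma_baseline(self) -> float:
        return self.value("risk.baseline.sigma")

    @property
    def usage_cv(self) -> float:
        return self.value("sm.usage_cv")

    @property
    def co_use_correlation(self) -> float:
        return self.value("sm.co_use_correlation")

    def band_ln_ors(self) -> np.ndarray:
        """ln(OR) per exposure band, reference band first (always 0)."""
        return np.array([0.0] + [self.value(f"risk.ln_or.{b}") for b in SM_BANDS])

    def ln_or(self, factor: str) -> float:
        return self.value(f"risk.ln_or.{factor}")

    def static_prevalence(self, factor: str, sex: str) -> float:
        return self.value(f"risk.prev.{factor}.{sex}")

    def tv_prevalence(self, factor: str, sex: str, age_group: str, year: int) -> float:
        """Time-varying prevalence with a linear year trend about the reference year."""
        base = self.value(f"risk.prev.{factor}.{sex}.{age_group}")
        trend = self.value(f"risk.trend.{factor}")
        p = base * (1.0 + trend * (year - self.trend_ref_year))
        return float(min(1.0, max(0.0, p)))

    def saturation(self, platform: str, sex: str, age_group: str) -> float:
        s = self.value(f"sm.{platform}.sat_{sex}")
        if age_group == "10_14":
            s *= self.sat_age_mult_10_14
        return float(min(1.0, max(0.0, s)))

    def mean_minutes(self, platform: str, sex: str, age_group: str, year: int) -> float:
        """Mean daily minutes among users of a platform; ramps up after launch."""
        m22 = self.value(f"sm.{platform}.mean_minutes_2022")
        launch = self.platform_launch[platform]
        span = max(1, 2022 - launch)
        ramp = self.minutes_ramp_floor + (1.0 - self.minutes_ramp_floor) * (
            (year - launch) / span
        )
        ramp = min(1.0, max(self.minutes_ramp_floor, ramp))
        return float(
            m22 * ramp * self.minutes_sex_mult[sex] * self.minutes_age_mult[age_group]
        )

    def validate(self) -> None:
        """Check cross-field invariants; raise :class:`ConfigError` on violation."""
        if self.cohort_end < self.cohort_start:
            raise ConfigError("cohort_end before cohort_start")
        if self.n_per_cohort < 1:
            raise ConfigError("n_per_cohort must be >= 1")
        if not 0.0 < self.usage_cv:
            raise ConfigError("sm.usage_cv must be > 0")
        if not 0.0 <= self.co_use_correlation < 1.0:
            raise ConfigError("sm.co_use_correlation must be in [0, 1)")
        if self.event_mode not in ("bernoulli", "threshold"):
            raise ConfigError(f"unknown event_mode {self.event_mode!r}")
        if self.risk_mode not in ("logistic", "exp"):
            raise ConfigError(f"unknown risk_mode {self.risk_mode!r}")
        if self.adult_mode not in ("risk_multiplier", "odds"):
            raise ConfigError(f"unknown adult_mode {self.adult_mode!r}")
        if list(self.band_edges) != sorted(self.band_edges) or self.band_edges[0] != 0:
            raise ConfigError("band_edges must be sorted and start at 0")
        calibrated = [n for n, s in self.params.items() if s.provenance == "calibrated"]
        if calibrated != ["risk.baseline.mu"]:
            raise ConfigError(
                "exactly one parameter must have provenance='calibrated' "
                f"(risk.baseline.mu); found {calibrated}"
            )
        for p in self.platforms:
            if self.value(f"sm.{p}.bass_p") <= 0:
                raise ConfigError(f"sm.{p}.bass_p must be > 0")
            if self.value(f"sm.{p}.bass_q") < 0:
                raise ConfigError(f"sm.{p}.bass_q must be >= 0")
            if self.value(f"sm.{p}.mean_minutes_2022") < 0:
                raise ConfigError(f"sm.{p}.mean_minutes_2022 must be >= 0")


def sample_config(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """Independently resample every non-calibrated parameter (one MC draw).

    The calibrated baseline mean is never resampled.
    """
    draws = {}
    for name, spec in config.params.items():
        if spec.provenance == "calibrated" or spec.sampling == "fixed":
            continue
        draws[name] = sample_parameter(spec, rng, ci_uniform=config.ci_uniform)
    return config.with_overrides(draws)


# ---------------------------------------------------------------------------
# Default registry


def _p(name, value, scale, sampling="uniform_pm20", ci=None, prov="placeholder"):
    lo, hi = (ci if ci is not None else (None, None))
    return ParameterSpec(
        name=name, value=value, ci_low=lo, ci_high=hi,
        scale=scale, sampling=sampling, provenance=prov,
    )


def _default_params() -> dict[str, ParameterSpec]:
    specs: list[ParameterSpec] = []

    # demographics (4)
    specs += [
        _p("demographics.sex_ratio_male", 0.512, "fraction", "fixed", prov="literature"),
        _p("demographics.births_per_year", 790_000, "count", "fixed", prov="literature"),
        _p("demographics.adolescent_mortality_q", 2.0e-4, "probability",
           "uniform_pm20", prov="literature"),
        _p("demographics.life_expectancy_years", 82.0, "years", "fixed",
           prov="literature"),
    ]

    # social media (2 + 6 platforms x 5 = 32)
    specs += [
        _p("sm.usage_cv", 0.20, "fraction", "uniform_pm20", prov="literature"),
        _p("sm.co_use_correlation", 0.10, "fraction", "uniform_pm20",
           prov="literature"),
    ]
    platform_defaults = {
        # name: (sat_female, sat_male, mean_minutes_2022)
        "facebook": (0.55, 0.50, 35.0),
        "twitter": (0.25, 0.30, 15.0),
        "whatsapp": (0.55, 0.50, 30.0),
        "instagram": (0.75, 0.60, 60.0),
        "snapchat": (0.70, 0.60, 50.0),
        "tiktok": (0.65, 0.55, 75.0),
    }
    for name, (sf, sm_, mm) in platform_defaults.items():
        specs += [
            _p(f"sm.{name}.bass_p", 0.03, "count"),
            _p(f"sm.{name}.bass_q", 0.38, "count"),
            _p(f"sm.{name}.sat_female", sf, "fraction"),
            _p(f"sm.{name}.sat_male", sm_, "fraction"),
            _p(f"sm.{name}.mean_minutes_2022", mm, "minutes"),
        ]

    # risk-equation coefficients (16): printed values verbatim where available.
    # NOTE: several printed signs are epidemiologically surprising (bullying,
    # COVID-19, male, SM 60-120); they are entered as printed and flagged via
    # provenance, not "corrected".
    printed = {
        "male": (0.2357, (-0.0392, 0.4943)),
        "physical_inactivity": (0.4780, (0.1278, 0.8210)),
        "bullying": (-0.4383, (-0.5710, -0.3001)),
        "physical_abuse": (0.1278, (-0.0100, 0.2614)),
        "covid_confinement": (-1.4816, (-1.6864, -1.2809)),
        "sm_30_60": (0.0513, (-0.3507, 0.4620)),
        "sm_60_120": (-0.2776, (-0.6881, 0.1278)),
    }
    for f, (v, ci) in printed.items():
        specs.append(_p(f"risk.ln_or.{f}", v, "log_odds", "normal_ci", ci,
                        prov="literature"))
    unprinted_lnor = {
        "parental_psychiatric_history": 0.25,
        "emotional_abuse": 0.20,
        "sexual_abuse": 0.20,
        "neglect": 0.20,
        "obesity_overweight": 0.15,
        "chronic_condition": 0.20,
        "substance_use": 0.20,
        "sm_120_360": 0.60,
        "sm_360_plus": 0.90,
    }
    for f, v in unprinted_lnor.items():
        specs.append(_p(f"risk.ln_or.{f}", v, "log_odds"))

    # static-factor prevalence by sex (6 x 2 = 12)
    static_prev = {
        "parental_psychiatric_history": (0.18, 0.18),
        "physical_abuse": (0.06, 0.08),
        "emotional_abuse": (0.10, 0.08),
        "sexual_abuse": (0.05, 0.02),
        "neglect": (0.06, 0.06),
        "bullying": (0.28, 0.25),
    }
    for f, (pf, pm) in static_prev.items():
        specs.append(_p(f"risk.prev.{f}.female", pf, "probability"))
        specs.append(_p(f"risk.prev.{f}.male", pm, "probability"))

    # time-varying prevalence by sex x age group at the reference year
    # (4 x 2 x 2 = 16) and per-factor linear year trends (4)
    tv_prev = {
        # factor: (f 10-14, f 15-17, m 10-14, m 15-17)
        "physical_inactivity": (0.40, 0.50, 0.30, 0.35),
        "obesity_overweight": (0.16, 0.17, 0.18, 0.17),
        "chronic_condition": (0.08, 0.10, 0.08, 0.10),
        "substance_use": (0.04, 0.22, 0.05, 0.25),
    }
    trends = {
        "physical_inactivity": 0.010,
        "obesity_overweight": 0.010,
        "chronic_condition": 0.005,
        "substance_use": -0.010,
    }
    for f, (f1, f2, m1, m2) in tv_prev.items():
        specs += [
            _p(f"risk.prev.{f}.female.10_14", f1, "probability"),
            _p(f"risk.prev.{f}.female.15_17", f2, "probability"),
            _p(f"risk.prev.{f}.male.10_14", m1, "probability"),
            _p(f"risk.prev.{f}.male.15_17", m2, "probability"),
        ]
        specs.append(_p(f"risk.trend.{f}", trends[f], "fraction"
                        if trends[f] >= 0 else "count"))

    # pandemic activity reduction (1): activity minutes fell 42% in 2020
    specs.append(_p("risk.covid_activity_reduction", 0.42, "fraction",
                    "uniform_pm20", prov="literature"))

    # baseline risk (2): the only calibrated parameter, plus its SD
    specs.append(ParameterSpec("risk.baseline.mu", -1.80, scale="log_odds",
                               sampling="fixed", provenance="calibrated"))
    specs.append(ParameterSpec("risk.baseline.sigma", 1.0, scale="log_odds",
                               sampling="fixed", provenance="expert"))

    # lifetime-outcome parameters (8). Per-case multipliers are the ratios
    # implied by the headline burden table (e.g. direct cost / lifetime cases);
    # documented as derived and overridable.
    specs += [
        _p("outcome.adult_base_prevalence", 0.083, "probability",
           "uniform_pm20", prov="literature"),
        _p("outcome.adult_recurrence_or", 2.78, "count", "normal_ci",
           (1.97, 3.93), prov="literature"),
        _p("outcome.excess_lifetime_multiplier", 0.72 / 0.59, "count",
           "uniform_pm20", prov="literature"),
        _p("outcome.suicide_deaths_per_case", 799 / 720_000.0, "probability",
           "uniform_pm20", prov="literature"),
        _p("outcome.attempts_per_death", 25.0, "count", "fixed",
           prov="literature"),
        _p("outcome.hale_years_per_case", 136_870 / 720_000.0, "years",
           "uniform_pm20", prov="literature"),
        _p("outcome.direct_cost_per_case", 2.56e9 / 720_000.0, "euros",
           "uniform_pm20", prov="literature"),
        _p("outcome.productivity_cost_per_case", 1.38e9 / 720_000.0, "euros",
           "uniform_pm20", prov="literature"),
    ]

    registry = {s.name: s for s in specs}
    assert len(registry) == len(specs), "duplicate parameter name"
    return registry


def default_config(**structural) -> ModelConfig:
    """The shipped default configuration (95 parameters, placeholders flagged).

    Keyword arguments override structural fields, e.g.
    ``default_config(n_per_cohort=200, event_mode="threshold")``.
    """
    cfg = ModelConfig(params=_default_params(), **structural)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# YAML persistence

_STRUCTURAL_FIELDS = (
    "cohort_start", "cohort_end", "n_per_cohort", "first_year", "last_year",
    "band_edges", "platform_launch", "sat_age_mult_10_14", "minutes_age_mult",
    "minutes_sex_mult", "minutes_ramp_floor", "gamma_total_mode",
    "trend_ref_year", "covid_years", "persistence", "active_latent_max",
    "inactivity_threshold", "event_mode", "threshold", "risk_mode",
    "adult_mode", "ci_uniform", "calib_max_iter", "calib_tol",
    "calib_restarts", "calib_start_low", "calib_start_high",
)


def write_config(config: ModelConfig, path) -> None:
    """Serialise a ModelConfig to YAML (round-trips through load_config)."""
    doc = {
        "structural": {
            k: _to_plain(getattr(config, k)) for k in _STRUCTURAL_FIELDS
        },
        "overrides": dict(config.overrides),
        "parameters": {
            name: {
                "value": spec.value,
                "ci_low": spec.ci_low,
                "ci_high": spec.ci_high,
                "scale": spec.scale,
                "sampling": spec.sampling,
                "provenance": spec.provenance,
            }
            for name, spec in config.params.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _to_plain(x):
    if isinstance(x, tuple):
        return list(x)
    if isinstance(x, Mapping):
        return dict(x)
    return x


def load_config(path) -> ModelConfig:
    """Load and fully validate a YAML configuration.

    Raises :class:`ConfigError` naming the offending field on any schema
    violation.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(doc) - {"structural", "parameters", "overrides"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "parameters" not in doc:
        raise ConfigError("missing required section 'parameters'")
    params = {}
    for name, entry in doc["parameters"].items():
        if not isinstance(entry, dict):
            raise ConfigError(f"parameter {name!r}: entry must be a mapping")
        bad = set(entry) - {"value", "ci_low", "ci_high", "scale", "sampling",
                            "provenance"}
        if bad:
            raise ConfigError(f"parameter {name!r}: unknown keys {sorted(bad)}")
        if "value" not in entry:
            raise ConfigError(f"parameter {name!r}: missing required field 'value'")
        params[name] = ParameterSpec(name=name, **entry)

    structural = doc.get("structural", {}) or {}
    bad = set(structural) - set(_STRUCTURAL_FIELDS)
    if bad:
        raise ConfigError(f"unknown structural fields: {sorted(bad)}")
    kwargs = {}
    for k, v in structural.items():
        if k in ("band_edges", "covid_years"):
            v = tuple(v)
        kwargs[k] = v
    cfg = ModelConfig(params=params, overrides=doc.get("overrides", {}) or {},
                      **kwargs)
    cfg.validate()
    _require_outcome_params(cfg)
    return cfg


def _require_outcome_params(cfg: ModelConfig) -> None:
    required = [
        "outcome.adult_base_prevalence", "outcome.adult_recurrence_or",
        "outcome.excess_lifetime_multiplier", "outcome.suicide_deaths_per_case",
        "outcome.attempts_per_death", "outcome.hale_years_per_case",
        "outcome.direct_cost_per_case", "outcome.productivity_cost_per_case",
    ]
    missing = [r for r in required if r not in cfg.params]
    if missing:
        raise ConfigError(f"missing outcome parameters: {missing}")
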