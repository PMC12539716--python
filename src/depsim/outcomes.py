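"""Lifetime burden projection and scenario comparison.

Adolescent-onset depression is carried into adulthood through an excess
recurrence multiplier, then converted into suicide deaths (sex-stratified
per-case rates), suicide attempts (a fixed attempts:death ratio, default
25:1), health-adjusted life-expectancy (HALE) loss and direct/productivity
costs, all through per-lifetime-case multipliers.  Counts simulated on a
reduced cohort are extrapolated to national scale by births-per-year /
persons-per-cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .config import ConfigError, ModelConfig

__all__ = [
    "OutcomeParams",
    "CaseLedger",
    "OutcomeReport",
    "ScenarioDelta",
    "adult_lifetime_prevalence",
    "project_outcomes",
    "extrapolate",
    "compare_scenarios",
]


@dataclass(frozen=True)
class OutcomeParams:
    adult_base_prevalence: float = 0.083
    adult_multiplier: float = 2.78
    attempts_per_death: float = 25.0
    suicide_deaths_per_case_female: float = 799 / 720_000.0
    suicide_deaths_per_case_male: float = 799 / 720_000.0
    excess_lifetime_multiplier: float = 0.72 / 0.59
    hale_years_per_case: float = 136_870 / 720_000.0
    direct_cost_per_case: float = 2.56e9 / 720_000.0
    productivity_cost_per_case: float = 1.38e9 / 720_000.0
    births_per_year: float = 790_000.0
    life_expectancy: float = 82.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                raise ConfigError(f"outcome parameter {f.name} is missing")
            if v < 0:
                raise ConfigError(f"outcome parameter {f.name} must be >= 0")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "OutcomeParams":
        v = config.value
        return cls(
            adult_base_prevalence=v("outcome.adult_base_prevalence"),
            adult_multiplier=v("outcome.adult_recurrence_or"),
            attempts_per_death=v("outcome.attempts_per_death"),
            suicide_deaths_per_case_female=v("outcome.suicide_deaths_per_case"),
            suicide_deaths_per_case_male=v("outcome.suicide_deaths_per_case"),
            excess_lifetime_multiplier=v("outcome.excess_lifetime_multiplier"),
            hale_years_per_case=v("outcome.hale_years_per_case"),
            direct_cost_per_case=v("outcome.direct_cost_per_case"),
            productivity_cost_per_case=v("outcome.productivity_cost_per_case"),
            births_per_year=v("demographics.births_per_year"),
            life_expectancy=v("demographics.life_expectancy_years"),
        )


@dataclass(frozen=True)
class CaseLedger:
    """Adolescent-onset case counts from a completed simulation."""

    onset_female: float
    onset_male: float

    @property
    def onset_total(self) -> float:
        return self.onset_female + self.onset_male


_FIELDS = (
    "cumulative_onset",
    "lifetime_cases",
    "suicide_deaths",
    "suicide_attempts",
    "hale_loss",
    "direct_cost",
    "productivity_cost",
    "total_cost",
)


@dataclass(frozen=True)
class OutcomeReport:
    """Scenario-level burden ledger."""

    cumulative_onset: float
    lifetime_cases: float
    suicide_deaths: float
    suicide_attempts: float
    hale_loss: float
    direct_cost: float
    productivity_cost: float
    total_cost: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in _FIELDS}


def adult_lifetime_prevalence(
    base: float, multiplier: float, mode: str = "risk_multiplier"
) -> float:
    """Expected adult depression prevalence among adolescent-onset cases.

    The default multiplies the base prevalence by the recurrence odds ratio
    directly (the source's own arithmetic: 2.78 x 8.3% ~ 23%), clipped to 1.
    ``mode='odds'`` applies the OR on the odds scale instead:
    p = OR*odds / (1 + OR*odds).
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError("base prevalence must be in [0, 1]")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if mode == "risk_multiplier":
        return min(1.0, base * multiplier)
    if mode == "odds":
        odds = multiplier * base / (1.0 - base)
        return odds / (1.0 + odds)
    raise ValueError(f"unknown mode {mode!r}")


def project_outcomes(cases: CaseLedger, params: OutcomeParams) -> OutcomeReport:
    """Convert adolescent-onset counts into the lifetime burden ledger."""
    lifetime_f = cases.onset_female * params.excess_lifetime_multiplier
    lifetime_m = cases.onset_male * params.excess_lifetime_multiplier
    lifetime = lifetime_f + lifetime_m
    deaths = (
        lifetime_f * params.suicide_deaths_per_case_female
        + lifetime_m * params.suicide_deaths_per_case_male
    )
    direct = lifetime * params.direct_cost_per_case
    productivity = lifetime * params.productivity_cost_per_case
    return OutcomeReport(
        cumulative_onset=cases.onset_total,
        lifetime_cases=lifetime,
        suicide_deaths=deaths,
        suicide_attempts=params.attempts_per_death * deaths,
        hale_loss=lifetime * params.hale_years_per_case,
        direct_cost=direct,
        productivity_cost=productivity,
        total_cost=direct + productivity,
    )


def extrapolate(
    report: OutcomeReport, n_per_cohort: int, params: OutcomeParams
) -> OutcomeReport:
    """Scale a reduced-cohort report to national scale (linear in all fields)."""
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    factor = params.births_per_year / n_per_cohort
    return OutcomeReport(**{f: getattr(report, f) * factor for f in _FIELDS})


@dataclass(frozen=True)
class ScenarioDelta:
    """Field-wise differences (alternative - reference) with percent change."""

    delta: dict[str, float]
    percent: dict[str, float]  # NaN where the reference field is 0


def compare_scenarios(
    reference: OutcomeReport, alternative: OutcomeReport
) -> ScenarioDelta:
    delta, percent = {}, {}
    for f in _FIELDS:
        ref, alt = getattr(reference, f), getattr(alternative, f)
        delta[f] = alt - ref
        percent[f] = 100.0 * (alt - ref) / ref if ref != 0 else (
            np.nan if alt != ref else 0.0
        )
    return ScenarioDelta(delta=delta, percent=percent)
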