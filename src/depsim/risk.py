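"""Annual depression risk and event simulation.

The annual risk for a person-year is built from an additive log-odds linear
predictor

    eta = sum_i ln(OR_i) A_i  +  ln(OR_band(SM minutes))  +  I

where A_i are the binary risk-factor indicators, the social-media exposure
band carries its own coefficient (reference band [0, 30) min/day has
ln OR = 0), and I is the person's baseline intercept.  The default reading
maps eta to a probability through the logistic function (coefficients are
odds ratios); a raw-exponential mode (risk = min(e^eta, 1)) is retained as
a sensitivity switch.

Two event mechanisms coexist in the source material and both are
implemented: annual Bernoulli(p) draws (simulation default) and the
deterministic >50% classification rule (calibration default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, SM_BANDS, STATIC_FACTORS, TIME_VARYING_FACTORS
from .population import Individual
from .social_media import band_index

__all__ = [
    "RiskFactorSpec",
    "ExposureBandSpec",
    "risk_factor_specs",
    "exposure_band_specs",
    "linear_predictor",
    "onset_probability",
    "simulate_individual_year",
    "annual_prevalence",
]

#: indicators handled by the sex term rather than the indicator map
_SEX_FACTOR = "male"


@dataclass(frozen=True)
class RiskFactorSpec:
    name: str
    ln_or: float
    time_varying: bool
    active_years: frozenset[int] | None = None  # e.g. COVID = {2020}


@dataclass(frozen=True)
class ExposureBandSpec:
    lower_minutes: float
    upper_minutes: float  # inf for the top band
    ln_or: float


def risk_factor_specs(config: ModelConfig) -> dict[str, RiskFactorSpec]:
    """All configured risk factors keyed by indicator name."""
    specs = {}
    for f in STATIC_FACTORS:
        specs[f] = RiskFactorSpec(f, config.ln_or(f), time_varying=False)
    for f in TIME_VARYING_FACTORS:
        specs[f] = RiskFactorSpec(f, config.ln_or(f), time_varying=True)
    specs["covid_confinement"] = RiskFactorSpec(
        "covid_confinement",
        config.ln_or("covid_confinement"),
        time_varying=True,
        active_years=frozenset(config.covid_years),
    )
    specs[_SEX_FACTOR] = RiskFactorSpec(
        _SEX_FACTOR, config.ln_or(_SEX_FACTOR), time_varying=False
    )
    return specs


def exposure_band_specs(config: ModelConfig) -> list[ExposureBandSpec]:
    """Exposure bands partitioning [0, inf); first band is the reference."""
    edges = list(config.band_edges) + [np.inf]
    lnors = config.band_ln_ors()
    return [
        ExposureBandSpec(edges[i], edges[i + 1], float(lnors[i]))
        for i in range(len(config.band_edges))
    ]


def linear_predictor(
    ind: Individual,
    indicators: dict[str, bool],
    band: ExposureBandSpec,
    config: ModelConfig,
) -> float:
    """eta for one person-year; pure function of its inputs.

    Raises on any indicator without a configured coefficient — indicators are
    never silently dropped.
    """
    specs = risk_factor_specs(config)
    eta = ind.baseline_risk + band.ln_or
    if ind.sex == "male":
        eta += specs[_SEX_FACTOR].ln_or
    for name, present in {**ind.static_factors, **indicators}.items():
        if name not in specs:
            raise KeyError(f"indicator {name!r} has no configured risk factor")
        if present:
            eta += specs[name].ln_or
    return float(eta)


def onset_probability(eta: float | np.ndarray, mode: str = "logistic") -> np.ndarray:
    """Map the linear predictor to an annual event probability.

    ``logistic`` (default): p = 1 / (1 + e^-eta), strictly increasing.
    ``exp``: p = min(e^eta, 1) — the literal exponential reading, capped.
    """
    eta = np.asarray(eta, dtype=float)
    if mode == "logistic":
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-eta))
    elif mode == "exp":
        with np.errstate(over="ignore"):
            p = np.minimum(np.exp(eta), 1.0)
    else:
        raise ValueError(f"unknown risk mode {mode!r}")
    return p if p.ndim else float(p)


def simulate_individual_year(
    ind: Individual,
    age: int,
    year: int,
    minutes: float,
    indicators: dict[str, bool],
    config: ModelConfig,
    rng: np.random.Generator,
) -> bool:
    """Stochastically assess one person-year; record any depressive event."""
    if not ind.alive:
        raise ValueError("cannot simulate a dead individual")
    if not 10 <= age <= 17:
        raise ValueError(f"age {age} outside 10-17")
    band = exposure_band_specs(config)[band_index(minutes, config.band_edges)]
    eta = linear_predictor(ind, indicators, band, config)
    if config.event_mode == "threshold":
        event = onset_probability(eta, config.risk_mode) > config.threshold
    else:
        event = rng.random() < onset_probability(eta, config.risk_mode)
    if event:
        ind.depression_years.add(year)
    return bool(event)


def annual_prevalence(
    population: list[Individual], year: int, sex: str | None = None
) -> float:
    """Share of alive 10-17-year-olds with a depressive event in ``year``."""
    at_risk = [
        p
        for p in population
        if p.alive and 10 <= p.age_in(year) <= 17 and (sex is None or p.sex == sex)
    ]
    if not at_risk:
        raise ValueError(f"no alive adolescents in {year} for stratum {sex or 'all'}")
    return sum(year in p.depression_years for p in at_risk) / len(at_risk)
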