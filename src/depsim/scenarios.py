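"""Counterfactual intervention scenarios.

Five exposure regimes are compared over a common study window with common
random numbers, so differences between scenarios reflect the intervention
alone:

* ``current`` — observed-trend baseline, no transformation;
* ``no_sm`` — social media never available (minutes forced to 0);
* ``cap_minutes`` — daily use capped (default 60 min);
* ``swap_physical_activity`` — users at >= 60 min/day lose 30 min of social
  media and gain 30 min of physical activity before the inactivity
  classification;
* ``restrict_high_risk`` — the top share (default 8.5%) of adolescents by
  non-SM depression risk stop (or cap) their use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ModelConfig, STATIC_FACTORS, TIME_VARYING_FACTORS
from .population import Individual, age_group
from .social_media import UsageRecord, band_index

__all__ = ["ScenarioSpec", "SCENARIOS", "transform_usage", "transform_minutes",
           "high_risk_selection", "high_risk_scores", "apply_pa_substitution"]

KINDS = ("current", "no_sm", "cap_minutes", "swap_physical_activity",
         "restrict_high_risk")


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str = "current"
    cap: float = 60.0
    swap: float = 30.0
    swap_eligibility: float = 60.0
    high_risk_fraction: float = 0.085
    high_risk_mode: str = "stop"  # or "cap60"
    window: tuple[int, int] = (2000, 2022)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.cap < 0 or self.swap < 0:
            raise ValueError("cap and swap must be >= 0")
        if self.kind == "restrict_high_risk" and not 0 < self.high_risk_fraction < 1:
            raise ValueError("high_risk_fraction must be in (0, 1)")
        if self.high_risk_mode not in ("stop", "cap60"):
            raise ValueError(f"unknown high_risk_mode {self.high_risk_mode!r}")


#: canonical scenario set in reporting order
SCENARIOS: dict[str, ScenarioSpec] = {
    "current": ScenarioSpec("current"),
    "no_sm": ScenarioSpec("no_sm"),
    "cap60": ScenarioSpec("cap_minutes", cap=60.0),
    "swap_pa": ScenarioSpec("swap_physical_activity"),
    "high_risk": ScenarioSpec("restrict_high_risk"),
}


def transform_minutes(
    minutes: np.ndarray | float,
    year: np.ndarray | int,
    scenario: ScenarioSpec,
    selected: np.ndarray | bool = True,
) -> np.ndarray | float:
    """Apply the scenario's exposure transformation to daily minutes.

    ``selected`` restricts the transformation to a subset of individuals
    (used by the targeted high-risk scenario).  Years outside the scenario
    window are unchanged.
    """
    minutes = np.asarray(minutes, dtype=float)
    year = np.asarray(year)
    in_window = (year >= scenario.window[0]) & (year <= scenario.window[1])
    apply = in_window & np.asarray(selected, dtype=bool)
    if scenario.kind == "current":
        out = minutes
    elif scenario.kind == "no_sm":
        out = np.where(apply, 0.0, minutes)
    elif scenario.kind == "cap_minutes":
        out = np.where(apply, np.minimum(minutes, scenario.cap), minutes)
    elif scenario.kind == "swap_physical_activity":
        eligible = apply & (minutes >= scenario.swap_eligibility)
        out = np.where(eligible, minutes - scenario.swap, minutes)
    elif scenario.kind == "restrict_high_risk":
        if scenario.high_risk_mode == "stop":
            out = np.where(apply, 0.0, minutes)
        else:
            out = np.where(apply, np.minimum(minutes, 60.0), minutes)
    else:  # pragma: no cover
        raise ValueError(scenario.kind)
    return out if out.ndim else float(out)


def transform_usage(usage: UsageRecord, scenario: ScenarioSpec,
                    config: ModelConfig, selected: bool = True) -> UsageRecord:
    """Scenario-transformed copy of a usage record (band recomputed)."""
    m = transform_minutes(usage.total_minutes, usage.year, scenario, selected)
    platforms = usage.platforms_used if m > 0 else frozenset()
    return UsageRecord(
        individual_id=usage.individual_id,
        year=usage.year,
        platforms_used=platforms,
        total_minutes=float(m),
        band=band_index(m, config.band_edges),
    )


def high_risk_scores(
    male: np.ndarray, static: np.ndarray, baseline: np.ndarray, config: ModelConfig
) -> np.ndarray:
    """Non-SM linear predictor at age-10 entry, used to rank risk.

    Static factors enter as drawn; time-varying factors enter at their
    expected (prevalence-weighted) contribution for the entry year, so the
    ranking does not peek at future stochastic draws.
    """
    score = baseline.astype(float).copy()
    score += np.where(male, config.ln_or("male"), 0.0)
    for j, f in enumerate(STATIC_FACTORS):
        score += static[:, j] * config.ln_or(f)
    year = config.first_year
    for f in TIME_VARYING_FACTORS:
        pf = config.tv_prevalence(f, "female", age_group(10), year)
        pm = config.tv_prevalence(f, "male", age_group(10), year)
        score += np.where(male, pm, pf) * config.ln_or(f)
    return score


def high_risk_selection(
    population: list[Individual], config: ModelConfig, fraction: float = 0.085
) -> set[int]:
    """Ids of the top ``fraction`` of individuals by non-SM depression risk.

    Selects ceil(fraction x N); ties broken by ascending id for determinism.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    male = np.array([p.sex == "male" for p in population])
    static = np.array(
        [[p.static_factors[f] for f in STATIC_FACTORS] for p in population]
    )
    baseline = np.array([p.baseline_risk for p in population])
    scores = high_risk_scores(male, static, baseline, config)
    ids = np.array([p.id for p in population])
    k = int(np.ceil(fraction * len(population)))
    order = np.lexsort((ids, -scores))  # descending score, ascending id on ties
    return set(ids[order[:k]].tolist())


def apply_pa_substitution(
    latent_activity_minutes: np.ndarray | float,
    received_swap: np.ndarray | bool,
    scenario: ScenarioSpec,
    threshold: float = 60.0,
) -> np.ndarray | float:
    """Add the substituted physical-activity minutes before classification.

    Recipients gain ``scenario.swap`` latent activity minutes; whoever
    crosses the 60-min/day threshold flips to active.  Returns the adjusted
    latent minutes (classification stays with the caller).
    """
    m = np.asarray(latent_activity_minutes, dtype=float)
    out = np.where(np.asarray(received_swap, dtype=bool), m + scenario.swap, m)
    return out if out.ndim else float(out)
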