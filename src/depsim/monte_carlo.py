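"""Uncertainty propagation and sensitivity analysis.

A probabilistic sensitivity ensemble resamples every non-calibrated
parameter independently per iteration (the calibrated baseline mean stays
fixed), reruns the full pipeline on a fresh simulation seed, and summarises
each burden field by its ensemble mean and percentile credible interval.
One-way (tornado) analysis instead moves a single parameter to its
uncertainty bounds under common random numbers, ranking parameters by the
outcome range they induce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rng as rngmod
from .config import ModelConfig, sample_config
from .engine import build_panel, simulate
from .outcomes import (
    CaseLedger,
    OutcomeParams,
    OutcomeReport,
    extrapolate,
    project_outcomes,
)
from .scenarios import SCENARIOS, ScenarioSpec

__all__ = [
    "EnsembleResult",
    "scenario_reports",
    "run_ensemble",
    "credible_interval",
    "tornado",
    "structural_sensitivity",
]


def scenario_reports(
    config: ModelConfig,
    seed: int,
    scenarios: dict[str, ScenarioSpec] | None = None,
    mode: str | None = None,
    national: bool = True,
) -> dict[str, OutcomeReport]:
    """Full pipeline: one panel, all scenarios under common random numbers."""
    scenarios = scenarios if scenarios is not None else SCENARIOS
    panel = build_panel(config, seed)
    params = OutcomeParams.from_config(config)
    out = {}
    for name, spec in scenarios.items():
        res = simulate(panel, config, scenario=spec, mode=mode)
        report = project_outcomes(
            CaseLedger(res.onset_female, res.onset_male), params
        )
        if national:
            report = extrapolate(report, config.n_per_cohort, params)
        out[name] = report
    return out


@dataclass
class EnsembleResult:
    """Monte Carlo ensemble summary over scenarios and burden fields."""

    draws: list[tuple[int, int, dict[str, OutcomeReport]]]  # (draw id, seed, reports)
    point_estimate: dict[str, dict[str, float]]  # scenario -> field -> mean
    interval: dict[str, dict[str, tuple[float, float]]]
    n_iterations: int

    def samples(self, scenario: str, field: str) -> np.ndarray:
        return np.array([getattr(r[scenario], field) for _, _, r in self.draws])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scen, means in self.point_estimate.items():
            for f, m in means.items():
                lo, hi = self.interval[scen][f]
                rows.append(
                    {"scenario": scen, "field": f, "mean": m, "lo95": lo, "hi95": hi}
                )
        return pd.DataFrame(rows)


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval with linear interpolation between order statistics."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)


def run_ensemble(
    config: ModelConfig,
    n_iter: int,
    base_seed: int,
    scenarios: dict[str, ScenarioSpec] | None = None,
    mode: str | None = None,
    level: float = 0.95,
) -> EnsembleResult:
    """Propagate parameter uncertainty through ``n_iter`` pipeline runs.

    Per iteration all non-calibrated parameters are independently resampled
    (the calibrated baseline mean is never redrawn) and the pipeline runs on
    a fresh simulation seed derived from ``base_seed``.
    """
    if n_iter < 2:
        raise ValueError("an ensemble needs at least 2 iterations")
    scenarios = scenarios if scenarios is not None else SCENARIOS
    draws = []
    for i in range(n_iter):
        sampled = sample_config(config, rngmod.stream(base_seed, "params", i))
        sim_seed = int(
            rngmod.stream(base_seed, "ensemble", i).integers(0, 2**31 - 1)
        )
        reports = scenario_reports(sampled, sim_seed, scenarios, mode=mode)
        draws.append((i, sim_seed, reports))

    from .outcomes import _FIELDS  # field order shared with OutcomeReport

    point, interval = {}, {}
    for scen in scenarios:
        point[scen], interval[scen] = {}, {}
        for f in _FIELDS:
            vals = np.array([getattr(r[scen], f) for _, _, r in draws])
            point[scen][f] = float(vals.mean())
            interval[scen][f] = credible_interval(vals, level)
    return EnsembleResult(
        draws=draws, point_estimate=point, interval=interval, n_iterations=n_iter
    )


def _bounds(spec) -> tuple[float, float]:
    if spec.ci_low is not None and spec.ci_high is not None:
        return float(spec.ci_low), float(spec.ci_high)
    lo, hi = sorted((0.8 * spec.value, 1.2 * spec.value))
    return float(lo), float(hi)


def _attributable_onset(config: ModelConfig, seed: int) -> float:
    """Default tornado outcome: SM-attributable onset (current minus no-SM)."""
    reports = scenario_reports(
        config, seed, {"current": SCENARIOS["current"], "no_sm": SCENARIOS["no_sm"]}
    )
    return reports["current"].cumulative_onset - reports["no_sm"].cumulative_onset


def tornado(
    config: ModelConfig,
    seed: int,
    parameters: list[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    outcome=None,
) -> pd.DataFrame:
    """One-way sensitivity: move each parameter to its bounds, all else central.

    ``bounds`` overrides the default CI-or-±20% deviation rule per parameter;
    ``outcome`` is a callable ``(config, seed) -> float`` (default:
    SM-attributable cumulative onset).  Returns a frame sorted by descending
    bar width |high - low|.
    """
    outcome = outcome or _attributable_onset
    bounds = bounds or {}
    if parameters is None:
        parameters = [
            n for n, s in config.params.items() if s.sampling != "fixed"
        ]
    rows = []
    for name in parameters:
        lo, hi = bounds.get(name, _bounds(config.params[name]))
        out_lo = outcome(config.with_overrides({name: lo}), seed)
        out_hi = outcome(config.with_overrides({name: hi}), seed)
        rows.append(
            {
                "parameter": name,
                "low_outcome": out_lo,
                "high_outcome": out_hi,
                "width": abs(out_hi - out_lo),
            }
        )
    frame = pd.DataFrame(rows).sort_values("width", ascending=False)
    return frame.reset_index(drop=True)


def structural_sensitivity(
    config: ModelConfig,
    seed: int,
    usage_cvs=(0.10, 0.30),
    correlations=(0.0, 0.30),
    mode: str | None = None,
) -> dict[str, float]:
    """Relative change in mean simulated prevalence under structural variants.

    Varies the gamma usage CV and the cross-platform co-use correlation one
    at a time against the config's defaults and reports
    |mean_prev_variant - mean_prev_base| / mean_prev_base per variant.
    """
    def mean_prev(cfg):
        res = simulate(build_panel(cfg, seed), cfg, mode=mode)
        return float(np.nanmean(res.prevalence))

    base = mean_prev(config)
    out = {"base_mean_prevalence": base}
    for cv in usage_cvs:
        v = mean_prev(config.with_overrides({"sm.usage_cv": cv}))
        out[f"usage_cv={cv:g}"] = abs(v - base) / base
    for rho in correlations:
        v = mean_prev(config.with_overrides({"sm.co_use_correlation": rho}))
        out[f"co_use_correlation={rho:g}"] = abs(v - base) / base
    return out
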