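"""Calibration of the single fitted parameter: the population mean baseline
risk mu.

The loss is the mean squared error between simulated and observed annual
prevalence (as proportions).  The objective is evaluated under common
random numbers — one fixed panel of pre-drawn randomness — so it is a
deterministic function of mu and the one-dimensional Nelder-Mead simplex
converges; without CRN the stochastic objective defeats the simplex.
Optimisation restarts from multiple uniform starting values to avoid local
minima, stopping a restart after the configured iteration cap or as soon as
the loss falls below the configured threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ModelConfig
from .engine import build_panel, prevalence_function
from . import rng as rngmod
from .scenarios import ScenarioSpec

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "calibration_loss",
    "calibrate",
    "fit_statistics",
    "targets_to_csv",
    "targets_from_csv",
]


@dataclass(frozen=True)
class CalibrationTarget:
    year: int
    observed_prevalence: float
    stratum: str = "all"  # all | female | male

    def __post_init__(self):
        if not 0.0 <= self.observed_prevalence <= 1.0:
            raise ValueError("observed prevalence must be in [0, 1]")
        if self.stratum not in ("all", "female", "male"):
            raise ValueError(f"unknown stratum {self.stratum!r}")


@dataclass
class CalibrationResult:
    mu_hat: float
    loss: float
    n_iterations: int
    converged: bool
    restart_values: list[tuple[float, float, float]]  # (start, mu, loss)
    mode: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu_hat": self.mu_hat,
                    "loss": self.loss,
                    "n_iterations": self.n_iterations,
                    "converged": self.converged,
                    "mode": self.mode,
                    "restarts": [
                        {"start": s, "mu": m, "loss": l}
                        for s, m, l in self.restart_values
                    ],
                },
                fh,
                indent=2,
            )


def _check_targets(targets) -> list[CalibrationTarget]:
    targets = list(targets)
    if not targets:
        raise ValueError("calibration requires at least one target")
    seen = set()
    for t in targets:
        key = (t.year, t.stratum)
        if key in seen:
            raise ValueError(f"duplicate target for {key}")
        seen.add(key)
    return targets


def _loss_from_prev(prev_by_stratum, years, targets) -> float:
    errs = []
    year_index = {int(y): i for i, y in enumerate(years)}
    for t in targets:
        i = year_index.get(t.year)
        if i is None:
            raise ValueError(f"target year {t.year} outside simulation window")
        predicted = prev_by_stratum[t.stratum][i]
        if np.isnan(predicted):
            raise ValueError(f"no at-risk adolescents simulated in {t.year}")
        errs.append(predicted - t.observed_prevalence)
    return float(np.mean(np.square(errs)))


def calibration_loss(
    mu: float,
    targets,
    config: ModelConfig,
    crn_seed: int,
    mode: str = "threshold",
    scenario: ScenarioSpec | None = None,
    _panel_cache: dict | None = None,
) -> float:
    """Mean squared prevalence error at baseline mean ``mu`` under CRN.

    In ``threshold`` mode a person-year counts as depressed iff its annual
    probability exceeds 50%; in ``bernoulli`` mode events are the stochastic
    draws of the panel.
    """
    targets = _check_targets(targets)
    fn = _prevalence_closure(config, crn_seed, mode, scenario, _panel_cache)
    p_all, p_f, p_m = fn(mu)
    years = np.arange(config.first_year, config.last_year + 1)
    return _loss_from_prev({"all": p_all, "female": p_f, "male": p_m}, years, targets)


def _prevalence_closure(config, crn_seed, mode, scenario, cache):
    key = ("fn", crn_seed, mode)
    if cache is not None and key in cache:
        return cache[key]
    panel = build_panel(config, crn_seed)
    fn = prevalence_function(panel, config, scenario=scenario, mode=mode)
    if cache is not None:
        cache[key] = fn
    return fn


def calibrate(
    targets,
    config: ModelConfig,
    crn_seed: int = 0,
    mode: str = "threshold",
    scenario: ScenarioSpec | None = None,
) -> CalibrationResult:
    """Fit the baseline mean with restarted one-dimensional Nelder-Mead.

    Each restart begins from a uniform draw on the configured start interval
    with initial simplex {start, start + 0.5}, runs at most
    ``calib_max_iter`` iterations and stops early once the loss falls below
    ``calib_tol``.  The best evaluation across all restarts is returned.
    """
    targets = _check_targets(targets)
    fn = _prevalence_closure(config, crn_seed, mode, scenario, cache={})
    years = np.arange(config.first_year, config.last_year + 1)

    def loss_of(mu: float) -> float:
        p_all, p_f, p_m = fn(float(mu))
        return _loss_from_prev(
            {"all": p_all, "female": p_f, "male": p_m}, years, targets
        )

    r = rngmod.stream(crn_seed, "calibration")
    starts = r.uniform(config.calib_start_low, config.calib_start_high,
                       size=config.calib_restarts)

    restart_values: list[tuple[float, float, float]] = []
    total_iter = 0
    best = (np.inf, np.nan)  # (loss, mu)
    for start in starts:
        tracker = {"best": (np.inf, np.nan)}

        def objective(x):
            l = loss_of(x[0])
            if l < tracker["best"][0]:
                tracker["best"] = (l, float(x[0]))
            if l < config.calib_tol:
                raise StopIteration
            return l

        try:
            res = optimize.minimize(
                objective,
                x0=[float(start)],
                method="Nelder-Mead",
                options={
                    "maxiter": config.calib_max_iter,
                    "initial_simplex": [[float(start)], [float(start) + 0.5]],
                    "xatol": 1e-4,
                    "fatol": 1e-12,
                },
            )
            total_iter += int(res.nit)
        except StopIteration:
            total_iter += 1
        r_loss, r_mu = tracker["best"]
        restart_values.append((float(start), r_mu, r_loss))
        if r_loss < best[0]:
            best = (r_loss, r_mu)

    if not np.isfinite(best[0]):
        raise RuntimeError("calibration failed: no restart produced a finite loss")
    return CalibrationResult(
        mu_hat=best[1],
        loss=best[0],
        n_iterations=total_iter,
        converged=best[0] < config.calib_tol,
        restart_values=restart_values,
        mode=mode,
    )


def fit_statistics(predicted, observed) -> dict[str, float]:
    """Goodness-of-fit summary: R^2, Pearson r, MAE and RMSE.

    R^2 is 1 - SS_res/SS_tot about the observed mean; with zero observed
    variance both R^2 and r are returned as NaN (flagged, not raised).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 2:
        raise ValueError("need at least two points")
    resid = predicted - observed
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0 or np.std(predicted) == 0.0:
        r = np.nan
        r2 = np.nan if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    else:
        r = float(stats.pearsonr(predicted, observed).statistic)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {
        "r_squared": r2,
        "pearson_r": r,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def targets_to_csv(targets, path) -> None:
    pd.DataFrame(
        [
            {"year": t.year, "stratum": t.stratum,
             "prevalence": t.observed_prevalence}
            for t in targets
        ]
    ).to_csv(path, index=False)


def targets_from_csv(path) -> list[CalibrationTarget]:
    frame = pd.read_csv(path)
    return [
        CalibrationTarget(int(r.year), float(r.prevalence), str(r.stratum))
        for r in frame.itertuples(index=False)
    ]
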