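"""Run manifests and burden-table rendering."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .config import ModelConfig
from .monte_carlo import EnsembleResult
from .outcomes import OutcomeReport

__all__ = ["RunManifest", "render_table2", "render_reports"]

_ROW_ORDER = (
    ("cumulative_onset", "Cumulative onset (cases)"),
    ("lifetime_cases", "Lifetime cases"),
    ("direct_cost", "Direct medical costs (EUR)"),
    ("productivity_cost", "Productivity loss (EUR)"),
    ("total_cost", "Total cost (EUR)"),
    ("hale_loss", "HALE loss (years)"),
    ("suicide_attempts", "Suicide attempts"),
    ("suicide_deaths", "Suicide deaths"),
)


@dataclass
class RunManifest:
    """Provenance stamp written next to every output file."""

    command: str
    seed: int | None
    config_hash: str
    version: str = "depsim 0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @classmethod
    def create(cls, command: str, seed: int | None, config: ModelConfig,
               notes: list[str] | None = None) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(
                {n: s.value for n, s in sorted(config.params.items())}
                | {"overrides": dict(sorted(config.overrides.items()))},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16]
        return cls(command=command, seed=seed, config_hash=digest,
                   notes=notes or [])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def render_reports(reports: dict[str, OutcomeReport]) -> pd.DataFrame:
    """Point-estimate burden table: rows = outcome fields, columns = scenarios."""
    if "current" not in reports:
        raise ValueError("rendering requires the 'current' scenario")
    data = {}
    for scen, rep in reports.items():
        col = rep.as_dict()
        if scen != "current":
            col = {
                f: col[f] - getattr(reports["current"], f) for f in col
            }
        data[scen] = col
    frame = pd.DataFrame(data)
    frame = frame.loc[[f for f, _ in _ROW_ORDER]]
    frame.index = [label for _, label in _ROW_ORDER]
    return frame


def render_table2(ensemble: EnsembleResult, reference: str = "current") -> pd.DataFrame:
    """Scenario-delta table with 95% credible intervals from an ensemble.

    Every numeric cell traces to an OutcomeReport field: deltas are computed
    per draw and summarised, never recomputed from rendered values.  A
    percent-reduction row for onset is appended.
    """
    scens = list(ensemble.point_estimate)
    if reference not in scens or len(scens) < 2:
        raise ValueError("need the reference scenario plus at least one alternative")
    rows = {}
    for fname, label in _ROW_ORDER:
        cells = {}
        for scen in scens:
            if scen == reference:
                vals = ensemble.samples(scen, fname)
            else:
                vals = ensemble.samples(scen, fname) - ensemble.samples(
                    reference, fname
                )
            lo, hi = np.percentile(vals, [2.5, 97.5])
            cells[scen] = f"{vals.mean():.4g} ({lo:.4g}; {hi:.4g})"
        rows[label] = cells
    onset_ref = ensemble.samples(reference, "cumulative_onset")
    pct = {}
    for scen in scens:
        if scen == reference:
            pct[scen] = "-"
            continue
        rel = 100.0 * (ensemble.samples(scen, "cumulative_onset") - onset_ref) / onset_ref
        pct[scen] = f"{rel.mean():+.1f}%"
    rows["Onset change vs reference (%)"] = pct
    return pd.DataFrame(rows).T


def echo(msg: str) -> None:
    print(msg, file=sys.stderr)
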