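"""End-to-end orchestration: simulate -> agreement maps -> fits -> ladder.

Everything downstream of the trial table is re-derivable from the trial
CSV alone; stimulus images are decorative. Runs are deterministic for a
fixed configuration (all seeds explicit, config hash recorded in the
report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .agreement_maps import agreement_matrix, plot_agreement
from .glmm import FitResult, fit_logistic_mixed, parametric_bootstrap_se
from .model_selection import compare_ladder, fit_model_ladder
from .stimulus_geometry import StimulusDesign
from .synthetic_respondents import (
    GROUPS,
    TRIAL_COLUMNS,
    RespondentModel,
    simulate_two_groups,
)

__all__ = [
    "TrialValidationError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "run_full_analysis",
    "parameter_recovery",
    "delta_recovery",
]

log = logging.getLogger("boubakit")


class TrialValidationError(ValueError):
    """Raised when a trial CSV violates the schema; names offending rows."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table to the canonical CSV schema (UTF-8, header)."""
    path = Path(path)
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False, encoding="utf-8")
    return path


def _bad_rows(mask: pd.Series, what: str) -> str:
    rows = (mask[mask].index + 2).tolist()  # +2: header line and 1-based lines
    head = ", ".join(map(str, rows[:5])) + (", ..." if len(rows) > 5 else "")
    return f"{what} at line(s) {head}"


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV; schema errors name the offending lines."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing column(s): {missing}")
    if df.empty:
        return df.loc[:, list(TRIAL_COLUMNS)]
    problems = []
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        problems.append(_bad_rows(bad_group, f"group not in {GROUPS}"))
    bad_resp = ~df["response"].isin([0, 1])
    if bad_resp.any():
        problems.append(_bad_rows(bad_resp, "response outside {0, 1}"))
    for col in ("frequency", "spikiness"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            problems.append(_bad_rows(bad, f"non-numeric {col}"))
    bad_amp = pd.to_numeric(df["amplitude"], errors="coerce").isna()
    if bad_amp.any():
        problems.append(_bad_rows(bad_amp, "non-numeric amplitude"))
    if problems:
        raise TrialValidationError("; ".join(problems))
    df["frequency"] = df["frequency"].astype(int)
    df["amplitude"] = df["amplitude"].astype(float)
    df["spikiness"] = df["spikiness"].astype(int)
    df["response"] = df["response"].astype(np.int8)
    return df.loc[:, list(TRIAL_COLUMNS)]


@dataclass
class RunConfig:
    """Full configuration of one end-to-end synthetic study run."""

    model_us: RespondentModel = field(default_factory=lambda: reference.US_MODEL)
    model_tw: RespondentModel = field(default_factory=lambda: reference.TW_MODEL)
    n_us: int = 150
    n_tw: int = 88
    seed: int = 1
    n_boot: int = 0
    bootstrap_seed: int = 1
    coding: str = "default"
    nodes: int = 15
    out_dir: str = "boubakit_run"
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("model_us", "model_tw"):
            if isinstance(d.get(key), dict):
                d[key] = RespondentModel(**d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Simulate both groups, then run every analysis stage in order.

    Writes ``trials.csv``, per-group agreement cell CSVs (and figures),
    per-group fit JSONs, the model-ladder JSON, and a consolidated
    ``report.json``. Returns the report as a dict.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: seed=%d n_us=%d n_tw=%d", config.seed, config.n_us, config.n_tw)
    trials = simulate_two_groups(
        config.model_us, config.model_tw, config.n_us, config.n_tw, seed=config.seed
    )
    write_trials(trials, out / "trials.csv")
    # Downstream stages re-read the CSV so every output is reproducible
    # from the trial file alone.
    trials = read_trials(out / "trials.csv")

    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "version": __version__,
        },
        "n_trials": int(len(trials)),
    }

    agreement = {}
    for grp in GROUPS:
        log.info("stage agreement: group=%s", grp)
        cells = agreement_matrix(trials, group=grp)
        cells.to_csv(out / f"agreement_{grp}.csv", index=False)
        if config.make_figures:
            plot_agreement(cells, out / f"agreement_{grp}.png")
        agreement[grp] = {
            "n_cells": int(len(cells)),
            "labels": cells["label"].value_counts().to_dict(),
        }
    report["agreement"] = agreement

    fits = {}
    for grp in GROUPS:
        log.info("stage fit: group=%s", grp)
        fit = fit_logistic_mixed(
            trials[trials["group"] == grp], "base",
            coding=config.coding, nodes=config.nodes,
        )
        if config.n_boot:
            parametric_bootstrap_se(fit, n_boot=config.n_boot, seed=config.bootstrap_seed)
            if fit.n_boot_dropped:
                log.warning("group %s: %d bootstrap replicates dropped", grp, fit.n_boot_dropped)
        log.info("group %s converged=%s logLik=%.1f", grp, fit.converged, fit.log_likelihood)
        (out / f"fit_{grp}.json").write_text(
            json.dumps(fit.to_dict(), indent=2), encoding="utf-8"
        )
        fits[grp] = fit.to_dict()
    report["group_fits"] = fits

    log.info("stage ladder")
    ladder = fit_model_ladder(trials, coding=config.coding, nodes=config.nodes)
    comparisons = compare_ladder(ladder)
    ladder_out = {
        "models": {m: f.to_dict() for m, f in ladder.items()},
        "comparisons": [dataclasses.asdict(c) for c in comparisons],
    }
    (out / "ladder.json").write_text(json.dumps(ladder_out, indent=2), encoding="utf-8")
    report["ladder"] = ladder_out

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    return report


# ---------------------------------------------------------------------------
# simulation studies (parameter recovery)


def parameter_recovery(
    model: RespondentModel,
    group: str = "US",
    n_participants: int = 150,
    n_replicates: int = 20,
    base_seed: int = 1,
    coding: str = "default",
    nodes: int = 15,
    design: StimulusDesign | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit study for the single-group base model.

    Returns one row per replicate with the recovered fixed effects and
    random-intercept SD; replicate r uses seed ``base_seed * 1000 + r``.
    """
    from .synthetic_respondents import simulate_group

    design = design or StimulusDesign()
    rows = []
    for r in range(1, n_replicates + 1):
        seed = base_seed * 1000 + r
        trials = simulate_group(model, n_participants, design, seed=seed, group=group)
        fit = fit_logistic_mixed(trials, "base", coding=coding, nodes=nodes)
        rows.append(
            {
                "replicate": r,
                "seed": seed,
                "converged": fit.converged,
                **fit.coefficients,
                "sigma_id": fit.variance_components["sigma_id"],
            }
        )
    return pd.DataFrame(rows)


def delta_recovery(
    model: RespondentModel,
    n_us: int = 150,
    n_tw: int = 88,
    n_replicates: int = 20,
    base_seed: int = 1,
    model_id: int = 3,
    coding: str = "default",
    nodes: int = 15,
) -> pd.DataFrame:
    """Simulate-and-refit study for a two-group ladder model (2 or 3)."""
    rows = []
    for r in range(1, n_replicates + 1):
        seed = base_seed * 1000 + r
        trials = simulate_two_groups(model, None, n_us, n_tw, seed=seed)
        fit = fit_logistic_mixed(trials, model_id, coding=coding, nodes=nodes)
        rows.append(
            {
                "replicate": r,
                "seed": seed,
                "converged": fit.converged,
                **fit.coefficients,
                **fit.variance_components,
            }
        )
    return pd.DataFrame(rows)
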