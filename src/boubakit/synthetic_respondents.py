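"""Synthetic two-alternative forced-choice respondents.

Generates trial-level Bouba/Kiki judgements from a logistic model with
participant random intercepts: each simulated participant sees every
condition of the factorial stimulus design once, in randomised order, and
responds "Kiki" (1) with probability

    P = logistic(beta0 + b_i + beta . x  [+ delta . x if US group])

where ``x`` are the coded stimulus predictors, ``b_i ~ N(0, sigma_id^2)``
is the participant's response bias, and the ``delta`` terms carry the
US-vs-Taiwan slope differences (Taiwan is the baseline group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stimulus_geometry import StimulusDesign

__all__ = [
    "CodingError",
    "RespondentModel",
    "GROUPS",
    "TRIAL_COLUMNS",
    "code_predictors",
    "code_matrix",
    "response_probability",
    "simulate_group",
    "simulate_two_groups",
]


class CodingError(ValueError):
    """Raised for an unknown predictor-coding tag."""


GROUPS = ("US", "TW")

#: Canonical trial CSV schema, in column order.
TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "frequency",
    "amplitude",
    "spikiness",
    "sound_order",
    "response",
)

CODINGS = ("default", "identity")


def code_predictors(
    frequency: float, amplitude: float, spikiness: float, coding: str = "default"
) -> tuple[float, float, float]:
    """Map raw design levels to the numeric predictors entering the model.

    The ``"default"`` coding leaves frequency (4-9) and spikiness (0, 1, 30)
    on their raw scales and rescales amplitude by 100 (0.1-0.4 -> 10-40),
    which is the unit system under which the published per-group slope
    magnitudes produce response probabilities spanning chance over the
    design. ``"identity"`` passes all three levels through unchanged.
    """
    if coding == "default":
        return (float(frequency), float(amplitude) * 100.0, float(spikiness))
    if coding == "identity":
        return (float(frequency), float(amplitude), float(spikiness))
    raise CodingError(f"unknown coding {coding!r}; expected one of {CODINGS}")


def code_matrix(trials: pd.DataFrame, coding: str = "default") -> np.ndarray:
    """Coded (frequency, amplitude, spikiness) columns for a trial table."""
    f = trials["frequency"].to_numpy(dtype=float)
    a = trials["amplitude"].to_numpy(dtype=float)
    s = trials["spikiness"].to_numpy(dtype=float)
    if coding == "default":
        a = a * 100.0
    elif coding != "identity":
        raise CodingError(f"unknown coding {coding!r}; expected one of {CODINGS}")
    return np.column_stack((f, a, s))


@dataclass(frozen=True)
class RespondentModel:
    """Generative logistic model for forced-choice Bouba/Kiki responses.

    Slopes are in logit units per coded predictor unit. The ``delta_*``
    terms are added to the corresponding slopes for the US group only
    (Taiwan baseline); they are zero for single-group models.
    """

    beta0: float
    beta_freq: float
    beta_amp: float
    beta_spike: float
    delta_freq: float = 0.0
    delta_amp: float = 0.0
    delta_spike: float = 0.0
    sigma_id: float = 1.0
    sigma_group: float = 0.0
    coding: str = "default"

    def __post_init__(self) -> None:
        if self.sigma_id < 0 or self.sigma_group < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if self.coding not in CODINGS:
            raise CodingError(f"unknown coding {self.coding!r}")

    def linear_predictor(
        self, coded: tuple[float, float, float], group: str, random_intercept: float = 0.0
    ) -> float:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
        us = 1.0 if group == "US" else 0.0
        f, a, s = coded
        return (
            self.beta0
            + random_intercept
            + (self.beta_freq + us * self.delta_freq) * f
            + (self.beta_amp + us * self.delta_amp) * a
            + (self.beta_spike + us * self.delta_spike) * s
        )


def response_probability(
    model: RespondentModel,
    coded: tuple[float, float, float],
    group: str = "US",
    random_intercept: float = 0.0,
) -> float:
    """P("Kiki") for one condition; inverse logit of the linear predictor."""
    from scipy.special import expit

    p = float(expit(model.linear_predictor(coded, group, random_intercept)))
    # expit is strictly inside (0, 1) for finite input; guard degenerate params.
    if not 0.0 < p < 1.0:
        raise ValueError("response probability left the open interval (0, 1)")
    return p


def _condition_logits(model: RespondentModel, design: StimulusDesign, group: str) -> np.ndarray:
    return np.array(
        [
            model.linear_predictor(code_predictors(f, a, s, model.coding), group)
            for f, a, s in design.conditions()
        ]
    )


def simulate_group(
    model: RespondentModel,
    n_participants: int,
    design: StimulusDesign | None = None,
    seed: int | np.random.Generator | None = None,
    group: str = "US",
    group_offset: float = 0.0,
) -> pd.DataFrame:
    """Simulate every participant's full pass through the design.

    Each participant receives one trial per design condition in an
    independently randomised order; sound presentation order alternates
    BK/KB across a participant's trials (counterbalanced, no effect in the
    model). Deterministic for a fixed integer seed.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    design = design or StimulusDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = np.array(design.conditions(), dtype=float)
    n_cond = len(conditions)
    logits = _condition_logits(model, design, group)

    b = rng.normal(0.0, model.sigma_id, size=n_participants)
    rows = []
    width = max(3, len(str(n_participants)))
    from scipy.special import expit

    for i in range(n_participants):
        order = rng.permutation(n_cond)
        p = expit(logits[order] + b[i] + group_offset)
        y = (rng.random(n_cond) < p).astype(np.int8)
        pid = f"{group}{i + 1:0{width}d}"
        for t in range(n_cond):
            f, a, s = conditions[order[t]]
            rows.append(
                (pid, group, int(f), float(a), int(s), "BK" if t % 2 == 0 else "KB", int(y[t]))
            )
    out = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    out["response"] = out["response"].astype(np.int8)
    return out


def simulate_two_groups(
    model_us: RespondentModel,
    model_tw: RespondentModel | None = None,
    n_us: int = 150,
    n_tw: int = 88,
    design: StimulusDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Concatenate a US and a Taiwanese simulated sample.

    With ``model_tw=None`` both groups share ``model_us``'s coefficients;
    group differences then come only from its ``delta_*`` terms (which act
    on the US group), so ``delta_* = 0`` gives an exchangeable null. If the
    shared model has ``sigma_group > 0`` a group-level intercept offset is
    drawn once per group.
    """
    design = design or StimulusDesign()
    rng = np.random.default_rng(seed)
    shared = model_tw is None
    model_tw = model_tw or model_us
    off_us = off_tw = 0.0
    sigma_g = model_us.sigma_group if shared else 0.0
    if sigma_g > 0:
        off_us, off_tw = rng.normal(0.0, sigma_g, size=2)
    us = simulate_group(model_us, n_us, design, rng, group="US", group_offset=off_us)
    tw = simulate_group(model_tw, n_tw, design, rng, group="TW", group_offset=off_tw)
    return pd.concat([us, tw], ignore_index=True)
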