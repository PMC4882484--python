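"""Per-condition agreement classification of Bouba/Kiki responses.

For every stimulus condition, pooled responses are tested against chance
(50%) with a one-degree-of-freedom Pearson chi-square goodness-of-fit
test; conditions with p < 0.05 are labelled "Kiki" or "Bouba" according to
the majority, otherwise "undetermined". Cells are reported with
significance bands at 0.05 / 0.01 / 0.001 and can be drawn as the familiar
red/white/blue matrix (one 6 x 4 frequency-by-amplitude panel per
spikiness level). An exact binomial test is available as an alternative.

The cell tests deliberately pool trials across participants (the
correlation-aware analysis lives in :mod:`boubakit.glmm`), and no
multiple-testing correction is applied: each cell is reported on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus_geometry import StimulusDesign

__all__ = [
    "AgreementCell",
    "chisq_against_chance",
    "exact_binomial_p",
    "significance_band",
    "classify_cell",
    "agreement_matrix",
    "two_proportion_compare",
    "plot_agreement",
]

LABELS = ("Bouba", "Kiki", "undetermined")
ALPHA = 0.05
_BANDS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass(frozen=True)
class AgreementCell:
    """Tally and chance-level test outcome for one stimulus condition."""

    condition: tuple[int, float, int]
    n: int
    kiki_count: int
    proportion_kiki: float
    chi2: float
    p_value: float
    label: str
    significance_band: str


def _check_counts(kiki_count: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= kiki_count <= n:
        raise ValueError(f"kiki_count must lie in [0, n={n}], got {kiki_count}")


def chisq_against_chance(kiki_count: int, n: int) -> tuple[float, float]:
    """Pearson chi-square (1 df) of a binary tally against 50:50 expectation.

    No continuity correction; the statistic reduces to ``(2k - n)^2 / n``.
    """
    _check_counts(kiki_count, n)
    chi2 = (2.0 * kiki_count - n) ** 2 / n
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def exact_binomial_p(kiki_count: int, n: int) -> float:
    """Two-sided exact binomial p-value against p=0.5 (oracle alternative)."""
    _check_counts(kiki_count, n)
    return float(stats.binomtest(kiki_count, n, 0.5).pvalue)


def significance_band(p_value: float) -> str:
    for cut, band in _BANDS:
        if p_value < cut:
            return band
    return "ns"


def classify_cell(
    kiki_count: int,
    n: int,
    condition: tuple[int, float, int] = (0, 0.0, 0),
    method: str = "chisq",
) -> AgreementCell:
    """Label one condition Bouba / Kiki / undetermined at alpha = 0.05."""
    if method == "chisq":
        chi2, p = chisq_against_chance(kiki_count, n)
    elif method == "binomial":
        chi2, _ = chisq_against_chance(kiki_count, n)
        p = exact_binomial_p(kiki_count, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    prop = kiki_count / n
    if p < ALPHA and prop > 0.5:
        label = "Kiki"
    elif p < ALPHA and prop < 0.5:
        label = "Bouba"
    else:
        label = "undetermined"
    return AgreementCell(
        condition=tuple(condition),
        n=n,
        kiki_count=int(kiki_count),
        proportion_kiki=prop,
        chi2=chi2,
        p_value=p,
        label=label,
        significance_band=significance_band(p),
    )


def agreement_matrix(
    trials: pd.DataFrame,
    group: str | None = None,
    design: StimulusDesign | None = None,
    method: str = "chisq",
) -> pd.DataFrame:
    """One classified cell per design condition, pooling trials across subjects.

    Returns a DataFrame with one row per (frequency, amplitude, spikiness)
    condition; conditions absent from the data are flagged ``missing`` with
    no fabricated statistics.
    """
    design = design or StimulusDesign()
    sub = trials if group is None else trials[trials["group"] == group]
    tallies = sub.groupby(["frequency", "amplitude", "spikiness"])["response"].agg(
        ["sum", "count"]
    )
    rows = []
    for cond in design.conditions():
        key = (cond[0], cond[1], cond[2])
        if key in tallies.index:
            k, n = int(tallies.loc[key, "sum"]), int(tallies.loc[key, "count"])
            cell = classify_cell(k, n, condition=cond, method=method)
            d = asdict(cell)
            d.pop("condition")
            rows.append({"frequency": cond[0], "amplitude": cond[1],
                         "spikiness": cond[2], "missing": False, **d})
        else:
            rows.append({"frequency": cond[0], "amplitude": cond[1], "spikiness": cond[2],
                         "missing": True, "n": 0, "kiki_count": 0,
                         "proportion_kiki": np.nan, "chi2": np.nan, "p_value": np.nan,
                         "label": "missing", "significance_band": "ns"})
    return pd.DataFrame(rows)


def two_proportion_compare(
    count1: int, n1: int, count2: int, n2: int
) -> tuple[float, float]:
    """2x2 contingency chi-square comparing two group proportions (no correction)."""
    _check_counts(count1, n1)
    _check_counts(count2, n2)
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]])
    if np.any(table.sum(axis=0) == 0):
        # Degenerate margin: all responses identical in both groups.
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


_BAND_ALPHA = {"p<0.001": 1.0, "p<0.01": 0.65, "p<0.05": 0.35, "ns": 0.0}


def plot_agreement(cells: pd.DataFrame, path: str | Path) -> Path:
    """Draw the red/white/blue agreement matrix, one panel per spikiness level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    spik = sorted(cells["spikiness"].unique())
    freqs = sorted(cells["frequency"].unique())
    amps = sorted(cells["amplitude"].unique())
    fig, axes = plt.subplots(1, len(spik), figsize=(4 * len(spik), 3.2), squeeze=False)
    for ax, s in zip(axes[0], spik):
        panel = cells[cells["spikiness"] == s]
        for _, row in panel.iterrows():
            i = freqs.index(row["frequency"])
            j = amps.index(row["amplitude"])
            if row["label"] == "Kiki":
                base = (0.13, 0.3, 0.89)
            elif row["label"] == "Bouba":
                base = (0.89, 0.16, 0.16)
            else:
                base = (1.0, 1.0, 1.0)
            alpha = _BAND_ALPHA.get(row["significance_band"], 0.0)
            face = tuple(1.0 - alpha * (1.0 - c) for c in base)
            ax.add_patch(Rectangle((i, j), 1, 1, facecolor=face, edgecolor="0.6"))
        ax.set_xlim(0, len(freqs))
        ax.set_ylim(0, len(amps))
        ax.set_xticks([i + 0.5 for i in range(len(freqs))], freqs)
        ax.set_yticks([j + 0.5 for j in range(len(amps))], amps)
        ax.set_xlabel("Frequency")
        ax.set_title(f"Spikiness {s}")
    axes[0][0].set_ylabel("Amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
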