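"""Dataset-level summary tables: accuracy, QE phase shares, per-participant
QE frequency, timing summaries and location proportions.

All summaries operate on tidy DataFrames (one row per trial or per QE
period) so they can be recomputed bit-identically from the event CSVs.
Rounding follows the printed-table conventions: accuracy as integers
(half-up), phase-share percents to 1 d.p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core import FINAL_THREE, PHASES


def round_half_up(x) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def accuracy_table(percent_table: pd.DataFrame) -> pd.DataFrame:
    """Append the per-participant multi-test average column and the column
    averages row to a participants x tests percent-accuracy table.

    Values are rounded half-up to integers, matching how shooting accuracy
    is conventionally printed.  Cells that are NaN (a participant with no
    trials for a test) stay empty and are excluded from the averages, with
    a warning.
    """
    tab = percent_table.astype(float).copy()
    if tab.isna().any().any():
        warnings.warn("accuracy table has empty cells; averages skip them")
    out = tab.copy()
    out[f"{len(tab.columns)}_test_average"] = tab.mean(axis=1, skipna=True)
    avg_row = out.mean(axis=0, skipna=True)
    out.loc["average"] = avg_row
    return out.map(lambda v: v if pd.isna(v) else round_half_up(v))


def accuracy_from_trials(trials: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Percent hits per participant per test/condition from trial metadata."""
    required = {"participant", "outcome", by}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing column(s): {sorted(missing)}")
    pct = (
        trials.assign(hit=lambda d: (d["outcome"] == "hit").astype(float))
        .pivot_table(index="participant", columns=by, values="hit", aggfunc="mean")
        * 100.0
    )
    return pct


@dataclass
class PhaseShareTable:
    """Counts and percents of QE periods per motor phase, plus the share of
    all fixations that qualified as a QE."""

    table: pd.DataFrame  # phase, n_qe, pct
    total_qe: int
    n_fixations: Optional[int]
    qe_share_of_fixations_pct: Optional[float]


def phase_share(
    qe: Optional[pd.DataFrame] = None,
    n_fixations: Optional[int] = None,
    *,
    counts: Optional[Mapping[str, int]] = None,
) -> PhaseShareTable:
    """Phase-share table from QE periods (or directly from printed counts).

    Percents are 100*count/total to 1 d.p. and sum to 100 up to rounding.
    """
    if counts is None:
        if qe is None:
            raise ValueError("provide either a QE table or counts")
        counts = qe["phase"].value_counts().to_dict()
    counts = {ph: int(counts.get(ph, 0)) for ph in PHASES}
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no QE periods; phase shares are all zero")
        pct = {ph: 0.0 for ph in PHASES}
    else:
        pct = {ph: round(100.0 * c / total, 1) for ph, c in counts.items()}
    table = pd.DataFrame(
        {"phase": list(PHASES), "n_qe": [counts[ph] for ph in PHASES],
         "pct": [pct[ph] for ph in PHASES]}
    )
    share = (
        round(100.0 * total / n_fixations, 2)
        if (n_fixations not in (None, 0))
        else None
    )
    return PhaseShareTable(
        table=table, total_qe=total, n_fixations=n_fixations,
        qe_share_of_fixations_pct=share,
    )


def qe_frequency(
    qe: pd.DataFrame,
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Mean QE count per trial, over all phases and over the final three
    shooting phases, by participant; the ``All`` row is the grand mean
    weighted by each participant's trial count.

    ``qe`` needs columns trial_id, phase; ``trials`` needs trial_id,
    participant (one row per trial, zero-QE trials included).
    """
    t = trials[["trial_id", "participant"]].drop_duplicates()
    counts_all = qe.groupby("trial_id").size()
    counts_f3 = qe[qe["phase"].isin(FINAL_THREE)].groupby("trial_id").size()
    t = t.assign(
        n_all=t["trial_id"].map(counts_all).fillna(0.0),
        n_final3=t["trial_id"].map(counts_f3).fillna(0.0),
    )
    per = (
        t.groupby("participant")[["n_all", "n_final3"]]
        .mean()
        .rename(columns={"n_all": "qe_freq_all_phases", "n_final3": "qe_freq_final3"})
    )
    per.loc["All"] = [t["n_all"].mean(), t["n_final3"].mean()]
    return per


def timing_summary(
    qe: pd.DataFrame,
    by: Sequence[str] = ("phase", "condition"),
) -> pd.DataFrame:
    """Group mean and standard error of QE onset/offset/duration (ms and %).

    SEs are computed across trials within each group (sd / sqrt(n)); groups
    with fewer than two periods report a missing SE.
    """
    metrics = [
        c
        for c in (
            "onset_ms", "offset_ms", "duration_ms",
            "onset_pct", "offset_pct", "duration_pct",
        )
        if c in qe.columns
    ]
    rows = []
    for key, g in qe.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(g)
        for mcol in metrics:
            row[f"{mcol}_mean"] = g[mcol].mean()
            row[f"{mcol}_se"] = (
                g[mcol].std(ddof=1) / math.sqrt(len(g)) if len(g) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(list(by)).reset_index(drop=True)


def location_probability(qe: pd.DataFrame) -> pd.DataFrame:
    """Observed hoop-centre vs non-centre proportion per phase, with Wilson
    95% confidence intervals for the hoop-centre proportion."""
    rows = []
    for phase, g in qe.groupby("phase"):
        n = len(g)
        k = int((g["location2"] == "hoop_centre").sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "phase": phase,
                "n": n,
                "p_hoop_centre": k / n,
                "p_non_centre": (n - k) / n,
                "ci95_low": lo,
                "ci95_high": hi,
            }
        )
    return pd.DataFrame(rows).sort_values("phase").reset_index(drop=True)


def plot_phase_mosaic(qe: pd.DataFrame, ax=None):
    """Stacked per-participant proportions of QE by phase (mosaic-style)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    share = (
        qe.groupby(["participant", "phase"]).size().unstack(fill_value=0)
        .reindex(columns=[p for p in PHASES], fill_value=0)
    )
    share = share.div(share.sum(axis=1), axis=0)
    bottom = np.zeros(len(share))
    for phase in share.columns:
        ax.bar(share.index, share[phase], bottom=bottom, label=phase)
        bottom += share[phase].to_numpy()
    ax.set_ylabel("proportion of QE periods")
    ax.legend(fontsize=7)
    return ax
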