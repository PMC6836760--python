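"""Inference on QE counts and trial metrics.

Two procedures ship with the pipeline:

* a Pearson chi-square goodness-of-fit test of QE counts against a
  hypothesized phase allocation (e.g. equal 25% per shooting phase);
* a stratified permutation contrast for condition/outcome effects on a
  per-trial metric.  Labels are permuted within participant strata, which
  respects the repeated-measures structure of the design without fitting a
  mixed model; the two-sided p-value uses the add-one correction
  ``p = (1 + #{|null| >= |obs|}) / (1 + n_perm)`` so it can never be zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray


@dataclass
class PermutationResult:
    observed_difference: float
    p_value: float
    n_permutations: int
    seed: int
    null_mean: float
    null_sd: float
    n_used: int
    excluded_strata: list = field(default_factory=list)


def chisq_gof(
    counts: Sequence[float],
    expected_proportions: Optional[Sequence[float]] = None,
) -> ChiSquareResult:
    """Pearson goodness-of-fit: statistic sum (O-E)^2 / E, df = k - 1."""
    obs = np.asarray(counts, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    k = obs.shape[0]
    if expected_proportions is None:
        props = np.full(k, 1.0 / k)
    else:
        props = np.asarray(expected_proportions, dtype=float)
        if props.shape[0] != k:
            raise ValueError("expected_proportions length mismatch")
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("expected_proportions must sum to 1")
    expected = total * props
    if np.any((expected == 0) & (obs > 0)):
        raise ValueError("observed count in a cell with zero expected probability")
    mask = expected > 0
    statistic = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    df = k - 1
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        expected_counts=expected,
    )


def chisq_statistic_batch(counts: np.ndarray, props: np.ndarray) -> np.ndarray:
    """Vectorized Pearson statistic for an (m, k) array of count vectors."""
    totals = counts.sum(axis=1, keepdims=True)
    expected = totals * props
    return np.sum((counts - expected) ** 2 / expected, axis=1)


def permutation_contrast(
    values: Sequence[float],
    groups: Sequence,
    strata: Optional[Sequence] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided stratified permutation test of a two-group mean difference.

    The observed statistic is mean(second group) - mean(first group) with
    groups ordered by sorted label.  Under the null, group labels are
    shuffled independently within each stratum (participant).  Strata that
    contain only one group label carry no information about the contrast
    and are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("metric values must be finite")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.shape[0] != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels.tolist()}")
    if strata is None:
        strata = np.zeros(values.shape[0], dtype=int)
    strata = np.asarray(strata)

    keep = np.ones(values.shape[0], dtype=bool)
    excluded = []
    for s in np.unique(strata):
        m = strata == s
        if np.unique(groups[m]).shape[0] < 2:
            keep &= ~m
            excluded.append(s)
    if excluded:
        warnings.warn(
            f"{len(excluded)} stratum/strata with a single group label excluded"
        )
    values, groups, strata = values[keep], groups[keep], strata[keep]
    if values.size == 0:
        raise ValueError("no informative strata remain")

    is_b = groups == labels[1]
    observed = float(values[is_b].mean() - values[~is_b].mean())

    rng = np.random.default_rng(seed)
    strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    null = np.empty(n_perm)
    perm_b = is_b.copy()
    for i in range(n_perm):
        for idx in strata_idx:
            perm_b[idx] = is_b[idx][rng.permutation(idx.shape[0])]
        null[i] = values[perm_b].mean() - values[~perm_b].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(
        observed_difference=observed,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else float("nan"),
        n_used=int(values.size),
        excluded_strata=excluded,
    )
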