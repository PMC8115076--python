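"""Condition-level statistics: Pearson chi-squared homogeneity tests on
correct/incorrect counts and binomial proportion confidence intervals.

The chi-squared statistic is computed from the textbook formula
``sum (O - E)^2 / E`` on the conditions x {correct, incorrect} table with
``df = #conditions - 1`` and *no* continuity correction; the no-correction
choice is what reproduces the published pooled masking-experiment statistics
from their printed proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ConditionCounts:
    """Correct/total trial counts for one experimental condition."""

    condition: str
    n_correct: int
    n_trials: int

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("need 0 <= n_correct <= n_trials")


def counts_from_proportion(condition: str, proportion: float,
                           n_trials: int) -> ConditionCounts:
    """Integer counts from a (possibly rounded) printed proportion."""
    return ConditionCounts(condition, int(round(proportion * n_trials)), n_trials)


def chi2_homogeneity(counts: Sequence[ConditionCounts]):
    """Pearson chi-squared test of equal proportions across conditions.

    Returns ``(statistic, df, p)`` for the ``k x 2`` table of correct and
    incorrect counts, ``df = k - 1``.  Raises if fewer than two conditions
    are given, any condition has zero trials, or an expected cell count is
    zero (all trials correct, or all incorrect, overall).
    """
    if len(counts) < 2:
        raise ValueError("need at least two conditions")
    obs = np.array([[c.n_correct, c.n_trials - c.n_correct] for c in counts],
                   dtype=float)
    if np.any(obs.sum(axis=1) == 0):
        raise ValueError("every condition needs at least one trial")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell count; test undefined")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    return stat, df, float(chi2_dist.sf(stat, df))


def binomial_ci(n_correct: int, n_trials: int, level: float = 0.95,
                method: str = "wilson") -> tuple[float, float]:
    """Two-sided binomial proportion confidence interval.

    The default is the Wilson score interval; ``method="clopper-pearson"``
    gives the exact interval.  The interval always contains the point
    estimate.
    """
    if not 0 <= n_correct <= n_trials or n_trials <= 0:
        raise ValueError("need 0 <= n_correct <= n_trials, n_trials > 0")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(n_correct, n_trials, alpha=1 - level,
                                method=sm_method)
    return float(lo), float(hi)


def load_pooled_reference() -> dict:
    """Bundled pooled proportions and design counts of the published masking
    experiment (nine observers, 200 trials per condition, 100 per congruent
    phase)."""
    with resources.files("ltbseg.data").joinpath(
            "pooled_proportions.json").open() as fh:
        return json.load(fh)


def pooled_reference_chi2() -> dict:
    """Recompute the five pooled chi-squared statistics from the bundled
    reference proportions.

    Returns a mapping from comparison name to ``(statistic, df, p)``.
    """
    ref = load_pooled_reference()
    props = ref["pooled_proportion_correct"]
    n_cond = ref["design"]["n_observers"] * ref["design"]["trials_per_condition"]
    n_phase = ref["design"]["n_observers"] * ref["design"]["trials_per_phase"]
    n_of = {"neu": n_cond, "con": n_cond, "inc": n_cond,
            "con_0": n_phase, "con_180": n_phase}
    out = {}
    for comp in ref["comparisons"]:
        counts = [counts_from_proportion(c, props[c], n_of[c])
                  for c in comp["conditions"]]
        out[comp["name"]] = chi2_homogeneity(counts)
    return out
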