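"""Measurement stage: matching fidelity, logistic-regression equivalence,
and the reward-stratified conditional-dependence score.

All R-squared quantities here are squared Pearson correlations (not
1 - SSE/SST), so they are invariant to affine rescaling of either argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sps

from .cue_world import CUES, PATTERN_BITS, TrainingSet
from .learner import Perceptron

__all__ = [
    "LogisticFit",
    "DependenceScore",
    "empirical_pattern_frequencies",
    "matching_r2",
    "fit_logistic",
    "structure_fit_r2",
    "conditional_dependence",
    "weight_to_odds_ratio",
]

PARAM_NAMES = ("intercept",) + CUES

# |coefficient| beyond this on the log-odds scale signals quasi-separation
# (fitted odds beyond ~e15 are not identifiable from 1600 Bernoulli trials)
_SEPARATION_BOUND = 15.0


def empirical_pattern_frequencies(ts: TrainingSet) -> np.ndarray:
    """Observed reward rate of each of the 16 configurations, in enumeration
    order — the 'actual probabilities' a trained unit is judged against."""
    counts = np.bincount(ts.pattern_indices, minlength=16)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"configurations {missing} absent from training set")
    rewarded = np.bincount(ts.pattern_indices, weights=ts.targets, minlength=16)
    return rewarded / counts


def matching_r2(responses: Sequence[float], actual: Sequence[float]) -> float:
    """Squared Pearson correlation between a unit's pattern responses and the
    observed per-pattern reward rates."""
    x = np.asarray(responses, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("responses and actual must be equal-length 1-D vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LogisticFit:
    """Main-effects Bernoulli logistic MLE for a training set.

    ``coefficients`` is indexed (intercept, a, b, x, y) on the log-odds
    scale, directly comparable with a trained unit's (bias, weights).
    ``log_likelihood`` is that of the grouped-binomial form (identical to the
    row-level Bernoulli likelihood up to an additive constant).
    """

    coefficients: pd.Series
    bse: pd.Series
    log_likelihood: float
    converged: bool
    iterations: int
    separation_suspected: bool = False

    def params(self) -> np.ndarray:
        return self.coefficients.to_numpy()

    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients.drop("intercept"))


def fit_logistic(ts: TrainingSet, maxiter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Fit logit P(reward) = b0 + b_a a + b_b b + b_x x + b_y y by IRLS.

    The fit is grouped by configuration (16 binomial cells), which has the
    same likelihood as the row-level Bernoulli fit up to a constant.  No
    interaction terms are included: the model embodies the same independence
    assumption as the four-input unit.  Quasi-separation (coefficients
    running away) is flagged rather than iterated on.
    """
    if ts.targets.min() == ts.targets.max():
        raise ValueError("degenerate training set: only one target value present")
    counts = np.bincount(ts.pattern_indices, minlength=16).astype(float)
    successes = np.bincount(ts.pattern_indices, weights=ts.targets, minlength=16)
    present = counts > 0
    endog = np.column_stack([successes, counts - successes])[present]
    exog = sm.add_constant(PATTERN_BITS, prepend=True)[present]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / convergence warnings handled below
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
    params = np.asarray(res.params)
    separated = bool(np.abs(params).max() > _SEPARATION_BOUND)
    converged = bool(getattr(res, "converged", True)) and not separated
    return LogisticFit(
        coefficients=pd.Series(params, index=PARAM_NAMES),
        bse=pd.Series(np.asarray(res.bse), index=PARAM_NAMES),
        log_likelihood=float(res.llf),
        converged=converged,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", maxiter))
        if hasattr(res, "fit_history")
        else maxiter,
        separation_suspected=separated,
    )


def structure_fit_r2(p: Perceptron, fit: LogisticFit) -> float:
    """Squared Pearson correlation of the five structural parameters of the
    unit (bias, w_a..w_y) with the five MLE coefficients (intercept, slopes)."""
    if not fit.converged:
        raise ValueError("logistic fit did not converge; structure comparison unreliable")
    return matching_r2(p.params(), fit.params())


@dataclass
class DependenceScore:
    """Reward-stratified chi-square pair measuring conditional dependence
    between a cue pair.  ``total`` is the operational dependence measure:
    larger means the pair's joint state carries more reward information than
    the two cues do independently."""

    chi2_rewarded: float
    chi2_unrewarded: float

    @property
    def total(self) -> float:
        return self.chi2_rewarded + self.chi2_unrewarded


def _chi2_2x2(table: np.ndarray) -> float:
    """Uncorrected Pearson chi-square of independence; zero-margin tables
    (or an empty stratum) contribute 0 by convention."""
    if table.sum() == 0:
        return 0.0
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0
    stat, _, _, _ = _sps.chi2_contingency(table, correction=False)
    return float(stat)


def conditional_dependence(
    ts: TrainingSet, cue_pair: tuple[str, str] = ("x", "y")
) -> DependenceScore:
    """Sum of the Pearson chi-squares of the 2x2 (cue u) x (cue v) count
    tables built separately among rewarded and unrewarded trials, collapsing
    over all other cues."""
    iu, iv = (CUES.index(c) for c in cue_pair)
    bits = PATTERN_BITS[ts.pattern_indices]
    u = bits[:, iu].astype(int)
    v = bits[:, iv].astype(int)
    scores = []
    for stratum in (1, 0):
        mask = ts.targets == stratum
        table = np.zeros((2, 2))
        np.add.at(table, (u[mask], v[mask]), 1.0)
        scores.append(_chi2_2x2(table))
    return DependenceScore(chi2_rewarded=scores[0], chi2_unrewarded=scores[1])


def weight_to_odds_ratio(weight: float) -> float:
    """exp(weight): the multiplicative change in reward odds attributable to
    the cue's presence, other cues held constant."""
    if not np.isfinite(weight):
        raise ValueError("weight must be finite")
    return float(np.exp(weight))
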