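"""Model/Results interface over the delta-rule learner.

`PerceptronModel` binds a training set to a training configuration;
`fit()` runs stochastic training and returns a `PerceptronResults` carrying
the learned structure, the response trajectory, matching diagnostics, and
the equivalent logistic-regression MLE (whose asymptotic standard errors
serve as the uncertainty scale of the estimates, since the SGD iterate
fluctuates around that MLE at a constant learning rate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as cstats
from .cue_world import (
    CUES,
    PATTERNS,
    RewardModel,
    TrainingSet,
    population_probabilities,
)
from .learner import Perceptron, TrainingConfig, TrajectoryRecord, train

__all__ = ["PerceptronModel", "PerceptronResults"]


class PerceptronModel:
    """A four-input logistic unit to be trained on a multi-cue reward sample.

    Parameters
    ----------
    training_set : TrainingSet
        The (pattern, reward) sample; see `cue_world.generate_training_set`.
    config : TrainingConfig, optional
        Training hyperparameters; keyword overrides are applied on top,
        e.g. ``PerceptronModel(ts, epochs=250, seed=7)``.
    """

    def __init__(self, training_set: TrainingSet, config: Optional[TrainingConfig] = None, **overrides):
        if config is None:
            config = TrainingConfig()
        if overrides:
            config = replace(config, **overrides)
        self.training_set = training_set
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        reward_model: RewardModel,
        seed: int = 0,
        **overrides,
    ) -> "PerceptronModel":
        """Build from an ``a,b,x,y,target`` frame (e.g. a stored CSV)."""
        bits = df[list(CUES)].to_numpy(dtype=np.int64)
        idx = bits[:, 0] * 8 + bits[:, 1] * 4 + bits[:, 2] * 2 + bits[:, 3]
        replicates = int(np.bincount(idx, minlength=16).max())
        ts = TrainingSet(
            pattern_indices=idx,
            targets=df["target"].to_numpy(dtype=np.int64),
            replicates=replicates,
            model=reward_model,
            seed=seed,
        )
        return cls(ts, **overrides)

    def fit(self, seed: Optional[int] = None) -> "PerceptronResults":
        """Train and return results; ``seed`` overrides the config seed."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        perceptron, trajectory = train(self.training_set, config)
        return PerceptronResults(self, config, perceptron, trajectory)


@dataclass
class PerceptronResults:
    """Trained-unit estimates, trajectory, and matching diagnostics."""

    model: PerceptronModel
    config: TrainingConfig
    perceptron: Perceptron
    trajectory: TrajectoryRecord

    @property
    def params(self) -> pd.Series:
        """(bias, w_a, w_b, w_x, w_y) on the log-odds scale."""
        return pd.Series(self.perceptron.params(), index=cstats.PARAM_NAMES)

    @property
    def bse(self) -> pd.Series:
        """Asymptotic standard errors of the equivalent logistic MLE."""
        return self.logistic_fit.bse

    @cached_property
    def responses(self) -> np.ndarray:
        from .learner import respond_all

        return respond_all(self.perceptron)

    @cached_property
    def actual_probabilities(self) -> np.ndarray:
        """Observed per-pattern reward rates of the training set."""
        return cstats.empirical_pattern_frequencies(self.model.training_set)

    @cached_property
    def logistic_fit(self) -> cstats.LogisticFit:
        return cstats.fit_logistic(self.model.training_set)

    @property
    def matching_r2(self) -> float:
        """Squared correlation of the 16 responses with observed rates."""
        return cstats.matching_r2(self.responses, self.actual_probabilities)

    @property
    def population_matching_r2(self) -> float:
        """Secondary diagnostic: matching against population probabilities."""
        pop = population_probabilities(self.model.training_set.model)
        return cstats.matching_r2(self.responses, pop)

    @property
    def structure_r2(self) -> float:
        """Squared correlation of (bias, weights) with the MLE coefficients."""
        return cstats.structure_fit_r2(self.perceptron, self.logistic_fit)

    @property
    def no_cue_response(self) -> float:
        """Response to the all-cues-absent pattern."""
        return float(self.responses[0])

    @property
    def odds_ratios(self) -> pd.Series:
        """exp(weight) per cue: multiplicative effect on reward odds."""
        return np.exp(self.params.drop("intercept"))

    def comparison_table(self) -> pd.DataFrame:
        """Per-pattern observed rate vs trained response (worked-example style)."""
        return pd.DataFrame(
            {
                "pattern": [p.label for p in PATTERNS],
                "actual_probability": self.actual_probabilities,
                "network_response": self.responses,
            }
        )

    def summary(self) -> str:
        """Plain-text summary of structure, equivalence and matching."""
        from statsmodels.iolib.table import SimpleTable

        fit = self.logistic_fit
        rows = [
            [
                name,
                f"{self.params[name]:.4f}",
                f"{fit.coefficients[name]:.4f}",
                f"{fit.bse[name]:.4f}",
                f"{np.exp(self.params[name]):.3f}",
            ]
            for name in cstats.PARAM_NAMES
        ]
        tbl = SimpleTable(
            rows,
            headers=["param", "trained", "logistic MLE", "MLE std err", "odds ratio"],
            title="Logistic perceptron (delta rule) vs logistic regression",
        )
        lines = [
            str(tbl),
            "",
            f"n trials: {self.model.training_set.n_rows}"
            f"   epochs: {self.config.epochs}   eta: {self.config.learning_rate}"
            f"   loss: {self.config.loss}   seed: {self.config.seed}",
            f"matching R2 (observed rates): {self.matching_r2:.4f}",
            f"structure R2 (vs MLE coefficients): {self.structure_r2:.4f}",
            f"no-cue response: {self.no_cue_response:.4f}",
        ]
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Response-vs-epoch curves for all 16 patterns (see plotting)."""
        from .plotting import plot_trajectory

        return plot_trajectory(self.trajectory, ax=ax)
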