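"""Single logistic output unit trained by the per-pattern delta rule.

The unit computes a = sigmoid(sum_i w_i x_i + theta) over the four binary cue
inputs and is trained by stochastic gradient descent: after every trial the
weights move by eta * delta * x and the bias by eta * delta, where delta is
(t - a) for the cross-entropy (Bernoulli log-likelihood) gradient — the
default, since it is what makes the trained unit converge on the logistic
regression MLE — or (t - a) * a * (1 - a) for the squared-error gradient.

The epoch loop presents all trials in a fresh uniform permutation each epoch.
The inner loop is numba-compiled; permutations are drawn by a numpy Generator
on the Python side and handed to the kernel in chunks, so training is a pure
deterministic function of (training set, config) that the pure-Python
reference path (`update_step` in a loop) reproduces bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .cue_world import CUES, PATTERN_BITS, PATTERNS, CuePattern, TrainingSet

__all__ = [
    "Perceptron",
    "TrainingConfig",
    "TrajectoryRecord",
    "TrainingDivergedError",
    "activate",
    "update_step",
    "respond_all",
    "train",
    "default_record_epochs",
]

_LOSSES = ("cross_entropy", "squared_error")


class TrainingDivergedError(RuntimeError):
    """Raised when a weight or the bias becomes non-finite during training."""

    def __init__(self, epoch: int, row: int):
        self.epoch = epoch
        self.row = row
        super().__init__(
            f"non-finite parameters at epoch {epoch}, row {row} of the shuffled order"
        )


@dataclass(frozen=True)
class Perceptron:
    """Connection weights and bias of the logistic unit, on the log-odds scale."""

    weights: dict[str, float]
    bias: float = 0.0

    def __post_init__(self) -> None:
        w = {c: float(self.weights.get(c, 0.0)) for c in CUES}
        if not all(np.isfinite(list(w.values()))) or not np.isfinite(self.bias):
            raise ValueError("weights and bias must be finite")
        object.__setattr__(self, "weights", w)

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[c] for c in CUES])

    def params(self) -> np.ndarray:
        """(bias, w_a, w_b, w_x, w_y) — aligned with logistic-regression
        coefficients (intercept, slopes)."""
        return np.concatenate(([self.bias], self.weight_vector()))

    @classmethod
    def from_vector(cls, weights: Sequence[float], bias: float) -> "Perceptron":
        return cls(weights=dict(zip(CUES, map(float, weights))), bias=float(bias))

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {"weights": self.weights, "bias": self.bias, **extra}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Perceptron":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        return cls(weights=data["weights"], bias=data["bias"])


def default_record_epochs(epochs: int) -> tuple[int, ...]:
    """Early dense then sparse recording schedule: 1, 5, 10, 15, 20, 25, 50,
    75, 100, then every 100 epochs, always including the final epoch."""
    sched = [e for e in (1, 5, 10, 15, 20, 25, 50, 75, 100) if e <= epochs]
    sched += list(range(200, epochs + 1, 100))
    if epochs not in sched:
        sched.append(epochs)
    return tuple(sorted(set(sched)))


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of a training run.

    learning_rate : step size eta of the delta rule (default 0.05).
    epochs : full passes over the training set (default 2500).
    init_half_range : weights start uniform in +/- this value; bias starts at 0.
    loss : 'cross_entropy' (default) or 'squared_error' gradient.
    seed : drives two independent streams (weight init, epoch permutations).
    record_epochs : epochs after which the 16 pattern responses are stored.
    """

    learning_rate: float = 0.05
    epochs: int = 2500
    init_half_range: float = 0.1
    loss: str = "cross_entropy"
    seed: int = 0
    record_epochs: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.init_half_range < 0:
            raise ValueError("init_half_range must be nonnegative")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}, got {self.loss!r}")
        if self.record_epochs is not None:
            rec = tuple(sorted(set(int(e) for e in self.record_epochs)))
            if rec and (rec[0] < 1 or rec[-1] > self.epochs):
                raise ValueError("record_epochs must lie within [1, epochs]")
            object.__setattr__(self, "record_epochs", rec)

    def resolved_record_epochs(self) -> tuple[int, ...]:
        if self.record_epochs is not None:
            return self.record_epochs
        return default_record_epochs(self.epochs)

    @classmethod
    def fast(cls, **kw) -> "TrainingConfig":
        """250-epoch profile; matching performance is statistically
        indistinguishable from the 2500-epoch default because the unit
        reaches its matching plateau within the first ~50 epochs."""
        kw.setdefault("epochs", 250)
        return cls(**kw)


@dataclass
class TrajectoryRecord:
    """Responses to all 16 patterns recorded after selected epochs."""

    epochs: np.ndarray  # (k,) int
    responses: np.ndarray  # (k, 16) float, each in (0, 1)

    def __getitem__(self, epoch: int) -> np.ndarray:
        pos = np.flatnonzero(self.epochs == epoch)
        if pos.size == 0:
            raise KeyError(f"epoch {epoch} was not recorded")
        return self.responses[pos[0]]

    def mean_response(self, min_epoch: int = 0) -> np.ndarray:
        """Responses averaged over recorded epochs >= ``min_epoch``.

        With a constant learning rate the per-epoch snapshot jitters around
        the maintained response level (jitter grows with eta); the late-time
        average is the stable summary of the matching behavior.
        """
        mask = self.epochs >= min_epoch
        if not mask.any():
            raise ValueError(f"no recorded epochs at or after {min_epoch}")
        return self.responses[mask].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = ["R|" + p.label for p in PATTERNS]
        df = pd.DataFrame(self.responses, columns=cols)
        df.insert(0, "epoch", self.epochs)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sigmoid(z: float) -> float:
    # stable two-branch logistic; never returns exactly 0 or 1 for finite z
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


def activate(p: Perceptron, pattern: CuePattern) -> float:
    """Logistic response a = sigmoid(w . x + theta), strictly in (0, 1)."""
    net = float(np.dot(p.weight_vector(), pattern.as_tuple()))
    return _sigmoid(net + p.bias)


def update_step(
    p: Perceptron, pattern: CuePattern, target: int, config: TrainingConfig
) -> Perceptron:
    """One delta-rule update after presenting (pattern, target).

    Weights of absent cues are untouched; the bias always moves with delta.
    """
    a = activate(p, pattern)
    err = target - a
    delta = err if config.loss == "cross_entropy" else err * a * (1.0 - a)
    step = config.learning_rate * delta
    w = {c: p.weights[c] + step * pattern[c] for c in CUES}
    return Perceptron(weights=w, bias=p.bias + step)


def respond_all(p: Perceptron) -> np.ndarray:
    """Responses to all 16 patterns, in enumeration order."""
    net = PATTERN_BITS @ p.weight_vector() + p.bias
    out = np.empty(16)
    for i in range(16):
        out[i] = _sigmoid(net[i])
    return out


@njit(cache=True)
def _sgd_chunk(bits, row_pattern, targets, order, w, bias, eta, use_ce,
               first_epoch, rec_epochs, rec_out, rec_start):
    """Run len(order) epochs of per-pattern SGD in place.

    order : (chunk_epochs, n_rows) presentation permutations
    rec_epochs : sorted 1-based epochs to record; rec_out : (k, 16) output
    Returns (status, epoch, row, bias, n_recorded): status 0 = ok, 1 = diverged.
    """
    n_rows = row_pattern.shape[0]
    rec_ptr = rec_start
    for e in range(order.shape[0]):
        epoch = first_epoch + e
        for r in range(n_rows):
            row = order[e, r]
            pi = row_pattern[row]
            net = bias
            for j in range(4):
                net += w[j] * bits[pi, j]
            if net >= 0.0:
                a = 1.0 / (1.0 + np.exp(-net))
            else:
                ez = np.exp(net)
                a = ez / (1.0 + ez)
            err = targets[row] - a
            if use_ce:
                delta = err
            else:
                delta = err * a * (1.0 - a)
            step = eta * delta
            bias += step
            for j in range(4):
                w[j] += step * bits[pi, j]
            if not np.isfinite(bias):
                return 1, epoch, r, bias, rec_ptr
        if rec_ptr < rec_epochs.shape[0] and rec_epochs[rec_ptr] == epoch:
            for i in range(16):
                net = bias
                for j in range(4):
                    net += w[j] * bits[i, j]
                if net >= 0.0:
                    rec_out[rec_ptr, i] = 1.0 / (1.0 + np.exp(-net))
                else:
                    ez = np.exp(net)
                    rec_out[rec_ptr, i] = ez / (1.0 + ez)
            rec_ptr += 1
    return 0, 0, 0, bias, rec_ptr


_CHUNK_EPOCHS = 500


def train(
    ts: TrainingSet, config: TrainingConfig | None = None
) -> tuple[Perceptron, TrajectoryRecord]:
    """Train a fresh unit on ``ts`` and record its response trajectory.

    Weight initialisation and epoch shuffling use two independent RNG streams
    spawned from ``config.seed``, so either can be varied alone.  Responses
    are recorded after the listed epochs complete (never mid-epoch).
    """
    if config is None:
        config = TrainingConfig()
    if ts.n_rows == 0:
        raise ValueError("training set is empty")

    init_ss, shuffle_ss = np.random.SeedSequence(config.seed).spawn(2)
    init_rng = np.random.default_rng(init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)

    w = init_rng.uniform(-config.init_half_range, config.init_half_range, size=4)
    bias = 0.0

    rec_epochs = np.asarray(config.resolved_record_epochs(), dtype=np.int64)
    rec_out = np.empty((len(rec_epochs), 16))
    rec_ptr = 0

    row_pattern = ts.pattern_indices.astype(np.int64)
    targets = ts.targets.astype(np.float64)
    n = ts.n_rows

    epoch = 1
    while epoch <= config.epochs:
        chunk = min(_CHUNK_EPOCHS, config.epochs - epoch + 1)
        order = np.empty((chunk, n), dtype=np.int64)
        for e in range(chunk):
            order[e] = shuffle_rng.permutation(n)
        status, bad_epoch, bad_row, bias, rec_ptr = _sgd_chunk(
            PATTERN_BITS,
            row_pattern,
            targets,
            order,
            w,
            bias,
            config.learning_rate,
            config.loss == "cross_entropy",
            epoch,
            rec_epochs,
            rec_out,
            rec_ptr,
        )
        if status != 0:
            raise TrainingDivergedError(epoch=bad_epoch, row=bad_row)
        epoch += chunk

    p = Perceptron.from_vector(w, bias)
    return p, TrajectoryRecord(epochs=rec_epochs.copy(), responses=rec_out)
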