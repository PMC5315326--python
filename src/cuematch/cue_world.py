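"""Stochastic multi-cue reward worlds and the training sets sampled from them.

The environment consists of four binary cues (A, B, X, Y).  Each trial presents
one of the 16 possible cue configurations; each active *reward source* (an
independently paying cue, a logical AND/XOR gate over a cue pair, or a no-cue
baseline lottery) fires an independent Bernoulli lottery, and the trial is
rewarded if at least one lottery fires.  Reward is granted at most once per
trial, so the reward probability of a configuration is the union probability

    P(reward | pattern) = 1 - prod_s (1 - p_s)

over the sources *s* active for that pattern, which for two sources is the
familiar addition rule P(A or B) = P(A) + P(B) - P(A)P(B).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

CUES: tuple[str, ...] = ("a", "b", "x", "y")

__all__ = [
    "CUES",
    "CuePattern",
    "PATTERNS",
    "pattern_index",
    "Gate",
    "RewardModel",
    "TrainingSet",
    "expected_reward_probability",
    "population_probabilities",
    "generate_training_set",
    "generate_validated_training_set",
    "validate_training_set",
    "ValidationReport",
]


@dataclass(frozen=True, order=True)
class CuePattern:
    """One of the 16 presence/absence configurations of cues A, B, X, Y."""

    a: int
    b: int
    x: int
    y: int

    def __post_init__(self) -> None:
        for cue in CUES:
            v = getattr(self, cue)
            if v not in (0, 1):
                raise ValueError(f"cue {cue!r} must be 0 or 1, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.x, self.y)

    def __getitem__(self, cue: str) -> int:
        return getattr(self, cue)

    @property
    def label(self) -> str:
        """Tilde notation, e.g. ``~A~BXY`` for pattern (0, 0, 1, 1)."""
        return "".join(
            c.upper() if getattr(self, c) else "~" + c.upper() for c in CUES
        )

    @property
    def index(self) -> int:
        return pattern_index(self)


def pattern_index(p: CuePattern) -> int:
    """Position of a pattern in the fixed enumeration (A is the most
    significant bit, Y the least, i.e. binary counting 0000..1111)."""
    return (p.a << 3) | (p.b << 2) | (p.x << 1) | p.y


#: All 16 cue configurations in fixed enumeration order.
PATTERNS: tuple[CuePattern, ...] = tuple(
    CuePattern(*bits) for bits in itertools.product((0, 1), repeat=4)
)

#: (16, 4) float design matrix of the enumeration, columns ordered (a, b, x, y).
PATTERN_BITS: np.ndarray = np.array([p.as_tuple() for p in PATTERNS], dtype=float)


def _check_prob(p: float, what: str) -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{what} must lie in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class Gate:
    """An interaction reward source: a lottery with probability ``prob`` that
    is armed only when a logical condition on a cue pair holds.

    ``kind='and'`` arms when both cues are present; ``kind='xor'`` arms when
    exactly one is.  XOR makes the reward structure linearly nonseparable.
    """

    kind: str
    prob: float
    cues: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        if self.kind not in ("and", "xor"):
            raise ValueError(f"gate kind must be 'and' or 'xor', got {self.kind!r}")
        _check_prob(self.prob, "gate prob")
        if len(set(self.cues)) != 2 or any(c not in CUES for c in self.cues):
            raise ValueError(f"gate cues must be two distinct cue labels, got {self.cues!r}")

    def fires(self, pattern: CuePattern) -> bool:
        u, v = (pattern[c] for c in self.cues)
        return bool(u and v) if self.kind == "and" else bool(u ^ v)


@dataclass(frozen=True)
class RewardModel:
    """Population reward structure.

    Parameters
    ----------
    independent_probs
        Map cue label -> reward probability for cues that pay independently.
        Cues participating in the gate must not appear here.
    gate
        Optional AND/XOR interaction source over a cue pair.
    baseline_prob
        Reward probability of the all-cues-absent pattern only; it is not a
        background lottery running on every trial.
    """

    independent_probs: Mapping[str, float]
    gate: Optional[Gate] = None
    baseline_prob: float = 0.0

    def __post_init__(self) -> None:
        probs = dict(self.independent_probs)
        for cue, p in probs.items():
            if cue not in CUES:
                raise ValueError(f"unknown cue label {cue!r}")
            _check_prob(p, f"probability for cue {cue!r}")
        _check_prob(self.baseline_prob, "baseline_prob")
        if self.gate is not None:
            overlap = set(self.gate.cues) & set(probs)
            if overlap:
                raise ValueError(
                    f"cues {sorted(overlap)} appear both in independent_probs and in the gate"
                )
        object.__setattr__(self, "independent_probs", probs)

    # -- presets -----------------------------------------------------------

    @classmethod
    def independent_preset(cls, baseline_prob: float = 0.0) -> "RewardModel":
        """Four conditionally independent cues paying 0.20/0.40/0.60/0.80."""
        return cls(
            independent_probs={"a": 0.20, "b": 0.40, "x": 0.60, "y": 0.80},
            baseline_prob=baseline_prob,
        )

    @classmethod
    def gated_preset(cls, kind: str, gate_prob: float) -> "RewardModel":
        """A at 0.2 and B at 0.4 independent; X,Y pay only through the gate."""
        return cls(
            independent_probs={"a": 0.20, "b": 0.40},
            gate=Gate(kind=kind, prob=gate_prob),
        )

    # -- semantics ---------------------------------------------------------

    def sources(self, pattern: CuePattern) -> list[float]:
        """Probabilities of the reward sources active for ``pattern``, in the
        fixed draw order a, b, x-or-gate, y (baseline last)."""
        out: list[float] = []
        gate_cues = self.gate.cues if self.gate is not None else ()
        for cue in CUES:
            if self.gate is not None and gate_cues and cue == gate_cues[0]:
                if self.gate.fires(pattern):
                    out.append(self.gate.prob)
            if cue in self.independent_probs and pattern[cue]:
                out.append(self.independent_probs[cue])
        if all(v == 0 for v in pattern.as_tuple()) and self.baseline_prob > 0:
            out.append(self.baseline_prob)
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "independent_probs": dict(self.independent_probs),
            "baseline_prob": self.baseline_prob,
        }
        if self.gate is not None:
            d["gate"] = {
                "kind": self.gate.kind,
                "prob": self.gate.prob,
                "cues": list(self.gate.cues),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RewardModel":
        gate = None
        if d.get("gate"):
            g = d["gate"]
            gate = Gate(
                kind=str(g["kind"]).lower(),
                prob=float(g["prob"]),
                cues=tuple(g.get("cues", ("x", "y"))),  # type: ignore[arg-type]
            )
        return cls(
            independent_probs={
                str(k).lower(): float(v)
                for k, v in dict(d.get("independent_probs", {})).items()
            },
            gate=gate,
            baseline_prob=float(d.get("baseline_prob", 0.0)),
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "RewardModel":
        """Read a JSON or YAML reward-model config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def expected_reward_probability(pattern: CuePattern, model: RewardModel) -> float:
    """Union probability that at least one active reward source fires."""
    q = 1.0
    for p in model.sources(pattern):
        q *= 1.0 - p
    return 1.0 - q


def population_probabilities(model: RewardModel) -> np.ndarray:
    """Expected reward probability of every pattern, in enumeration order."""
    return np.array([expected_reward_probability(p, model) for p in PATTERNS])


@dataclass
class TrainingSet:
    """A sample of (pattern, binary reward) trials from a :class:`RewardModel`.

    Rows are stored in the order they were generated (enumeration order for
    generator output: all replicates of pattern 0, then pattern 1, ...);
    per-epoch shuffling is the trainer's job, not the sampler's.
    """

    pattern_indices: np.ndarray  # (n_rows,) int, values in 0..15
    targets: np.ndarray  # (n_rows,) int, values in {0, 1}
    replicates: int
    model: RewardModel
    seed: int

    def __post_init__(self) -> None:
        self.pattern_indices = np.asarray(self.pattern_indices, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.pattern_indices.shape != self.targets.shape:
            raise ValueError("pattern_indices and targets must have equal length")
        if not np.isin(self.targets, (0, 1)).all():
            raise ValueError("targets must be binary")
        if self.pattern_indices.size and (
            self.pattern_indices.min() < 0 or self.pattern_indices.max() > 15
        ):
            raise ValueError("pattern indices must lie in 0..15")
        # generated sets carry all 16 configurations; hand-built toy sets may
        # omit some, but any present configuration must occur exactly
        # `replicates` times so per-configuration rates are well defined
        counts = np.bincount(self.pattern_indices, minlength=16)
        present = counts[counts > 0]
        if present.size == 0 or not (present == self.replicates).all():
            raise ValueError(
                "each present configuration must occur exactly "
                f"{self.replicates} times"
            )

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def n_rows(self) -> int:
        return len(self.targets)

    def design_matrix(self) -> np.ndarray:
        """(n_rows, 4) float matrix of cue indicators, columns (a, b, x, y)."""
        return PATTERN_BITS[self.pattern_indices]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.design_matrix().astype(int), columns=list(CUES))
        df["target"] = self.targets
        return df

    def shuffled(self, seed: int) -> "TrainingSet":
        """Row-permuted copy (same sample, different storage order)."""
        order = np.random.default_rng(seed).permutation(self.n_rows)
        return replace(
            self,
            pattern_indices=self.pattern_indices[order],
            targets=self.targets[order],
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write rows as ``a,b,x,y,target`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "model": self.model.to_dict(),
                "replicates": self.replicates,
                "seed": self.seed,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "TrainingSet":
        path = Path(path)
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        meta = json.loads(Path(sidecar).read_text())
        df = pd.read_csv(path)
        bits = df[list(CUES)].to_numpy(dtype=np.int64)
        idx = bits[:, 0] * 8 + bits[:, 1] * 4 + bits[:, 2] * 2 + bits[:, 3]
        return cls(
            pattern_indices=idx,
            targets=df["target"].to_numpy(dtype=np.int64),
            replicates=int(meta["replicates"]),
            model=RewardModel.from_dict(meta["model"]),
            seed=int(meta["seed"]),
        )


def generate_training_set(
    model: RewardModel, replicates: int = 100, seed: int = 0
) -> TrainingSet:
    """Sample a training set of ``16 * replicates`` trials from ``model``.

    For every configuration and replicate, one uniform draw is consumed per
    active reward source, in the fixed order a, b, x-or-gate, y (baseline
    last); the trial is rewarded if any draw falls at or below its source's
    probability.  A single explicitly seeded RNG stream drives the whole set,
    so identical (model, replicates, seed) reproduce it exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    targets = np.empty((16, replicates), dtype=np.int64)
    for i, pattern in enumerate(PATTERNS):
        probs = np.array(model.sources(pattern))
        if probs.size == 0:
            targets[i] = 0
        else:
            u = rng.random((replicates, probs.size))
            targets[i] = (u <= probs).any(axis=1)
    return TrainingSet(
        pattern_indices=np.repeat(np.arange(16), replicates),
        targets=targets.reshape(-1),
        replicates=replicates,
        model=model,
        seed=seed,
    )


@dataclass
class ValidationReport:
    """Per-configuration goodness-of-fit of observed reward rates."""

    table: pd.DataFrame  # columns: pattern, label, n, expected_p, observed_p, chi2, passed
    alpha: float

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "all passed" if self.all_passed else "FAILURES"
        return f"<ValidationReport alpha={self.alpha} {status}>\n{self.table.to_string(index=False)}"


def validate_training_set(ts: TrainingSet, alpha: float = 0.05) -> ValidationReport:
    """Compare each configuration's observed reward rate to its population
    expectation with a 1-df Pearson goodness-of-fit chi-square.

    Cells with zero expected count (only possible when the expected
    probability is exactly 0 or 1) are skipped; such configurations pass
    only if the observed counts are correspondingly degenerate.
    """
    if ts.n_rows == 0:
        raise ValueError("training set is empty")
    if (np.bincount(ts.pattern_indices, minlength=16) == 0).any():
        raise ValueError("cannot validate a set with absent configurations")
    expected = population_probabilities(ts.model)
    n = ts.replicates
    rewarded = np.bincount(ts.pattern_indices, weights=ts.targets, minlength=16)
    crit = _sps.chi2.ppf(1.0 - alpha, df=1)
    rows = []
    for i, pattern in enumerate(PATTERNS):
        p = expected[i]
        o1, o0 = rewarded[i], n - rewarded[i]
        e1, e0 = n * p, n * (1.0 - p)
        chi2 = 0.0
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if e0 > 0:
            chi2 += (o0 - e0) ** 2 / e0
        if p in (0.0, 1.0):
            passed = (o1 == e1) and (o0 == e0)
        else:
            passed = chi2 <= crit
        rows.append(
            {
                "pattern": pattern.as_tuple(),
                "label": pattern.label,
                "n": n,
                "expected_p": p,
                "observed_p": o1 / n,
                "chi2": chi2,
                "passed": bool(passed),
            }
        )
    return ValidationReport(table=pd.DataFrame(rows), alpha=alpha)


def generate_validated_training_set(
    model: RewardModel,
    replicates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    max_attempts: int = 20,
) -> tuple[TrainingSet, ValidationReport]:
    """Generate a set, retrying with the next seed (seed+1, seed+2, ...) until
    every configuration passes validation or ``max_attempts`` is exhausted.
    Returns the last attempt either way, together with its report.
    """
    ts = generate_training_set(model, replicates, seed)
    report = validate_training_set(ts, alpha)
    for attempt in range(1, max_attempts):
        if report.all_passed:
            break
        ts = generate_training_set(model, replicates, seed + attempt)
        report = validate_training_set(ts, alpha)
    return ts, report
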