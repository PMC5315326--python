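"""Orchestration of the two simulation studies.

Study 1: four conditionally independent cues (0.20/0.40/0.60/0.80), optional
no-cue baseline; quantifies probability matching and SGD-vs-MLE structural
equivalence across training sets and random restarts.

Study 2: a 2x2 factorial crossing gate logic (AND vs XOR over X,Y) with gate
payout (0.6 vs 0.1), A and B independent; relates matching fidelity to the
reward-stratified conditional-dependence score, via a two-way ANOVA and two
competing single-predictor regressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import __version__ as _pkg_version
from .cue_world import (
    RewardModel,
    TrainingSet,
    generate_training_set,
    validate_training_set,
)
from .learner import TrainingConfig
from .model import PerceptronModel
from .stats import conditional_dependence, fit_logistic, structure_fit_r2

__all__ = [
    "ExperimentResult",
    "run_simulation1",
    "run_simulation2",
    "two_way_anova",
    "regress_fit",
    "AnovaTable",
    "RegressionResult",
]

SIM2_CONDITIONS: tuple[tuple[str, float], ...] = (
    ("and", 0.6),
    ("and", 0.1),
    ("xor", 0.6),
    ("xor", 0.1),
)


def _derive_seed(ss: np.random.SeedSequence) -> int:
    # keep recorded integer seeds below 2^31
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class ExperimentResult:
    """Tidy per-network records, per-set records, and a condition summary."""

    name: str
    records: pd.DataFrame  # one row per trained network
    set_records: pd.DataFrame  # one row per training set
    summary: pd.DataFrame  # one row per condition
    config: TrainingConfig
    master_seed: int

    def save(self, outdir: str | Path) -> dict:
        """Write records/summary CSVs plus a JSON manifest; returns manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": outdir / f"{self.name}_records.csv",
            "set_records": outdir / f"{self.name}_sets.csv",
            "summary": outdir / f"{self.name}_summary.csv",
        }
        self.records.to_csv(paths["records"], index=False)
        self.set_records.to_csv(paths["set_records"], index=False)
        self.summary.to_csv(paths["summary"], index=False)
        manifest = {
            "experiment": self.name,
            "master_seed": self.master_seed,
            "config": {
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "init_half_range": self.config.init_half_range,
                "loss": self.config.loss,
            },
            "version": _pkg_version,
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        (outdir / f"{self.name}_manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _train_nets_on_set(
    ts: TrainingSet,
    set_id: int,
    nets_per_set: int,
    config: TrainingConfig,
    set_ss: np.random.SeedSequence,
    extra: dict,
) -> list[dict]:
    pm = PerceptronModel(ts, config)
    fit = fit_logistic(ts)
    rows = []
    for net_ss in set_ss.spawn(nets_per_set):
        net_seed = _derive_seed(net_ss)
        res = pm.fit(seed=net_seed)
        row = {
            "set_id": set_id,
            "set_seed": ts.seed,
            "net_seed": net_seed,
            "matching_r2": res.matching_r2,
            "structure_r2": structure_fit_r2(res.perceptron, fit),
            "no_cue_response": res.no_cue_response,
            "bias": res.perceptron.bias,
            **{f"w_{c}": w for c, w in res.perceptron.weights.items()},
            **extra,
        }
        rows.append(row)
    return rows


def run_simulation1(
    sets: int = 5,
    nets_per_set: int = 20,
    baseline_prob: float = 0.0,
    config: Optional[TrainingConfig] = None,
    master_seed: int = 0,
) -> ExperimentResult:
    """Independent-cue study: ``sets`` training sets under the 0.2/0.4/0.6/0.8
    preset (with the given no-cue baseline), ``nets_per_set`` random restarts
    each.  Summary reports mean/SD of matching R2, structure R2 and the
    no-cue response across all networks."""
    if sets < 1 or nets_per_set < 1:
        raise ValueError("sets and nets_per_set must be >= 1")
    if config is None:
        config = TrainingConfig()
    model = RewardModel.independent_preset(baseline_prob=baseline_prob)
    root = np.random.SeedSequence(master_seed)
    records: list[dict] = []
    set_rows: list[dict] = []
    for set_id, set_ss in enumerate(root.spawn(sets)):
        gen_ss, nets_ss = set_ss.spawn(2)
        ts = generate_training_set(model, replicates=100, seed=_derive_seed(gen_ss))
        report = validate_training_set(ts)
        set_rows.append(
            {
                "set_id": set_id,
                "set_seed": ts.seed,
                "baseline_prob": baseline_prob,
                "validation_passed": report.all_passed,
                "n_failed_configs": int((~report.table["passed"]).sum()),
            }
        )
        records.extend(
            _train_nets_on_set(
                ts, set_id, nets_per_set, config, nets_ss,
                extra={"baseline_prob": baseline_prob},
            )
        )
    rec = pd.DataFrame(records)
    summary = pd.DataFrame(
        [
            {
                "condition": f"independent/baseline={baseline_prob}",
                "n_networks": len(rec),
                "matching_r2_mean": rec["matching_r2"].mean(),
                "matching_r2_sd": rec["matching_r2"].std(ddof=1),
                "structure_r2_mean": rec["structure_r2"].mean(),
                "structure_r2_sd": rec["structure_r2"].std(ddof=1),
                "no_cue_response_mean": rec["no_cue_response"].mean(),
                "no_cue_response_sd": rec["no_cue_response"].std(ddof=1),
            }
        ]
    )
    return ExperimentResult(
        name="sim1",
        records=rec,
        set_records=pd.DataFrame(set_rows),
        summary=summary,
        config=config,
        master_seed=master_seed,
    )


def run_simulation2(
    sets_per_condition: int = 5,
    nets_per_set: int = 20,
    config: Optional[TrainingConfig] = None,
    master_seed: int = 0,
) -> ExperimentResult:
    """Gated-cue study over the four conditions {AND, XOR} x {0.6, 0.1}.

    Every network record carries its training set's conditional-dependence
    total, so the per-network regressions can be run directly on ``records``.
    """
    if sets_per_condition < 1 or nets_per_set < 1:
        raise ValueError("sets_per_condition and nets_per_set must be >= 1")
    if config is None:
        config = TrainingConfig()
    root = np.random.SeedSequence(master_seed)
    records: list[dict] = []
    set_rows: list[dict] = []
    for (kind, gate_prob), cond_ss in zip(SIM2_CONDITIONS, root.spawn(len(SIM2_CONDITIONS))):
        model = RewardModel.gated_preset(kind, gate_prob)
        for set_id, set_ss in enumerate(cond_ss.spawn(sets_per_condition)):
            gen_ss, nets_ss = set_ss.spawn(2)
            ts = generate_training_set(model, replicates=100, seed=_derive_seed(gen_ss))
            dep = conditional_dependence(ts)
            report = validate_training_set(ts)
            set_rows.append(
                {
                    "gate_kind": kind,
                    "gate_prob": gate_prob,
                    "set_id": set_id,
                    "set_seed": ts.seed,
                    "chi2_rewarded": dep.chi2_rewarded,
                    "chi2_unrewarded": dep.chi2_unrewarded,
                    "dependence_total": dep.total,
                    "validation_passed": report.all_passed,
                }
            )
            records.extend(
                _train_nets_on_set(
                    ts, set_id, nets_per_set, config, nets_ss,
                    extra={
                        "gate_kind": kind,
                        "gate_prob": gate_prob,
                        "dependence_total": dep.total,
                    },
                )
            )
    rec = pd.DataFrame(records)
    sets_df = pd.DataFrame(set_rows)
    summary_rows = []
    for kind, gate_prob in SIM2_CONDITIONS:
        cell = rec[(rec["gate_kind"] == kind) & (rec["gate_prob"] == gate_prob)]
        cell_sets = sets_df[
            (sets_df["gate_kind"] == kind) & (sets_df["gate_prob"] == gate_prob)
        ]
        summary_rows.append(
            {
                "gate_kind": kind,
                "gate_prob": gate_prob,
                "n_networks": len(cell),
                "matching_r2_mean": cell["matching_r2"].mean(),
                "matching_r2_sd": cell["matching_r2"].std(ddof=1),
                "dependence_mean": cell_sets["dependence_total"].mean(),
                "dependence_sd": cell_sets["dependence_total"].std(ddof=1),
            }
        )
    return ExperimentResult(
        name="sim2",
        records=rec,
        set_records=sets_df,
        summary=pd.DataFrame(summary_rows),
        config=config,
        master_seed=master_seed,
    )


@dataclass
class AnovaTable:
    """Fixed-effects two-way ANOVA with interaction on a balanced 2x2 design."""

    table: pd.DataFrame  # rows: factor A, factor B, interaction, residual

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


def two_way_anova(
    records: pd.DataFrame,
    response: str = "matching_r2",
    factors: tuple[str, str] = ("gate_kind", "gate_prob"),
) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA computed from cell sums of squares.

    Raises if the design is unbalanced (unequal cell counts) or either factor
    does not have exactly two levels.
    """
    fa, fb = factors
    y = records[response].to_numpy(dtype=float)
    la = records[fa].to_numpy()
    lb = records[fb].to_numpy()
    levels_a, levels_b = np.unique(la), np.unique(lb)
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("each factor must have exactly two levels")
    n_cell = None
    for va in levels_a:
        for vb in levels_b:
            c = int(((la == va) & (lb == vb)).sum())
            if n_cell is None:
                n_cell = c
            elif c != n_cell:
                raise ValueError("unbalanced design: unequal cell counts")
    if not n_cell:
        raise ValueError("empty cells")
    N = len(y)
    grand = y.mean()
    ss_a = sum(((y[la == va].mean() - grand) ** 2) * (la == va).sum() for va in levels_a)
    ss_b = sum(((y[lb == vb].mean() - grand) ** 2) * (lb == vb).sum() for vb in levels_b)
    ss_ab = 0.0
    ss_err = 0.0
    for va in levels_a:
        for vb in levels_b:
            mask = (la == va) & (lb == vb)
            cell_mean = y[mask].mean()
            ss_ab += n_cell * (
                cell_mean - y[la == va].mean() - y[lb == vb].mean() + grand
            ) ** 2
            ss_err += ((y[mask] - cell_mean) ** 2).sum()
    df_err = N - 4
    ms_err = ss_err / df_err
    effects = [(fa, ss_a), (fb, ss_b), (f"{fa}:{fb}", ss_ab)]
    data = []
    for name, ss in effects:
        F = (ss / 1.0) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        p = float(_sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        data.append({"effect": name, "ss": ss, "df": 1, "F": F, "p": p})
    data.append({"effect": "residual", "ss": ss_err, "df": df_err, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(data).set_index("effect")
    return AnovaTable(table=table)


@dataclass
class RegressionResult:
    """Simple OLS regression of one response on one predictor."""

    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    slope: float
    intercept: float


def regress_fit(predictor: Sequence[float], response: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares simple regression; R2 is the squared Pearson
    correlation and F = (N-2) R2 / (1 - R2) on (1, N-2) df."""
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    n = x.size
    if r2 >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (n - 2) * r2 / (1.0 - r2)
        p = float(_sps.f.sf(f_stat, 1, n - 2))
    slope = r * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = float(y.mean() - slope * x.mean())
    return RegressionResult(
        r2=r2, f_stat=float(f_stat), df=(1, n - 2), p_value=p,
        slope=float(slope), intercept=intercept,
    )
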