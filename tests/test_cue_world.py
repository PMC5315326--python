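"""Reward-world semantics: union probabilities, sampling, validation, I/O."""

import json

import numpy as np
import pytest

from cuematch.cue_world import (
    PATTERNS,
    CuePattern,
    Gate,
    RewardModel,
    TrainingSet,
    expected_reward_probability,
    generate_training_set,
    generate_validated_training_set,
    pattern_index,
    population_probabilities,
    validate_training_set,
)

SIM1 = RewardModel.independent_preset()
AND6 = RewardModel.gated_preset("and", 0.6)
XOR6 = RewardModel.gated_preset("xor", 0.6)


class TestCuePattern:
    def test_enumeration_is_binary_counting_a_msb(self):
        assert [p.as_tuple() for p in PATTERNS[:3]] == [(0, 0, 0, 0), (0, 0, 0, 1), (0, 0, 1, 0)]
        assert PATTERNS[-1].as_tuple() == (1, 1, 1, 1)
        assert len(set(PATTERNS)) == 16
        for i, p in enumerate(PATTERNS):
            assert pattern_index(p) == i

    def test_labels(self):
        assert PATTERNS[0].label == "~A~B~X~Y"
        assert PATTERNS[3].label == "~A~BXY"

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            CuePattern(2, 0, 0, 0)


class TestExpectedRewardProbability:
    @pytest.mark.parametrize(
        "pattern,model,expected",
        [
            ((0, 0, 0, 0), SIM1, 0.0),
            ((1, 1, 0, 0), SIM1, 0.52),  # 0.2 + 0.4 - 0.2*0.4
            ((1, 1, 1, 1), SIM1, 1 - 0.8 * 0.6 * 0.4 * 0.2),
            ((0, 0, 1, 1), AND6, 0.6),  # gate pays only when both present
            ((0, 0, 1, 0), AND6, 0.0),
            ((0, 0, 1, 0), XOR6, 0.6),
            ((0, 0, 1, 1), XOR6, 0.0),
            ((1, 0, 1, 1), AND6, 0.2 + 0.6 - 0.2 * 0.6),
            ((0, 0, 0, 0), RewardModel.independent_preset(baseline_prob=0.05), 0.05),
            ((1, 0, 0, 0), RewardModel.independent_preset(baseline_prob=0.05), 0.20),
        ],
    )
    def test_union_rule(self, pattern, model, expected):
        assert expected_reward_probability(CuePattern(*pattern), model) == pytest.approx(expected)

    def test_matches_inclusion_exclusion_on_three_sources(self):
        # independent oracle: explicit inclusion-exclusion expansion
        p = CuePattern(0, 1, 1, 1)
        pb, px, py = 0.4, 0.6, 0.8
        incl_excl = (
            pb + px + py - pb * px - pb * py - px * py + pb * px * py
        )
        assert expected_reward_probability(p, SIM1) == pytest.approx(incl_excl)

    def test_monotone_in_each_source_probability(self):
        base = expected_reward_probability(CuePattern(1, 1, 0, 0), SIM1)
        richer = RewardModel(independent_probs={"a": 0.5, "b": 0.4, "x": 0.6, "y": 0.8})
        assert expected_reward_probability(CuePattern(1, 1, 0, 0), richer) > base

    def test_bounds(self):
        for model in (SIM1, AND6, XOR6):
            probs = population_probabilities(model)
            assert ((probs >= 0) & (probs <= 1)).all()


class TestRewardModelValidation:
    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ValueError):
            RewardModel(independent_probs={"a": 1.3})

    def test_rejects_gated_cue_with_independent_prob(self):
        with pytest.raises(ValueError):
            RewardModel(independent_probs={"x": 0.5}, gate=Gate("and", 0.6))

    def test_rejects_unknown_gate_kind(self):
        with pytest.raises(ValueError):
            Gate("nand", 0.6)

    def test_config_roundtrip_json_and_yaml(self, tmp_path):
        model = RewardModel.gated_preset("xor", 0.1)
        jpath = tmp_path / "m.json"
        jpath.write_text(json.dumps(model.to_dict()))
        assert RewardModel.from_config(jpath) == model
        ypath = tmp_path / "m.yaml"
        ypath.write_text(
            "independent_probs: {a: 0.2, b: 0.4}\ngate: {kind: xor, prob: 0.1}\n"
        )
        assert RewardModel.from_config(ypath) == model


class TestGenerateTrainingSet:
    def test_structure_and_determinism(self):
        a = generate_training_set(SIM1, replicates=100, seed=7)
        b = generate_training_set(SIM1, replicates=100, seed=7)
        assert a.n_rows == 1600
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.pattern_indices, np.repeat(np.arange(16), 100))
        c = generate_training_set(SIM1, replicates=100, seed=8)
        assert not np.array_equal(a.targets, c.targets)

    def test_zero_probability_model_never_rewards(self):
        model = RewardModel(independent_probs={c: 0.0 for c in "abxy"})
        ts = generate_training_set(model, replicates=100, seed=0)
        assert ts.targets.sum() == 0

    def test_deterministic_and_gate(self):
        model = RewardModel(independent_probs={}, gate=Gate("and", 1.0))
        ts = generate_training_set(model, replicates=10, seed=0)
        both_present = [i for i, p in enumerate(PATTERNS) if p.x and p.y]
        for i in range(16):
            block = ts.targets[ts.pattern_indices == i]
            assert block.sum() == (10 if i in both_present else 0)

    def test_observed_rate_within_central_binomial_interval(self):
        # binomial oracle: central 99% interval for n=100, p=0.2
        from scipy.stats import binom

        lo, hi = binom.ppf(0.005, 100, 0.2), binom.ppf(0.995, 100, 0.2)
        ts = generate_training_set(SIM1, replicates=100, seed=3)
        k = ts.targets[ts.pattern_indices == 8].sum()  # pattern (1,0,0,0)
        assert lo <= k <= hi

    def test_calibration_over_many_seeds(self):
        # mean observed rate converges to the union-rule expectation
        expected = population_probabilities(SIM1)
        rates = np.mean(
            [
                [generate_training_set(SIM1, 100, seed=s).targets[
                    generate_training_set(SIM1, 100, seed=s).pattern_indices == i
                ].mean() for i in range(16)]
                for s in range(12)
            ],
            axis=0,
        )
        # SE of each mean rate is at most 0.5/sqrt(1200) ~ 0.0145
        assert np.abs(rates - expected).max() < 0.05

    def test_rejects_nonpositive_replicates(self):
        with pytest.raises(ValueError):
            generate_training_set(SIM1, replicates=0, seed=0)


class TestValidateTrainingSet:
    def test_exact_rates_give_zero_chi2(self):
        model = RewardModel(independent_probs={"a": 0.5})
        idx = np.repeat(np.arange(16), 10)
        pop = population_probabilities(model)
        targets = np.concatenate(
            [(np.arange(10) < round(pop[i] * 10)).astype(int) for i in range(16)]
        )
        ts = TrainingSet(idx, targets, 10, model, 0)
        rep = validate_training_set(ts)
        assert rep.all_passed
        assert rep.table["chi2"].max() == pytest.approx(0.0)

    def test_generated_sets_typically_pass(self):
        ts = generate_training_set(SIM1, 100, seed=11)
        assert validate_training_set(ts, alpha=0.05).all_passed

    def test_corrupted_configuration_fails(self):
        ts = generate_training_set(SIM1, 100, seed=11)
        targets = ts.targets.copy()
        targets[ts.pattern_indices == 8] = 1  # force pattern (1,0,0,0) to all-reward
        bad = TrainingSet(ts.pattern_indices, targets, 100, SIM1, 11)
        rep = validate_training_set(bad)
        row = rep.table.iloc[8]
        assert not row["passed"]
        assert row["chi2"] == pytest.approx(400.0)  # 100*(1-0.2)^2/0.2 + 100*0.2... = 400

    def test_degenerate_expected_probabilities(self):
        model = RewardModel(independent_probs={})  # everything expected 0
        idx = np.repeat(np.arange(16), 5)
        ts = TrainingSet(idx, np.zeros(80, int), 5, model, 0)
        assert validate_training_set(ts).all_passed
        bad = TrainingSet(idx, (idx == 3).astype(int), 5, model, 0)
        assert not validate_training_set(bad).all_passed

    def test_regeneration_loop_returns_passing_set(self):
        ts, rep = generate_validated_training_set(SIM1, 100, seed=0)
        assert rep.all_passed


class TestTrainingSetIO:
    def test_csv_roundtrip_identical(self, tmp_path):
        ts = generate_training_set(AND6, 100, seed=2)
        path = tmp_path / "ts.csv"
        ts.to_csv(path)
        back = TrainingSet.read_csv(path)
        assert np.array_equal(back.targets, ts.targets)
        assert np.array_equal(back.pattern_indices, ts.pattern_indices)
        assert back.model == ts.model
        assert back.seed == ts.seed and back.replicates == ts.replicates

    def test_frame_columns(self):
        df = generate_training_set(SIM1, 2, seed=0).to_frame()
        assert list(df.columns) == ["a", "b", "x", "y", "target"]
        assert len(df) == 32
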