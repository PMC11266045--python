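"""Threshold metrics, ROC/PR areas, evaluation and the ablation harness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pspi.metrics import (
    ConfusionCounts,
    confusion,
    pr_auc,
    roc_auc,
    threshold_metrics,
)


def pairwise_auroc_oracle(scores, labels):
    """O(P*N) comparison of every (positive, negative) pair; ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if sp > sn else 0.5 if sp == sn else 0.0
        for sp, sn in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def step_sum_ap_oracle(scores, labels):
    """Average precision as the explicit sum over positives' recall steps."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = int(y.sum())
    ap, tp = 0.0, 0
    for i, yi in enumerate(y, start=1):
        if yi == 1:
            tp += 1
            ap += tp / i
    return ap / n_pos


class TestConfusion:
    def test_mixed_tally(self):
        cc = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (1, 1, 1, 1)

    def test_identical_vectors(self):
        cc = confusion([1, 0, 1], [1, 0, 1])
        assert cc.fp == cc.fn == 0
        assert cc.total == 3

    def test_empty(self):
        assert confusion([], []).total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestThresholdMetrics:
    def test_balanced_toy_table(self):
        vals = threshold_metrics(ConfusionCounts(tp=9, fp=1, tn=9, fn=1))
        assert vals == pytest.approx((0.9, 0.9, 0.9, 0.9))

    def test_perfect_counts(self):
        vals = threshold_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert vals == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_reports_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            prec, *_ = threshold_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert prec == 0.0

    def test_f1_is_harmonic_mean(self):
        prec, sens, _, f1 = threshold_metrics(
            ConfusionCounts(tp=6, fp=2, tn=7, fn=4)
        )
        assert f1 == pytest.approx(2 * prec * sens / (prec + sens))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(123)
        n = 10_000
        scores = rng.random(n)
        labels = rng.integers(2, size=n)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.02

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            labels = rng.integers(2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            # quantized scores force ties through the tie-averaging path
            scores = np.round(rng.random(n), 1)
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auroc_oracle(scores, labels)
            )

    @given(shift=st.floats(0.1, 5.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(7)
        scores = rng.random(100)
        labels = rng.integers(2, size=100)
        base = roc_auc(scores, labels)
        assert roc_auc(scale * scores + shift, labels) == pytest.approx(base)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)

    def test_label_swap_reflects_area(self, rng):
        scores = rng.random(80)
        labels = rng.integers(2, size=80)
        a = roc_auc(scores, labels)
        assert roc_auc(scores, 1 - labels) == pytest.approx(1 - a)


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.5, 0.6], [0, 0])

    def test_null_scores_near_prevalence(self):
        rng = np.random.default_rng(99)
        n = 10_000
        prevalence = 0.2
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert pr_auc(scores, labels) == pytest.approx(prevalence, abs=0.03)

    def test_matches_step_sum_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 100))
            labels = rng.integers(2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.random(n)  # distinct scores: unambiguous steps
            assert pr_auc(scores, labels) == pytest.approx(
                step_sum_ap_oracle(scores, labels)
            )


class TestEvaluateAndAblation:
    """End-to-end evaluation with real (small) trained models."""

    @pytest.fixture(scope="class")
    def tiny_data(self):
        from pspi.synthdata import SynthConfig, gen_dataset

        cfg = SynthConfig(n_pos=80, n_neg=80, seed=21)
        return gen_dataset(cfg)

    @pytest.fixture(scope="class")
    def tiny_model(self, tiny_data):
        from pspi.classifier import ModelConfig, train
        from pspi.features import FeatureConfig, NkSpec

        tr, _ = tiny_data
        cfg = ModelConfig(recurrent_units=8, epochs=4, seed=1,
                          feature_config=FeatureConfig(specs=(NkSpec(4, 2),)))
        return train(tr.peptides, tr.labels, cfg)

    def test_report_counts_match_input(self, tiny_data, tiny_model):
        from pspi.metrics import evaluate

        _, te = tiny_data
        report = evaluate(tiny_model, te.peptides, te.labels)
        assert report.n_pos == sum(te.labels)
        assert report.n_neg == len(te.labels) - sum(te.labels)
        for v in (report.precision, report.sensitivity, report.specificity,
                  report.f1, report.auroc, report.aupr):
            assert 0.0 <= v <= 1.0

    def test_oracle_scorer_yields_perfect_metrics(self, tiny_data, tiny_model):
        # bypass the network: score = true label
        from pspi.metrics import (confusion, pr_auc, roc_auc,
                                  threshold_metrics)

        _, te = tiny_data
        y = np.array(te.labels)
        s = y.astype(float)
        assert roc_auc(s, y) == 1.0
        assert pr_auc(s, y) == 1.0
        vals = threshold_metrics(confusion(y, (s >= 0.75).astype(int)))
        assert vals == (1.0, 1.0, 1.0, 1.0)

    def test_constant_scorer_gives_half_auroc(self):
        y = np.array([1, 0] * 20)
        s = np.full(40, 0.5)
        assert roc_auc(s, y) == 0.5

    def test_ablation_table_shape_and_reproducibility(self, tiny_data):
        from pspi.classifier import ModelConfig
        from pspi.features import FeatureConfig, NkSpec
        from pspi.metrics import ablation_run

        tr, te = tiny_data
        grid = {
            "baseline": FeatureConfig(specs=()),
            "(4,2)": FeatureConfig(specs=(NkSpec(4, 2),)),
        }
        base = ModelConfig(recurrent_units=8, epochs=3)
        sets = {"test": (te.peptides, te.labels)}
        t1 = ablation_run((tr.peptides, tr.labels), sets, grid, base, seed=5)
        t2 = ablation_run((tr.peptides, tr.labels), sets, grid, base, seed=5)
        assert len(t1) == len(grid) * len(sets)
        assert set(t1["features"]) == set(grid)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self, tiny_data):
        from pspi.metrics import ablation_run

        tr, te = tiny_data
        with pytest.raises(ValueError):
            ablation_run((tr.peptides, tr.labels),
                         {"t": (te.peptides, te.labels)}, {})
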