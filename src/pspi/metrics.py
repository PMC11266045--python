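"""Evaluation: threshold metrics, ROC/PR areas, and the ablation harness.

AUROC is computed as the rank (Mann-Whitney) statistic with tie averaging:
the probability that a random positive outscores a random negative, ties
counted half.  AUPR is average precision (the sum of precision at each
positive's recall step), not trapezoidal interpolation of the PR curve,
which is known to over-estimate the area.

Zero-denominator threshold metrics (e.g. precision with no positive calls)
are reported as 0.0 with a warning rather than NaN, so tables built from
many evaluations stay numeric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from pspi.classifier import ModelConfig, TrainedModel, classify, score, train
from pspi.features import FeatureConfig


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """One model's metrics on one labeled set at one threshold."""

    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int
    threshold: float

    def as_dict(self) -> dict[str, float | int]:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "threshold": self.threshold,
        }


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Standard 2x2 tally of binary truth vs binary prediction."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: {t.shape[0]} truths vs {p.shape[0]} predictions"
        )
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name}: zero denominator, reporting 0.0", RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def threshold_metrics(cc: ConfusionCounts) -> tuple[float, float, float, float]:
    """(precision, sensitivity, specificity, F1) from confusion counts."""
    precision = _safe_div(cc.tp, cc.tp + cc.fp, "precision")
    sensitivity = _safe_div(cc.tp, cc.tp + cc.fn, "sensitivity")
    specificity = _safe_div(cc.tn, cc.tn + cc.fp, "specificity")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "f1")
    return precision, sensitivity, specificity, f1


def roc_auc(scores, true_labels) -> float:
    """AUROC via the rank statistic: P(score_pos > score_neg) + P(tie)/2."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(true_labels, dtype=np.int64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(s)  # average ranks on ties
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, true_labels) -> float:
    """AUPR via average precision (step-sum over positives' recall steps)."""
    y = np.asarray(true_labels, dtype=np.int64)
    if (y == 1).sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


def evaluate(
    model: TrainedModel,
    peptides: list[str],
    labels,
    threshold: float | None = None,
) -> EvalReport:
    """Score a labeled peptide set and compute the full metric suite."""
    y = np.asarray(labels, dtype=np.int64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("evaluation requires both classes present")
    if threshold is None:
        threshold = model.config.threshold
    s = score(model, peptides)
    calls = classify(s, threshold)
    prec, sens, spec, f1 = threshold_metrics(confusion(y, calls))
    return EvalReport(
        precision=prec,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        auroc=roc_auc(s, y),
        aupr=pr_auc(s, y),
        n_pos=n_pos,
        n_neg=n_neg,
        threshold=threshold,
    )


def ablation_run(
    train_set: tuple[list[str], list[int]],
    test_sets: dict[str, tuple[list[str], list[int]]],
    spec_grid: dict[str, FeatureConfig],
    base_config: ModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per feature configuration and evaluate on every set.

    ``spec_grid`` maps a configuration name (e.g. ``"baseline"``,
    ``"(4,2)"``) to its :class:`FeatureConfig`; the conventional grid spans
    the one-hot-only baseline, 1-mers, and (n,k) blocks for n in [3,10] and
    k in {2,3,4}, singly or combined.  Each (config, test set) cell gets a
    model trained with a seed fixed by the cell's position, so the whole
    table is reproducible.  Returns a tidy DataFrame with one row per cell.
    """
    if not spec_grid:
        raise ValueError("spec_grid must be nonempty")
    if base_config is None:
        base_config = ModelConfig()
    X_train, y_train = train_set
    rows = []
    for i, (name, fc) in enumerate(spec_grid.items()):
        cfg = ModelConfig(
            recurrent_units=base_config.recurrent_units,
            dropout_rate=base_config.dropout_rate,
            threshold=base_config.threshold,
            feature_config=fc,
            epochs=base_config.epochs,
            batch_size=base_config.batch_size,
            learning_rate=base_config.learning_rate,
            seed=seed + i,
        )
        model = train(X_train, y_train, cfg)
        for set_name, (X_test, y_test) in test_sets.items():
            report = evaluate(model, X_test, y_test)
            rows.append(
                {"features": name, "test_set": set_name, **report.as_dict()}
            )
    return pd.DataFrame(rows)


def default_ablation_grid(max_len: int = 100) -> dict[str, FeatureConfig]:
    """The conventional feature grid: baseline, 1-mers, (4,k) blocks, all."""
    from pspi.features import NkSpec

    grid: dict[str, FeatureConfig] = {
        "baseline": FeatureConfig(use_onehot=True, max_len=max_len, specs=()),
        "1mers": FeatureConfig(max_len=max_len, specs=(NkSpec(3, 1),)),
        "(4,2)": FeatureConfig(max_len=max_len, specs=(NkSpec(4, 2),)),
        "(4,3)": FeatureConfig(max_len=max_len, specs=(NkSpec(4, 3),)),
        "(4,4)": FeatureConfig(max_len=max_len, specs=(NkSpec(4, 4),)),
        "all": FeatureConfig(
            max_len=max_len,
            specs=(NkSpec(3, 1), NkSpec(4, 2), NkSpec(4, 3), NkSpec(4, 4)),
        ),
    }
    return grid
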