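"""Classification metrics with percentile-bootstrap confidence intervals.

Balanced accuracy — the arithmetic mean of sensitivity and specificity —
is the headline metric: it equals 0.5 for any constant predictor, which
makes the all-negative baseline a natural reference on imbalanced data.
Significance against that baseline is the one-sided bootstrap exceedance
probability of the balanced-accuracy delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("balanced_accuracy", "roc_auc", "pr_auc", "sensitivity", "specificity")


class UndefinedMetricError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def confusion_metrics(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("balanced accuracy needs both classes in the labels")
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def _rank_roc_auc(y: np.ndarray, s: np.ndarray) -> float:
    # normalized Mann-Whitney U via midranks; ties count half
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _average_precision(y: np.ndarray, s: np.ndarray) -> float:
    # step-wise sum of precision * recall increments over distinct
    # descending thresholds (tied scores step together)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # last index of each tied-score group
    ends = np.nonzero(np.r_[ss[1:] != ss[:-1], True])[0]
    recall = tp[ends] / tp[-1]
    precision = tp[ends] / (tp[ends] + fp[ends])
    return float(np.sum(precision * np.diff(np.r_[0.0, recall])))


def roc_auc(labels, scores) -> float:
    """ROC AUC: the normalized Mann-Whitney U statistic (ties count half)."""
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("ROC AUC needs both classes")
    return _rank_roc_auc(y, np.asarray(scores, dtype=float))


def pr_auc(labels, scores) -> float:
    """Average precision: step-wise precision x recall-increment sum."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise UndefinedMetricError("PR AUC needs at least one positive")
    return _average_precision(y, np.asarray(scores, dtype=float))


@dataclass
class MetricReport:
    point: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    baseline_delta: float
    p_value: float
    n_boot: int
    n_redrawn: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "metrics": {
                m: {"value": self.point[m], "ci_low": self.ci_low[m], "ci_high": self.ci_high[m]}
                for m in METRIC_NAMES
            },
            "baseline_delta": self.baseline_delta,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "n_redrawn": self.n_redrawn,
            "seed": self.seed,
        }

    def to_text(self) -> str:
        lines = [f"{'Metric':<20}{'Value':>8}  95% CI"]
        for m in METRIC_NAMES:
            lines.append(
                f"{m:<20}{self.point[m]:>8.2f}  {self.ci_low[m]:.2f}-{self.ci_high[m]:.2f}"
            )
        lines.append(
            f"baseline delta (balanced accuracy - 0.5): {self.baseline_delta:.2f}, "
            f"one-sided bootstrap p = {self.p_value:.3f}"
        )
        return "\n".join(lines)


def _point_metrics(y: np.ndarray, scores: np.ndarray, threshold: float) -> dict[str, float]:
    cm = confusion_metrics(y, scores >= threshold)
    return {
        "balanced_accuracy": cm.balanced_accuracy,
        "roc_auc": roc_auc(y, scores),
        "pr_auc": pr_auc(y, scores),
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
    }


def bootstrap_metrics(
    labels,
    scores,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricReport:
    """Bootstrap the full metric panel by resampling regions with replacement.

    CIs are percentile (2.5-97.5); replicates that lose a class are redrawn
    (the count is reported) so exactly ``n_boot`` replicates enter every
    interval.  The p-value is the fraction of replicates whose balanced
    accuracy does not exceed the 0.5 baseline.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s) or len(y) == 0:
        raise ValueError("labels and scores must be equal-length and non-empty")
    point = _point_metrics(y, s, threshold)

    rng = np.random.default_rng(seed)
    n = len(y)
    reps = {m: np.empty(n_boot) for m in METRIC_NAMES}
    n_redrawn = 0
    for r in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if y[idx].min() != y[idx].max():
                break
            n_redrawn += 1
        vals = _point_metrics(y[idx], s[idx], threshold)
        for m in METRIC_NAMES:
            reps[m][r] = vals[m]

    ci_low = {m: float(np.percentile(reps[m], 2.5)) for m in METRIC_NAMES}
    ci_high = {m: float(np.percentile(reps[m], 97.5)) for m in METRIC_NAMES}
    delta = reps["balanced_accuracy"] - 0.5
    return MetricReport(
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        baseline_delta=float(point["balanced_accuracy"] - 0.5),
        p_value=float((delta <= 0).mean()),
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )
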