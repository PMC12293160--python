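"""Confusion statistics, precision-recall curves and Monte-Carlo thresholds.

The headline metrics are *balanced accuracy* — the mean of sensitivity
(recall on the positive class) and specificity (recall on the negative
class) — and *balanced precision* (macro-averaged precision) — the mean of
the positive and negative predictive values.  Both are robust to the class
imbalance typical of clinical cohorts (e.g. 41 TD vs 13 SSD).

Significance of an observed statistic is assessed against a Monte-Carlo null
in which predictions carry no information about the truth.  The default
null fixes the observed number of predicted positives m and assigns them to
a uniformly random subset of the N cases; the true-positive overlap is then
hypergeometric, and :func:`exact_fixed_margin_threshold` provides the
closed-form enumeration of the same null for cross-checking the simulation.
An alternative ``bernoulli_rate`` null draws each case's prediction
independently at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    """Undefined statistic (empty class or margin)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report parity with
    conventionally rounded published tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts; the positive class is context-dependent
    (SSD for diagnosis, "inappropriate" for word-level classification)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, truth: Sequence[int], predicted: Sequence[int]) -> "ConfusionSummary":
        truth = np.asarray(truth, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if truth.shape != predicted.shape:
            raise EvaluationError("truth and predictions must align")
        return cls(
            tp=int(((truth == 1) & (predicted == 1)).sum()),
            fn=int(((truth == 1) & (predicted == 0)).sum()),
            fp=int(((truth == 0) & (predicted == 1)).sum()),
            tn=int(((truth == 0) & (predicted == 0)).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise EvaluationError("no positive cases; sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise EvaluationError("no negative cases; specificity undefined")
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        if self.tp + self.fp == 0:
            raise EvaluationError("no predicted positives; PPV undefined")
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        if self.tn + self.fn == 0:
            raise EvaluationError("no predicted negatives; NPV undefined")
        return self.tn / (self.tn + self.fn)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    @property
    def balanced_precision(self) -> float:
        return (self.ppv + self.npv) / 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "balanced_accuracy": self.balanced_accuracy,
            "balanced_precision": self.balanced_precision,
        }


def balanced_accuracy(cm: ConfusionSummary) -> float:
    """(sensitivity + specificity) / 2."""
    return cm.balanced_accuracy


def balanced_precision(cm: ConfusionSummary) -> float:
    """(PPV + NPV) / 2; undefined (raises) when a predicted class is empty."""
    return cm.balanced_precision


def precision_recall_points(
    probabilities: Sequence[float], truth: Sequence[int]
) -> pd.DataFrame:
    """(threshold, recall, precision) at every distinct threshold.

    A case is predicted positive when its probability >= threshold;
    thresholds run from high to low so recall is non-decreasing along the
    output order.  Ties in probability are grouped at a single threshold.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if not np.isfinite(probabilities).all():
        raise EvaluationError("non-finite probability")
    if len(set(truth.tolist())) < 2:
        raise EvaluationError("precision-recall needs both classes in truth")
    thresholds = np.unique(probabilities)[::-1]
    n_pos = int((truth == 1).sum())
    records = []
    for threshold in thresholds:
        predicted = probabilities >= threshold
        tp = int((predicted & (truth == 1)).sum())
        records.append(
            (float(threshold), tp / n_pos, tp / int(predicted.sum()))
        )
    return pd.DataFrame(records, columns=["threshold", "recall", "precision"])


def plot_precision_recall(points: pd.DataFrame, ax=None, label: str | None = None):
    """Plot a precision-recall curve from :func:`precision_recall_points`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(points["recall"], points["precision"], marker=".", label=label)
    ax.set_xlabel("recall (sensitivity)")
    ax.set_ylabel("precision (PPV)")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax


@dataclass(frozen=True)
class ThresholdEstimate:
    statistic: str
    alpha: float
    n_runs: int
    null_model: str
    threshold: float
    seed: int
    null_mean: float


def _stat_from_counts(
    tp: np.ndarray, n_pos: int, n_neg: int, m: np.ndarray, statistic: str
) -> np.ndarray:
    tn = n_neg - (m - tp)
    if statistic == "balanced_accuracy":
        return (tp / n_pos + tn / n_neg) / 2.0
    if statistic == "balanced_precision":
        with np.errstate(invalid="ignore", divide="ignore"):
            return (tp / m + tn / (n_pos + n_neg - m)) / 2.0
    raise EvaluationError(f"unknown statistic {statistic!r}")


def _quantile_index(n: int, alpha: float) -> int:
    """1-based order statistic defining the empirical (1 - alpha) quantile."""
    return int(ceil((1.0 - alpha) * n))


def mc_significance_threshold(
    truth: Sequence[int],
    m: int,
    statistic: str = "balanced_accuracy",
    alpha: float = 0.01,
    n_runs: int = 1_000_000,
    null_model: str = "fixed_margin_permutation",
    seed: int = 0,
) -> ThresholdEstimate:
    """Monte-Carlo estimate of the null (1 - alpha) quantile of a statistic.

    ``truth`` are the binary labels; ``m`` the number of predicted positives.
    Under ``fixed_margin_permutation`` each run assigns the m positive
    predictions to a uniformly random subset of cases, which makes the
    true-positive overlap hypergeometric and is sampled as such.  Under
    ``bernoulli_rate`` each case is predicted positive independently at rate
    ``m / N``; runs with an empty predicted class are discarded (the
    statistic is undefined there).
    """
    truth = np.asarray(truth, dtype=int)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    n_total = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present in truth")
    if not 0 < alpha < 1:
        raise EvaluationError("alpha must lie in (0, 1)")
    if n_runs < 10_000:
        raise EvaluationError("n_runs must be >= 10000")
    rng = np.random.default_rng(seed)
    if null_model == "fixed_margin_permutation":
        if not 0 < m < n_total:
            raise EvaluationError("fixed-margin null needs 0 < m < N")
        tp = rng.hypergeometric(n_pos, n_neg, m, size=n_runs)
        m_run = np.full(n_runs, m)
    elif null_model == "bernoulli_rate":
        rate = m / n_total
        tp = rng.binomial(n_pos, rate, size=n_runs)
        fp = rng.binomial(n_neg, rate, size=n_runs)
        m_run = tp + fp
        keep = (m_run > 0) & (m_run < n_total)
        tp, m_run = tp[keep], m_run[keep]
    else:
        raise EvaluationError(f"unknown null model {null_model!r}")
    sample = _stat_from_counts(tp.astype(float), n_pos, n_neg, m_run.astype(float), statistic)
    sample.sort()
    threshold = float(sample[_quantile_index(sample.size, alpha) - 1])
    return ThresholdEstimate(
        statistic=statistic,
        alpha=alpha,
        n_runs=n_runs,
        null_model=null_model,
        threshold=threshold,
        seed=seed,
        null_mean=float(sample.mean()),
    )


def exact_fixed_margin_threshold(
    n_pos: int, n_neg: int, m: int, statistic: str = "balanced_accuracy",
    alpha: float = 0.01,
) -> float:
    """Closed-form (1 - alpha) quantile under the fixed-margin null.

    Enumerates every possible true-positive overlap k, weights it by the
    hypergeometric pmf, and returns the smallest achievable statistic value
    whose exceedance probability is <= alpha.
    """
    n_total = n_pos + n_neg
    if not 0 < m < n_total:
        raise EvaluationError("fixed-margin null needs 0 < m < N")
    k = np.arange(max(0, m - n_neg), min(n_pos, m) + 1)
    pmf = stats.hypergeom.pmf(k, n_total, n_pos, m)
    values = _stat_from_counts(k.astype(float), n_pos, n_neg, float(m), statistic)
    order = np.argsort(values)
    values, pmf = values[order], pmf[order]
    cdf = np.cumsum(pmf)
    # smallest value with P(X <= value) >= 1 - alpha
    idx = int(np.searchsorted(cdf, 1.0 - alpha - 1e-12))
    return float(values[min(idx, values.size - 1)])


def significance_verdict(observed: float, estimate: ThresholdEstimate) -> str:
    """"significant" iff the observed statistic strictly exceeds the
    estimated null threshold."""
    return "significant" if observed > estimate.threshold else "not significant"
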