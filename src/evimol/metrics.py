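"""Evaluation metrics: calibration, overconfidence, confidence-percentile
curves, and virtual-screening early-recognition measures.

Conventions used throughout:

* predictions are probabilities of the positive class, labels are {0, 1};
* the hard prediction at threshold 0.5 is ``p > 0.5``;
* "high confidence" means p < 0.1 or p > 0.9;
* rankings use stable descending sorts with input-order tie-breaking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Metric name -> value, plus the settings that produced them."""

    values: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_dict(self) -> dict:
        return {"metrics": dict(self.values), "settings": dict(self.settings)}


def _validate(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape != y.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("probs and labels must be equal-length nonempty 1-D arrays")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0 or 1")
    return p, y.astype(np.int64)


def ece(probs, labels, n_bins: int = 10) -> float:
    """Expected calibration error with equal-width confidence bins.

    Confidence is max(p, 1-p); bins partition [0, 1] into ``n_bins`` equal
    intervals (the last bin right-closed); ECE is the sample-weighted mean
    absolute gap between per-bin accuracy and per-bin mean confidence.
    """
    p, y = _validate(probs, labels)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    conf = np.maximum(p, 1.0 - p)
    correct = ((p > 0.5).astype(np.int64) == y)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    total = 0.0
    n = len(p)
    for b in range(n_bins):
        if b < n_bins - 1:
            mask = (conf >= edges[b]) & (conf < edges[b + 1])
        else:
            mask = (conf >= edges[b]) & (conf <= edges[b + 1])
        if not mask.any():
            continue
        acc_b = correct[mask].mean()
        conf_b = conf[mask].mean()
        total += mask.sum() / n * abs(acc_b - conf_b)
    return float(total)


def brier(probs, labels) -> float:
    """Mean squared error between predicted probability and binary label."""
    p, y = _validate(probs, labels)
    return float(np.mean((p - y) ** 2))


def ofr(probs, labels, lo: float = 0.1, hi: float = 0.9) -> float:
    """Overconfident-false rate among high-confidence predictions.

    Fraction of samples with p < lo or p > hi that are wrong
    (p < lo with y = 1, or p > hi with y = 0).  Returns NaN when no
    prediction is high-confidence.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    p, y = _validate(probs, labels)
    high = (p < lo) | (p > hi)
    if not high.any():
        logger.warning("no high-confidence predictions; OFR undefined")
        return float("nan")
    wrong = ((p < lo) & (y == 1)) | ((p > hi) & (y == 0))
    return float(wrong.sum() / high.sum())


def ofn(probs, labels, lo: float = 0.1) -> float:
    """Overconfident-negative rate: confident-negative errors over all N."""
    p, y = _validate(probs, labels)
    return float(((p < lo) & (y == 1)).sum() / len(p))


def confidence_percentile_curve(probs, labels,
                                removal_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5,
                                              0.6, 0.7, 0.8, 0.9)):
    """Accuracy of the retained predictions as the most uncertain are removed.

    Predictions are ranked by the binary entropy of p (higher = more
    uncertain, ties broken by input order); for each fraction f the
    ceil(f*N) most uncertain are dropped and accuracy at threshold 0.5 is
    computed on the rest.  f = 1 is skipped with a warning.
    """
    from .posterior import binary_entropy

    p, y = _validate(probs, labels)
    ent = np.atleast_1d(binary_entropy(p))
    order = np.argsort(-ent, kind="stable")  # most uncertain first
    n = len(p)
    out = []
    for f in removal_grid:
        if f >= 1.0 or math.ceil(f * n) >= n:
            logger.warning("removal fraction %s leaves no samples; skipped", f)
            continue
        k = math.ceil(f * n)
        keep = order[k:]
        acc = float(((p[keep] > 0.5).astype(np.int64) == y[keep]).mean())
        out.append((float(f), acc))
    return out


def enrichment_factor(scores, labels, fraction: float = 0.01) -> float:
    """Active hit-rate in the top-scored fraction relative to the base rate.

    EF_f = (actives in top ceil(f*N) / ceil(f*N)) / (A / N) with a stable
    descending sort on scores.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1 or len(s) == 0:
        raise ValueError("scores and labels must be equal-length nonempty 1-D arrays")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0 or 1")
    y = y.astype(np.int64)
    n_actives = int(y.sum())
    if n_actives == 0:
        raise ValueError("enrichment factor requires at least one active")
    n = len(s)
    k = math.ceil(fraction * n)
    top = np.argsort(-s, kind="stable")[:k]
    hits = int(y[top].sum())
    return float((hits / k) / (n_actives / n))


def bedroc(scores, labels, alpha: float = 80.5) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon-Bayly).

    Exponentially weights early recognition with parameter ``alpha``;
    bounded in [0, 1], with 1 for a perfect ranking of actives first.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(np.int64)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n = len(s)
    n_act = int(y.sum())
    if n_act == 0 or n_act == n:
        raise ValueError("bedroc requires at least one active and one inactive")
    order = np.argsort(-s, kind="stable")
    ranks = np.nonzero(y[order])[0] + 1  # 1-based ranks of actives
    ra = n_act / n
    sum_exp = np.exp(-alpha * ranks / n).sum()
    rand_sum = n_act * (1 - np.exp(-alpha)) / (n * (np.exp(alpha / n) - 1))
    rie = sum_exp / rand_sum
    factor = ra * np.sinh(alpha / 2) / (np.cosh(alpha / 2)
                                        - np.cosh(alpha / 2 - alpha * ra))
    const = 1.0 / (1 - np.exp(alpha * (1 - ra)))
    return float(rie * factor + const)


def classification_summary(probs, labels, threshold: float = 0.5,
                           n_bins: int = 10, ef_fraction: float = 0.01,
                           bedroc_alpha: float = 80.5) -> EvaluationReport:
    """Standard classification metrics plus the calibration/overconfidence
    suite, bundled with the settings used.

    auROC of a constant predictor is 0.5 under the trapezoidal tie
    convention.  EF/BEDROC are included only when both classes are present.
    """
    p, y = _validate(probs, labels)
    pred = (p > threshold).astype(np.int64)
    vals = {
        "accuracy": float(skm.accuracy_score(y, pred)),
        "precision": float(skm.precision_score(y, pred, zero_division=0)),
        "recall": float(skm.recall_score(y, pred, zero_division=0)),
        "f1": float(skm.f1_score(y, pred, zero_division=0)),
        "mcc": float(skm.matthews_corrcoef(y, pred)),
        "brier": brier(p, y),
        "ece": ece(p, y, n_bins=n_bins),
        "ofr": ofr(p, y),
        "ofn": ofn(p, y),
    }
    if len(np.unique(y)) == 2:
        vals["auroc"] = float(skm.roc_auc_score(y, p))
        vals["auprc"] = float(skm.average_precision_score(y, p))
        vals["ef"] = enrichment_factor(p, y, fraction=ef_fraction)
        vals["bedroc"] = bedroc(p, y, alpha=bedroc_alpha)
    return EvaluationReport(
        values=vals,
        settings={"threshold": threshold, "n_bins": n_bins,
                  "ef_fraction": ef_fraction, "bedroc_alpha": bedroc_alpha,
                  "confidence_lo": 0.1, "confidence_hi": 0.9},
    )


def paired_t_test(metric_a, metric_b):
    """Two-sided paired t-test between per-fold metric vectors (reporting aid)."""
    from scipy import stats

    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
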