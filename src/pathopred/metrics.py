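"""Balanced-precision evaluation of pathogenicity classifiers.

Precision-based measures depend on the test-set prior (the fraction of
positive examples), which makes them incomparable across test sets. Writing
``L`` for the likelihood ratio P(predicted+|pathogenic)/P(predicted+|benign),
precision relates to the prior by ``precision/(1-precision) = L * prior/(1-prior)``.
Because ``L`` does not depend on the prior, each empirical precision can be
mapped to the precision expected at a balanced (50%) prior::

    balanced_precision = precision * (1 - prior)
                         / (precision * (1 - prior) + (1 - precision) * prior)

The suite computes the precision-recall curve (descending score thresholds,
ties grouped), AUPRC as interpolation-free average precision, the balanced
curve and its area both pointwise (transforming each precision before the
weighted mean) and via the closed-form prior transform of AUPRC, the recall at
90% balanced precision (R90BP, linearly interpolated on the balanced curve),
and AUROC. Two significance procedures compare classifiers: a one-sided Z test
over bootstrap resamples of one test set, and a one-sided paired t test over
cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError, DegenerateLabelsError

__all__ = [
    "balanced_precision",
    "precision_from_balanced",
    "MetricBundle",
    "ComparisonResult",
    "pr_curve",
    "evaluate_binary",
    "compare",
]


def balanced_precision(precision: float, prior: float) -> float:
    """Precision expected at a balanced prior, given the empirical prior."""
    if not 0.0 < prior < 1.0:
        raise DegenerateLabelsError(f"prior must lie strictly in (0,1), got {prior}")
    p = np.asarray(precision, dtype=float)
    num = p * (1.0 - prior)
    out = num / (num + (1.0 - p) * prior)
    return out.item() if np.isscalar(precision) else out


def precision_from_balanced(bp: float, prior: float) -> float:
    """Inverse of :func:`balanced_precision`: back to the empirical prior."""
    if not 0.0 < prior < 1.0:
        raise DegenerateLabelsError(f"prior must lie strictly in (0,1), got {prior}")
    b = np.asarray(bp, dtype=float)
    num = b * prior
    out = num / (num + (1.0 - b) * (1.0 - prior))
    return out.item() if np.isscalar(bp) else out


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a one-sided classifier comparison (a better than b)."""

    statistic: float
    p_value: float
    method: str
    n_resamples_or_df: int
    degenerate: bool = False


@dataclass
class MetricBundle:
    """Evaluation results for one scored test set."""

    prior: float
    auroc: float
    auprc: float
    aubprc_pointwise: float
    aubprc_eq7: float
    r90bp: float
    curve: pd.DataFrame  # threshold, precision, recall, balanced_precision


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Precision-recall sweep over descending unique score thresholds.

    Tied scores collapse into a single threshold, so the curve has one point
    per unique score; recall is non-decreasing along the sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("labels must include both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # last index of each tie group = the threshold point
    is_last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    thresholds = sorted_scores[is_last]
    tp, fp = tp[is_last], fp[is_last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prior = n_pos / len(labels)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "precision": precision,
            "recall": recall,
            "balanced_precision": balanced_precision(precision, prior),
        }
    )


def _average_precision(recall: np.ndarray, height: np.ndarray) -> float:
    """Step-weighted mean of ``height`` over recall increments (no interpolation)."""
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * height))


def _recall_at_bp(recall: np.ndarray, bp: np.ndarray, target: float) -> float:
    """Largest recall where the balanced-precision polyline reaches ``target``.

    The balanced curve is not monotone; we take the last downward crossing,
    linearly interpolated between adjacent curve points — 1 if the curve ends
    at or above the target, 0 if it never reaches it.
    """
    if bp[-1] >= target:
        return 1.0
    for i in range(len(bp) - 2, -1, -1):
        if bp[i] >= target > bp[i + 1]:
            if bp[i] == bp[i + 1]:
                return float(recall[i])
            frac = (bp[i] - target) / (bp[i] - bp[i + 1])
            return float(recall[i] + frac * (recall[i + 1] - recall[i]))
    return 0.0


def evaluate_binary(
    scores: Sequence[float],
    labels: Sequence[int],
    bp_target: float = 0.9,
) -> MetricBundle:
    """Full metric bundle for one scored test set (higher score = pathogenic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    curve = pr_curve(scores, labels)
    prior = labels.mean()
    recall = curve["recall"].to_numpy()
    precision = curve["precision"].to_numpy()
    bp = curve["balanced_precision"].to_numpy()
    auprc = _average_precision(recall, precision)
    aubprc_pointwise = _average_precision(recall, bp)
    aubprc_eq7 = balanced_precision(auprc, prior)
    return MetricBundle(
        prior=float(prior),
        auroc=float(roc_auc_score(labels, scores)),
        auprc=auprc,
        aubprc_pointwise=aubprc_pointwise,
        aubprc_eq7=aubprc_eq7,
        r90bp=_recall_at_bp(recall, bp, bp_target),
        curve=curve,
    )


_METRIC_FNS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "auroc": lambda s, y: evaluate_binary(s, y).auroc,
    "auprc": lambda s, y: evaluate_binary(s, y).auprc,
    "aubprc": lambda s, y: evaluate_binary(s, y).aubprc_pointwise,
    "aubprc_eq7": lambda s, y: evaluate_binary(s, y).aubprc_eq7,
    "r90bp": lambda s, y: evaluate_binary(s, y).r90bp,
}


def compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int] | None = None,
    metric: str = "aubprc",
    method: str = "bootstrap_z",
    n: int = 2000,
    seed: int | None = None,
) -> ComparisonResult:
    """One-sided comparison of two classifiers ("a outperforms b").

    ``bootstrap_z`` resamples the shared test set with replacement ``n`` times,
    computes the per-resample metric difference, and refers mean/sd of the
    differences to the normal upper tail. ``paired_t`` treats ``scores_a`` and
    ``scores_b`` as per-fold metric vectors and runs a one-sided paired t test
    with len-1 degrees of freedom. Zero-variance differences short-circuit to
    p = 0 (positive mean) or p = 1, flagged degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if method == "paired_t":
        if len(a) != len(b):
            raise ConfigurationError("paired fold vectors must have equal length")
        diffs = a - b
        df = len(diffs) - 1
        if np.std(diffs, ddof=1) == 0 or df < 1:
            return ComparisonResult(
                statistic=np.inf if diffs.mean() > 0 else -np.inf,
                p_value=0.0 if diffs.mean() > 0 else 1.0,
                method=method,
                n_resamples_or_df=max(df, 0),
                degenerate=True,
            )
        res = stats.ttest_rel(a, b, alternative="greater")
        return ComparisonResult(float(res.statistic), float(res.pvalue), method, df)
    if method != "bootstrap_z":
        raise ConfigurationError(f"unknown comparison method {method!r}")
    if labels is None:
        raise ConfigurationError("bootstrap_z requires per-variant labels")
    y = np.asarray(labels).astype(int)
    if not (len(a) == len(b) == len(y)):
        raise ConfigurationError("scores and labels must be aligned per variant")
    fn = _METRIC_FNS[metric]
    rng = np.random.default_rng(seed)
    diffs = np.empty(n)
    m = len(y)
    for i in range(n):
        idx = rng.integers(0, m, size=m)
        for _ in range(1000):
            if 0 < y[idx].sum() < m:
                break
            idx = rng.integers(0, m, size=m)
        else:  # pragma: no cover - requires pathological label balance
            raise DegenerateLabelsError("could not draw a two-class bootstrap sample")
        diffs[i] = fn(a[idx], y[idx]) - fn(b[idx], y[idx])
    sd = diffs.std(ddof=1)
    if sd == 0:
        return ComparisonResult(
            statistic=np.inf if diffs.mean() > 0 else -np.inf,
            p_value=0.0 if diffs.mean() > 0 else 1.0,
            method=method,
            n_resamples_or_df=n,
            degenerate=True,
        )
    z = diffs.mean() / sd
    return ComparisonResult(float(z), float(stats.norm.sf(z)), method, n)
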