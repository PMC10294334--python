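"""Benchmark metrics for differential-composition calls.

P-values act as scores (smaller = stronger evidence of differential
abundance); binary decisions use ``p < alpha``.  Metrics pool the
(p-value, truth) pairs across simulation runs; bootstrap intervals
resample whole runs.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import average_precision_score, roc_auc_score

from .counts import CellCountTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ["mcc", "f1", "sensitivity", "specificity", "roc_auc", "pr_auc"]


def _confusion(decisions: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(decisions & truth))
    fp = int(np.sum(decisions & ~truth))
    tn = int(np.sum(~decisions & ~truth))
    fn = int(np.sum(~decisions & truth))
    return tp, fp, tn, fn


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def classification_metrics(
    p_values: np.ndarray, truth: np.ndarray, alpha: float = 0.05
) -> dict:
    """MCC, F1, sensitivity, specificity, ROC AUC and PR AUC.

    AUCs use ``1 - p`` as the score so smaller p-values rank as more
    positive; single-class truth yields NaN AUCs with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p.shape != truth.shape:
        raise ValidationError("p_values and truth must align")
    ok = np.isfinite(p)
    if not ok.all():
        logger.warning("dropping %d NA p-values", int((~ok).sum()))
        p, truth = p[ok], truth[ok]
    decisions = p < alpha
    tp, fp, tn, fn = _confusion(decisions, truth)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    if truth.all() or not truth.any():
        logger.warning("single-class truth: AUCs undefined")
        roc = pr = np.nan
    else:
        roc = float(roc_auc_score(truth, 1 - p))
        pr = float(average_precision_score(truth, 1 - p))
    return {
        "mcc": mcc_from_counts(tp, fp, tn, fn),
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
        "roc_auc": roc,
        "pr_auc": pr,
        "n": len(p),
        "decision_threshold": alpha,
    }


def bootstrap_ci(
    run_pvalues: Sequence[np.ndarray],
    run_truths: Sequence[np.ndarray],
    alpha: float = 0.05,
    n_boot: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """95% percentile intervals by resampling whole runs with replacement."""
    if len(run_pvalues) < 2:
        raise ValidationError("bootstrap needs at least 2 runs")
    rng = np.random.default_rng(seed)
    point = classification_metrics(
        np.concatenate(run_pvalues), np.concatenate(run_truths), alpha
    )
    samples: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    n_runs = len(run_pvalues)
    for _ in range(n_boot):
        idx = rng.integers(0, n_runs, size=n_runs)
        p = np.concatenate([run_pvalues[i] for i in idx])
        t = np.concatenate([run_truths[i] for i in idx])
        if t.all() or not t.any():
            logger.warning("degenerate bootstrap resample skipped for AUCs")
        met = classification_metrics(p, t, alpha)
        for m in METRIC_NAMES:
            if np.isfinite(met[m]):
                samples[m].append(met[m])
    rows = []
    for m in METRIC_NAMES:
        vals = np.array(samples[m])
        lo, hi = (
            np.percentile(vals, [2.5, 97.5]) if vals.size else (np.nan, np.nan)
        )
        rows.append({"metric": m, "estimate": point[m], "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def fisher_pooled(counts: CellCountTable, condition: np.ndarray) -> pd.Series:
    """Fisher's exact test on replicate-pooled counts, per cell type.

    Counts are summed over replicates within each condition and each cell
    type is tested with a two-sided Fisher's exact test of its pooled
    count against the pooled remainder.
    """
    condition = np.asarray(condition)
    levels = np.unique(condition)
    if len(levels) != 2:
        raise ValidationError(f"need exactly two conditions, got {levels}")
    pooled = np.array(
        [counts.counts[condition == lv].sum(axis=0) for lv in levels]
    )
    tot = pooled.sum(axis=1)
    if np.any(tot == 0):
        raise ValidationError("a condition has zero total cells")
    pvals = []
    for j in range(counts.k):
        table = [
            [pooled[0, j], tot[0] - pooled[0, j]],
            [pooled[1, j], tot[1] - pooled[1, j]],
        ]
        pvals.append(fisher_exact(table, alternative="two-sided")[1])
    return pd.Series(pvals, index=counts.labels, name="pval")
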