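"""Binary-classification and rank metrics for contact prediction.

ROC construction sweeps descending unique score thresholds (ties move
together), AUROC is the trapezoid area — equal to the normalized
Mann-Whitney U statistic — and average precision is the step integral of
the precision-recall curve.  Spearman correlation is the Pearson
correlation of mid-ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_curve, auc

from .genome import gc_fraction


@dataclass
class EvalReport:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    average_precision: float
    n_pos: int
    n_neg: int
    strata: dict = field(default_factory=dict)


def binary_metrics(labels: np.ndarray, scores: np.ndarray) -> EvalReport:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary_metrics requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return EvalReport(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auroc=float(auc(fpr, tpr)),
        average_precision=float(average_precision_score(labels, scores)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance input; Spearman undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def gc_baseline(pairs, store, window_bp: int) -> np.ndarray:
    """Mean GC fraction of the two windows of each (chromA, startA, chromB,
    startB) pair — the sequence-composition contact predictor."""
    out = np.empty(len(pairs))
    for k, (ca, sa, cb, sb) in enumerate(pairs):
        ga = gc_fraction(store.fetch_window(ca, sa, window_bp).seq)
        gb = gc_fraction(store.fetch_window(cb, sb, window_bp).seq)
        out[k] = 0.5 * (ga + gb)
    return out


def stratified_metrics(labels, scores, pair_strata) -> dict[str, EvalReport | None]:
    """binary_metrics per stratum; one-class strata map to None (flagged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pair_strata = np.asarray(pair_strata)
    out: dict[str, EvalReport | None] = {}
    for stratum in np.unique(pair_strata):
        sel = pair_strata == stratum
        try:
            out[str(stratum)] = binary_metrics(labels[sel], scores[sel])
        except ValueError:
            out[str(stratum)] = None
    return out
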