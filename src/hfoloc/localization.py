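"""SOZ localization from channel HFO rates: ROC-AUC, PR maximal F1, and
across-patient method comparison.

Channels are classified as seizure-onset-zone (SOZ) or not by thresholding
their HFO rate (events/min).  A channel is predicted SOZ when its rate
strictly exceeds the threshold; sweeping the threshold over all observed
rates (plus sentinels) traces a ROC curve (TPR vs FPR, area by trapezoid)
and a precision-recall curve, summarized by its maximal F1.  The two views
are complementary: with many more nSOZ than SOZ channels the ROC can look
favorable while precision — and hence the maximal F1 — stays low.

Method comparison across patients uses the Wilcoxon signed-rank test on
paired AUC (and maximal-F1) vectors and the Pearson correlation of the
maximal F1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .montage_io import ChannelLabels, EventSet

__all__ = [
    "RateTable",
    "LocalizationResult",
    "compute_rates",
    "roc_auc",
    "pr_max_f1",
    "localize",
    "compare_methods",
]


@dataclass
class RateTable:
    """Per-channel HFO rates (events/min) over the analyzed minutes."""

    rates: dict[str, float]
    minutes: float

    def __post_init__(self) -> None:
        if self.minutes <= 0:
            raise ValueError("analyzed minutes must be positive")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")

    def __getitem__(self, channel: str) -> float:
        return self.rates[channel]

    def to_series(self) -> pd.Series:
        return pd.Series(self.rates, name="rate_per_min").sort_index()


@dataclass
class LocalizationResult:
    """ROC and PR summaries of rate-based SOZ classification."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    recall: np.ndarray
    precision: np.ndarray
    max_f1: float
    thresholds: np.ndarray
    extras: dict = field(default_factory=dict)


def compute_rates(
    events: EventSet,
    epochs: list[tuple[float, float]],
    channels: list[str],
) -> RateTable:
    """Events per minute per channel, pooled over all epochs."""
    minutes = sum(stop - start for start, stop in epochs) / 60.0
    if minutes <= 0:
        raise ValueError("zero analyzed minutes")
    counts = events.counts()
    return RateTable(
        rates={ch: counts.get(ch, 0) / minutes for ch in channels}, minutes=minutes
    )


def _rate_vectors(
    rates: RateTable | Mapping[str, float], labels: ChannelLabels
) -> tuple[np.ndarray, np.ndarray]:
    getter = rates.rates if isinstance(rates, RateTable) else rates
    soz = np.array([getter[c] for c in sorted(labels.soz)], dtype=float)
    nsoz = np.array([getter[c] for c in sorted(labels.nsoz)], dtype=float)
    return soz, nsoz


def _thresholds(soz: np.ndarray, nsoz: np.ndarray) -> np.ndarray:
    uniq = np.unique(np.concatenate([soz, nsoz]))
    return np.concatenate(([-np.inf], uniq, [np.inf]))


def roc_auc(
    rates: RateTable | Mapping[str, float], labels: ChannelLabels
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """ROC curve of the rate-threshold classifier and its trapezoidal AUC.

    A channel is predicted SOZ when its rate strictly exceeds the threshold;
    sentinel thresholds put (0,0) and (1,1) on the curve.  Both classes must
    be non-empty.  Returns (fpr, tpr, auc, thresholds) with points ordered
    by increasing FPR.
    """
    soz, nsoz = _rate_vectors(rates, labels)
    if soz.size == 0 or nsoz.size == 0:
        raise ValueError("both SOZ and nSOZ classes must be non-empty")
    thr = _thresholds(soz, nsoz)
    tpr = np.array([(soz > t).mean() for t in thr])
    fpr = np.array([(nsoz > t).mean() for t in thr])
    # thresholds ascend, so FPR/TPR descend; reverse for a left-to-right curve
    fpr_curve = fpr[::-1]
    tpr_curve = tpr[::-1]
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    return fpr_curve, tpr_curve, auc, thr[::-1]


def pr_max_f1(
    rates: RateTable | Mapping[str, float], labels: ChannelLabels
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Precision-recall curve over the same threshold sweep and its max F1.

    Thresholds where no channel is predicted SOZ leave precision (and F1)
    undefined; such points are skipped in the maximum rather than scored 0.
    Returns (recall, precision, max_f1, thresholds) for the defined points.
    """
    soz, nsoz = _rate_vectors(rates, labels)
    if soz.size == 0:
        raise ValueError("SOZ class must be non-empty")
    thr = _thresholds(soz, nsoz)
    recall, precision, f1s, kept_thr = [], [], [], []
    for t in thr:
        tp = int((soz > t).sum())
        fp = int((nsoz > t).sum())
        fn = soz.size - tp
        if tp + fp == 0:
            continue
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        recall.append(r)
        precision.append(p)
        f1s.append(tp / (tp + 0.5 * (fp + fn)))
        kept_thr.append(t)
    if not f1s:
        raise ValueError("no threshold yields a defined precision")
    return (
        np.array(recall),
        np.array(precision),
        float(max(f1s)),
        np.array(kept_thr),
    )


def localize(
    rates: RateTable | Mapping[str, float], labels: ChannelLabels
) -> LocalizationResult:
    """Full ROC + PR localization summary for one rate table."""
    fpr, tpr, auc, thr = roc_auc(rates, labels)
    recall, precision, max_f1, _ = pr_max_f1(rates, labels)
    return LocalizationResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        recall=recall,
        precision=precision,
        max_f1=max_f1,
        thresholds=thr,
    )


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> dict:
    d = x - y
    if np.all(d == 0):
        return {"p": None, "degenerate": True, "note": "all paired differences are zero"}
    try:
        res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                             method="exact")
    except ValueError:
        res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                             method="auto")
    return {"p": float(res.pvalue), "degenerate": False}


def compare_methods(
    auc_scores: pd.DataFrame, f1_scores: pd.DataFrame
) -> dict[tuple[str, str], dict]:
    """Pairwise comparison of detection methods across patients.

    Both frames are patients x methods with identical shape.  For each
    method pair: two-sided Wilcoxon signed-rank p on the AUCs and on the
    maximal F1s (exact distribution where available, zero differences
    dropped; all-zero difference vectors are reported as degenerate), and
    the Pearson correlation (r, p) of the maximal F1s.  Constant vectors
    leave the correlation undefined.
    """
    if list(auc_scores.columns) != list(f1_scores.columns):
        raise ValueError("method columns must match")
    if len(auc_scores) < 5:
        raise ValueError("need at least 5 paired patients")
    out: dict[tuple[str, str], dict] = {}
    methods = list(auc_scores.columns)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            entry = {
                "wilcoxon_auc": _wilcoxon(
                    auc_scores[m1].to_numpy(float), auc_scores[m2].to_numpy(float)
                ),
                "wilcoxon_max_f1": _wilcoxon(
                    f1_scores[m1].to_numpy(float), f1_scores[m2].to_numpy(float)
                ),
            }
            x = f1_scores[m1].to_numpy(float)
            y = f1_scores[m2].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                entry["pearson_max_f1"] = {"r": None, "p": None,
                                           "note": "constant vector; correlation undefined"}
            else:
                r, p = stats.pearsonr(x, y)
                entry["pearson_max_f1"] = {"r": float(r), "p": float(p)}
            out[(m1, m2)] = entry
    return out
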