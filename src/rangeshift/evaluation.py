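"""Discrimination, thresholding and calibration metrics for
presence/background models.

AUC is the Mann-Whitney statistic (ties count one half): the probability a
random presence outscores a random background point. Binarization
thresholds equalize sensitivity and specificity; the true skill statistic
TSS = sensitivity + specificity - 1 is the headline threshold-dependent
score because, unlike kappa, it is insensitive to prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


def roc_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney U / (n1 * n0), ties counted one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def swets_accuracy_class(auc: float) -> str:
    """Conventional AUC accuracy labels: >0.9 high, 0.7-0.9 good, <0.7 low."""
    if auc > 0.9:
        return "high"
    if auc >= 0.7:
        return "good"
    return "low"


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.sort(np.concatenate([uniq, mids]))


def classification_metrics(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    threshold: float,
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, tss, percent_correct) at ``threshold``.

    A score exactly at the threshold counts as predicted-present.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    sens = float(np.mean(p >= threshold))
    spec = float(np.mean(b < threshold))
    tss = sens + spec - 1.0
    correct = float((p >= threshold).sum() + (b < threshold).sum())
    pct = 100.0 * correct / (p.size + b.size)
    return sens, spec, tss, pct


def threshold_sens_eq_spec(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Threshold minimizing |sensitivity - specificity|.

    Candidates are the union of observed scores and midpoints between
    consecutive distinct scores; exact ties break toward the smallest
    threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    best_t, best_gap = None, np.inf
    for t in _candidate_thresholds(np.concatenate([p, b])):
        sens, spec, _, _ = classification_metrics(p, b, t)
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_t, best_gap = float(t), gap
    return best_t


def calibration_bins(
    presence_scores: np.ndarray, background_scores: np.ndarray, n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Equal-width probability bins: (mean predicted, observed presence
    fraction, count) per nonempty bin."""
    if n_bins < 2:
        raise ValueError("need at least 2 calibration bins")
    scores = np.concatenate([presence_scores, background_scores]).astype(float)
    y = np.concatenate([np.ones(len(presence_scores)), np.zeros(len(background_scores))])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    out = []
    for k in range(n_bins):
        sel = idx == k
        if sel.any():
            out.append((float(scores[sel].mean()), float(y[sel].mean()), int(sel.sum())))
    return out


def deviance_residuals(y: np.ndarray, prob: np.ndarray, clamp: float = 1e-6) -> np.ndarray:
    """Signed Bernoulli deviance residuals with probability clamping."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(prob, dtype=float), clamp, 1.0 - clamp)
    dev = -2.0 * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return np.sign(y - p) * np.sqrt(dev)


@dataclass
class EvaluationReport:
    """Per-model scorecard at the sensitivity=specificity threshold."""

    family: str
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    percent_correct: float
    accuracy_class: str
    calibration: list[tuple[float, float, int]] = field(default_factory=list)
    deviance: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "auc": round(self.auc, 4),
            "threshold": round(self.threshold, 6),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "tss": round(self.tss, 4),
            "percent_correct": round(self.percent_correct, 2),
            "accuracy_class": self.accuracy_class,
        }


def evaluate_model(
    family: str,
    train_presence: np.ndarray,
    train_background: np.ndarray,
    test_presence: np.ndarray,
    test_background: np.ndarray,
    n_bins: int = 10,
) -> EvaluationReport:
    """Score a model: threshold fitted on training scores and frozen; AUC,
    TSS and correct-classification rate reported on the held-out test split."""
    threshold = threshold_sens_eq_spec(train_presence, train_background)
    auc = roc_auc(test_presence, test_background)
    sens, spec, tss, pct = classification_metrics(test_presence, test_background, threshold)
    y = np.concatenate([np.ones(len(test_presence)), np.zeros(len(test_background))])
    probs = np.concatenate([test_presence, test_background])
    return EvaluationReport(
        family=family,
        auc=auc,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        tss=tss,
        percent_correct=pct,
        accuracy_class=swets_accuracy_class(auc),
        calibration=calibration_bins(test_presence, test_background, n_bins=n_bins),
        deviance=deviance_residuals(y, probs),
    )
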