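"""Site-level scoring and operating-point metrics.

Sites with multiple captures are scored by their highest-scoring image.
The ROC AUC is the Mann–Whitney concordance probability; the operating
threshold maximizes the Youden index (sensitivity + specificity − 1) on the
*validation* scores and is then applied unchanged to the test set.
Probability quality is summarized by the Brier score and the Brier Skill
Score against a climatology (base-rate) reference forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class SiteScore:
    site_id: str
    image_level_scores: list[float]
    site_score: float
    truth: Optional[int] = None
    predicted: Optional[int] = None


def aggregate_site_scores(
    image_scores: Mapping[str, Sequence[float]],
    truths: Optional[Mapping[str, int]] = None,
) -> list[SiteScore]:
    """Max-aggregate image-level scores per site (order-invariant)."""
    out = []
    for site_id in sorted(image_scores):
        scores = [float(s) for s in image_scores[site_id]]
        if not scores:
            raise ValueError(f"site {site_id} has no image scores")
        out.append(
            SiteScore(
                site_id=site_id,
                image_level_scores=scores,
                site_score=max(scores),
                truth=None if truths is None else int(truths[site_id]),
            )
        )
    return out


def _check_two_classes(truths: np.ndarray) -> None:
    if len(np.unique(truths)) < 2:
        raise ValueError("AUC undefined: only one class present")


def roc_auc(site_scores: Sequence[float], truths: Sequence[int]) -> float:
    """Area under the ROC curve = P(score+ > score−) + ½ P(tie)."""
    truths = np.asarray(truths)
    _check_two_classes(truths)
    return float(roc_auc_score(truths, np.asarray(site_scores, dtype=float)))


def youden_candidates(scores: np.ndarray) -> np.ndarray:
    """Candidate thresholds: midpoints of adjacent unique scores plus one
    below the minimum and one above the maximum."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 0.5], mids, [u[-1] + 0.5]])


def youden_threshold(site_scores: Sequence[float], truths: Sequence[int]) -> float:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken toward the larger threshold (higher specificity).
    Computed on validation scores; the caller applies it to the test set.
    """
    scores = np.asarray(site_scores, dtype=float)
    truths = np.asarray(truths)
    _check_two_classes(truths)
    best_t, best_j = None, -np.inf
    for t in youden_candidates(scores):
        pred = scores >= t
        sens = (pred & (truths == 1)).sum() / (truths == 1).sum()
        spec = (~pred & (truths == 0)).sum() / (truths == 0).sum()
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, float(t)
    return best_t


def confusion_metrics(
    site_scores: Sequence[float], truths: Sequence[int], threshold: float
) -> dict:
    """Exact integer confusion counts at ``score >= threshold``.

    Sensitivity and specificity are percentages reported to one decimal.
    """
    scores = np.asarray(site_scores, dtype=float)
    truths = np.asarray(truths)
    pred = scores >= threshold
    tp = int((pred & (truths == 1)).sum())
    fn = int((~pred & (truths == 1)).sum())
    tn = int((~pred & (truths == 0)).sum())
    fp = int((pred & (truths == 0)).sum())
    sens = round(100.0 * tp / (tp + fn), 1) if tp + fn else float("nan")
    spec = round(100.0 * tn / (tn + fp), 1) if tn + fp else float("nan")
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "sensitivity": sens,
        "specificity": spec,
        "threshold": float(threshold),
    }


def brier(site_scores: Sequence[float], truths: Sequence[int]) -> float:
    """Mean squared difference between forecast probability and outcome."""
    scores = np.asarray(site_scores, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    return float(np.mean((scores - truths) ** 2))


def brier_skill(site_scores: Sequence[float], truths: Sequence[int]) -> float:
    """1 − Brier/Brier_ref with a constant base-rate reference forecast.

    0 for the climatology forecast itself; 1 iff the forecast is perfect;
    negative when worse than climatology.
    """
    truths_arr = np.asarray(truths, dtype=float)
    base = float(truths_arr.mean())
    b_ref = brier(np.full_like(truths_arr, base), truths)
    b = brier(site_scores, truths)
    if b_ref == 0.0:
        return 1.0 if b == 0.0 else -np.inf
    return float(1.0 - b / b_ref)


@dataclass
class EvalReport:
    """Full evaluation of one model on a validation/test split pair."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    confusion: dict = field(default_factory=dict)
    brier: float = float("nan")
    brier_skill: float = float("nan")
    n_sites: dict = field(default_factory=dict)
    validation_auc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "validation_auc": self.validation_auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion,
            "brier": self.brier,
            "brier_skill": self.brier_skill,
            "n_sites": self.n_sites,
        }


def evaluate_split_pair(
    val_scores: Sequence[float],
    val_truths: Sequence[int],
    test_scores: Sequence[float],
    test_truths: Sequence[int],
) -> EvalReport:
    """Threshold from validation, all metrics on the test set."""
    threshold = youden_threshold(val_scores, val_truths)
    cm = confusion_metrics(test_scores, test_truths, threshold)
    test_truths_arr = np.asarray(test_truths)
    return EvalReport(
        auc=roc_auc(test_scores, test_truths),
        validation_auc=roc_auc(val_scores, val_truths),
        threshold=threshold,
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        confusion={k: cm[k] for k in ("TP", "FP", "TN", "FN")},
        brier=brier(test_scores, test_truths),
        brier_skill=brier_skill(test_scores, test_truths),
        n_sites={
            "positive": int((test_truths_arr == 1).sum()),
            "negative": int((test_truths_arr == 0).sum()),
        },
    )
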