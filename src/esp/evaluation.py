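"""Metrics, stratified reports, uncertainty bands and model-comparison tests.

Core metrics are accuracy, ROC-AUC and the Matthews correlation coefficient
(MCC) at the ≥0.5 decision threshold. Reports stratify the test set by
enzyme identity band, by whether the molecule was seen among training
positives, and by prediction-score band (scores in [0.4, 0.6] are treated
as uncertain). Model comparisons use McNemar's test on paired predictions
and the two-sided Mann-Whitney U test on per-example error indicators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from esp.classifier import classify

__all__ = [
    "ConfusionCounts",
    "MetricsBundle",
    "ScoreBandReport",
    "confusion",
    "mcc",
    "roc_auc",
    "roc_curve",
    "compute_metrics",
    "stratified_report",
    "score_band_report",
    "mcnemar",
    "mannwhitney",
    "learning_curve",
    "molecule_occurrence_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def fnr(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


@dataclass
class MetricsBundle:
    accuracy: float
    roc_auc: float | None
    mcc: float | None
    confusion: ConfusionCounts
    n: int
    stratum: str = "overall"

    def as_dict(self) -> dict:
        return {"stratum": self.stratum, "n": self.n, "accuracy": self.accuracy,
                "roc_auc": self.roc_auc, "mcc": self.mcc,
                "tp": self.confusion.tp, "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn}


def confusion(scores: np.ndarray, labels: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    scores, labels = np.asarray(scores), np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    preds = classify(scores, threshold)
    return ConfusionCounts(
        tp=int(np.sum((preds == 1) & (labels == 1))),
        tn=int(np.sum((preds == 0) & (labels == 0))),
        fp=int(np.sum((preds == 1) & (labels == 0))),
        fn=int(np.sum((preds == 0) & (labels == 1))),
    )


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return None
    return (c.tp * c.tn - c.fp * c.fn) / denom


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; ties receive half credit (mid-rank U)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def roc_curve(scores: np.ndarray, labels: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fpr, tpr, thr = _sk_roc_curve(np.asarray(labels), np.asarray(scores))
    return fpr, tpr, thr


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5, stratum: str = "overall"
                    ) -> MetricsBundle:
    c = confusion(scores, labels, threshold)
    labels = np.asarray(labels)
    auc = roc_auc(scores, labels) if len(np.unique(labels)) == 2 else None
    return MetricsBundle(accuracy=(c.tp + c.tn) / c.n, roc_auc=auc, mcc=mcc(c),
                         confusion=c, n=c.n, stratum=stratum)


def stratified_report(scores: np.ndarray, labels: np.ndarray,
                      strata: dict[str, np.ndarray],
                      threshold: float = 0.5) -> dict[str, list[MetricsBundle]]:
    """Per-stratum metrics for each stratification key, plus the overall bundle.

    Empty strata appear as bundles with n=0 and missing metrics rather than
    being dropped silently.
    """
    scores, labels = np.asarray(scores), np.asarray(labels)
    report = {"overall": [compute_metrics(scores, labels, threshold)]}
    for key, stratum_labels in strata.items():
        stratum_labels = np.asarray(stratum_labels)
        if stratum_labels.shape != scores.shape:
            raise ValueError(f"stratum {key!r} does not cover the evaluated set")
        bundles = []
        for value in sorted(map(str, np.unique(stratum_labels))):
            mask = stratum_labels.astype(str) == value
            if mask.sum() == 0:
                bundles.append(MetricsBundle(float("nan"), None, None,
                                             ConfusionCounts(0, 0, 0, 0), 0,
                                             stratum=f"{key}={value}"))
                continue
            bundles.append(compute_metrics(scores[mask], labels[mask], threshold,
                                           stratum=f"{key}={value}"))
        report[key] = bundles
    return report


@dataclass
class ScoreBandReport:
    band: tuple[float, float]
    fraction_in_band: float
    in_band: MetricsBundle | None
    overall: MetricsBundle


def score_band_report(scores: np.ndarray, labels: np.ndarray,
                      band: tuple[float, float] = (0.4, 0.6)) -> ScoreBandReport:
    """Fraction and quality of predictions inside the uncertainty score band.

    Band membership is a closed interval; scores in [0.4, 0.6] are the
    predictions a user should treat as uncertain.
    """
    lo, hi = band
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"invalid score band {band}")
    scores, labels = np.asarray(scores), np.asarray(labels)
    mask = (scores >= lo) & (scores <= hi)
    overall = compute_metrics(scores, labels)
    in_band = None
    if mask.any():
        c = confusion(scores[mask], labels[mask])
        auc = roc_auc(scores[mask], labels[mask]) \
            if len(np.unique(labels[mask])) == 2 else None
        in_band = MetricsBundle((c.tp + c.tn) / c.n, auc, mcc(c), c, c.n,
                                stratum="in_band")
    return ScoreBandReport(band=(lo, hi), fraction_in_band=float(mask.mean()),
                           in_band=in_band, overall=overall)


def mcnemar(preds_a: np.ndarray, preds_b: np.ndarray,
            labels: np.ndarray) -> float:
    """McNemar's test on the discordant error counts of two models.

    b = examples model A got right and B wrong; c = the reverse. Exact
    two-sided binomial when b + c < 25, else chi-squared with continuity
    correction. Identical error patterns give p = 1.
    """
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    labels = np.asarray(labels)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction and label arrays must share a length")
    right_a = preds_a == labels
    right_b = preds_b == labels
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
        return float(min(1.0, p))
    chi2 = (abs(b - c) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


def mannwhitney(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U test on two error samples.

    Exact enumeration of all rank splits (with mid-rank ties) when both
    samples have ≤ 8 observations; otherwise the normal approximation with
    tie correction.
    """
    a, b = np.asarray(errors_a, dtype=float), np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # mid-ranks
        mu = n1 * n2 / 2.0
        obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        obs_dev = abs(obs_u - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        return count / total
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def learning_curve(fractions: list[float], trainer, enzyme_order: list[str],
                   train_pairs, test_scores_fn) -> pd.DataFrame:
    """Train on nested enzyme subsets and score a fixed test set.

    ``enzyme_order`` is one seeded random ordering of training enzymes;
    the subset at fraction f contains the pairs of the first ceil(f·n)
    enzymes, so subsets are nested by construction. ``trainer(pairs)``
    returns a fitted model and ``test_scores_fn(model)`` returns
    (scores, labels) on the fixed test set. The returned frame carries
    per-fraction metrics and Spearman trend correlations as attributes
    ``spearman_accuracy`` / ``spearman_auc``.
    """
    rows = []
    n = len(enzyme_order)
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        keep = set(enzyme_order[: math.ceil(frac * n)])
        subset = [p for p in train_pairs if p.enzyme_id in keep]
        labels = {p.label for p in subset}
        if labels != {0, 1}:
            import warnings

            warnings.warn(f"fraction {frac}: single-class subset, skipped")
            continue
        model = trainer(subset)
        scores, test_labels = test_scores_fn(model)
        m = compute_metrics(scores, test_labels)
        rows.append({"fraction": frac, "n_train": len(subset),
                     "accuracy": m.accuracy, "roc_auc": m.roc_auc, "mcc": m.mcc})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        df.attrs["spearman_accuracy"] = float(
            stats.spearmanr(df["fraction"], df["accuracy"]).statistic)
        df.attrs["spearman_auc"] = float(
            stats.spearmanr(df["fraction"], df["roc_auc"]).statistic)
    return df


_BUCKETS = ("0", "1", "2", "3-5", ">5")


def _bucket(count: int) -> str:
    if count <= 2:
        return str(count)
    return "3-5" if count <= 5 else ">5"


def molecule_occurrence_report(scores: np.ndarray, labels: np.ndarray,
                               molecule_ids: list[str],
                               train_positive_counts: dict[str, int]
                               ) -> pd.DataFrame:
    """Test metrics grouped by how often the molecule was a training substrate."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    buckets = np.array([_bucket(train_positive_counts.get(m, 0))
                        for m in molecule_ids])
    rows = []
    for b in _BUCKETS:
        mask = buckets == b
        if not mask.any():
            continue
        c = confusion(scores[mask], labels[mask])
        auc = roc_auc(scores[mask], labels[mask]) \
            if len(np.unique(labels[mask])) == 2 else None
        rows.append({"bucket": b, "n": int(mask.sum()),
                     "accuracy": (c.tp + c.tn) / c.n, "roc_auc": auc,
                     "mcc": mcc(c)})
    return pd.DataFrame(rows)
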