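"""Binary-classification evaluation: confusion metrics, AUC, fold summaries
with t-distribution confidence intervals, bootstrap CIs, and DeLong's test.

Conventions

* Zero-denominator metrics (e.g. PPV with no predicted positives) are
  reported as NaN and listed in the report's ``undefined`` set — never
  silently 0.
* Fold summaries use the population SD (denominator k) by default, with the
  sample convention available via ``ddof=1``; the 95% CI uses Student's t
  with k-1 degrees of freedom and SE = SD/sqrt(k).
* The bootstrap CI is non-stratified percentile case resampling.
* DeLong's test uses the structural-components formulation with midranks
  (O(n log n)); identical score vectors have zero variance and return p = 1
  by convention (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_and_metrics",
    "auc_score",
    "fold_summary",
    "bootstrap_ci",
    "delong_test",
    "METRIC_COLUMNS",
]

#: Column order used by every emitted metric table.
METRIC_COLUMNS = ["AUC", "ACC", "SEN", "SPE", "F1", "PPV", "NPV"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def confusion_and_metrics(labels, predictions) -> tuple[ConfusionCounts, MetricReport]:
    """Confusion counts and the six threshold metrics from hard predictions."""
    labels = np.asarray(labels).reshape(-1).astype(int)
    predictions = np.asarray(predictions).reshape(-1).astype(int)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    counts = ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )
    undefined: set[str] = set()
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    ppv = _ratio(tp, tp + fp, "PPV", undefined)
    npv = _ratio(tn, tn + fn, "NPV", undefined)
    sen = _ratio(tp, tp + fn, "SEN", undefined)
    spe = _ratio(tn, tn + fp, "SPE", undefined)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1", undefined)
    report = MetricReport(
        values={"ACC": acc, "PPV": ppv, "NPV": npv, "SEN": sen, "SPE": spe, "F1": f1},
        undefined=undefined,
    )
    return counts, report


def auc_score(labels, scores) -> float:
    """ROC AUC as the tie-corrected concordance probability, via midranks."""
    labels = np.asarray(labels).reshape(-1).astype(int)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def fold_summary(values, ddof: int = 0, confidence: float = 0.95) -> dict[str, float]:
    """Mean, SD and Student-t CI over per-fold metric values."""
    values = np.asarray(values, dtype=float).reshape(-1)
    k = values.size
    if k < 2:
        raise ValueError("need at least two folds")
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    se = sd / np.sqrt(k)
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, df=k - 1))
    return {
        "mean": mean,
        "sd": sd,
        "ci_lower": mean - t_crit * se,
        "ci_upper": mean + t_crit * se,
        "df": k - 1,
    }


def bootstrap_ci(
    labels,
    scores,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for ``metric(labels, scores)`` over case
    resamples.  Resamples on which the metric is undefined (NaN or raising)
    are redrawn; the redraw count is returned as the third element."""
    labels = np.asarray(labels).reshape(-1)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    def evaluate(lab, sco) -> float:
        try:
            value = float(metric(lab, sco))
        except ValueError:
            return float("nan")
        return value

    if np.isnan(evaluate(labels, scores)):
        raise ValueError("metric undefined on the full sample")

    rng = np.random.default_rng(seed)
    n = labels.size
    draws = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            value = evaluate(labels[idx], scores[idx])
            if not np.isnan(value):
                draws[b] = value
                break
            redraws += 1
            if redraws > 100 * n_boot:  # pragma: no cover - pathological input
                raise RuntimeError("metric undefined on almost every resample")
    alpha = 1.0 - confidence
    lower, upper = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lower), float(upper), redraws


def _structural_components(labels: np.ndarray, scores: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong V10 (per positive) and V01 (per negative) components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - ranks_pos) / n  # per positive sample
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m  # per negative sample
    return float(auc), v10, v01


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Two-sided DeLong test for paired ROC AUCs.

    Returns (AUC_A - AUC_B, p).  Zero variance of the difference (identical
    score vectors) returns p = 1 by convention.
    """
    labels = np.asarray(labels).reshape(-1).astype(int)
    scores_a = np.asarray(scores_a, dtype=float).reshape(-1)
    scores_b = np.asarray(scores_b, dtype=float).reshape(-1)
    if not (labels.size == scores_a.size == scores_b.size):
        raise ValueError("paired scores must match the labels in length")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong's test requires both classes present")

    auc_a, v10_a, v01_a = _structural_components(labels, scores_a)
    auc_b, v10_b, v01_b = _structural_components(labels, scores_b)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return float(diff), 1.0
    z = diff / np.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(diff), p
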