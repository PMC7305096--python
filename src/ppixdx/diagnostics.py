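"""Node-level diagnostic statistics.

Given per-node scalar scores and binary ground-truth labels this module
provides the Mann–Whitney U comparison of the two groups, the ROC curve and
its trapezoid AUC, cutoff calibration (Youden's J by default), binary
classification at a cutoff (score >= cutoff ⇒ positive, ties-to-positive),
confusion-matrix metrics rounded half-up to one decimal in percent, and a
stratified bootstrap CI for the AUC.

``CutoffClassifier`` wraps calibrate-then-classify as a sklearn estimator so
the whole scoring + calibration chain composes into a ``Pipeline``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import DataError, SingleClassError, UndefinedMetricError, ValidationError

#: Largest per-group size for which the Mann–Whitney p-value is computed by
#: exact enumeration of group assignments (handles ties correctly).
EXACT_ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  #: number of (positive, negative) pairs with pos > neg, + ½ ties
    p_value: float
    method: str  #: "exact" or "normal"


def mann_whitney(scores_pos, scores_neg) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    U is the rank-sum statistic with midranks for ties.  The p-value uses
    exact enumeration of all group assignments when both groups have at most
    ``EXACT_ENUMERATION_MAX_N`` observations, otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(scores_pos, dtype=float)
    y = np.asarray(scores_neg, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("mann_whitney requires both groups to be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    if n1 <= EXACT_ENUMERATION_MAX_N and n2 <= EXACT_ENUMERATION_MAX_N:
        p = _exact_p(np.concatenate([x, y]), n1, u)
        return MannWhitneyResult(u=u, p_value=p, method="exact")
    combined = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mean = n1 * n2 / 2.0
    if var == 0:  # all observations identical
        return MannWhitneyResult(u=u, p_value=1.0, method="normal")
    z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return MannWhitneyResult(u=u, p_value=p, method="normal")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[: x.size].sum())
    return r1 - x.size * (x.size + 1) / 2.0


def _exact_p(combined: np.ndarray, n1: int, u_obs: float) -> float:
    n = combined.size
    mean = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mean) - 1e-12
    count = total = 0
    ranks = stats.rankdata(combined)
    base = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = float(ranks[list(idx)].sum()) - base
        total += 1
        if abs(u - mean) >= dev_obs:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """ROC operating points (thresholds descending, rule: score >= threshold)."""

    thresholds: np.ndarray
    sensitivities: np.ndarray  #: true-positive rates
    one_minus_specificities: np.ndarray  #: false-positive rates
    auc: float
    cutoff: float | None = None
    cutoff_rule: str | None = None


def _as_binary(labels, pos_label) -> np.ndarray:
    labels = np.asarray(labels)
    y = labels == pos_label
    if y.all() or not y.any():
        present = sorted({str(v) for v in labels})
        raise SingleClassError(
            f"both classes required, got only {present} (pos_label={pos_label!r})"
        )
    return y


def roc_curve(scores, labels, pos_label=1) -> RocResult:
    """ROC over the distinct scores; AUC by the trapezoid rule.

    With midrank tie handling this AUC equals the Mann–Whitney
    ``U / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, pos_label)
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=thr, sensitivities=tpr, one_minus_specificities=fpr, auc=auc
    )


def _select_cutoff(roc: RocResult, objective: np.ndarray) -> float:
    """Pick the objective-maximizing finite threshold (ties: higher
    specificity, then higher threshold) and return the midpoint between it
    and the next-lower distinct score."""
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise DataError("ROC has no finite thresholds")
    idx = np.flatnonzero(finite)
    obj = objective[idx]
    fpr = roc.one_minus_specificities[idx]
    thr = roc.thresholds[idx]
    order = np.lexsort((thr, -fpr, obj))
    best = idx[order[-1]]
    s = roc.thresholds[best]
    lower = roc.thresholds[np.isfinite(roc.thresholds) & (roc.thresholds < s)]
    return float((s + lower.max()) / 2.0) if lower.size else float(s)


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity, then higher threshold.  The
    returned cutoff is the midpoint between the selected score and the next
    lower distinct score (on complete separation: the midpoint of the gap),
    which classifies identically but sits away from measured values.
    """
    j = roc.sensitivities - roc.one_minus_specificities
    return _select_cutoff(roc, j)


def closest_topleft_cutoff(roc: RocResult) -> float:
    """Alternative rule: threshold closest to the (0, 1) ROC corner."""
    d = np.hypot(roc.one_minus_specificities, 1.0 - roc.sensitivities)
    return _select_cutoff(roc, -d)


CUTOFF_RULES = {"youden": youden_cutoff, "closest_topleft": closest_topleft_cutoff}


def calibrate(scores, labels, pos_label=1, rule: str = "youden") -> RocResult:
    """ROC + cutoff in one step; returns a RocResult with cutoff filled in."""
    if rule not in CUTOFF_RULES:
        raise ValidationError(f"unknown cutoff rule {rule!r}; know {sorted(CUTOFF_RULES)}")
    roc = roc_curve(scores, labels, pos_label)
    return replace(roc, cutoff=CUTOFF_RULES[rule](roc), cutoff_rule=rule)


# ---------------------------------------------------------------------------
# classification and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify(scores, labels, cutoff: float, pos_label=1) -> ConfusionMatrix:
    """Tally predictions (score >= cutoff ⇒ positive) against truth."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == pos_label
    pred = scores >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


def _pct(numer: int, denom: int) -> float:
    q = (Decimal(100 * numer) / Decimal(denom)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %), half-up to one decimal."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    return (
        _pct(cm.tp, cm.tp + cm.fn),
        _pct(cm.tn, cm.tn + cm.fp),
        _pct(cm.tp + cm.tn, cm.total),
    )


def confusion_from_rates(
    n_pos: int, n_neg: int, sensitivity_pct: float, specificity_pct: float
) -> ConfusionMatrix:
    """Confusion counts implied by printed sensitivity/specificity on a cohort
    of known class sizes (counts rounded half-up to the nearest integer)."""

    def hr(x: float) -> int:
        return int(np.floor(x + 0.5))

    tp = hr(n_pos * sensitivity_pct / 100.0)
    tn = hr(n_neg * specificity_pct / 100.0)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


# ---------------------------------------------------------------------------
# bootstrap


def auc_ci_bootstrap(
    scores, labels, pos_label=1, n_boot: int = 2000, seed: int | None = 0
) -> tuple[float, float]:
    """Percentile 95 % CI for the trapezoid AUC by stratified bootstrap
    (resampling positives and negatives separately), seed-reproducible."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels, pos_label)
    pos, neg = scores[y], scores[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        n = rng.choice(neg, size=neg.size, replace=True)
        aucs[i] = _u_statistic(p, n) / (p.size * n.size)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# sklearn estimator


class CutoffClassifier(ClassifierMixin, BaseEstimator):
    """Calibrated threshold classifier on a scalar score.

    fit(X, y) computes the ROC on the training scores, calibrates the cutoff
    with the configured rule, and stores ``roc_``, ``auc_`` and ``cutoff_``;
    predict applies score >= cutoff_ ⇒ positive.  X is ``(n,)`` or ``(n, 1)``.
    """

    def __init__(self, cutoff_rule: str = "youden", pos_label=1):
        self.cutoff_rule = cutoff_rule
        self.pos_label = pos_label

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValidationError(
                f"expected a single score per node, got array of shape {X.shape}"
            )
        return X

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y)
        if s.size != y.size:
            raise ValidationError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.pos_label not in self.classes_:
            raise ValidationError(
                f"pos_label {self.pos_label!r} not among classes {list(self.classes_)}"
            )
        self.roc_ = calibrate(s, y, pos_label=self.pos_label, rule=self.cutoff_rule)
        self.auc_ = self.roc_.auc
        self.cutoff_ = self.roc_.cutoff
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X) - self.cutoff_

    def predict(self, X) -> np.ndarray:
        s = self._scores(X)
        neg = self.classes_[self.classes_ != self.pos_label][0]
        return np.where(s >= self.cutoff_, self.pos_label, neg)
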