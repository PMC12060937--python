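"""Binary net-benefit machinery.

Net benefit at a risk threshold ``r`` values a true positive at 1 and a false
positive at the odds ``r/(1-r)``::

    NB(r) = TP(r)/N - FP(r)/N * r/(1-r)

where a subject tests positive when their predicted risk is *strictly* greater
than ``r``.  Standardized net benefit divides by the outcome prevalence ``P``
(its maximum), so sNB is the proportion of the maximum achievable net benefit.
The reference strategies Treat All (everyone positive) and Treat None (no one
positive) have ``NB = P - (1-P) r/(1-r)`` and ``NB = 0`` respectively.

A polytomous outcome with categories ``0..K`` enters this machinery through
binary splits: cumulative (upper-set) splits ``Y > j`` for ordinal outcomes,
one-vs-rest and one-vs-one splits for nominal outcomes.  For ordinal outcomes
only cumulative dichotomizations are generated — comparing a middle category
against the union of both extremes is meaningful only for unordered outcomes,
so :func:`ovr_splits` refuses interior classes unless ``nominal=True``.

Thresholds live in ``[0, 1)``: the odds ``r/(1-r)`` diverge at 1, and a
threshold of exactly 1 corresponds to Treat None.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSplitError, ValidationError
from .io import CohortTable, RiskMatrix

__all__ = [
    "BinarySplit",
    "ConfusionAtThreshold",
    "ExchangeRate",
    "cumulative_splits",
    "ovr_splits",
    "ovo_split",
    "confusion_at_threshold",
    "net_benefit_at",
    "standardized_nb_at",
    "treat_all_nb",
    "treat_none_nb",
    "threshold_from_ratio",
]


@dataclass(frozen=True)
class BinarySplit:
    """One dichotomization of a polytomous outcome.

    ``risks[i]`` is subject ``i``'s predicted probability of the positive
    class; ``labels[i]`` the observed 0/1 truth.  ``positive_categories``
    records which original categories count as positive; for ``kind ==
    "cumulative"`` this is an upper set ``{j+1, ..., K}``.
    """

    name: str
    positive_categories: tuple[int, ...]
    risks: np.ndarray
    labels: np.ndarray
    kind: str = "cumulative"

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(
            self, "positive_categories", tuple(sorted(self.positive_categories))
        )
        if risks.shape != labels.shape or risks.ndim != 1:
            raise ValidationError("risks and labels must be equal-length vectors")
        if risks.size == 0:
            raise ValidationError("empty split")
        if np.any(risks < 0) or np.any(risks > 1):
            raise ValidationError("risks must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be binary")
        if self.kind == "cumulative" and self.positive_categories:
            top = max(self.positive_categories)
            expected = tuple(range(min(self.positive_categories), top + 1))
            if self.positive_categories != expected:
                raise ValidationError(
                    "cumulative split must dichotomize at an upper set of categories"
                )

    @property
    def n_subjects(self) -> int:
        return self.risks.size

    @property
    def prevalence(self) -> float:
        """Empirical proportion of positive labels; the maximum achievable NB."""
        return float(self.labels.mean())

    # sorted views cached for O(log n) confusion counts at many thresholds
    @property
    def _sorted(self) -> tuple[np.ndarray, np.ndarray]:
        cached = self.__dict__.get("_sorted_cache")
        if cached is None:
            order = np.argsort(self.risks, kind="stable")
            risks_sorted = self.risks[order]
            # tp_suffix[i] = number of positive labels among risks_sorted[i:]
            tp_suffix = np.concatenate(
                [np.cumsum(self.labels[order][::-1])[::-1], [0]]
            )
            cached = (risks_sorted, tp_suffix)
            self.__dict__["_sorted_cache"] = cached
        return cached

    def counts_at(self, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (TP, FP) counts at each threshold (positive iff risk > r)."""
        r = np.asarray(thresholds, dtype=float)
        if np.any(r < 0) or np.any(r >= 1):
            raise ValidationError("thresholds must lie in [0, 1)")
        risks_sorted, tp_suffix = self._sorted
        idx = np.searchsorted(risks_sorted, r, side="right")
        n_pos_calls = risks_sorted.size - idx
        tp = tp_suffix[idx]
        fp = n_pos_calls - tp
        return tp, fp

    def net_benefit(self, thresholds: np.ndarray) -> np.ndarray:
        """NB(r) on an array of thresholds, vectorized."""
        r = np.asarray(thresholds, dtype=float)
        tp, fp = self.counts_at(r)
        n = self.n_subjects
        return tp / n - (fp / n) * r / (1.0 - r)

    def standardized_net_benefit(self, thresholds: np.ndarray) -> np.ndarray:
        p = self.prevalence
        if p == 0:
            raise DegenerateSplitError(
                f"split {self.name!r} has no positive subjects; sNB is undefined"
            )
        return self.net_benefit(thresholds) / p


@dataclass(frozen=True)
class ConfusionAtThreshold:
    """Counts of the four decision outcomes at one risk threshold."""

    r: float
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if not 0 <= self.r < 1:
            raise ValidationError("threshold must lie in [0, 1)")
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.N == 0:
            raise ValidationError("empty confusion table")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.FP + self.TN)

    @property
    def prevalence(self) -> float:
        return (self.TP + self.FN) / self.N


@dataclass(frozen=True)
class ExchangeRate:
    """Clinical exchange rate: one true positive is worth ``K_ratio`` false positives."""

    K_ratio: float

    def __post_init__(self) -> None:
        if not self.K_ratio > 0:
            raise ValidationError("exchange rate must be positive")


def cumulative_splits(risks: RiskMatrix, cohort: CohortTable) -> list[BinarySplit]:
    """All K upper-set dichotomizations of an ordinal outcome.

    Split ``j`` (``j = 0..K-1``) compares ``Y > j`` against ``Y <= j`` with
    per-subject risk ``sum_{c > j} p_ic``.  For a three-category outcome these
    are "any vs none" (j=0) and "severe vs rest" (j=1); with more than three
    categories the interior splits are of some-vs-rest form.
    """
    K1 = risks.n_categories
    if K1 < 2:
        raise ValidationError("need at least two outcome categories")
    y = cohort.outcomes
    if y.size != risks.n_subjects:
        raise ValidationError("cohort and risk matrix sizes differ")
    splits = []
    for j in range(K1 - 1):
        upper = tuple(range(j + 1, K1))
        name = ">" + risks.category_labels[j]
        splits.append(
            BinarySplit(
                name=name,
                positive_categories=upper,
                risks=risks.probs[:, j + 1 :].sum(axis=1),
                labels=(y > j).astype(int),
                kind="cumulative",
            )
        )
    return splits


def ovr_splits(
    risks: RiskMatrix, cohort: CohortTable, nominal: bool = False
) -> list[BinarySplit]:
    """One-vs-rest splits: class ``c`` against all others.

    For an ordinal outcome, interior classes pooled against the union of both
    extremes are not clinically interpretable, so only the two extreme classes
    are returned unless ``nominal=True``.
    """
    K1 = risks.n_categories
    y = cohort.outcomes
    classes = range(K1) if nominal else (0, K1 - 1)
    out = []
    for c in classes:
        out.append(
            BinarySplit(
                name=f"{risks.category_labels[c]}_vs_rest",
                positive_categories=(c,),
                risks=risks.probs[:, c],
                labels=(y == c).astype(int),
                kind="ovr",
            )
        )
    return out


def ovo_split(
    risks: RiskMatrix, cohort: CohortTable, class_a: int, class_b: int
) -> BinarySplit:
    """One-vs-one split restricted to subjects in either class.

    The risk is the conditional probability ``p_a / (p_a + p_b)``; a retained
    subject with ``p_a + p_b = 0`` has no defined conditional risk and raises.
    """
    y = cohort.outcomes
    keep = np.isin(y, (class_a, class_b))
    if not keep.any():
        raise ValidationError(
            f"no subjects in classes {class_a} or {class_b}; one-vs-one split is empty"
        )
    pa = risks.probs[keep, class_a]
    pb = risks.probs[keep, class_b]
    denom = pa + pb
    if np.any(denom == 0):
        i = int(np.argmax(denom == 0))
        raise ValidationError(
            f"retained subject (restricted row {i}) has zero probability on both "
            f"classes {class_a} and {class_b}; conditional risk undefined"
        )
    return BinarySplit(
        name=f"{risks.category_labels[class_a]}_vs_{risks.category_labels[class_b]}",
        positive_categories=(class_a,),
        risks=pa / denom,
        labels=(y[keep] == class_a).astype(int),
        kind="ovo",
    )


def confusion_at_threshold(split: BinarySplit, r: float) -> ConfusionAtThreshold:
    """Tally decisions (positive iff risk strictly exceeds ``r``) against labels."""
    if not 0 <= r < 1:
        raise ValidationError(f"threshold {r} outside [0, 1)")
    call_pos = split.risks > r
    labels = split.labels.astype(bool)
    return ConfusionAtThreshold(
        r=float(r),
        TP=int(np.sum(call_pos & labels)),
        FP=int(np.sum(call_pos & ~labels)),
        TN=int(np.sum(~call_pos & ~labels)),
        FN=int(np.sum(~call_pos & labels)),
    )


def net_benefit_at(conf: ConfusionAtThreshold) -> float:
    """NB = TP/N - (FP/N) * r/(1-r); units of true positives per subject."""
    n = conf.N
    return conf.TP / n - (conf.FP / n) * conf.r / (1.0 - conf.r)


def standardized_nb_at(conf: ConfusionAtThreshold) -> float:
    """sNB = NB / prevalence; at most 1, attained by a perfect classifier."""
    p = conf.prevalence
    if p == 0:
        raise DegenerateSplitError("prevalence is 0; standardized NB is undefined")
    return net_benefit_at(conf) / p


def treat_all_nb(prevalence: float, r: float) -> float:
    """Net benefit of treating everyone: ``P - (1-P) r/(1-r)``; equals P at r=0."""
    if not 0 <= prevalence <= 1:
        raise ValidationError("prevalence must lie in [0, 1]")
    if not 0 <= r < 1:
        raise ValidationError("threshold must lie in [0, 1)")
    return prevalence - (1.0 - prevalence) * r / (1.0 - r)


def treat_none_nb() -> float:
    """Net benefit of treating no one: exactly 0 at every threshold."""
    return 0.0


def threshold_from_ratio(exchange: ExchangeRate | float) -> float:
    """Risk threshold implied by an exchange rate via equipoise: ``r = 1/(1+K)``.

    A clinician willing to treat ``K`` unaffected subjects to catch one
    affected subject is indifferent at predicted risk ``1/(1+K)``; the inverse
    odds relation ``(1-r)/r = K`` holds exactly.
    """
    k = exchange.K_ratio if isinstance(exchange, ExchangeRate) else float(exchange)
    if not k > 0:
        raise ValidationError("exchange rate must be positive")
    return 1.0 / (1.0 + k)
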