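"""Rule-based dehydration classification (WHO IMAI) as a degenerate risk model.

The WHO Integrated Management of Adolescent and Adult Illness (IMAI) algorithm
assigns one of three dehydration categories from bedside signs using
"m-of-n signs" rules, evaluated most-severe first:

* SEVERE (2): at least two of {lethargic or unconscious, sunken eyes, not able
  to drink / drinking poorly, skin pinch goes back very slowly};
* SOME (1): otherwise, at least two of {sunken eyes, drinks eagerly / thirsty,
  skin pinch goes back slowly};
* NONE (0): not enough signs for either.

Severe-before-some precedence matters because the sign sets overlap (sunken
eyes appears in both).  To enter a decision-curve comparison alongside
probabilistic models, rule outputs are lifted to a degenerate risk matrix
whose rows are indicator vectors, so every predicted "probability" is exactly
0 or 1 and the resulting net-benefit curve is linear in the threshold odds
r/(1-r).

Arbitrary rule sets in the same schema (an ordered list of (category,
min_count, signs) clauses) can be supplied for variants such as the under-five
IMCI algorithm; IMAI is the only built-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError
from .io import CohortTable, RiskMatrix

__all__ = [
    "SignProfile",
    "RuleClause",
    "RuleSet",
    "IMAI_RULES",
    "classify_imai",
    "classify_cohort",
    "rules_to_risk_matrix",
]

IMAI_SIGNS = (
    "lethargic_or_unconscious",
    "sunken_eyes",
    "unable_or_poor_drinking",
    "skin_pinch_very_slow",
    "drinks_eagerly_thirsty",
    "skin_pinch_slow",
)


@dataclass(frozen=True)
class SignProfile:
    """Boolean bedside signs for one subject."""

    lethargic_or_unconscious: bool = False
    sunken_eyes: bool = False
    unable_or_poor_drinking: bool = False
    skin_pinch_very_slow: bool = False
    drinks_eagerly_thirsty: bool = False
    skin_pinch_slow: bool = False

    def __post_init__(self) -> None:
        if self.skin_pinch_very_slow and self.skin_pinch_slow:
            raise ValidationError(
                "skin pinch cannot be both 'slow' and 'very slow' for one subject"
            )


@dataclass(frozen=True)
class RuleClause:
    """Assign ``category`` when at least ``min_count`` of ``signs`` are present."""

    category: int
    min_count: int
    signs: tuple[str, ...]


@dataclass(frozen=True)
class RuleSet:
    """Ordered rule clauses; first matching clause wins, else ``default_category``."""

    clauses: tuple[RuleClause, ...]
    default_category: int = 0

    def classify(self, signs: dict[str, bool]) -> int:
        for clause in self.clauses:
            hits = sum(bool(signs.get(s, False)) for s in clause.signs)
            if hits >= clause.min_count:
                return clause.category
        return self.default_category


#: the IMAI table: severe clause first (precedence), then some, else none
IMAI_RULES = RuleSet(
    clauses=(
        RuleClause(
            category=2,
            min_count=2,
            signs=(
                "lethargic_or_unconscious",
                "sunken_eyes",
                "unable_or_poor_drinking",
                "skin_pinch_very_slow",
            ),
        ),
        RuleClause(
            category=1,
            min_count=2,
            signs=("sunken_eyes", "drinks_eagerly_thirsty", "skin_pinch_slow"),
        ),
    ),
    default_category=0,
)


def classify_imai(profile: SignProfile) -> int:
    """IMAI dehydration category (0 none, 1 some, 2 severe) for one subject."""
    signs = {name: getattr(profile, name) for name in IMAI_SIGNS}
    return IMAI_RULES.classify(signs)


def classify_cohort(
    cohort: CohortTable,
    rules: RuleSet = IMAI_RULES,
    sign_columns: Sequence[str] = IMAI_SIGNS,
) -> np.ndarray:
    """Apply a rule set to boolean sign columns of a cohort; returns categories."""
    sign_arrays = {name: cohort.covariate(name).astype(bool) for name in sign_columns}
    if "skin_pinch_very_slow" in sign_arrays and "skin_pinch_slow" in sign_arrays:
        both = sign_arrays["skin_pinch_very_slow"] & sign_arrays["skin_pinch_slow"]
        if both.any():
            raise ValidationError(
                f"subject row {int(np.argmax(both))}: skin pinch flagged both "
                "'slow' and 'very slow'"
            )
    out = np.empty(cohort.n_subjects, dtype=int)
    for i in range(cohort.n_subjects):
        out[i] = rules.classify({k: bool(v[i]) for k, v in sign_arrays.items()})
    return out


def rules_to_risk_matrix(
    categories: Iterable[int],
    n_categories: int,
    category_labels: Sequence[str] | None = None,
) -> RiskMatrix:
    """Lift hard categorical assignments to a degenerate (0/1) risk matrix."""
    cats = np.asarray(list(categories), dtype=int)
    if cats.size and (cats.min() < 0 or cats.max() >= n_categories):
        bad = cats[(cats < 0) | (cats >= n_categories)][0]
        raise ValidationError(
            f"category {bad} out of range for {n_categories} categories"
        )
    probs = np.zeros((cats.size, n_categories))
    probs[np.arange(cats.size), cats] = 1.0
    labels = (
        tuple(category_labels)
        if category_labels is not None
        else tuple(f"cat{j}" for j in range(n_categories))
    )
    return RiskMatrix(probs, labels)
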