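"""Predicted probabilities from published ordinal / nominal logit coefficients.

This module turns a *printed* coefficient table — as found in the publications
of clinical prediction models — into a per-subject probability matrix over the
outcome categories.  No model fitting happens here; fitting appears only as a
test oracle elsewhere.

Parameterization
----------------
For an ordinal outcome ``Y in {0..K}`` the cumulative-logit model is encoded
through ordered cutpoints ``zeta_0 < ... < zeta_{K-1}``::

    logit P(Y <= j | x) = zeta_j - x'beta

so that a *positive* coefficient moves probability mass toward more severe
categories, and the printed intercepts — which increase with severity in the
published dehydration models — are the ordered cutpoints.  This is the
standard ordinal-regression convention (it is also the one used by
``statsmodels`` ``OrderedModel`` and R's ``MASS::polr``).  Published tables
sometimes write the model as ``logit P(Y > j) = alpha_j + x'beta`` instead;
that form needs *decreasing* intercepts, which is inconsistent with the
increasing printed values, so the cutpoint convention above is adopted and
documented rather than guessed per table.

Continuous covariates enter on their printed scale: a coefficient reported
"per 10 mmHg increase" multiplies ``value / 10``.  Categorical covariates use
the printed reference level with implicit coefficient 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, ValidationError
from .io import CohortTable, RiskMatrix

__all__ = [
    "Term",
    "ModelSpec",
    "predict_cumulative_logit",
    "predict_baseline_logit",
    "coefficient_odds_ratio",
    "load_published_model",
    "PUBLISHED_MODELS",
]

#: tolerance for the cumulative-monotonicity check on predicted probabilities
_MONOTONE_TOL = 1e-10


@dataclass(frozen=True)
class Term:
    """One row of a coefficient table.

    ``level`` is ``None`` for a continuous (linear) term, otherwise the
    categorical level the coefficient attaches to.  ``scale`` divides a
    continuous covariate before multiplication, encoding printed "per <scale>
    units increase" coefficients.  ``coefficients`` holds one value for
    proportional models and K values (one per cumulative split) otherwise.
    """

    covariate: str
    coefficients: tuple[float, ...]
    level: str | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if self.scale <= 0:
            raise ConfigurationError(f"term {self.covariate!r}: scale must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified categorical-outcome regression model.

    For ``family="cumulative_logit"``, ``cutpoints`` are the ordered
    ``zeta_j`` of ``logit P(Y <= j) = zeta_j - x'beta``.  For
    ``family="baseline_category"`` they are the intercepts ``alpha_j`` of
    ``log(P(Y=j)/P(Y=0)) = alpha_j + x'beta_j``, ``j = 1..K`` (no ordering
    constraint).  ``cutpoints=None`` marks a published table that prints no
    intercepts; such a spec refuses prediction until cutpoints are supplied.
    """

    family: str  # cumulative_logit | baseline_category
    proportional: bool
    terms: tuple[Term, ...]
    cutpoints: tuple[float, ...] | None
    category_count: int
    reference_levels: Mapping[str, str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("cumulative_logit", "baseline_category"):
            raise ConfigurationError(f"unknown model family {self.family!r}")
        K = self.category_count - 1
        if K < 1:
            raise ConfigurationError("category_count must be >= 2")
        if self.cutpoints is not None:
            cps = tuple(float(c) for c in self.cutpoints)
            object.__setattr__(self, "cutpoints", cps)
            if len(cps) != K:
                raise ConfigurationError(
                    f"expected {K} cutpoints for {self.category_count} categories, "
                    f"got {len(cps)}"
                )
            if self.family == "cumulative_logit" and any(
                b <= a for a, b in zip(cps, cps[1:])
            ):
                raise ConfigurationError(
                    "cumulative-logit cutpoints must be strictly increasing"
                )
        n_expected = 1 if self.proportional else K
        for t in self.terms:
            if len(t.coefficients) != n_expected:
                raise ConfigurationError(
                    f"term {t.covariate!r}/{t.level!r}: expected {n_expected} "
                    f"coefficient(s), got {len(t.coefficients)}"
                )

    def with_cutpoints(self, cutpoints: tuple[float, ...]) -> "ModelSpec":
        """Return a copy with user-supplied cutpoints (for tables without them)."""
        return replace(self, cutpoints=tuple(cutpoints))


def _linear_predictors(spec: ModelSpec, cohort: CohortTable) -> np.ndarray:
    """Per-subject linear predictor, shape (n, K); proportional specs broadcast."""
    n = cohort.n_subjects
    K = spec.category_count - 1
    eta = np.zeros((n, K))
    cat_levels: dict[str, set[str]] = {}
    for term in spec.terms:
        values = cohort.covariate(term.covariate)
        coefs = np.asarray(term.coefficients, dtype=float)
        if len(coefs) == 1:
            coefs = np.repeat(coefs, K)
        if term.level is None:
            x = np.asarray(values, dtype=float)
            if np.isnan(x).any():
                raise ValidationError(
                    f"missing value in continuous covariate {term.covariate!r}; "
                    "no imputation is performed"
                )
            eta += (x / term.scale)[:, None] * coefs[None, :]
        else:
            cat_levels.setdefault(term.covariate, set()).add(term.level)
            mask = np.asarray(values).astype(str) == term.level
            eta += mask[:, None].astype(float) * coefs[None, :]
    # categorical coverage: every observed level must be a term level or the
    # stated reference level
    refs = dict(spec.reference_levels or {})
    for cov, levels in cat_levels.items():
        allowed = set(levels)
        if cov in refs:
            allowed.add(refs[cov])
        observed = {str(v) for v in np.unique(cohort.covariate(cov))}
        unseen = sorted(observed - allowed)
        if unseen:
            raise ValidationError(
                f"covariate {cov!r} has level(s) {unseen} not covered by the model "
                f"(known levels: {sorted(allowed)})"
            )
    return eta


def predict_cumulative_logit(spec: ModelSpec, cohort: CohortTable) -> RiskMatrix:
    """Evaluate a cumulative-logit model on a cohort.

    Returns an N x (K+1) matrix with rows on the probability simplex; the
    cumulative probabilities ``P(Y <= j)`` are checked to be monotone in
    ``j`` for every subject (a non-proportional coefficient table can violate
    this for some covariate patterns, which is reported rather than patched).
    """
    if spec.family != "cumulative_logit":
        raise ConfigurationError(f"spec family is {spec.family!r}, not cumulative_logit")
    if spec.cutpoints is None:
        raise ConfigurationError(
            f"model {spec.name or '<unnamed>'!r} has no cutpoints (the published "
            "table prints none); supply them via ModelSpec.with_cutpoints before "
            "predicting"
        )
    eta = _linear_predictors(spec, cohort)  # (n, K)
    zeta = np.asarray(spec.cutpoints)  # (K,)
    cum = expit(zeta[None, :] - eta)  # P(Y <= j), (n, K)
    if np.any(np.diff(cum, axis=1) < -_MONOTONE_TOL):
        i = int(np.argwhere(np.diff(cum, axis=1) < -_MONOTONE_TOL)[0, 0])
        raise ValidationError(
            f"subject row {i}: cumulative probabilities are not monotone "
            "(non-proportional coefficients crossed for this covariate pattern)"
        )
    full = np.hstack([np.zeros((cum.shape[0], 1)), cum, np.ones((cum.shape[0], 1))])
    probs = np.diff(full, axis=1)
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)  # remove O(tol) rounding only
    labels = tuple(f"cat{j}" for j in range(spec.category_count))
    return RiskMatrix(probs, labels)


def predict_baseline_logit(spec: ModelSpec, cohort: CohortTable) -> RiskMatrix:
    """Evaluate a baseline-category logit model (softmax over ``{0, eta_j}``)."""
    if spec.family != "baseline_category":
        raise ConfigurationError(f"spec family is {spec.family!r}, not baseline_category")
    if spec.cutpoints is None:
        raise ConfigurationError("baseline-category model requires intercepts")
    eta = _linear_predictors(spec, cohort)  # (n, K)
    alpha = np.asarray(spec.cutpoints)
    logits = np.hstack([np.zeros((eta.shape[0], 1)), alpha[None, :] + eta])
    logits -= logits.max(axis=1, keepdims=True)
    num = np.exp(logits)
    probs = num / num.sum(axis=1, keepdims=True)
    labels = tuple(f"cat{j}" for j in range(spec.category_count))
    return RiskMatrix(probs, labels)


def coefficient_odds_ratio(beta: float) -> float:
    """Odds ratio ``exp(beta)`` for a printed log-odds coefficient."""
    if not math.isfinite(beta):
        raise ValidationError("coefficient must be finite")
    return math.exp(beta)


def _prop(cov: str, level: str | None, coef: float, scale: float = 1.0) -> Term:
    return Term(covariate=cov, coefficients=(coef,), level=level, scale=scale)


# Published cumulative-logit models for dehydration severity (none / some /
# severe) in patients with acute diarrhea.  DHAKA targets children under five;
# the NIRUDAK models target patients over five.  Coefficients are the printed
# values; the DHAKA publication prints no intercepts, so its spec carries
# cutpoints=None and refuses prediction until cutpoints are supplied.
PUBLISHED_MODELS: dict[str, ModelSpec] = {
    "dhaka": ModelSpec(
        family="cumulative_logit",
        proportional=True,
        terms=(
            _prop("general_appearance", "restless_irritable", 0.72),
            _prop("general_appearance", "lethargic_unconscious", 1.23),
            _prop("respiration_depth", "deep", 0.47),
            _prop("skin_pinch", "slow", 0.82),
            _prop("skin_pinch", "very_slow", 1.37),
            _prop("tears", "decreased", 0.34),
            _prop("tears", "absent", 0.74),
        ),
        cutpoints=None,
        category_count=3,
        reference_levels={
            "general_appearance": "normal",
            "respiration_depth": "normal",
            "skin_pinch": "normal",
            "tears": "normal",
        },
        name="dhaka",
    ),
    "nirudak_full": ModelSpec(
        family="cumulative_logit",
        proportional=True,
        terms=(
            _prop("age", None, -0.01),  # per 1 yr
            _prop("skin_pinch", "slow", 0.71),
            _prop("skin_pinch", "very_slow", 1.53),
            _prop("eye_level", "sunken", 0.70),
            _prop("respiration_depth", "deep", 0.37),
            _prop("vomiting_24h", "1_5", 0.39),
            _prop("vomiting_24h", "6_10", 0.69),
            _prop("vomiting_24h", "gt10", 0.91),
            _prop("systolic_bp", None, -0.14, scale=10.0),  # per 10 mmHg
            _prop("muac", None, -0.09, scale=10.0),  # per 10 mm
            _prop("sex", "male", 0.36),
        ),
        cutpoints=(-3.38, 0.66),  # any-dehydration, severe-dehydration
        category_count=3,
        reference_levels={
            "skin_pinch": "rapid",
            "eye_level": "normal",
            "respiration_depth": "normal",
            "vomiting_24h": "lt1",
            "sex": "female",
        },
        name="nirudak_full",
    ),
    "nirudak_simplified": ModelSpec(
        family="cumulative_logit",
        proportional=True,
        terms=(
            _prop("skin_pinch", "slow", 0.68),
            _prop("skin_pinch", "very_slow", 1.34),
            _prop("eye_level", "sunken", 0.60),
            _prop("respiration_depth", "deep", 0.58),
            _prop("urine_output", "decreased", 0.29),
            _prop("urine_output", "minimal", 0.58),
            _prop("radial_pulse", "decreased", 0.44),
            _prop("radial_pulse", "absent", 1.07),
        ),
        cutpoints=(0.29, 4.08),  # any-dehydration, severe-dehydration
        category_count=3,
        reference_levels={
            "skin_pinch": "rapid",
            "eye_level": "normal",
            "respiration_depth": "normal",
            "urine_output": "normal",
            "radial_pulse": "strong",
        },
        name="nirudak_simplified",
    ),
}


def load_published_model(name: str) -> ModelSpec:
    """Return the spec of a published dehydration model by name.

    Recognized names: ``dhaka``, ``nirudak_full``, ``nirudak_simplified``.
    """
    try:
        return PUBLISHED_MODELS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown published model {name!r}; choose from "
            f"{sorted(PUBLISHED_MODELS)}"
        ) from None
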