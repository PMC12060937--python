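"""Synthetic ordinal cohorts with known data-generating parameters.

The generator emulates a dehydration-severity cohort: bedside signs are drawn
from stated marginal distributions, a cumulative-logit model (by default the
published simplified adult model) maps them to true category probabilities,
and the observed three-level outcome (0 none, 1 some, 2 severe) is drawn from
those probabilities.  The true probability matrix is returned alongside the
cohort, so downstream utility statistics can be evaluated both under the true
model and under misspecified competitors without any external data.

Sign prevalences are fixture choices tuned so that all three outcome
categories carry at least 10% of the mass under the default truth — they are
not estimates of any real cohort's sign frequencies.  Covariates are drawn
independently of each other, outcomes are conditionally independent given the
signs, and there is no missingness or measurement error; real bedside data
violate all three.

The module also carries the outcome-definition arithmetic used by the
dehydration studies: percent dehydration as the relative weight change after
rehydration, and its categorization at 3% and 9%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import CohortTable, RiskMatrix
from .ordinal import ModelSpec, load_published_model, predict_baseline_logit, predict_cumulative_logit

__all__ = [
    "Categorical",
    "Continuous",
    "Bernoulli",
    "GeneratorSpec",
    "default_generator_spec",
    "generate_cohort",
    "percent_dehydration",
    "categorize_dehydration",
]


@dataclass(frozen=True)
class Categorical:
    """Categorical covariate: named levels with sampling probabilities."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ConfigurationError("levels and probs must have equal length")
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"level probabilities must be non-negative and sum to 1, got {p}"
            )


@dataclass(frozen=True)
class Continuous:
    """Continuous covariate drawn from a normal distribution."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be non-negative")


@dataclass(frozen=True)
class Bernoulli:
    """Boolean covariate (e.g. a bedside sign outside the model)."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError("Bernoulli probability must lie in [0, 1]")


Scheme = Union[Categorical, Continuous, Bernoulli]


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to simulate one cohort from a known truth."""

    n: int
    model: ModelSpec
    covariate_scheme: Mapping[str, Scheme]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size must be >= 1")
        for name, scheme in self.covariate_scheme.items():
            if not isinstance(scheme, (Categorical, Continuous, Bernoulli)):
                raise ConfigurationError(
                    f"covariate {name!r}: unknown scheme {type(scheme).__name__}"
                )


#: sign prevalences of the default synthetic cohort (fixture choices, see
#: module docstring) paired with the published simplified adult model as truth
DEFAULT_SCHEME: dict[str, Scheme] = {
    "skin_pinch": Categorical(("rapid", "slow", "very_slow"), (0.38, 0.34, 0.28)),
    "eye_level": Categorical(("normal", "sunken"), (0.46, 0.54)),
    "respiration_depth": Categorical(("normal", "deep"), (0.60, 0.40)),
    "urine_output": Categorical(("normal", "decreased", "minimal"), (0.40, 0.36, 0.24)),
    "radial_pulse": Categorical(("strong", "decreased", "absent"), (0.50, 0.36, 0.14)),
    # extra bedside signs used only by rule-based classifiers
    "lethargic_or_unconscious": Bernoulli(0.06),
    "unable_or_poor_drinking": Bernoulli(0.10),
    "drinks_eagerly_thirsty": Bernoulli(0.30),
}


def default_generator_spec(n: int = 2000, seed: int = 0) -> GeneratorSpec:
    """Default cohort: simplified adult dehydration model as the truth."""
    return GeneratorSpec(
        n=n,
        model=load_published_model("nirudak_simplified"),
        covariate_scheme=dict(DEFAULT_SCHEME),
        seed=seed,
    )


def generate_cohort(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[CohortTable, RiskMatrix]:
    """Simulate a cohort and return it with its true probability matrix.

    Covariates are drawn independently per the scheme; the outcome of subject
    ``i`` is drawn from row ``i`` of the true probability matrix.  When the
    scheme contains a ``skin_pinch`` or ``eye_level`` covariate, the derived
    boolean sign columns (``skin_pinch_slow``, ``skin_pinch_very_slow``,
    ``sunken_eyes``) are added so rule-based classifiers can run on the same
    table.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    columns: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for name, scheme in spec.covariate_scheme.items():
        if isinstance(scheme, Categorical):
            columns[name] = rng.choice(scheme.levels, size=n, p=scheme.probs)
        elif isinstance(scheme, Continuous):
            columns[name] = rng.normal(scheme.mean, scheme.sd, size=n)
        else:
            columns[name] = rng.random(n) < scheme.p
    if "skin_pinch" in columns:
        columns["skin_pinch_slow"] = columns["skin_pinch"] == "slow"
        columns["skin_pinch_very_slow"] = columns["skin_pinch"] == "very_slow"
    if "eye_level" in columns:
        columns["sunken_eyes"] = columns["eye_level"] == "sunken"
    df = pd.DataFrame(columns)
    df["outcome"] = 0  # placeholder; CohortTable requires the column
    cohort = CohortTable(df, id_column="id", outcome_column="outcome")
    if spec.model.family == "cumulative_logit":
        truth = predict_cumulative_logit(spec.model, cohort)
    else:
        truth = predict_baseline_logit(spec.model, cohort)
    # inverse-CDF draw of the outcome from each subject's true probabilities
    u = rng.random(n)
    cum = np.cumsum(truth.probs, axis=1)
    outcomes = (u[:, None] > cum).sum(axis=1)
    df = df.assign(outcome=outcomes)
    return CohortTable(df, id_column="id", outcome_column="outcome"), truth


def percent_dehydration(stable_weight: float, admission_weight: float) -> float:
    """Percent weight change after rehydration: ``100 (stable - admission) / stable``.

    Signed: a patient admitted *above* their stable weight yields a negative
    value, which is passed through unclamped.
    """
    stable = np.asarray(stable_weight, dtype=float)
    if np.any(stable <= 0):
        raise ValidationError("stable weight must be positive")
    admission = np.asarray(admission_weight, dtype=float)
    out = 100.0 * (stable - admission) / stable
    return float(out) if out.ndim == 0 else out


def categorize_dehydration(percent: float) -> int:
    """Three-level dehydration category from percent weight loss.

    Severe (2) above 9%, some (1) for 3-9% inclusive of both boundaries,
    none (0) below 3%.
    """
    p = np.asarray(percent, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValidationError("percent dehydration must be finite")
    out = np.where(p > 9.0, 2, np.where(p >= 3.0, 1, 0))
    return int(out) if out.ndim == 0 else out
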