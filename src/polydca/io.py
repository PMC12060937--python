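"""Cohort tables, risk matrices, analysis configuration, and CSV readers/writers.

CSV is the interchange format throughout: a cohort file carries one row per
subject (id, ordinal outcome, covariates); a risk file carries the id plus one
predicted-probability column per outcome category.  Probabilities are written
with 12 significant digits so that a write/read round trip reproduces values
to better than 1e-12, the precision any downstream statistic can resolve.

Outcome categories are integers ``0..K`` with 0 the least severe level.  When
outcomes are encoded as text labels, the caller must state the level order
explicitly; alphabetical inference is refused because a silently misordered
ordinal outcome corrupts every cumulative dichotomization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "CohortTable",
    "RiskMatrix",
    "AnalysisConfig",
    "read_cohort",
    "read_risk_matrix",
    "write_cohort",
    "write_risk_matrix",
    "write_summary",
    "load_config",
]

#: row sums of a risk matrix may deviate from 1 by at most this much on read
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class CohortTable:
    """A study cohort: one row per subject, ordinal outcome in ``0..K``.

    Parameters
    ----------
    data
        One row per subject.  Covariate columns are free-form (categorical
        levels as strings, continuous as floats).
    id_column, outcome_column
        Names of the subject-identifier and outcome columns in ``data``.
    """

    data: pd.DataFrame
    id_column: str = "id"
    outcome_column: str = "outcome"

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValidationError("cohort must contain at least one subject")
        for col in (self.id_column, self.outcome_column):
            if col not in self.data.columns:
                raise ConfigurationError(f"cohort is missing required column {col!r}")
        ids = self.data[self.id_column]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject id {dup!r}")
        y = self.outcomes
        if (y < 0).any():
            raise ValidationError("outcome categories must be non-negative integers")
        observed = set(np.unique(y).tolist())
        expected = set(range(max(observed) + 1))
        missing = sorted(expected - observed)
        if missing:
            raise ValidationError(
                f"outcome categories must be contiguous from 0; missing {missing}"
            )

    @property
    def outcomes(self) -> np.ndarray:
        """Integer outcome vector, shape ``(n,)``."""
        y = self.data[self.outcome_column].to_numpy()
        try:
            out = np.asarray(y, dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"outcome column is not numeric: {exc}") from exc
        if not np.all(out == np.floor(out)):
            raise ValidationError("outcome column contains non-integer values")
        return out.astype(int)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_categories(self) -> int:
        """K + 1, the number of outcome categories."""
        return int(self.outcomes.max()) + 1

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ConfigurationError(f"cohort has no covariate column {name!r}")
        return self.data[name].to_numpy()


@dataclass(frozen=True)
class RiskMatrix:
    """Per-subject predicted probabilities over the K+1 outcome categories.

    Rows must lie on the probability simplex; degenerate 0/1 rows (as produced
    by deterministic rule-based classifiers) are allowed.
    """

    probs: np.ndarray
    category_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "category_labels", tuple(self.category_labels))
        if probs.ndim != 2:
            raise ValidationError("risk matrix must be two-dimensional")
        if probs.shape[1] != len(self.category_labels):
            raise ValidationError(
                f"{probs.shape[1]} probability columns but "
                f"{len(self.category_labels)} category labels"
            )
        if probs.shape[1] < 2:
            raise ValidationError("risk matrix needs at least two categories")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        bad = np.nonzero(np.abs(probs.sum(axis=1) - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"row {bad[0]} sums to {probs[bad[0]].sum():.8f}, not 1 "
                f"(tolerance {ROW_SUM_TOL:g}); refusing to renormalize silently"
            )

    @property
    def n_subjects(self) -> int:
        return self.probs.shape[0]

    @property
    def n_categories(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Configuration of one binary dichotomization of the polytomous outcome."""

    kind: str  # cumulative | ovr | ovo
    name: str = ""
    index: int | None = None  # cumulative: split at Y > index; ovr: class index
    classes: tuple[int, int] | None = None  # ovo only

    def __post_init__(self) -> None:
        if self.kind not in ("cumulative", "ovr", "ovo"):
            raise ConfigurationError(f"unknown split kind {self.kind!r}")
        if self.kind == "ovo" and self.classes is None:
            raise ConfigurationError("ovo split requires a pair of classes")
        if self.kind in ("cumulative", "ovr") and self.index is None:
            raise ConfigurationError(f"{self.kind} split requires an index")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully resolved configuration of one analysis run.

    One threshold distribution per split; importance weights apply to the
    splits (not the K+1 categories).  ``grid_step`` controls the threshold
    grid used when exporting plottable decision curves.
    """

    splits: tuple[SplitSpec, ...]
    threshold_dists: tuple[Any, ...]  # ThresholdDistribution per split
    weight_dist: Any = None  # ImportanceWeightDistribution
    mc_draws: int = 10_000
    bootstrap_reps: int = 1000
    seed: int = 0
    grid_step: float = 0.001

    def __post_init__(self) -> None:
        if len(self.threshold_dists) != len(self.splits):
            raise ConfigurationError(
                f"{len(self.splits)} splits but {len(self.threshold_dists)} "
                "threshold distributions; exactly one per split is required"
            )
        if self.mc_draws < 1:
            raise ConfigurationError("mc_draws must be >= 1")
        if self.bootstrap_reps < 2:
            raise ConfigurationError("bootstrap_reps must be >= 2")
        if not 0 < self.grid_step <= 0.1:
            raise ConfigurationError("grid_step must lie in (0, 0.1]")


def read_cohort(
    path: str | Path,
    outcome_column: str = "outcome",
    id_column: str = "id",
    outcome_levels: Sequence[str] | None = None,
) -> CohortTable:
    """Read a cohort CSV, remapping a labelled outcome to integers ``0..K``.

    Parameters
    ----------
    outcome_levels
        Explicit ordered list of outcome labels (least severe first).
        Required when the outcome column is not already integer-coded;
        alphabetical inference is refused for ordinal outcomes.
    """
    df = pd.read_csv(path)
    for col in (id_column, outcome_column):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    y = df[outcome_column]
    if outcome_levels is not None:
        levels = list(outcome_levels)
        unseen = set(y.unique()) - set(levels)
        if unseen:
            raise ValidationError(
                f"outcome labels {sorted(map(str, unseen))} not in the stated level order"
            )
        df = df.copy()
        df[outcome_column] = y.map({lab: i for i, lab in enumerate(levels)})
    elif not pd.api.types.is_numeric_dtype(y):
        raise ConfigurationError(
            "outcome column is not integer-coded; pass outcome_levels with the "
            "ordered labels (alphabetical inference is refused for ordinal outcomes)"
        )
    return CohortTable(df, id_column=id_column, outcome_column=outcome_column)


def read_risk_matrix(
    path: str | Path,
    prob_columns: Sequence[str],
) -> RiskMatrix:
    """Read an N x (K+1) predicted-probability matrix from CSV.

    Row normalization is *checked*, never silently applied: a row whose sum
    deviates from 1 by more than ``ROW_SUM_TOL`` raises a ``ValidationError``
    naming the row.
    """
    df = pd.read_csv(path)
    missing = [c for c in prob_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing probability columns {missing}")
    block = df[list(prob_columns)]
    for c in prob_columns:
        if not pd.api.types.is_numeric_dtype(block[c]):
            raise ValidationError(f"{path}: column {c!r} is not numeric")
    return RiskMatrix(block.to_numpy(dtype=float), tuple(prob_columns))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False)


def write_risk_matrix(
    risks: RiskMatrix,
    path: str | Path,
    ids: Sequence[Any] | None = None,
    id_column: str = "id",
) -> None:
    """Write a risk matrix to CSV with 12 significant digits per probability."""
    df = pd.DataFrame(risks.probs, columns=list(risks.category_labels))
    if ids is not None:
        df.insert(0, id_column, list(ids))
    df.to_csv(path, index=False, float_format="%.12g")


def _format_ci(point: float, lo: float, hi: float) -> str:
    if point == 0.0 and lo == 0.0 and hi == 0.0:
        return "0"
    return f"{point:.2f} ({lo:.2f}, {hi:.2f})"


def write_summary(summary: "UtilitySummary", path: str | Path) -> None:  # noqa: F821
    """Write a utility summary as a CSV table.

    Layout: one row per treatment-guiding strategy; one column per binary
    split holding ``wAUCsNB (lo, hi)``; a final column with the integrated
    (importance-weighted) value and its interval.  Exact zeros (the Treat
    None reference) print as a bare ``0``.
    """
    if not summary.strategies:
        raise ValidationError("summary contains no strategies")
    rows = []
    for name in summary.strategies:
        row: dict[str, str] = {"strategy": name}
        for split_name in summary.split_names:
            pt, lo, hi = summary.per_split[name][split_name]
            row[f"wAUCsNB_{split_name}"] = _format_ci(pt, lo, hi)
        pt, lo, hi = summary.integrated[name]
        row["IwAUCsNB"] = _format_ci(pt, lo, hi)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a structured (YAML) config file into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return dict(cfg)
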