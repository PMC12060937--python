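"""Importance-weighted integration of per-split utilities, with bootstrap CIs.

A polytomous outcome yields K binary splits, each with its own weighted area
under the standardized net-benefit curve.  Clinicians attach different
importance to the different dichotomizations (missing a severe case matters
more than over-treating a mild one), expressed as simplex weights
``w = (w_1..w_K)`` with a preference distribution ``f(w)``.  For one clinician
at thresholds ``r = (r_1..r_K)`` and weights ``w`` the integrated standardized
net benefit is::

    IsNB(r, w) = sum_k sNB_k(r_k) * w_k

and averaging over both preference distributions gives the headline summary::

    IwAUC_sNB = ∫∫ IsNB(r, w) f(r) f(w) dr dw = ∫ wAUC_sNB(w) f(w) dw

Threshold draws across splits and weight draws are sampled mutually
independently by default, so the double integral factorizes as
``sum_k E[w_k] * wAUC_sNB_k`` — the identity used as the primary correctness
oracle in the test suite.  A comonotone option couples the threshold draws of
all splits through one shared uniform, for sensitivity analyses in which a
risk-averse clinician is risk-averse on every split at once.

Uncertainty is quantified by nonparametric subject-level bootstrap (labels and
risks resampled jointly) with percentile intervals; Monte Carlo sub-seeds are
spawned deterministically from the master seed so reruns are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, NamedTuple, Sequence

import numpy as np

from .curves import ThresholdDistribution, strategy_snb, wauc_snb
from .exceptions import ConfigurationError, DegenerateSplitError, PolyDCAError, ValidationError
from .net_benefit import BinarySplit

__all__ = [
    "ImportanceWeightDistribution",
    "UtilitySummary",
    "BootstrapCI",
    "isnb",
    "sample_importance_weights",
    "iwauc_snb",
    "weight_sensitivity_profile",
    "bootstrap_ci",
    "utility_summary",
]


@dataclass(frozen=True)
class ImportanceWeightDistribution:
    """Distribution ``f(w)`` over simplex weights for the K binary splits.

    Families: ``fixed`` (a degenerate point mass at a given weight vector),
    ``beta`` with params ``(a, b)`` for exactly two splits (a draw ``w`` gives
    the vector ``(w, 1-w)``, so the Beta describes the weight of the *first*
    split), and ``dirichlet`` with a concentration vector for K >= 2 splits.
    No weight attaches to the reference category of the outcome — weights live
    on the splits.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if self.family == "fixed":
            w = np.asarray(params)
            if w.size < 1 or np.any(w < 0) or np.any(w > 1):
                raise ConfigurationError("fixed weights must lie in [0, 1]")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"fixed weights sum to {w.sum():.12g}, not 1"
                )
        elif self.family == "beta":
            if len(params) != 2 or min(params) <= 0:
                raise ConfigurationError("beta weights need positive (a, b)")
        elif self.family == "dirichlet":
            if len(params) < 2 or min(params) <= 0:
                raise ConfigurationError(
                    "dirichlet weights need >= 2 positive concentrations"
                )
        else:
            raise ConfigurationError(f"unknown weight family {self.family!r}")

    @property
    def n_splits(self) -> int:
        if self.family == "beta":
            return 2
        return len(self.params)

    @property
    def mean(self) -> np.ndarray:
        """E[w], the mean weight vector."""
        if self.family == "fixed":
            return np.asarray(self.params)
        if self.family == "beta":
            a, b = self.params
            return np.asarray([a / (a + b), b / (a + b)])
        conc = np.asarray(self.params)
        return conc / conc.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` weight vectors, shape ``(n, K)``, each on the simplex."""
        if n < 1:
            raise ConfigurationError("need at least one draw")
        if self.family == "fixed":
            return np.tile(np.asarray(self.params), (n, 1))
        if self.family == "beta":
            a, b = self.params
            w = rng.beta(a, b, size=n)
            return np.column_stack([w, 1.0 - w])
        return rng.dirichlet(np.asarray(self.params), size=n)


class BootstrapCI(NamedTuple):
    """Percentile bootstrap interval around a point estimate."""

    lo: float
    point: float
    hi: float


@dataclass(frozen=True)
class UtilitySummary:
    """Per-split and integrated utility of each strategy, with intervals.

    ``per_split[strategy][split]`` and ``integrated[strategy]`` hold
    ``(point, lo, hi)`` triples; ``metadata`` records the distributions,
    draw counts, bootstrap replicates and seed that produced them.
    """

    strategies: tuple[str, ...]
    split_names: tuple[str, ...]
    per_split: dict[str, dict[str, tuple[float, float, float]]]
    integrated: dict[str, tuple[float, float, float]]
    metadata: dict[str, Any] = field(default_factory=dict)


def isnb(snb_values: Sequence[float], weights: Sequence[float]) -> float:
    """Integrated sNB for one clinician: ``sum_k sNB_k(r_k) * w_k``."""
    s = np.asarray(snb_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape or s.ndim != 1:
        raise ValidationError("sNB values and weights must be equal-length vectors")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights sum to {w.sum():.12g}, not 1")
    return float(s @ w)


def sample_importance_weights(
    dist: ImportanceWeightDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Reproducible weight-vector draws from ``f(w)``, shape ``(n, K)``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.sample(n, rng)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def iwauc_snb(
    splits: Sequence[BinarySplit],
    threshold_dists: Sequence[ThresholdDistribution],
    weight_dist: ImportanceWeightDistribution,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    strategy: str = "model",
    comonotone: bool = False,
) -> float:
    """Monte Carlo estimate of the integrated weighted area under sNB curves.

    With independent draws (the default) this estimates
    ``sum_k E[w_k] * wAUC_sNB_k``; ``comonotone=True`` instead drives all
    splits' threshold draws with one shared uniform per clinician.
    """
    if len(splits) != len(threshold_dists):
        raise ConfigurationError(
            f"{len(splits)} splits but {len(threshold_dists)} threshold "
            "distributions; exactly one per split is required"
        )
    if weight_dist.n_splits != len(splits):
        raise ConfigurationError(
            f"weight distribution describes {weight_dist.n_splits} splits, "
            f"got {len(splits)}"
        )
    rng = _as_rng(seed)
    if comonotone:
        u = rng.random(n_draws)
        thresholds = [d.ppf(u) for d in threshold_dists]
    else:
        thresholds = [d.sample(n_draws, rng) for d in threshold_dists]
    snb = np.column_stack(
        [strategy_snb(s, strategy, r) for s, r in zip(splits, thresholds)]
    )
    w = weight_dist.sample(n_draws, rng)
    return float(np.mean(np.sum(snb * w, axis=1)))


def weight_sensitivity_profile(
    splits: Sequence[BinarySplit],
    threshold_dists: Sequence[ThresholdDistribution],
    w_grid: Sequence[float],
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    strategy: str = "model",
) -> list[tuple[float, float]]:
    """Integrated utility at fixed first-split weights ``w`` in ``[0, 1]``.

    Only defined for two splits; the profile is exactly linear in ``w``
    (``w * wAUC_1 + (1-w) * wAUC_2``), so its endpoints recover the two
    per-split weighted areas.
    """
    if len(splits) != 2 or len(threshold_dists) != 2:
        raise ConfigurationError(
            "weight-sensitivity profile is defined for exactly two splits"
        )
    rng = _as_rng(seed)
    waucs = [
        wauc_snb(s, d, n_draws, rng, strategy)
        for s, d in zip(splits, threshold_dists)
    ]
    out = []
    for w in w_grid:
        w = float(w)
        if not 0.0 <= w <= 1.0:
            raise ValidationError(f"weight {w} outside [0, 1]")
        out.append((w, w * waucs[0] + (1.0 - w) * waucs[1]))
    return out


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.random.Generator], float],
    n_subjects: int,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap interval for a subject-level statistic.

    ``statistic(indices, rng)`` must evaluate the summary on the subjects
    selected by ``indices`` (labels and risks resampled jointly), using
    ``rng`` for any internal Monte Carlo; it must be deterministic given both.
    The point estimate uses the original subject order.  A resample on which
    the statistic is undefined (``DegenerateSplitError``, e.g. a split with no
    positive subjects) is redrawn and counted; after ``10 * B`` failed
    resamples the bootstrap aborts.
    """
    if B < 2:
        raise ConfigurationError("bootstrap needs B >= 2 replicates")
    if not 0 < level < 1:
        raise ConfigurationError("confidence level must lie in (0, 1)")
    ss = np.random.SeedSequence(seed)
    point_rng = np.random.default_rng(ss.spawn(1)[0])
    point = float(statistic(np.arange(n_subjects), point_rng))
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    stats = np.empty(B)
    failures = 0
    b = 0
    while b < B:
        idx = resample_rng.integers(0, n_subjects, size=n_subjects)
        sub_rng = np.random.default_rng(ss.spawn(1)[0])
        try:
            stats[b] = statistic(idx, sub_rng)
        except DegenerateSplitError:
            failures += 1
            if failures >= 10 * B:
                raise PolyDCAError(
                    f"bootstrap aborted: {failures} degenerate resamples "
                    f"(limit {10 * B}); the statistic is undefined on too many "
                    "resamples of this cohort"
                )
            continue
        b += 1
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1.0 - alpha / 2])
    return BootstrapCI(lo=float(lo), point=point, hi=float(hi))


def _resampled_split(split: BinarySplit, idx: np.ndarray) -> BinarySplit:
    return BinarySplit(
        name=split.name,
        positive_categories=split.positive_categories,
        risks=split.risks[idx],
        labels=split.labels[idx],
        kind=split.kind,
    )


def utility_summary(
    splits_by_strategy: dict[str, Sequence[BinarySplit]],
    threshold_dists: Sequence[ThresholdDistribution],
    weight_dist: ImportanceWeightDistribution,
    mc_draws: int = 10_000,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    reference_strategies: tuple[str, ...] = ("Treat All", "Treat None"),
) -> UtilitySummary:
    """Full utility table: wAUC_sNB per split and IwAUC_sNB per strategy.

    ``splits_by_strategy`` maps each model name to its list of binary splits
    (same dichotomizations, same subject order, model-specific risks).  The
    Treat All / Treat None reference rows are derived from the first model's
    splits, whose labels they share.  One joint bootstrap resamples subjects
    once per replicate and re-evaluates every cell, so intervals across cells
    are computed on common resamples.
    """
    if not splits_by_strategy:
        raise ValidationError("no strategies supplied")
    model_names = list(splits_by_strategy)
    first = list(splits_by_strategy[model_names[0]])
    split_names = tuple(s.name for s in first)
    for name, splits in splits_by_strategy.items():
        if tuple(s.name for s in splits) != split_names:
            raise ConfigurationError(
                f"strategy {name!r} has different splits than {model_names[0]!r}"
            )
    ref_map = {"Treat All": "treat_all", "Treat None": "treat_none"}
    strategies: list[tuple[str, str]] = [(m, "model") for m in model_names]
    for ref in reference_strategies:
        if ref not in ref_map:
            raise ConfigurationError(f"unknown reference strategy {ref!r}")
        strategies.append((ref, ref_map[ref]))
    K = len(split_names)
    if weight_dist.n_splits != K:
        raise ConfigurationError(
            f"weight distribution describes {weight_dist.n_splits} splits, "
            f"but the analysis has {K}"
        )
    n = first[0].n_subjects

    def stat_vector(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        thresholds = [d.sample(mc_draws, rng) for d in threshold_dists]
        weights = weight_dist.sample(mc_draws, rng)
        out = np.empty((len(strategies), K + 1))
        for i, (name, kind) in enumerate(strategies):
            base = splits_by_strategy.get(name, first)
            res = [_resampled_split(s, idx) for s in base]
            snb_draws = np.column_stack(
                [strategy_snb(s, kind, r) for s, r in zip(res, thresholds)]
            )
            out[i, :K] = snb_draws.mean(axis=0)
            out[i, K] = float(np.mean(np.sum(snb_draws * weights, axis=1)))
        return out

    ss = np.random.SeedSequence(seed)
    point = stat_vector(np.arange(n), np.random.default_rng(ss.spawn(1)[0]))
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    boots = np.empty((bootstrap_reps, len(strategies), K + 1))
    failures = 0
    b = 0
    while b < bootstrap_reps:
        idx = resample_rng.integers(0, n, size=n)
        sub_rng = np.random.default_rng(ss.spawn(1)[0])
        try:
            boots[b] = stat_vector(idx, sub_rng)
        except DegenerateSplitError:
            failures += 1
            if failures >= 10 * bootstrap_reps:
                raise PolyDCAError(
                    f"bootstrap aborted after {failures} degenerate resamples"
                )
            continue
        b += 1
    alpha = 1.0 - level
    lo = np.quantile(boots, alpha / 2, axis=0)
    hi = np.quantile(boots, 1.0 - alpha / 2, axis=0)

    per_split: dict[str, dict[str, tuple[float, float, float]]] = {}
    integrated: dict[str, tuple[float, float, float]] = {}
    for i, (name, kind) in enumerate(strategies):
        if kind == "treat_none":  # exactly zero by definition, at every cell
            per_split[name] = {s: (0.0, 0.0, 0.0) for s in split_names}
            integrated[name] = (0.0, 0.0, 0.0)
            continue
        per_split[name] = {
            s: (float(point[i, k]), float(lo[i, k]), float(hi[i, k]))
            for k, s in enumerate(split_names)
        }
        integrated[name] = (float(point[i, K]), float(lo[i, K]), float(hi[i, K]))
    return UtilitySummary(
        strategies=tuple(name for name, _ in strategies),
        split_names=split_names,
        per_split=per_split,
        integrated=integrated,
        metadata={
            "threshold_dists": [
                {"family": d.family, "params": list(d.params)} for d in threshold_dists
            ],
            "weight_dist": {
                "family": weight_dist.family,
                "params": list(weight_dist.params),
            },
            "mc_draws": mc_draws,
            "bootstrap_reps": bootstrap_reps,
            "seed": seed,
            "level": level,
            "n_subjects": n,
            "degenerate_resamples_redrawn": failures,
        },
    )
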