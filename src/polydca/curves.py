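"""Decision curves and (weighted) areas under the net-benefit curve.

A decision curve evaluates the net benefit of a treatment-guiding strategy
over a grid of risk thresholds, always alongside the Treat All and Treat None
references.  To summarize a curve over the thresholds a clinician population
actually holds, net benefit is integrated against a threshold-preference
distribution ``f(r)``::

    wAUC_NB  = E_f[NB(r)]        wAUC_sNB = E_f[sNB(r)]

estimated by Monte Carlo with inverse-CDF sampling (bit-reproducible under a
fixed seed).  For a uniform ``f(r)`` the same quantity is also available in
closed form: between consecutive order statistics of the predicted risks the
confusion counts are constant, so ``∫ NB(r) dr`` reduces to a sum of
segment integrals of ``c1 - c2·r/(1-r)``, which integrate analytically
(``∫ r/(1-r) dr = -r - log(1-r)``).  That exact quadrature is the oracle the
Monte Carlo path is tested against.

Normal threshold distributions are truncated to (0,1) and renormalized; a
normal with half or more of its mass outside (0,1) is rejected as a
configuration error rather than silently concentrated at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .exceptions import ConfigurationError, DegenerateSplitError, ValidationError
from .net_benefit import BinarySplit

__all__ = [
    "ThresholdDistribution",
    "DecisionCurve",
    "STRATEGIES",
    "strategy_nb",
    "strategy_snb",
    "decision_curve",
    "auc_nb",
    "sample_thresholds",
    "wauc_nb",
    "wauc_snb",
]

STRATEGIES = ("model", "treat_all", "treat_none")


@dataclass(frozen=True)
class ThresholdDistribution:
    """Distribution ``f(r)`` of clinically relevant risk thresholds.

    ``uniform`` with params ``(lo, hi)`` on ``0 <= lo < hi < 1``, or
    ``normal`` with params ``(mean, sd)`` truncated to (0,1).
    """

    family: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = (float(self.params[0]), float(self.params[1]))
        object.__setattr__(self, "params", (a, b))
        if self.family == "uniform":
            if not (0.0 <= a < b < 1.0):
                raise ConfigurationError(
                    f"uniform threshold range ({a}, {b}) must satisfy 0 <= lo < hi < 1"
                )
        elif self.family == "normal":
            if b <= 0:
                raise ConfigurationError("normal threshold sd must be positive")
            mass = norm.cdf((1.0 - a) / b) - norm.cdf((0.0 - a) / b)
            if mass < 0.5:
                raise ConfigurationError(
                    f"normal({a}, {b}) places {1 - mass:.0%} of its mass outside "
                    "(0, 1); truncation would be degenerate"
                )
        else:
            raise ConfigurationError(f"unknown threshold family {self.family!r}")

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            return self.params
        return (0.0, 1.0)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF on uniforms ``u``; values strictly inside (0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.family == "uniform":
            lo, hi = self.params
            return lo + (hi - lo) * u
        mean, sd = self.params
        x = truncnorm.ppf(u, (0.0 - mean) / sd, (1.0 - mean) / sd, loc=mean, scale=sd)
        return np.clip(x, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` inverse-CDF draws, all strictly inside (0, 1)."""
        if n < 1:
            raise ConfigurationError("need at least one draw")
        return self.ppf(rng.random(n))


@dataclass(frozen=True)
class DecisionCurve:
    """Per-strategy NB and sNB on a shared increasing threshold grid."""

    split_name: str
    grid: np.ndarray
    nb: dict[str, np.ndarray]
    snb: dict[str, np.ndarray]
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (threshold, strategy, NB, sNB) ready for plotting."""
        frames = []
        for strategy, values in self.nb.items():
            frames.append(
                pd.DataFrame(
                    {
                        "split": self.split_name,
                        "threshold": self.grid,
                        "strategy": strategy,
                        "NB": values,
                        "sNB": self.snb[strategy],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def strategy_nb(split: BinarySplit, strategy: str, thresholds: np.ndarray) -> np.ndarray:
    """NB of one strategy on an array of thresholds."""
    r = np.asarray(thresholds, dtype=float)
    if strategy == "model":
        return split.net_benefit(r)
    if strategy == "treat_all":
        p = split.prevalence
        return p - (1.0 - p) * r / (1.0 - r)
    if strategy == "treat_none":
        return np.zeros_like(r)
    raise ConfigurationError(f"unknown strategy {strategy!r}")


def strategy_snb(
    split: BinarySplit, strategy: str, thresholds: np.ndarray
) -> np.ndarray:
    """sNB of one strategy on an array of thresholds (NB / prevalence)."""
    p = split.prevalence
    if p == 0:
        raise DegenerateSplitError(
            f"split {split.name!r} has no positive subjects; sNB is undefined"
        )
    return strategy_nb(split, strategy, thresholds) / p


def decision_curve(
    split: BinarySplit,
    grid: np.ndarray | None = None,
    grid_step: float = 0.001,
    strategies: tuple[str, ...] = STRATEGIES,
) -> DecisionCurve:
    """Evaluate NB and sNB for each strategy on a threshold grid.

    The default grid covers ``[0, 1 - grid_step]`` in steps of ``grid_step``
    (the odds weight diverges at 1, so the grid stops one step short).
    """
    if grid is None:
        grid = np.arange(0.0, 1.0 - grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty threshold grid")
    if np.any(grid < 0) or np.any(grid >= 1):
        raise ValidationError("grid thresholds must lie in [0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")
    p = split.prevalence
    if p == 0:
        raise DegenerateSplitError(
            f"split {split.name!r} has no positive subjects; sNB is undefined"
        )
    nb = {s: strategy_nb(split, s, grid) for s in strategies}
    snb = {s: v / p for s, v in nb.items()}
    return DecisionCurve(
        split_name=split.name, grid=grid, nb=nb, snb=snb, prevalence=p
    )


def _int_odds(a: float, b: float) -> float:
    """Closed form of ``∫_a^b r/(1-r) dr`` for ``0 <= a <= b < 1``."""
    return (a - b) + math.log((1.0 - a) / (1.0 - b))


def auc_nb(
    split: BinarySplit,
    a: float,
    b: float,
    strategy: str = "model",
) -> float:
    """Exact ``∫_a^b NB(r) dr`` by piecewise-analytic quadrature.

    The confusion counts of a model-based strategy are step functions of the
    threshold, changing only at the distinct predicted risks; within each
    segment NB is ``TP/N - (FP/N)·r/(1-r)``, which integrates in closed form.
    Treat All uses the same closed form with fixed counts; Treat None is 0.
    """
    if not (0.0 <= a < b < 1.0):
        raise ValidationError(f"integration range ({a}, {b}) must satisfy 0 <= a < b < 1")
    if strategy == "treat_none":
        return 0.0
    n = split.n_subjects
    if strategy == "treat_all":
        p = split.prevalence
        return p * (b - a) - (1.0 - p) * _int_odds(a, b)
    if strategy != "model":
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    knots = np.unique(split.risks)
    knots = knots[(knots > a) & (knots < b)]
    edges = np.concatenate([[a], knots, [b]])
    lo, hi = edges[:-1], edges[1:]
    tp, fp = split.counts_at(lo)  # counts are constant on (edge, next edge)
    int_odds = (lo - hi) + np.log((1.0 - lo) / (1.0 - hi))
    return float(np.sum((tp / n) * (hi - lo) - (fp / n) * int_odds))


def sample_thresholds(
    dist: ThresholdDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Reproducible threshold draws from ``f(r)``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.sample(n, rng)


def wauc_nb(
    split: BinarySplit,
    dist: ThresholdDistribution,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    strategy: str = "model",
    thresholds: np.ndarray | None = None,
) -> float:
    """Monte Carlo estimate of ``∫ NB(r) f(r) dr``.

    Pass ``thresholds`` to reuse a fixed draw (e.g. to share draws across
    strategies or with :func:`wauc_snb` so the ``sNB = NB/P`` identity holds
    exactly on the estimates).
    """
    if thresholds is None:
        thresholds = sample_thresholds(dist, n_draws, seed)
    return float(np.mean(strategy_nb(split, strategy, thresholds)))


def wauc_snb(
    split: BinarySplit,
    dist: ThresholdDistribution,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    strategy: str = "model",
    thresholds: np.ndarray | None = None,
) -> float:
    """Monte Carlo estimate of ``∫ sNB(r) f(r) dr`` (wAUC_NB / prevalence)."""
    p = split.prevalence
    if p == 0:
        raise DegenerateSplitError(
            f"split {split.name!r} has no positive subjects; sNB is undefined"
        )
    return wauc_nb(split, dist, n_draws, seed, strategy, thresholds) / p
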