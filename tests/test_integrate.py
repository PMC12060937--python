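import numpy as np
import pytest

from polydca import (
    ConfigurationError,
    ImportanceWeightDistribution,
    ThresholdDistribution,
    ValidationError,
    bootstrap_ci,
    isnb,
    iwauc_snb,
    sample_importance_weights,
    utility_summary,
    wauc_snb,
    weight_sensitivity_profile,
)
from polydca.exceptions import DegenerateSplitError, PolyDCAError

SEV_DIST = ThresholdDistribution("uniform", (0.05, 0.15))
ANY_DIST = ThresholdDistribution("uniform", (0.6, 0.8))
BETA = ImportanceWeightDistribution("beta", (20.0, 10.0))


class TestIsnb:
    def test_weighted_average(self):
        assert isnb([0.6, 0.3], [2 / 3, 1 / 3]) == pytest.approx(0.5)

    def test_single_split_degenerate(self):
        assert isnb([0.42], [1.0]) == pytest.approx(0.42)

    def test_point_mass_selects_one_split(self):
        assert isnb([0.6, 0.3], [1.0, 0.0]) == pytest.approx(0.6)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            isnb([0.5, 0.5], [0.5, 0.6])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            isnb([0.5], [0.5, 0.5])


class TestImportanceWeights:
    def test_beta_mean_is_two_thirds(self):
        w = sample_importance_weights(BETA, 100_000, seed=1)
        se = np.sqrt(BETA.mean[0] * (1 - BETA.mean[0]) / 31) / np.sqrt(100_000)
        assert abs(w[:, 0].mean() - 2 / 3) < 3 * se
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_weights_are_constant(self):
        dist = ImportanceWeightDistribution("fixed", (0.5, 0.5))
        w = sample_importance_weights(dist, 50, seed=2)
        assert np.all(w == 0.5)

    def test_flat_dirichlet_component_means(self):
        dist = ImportanceWeightDistribution("dirichlet", (1.0, 1.0, 1.0))
        w = sample_importance_weights(dist, 100_000, seed=3)
        # Dirichlet(1,1,1) component mean 1/3, variance 1/18
        se = np.sqrt(1 / 18 / 100_000)
        assert np.all(np.abs(w.mean(axis=0) - 1 / 3) < 3 * se)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            ImportanceWeightDistribution("beta", (20.0, -1.0))
        with pytest.raises(ConfigurationError):
            ImportanceWeightDistribution("fixed", (0.5, 0.6))


class TestIwaucSnb:
    def test_fixed_weights_give_exact_linear_combination(self, severe_any_splits):
        severe, any_ = severe_any_splits
        rng_master = np.random.default_rng(10)
        # shared threshold draws: iwauc with fixed weights must equal the
        # same weighted combination of per-split means computed by hand
        dist = ImportanceWeightDistribution("fixed", (2 / 3, 1 / 3))
        value = iwauc_snb([severe, any_], [SEV_DIST, ANY_DIST], dist, 5000, seed=10)
        rng = np.random.default_rng(10)
        r_sev = SEV_DIST.sample(5000, rng)
        r_any = ANY_DIST.sample(5000, rng)
        expected = (2 / 3) * severe.standardized_net_benefit(r_sev).mean() + (
            1 / 3
        ) * any_.standardized_net_benefit(r_any).mean()
        assert value == pytest.approx(expected, abs=1e-12)

    def test_beta_weights_match_linearity_of_expectation(self, severe_any_splits):
        severe, any_ = severe_any_splits
        n = 100_000
        value = iwauc_snb([severe, any_], [SEV_DIST, ANY_DIST], BETA, n, seed=11)
        wauc_sev = wauc_snb(severe, SEV_DIST, n, seed=12)
        wauc_any = wauc_snb(any_, ANY_DIST, n, seed=13)
        expected = (2 / 3) * wauc_sev + (1 / 3) * wauc_any
        # conservative MC error bound: sNB values here are O(1)
        assert abs(value - expected) < 3 * (1.0 / np.sqrt(n)) * 3
        assert abs(value - expected) < 0.02

    def test_single_split_reduces_to_its_wauc(self, severe_any_splits):
        severe, _ = severe_any_splits
        dist = ImportanceWeightDistribution("fixed", (1.0,))
        value = iwauc_snb([severe], [SEV_DIST], dist, 5000, seed=14)
        rng = np.random.default_rng(14)
        expected = wauc_snb(severe, SEV_DIST, thresholds=SEV_DIST.sample(5000, rng))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_all_weight_on_one_split_recovers_that_split(self, severe_any_splits):
        severe, any_ = severe_any_splits
        dist = ImportanceWeightDistribution("fixed", (1.0, 0.0))
        value = iwauc_snb([severe, any_], [SEV_DIST, ANY_DIST], dist, 5000, seed=15)
        rng = np.random.default_rng(15)
        r_sev = SEV_DIST.sample(5000, rng)
        assert value == pytest.approx(
            severe.standardized_net_benefit(r_sev).mean(), abs=1e-12
        )

    def test_invariant_to_consistent_split_permutation(self, severe_any_splits):
        severe, any_ = severe_any_splits
        a = iwauc_snb(
            [severe, any_], [SEV_DIST, ANY_DIST],
            ImportanceWeightDistribution("fixed", (0.7, 0.3)), 4000, seed=16,
        )
        b = iwauc_snb(
            [any_, severe], [ANY_DIST, SEV_DIST],
            ImportanceWeightDistribution("fixed", (0.3, 0.7)), 4000, seed=16,
        )
        # same seed => same underlying uniforms per draw position, but the
        # split-to-stream assignment changes; compare within MC error
        assert abs(a - b) < 0.02

    def test_mismatched_distributions_rejected(self, severe_any_splits):
        severe, any_ = severe_any_splits
        with pytest.raises(ConfigurationError):
            iwauc_snb([severe, any_], [SEV_DIST], BETA, 100, seed=0)


class TestWeightSensitivityProfile:
    def test_endpoints_recover_per_split_areas(self, severe_any_splits):
        severe, any_ = severe_any_splits
        profile = dict(
            weight_sensitivity_profile(
                [severe, any_], [SEV_DIST, ANY_DIST], [0.0, 0.5, 1.0], 5000, seed=17
            )
        )
        rng = np.random.default_rng(17)
        wauc_sev = severe.standardized_net_benefit(SEV_DIST.sample(5000, rng)).mean()
        wauc_any = any_.standardized_net_benefit(ANY_DIST.sample(5000, rng)).mean()
        assert profile[1.0] == pytest.approx(wauc_sev, abs=1e-12)
        assert profile[0.0] == pytest.approx(wauc_any, abs=1e-12)
        assert profile[0.5] == pytest.approx((wauc_sev + wauc_any) / 2, abs=1e-12)

    def test_profile_is_exactly_linear(self, severe_any_splits):
        severe, any_ = severe_any_splits
        grid = np.linspace(0, 1, 11)
        pairs = weight_sensitivity_profile(
            [severe, any_], [SEV_DIST, ANY_DIST], grid, 2000, seed=18
        )
        w = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        # two-point fit reproduces every grid point
        slope = v[-1] - v[0]
        assert np.allclose(v, v[0] + slope * w, atol=1e-12)

    def test_three_splits_not_supported(self, severe_any_splits):
        severe, any_ = severe_any_splits
        with pytest.raises(ConfigurationError):
            weight_sensitivity_profile(
                [severe, any_, severe], [SEV_DIST, ANY_DIST, SEV_DIST], [0.5]
            )


class TestBootstrap:
    def test_constant_statistic_gives_zero_width_interval(self):
        ci = bootstrap_ci(lambda idx, rng: 1.7, n_subjects=50, B=100, seed=1)
        assert ci.lo == ci.point == ci.hi == 1.7

    def test_interval_contains_point_for_smooth_statistic(self, severe_any_splits):
        severe, _ = severe_any_splits

        def stat(idx, rng):
            return float(severe.risks[idx].mean())

        ci = bootstrap_ci(stat, severe.n_subjects, B=200, seed=2)
        assert ci.lo <= ci.point <= ci.hi
        assert ci.hi - ci.lo > 0

    def test_reproducible_under_fixed_seed(self, severe_any_splits):
        severe, _ = severe_any_splits

        def stat(idx, rng):
            return wauc_snb(severe, SEV_DIST, 200, rng)

        a = bootstrap_ci(stat, 100, B=50, seed=3)
        b = bootstrap_ci(stat, 100, B=50, seed=3)
        assert a == b

    def test_degenerate_resamples_are_redrawn_then_abort(self):
        calls = {"n": 0}

        def flaky(idx, rng):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise DegenerateSplitError("no positives")
            return 1.0

        ci = bootstrap_ci(flaky, 10, B=20, seed=4)
        assert ci.point == 1.0

        def always_degenerate(idx, rng):
            if len(idx) == len(set(idx.tolist())):  # point estimate passes
                return 1.0
            raise DegenerateSplitError("no positives")

        with pytest.raises(PolyDCAError, match="aborted"):
            bootstrap_ci(always_degenerate, 10, B=5, seed=5)


class TestUtilitySummary:
    def test_reproducible_and_consistent(self, severe_any_splits):
        severe, any_ = severe_any_splits
        kwargs = dict(
            threshold_dists=[SEV_DIST, ANY_DIST],
            weight_dist=BETA,
            mc_draws=1000,
            bootstrap_reps=50,
            seed=9,
        )
        a = utility_summary({"truth": [severe, any_]}, **kwargs)
        b = utility_summary({"truth": [severe, any_]}, **kwargs)
        assert a.per_split == b.per_split
        assert a.integrated == b.integrated
        # treat-none row exactly zero, intervals bracket points elsewhere
        assert a.integrated["Treat None"] == (0.0, 0.0, 0.0)
        for strategy in ("truth", "Treat All"):
            pt, lo, hi = a.integrated[strategy]
            assert lo <= pt <= hi
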