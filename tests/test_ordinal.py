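import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from polydca import (
    CohortTable,
    ConfigurationError,
    ModelSpec,
    Term,
    ValidationError,
    coefficient_odds_ratio,
    load_published_model,
    predict_baseline_logit,
    predict_cumulative_logit,
)


def _cohort(**columns):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"id": range(n), "outcome": [0] * n, **columns})
    return CohortTable(df)


def _reference_cohort():
    return _cohort(
        skin_pinch=["rapid"],
        eye_level=["normal"],
        respiration_depth=["normal"],
        urine_output=["normal"],
        radial_pulse=["strong"],
    )


class TestCumulativeLogit:
    def test_reference_subject_matches_hand_computed_cutpoint_probs(self):
        # all covariates at reference => linear predictor 0, so the category
        # probabilities come straight from the cutpoints (0.29, 4.08)
        spec = load_published_model("nirudak_simplified")
        rm = predict_cumulative_logit(spec, _reference_cohort())
        p_none, p_some, p_severe = rm.probs[0]
        assert p_none == pytest.approx(expit(0.29), abs=1e-12)
        assert p_severe == pytest.approx(1 - expit(4.08), abs=1e-12)
        assert p_some == pytest.approx(expit(4.08) - expit(0.29), abs=1e-12)

    def test_rows_sum_to_one_and_cumulatives_monotone(self):
        spec = load_published_model("nirudak_simplified")
        rng = np.random.default_rng(2)
        n = 200
        cohort = _cohort(
            skin_pinch=rng.choice(["rapid", "slow", "very_slow"], n),
            eye_level=rng.choice(["normal", "sunken"], n),
            respiration_depth=rng.choice(["normal", "deep"], n),
            urine_output=rng.choice(["normal", "decreased", "minimal"], n),
            radial_pulse=rng.choice(["strong", "decreased", "absent"], n),
        )
        rm = predict_cumulative_logit(spec, cohort)
        assert np.allclose(rm.probs.sum(axis=1), 1.0, atol=1e-12)
        cum = np.cumsum(rm.probs, axis=1)
        assert np.all(np.diff(cum, axis=1) >= -1e-12)

    def test_proportional_odds_property_exact(self):
        # the logit difference between two subjects is the same at every
        # cumulative split for a proportional model
        spec = load_published_model("nirudak_simplified")
        cohort = _cohort(
            skin_pinch=["rapid", "very_slow"],
            eye_level=["normal", "sunken"],
            respiration_depth=["normal", "deep"],
            urine_output=["normal", "minimal"],
            radial_pulse=["strong", "absent"],
        )
        rm = predict_cumulative_logit(spec, cohort)
        cum = np.cumsum(rm.probs, axis=1)[:, :-1]  # P(Y <= j)
        diffs = logit(cum[0]) - logit(cum[1])
        assert np.ptp(diffs) < 1e-10

    def test_continuous_covariates_use_printed_scale(self):
        # systolic BP enters per 10 mmHg: +10 mmHg shifts the linear
        # predictor by exactly the printed coefficient -0.14
        spec = load_published_model("nirudak_full")
        base = dict(
            age=[30.0, 30.0],
            skin_pinch=["rapid", "rapid"],
            eye_level=["normal", "normal"],
            respiration_depth=["normal", "normal"],
            vomiting_24h=["lt1", "lt1"],
            muac=[250.0, 250.0],
            sex=["female", "female"],
        )
        cohort = _cohort(systolic_bp=[100.0, 110.0], **base)
        rm = predict_cumulative_logit(spec, cohort)
        cum = np.cumsum(rm.probs, axis=1)[:, 0]
        assert logit(cum[1]) - logit(cum[0]) == pytest.approx(0.14, abs=1e-10)

    def test_unseen_categorical_level_named_in_error(self):
        spec = load_published_model("nirudak_simplified")
        cohort = _cohort(
            skin_pinch=["sluggish"],
            eye_level=["normal"],
            respiration_depth=["normal"],
            urine_output=["normal"],
            radial_pulse=["strong"],
        )
        with pytest.raises(ValidationError, match="sluggish"):
            predict_cumulative_logit(spec, cohort)

    def test_missing_continuous_value_not_imputed(self):
        spec = load_published_model("nirudak_full")
        cohort = _cohort(
            age=[np.nan],
            skin_pinch=["rapid"],
            eye_level=["normal"],
            respiration_depth=["normal"],
            vomiting_24h=["lt1"],
            systolic_bp=[100.0],
            muac=[250.0],
            sex=["female"],
        )
        with pytest.raises(ValidationError, match="missing"):
            predict_cumulative_logit(spec, cohort)


class TestBaselineCategoryLogit:
    def test_zero_linear_predictors_give_uniform_probs(self):
        spec = ModelSpec(
            family="baseline_category",
            proportional=False,
            terms=(),
            cutpoints=(0.0, 0.0),
            category_count=3,
        )
        rm = predict_baseline_logit(spec, _cohort(x=[1.0]))
        assert np.allclose(rm.probs[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_matches_brute_force_softmax(self):
        rng = np.random.default_rng(7)
        alphas = tuple(rng.normal(size=2))
        betas = [tuple(rng.normal(size=2)) for _ in range(2)]
        spec = ModelSpec(
            family="baseline_category",
            proportional=False,
            terms=(
                Term("x1", betas[0]),
                Term("x2", betas[1]),
            ),
            cutpoints=alphas,
            category_count=3,
        )
        x1, x2 = rng.normal(size=5), rng.normal(size=5)
        rm = predict_baseline_logit(spec, _cohort(x1=x1, x2=x2))
        for i in range(5):
            eta = np.array(
                [0.0]
                + [
                    alphas[j] + betas[0][j] * x1[i] + betas[1][j] * x2[i]
                    for j in range(2)
                ]
            )
            soft = np.exp(eta) / np.exp(eta).sum()
            assert np.abs(rm.probs[i] - soft).max() < 1e-12

    def test_large_negative_logit_drives_category_to_zero(self):
        spec = ModelSpec(
            family="baseline_category",
            proportional=False,
            terms=(),
            cutpoints=(-50.0, 0.0),
            category_count=3,
        )
        rm = predict_baseline_logit(spec, _cohort(x=[0.0]))
        assert rm.probs[0, 1] < 1e-20


class TestCoefficientOddsRatio:
    @pytest.mark.parametrize(
        "beta,printed_or",
        [(0.82, 2.27), (0.91, 2.48), (0.0, 1.0)],
    )
    def test_matches_printed_odds_ratios(self, beta, printed_or):
        assert round(coefficient_odds_ratio(beta), 2) == printed_or

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_odds_ratio(math.inf)


class TestPublishedModels:
    def test_simplified_model_has_five_signs_and_printed_cutpoints(self):
        spec = load_published_model("nirudak_simplified")
        assert spec.cutpoints == (0.29, 4.08)
        assert len({t.covariate for t in spec.terms}) == 5

    def test_full_model_includes_continuous_terms(self):
        spec = load_published_model("nirudak_full")
        continuous = {t.covariate for t in spec.terms if t.level is None}
        assert continuous == {"age", "systolic_bp", "muac"}
        assert spec.cutpoints == (-3.38, 0.66)

    def test_dhaka_without_cutpoints_refuses_prediction(self):
        spec = load_published_model("dhaka")
        assert spec.cutpoints is None
        cohort = _cohort(
            general_appearance=["normal"],
            respiration_depth=["normal"],
            skin_pinch=["normal"],
            tears=["normal"],
        )
        with pytest.raises(ConfigurationError, match="cutpoints"):
            predict_cumulative_logit(spec, cohort)
        rm = predict_cumulative_logit(spec.with_cutpoints((0.0, 2.0)), cohort)
        assert rm.probs.shape == (1, 3)

    def test_unknown_model_name_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            load_published_model("nope")

    def test_cutpoints_must_increase(self):
        spec = load_published_model("nirudak_simplified")
        with pytest.raises(ConfigurationError, match="increasing"):
            spec.with_cutpoints((4.08, 0.29))
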