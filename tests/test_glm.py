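"""IRLS logistic regression: published-table replication, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from interlogit.data import CellTable, ObservationSet, expand_to_observations
from interlogit.glm import (
    LogitGlm,
    ModelFormula,
    RankDeficientDesignError,
    SeparationWarning,
    build_design,
    deviance_of,
    inverse_logit,
    inverse_logit_gradient,
    linear_predictor_comparison,
)


class TestModelFormula:
    @pytest.mark.parametrize(
        "spec, terms",
        [
            ("Method ~ Relationship * Motivation", ModelFormula.full().terms),
            ("Relationship + Motivation", ("Relationship", "Motivation")),
            ("~ 1", ()),
            ("R + M + R:M", ModelFormula.full().terms),
            ("Motivation", ("Motivation",)),
        ],
    )
    def test_parse(self, spec, terms):
        assert ModelFormula.from_string(spec).terms == terms

    def test_unknown_term(self):
        with pytest.raises(ValueError, match="unknown model term"):
            ModelFormula.of("Age")

    def test_labels(self):
        assert ModelFormula.full().labels == (
            "Intercept",
            "Relationship",
            "Motivation",
            "Relationship:Motivation",
        )
        assert ModelFormula.single_factor_mode().labels == (
            "Intercept",
            "Rel(1)-Mot(0)",
            "Rel(0)-Mot(1)",
            "Rel(1)-Mot(1)",
        )


class TestDesign:
    def test_full_design_shape_and_interaction_column(self, example_obs):
        design = build_design(example_obs, ModelFormula.full())
        assert design.X.shape == (110, 4)
        assert design.X[:, 3].sum() == 52  # rows with both rel=1 and mot=1

    def test_intercept_only(self, example_obs):
        design = build_design(example_obs, ModelFormula.intercept_only())
        assert design.X.shape == (110, 1)
        assert np.all(design.X == 1)

    def test_single_factor_spans_full_space(self, example_obs):
        d_full = build_design(example_obs, ModelFormula.full())
        d_sf = build_design(example_obs, ModelFormula.single_factor_mode())
        # identical column spans: mutual least-squares residuals are zero
        for A, B in ((d_full.X, d_sf.X), (d_sf.X, d_full.X)):
            proj = B @ np.linalg.lstsq(B, A, rcond=None)[0]
            assert np.allclose(proj, A, atol=1e-10)


class TestWorkedExampleFits:
    def test_full_model_matches_published_summary(self, full_fit):
        np.testing.assert_allclose(
            full_fit.params.to_numpy(), [-1.25, 0.27, 0.61, 0.84], atol=0.005
        )
        np.testing.assert_allclose(
            full_fit.bse.to_numpy(), [0.57, 0.88, 0.69, 1.01], atol=0.005
        )
        np.testing.assert_allclose(
            full_fit.zvalues.to_numpy(), [-2.21, 0.31, 0.89, 0.83], atol=0.005
        )
        np.testing.assert_allclose(
            full_fit.pvalues.to_numpy(), [0.03, 0.76, 0.37, 0.40], atol=0.005
        )
        assert full_fit.df_resid == 106
        assert full_fit.deviance == pytest.approx(138.62, abs=0.005)

    def test_single_factor_matches_published_summary(self, single_factor_fit):
        fit = single_factor_fit
        np.testing.assert_allclose(
            fit.params.to_numpy(), [-1.25, 0.27, 0.61, 1.72], atol=0.005
        )
        np.testing.assert_allclose(
            fit.bse.to_numpy(), [0.57, 0.88, 0.69, 0.63], atol=0.005
        )

    def test_main_effects_matches_published_summary(self, main_effects_fit):
        fit = main_effects_fit
        np.testing.assert_allclose(
            fit.params.to_numpy(), [-1.54, 0.92, 1.03, ][: len(fit.params)], atol=0.005
        )
        np.testing.assert_allclose(fit.bse.to_numpy(), [0.49, 0.42, 0.50], atol=0.005)
        assert fit.deviance == pytest.approx(139.32, abs=0.005)
        assert fit.df_resid == 107

    def test_intercept_only_closed_form(self, example_obs):
        fit = LogitGlm.from_observations(example_obs, ModelFormula.intercept_only()).fit()
        assert fit.params.iloc[0] == pytest.approx(float(logit(49 / 110)), abs=1e-8)

    def test_statsmodels_oracle_agrees(self, example_obs):
        sm = pytest.importorskip("statsmodels.api")
        for formula in (ModelFormula.full(), ModelFormula.main_effects()):
            design = build_design(example_obs, formula)
            ours = LogitGlm(design).fit()
            ref = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
            np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-6)
            np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, atol=1e-6)
            assert ours.deviance == pytest.approx(ref.deviance, abs=1e-6)


class TestFitInvariants:
    def test_saturated_fit_reproduces_cell_proportions(self, example_cells):
        fit = LogitGlm.from_cells(example_cells, ModelFormula.full()).fit()
        np.testing.assert_allclose(
            fit.cell_probabilities(), example_cells.proportions(), atol=1e-8
        )

    def test_parameterization_invariance(self, full_fit, single_factor_fit):
        np.testing.assert_allclose(
            full_fit.cell_probabilities(),
            single_factor_fit.cell_probabilities(),
            atol=1e-8,
        )
        assert full_fit.deviance == pytest.approx(single_factor_fit.deviance, abs=1e-8)
        # known linear map between the codings: level-4 effect = sum of
        # relationship, motivation and interaction coefficients
        assert single_factor_fit.params.iloc[3] == pytest.approx(
            full_fit.params.iloc[1:].sum(), abs=1e-8
        )

    def test_grouped_and_rowlevel_fits_agree(self, example_obs, example_cells):
        a = LogitGlm.from_observations(example_obs, ModelFormula.full()).fit()
        b = LogitGlm.from_cells(example_cells, ModelFormula.full()).fit()
        np.testing.assert_allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-10)
        assert a.deviance == pytest.approx(b.deviance, abs=1e-8)
        assert a.df_resid == b.df_resid

    def test_covariance_matches_finite_difference_hessian(self, example_cells):
        model = LogitGlm.from_cells(example_cells, ModelFormula.full())
        fit = model.fit()
        beta = fit.params.to_numpy()
        eps = 1e-5
        H = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                ei, ej = np.zeros(4), np.zeros(4)
                ei[i], ej[j] = eps, eps
                H[i, j] = (
                    model.loglike(beta + ei + ej)
                    - model.loglike(beta + ei - ej)
                    - model.loglike(beta - ei + ej)
                    + model.loglike(beta - ei - ej)
                ) / (4 * eps * eps)
        np.testing.assert_allclose(fit.cov_params.to_numpy(), np.linalg.inv(-H), rtol=1e-3)

    def test_rank_deficient_design_raises(self):
        # constant motivation column makes the interaction collinear
        cells = CellTable((20, 20, 0, 0), (5, 8, 0, 0))
        with pytest.raises(RankDeficientDesignError):
            LogitGlm.from_cells(cells, ModelFormula.full()).fit()

    def test_separation_warns_and_keeps_finite_deviance(self):
        frame = pd.DataFrame(
            {
                "Method": [1] * 10 + [0] * 10,
                "Relationship": [1] * 10 + [0] * 10,
                "Motivation": [0] * 20,
            }
        )
        obs = ObservationSet(frame)
        with pytest.warns(SeparationWarning):
            fit = LogitGlm.from_observations(obs, ModelFormula.of("Relationship")).fit()
        assert np.isfinite(fit.deviance)


class TestLinkFunctions:
    def test_published_values(self):
        assert inverse_logit(0.0) == pytest.approx(0.5)
        assert inverse_logit_gradient(0.0) == pytest.approx(0.25)
        assert inverse_logit(-1.25) == pytest.approx(0.22, abs=0.005)
        assert inverse_logit(0.47) == pytest.approx(0.62, abs=0.005)
        assert inverse_logit_gradient(0.47) == pytest.approx(0.24, abs=0.005)

    @given(st.floats(-700, 700))
    def test_gradient_identity_and_range(self, eta):
        p = inverse_logit(eta)
        assert 0.0 <= p <= 1.0
        assert inverse_logit_gradient(eta) == pytest.approx(p * (1 - p), abs=1e-12)

    @given(st.floats(-30, 30), st.floats(-30, 30))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert inverse_logit(lo) <= inverse_logit(hi)

    def test_stable_at_extremes(self):
        assert inverse_logit(800.0) == 1.0
        assert inverse_logit(-800.0) == 0.0


class TestLinearPredictorComparison:
    def test_published_cell_table(self, full_fit, main_effects_fit, example_cells):
        table = linear_predictor_comparison(full_fit, main_effects_fit, example_cells)
        np.testing.assert_allclose(
            table["lp"], [-1.25, -0.98, -0.64, 0.47], atol=0.005
        )
        np.testing.assert_allclose(
            table["probability"], [0.22, 0.27, 0.34, 0.62], atol=0.005
        )
        # the published gradient column is inconsistently rounded (exact
        # values 0.173, 0.198, 0.224, 0.237)
        np.testing.assert_allclose(
            table["gradient"], [0.17, 0.19, 0.22, 0.24], atol=0.011
        )
        np.testing.assert_allclose(table["n"], [18, 11, 29, 52])
        np.testing.assert_allclose(
            table["lp_reduced"], [-1.54, -0.63, -0.51, 0.40], atol=0.01
        )
        np.testing.assert_allclose(
            table["change"], [0.29, -0.35, -0.12, 0.06], atol=0.011
        )

    def test_same_fit_gives_zero_change(self, full_fit, example_cells):
        table = linear_predictor_comparison(full_fit, full_fit, example_cells)
        np.testing.assert_allclose(table["change"], 0.0, atol=1e-12)


def test_deviance_of_is_minus_twice_loglik(full_fit):
    assert deviance_of(full_fit) == pytest.approx(-2.0 * full_fit.llf, abs=1e-10)


def test_fit_serialization_round_trip(full_fit):
    import json

    payload = json.loads(full_fit.to_json())
    assert payload["df_resid"] == 106
    np.testing.assert_allclose(
        payload["coefficients"], full_fit.params.to_numpy(), atol=1e-12
    )
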