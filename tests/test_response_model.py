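"""Probit GLM fitting (vs an independent likelihood oracle) and
discrimination-vector geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from seqnum.observer_sim import ObserverParams, simulate_session, single_feature_observer
from seqnum.response_model import (
    DiscriminationVector,
    GlmFit,
    SeparationError,
    adjusted_r2,
    feature_axis,
    fit_group,
    fit_probit_glm,
    lr_test_vs_null,
    project_onto_feature,
    vector_angle,
)

SQ2 = math.sqrt(2.0)


def probit_loglik(beta, X, y):
    """Independent log-likelihood (no statsmodels)."""
    eta = X @ beta
    p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def grid_search_ml(X, y, span=6.0, points=9, refinements=14):
    """Brute-force ML: nested grid refinement over the 4 coefficients."""
    center = np.zeros(4)
    width = span
    for _ in range(refinements):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        eta = cand @ X.T
        p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        ll = (np.log(p) @ y) + (np.log1p(-p) @ (1 - y))
        center = cand[int(np.argmax(ll))]
        width *= 2.0 / (points - 1)  # keep the previous neighbors inside
    return center


@pytest.fixture(scope="module")
def twelve_trial_fixture():
    """Small deterministic session with mixed responses and interior MLE."""
    rng = np.random.default_rng(3)
    x = rng.integers(1, 7, size=(12, 3)) * rng.choice([-1, 1], size=(12, 3)) / 6.0
    eta = 1.2 * x[:, 0] - 0.4 * x[:, 1] + 0.3 * x[:, 2]
    y = (rng.random(12) < norm.cdf(eta)).astype(int)
    assert 0 < y.sum() < 12
    df = pd.DataFrame(
        {
            "subject_id": "fix",
            "response": np.where(y == 1, 2, 1),
            "log2_r_num": x[:, 0],
            "log2_r_dur": x[:, 1],
            "log2_r_tmsp": x[:, 2],
        }
    )
    return df, x, y


class TestProbitFit:
    def test_matches_grid_search_oracle(self, twelve_trial_fixture):
        df, x, y = twelve_trial_fixture
        fit = fit_probit_glm(df, min_trials=12)
        X = np.column_stack([np.ones(12), x])
        oracle = grid_search_ml(X, y.astype(float))
        got = np.array([fit.beta0, *fit.betas])
        np.testing.assert_allclose(got, oracle, atol=1e-3)

    def test_lr_chi2_matches_oracle_loglik_difference(self, twelve_trial_fixture):
        df, x, y = twelve_trial_fixture
        fit = fit_probit_glm(df, min_trials=12)
        X = np.column_stack([np.ones(12), x])
        ll_full = probit_loglik(grid_search_ml(X, y.astype(float)), X, y)
        # null model: intercept only, ML intercept = Phi^{-1}(mean)
        b0 = norm.ppf(y.mean())
        ll_null = probit_loglik(np.array([b0, 0, 0, 0]), X, y)
        chi2, dof, p = lr_test_vs_null(fit)
        assert dof == 3
        assert chi2 == pytest.approx(2 * (ll_full - ll_null), abs=1e-3)
        assert 0 <= p <= 1

    def test_one_sided_responses_raise_separation(self, subsample120):
        params = ObserverParams(beta_num=0.0, beta0=50.0)  # always "second"
        sess = simulate_session(subsample120, params, np.random.default_rng(0))
        assert (sess.test_trials["response"] == 2).all()
        with pytest.raises(SeparationError):
            fit_probit_glm(sess)

    def test_too_few_trials_rejected(self, twelve_trial_fixture):
        df, _, _ = twelve_trial_fixture
        with pytest.raises(ValueError, match="trials"):
            fit_probit_glm(df, min_trials=20)

    def test_label_swap_negates_intercept_keeps_slopes(self, subsample120):
        """Swapping first/second (regressors negated, responses recoded)
        must negate the intercept and preserve the slope estimates."""
        params = ObserverParams(beta_num=1.8, beta_dur=-0.2, beta_tmsp=0.3, beta0=0.2)
        sess = simulate_session(subsample120, params, np.random.default_rng(3))
        fit = fit_probit_glm(sess)
        swapped = sess.test_trials.copy()
        for col in ("log2_r_num", "log2_r_dur", "log2_r_tmsp"):
            swapped[col] = -swapped[col]
        swapped["response"] = 3 - swapped["response"]
        fit2 = fit_probit_glm(swapped)
        np.testing.assert_allclose(fit2.betas, fit.betas, atol=1e-6)
        assert fit2.beta0 == pytest.approx(-fit.beta0, abs=1e-6)


def _fit_like(deviance, null_deviance, n):
    return GlmFit(
        subject_id="x",
        beta0=0.0,
        beta_num=1.0,
        beta_dur=0.0,
        beta_tmsp=0.0,
        se=(0.1, 0.1, 0.1, 0.1),
        deviance=deviance,
        null_deviance=null_deviance,
        n_trials=n,
        converged=True,
    )


class TestFitQuality:
    def test_perfect_predictions_give_unit_r2(self):
        assert adjusted_r2(_fit_like(0.0, 150.0, 120)) == pytest.approx(1.0)

    def test_no_improvement_gives_small_negative_r2(self):
        # equal deviances: 1 - (n-1)/(n-p) = -(p-1)/(n-p)
        n = 120
        assert adjusted_r2(_fit_like(150.0, 150.0, n)) == pytest.approx(
            -3 / (n - 4), abs=1e-12
        )

    def test_r2_decreasing_in_residual_deviance(self):
        values = [adjusted_r2(_fit_like(d, 160.0, 120)) for d in (10, 40, 80, 159)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_r2_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="undefined"):
            adjusted_r2(_fit_like(1.0, 2.0, 4))

    def test_null_fit_has_zero_chi2_p_one(self):
        chi2, dof, p = lr_test_vs_null(_fit_like(150.0, 150.0, 120))
        assert chi2 == 0 and dof == 3 and p == pytest.approx(1.0)


class TestGeometry:
    @pytest.mark.parametrize(
        "vec,angle",
        [
            ((2.5, 0.0, 0.0), 0.0),
            ((1.0, 1.0, 0.0), 45.0),
            ((1.0, 1.0, 1.0), 54.7356103),
        ],
    )
    def test_angles_from_numerosity_axis(self, vec, angle):
        assert vector_angle(vec) == pytest.approx(angle, abs=1e-6)

    def test_zero_vector_angle_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            vector_angle((0.0, 0.0, 0.0))

    def test_feature_axes_are_unit_normalized_half_weights(self):
        np.testing.assert_allclose(feature_axis("numerosity"), [1, 0, 0])
        np.testing.assert_allclose(feature_axis("ted"), [1 / SQ2, 1 / SQ2, 0])
        np.testing.assert_allclose(feature_axis("mep"), [-1 / SQ2, 0, 1 / SQ2])
        with pytest.raises(ValueError, match="unknown feature"):
            feature_axis("density")

    def test_projections(self):
        assert project_onto_feature((1.0, 1.0, 0.0), "ted") == pytest.approx(SQ2)
        assert project_onto_feature((1.0, 0.0, 0.0), "numerosity") == 1.0
        # group-mean coefficient vector onto the TSD line
        assert project_onto_feature((1.89, -0.16, 0.24), "tsd") == pytest.approx(
            (1.89 + 0.24) / SQ2, abs=1e-10
        )

    def test_discrimination_vector_bundle(self):
        dv = DiscriminationVector(1.0, 1.0, 0.0)
        assert dv.norm == pytest.approx(SQ2)
        assert dv.angle_deg == pytest.approx(45.0)
        assert dv.projections["ted"] == pytest.approx(SQ2)


class TestObserverRecovery:
    def test_single_feature_observer_angles(self):
        for feature, angle in (("numerosity", 0.0), ("ted", 45.0), ("med", 135.0)):
            v = single_feature_observer(feature, 2.0).betas
            assert vector_angle(v) == pytest.approx(angle)

    def test_pure_ted_cohort_shows_diagnostic_signature(self, dataset500, subsample120):
        """A total-event-duration reader yields beta_num ≈ beta_dur and a TED
        projection exceeding beta_num (c*sqrt(2) > c)."""
        params = single_feature_observer("ted", 2.0)
        fits = []
        for i in range(25):
            rng = np.random.default_rng(400 + i)
            fits.append(fit_probit_glm(simulate_session(subsample120, params, rng)))
        bn = np.mean([f.beta_num for f in fits])
        bd = np.mean([f.beta_dur for f in fits])
        proj = np.mean([project_onto_feature(f.betas, "ted") for f in fits])
        assert bn == pytest.approx(bd, abs=0.12)
        assert proj > bn

    def test_fit_group_flags_failures_instead_of_dropping(self, subsample120):
        good = simulate_session(
            subsample120, ObserverParams(beta_num=1.8), np.random.default_rng(1), "ok"
        )
        bad = simulate_session(
            subsample120,
            ObserverParams(beta_num=0.0, beta0=50.0),
            np.random.default_rng(2),
            "sep",
        )
        df = fit_group([good, bad])
        assert df.set_index("subject_id").loc["ok", "fit_ok"]
        assert not df.set_index("subject_id").loc["sep", "fit_ok"]
        assert len(df) == 2
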