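"""Group-level tests, JZS Bayes factors, and Monte Carlo power."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqnum.group_stats import (
    estimate_power,
    jzs_bayes_factor,
    modality_contrast,
    one_sample_test,
    paired_projection_tests,
)
from seqnum.observer_sim import FEATURE_DIRECTIONS
from seqnum.response_model import project_onto_feature

FIXTURE_10 = [0.42, -0.11, 0.35, 0.18, 0.77, -0.05, 0.29, 0.51, 0.08, 0.23]


class TestOneSampleTest:
    def test_matches_textbook_t_formula(self):
        x = np.array(FIXTURE_10)
        res = one_sample_test(x, 0.0)
        t_manual = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(x) - 1)
        assert res.method == "t"
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.p == pytest.approx(p_manual, abs=1e-10)
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-12)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_test([0.3] * 10, 0.3)

    def test_nonnormal_data_routes_to_wilcoxon(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 1.5, 40))  # heavily skewed
        res = one_sample_test(x, 0.0)
        assert res.method == "wilcoxon"
        assert res.effect_label == "rank_biserial"
        assert res.effect_size == pytest.approx(1.0)  # all values positive

    def test_bayes_flag_attaches_bf10(self):
        res = one_sample_test(FIXTURE_10, 0.0, bayes=True)
        assert res.bf10 is not None and res.bf10 > 0


class TestProjectionContrasts:
    @staticmethod
    def _fits_from_betas(betas: np.ndarray) -> pd.DataFrame:
        rows = []
        for b in betas:
            row = {"fit_ok": True, "beta_num": b[0], "beta_dur": b[1],
                   "beta_tmsp": b[2]}
            for f in FEATURE_DIRECTIONS:
                row[f"proj_{f}"] = project_onto_feature(b, f)
            rows.append(row)
        return pd.DataFrame(rows)

    def test_pure_numerosity_group_always_closest_to_numerosity(self):
        rng = np.random.default_rng(1)
        betas = np.column_stack(
            [2.0 + 0.3 * rng.standard_normal(40), np.zeros(40), np.zeros(40)]
        )
        results = paired_projection_tests(self._fits_from_betas(betas))
        assert set(results) == {"ted", "med", "tsd", "mep", "cov"}
        for res in results.values():
            diffs_positive = res.statistic > 0 if res.method == "t" else res.effect_size > 0
            assert diffs_positive
            assert res.p_corrected < 0.01

    def test_pure_ted_group_is_closer_to_ted_line(self):
        rng = np.random.default_rng(2)
        c = 1.0 + 0.1 * rng.standard_normal(30)
        betas = np.column_stack([c, c, np.zeros(30)])  # TED readers
        results = paired_projection_tests(self._fits_from_betas(betas))
        # beta_num - proj_ted = c - c*sqrt(2) < 0
        assert results["ted"].effect_size < 0

    def test_bonferroni_factor_of_five(self):
        res = one_sample_test(FIXTURE_10, 0.0, correction_k=5)
        assert res.p_corrected == pytest.approx(min(1.0, 5 * res.p))
        assert res.p_corrected >= res.p


class TestModalityContrast:
    def test_matches_pooled_t_formula(self):
        a = np.array(FIXTURE_10)
        b = np.array(FIXTURE_10) + 0.3
        res = modality_contrast(a, b)
        n1 = n2 = len(a)
        sp = math.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
        t_manual = (a.mean() - b.mean()) / (sp * math.sqrt(1 / n1 + 1 / n2))
        assert res.method == "t"
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.effect_size == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-10)

    def test_identical_groups_near_null(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.9, 0.5, 40)
        res = modality_contrast(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_shifted_groups_detected_at_noncentral_t_rate(self):
        """d = 1 with n = 40/40 rejects at the rate the noncentral-t
        closed form predicts (~0.99); checked at moderate reps."""
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 300
        for _ in range(reps):
            a = rng.standard_normal(40)
            b = rng.standard_normal(40) + 1.0
            rejections += modality_contrast(a, b).p < 0.05
        ncp = 1.0 * math.sqrt(40 * 40 / 80)
        tcrit = stats.t.ppf(0.975, 78)
        power = stats.nct.sf(tcrit, 78, ncp) + stats.nct.cdf(-tcrit, 78, ncp)
        assert rejections / reps == pytest.approx(power, abs=0.05)


class TestJZSBayesFactor:
    def test_null_centered_t_supports_null(self):
        assert jzs_bayes_factor(0.0, n=50) < 1.0

    def test_monotone_in_t_magnitude(self):
        values = [jzs_bayes_factor(t, n=30) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_matches_fine_grid_quadrature(self):
        """Brute-force integration on a dense transformed grid."""
        for t, n in ((2.5, 30), (1.2, 12), (4.0, 80)):
            nu, big_n, r2 = n - 1, n, 0.707 ** 2
            # substitute g = u/(1-u) to integrate over (0, 1)
            u = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
            g = u / (1 - u)
            jac = 1 / (1 - u) ** 2
            c = 1 + big_n * g * r2
            integrand = (
                c ** -0.5
                * (1 + t * t / (c * nu)) ** (-(nu + 1) / 2)
                * (2 * np.pi) ** -0.5
                * g ** -1.5
                * np.exp(-1 / (2 * g))
            ) * jac
            brute = np.trapezoid(integrand, u) / (1 + t * t / nu) ** (-(nu + 1) / 2)
            assert jzs_bayes_factor(t, n=n) == pytest.approx(brute, rel=1e-6)

    def test_agrees_with_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((2.0, 25), (3.5, 40)):
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bayes_factor(t, n=n) == pytest.approx(ref, rel=1e-4)

    def test_two_sample_effective_n(self):
        one = jzs_bayes_factor(2.0, n=20)
        two = jzs_bayes_factor(2.0, n1=20, n2=20)
        assert one != two  # different effective N and df


class TestEstimatePower:
    def test_zero_effect_calibrates_to_alpha(self):
        df = estimate_power(0.0, 1.0, [20], reps=2000, seed=5)
        row = df.iloc[0]
        assert row["ci_low"] <= 0.05 <= row["ci_high"]

    def test_matches_noncentral_t_closed_form(self):
        # one-sample t, d = 0.6, n = 20 -> ~0.71
        df = estimate_power(0.6, 1.0, [20], reps=3000, seed=6)
        ncp = 0.6 * math.sqrt(20)
        tcrit = stats.t.ppf(0.975, 19)
        closed = stats.nct.sf(tcrit, 19, ncp) + stats.nct.cdf(-tcrit, 19, ncp)
        assert closed == pytest.approx(0.721, abs=0.005)
        row = df.iloc[0]
        assert row["ci_low"] - 0.02 <= closed <= row["ci_high"] + 0.02

    def test_power_nondecreasing_in_n(self):
        df = estimate_power(0.5, 1.0, [10, 20, 40, 80], reps=800, seed=7)
        p = df["power"].to_numpy()
        # allow Monte Carlo wiggle inside the CI width
        assert all(p[i + 1] >= p[i] - 0.05 for i in range(len(p) - 1))

    def test_rep_floor_enforced(self):
        with pytest.raises(ValueError, match="reps"):
            estimate_power(0.5, 1.0, [10], reps=10)

    def test_pipeline_method_requires_stimulus_set(self):
        with pytest.raises(ValueError, match="full_set"):
            estimate_power([1.9, 0, 0], [0.5, 0.3, 0.4], [10], method="pipeline")
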