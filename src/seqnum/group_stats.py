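"""Group-level inference and Monte Carlo power analysis.

Coefficients and projections estimated per participant are tested at the
group level with one-sample / paired / two-sample tests.  Each test is
gated by a Shapiro–Wilk normality check at alpha = .05: the parametric
branch (Student t, Cohen's d) is used when normality is not rejected, the
nonparametric branch (Wilcoxon signed-rank or Mann–Whitney U, rank-biserial
correlation) otherwise.  Bonferroni correction handles the five projection
contrasts.  Bayes factors for t-tests use the Jeffreys–Zellner–Siow default
Cauchy prior (scale 0.707) evaluated by adaptive quadrature.

The power engine estimates rejection rates over replicate simulated
cohorts, either by drawing per-subject coefficients directly from the
population normal ("draws") or by running the full chain
simulate_group -> probit GLM -> group test ("pipeline").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .dataset_builder import StimulusSet
from .observer_sim import simulate_group
from .response_model import fit_group

__all__ = [
    "TestResult",
    "one_sample_test",
    "paired_projection_tests",
    "modality_contrast",
    "jzs_bayes_factor",
    "estimate_power",
    "PROJECTION_FEATURES",
]

#: Features contrasted against the numerosity coefficient (5 comparisons).
PROJECTION_FEATURES = ("ted", "med", "tsd", "mep", "cov")

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one group-level test."""

    name: str
    method: str  # "t", "wilcoxon", or "mannwhitney"
    statistic: float
    df: float | None
    n: int
    p: float
    p_corrected: float
    effect_size: float
    effect_label: str  # "cohen_d" or "rank_biserial"
    correction: str = "none"
    bf10: float | None = None
    normality_p: float | None = None


def _rank_biserial_signed(diffs: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation (W+ − W−)/(W+ + W−)."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def one_sample_test(
    values: Sequence[float],
    mu: float = 0.0,
    name: str = "one_sample",
    correction_k: int = 1,
    bayes: bool = False,
    prior_scale: float = 0.707,
) -> TestResult:
    """One-sample test of ``values`` against ``mu``.

    Shapiro–Wilk at alpha = .05 selects Student's t (effect size Cohen's
    d = mean/SD of the centered values) or the Wilcoxon signed-rank test
    (matched-pairs rank-biserial correlation).  ``correction_k`` applies a
    Bonferroni factor to p.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 values, got {n}")
    centered = x - mu
    if np.allclose(centered, centered[0]):
        raise ValueError("degenerate data: zero variance")
    sw_p = float(stats.shapiro(x).pvalue)
    if sw_p >= NORMALITY_ALPHA:
        res = stats.ttest_1samp(x, mu)
        stat, p = float(res.statistic), float(res.pvalue)
        effect = float(centered.mean() / centered.std(ddof=1))
        method, label, df = "t", "cohen_d", float(n - 1)
        bf = jzs_bayes_factor(stat, n=n, prior_scale=prior_scale) if bayes else None
    else:
        res = stats.wilcoxon(centered)
        stat, p = float(res.statistic), float(res.pvalue)
        effect = _rank_biserial_signed(centered)
        method, label, df = "wilcoxon", "rank_biserial", None
        bf = None
    return TestResult(
        name=name,
        method=method,
        statistic=stat,
        df=df,
        n=n,
        p=p,
        p_corrected=min(1.0, correction_k * p),
        effect_size=effect,
        effect_label=label,
        correction=f"bonferroni_{correction_k}" if correction_k > 1 else "none",
        bf10=bf,
        normality_p=sw_p,
    )


def paired_projection_tests(fits: pd.DataFrame) -> Dict[str, TestResult]:
    """Contrast beta_num against each feature projection across subjects.

    For every feature line (TED, MED, TSD, MEP, coverage), the per-subject
    difference beta_num − projection is tested against zero with the gated
    paired test; the five p values are Bonferroni-corrected (×5).  Positive
    differences indicate discrimination vectors closer to the numerosity
    axis than to that feature.
    """
    if "fit_ok" in fits.columns:
        fits = fits[fits["fit_ok"]]
    if len(fits) < 3:
        raise ValueError("need >= 3 fitted subjects")
    out = {}
    k = len(PROJECTION_FEATURES)
    for feature in PROJECTION_FEATURES:
        diffs = fits["beta_num"].to_numpy() - fits[f"proj_{feature}"].to_numpy()
        out[feature] = one_sample_test(
            diffs, 0.0, name=f"beta_num_vs_proj_{feature}", correction_k=k
        )
    return out


def _rank_biserial_two_sample(u_stat: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation from a Mann–Whitney U (group-1 wins)."""
    return float(1.0 - 2.0 * u_stat / (n1 * n2))


def modality_contrast(
    group_a: Sequence[float],
    group_b: Sequence[float],
    name: str = "modality_contrast",
    bayes: bool = False,
    prior_scale: float = 0.707,
) -> TestResult:
    """Two-sample contrast (e.g. visual vs auditory coefficients).

    Pooled-variance Student t with Cohen's d when both samples pass the
    normality gate; Mann–Whitney U with rank-biserial correlation
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 3:
        raise ValueError("both groups need >= 3 values")
    sw_a = float(stats.shapiro(a).pvalue)
    sw_b = float(stats.shapiro(b).pvalue)
    sw_p = min(sw_a, sw_b)
    if sw_p >= NORMALITY_ALPHA:
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        sp = math.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        )
        effect = float((a.mean() - b.mean()) / sp)
        method, label, df = "t", "cohen_d", float(n1 + n2 - 2)
        bf = (
            jzs_bayes_factor(stat, n1=n1, n2=n2, prior_scale=prior_scale)
            if bayes
            else None
        )
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        effect = _rank_biserial_two_sample(stat, n1, n2)
        method, label, df = "mannwhitney", "rank_biserial", None
        bf = None
    return TestResult(
        name=name,
        method=method,
        statistic=stat,
        df=df,
        n=n1 + n2,
        p=p,
        p_corrected=p,
        effect_size=effect,
        effect_label=label,
        bf10=bf,
        normality_p=sw_p,
    )


def jzs_bayes_factor(
    t: float,
    n: int | None = None,
    n1: int | None = None,
    n2: int | None = None,
    prior_scale: float = 0.707,
) -> float:
    """JZS Bayes factor BF10 for a t statistic (default Cauchy prior).

    Integrates the Zellner–Siow mixture over the prior on the variance
    ratio g (inverse-gamma(1/2, 1/2)), with effective sample size N = n for
    one-sample/paired designs or n1*n2/(n1+n2) for two-sample designs.
    BF10 > 1 favors a nonzero effect.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n is not None:
        if n < 2:
            raise ValueError("need n >= 2")
        big_n, nu = float(n), float(n - 1)
    elif n1 is not None and n2 is not None:
        if min(n1, n2) < 2:
            raise ValueError("need n1, n2 >= 2")
        big_n, nu = n1 * n2 / (n1 + n2), float(n1 + n2 - 2)
    else:
        raise ValueError("pass n (one-sample) or n1 and n2 (two-sample)")
    r2 = prior_scale * prior_scale

    def integrand(g: float) -> float:
        c = 1.0 + big_n * g * r2
        return (
            c ** -0.5
            * (1.0 + t * t / (c * nu)) ** (-(nu + 1.0) / 2.0)
            * (2.0 * math.pi) ** -0.5
            * g ** -1.5
            * math.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not math.isfinite(num) or (num > 0 and err / num > 1e-6):
        raise RuntimeError(f"JZS quadrature did not converge (err={err:g})")
    denom = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
    return num / denom


def _wilson_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def estimate_power(
    pop_mean,
    pop_sd,
    n_grid: Sequence[int],
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "draws",
    coefficient: str = "beta_tmsp",
    full_set: StimulusSet | None = None,
    m_trials: int = 120,
    gate_normality: bool = False,
) -> pd.DataFrame:
    """Monte Carlo power of the group one-sample test across sample sizes.

    Parameters
    ----------
    pop_mean, pop_sd
        Population mean and SD.  For ``method="draws"`` scalars for the
        tested coefficient; for ``method="pipeline"`` length-3 vectors
        (num, dur, tmsp) fed to :func:`~seqnum.observer_sim.simulate_group`.
    n_grid
        Cohort sizes to evaluate.
    method
        ``"draws"`` samples per-subject coefficients directly from the
        population normal (comparable to the noncentral-t closed form);
        ``"pipeline"`` runs the full simulate → fit → test chain and
        requires ``full_set``.
    gate_normality
        If True, use the Shapiro-gated test instead of the plain t-test.

    Returns a frame with columns n, power, ci_low, ci_high, reps.
    """
    if reps < 100:
        raise ValueError("need reps >= 100 for a stable estimate")
    if method not in ("draws", "pipeline"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pipeline" and full_set is None:
        raise ValueError("pipeline method requires full_set")
    coef_idx = {"beta_num": 0, "beta_dur": 1, "beta_tmsp": 2}[coefficient]
    rows = []
    master = np.random.SeedSequence(seed)
    for n_subj, child in zip(n_grid, master.spawn(len(n_grid))):
        rejections = 0
        if method == "draws":
            mu = (
                float(pop_mean)
                if np.ndim(pop_mean) == 0
                else float(np.asarray(pop_mean)[coef_idx])
            )
            sd = (
                float(pop_sd)
                if np.ndim(pop_sd) == 0
                else float(np.asarray(pop_sd)[coef_idx])
            )
            rng = np.random.default_rng(child)
            for _ in range(reps):
                x = mu + sd * rng.standard_normal(n_subj)
                p = _group_p(x, gate_normality)
                rejections += p < alpha
        else:
            for rep_child in child.spawn(reps):
                sessions = simulate_group(
                    list(pop_mean),
                    list(pop_sd),
                    n_subj,
                    full_set,
                    seed=rep_child,
                    m_trials=m_trials,
                )
                fits = fit_group(sessions)
                x = fits.loc[fits["fit_ok"], coefficient].to_numpy()
                p = _group_p(x, gate_normality)
                rejections += p < alpha
        lo, hi = _wilson_ci(rejections, reps)
        rows.append(
            {
                "n": n_subj,
                "power": rejections / reps,
                "ci_low": lo,
                "ci_high": hi,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def _group_p(x: np.ndarray, gate_normality: bool) -> float:
    if gate_normality:
        return one_sample_test(x, 0.0).p
    return float(stats.ttest_1samp(x, 0.0).pvalue)
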