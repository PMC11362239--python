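"""Per-participant probit GLM and discrimination-vector geometry.

Trial-level responses (1 = chose first, 2 = chose second) are modeled with
a binomial GLM with probit link on the second/first log2 ratios of
numerosity, duration and temporal spacing.  The three slope estimates form
a *discrimination vector* in cardinal coefficient space: its norm tracks
overall acuity, its angle from the numerosity axis quantifies non-numerical
bias, and its scalar projections onto the feature lines (TED, MED, TSD,
MEP, coverage — the half-weight directions of the log-linear feature
algebra, normalized to unit length) identify which single feature a
participant's strategy most resembles.

Model quality is summarized by a deviance-based adjusted pseudo-R² and a
likelihood-ratio test against the constant-only model (3 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist

from .observer_sim import FEATURE_DIRECTIONS, SessionData

__all__ = [
    "GlmFit",
    "DiscriminationVector",
    "SeparationError",
    "REGRESSORS",
    "fit_probit_glm",
    "adjusted_r2",
    "lr_test_vs_null",
    "vector_angle",
    "feature_axis",
    "project_onto_feature",
    "discrimination_vector",
    "fit_group",
]

REGRESSORS = ["log2_r_num", "log2_r_dur", "log2_r_tmsp"]

#: Parameters of the full model: intercept + three slopes.
N_PARAMS = 4


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: ML estimates are unusable."""


@dataclass(frozen=True)
class GlmFit:
    """Probit GLM fit for one participant."""

    subject_id: str
    beta0: float
    beta_num: float
    beta_dur: float
    beta_tmsp: float
    se: Tuple[float, float, float, float]
    deviance: float
    null_deviance: float
    n_trials: int
    converged: bool

    @property
    def betas(self) -> Tuple[float, float, float]:
        return (self.beta_num, self.beta_dur, self.beta_tmsp)

    @property
    def r2_adj(self) -> float:
        return adjusted_r2(self)

    @property
    def lr_chi2(self) -> float:
        return self.null_deviance - self.deviance

    @property
    def lr_p(self) -> float:
        return lr_test_vs_null(self)[2]


def fit_probit_glm(
    session: SessionData | pd.DataFrame,
    min_trials: int = 20,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> GlmFit:
    """Maximum-likelihood probit fit of one session's test trials.

    Uses iteratively reweighted least squares with convergence tolerance
    ``tol`` on the deviance; standard errors come from the observed
    information matrix.

    Raises
    ------
    SeparationError
        If the responses are one-sided or the likelihood is unbounded
        (perfect separation).
    RuntimeError
        If IRLS fails to converge within ``maxiter`` iterations.
    """
    if isinstance(session, SessionData):
        df = session.test_trials
        subject_id = session.subject_id
    else:
        df = session
        subject_id = str(df["subject_id"].iloc[0]) if "subject_id" in df else ""
    if len(df) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(df)}")
    y = (df["response"].to_numpy() == 2).astype(float)
    if y.min() == y.max():
        raise SeparationError("all responses identical: probit MLE does not exist")
    X = sm.add_constant(df[REGRESSORS].to_numpy(), has_constant="add")

    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        res = model.fit(tol=tol, maxiter=maxiter)
    except Exception as e:  # statsmodels raises PerfectSeparationError here
        if "separation" in str(e).lower() or "Perfect" in type(e).__name__:
            raise SeparationError(str(e)) from e
        raise
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations (subject {subject_id})"
        )
    if np.max(np.abs(res.params)) > 50:
        raise SeparationError(
            "estimates diverged (|beta| > 50): quasi-perfect separation"
        )
    return GlmFit(
        subject_id=subject_id,
        beta0=float(res.params[0]),
        beta_num=float(res.params[1]),
        beta_dur=float(res.params[2]),
        beta_tmsp=float(res.params[3]),
        se=tuple(float(s) for s in res.bse),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        n_trials=int(len(df)),
        converged=bool(res.converged),
    )


def adjusted_r2(fit: GlmFit, n_params: int = N_PARAMS) -> float:
    """Deviance-based adjusted pseudo-R²:
    ``1 - (D_res/(n-p)) / (D_null/(n-1))`` with p = 4 parameters.
    """
    n = fit.n_trials
    if n <= n_params:
        raise ValueError(f"adjusted R² undefined for n={n} <= p={n_params}")
    return 1.0 - (fit.deviance / (n - n_params)) / (fit.null_deviance / (n - 1))


def lr_test_vs_null(fit: GlmFit) -> Tuple[float, int, float]:
    """Likelihood-ratio test of the full model against the constant model.

    Returns (chi2, df, p); chi2 is the deviance drop, df = 3 slopes.
    """
    chi2 = fit.null_deviance - fit.deviance
    df = N_PARAMS - 1
    return chi2, df, float(chi2_dist.sf(chi2, df))


# ---------------------------------------------------------------------------
# discrimination-vector geometry

def feature_axis(feature: str) -> np.ndarray:
    """Unit direction of a feature line in (num, dur, tmsp) coefficient space.

    Normalized from the half-weight feature directions, e.g. TED ->
    (1, 1, 0)/sqrt(2); numerosity is the first cardinal axis (1, 0, 0).
    """
    if feature not in FEATURE_DIRECTIONS:
        raise ValueError(
            f"unknown feature {feature!r}; expected one of {sorted(FEATURE_DIRECTIONS)}"
        )
    d = np.asarray(FEATURE_DIRECTIONS[feature], dtype=float)
    return d / np.linalg.norm(d)


def vector_angle(v: Sequence[float]) -> float:
    """Angle (degrees, in [0, 180]) between a coefficient vector and the
    numerosity axis: arccos(beta_num / ||beta||)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("angle undefined for the zero vector")
    return math.degrees(math.acos(np.clip(v[0] / norm, -1.0, 1.0)))


def project_onto_feature(v: Sequence[float], feature: str) -> float:
    """Scalar projection of a coefficient vector onto a feature line."""
    return float(np.dot(np.asarray(v, dtype=float), feature_axis(feature)))


@dataclass(frozen=True)
class DiscriminationVector:
    """Fitted slopes viewed as a direction in cardinal coefficient space."""

    beta_num: float
    beta_dur: float
    beta_tmsp: float

    @property
    def vec(self) -> np.ndarray:
        return np.array([self.beta_num, self.beta_dur, self.beta_tmsp])

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vec))

    @property
    def angle_deg(self) -> float:
        return vector_angle(self.vec)

    @property
    def projections(self) -> Dict[str, float]:
        return {f: project_onto_feature(self.vec, f) for f in FEATURE_DIRECTIONS}


def discrimination_vector(fit: GlmFit) -> DiscriminationVector:
    return DiscriminationVector(*fit.betas)


def fit_group(sessions: Sequence[SessionData], min_trials: int = 20) -> pd.DataFrame:
    """Fit every session; one row per subject with coefficients, SEs, fit
    quality, angle and the six feature projections.

    Sessions whose fit fails (separation / non-convergence) get NaN
    estimates and ``fit_ok = False`` rather than being dropped silently.
    """
    rows = []
    for s in sessions:
        base = {"subject_id": s.subject_id, "modality": s.modality}
        try:
            fit = fit_probit_glm(s, min_trials=min_trials)
        except (SeparationError, RuntimeError, ValueError) as e:
            rows.append({**base, "fit_ok": False, "fit_error": str(e)})
            continue
        dv = discrimination_vector(fit)
        chi2, dof, p = lr_test_vs_null(fit)
        rows.append(
            {
                **base,
                "fit_ok": True,
                "fit_error": "",
                "beta0": fit.beta0,
                "beta_num": fit.beta_num,
                "beta_dur": fit.beta_dur,
                "beta_tmsp": fit.beta_tmsp,
                "se_beta0": fit.se[0],
                "se_beta_num": fit.se[1],
                "se_beta_dur": fit.se[2],
                "se_beta_tmsp": fit.se[3],
                "deviance": fit.deviance,
                "null_deviance": fit.null_deviance,
                "n_trials": fit.n_trials,
                "r2_adj": fit.r2_adj,
                "lr_chi2": chi2,
                "lr_df": dof,
                "lr_p": p,
                "angle_deg": dv.angle_deg,
                **{f"proj_{k}": v for k, v in dv.projections.items()},
            }
        )
    return pd.DataFrame(rows)
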