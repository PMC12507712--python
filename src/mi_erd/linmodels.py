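"""Linear (LR) and random-intercept mixed-effects (LME) embodiment models.

Both relate a per-observation embodiment score to an EEG outcome (window ERD
per hand, in %, or LI in %), one observation per subject x condition:

    LR:   outcome = b0 + b1 * embodiment + e
    LME:  outcome = b0 + b1 * embodiment + u_subject + e,  u ~ N(0, sd_b^2)

The LME is fitted by maximum likelihood (not REML) so AIC/BIC are comparable
with the LR fit. The headline R^2 for the LME is the conditional R^2
(fixed + random variance share, Nakagawa-style); the marginal R^2 is also
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ModelFit", "fit_linear", "fit_mixed"]


@dataclass
class ModelFit:
    """Estimates and diagnostics for one LR or LME fit."""

    kind: str  # "LR" | "LME"
    beta0: float
    beta1: float
    se: tuple
    t: tuple
    p: tuple
    aic: float
    bic: float
    r2: float
    r2_marginal: float = None
    random_intercept_sd: float = None
    random_intercept_sd_se: float = None
    n_obs: int = 0
    n_subjects: int = None
    converged: bool = True

    def summary_rows(self, outcome: str = "") -> list[dict]:
        """Two table rows (intercept, embodiment slope), Table-3 layout."""
        rows = []
        for name, est, se, t, p in zip(
            ("beta0", "embodiment"), (self.beta0, self.beta1), self.se, self.t, self.p
        ):
            rows.append({
                "outcome": outcome, "model": self.kind, "variable": name,
                "estimate": est, "se": se, "t": t, "p_value": p,
                "aic": self.aic, "bic": self.bic, "r2": self.r2,
            })
        return rows


def _check_inputs(embodiment, outcome):
    x = np.asarray(embodiment, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise ValueError("embodiment and outcome must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: model is rank deficient")
    return x, y


def fit_linear(embodiment, outcome) -> ModelFit:
    """Ordinary least squares of outcome on embodiment score."""
    x, y = _check_inputs(embodiment, outcome)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        kind="LR",
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        se=tuple(res.bse), t=tuple(res.tvalues), p=tuple(res.pvalues),
        aic=float(res.aic), bic=float(res.bic), r2=float(res.rsquared),
        n_obs=int(res.nobs),
    )


def fit_mixed(embodiment, outcome, subject) -> ModelFit:
    """Random-intercept-per-subject mixed model, fitted by ML.

    Falls back to the OLS solution with zero random variance when every
    subject contributes a single observation (the between/within variance
    split is unidentified there) or when the optimizer lands on the boundary.
    """
    x, y = _check_inputs(embodiment, outcome)
    groups = np.asarray(subject)
    if groups.size != x.size:
        raise ValueError("one subject label per observation required")
    n_subjects = np.unique(groups).size
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    sizes = pd.Series(groups).value_counts()
    if (sizes == 1).all():
        warnings.warn("all subjects have a single observation; "
                      "random variance fixed at 0 (OLS-equivalent fit)")
        ols = fit_linear(x, y)
        return ModelFit(
            kind="LME", beta0=ols.beta0, beta1=ols.beta1, se=ols.se, t=ols.t,
            p=ols.p, aic=ols.aic, bic=ols.bic, r2=ols.r2, r2_marginal=ols.r2,
            random_intercept_sd=0.0, n_obs=ols.n_obs, n_subjects=n_subjects,
        )

    X = sm.add_constant(x)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if res is None:
            raise np.linalg.LinAlgError("mixed-model likelihood optimization failed")
    converged = bool(res.converged)

    beta = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    tvals = beta / se
    pvals = np.asarray(res.pvalues, dtype=float)[:2]

    var_b = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    if var_b < 0 or not np.isfinite(var_b):
        var_b = 0.0
    # delta-method SE of the random-intercept SD (residual scale held fixed)
    sd_b = np.sqrt(var_b)
    se_var = float(np.asarray(res.bse)[-1]) * var_e
    sd_b_se = se_var / (2.0 * sd_b) if sd_b > 0 and np.isfinite(se_var) else np.nan

    # ML likelihood-based information criteria, comparable with OLS:
    # k = 2 fixed effects + random-intercept variance + residual variance.
    k = 4
    llf = float(res.llf)
    n = x.size
    aic = -2 * llf + 2 * k
    bic = -2 * llf + k * np.log(n)

    fitted_fixed = X @ beta
    var_f = float(np.var(fitted_fixed))
    denom = var_f + var_b + var_e
    r2_marginal = var_f / denom
    r2_conditional = (var_f + var_b) / denom

    return ModelFit(
        kind="LME",
        beta0=float(beta[0]), beta1=float(beta[1]),
        se=(float(se[0]), float(se[1])),
        t=(float(tvals[0]), float(tvals[1])),
        p=(float(pvals[0]), float(pvals[1])),
        aic=aic, bic=bic,
        r2=r2_conditional, r2_marginal=r2_marginal,
        random_intercept_sd=float(sd_b),
        random_intercept_sd_se=float(sd_b_se),
        n_obs=n, n_subjects=n_subjects, converged=converged,
    )
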