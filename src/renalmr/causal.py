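"""One-sample instrumental-variable models.

Two-stage least squares (2SLS) with a genetic score instrument,
multivariable MR (MVMR) giving each exposure's direct effect conditional
on the others, and the mediation decomposition: total effect from
univariable 2SLS, direct effect from MVMR including the mediator(s),
indirect = total - direct, proportion mediated = indirect / total, with a
seeded nonparametric bootstrap over individuals for uncertainty.

Binary outcomes are handled by predictor substitution (logistic second
stage on the stage-1 fitted exposure), so effects and the mediation
arithmetic live on the log-odds scale; log-odds effects are
non-collapsible, which the results flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TSLSResult", "MediationResult", "tsls", "mvmr_tsls",
           "mediation_decompose"]

WEAK_INSTRUMENT_F = 10.0


@dataclass
class TSLSResult:
    beta: float                      # log-odds for binary outcomes
    se: float
    p: float
    first_stage: dict                # {"F": ..., "partial_r2": ...}
    outcome_type: str
    weak_instrument: bool
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.outcome_type == "binary" else None


@dataclass
class MediationResult:
    total: float
    direct: float
    indirect: float
    proportion: float | None
    proportion_defined: bool
    bootstrap: dict
    outcome_scale: str
    notes: list = field(default_factory=list)


def _design(cohort, covariate_names: Sequence[str]) -> np.ndarray:
    n = cohort.n
    return np.column_stack(
        [np.ones(n)] + [cohort.covariates[c].to_numpy() for c in covariate_names])


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _first_stage(x: np.ndarray, Z: np.ndarray, C: np.ndarray):
    """Stage-1 fit plus instrument F statistic and partial R^2."""
    full = np.column_stack([Z, C])
    coef = _ols(full, x)
    fitted = full @ coef
    rss1 = float(np.sum((x - fitted) ** 2))
    coef0 = _ols(C, x)
    rss0 = float(np.sum((x - C @ coef0) ** 2))
    k = Z.shape[1]
    df2 = len(x) - full.shape[1]
    if rss0 <= 0 or rss1 < 0 or df2 <= 0:
        raise ValueError("degenerate first stage")
    partial_r2 = max(0.0, (rss0 - rss1) / rss0)
    F = ((rss0 - rss1) / k) / (rss1 / df2) if rss1 > 0 else np.inf
    return fitted, float(F), float(partial_r2)


def _tsls_continuous(y, X_endog, Z, C):
    """2SLS point estimates with conventional IV standard errors.

    X = [endogenous regressors, covariates], instruments [Z, covariates];
    sigma^2 from residuals at the *observed* (not fitted) regressors.
    """
    X = np.column_stack([X_endog, C])
    W = np.column_stack([Z, C])
    Xh = W @ np.linalg.lstsq(W, X, rcond=None)[0]   # projection onto span(W)
    XtX = Xh.T @ X
    beta = np.linalg.solve(XtX, Xh.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xh.T @ Xh)
    se = np.sqrt(np.diag(cov))
    return beta, se, dof


def tsls(cohort, exposure: str, outcome: str, instrument: np.ndarray,
         covariate_names: Sequence[str] = (), n_boot: int = 200,
         seed: int = 0) -> TSLSResult:
    """One-sample MR by two-stage least squares with a genetic score.

    Continuous outcomes: standard 2SLS with IV-consistent standard errors.
    Binary outcomes: logistic regression of the outcome on the stage-1
    fitted exposure (predictor substitution) with a seeded nonparametric
    bootstrap SE.  A first-stage F below 10 raises a weak-instrument flag
    on the result, not an error.
    """
    import statsmodels.api as sm

    x = cohort.trait(exposure)
    y = cohort.trait(outcome)
    z = np.asarray(instrument, dtype=float).reshape(-1, 1)
    if np.ptp(z) == 0:
        raise ValueError("instrument does not vary")
    C = _design(cohort, covariate_names)
    fitted, F, partial_r2 = _first_stage(x, z, C)
    if partial_r2 == 0:
        raise ValueError("stage-1 partial R^2 is zero: instrument irrelevant")
    weak = F < WEAK_INSTRUMENT_F
    if weak:
        warnings.warn(f"weak instrument: first-stage F = {F:.2f} < 10", stacklevel=2)

    binary = set(np.unique(y)) <= {0.0, 1.0}
    if not binary:
        from statsmodels.sandbox.regression.gmm import IV2SLS

        fit = IV2SLS(y, np.column_stack([x, C]), np.column_stack([z, C])).fit()
        b, s = float(fit.params[0]), float(fit.bse[0])
        p = 2 * sps.t.sf(abs(b / s), fit.df_resid)
        return TSLSResult(b, s, float(p), {"F": F, "partial_r2": partial_r2},
                          "continuous", weak, cohort.n)

    Xd = np.column_stack([fitted, C])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = float(sm.Logit(y, Xd).fit(disp=0, maxiter=200).params[0])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = cohort.n
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            fit_i, *_ = _first_stage(x[idx], z[idx], C[idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                boots[i] = sm.Logit(y[idx], np.column_stack([fit_i, C[idx]])) \
                    .fit(disp=0, maxiter=200).params[0]
        except Exception:
            boots[i] = np.nan
    se = float(np.nanstd(boots, ddof=1))
    p = 2 * sps.norm.sf(abs(b / se))
    return TSLSResult(b, se, float(p), {"F": F, "partial_r2": partial_r2},
                      "binary", weak, cohort.n)


def mvmr_tsls(cohort, exposures: Sequence[str], outcome: str,
              instruments: Sequence[np.ndarray],
              covariate_names: Sequence[str] = (), n_boot: int = 200,
              seed: int = 0) -> pd.DataFrame:
    """Multivariable MR: per-exposure direct effects conditional on the rest.

    Stage 1 regresses each exposure on ALL instruments plus covariates;
    stage 2 regresses the outcome on all fitted exposures (2SLS for
    continuous outcomes, predictor-substitution logistic with bootstrap SE
    for binary).  A conditional instrument-strength F is reported per
    exposure: the F of the instruments for the part of each exposure not
    explained by the other fitted exposures.
    """
    import statsmodels.api as sm

    if len(exposures) < 2:
        raise ValueError("MVMR needs >= 2 exposures (use tsls)")
    if len(instruments) < len(exposures):
        raise ValueError("need at least as many instruments as exposures")
    X = np.column_stack([cohort.trait(e) for e in exposures])
    y = cohort.trait(outcome)
    Z = np.column_stack([np.asarray(z, float) for z in instruments])
    C = _design(cohort, covariate_names)

    W = np.column_stack([Z, C])
    coef = _ols(W, X)
    Xhat = W @ coef

    # collinearity of fitted exposures breaks identification
    Xh_c = Xhat - Xhat.mean(axis=0)
    s = np.linalg.svd(Xh_c, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > 1e8:
        raise ValueError(
            "fitted exposures are collinear (condition number "
            f"{s[0] / max(s[-1], 1e-300):.2e}); instruments do not separate them")

    cond_F = []
    for k in range(len(exposures)):
        others = np.delete(Xhat, k, axis=1)
        resid = X[:, k] - np.column_stack([others, C]) @ _ols(
            np.column_stack([others, C]), X[:, k])
        _, Fk, _ = _first_stage(resid, Z, C)
        cond_F.append(Fk)

    binary = set(np.unique(y)) <= {0.0, 1.0}
    if not binary:
        from statsmodels.sandbox.regression.gmm import IV2SLS

        fit = IV2SLS(y, np.column_stack([X, C]), W).fit()
        k = len(exposures)
        b, serr = fit.params[:k], fit.bse[:k]
        p = 2 * sps.t.sf(np.abs(b / serr), fit.df_resid)
    else:
        Xd = np.column_stack([Xhat, C])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        k = len(exposures)
        b = fit.params[:k]
        rng = np.random.default_rng(seed)
        boots = np.full((n_boot, k), np.nan)
        n = cohort.n
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                Wi = W[idx]
                Xh_i = Wi @ _ols(Wi, X[idx])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    boots[i] = sm.Logit(y[idx], np.column_stack([Xh_i, C[idx]])) \
                        .fit(disp=0, maxiter=200).params[:k]
            except Exception:
                pass
        serr = np.nanstd(boots, axis=0, ddof=1)
        p = 2 * sps.norm.sf(np.abs(b / serr))

    return pd.DataFrame({
        "exposure": list(exposures), "beta": b, "se": serr, "p": p,
        "conditional_F": cond_F,
        "outcome_type": "binary" if binary else "continuous",
    })


def _point_decomposition(x, y, M, z_exp, Z_med, C, binary):
    """Total, direct on one bootstrap draw (fast numpy/logit path)."""
    import statsmodels.api as sm

    if not binary:
        bt, _, _ = _tsls_continuous(y, x.reshape(-1, 1), z_exp.reshape(-1, 1), C)
        total = float(bt[0])
        Xm = np.column_stack([x.reshape(-1, 1), M])
        Z_all = np.column_stack([z_exp.reshape(-1, 1), Z_med])
        bd, _, _ = _tsls_continuous(y, Xm, Z_all, C)
        direct = float(bd[0])
    else:
        f1, *_ = _first_stage(x, z_exp.reshape(-1, 1), C)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total = float(sm.Logit(y, np.column_stack([f1, C]))
                          .fit(disp=0, maxiter=200).params[0])
        Z_all = np.column_stack([z_exp.reshape(-1, 1), Z_med])
        W = np.column_stack([Z_all, C])
        Xm = np.column_stack([x.reshape(-1, 1), M])
        Xh = W @ _ols(W, Xm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = float(sm.Logit(y, np.column_stack([Xh, C]))
                           .fit(disp=0, maxiter=200).params[0])
    return total, direct


def mediation_decompose(cohort, exposure: str, mediators: Sequence[str],
                        outcome: str, instruments: dict,
                        covariate_names: Sequence[str] = (),
                        n_boot: int = 1000, seed: int = 0,
                        total_tolerance: float = 1e-8) -> MediationResult:
    """Proportion of the exposure's causal effect transmitted by mediators.

    ``instruments`` maps the exposure name and each mediator name to its
    genetic score vector.  Total effect: univariable 2SLS of the outcome on
    the exposure.  Direct effect: MVMR including the selected mediators.
    indirect = total - direct (an identity, asserted on every run);
    proportion = indirect / total, undefined (flagged, not NaN-propagated)
    when |total| is below ``total_tolerance``.  Percentile bootstrap CI and
    SE over individual resamples, seeded.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    x = cohort.trait(exposure)
    y = cohort.trait(outcome)
    M = np.column_stack([cohort.trait(m) for m in mediators])
    z_exp = np.asarray(instruments[exposure], float)
    Z_med = np.column_stack([np.asarray(instruments[m], float) for m in mediators])
    C = _design(cohort, covariate_names)
    binary = set(np.unique(y)) <= {0.0, 1.0}

    total, direct = _point_decomposition(x, y, M, z_exp, Z_med, C, binary)
    indirect = total - direct
    assert np.isclose(indirect, total - direct)  # decomposition identity
    defined = abs(total) > total_tolerance
    proportion = indirect / total if defined else None

    rng = np.random.default_rng(seed)
    n = cohort.n
    boot_prop = np.full(n_boot, np.nan)
    boot_total = np.full(n_boot, np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            t_i, d_i = _point_decomposition(
                x[idx], y[idx], M[idx], z_exp[idx], Z_med[idx], C[idx], binary)
            boot_total[i] = t_i
            if abs(t_i) > total_tolerance:
                boot_prop[i] = (t_i - d_i) / t_i
        except Exception:
            pass
    valid = boot_prop[np.isfinite(boot_prop)]
    if valid.size >= 50:
        ci = (float(np.percentile(valid, 2.5)), float(np.percentile(valid, 97.5)))
        se = float(np.std(valid, ddof=1))
    else:
        ci, se = (np.nan, np.nan), np.nan

    notes = []
    if binary:
        notes.append("log-odds scale; non-collapsible across adjustment sets")
    if not defined:
        notes.append("total effect indistinguishable from zero: proportion undefined")
    return MediationResult(
        total=total, direct=direct, indirect=indirect,
        proportion=proportion, proportion_defined=defined,
        bootstrap={"n_boot": n_boot, "se": se, "ci95": ci, "seed": seed,
                   "n_valid": int(valid.size)},
        outcome_scale="log_odds" if binary else "identity", notes=notes)
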