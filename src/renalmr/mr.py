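"""Two-sample Mendelian randomization estimators and diagnostics.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression with
fixed and multiplicative-random-effects variants, MR-Egger regression with
its intercept test for directional pleiotropy, the weighted-median
estimator with a parametric bootstrap, radial IVW with per-SNP Cochran Q
outlier detection, a simulation-based residual-sum-of-squares outlier test
(global, per-SNP and distortion components), and the triangulation rule
that declares evidence of causality only when at least three of the four
estimators agree after false-discovery-rate control and the Egger
intercept shows no pleiotropy signal.

All estimators consume a harmonized instrument table (columns
``beta_exposure``, ``se_exposure``, ``beta_outcome``, ``se_outcome``) and
use first-order weights w_j = beta_Xj^2 / se_Yj^2 for the ratio estimates
beta_j = beta_Yj / beta_Xj.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instruments import EmptyInstrumentSetError

__all__ = [
    "MREstimate", "PressoResult", "TriangulationVerdict",
    "wald_ratio", "ivw", "egger", "weighted_median", "radial_ivw",
    "mr_presso", "triangulate", "run_estimator_suite",
]

TRIANGULATION_METHODS = ("ivw", "weighted_median", "radial_ivw", "presso")


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_snp_outlier_p: np.ndarray
    outlier_indices: list
    beta_raw: MREstimate
    beta_corrected: MREstimate
    distortion_p: float
    n_simulations: int
    seed: int


def _columns(instruments: pd.DataFrame):
    if isinstance(instruments, pd.DataFrame):
        if "harmonization_action" in instruments.columns:
            keep = instruments["harmonization_action"].isin(["kept", "flipped"])
            instruments = instruments[keep]
        bx = instruments["beta_exposure"].to_numpy(float)
        sx = instruments["se_exposure"].to_numpy(float)
        by = instruments["beta_outcome"].to_numpy(float)
        sy = instruments["se_outcome"].to_numpy(float)
    else:
        bx, sx, by, sy = map(np.asarray, instruments)
    ok = np.isfinite(bx) & np.isfinite(by) & np.isfinite(sx) & np.isfinite(sy) & (sy > 0)
    return bx[ok], sx[ok], by[ok], sy[ok]


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float) -> MREstimate:
    """Single-instrument causal estimate beta_Y / beta_X.

    First-order delta-method standard error se_Y / |beta_X| (exposure
    uncertainty ignored, the convention under strong instruments).
    """
    if beta_exposure == 0:
        raise ValueError("wald ratio undefined for beta_exposure = 0")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    p = 2 * sps.norm.sf(abs(beta / se))
    return MREstimate("wald", beta, se, p, 1)


def _ivw_core(bx, by, sy):
    w = bx ** 2 / sy ** 2           # first-order weights for ratio estimates
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q, w, ratios


def ivw(instruments, model: str = "multiplicative_random",
        allow_single: bool = False) -> MREstimate:
    """Inverse-variance-weighted estimate.

    beta = sum(bX bY / sY^2) / sum(bX^2 / sY^2); fixed-effect
    se = (sum bX^2/sY^2)^-1/2, inflated by sqrt(max(1, Q/(J-1))) under the
    multiplicative random-effects model (the default).  Cochran's Q over
    ratio estimates with first-order weights is reported in ``extras``.
    """
    bx, sx, by, sy = _columns(instruments)
    J = bx.size
    if J == 0:
        raise EmptyInstrumentSetError("no instruments available for IVW")
    if J == 1:
        if allow_single:
            est = wald_ratio(bx[0], sx[0], by[0], sy[0])
            est.method = "ivw"
            return est
        raise ValueError("IVW needs >= 2 instruments (use wald_ratio)")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    beta, se_fixed, q, w, _ = _ivw_core(bx, by, sy)
    phi = max(1.0, q / (J - 1))
    se = se_fixed * np.sqrt(phi) if model == "multiplicative_random" else se_fixed
    p = 2 * sps.norm.sf(abs(beta / se))
    return MREstimate("ivw", beta, float(se), float(p), J, extras={
        "model": model, "se_fixed": se_fixed,
        "se_random": se_fixed * np.sqrt(phi),
        "Q": q, "Q_df": J - 1, "Q_p": float(sps.chi2.sf(q, J - 1)),
    })


def egger(instruments) -> MREstimate:
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    Records are oriented so every beta_X > 0 before fitting (required for
    the intercept to be interpretable); weights 1/se_Y^2; t reference with
    J - 2 df; multiplicative over-dispersion floored at 1.  The intercept,
    its SE and two-sided p — the directional-pleiotropy test — are in
    ``extras``.
    """
    bx, sx, by, sy = _columns(instruments)
    J = bx.size
    if J < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, q / (J - 2))
    cov = np.linalg.inv(xtwx) * phi
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * sps.t.sf(np.abs(tvals), J - 2)
    return MREstimate("egger", float(coef[1]), float(se[1]), float(pvals[1]), J, extras={
        "intercept": float(coef[0]), "intercept_se": float(se[0]),
        "intercept_p": float(pvals[0]),
        "Q": q, "Q_df": J - 2, "Q_p": float(sps.chi2.sf(q, J - 2)),
    })


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    s = np.cumsum(w)
    pj = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, pj, v))


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator: consistent if >= 50% of weight is valid.

    Ratio estimates ordered; inverse-variance weights of the ratios
    (first-order); median located by linear interpolation of the cumulative
    weight at probability 0.5.  SE from a seeded parametric bootstrap
    resampling beta_X and beta_Y from their sampling normals.
    """
    bx, sx, by, sy = _columns(instruments)
    J = bx.size
    if J < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    if np.any(w <= 0):
        raise ValueError("non-positive weights")
    beta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    bx_b[bx_b == 0] = np.finfo(float).tiny
    ratios_b = by_b / bx_b
    w_b = bx_b ** 2 / sy ** 2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(ratios_b[i], w_b[i])
    se = float(np.std(boots, ddof=1))
    p = 2 * sps.norm.sf(abs(beta / se))
    return MREstimate("weighted_median", beta, se, float(p), J,
                      extras={"n_boot": n_boot, "seed": seed})


def radial_ivw(instruments, outlier_alpha: float = 0.05) -> MREstimate:
    """Radial IVW: origin regression of beta_j sqrt(w_j) on sqrt(w_j).

    The slope is algebraically the IVW estimate under first-order weights;
    the per-SNP contributions Q_j = w_j (beta_j - beta_hat)^2 are referred
    to chi2(1) and flagged as outliers at a Bonferroni-adjusted
    ``outlier_alpha``.  The estimate recomputed without outliers is
    reported in ``extras``.
    """
    bx, sx, by, sy = _columns(instruments)
    J = bx.size
    if J < 2:
        raise ValueError("radial IVW needs >= 2 instruments")
    beta, se_fixed, q, w, ratios = _ivw_core(bx, by, sy)
    qj = w * (ratios - beta) ** 2
    pj = sps.chi2.sf(qj, 1)
    outliers = np.where(pj < outlier_alpha / J)[0]
    phi = max(1.0, q / (J - 1))
    se = se_fixed * np.sqrt(phi)
    p = 2 * sps.norm.sf(abs(beta / se))

    extras = {"Q": q, "Q_df": J - 1, "Q_p": float(sps.chi2.sf(q, J - 1)),
              "q_contributions": qj, "q_p": pj,
              "outlier_indices": outliers.tolist()}
    if outliers.size and outliers.size < J - 1:
        keep = np.setdiff1d(np.arange(J), outliers)
        b2, se2_f, q2, w2, _ = _ivw_core(bx[keep], by[keep], sy[keep])
        se2 = se2_f * np.sqrt(max(1.0, q2 / (keep.size - 1)))
        extras["beta_outlier_corrected"] = b2
        extras["se_outlier_corrected"] = float(se2)
    else:
        extras["beta_outlier_corrected"] = beta
        extras["se_outlier_corrected"] = float(se)
    return MREstimate("radial_ivw", beta, float(se), float(p), J, extras=extras)


def mr_presso(instruments, n_simulations: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Simulation-based outlier test (global, per-SNP, distortion).

    The observed global statistic is the weighted residual sum of squares
    around leave-one-out IVW predictions,
    RSS = sum_j w_j (beta_Yj - beta_(-j) beta_Xj)^2 with w_j = 1/se_Yj^2.
    Its null distribution comes from simulating beta_Yj* ~ Normal(
    beta_(-j) beta_Xj, se_Yj) ``n_simulations`` times.  Per-SNP outlier
    p-values compare each SNP's observed residual term with its simulated
    distribution (Bonferroni-adjusted).  The distortion test compares the
    raw-vs-corrected shift against shifts from removing random same-size
    SNP subsets.
    """
    bx, sx, by, sy = _columns(instruments)
    J = bx.size
    if J < 4:
        raise ValueError("outlier simulation test needs >= 4 instruments")
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    rng = np.random.default_rng(seed)

    wy = 1.0 / sy ** 2
    A = float(np.sum(bx * by * wy))
    B = float(np.sum(bx ** 2 * wy))
    beta_loo = (A - bx * by * wy) / (B - bx ** 2 * wy)   # leave-one-out IVW
    pred = beta_loo * bx
    res_obs = wy * (by - pred) ** 2
    rss_obs = float(np.sum(res_obs))

    by_sim = rng.normal(pred, sy, size=(n_simulations, J))
    A_s = by_sim @ (bx * wy)
    loo_s = (A_s[:, None] - bx * by_sim * wy) / (B - bx ** 2 * wy)
    res_sim = wy * (by_sim - loo_s * bx) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_simulations + 1))
    p_snp = (1 + np.sum(res_sim >= res_obs, axis=0)) / (n_simulations + 1)
    p_adj = np.minimum(1.0, p_snp * J)
    outliers = np.where(p_adj < outlier_alpha)[0]

    raw = ivw(( bx, sx, by, sy ))
    raw.method = "presso_raw"
    if outliers.size and J - outliers.size >= 2:
        keep = np.setdiff1d(np.arange(J), outliers)
        corrected = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
    else:
        corrected = ivw((bx, sx, by, sy))
    corrected.method = "presso"

    if outliers.size and J - outliers.size >= 2:
        k = outliers.size
        shifts = np.empty(n_simulations)
        for s in range(n_simulations):
            drop = rng.choice(J, size=k, replace=False)
            keep_s = np.setdiff1d(np.arange(J), drop)
            b_s, *_ = _ivw_core(bx[keep_s], by[keep_s], sy[keep_s])
            shifts[s] = raw.beta - b_s
        obs_shift = raw.beta - corrected.beta
        distortion_p = float((1 + np.sum(np.abs(shifts) >= abs(obs_shift)))
                             / (n_simulations + 1))
    else:
        distortion_p = 1.0

    return PressoResult(
        global_rss=rss_obs, global_p=global_p, per_snp_outlier_p=p_adj,
        outlier_indices=outliers.tolist(), beta_raw=raw, beta_corrected=corrected,
        distortion_p=distortion_p, n_simulations=n_simulations, seed=seed)


@dataclass
class TriangulationVerdict:
    causal: bool | None
    n_significant_concordant: int
    egger_intercept_ok: bool | None
    components: dict


def triangulate(estimates: dict, q_values: dict,
                egger_intercept_q: float | None) -> TriangulationVerdict:
    """Evidence-of-causality rule across the four estimators.

    True iff at least 3 of {IVW, weighted median, radial IVW,
    outlier-corrected} have FDR-adjusted q < 0.05 with sign-concordant
    betas AND the Egger-intercept q >= 0.05 (no pleiotropy signal).  A
    missing method leaves the verdict undetermined (None), never False.
    """
    missing = [m for m in TRIANGULATION_METHODS
               if m not in estimates or m not in q_values]
    components = {}
    for m in TRIANGULATION_METHODS:
        if m in estimates and m in q_values:
            components[m] = {"beta": estimates[m].beta, "q": q_values[m],
                             "significant": q_values[m] < 0.05}
    if missing or egger_intercept_q is None:
        return TriangulationVerdict(None, 0, None, components)

    best = 0
    for sign in (-1.0, 1.0):
        best = max(best, sum(1 for c in components.values()
                             if c["significant"] and np.sign(c["beta"]) == sign))
    egger_ok = egger_intercept_q >= 0.05
    return TriangulationVerdict(bool(best >= 3 and egger_ok), best, egger_ok,
                                components)


def run_estimator_suite(instruments, seed: int = 0, n_boot: int = 1000,
                        n_simulations: int = 1000) -> dict:
    """All four triangulation estimators plus Egger on one instrument set."""
    out = {"ivw": ivw(instruments)}
    out["weighted_median"] = weighted_median(instruments, n_boot=n_boot, seed=seed)
    out["radial_ivw"] = radial_ivw(instruments)
    presso = mr_presso(instruments, n_simulations=n_simulations, seed=seed + 1)
    out["presso"] = presso.beta_corrected
    out["presso_full"] = presso
    out["egger"] = egger(instruments)
    return out
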