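"""Synthetic cohorts with known causal structure.

Generates individual-level data under a linear structural model

    X  = sum_j gamma_j g_j + q_x U + e_x                  (exposure, SD units)
    M_k = a_k X + GRS_k + e_mk                            (mediators, SD units)
    Y  = c X + sum_k b_k M_k + q_y U + sum_j alpha_j g_j + e_y

with bi-allelic SNPs drawn under Hardy-Weinberg equilibrium, a single
standard-normal confounder ``U``, optional pleiotropic direct effects
``alpha_j`` on an invalid instrument subset, and binary outcomes produced
through a logistic link whose intercept is solved to hit a target
prevalence.  Each mediator carries its own block of instrument SNPs so
that multivariable models remain identified.

Every output is a pure function of the configuration and its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "MediatorSpec",
    "PleiotropySpec",
    "SimulationConfig",
    "Cohort",
    "CohortTruth",
    "simulate_cohort",
    "cohort_to_summary",
    "make_two_sample_pair",
]

_BASES = np.array(list("ACGT"))

SUMMARY_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]


@dataclass(frozen=True)
class MediatorSpec:
    """One mediator on the exposure -> mediator -> outcome path.

    ``a`` is the exposure effect on the mediator and ``b`` the mediator
    effect on the outcome, both per SD.  Each mediator receives its own
    ``n_snps`` instruments explaining ``h2`` of its variance.
    """

    name: str
    a: float
    b: float
    h2: float = 0.1
    n_snps: int = 20


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct SNP -> outcome effects on a random invalid instrument subset.

    ``mean_direct`` = 0 with ``sd_direct`` > 0 gives balanced pleiotropy;
    a non-zero mean gives directional pleiotropy.  With
    ``inside_violation`` the direct effects are made proportional to
    instrument strength, breaking the InSiDE assumption that MR-Egger
    relies on.
    """

    prop_invalid: float = 0.0
    mean_direct: float = 0.0
    sd_direct: float = 0.0
    inside_violation: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 10_000
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.1
    beta_causal: float = 0.0
    confounder_effects: tuple[float, float] = (0.0, 0.0)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    mediators: tuple[MediatorSpec, ...] = ()
    outcome_type: str = "continuous"
    baseline_prevalence: float | None = None
    with_biomarkers: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mediators", tuple(
            m if isinstance(m, MediatorSpec) else MediatorSpec(**m)
            for m in self.mediators))
        if not isinstance(self.pleiotropy, PleiotropySpec):
            object.__setattr__(self, "pleiotropy", PleiotropySpec(**self.pleiotropy))
        object.__setattr__(self, "maf_range", tuple(self.maf_range))
        object.__setattr__(self, "confounder_effects", tuple(self.confounder_effects))
        self.validate()

    def validate(self) -> None:
        numeric = [self.h2_exposure, self.beta_causal, *self.confounder_effects,
                   *self.maf_range, self.pleiotropy.prop_invalid,
                   self.pleiotropy.mean_direct, self.pleiotropy.sd_direct]
        numeric += [v for m in self.mediators for v in (m.a, m.b, m.h2)]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("non-finite simulation parameter")
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.h2_exposure < 1:
            raise ValueError("h2_exposure must be in [0, 1)")
        if not 0 <= self.pleiotropy.prop_invalid <= 1:
            raise ValueError("prop_invalid must be in [0, 1]")
        if self.pleiotropy.sd_direct < 0:
            raise ValueError("sd_direct must be non-negative")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary":
            if self.baseline_prevalence is None or not 0 < self.baseline_prevalence < 1:
                raise ValueError("binary outcome requires baseline_prevalence in (0, 1)")
        qx, _ = self.confounder_effects
        if self.h2_exposure + qx ** 2 >= 1:
            raise ValueError("h2_exposure + confounder variance on exposure must be < 1")
        for m in self.mediators:
            if m.a ** 2 + m.h2 >= 1:
                raise ValueError(f"mediator {m.name!r}: a^2 + h2 must be < 1")
            if m.n_snps < 1 or not 0 <= m.h2 < 1:
                raise ValueError(f"mediator {m.name!r}: invalid h2 or n_snps")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortTruth:
    """Realized generating parameters attached to each cohort."""

    config: SimulationConfig
    maf: np.ndarray                      # all SNPs (exposure block first)
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    gamma: np.ndarray                    # exposure effects, exposure block
    alpha: np.ndarray                    # pleiotropic direct effects, exposure block
    invalid_idx: np.ndarray
    mediator_gammas: dict
    mediator_blocks: dict                # name -> column slice into dosages
    exposure_block: slice
    variance_fractions: dict


@dataclass
class Cohort:
    dosages: np.ndarray
    exposure: np.ndarray
    mediators: pd.DataFrame
    outcome: np.ndarray
    covariates: pd.DataFrame
    truth: CohortTruth
    biomarkers: pd.DataFrame | None = None
    icd_codes: list | None = None

    @property
    def n(self) -> int:
        return len(self.exposure)

    def trait(self, name: str) -> np.ndarray:
        """Look up a phenotype vector by name."""
        if name == "exposure":
            return self.exposure
        if name == "outcome":
            return np.asarray(self.outcome, dtype=float)
        if name in self.mediators.columns:
            return self.mediators[name].to_numpy()
        if self.biomarkers is not None and name in self.biomarkers.columns:
            return self.biomarkers[name].to_numpy()
        raise KeyError(f"trait {name!r} not present in cohort")


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> CohortTruth:
    n_med_snps = sum(m.n_snps for m in config.mediators)
    total = config.n_snps + n_med_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=total)

    # sparse genomic coordinates: >1 Mb apart within chromosome so that
    # distance pruning treats the panel as independent
    chrom = (np.arange(total) % 22) + 1
    pos = 1_000_000 + (np.arange(total) // 22) * 2_000_000
    ea_i = rng.integers(0, 4, size=total)
    oa_i = (ea_i + rng.integers(1, 4, size=total)) % 4
    ea, oa = _BASES[ea_i], _BASES[oa_i]
    snp_ids = [f"rs{100 + j}" for j in range(total)]

    var_per_allele = 2 * maf * (1 - maf)

    def scaled_effects(idx: np.ndarray, h2: float) -> np.ndarray:
        raw = rng.normal(size=idx.size)
        if h2 == 0:
            return np.zeros(idx.size)
        scale = math.sqrt(h2 / float(np.sum(raw ** 2 * var_per_allele[idx])))
        return raw * scale

    exp_idx = np.arange(config.n_snps)
    gamma = scaled_effects(exp_idx, config.h2_exposure)

    pl = config.pleiotropy
    n_invalid = int(round(pl.prop_invalid * config.n_snps))
    directional_requested = pl.mean_direct != 0 or pl.sd_direct > 0
    if pl.prop_invalid > 0 and n_invalid < 1 and directional_requested:
        warnings.warn("prop_invalid * n_snps < 1: no invalid instruments realized",
                      stacklevel=3)
    invalid_idx = np.sort(rng.choice(config.n_snps, size=n_invalid, replace=False))
    alpha = np.zeros(config.n_snps)
    if n_invalid:
        base = pl.mean_direct + pl.sd_direct * rng.normal(size=n_invalid)
        g_inv = gamma[invalid_idx]
        if pl.inside_violation:
            # direct effect proportional to instrument strength: InSiDE broken
            denom = float(np.mean(np.abs(g_inv))) or 1.0
            alpha[invalid_idx] = base * g_inv / denom
        else:
            # "directional" means directional on the exposure-increasing
            # allele, so align the direct effect with each SNP's orientation
            alpha[invalid_idx] = base * np.where(g_inv >= 0, 1.0, -1.0)

    mediator_gammas, mediator_blocks = {}, {}
    start = config.n_snps
    for m in config.mediators:
        block = slice(start, start + m.n_snps)
        mediator_blocks[m.name] = block
        mediator_gammas[m.name] = scaled_effects(np.arange(block.start, block.stop), m.h2)
        start = block.stop

    return CohortTruth(
        config=config, maf=maf, snp_ids=snp_ids, chrom=chrom, pos=pos,
        ea=ea, oa=oa, gamma=gamma, alpha=alpha, invalid_idx=invalid_idx,
        mediator_gammas=mediator_gammas, mediator_blocks=mediator_blocks,
        exposure_block=slice(0, config.n_snps), variance_fractions={},
    )


def _draw_covariates(n: int, rng: np.random.Generator, n_pcs: int = 4) -> pd.DataFrame:
    age = rng.integers(40, 71, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)
    centre = rng.integers(0, 5, size=n).astype(float)
    cov = {"age": age, "age2": age ** 2, "sex": sex, "centre": centre}
    for k in range(n_pcs):
        cov[f"pc{k + 1}"] = rng.normal(size=n)
    return pd.DataFrame(cov)


def _solve_logistic_intercept(eta: np.ndarray, prevalence: float) -> float:
    f = lambda b0: float(np.mean(expit(b0 + eta))) - prevalence
    return brentq(f, -40.0, 40.0)


def _draw_biomarkers(outcome_liability: np.ndarray, covariates: pd.DataFrame,
                     rng: np.random.Generator):
    """Biomarker panel tied to a latent renal-function variable.

    Lower latent function -> higher creatinine/cystatin C/BUN/uACR and a
    higher chance of a kidney ICD-10 code, so composite-index builders see
    realistic joint structure.
    """
    n = len(outcome_liability)
    damage = 0.6 * (outcome_liability - outcome_liability.mean()) / (outcome_liability.std() or 1.0) \
        + 0.8 * rng.normal(size=n)
    sex = covariates["sex"].to_numpy()
    age = covariates["age"].to_numpy()
    scr = np.exp(np.log(62.0) + 0.12 * sex + 0.002 * (age - 55) + 0.12 * damage
                 + 0.08 * rng.normal(size=n))                     # umol/L
    cys = np.exp(np.log(0.85) + 0.003 * (age - 55) + 0.10 * damage
                 + 0.07 * rng.normal(size=n))                     # mg/L
    bun = np.exp(np.log(5.0) + 0.004 * (age - 55) + 0.10 * damage
                 + 0.10 * rng.normal(size=n))                     # mmol/L
    uacr = np.exp(np.log(0.8) + 0.45 * damage + 0.6 * rng.normal(size=n))  # mg/mmol
    panel = pd.DataFrame({
        "serum_creatinine": scr, "serum_cystatin_c": cys,
        "bun": bun, "uacr": uacr, "age": age, "sex": sex,
    })
    p_icd = expit(-4.0 + 1.2 * damage)
    has_icd = rng.random(n) < p_icd
    renal = ["N18", "N17", "N04", "I12"]
    codes = []
    for flag in has_icd:
        if flag:
            codes.append([renal[rng.integers(0, len(renal))] + f".{rng.integers(0, 5)}"])
        else:
            codes.append([])
    return panel, codes


def simulate_cohort(config: SimulationConfig,
                    truth: CohortTruth | None = None,
                    individual_seed: int | None = None) -> Cohort:
    """Draw one cohort.

    ``truth`` may be supplied to reuse realized per-SNP effects across
    cohorts (the two-sample contract); otherwise it is drawn from
    ``config.seed``.  ``individual_seed`` overrides the stream used for
    individual-level draws, keeping the truth fixed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    truth_ss, indiv_ss = ss.spawn(2)
    if truth is None:
        truth = _draw_truth(config, np.random.default_rng(truth_ss))
    if individual_seed is not None:
        indiv_ss = np.random.SeedSequence(individual_seed)
    rng = np.random.default_rng(indiv_ss)

    n = config.n_individuals
    G = rng.binomial(2, truth.maf, size=(n, truth.maf.size)).astype(float)
    Gc = G - 2 * truth.maf  # theoretical centering keeps effects orthogonal to mean

    qx, qy = config.confounder_effects
    U = rng.normal(size=n)
    grs_x = Gc[:, truth.exposure_block] @ truth.gamma
    var_ex = 1.0 - config.h2_exposure - qx ** 2
    X = grs_x + qx * U + math.sqrt(var_ex) * rng.normal(size=n)

    med = {}
    for m in config.mediators:
        grs_m = Gc[:, truth.mediator_blocks[m.name]] @ truth.mediator_gammas[m.name]
        var_em = 1.0 - m.a ** 2 - m.h2
        med[m.name] = m.a * X + grs_m + math.sqrt(var_em) * rng.normal(size=n)
    mediators = pd.DataFrame(med, index=range(n))

    eta = config.beta_causal * X + qy * U + Gc[:, truth.exposure_block] @ truth.alpha
    for m in config.mediators:
        eta = eta + m.b * mediators[m.name].to_numpy()

    if config.outcome_type == "continuous":
        var_eta = float(np.var(eta))
        var_ey = max(1.0 - var_eta, 0.05)
        outcome = eta + math.sqrt(var_ey) * rng.normal(size=n)
        liability = outcome
    else:
        b0 = _solve_logistic_intercept(eta, config.baseline_prevalence)
        p = expit(b0 + eta)
        outcome = (rng.random(n) < p).astype(int)
        liability = eta

    covariates = _draw_covariates(n, rng)

    biomarkers = icd = None
    if config.with_biomarkers:
        biomarkers, icd = _draw_biomarkers(liability, covariates, rng)

    truth.variance_fractions = {
        "exposure_instrument": config.h2_exposure,
        "exposure_confounder": qx ** 2,
        "exposure_noise": var_ex,
    }
    return Cohort(dosages=G, exposure=X, mediators=mediators, outcome=outcome,
                  covariates=covariates, truth=truth, biomarkers=biomarkers,
                  icd_codes=icd)


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out the column space of C (with intercept already included)."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def cohort_to_summary(cohort: Cohort, trait: str,
                      covariate_names: Sequence[str] = ()) -> pd.DataFrame:
    """Per-SNP GWAS of one trait: linear for continuous, logistic for binary.

    Returns a summary-statistics table with the standard header
    ``snp chr pos ea oa eaf beta se p n``.  Monomorphic SNPs yield NaN
    beta/se/p and are excluded downstream.
    """
    from scipy import stats as sps

    y = cohort.trait(trait)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant; GWAS undefined")
    binary = set(np.unique(y)) <= {0.0, 1.0} and trait == "outcome" \
        and cohort.truth.config.outcome_type == "binary"

    n, J = cohort.dosages.shape
    C = np.column_stack([np.ones(n)] +
                        [cohort.covariates[c].to_numpy() for c in covariate_names])
    eaf = cohort.dosages.mean(axis=0) / 2.0
    mono = (cohort.dosages.std(axis=0) == 0)

    beta = np.full(J, np.nan)
    se = np.full(J, np.nan)
    pval = np.full(J, np.nan)

    if not binary:
        Gr = _residualize(cohort.dosages, C)
        yr = _residualize(y.astype(float), C)
        gtg = np.einsum("ij,ij->j", Gr, Gr)
        ok = ~mono & (gtg > 0)
        b = np.zeros(J)
        b[ok] = (Gr[:, ok].T @ yr) / gtg[ok]
        df = n - C.shape[1] - 1
        rss = np.sum(yr ** 2) - b ** 2 * gtg
        sigma2 = np.maximum(rss, 0.0) / df
        beta[ok] = b[ok]
        se[ok] = np.sqrt(sigma2[ok] / gtg[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pval[ok] = 2 * sps.t.sf(np.abs(t[ok]), df)
    else:
        import statsmodels.api as sm
        for j in range(J):
            if mono[j]:
                continue
            Xd = np.column_stack([cohort.dosages[:, j], C])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, Xd).fit(disp=0, maxiter=100)
                beta[j], se[j], pval[j] = res.params[0], res.bse[0], res.pvalues[0]
            except Exception:
                pass

    t = cohort.truth
    return pd.DataFrame({
        "snp": t.snp_ids, "chr": t.chrom, "pos": t.pos,
        "ea": t.ea, "oa": t.oa, "eaf": eaf,
        "beta": beta, "se": se, "p": np.clip(pval, np.nextafter(0, 1), 1.0),
        "n": n,
    })


def make_two_sample_pair(config: SimulationConfig, seeds: tuple[int, int],
                         exposure_trait: str = "exposure",
                         outcome_trait: str = "outcome",
                         n_per_sample: tuple[int, int] | None = None,
                         return_cohorts: bool = False):
    """Two non-overlapping cohorts sharing one generative truth.

    The exposure GWAS comes from the first cohort and the outcome GWAS
    from the second, so no individual contributes to both sides — the
    two-sample contract.  Identical seeds are rejected as a sample-overlap
    violation.  ``n_per_sample`` overrides the cohort sizes, e.g. to pair a
    consortium-scale exposure GWAS with a smaller outcome sample.
    """
    s1, s2 = seeds
    if s1 == s2:
        raise ValueError("two-sample pair requires distinct seeds (sample overlap)")
    n1, n2 = n_per_sample if n_per_sample else (config.n_individuals,) * 2
    truth = _draw_truth(config, np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[0]))
    c1 = simulate_cohort(replace(config, n_individuals=n1),
                         truth=truth, individual_seed=s1)
    c2 = simulate_cohort(replace(config, n_individuals=n2),
                         truth=truth, individual_seed=s2)
    exp_stats = cohort_to_summary(c1, exposure_trait)
    out_stats = cohort_to_summary(c2, outcome_trait)
    if return_cohorts:
        return exp_stats, out_stats, c1, c2
    return exp_stats, out_stats
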