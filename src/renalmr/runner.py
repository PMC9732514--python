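"""Observational baselines, FDR control, the phenome-wide scan, and the
four-stage study orchestrator.

``run_study`` executes the full synthetic study: (1) obesity trait ->
quantitative renal biomarker MR, (2) obesity -> binary kidney-health-index
MR, (3) obesity -> kidney-disease MR, (4) mediation of the index effect
through blood-pressure- and liability-style mediators — each stage with
two-sample estimation, a one-sample 2SLS companion, an observational
baseline, sensitivity re-runs after instrument-exclusion filters, and a
reverse-direction check.  FDR correction is applied within each stage's
family of tests, never across stages.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import instruments as ins
from . import mr as mrmod
from .causal import tsls, mediation_decompose
from .simulate import (SimulationConfig, MediatorSpec, PleiotropySpec,
                       make_two_sample_pair, simulate_cohort)

__all__ = ["AssociationRecord", "StudyConfig", "StudyReport",
           "observational_assoc", "bh_fdr", "phenome_scan", "run_study"]

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE_FAILURE = 0, 2, 3

DEFAULT_CATEGORIES = (
    "kidney and urinary tract", "cardiovascular", "hypertension", "diabetes",
    "metabolic", "respiratory", "gastrointestinal", "hepatobiliary",
    "neurological", "psychiatric", "musculoskeletal", "dermatological",
    "haematological", "immunological", "infectious", "endocrine",
    "ophthalmic", "ENT", "gynaecological", "urological", "oncological",
    "other",
)


@dataclass
class AssociationRecord:
    trait_name: str
    category: str | None
    n_cases: int | None
    estimate: float
    se: float
    p: float
    q: float | None = None
    separation_flag: bool = False


def observational_assoc(cohort, predictor: str, outcome: str,
                        covariate_names: Sequence[str] = ()) -> AssociationRecord:
    """Covariate-adjusted linear (continuous) or logistic (binary) regression."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = cohort.trait(predictor)
    y = cohort.trait(outcome)
    n = cohort.n
    C = np.column_stack([np.ones(n)] +
                        [cohort.covariates[c].to_numpy() for c in covariate_names])
    X = np.column_stack([x, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("model matrix not full rank")
    binary = set(np.unique(y)) <= {0.0, 1.0}
    separation = False
    if binary:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:
                fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8)
                separation = True
            separation |= any(issubclass(w.category, PerfectSeparationWarning)
                              for w in caught)
        separation |= not np.isfinite(fit.bse[0]) or fit.bse[0] > 50
        n_cases = int(np.sum(y))
    else:
        fit = sm.OLS(y, X).fit()
        n_cases = None
    return AssociationRecord(outcome, None, n_cases, float(fit.params[0]),
                             float(fit.bse[0]), float(fit.pvalues[0]),
                             separation_flag=separation)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def phenome_scan(cohort, index: np.ndarray, traits: pd.DataFrame,
                 covariate_names: Sequence[str] = (), min_cases: int = 100,
                 categories: dict | None = None) -> pd.DataFrame:
    """Scan binary traits for association with the kidney health index.

    Traits with case counts not strictly above ``min_cases`` are excluded;
    each retained trait is regressed (logistic) on the index plus
    covariates, and q-values are computed over the retained family.
    """
    import statsmodels.api as sm

    index = np.asarray(index, dtype=float)
    n = cohort.n
    C = np.column_stack([np.ones(n)] +
                        [cohort.covariates[c].to_numpy() for c in covariate_names])
    records = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError(f"trait {trait!r} is not binary")
        n_cases = int(y.sum())
        if n_cases <= min_cases:
            continue
        X = np.column_stack([index, C])
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            est, se, p = fit.params[0], fit.bse[0], fit.pvalues[0]
            separation = not np.isfinite(se) or se > 50
        except Exception:
            est, se, p, separation = np.nan, np.nan, 1.0, True
        records.append({
            "trait_name": trait,
            "category": (categories or {}).get(trait, "other"),
            "n_cases": n_cases, "estimate": est, "se": se, "p": p,
            "separation_flag": separation,
        })
    if not records:
        warnings.warn("no trait passes the case filter; empty scan", stacklevel=2)
        return pd.DataFrame(columns=["trait_name", "category", "n_cases",
                                     "estimate", "se", "p", "q", "separation_flag"])
    out = pd.DataFrame(records)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# study orchestration


@dataclass
class StudyConfig:
    """Four-stage synthetic study configuration (scaled-down by default)."""

    n_per_sample: int = 5000
    n_snps: int = 40
    h2_exposure: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    confounder_effects: tuple[float, float] = (0.3, 0.3)
    beta_biomarker: float = -0.2        # stage 1: exposure -> renal biomarker
    beta_index: float = -0.35           # stage 2: exposure -> index liability
    index_prevalence: float = 0.7
    beta_disease: float = 0.5           # stage 3: exposure -> disease liability
    disease_prevalence: float = 0.05
    mediation_direct: float = 0.3       # stage 4 structural coefficients
    mediator_bp: tuple[float, float] = (0.4, 0.3)     # (a, b)
    mediator_t2d: tuple[float, float] = (0.35, 0.35)
    p_threshold: float = 5e-8
    n_boot: int = 200
    n_simulations: int = 500
    mr_covariates: tuple[str, ...] = ("age", "age2", "sex", "pc1", "pc2")
    obs_covariates: tuple[str, ...] = ("age", "age2", "sex", "centre")
    sensitivity_regions: tuple = ()     # (chrom, start, end) triples
    sensitivity_blocklist: tuple = ()
    seed: int = 0

    def validate(self):
        if self.n_per_sample < 100 or self.n_snps < 4:
            raise ValueError("study too small to run all estimators")
        if not 0 < self.index_prevalence < 1 or not 0 < self.disease_prevalence < 1:
            raise ValueError("prevalences must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)


@dataclass
class StudyReport:
    config: dict
    tables: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_dir(self, outdir) -> None:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.10g")
        meta = {"config": self.config, "verdicts": self.verdicts,
                "seeds": self.seeds, "failures": self.failures,
                "versions": self.versions}
        (outdir / "report.json").write_text(json.dumps(meta, indent=2,
                                                       sort_keys=True, default=str))


def _method_table(pair_name: str, suite: dict, stage_family_p: list) -> pd.DataFrame:
    rows = []
    for m in (*mrmod.TRIANGULATION_METHODS, "egger"):
        est = suite[m]
        rows.append({"pair": pair_name, "method": m, "beta": est.beta,
                     "se": est.se, "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                     "p": est.p, "n_snps": est.n_snps})
        stage_family_p.append((pair_name, m, est.p))
    rows.append({"pair": pair_name, "method": "egger_intercept",
                 "beta": suite["egger"].extras["intercept"],
                 "se": suite["egger"].extras["intercept_se"],
                 "ci_low": np.nan, "ci_high": np.nan,
                 "p": suite["egger"].extras["intercept_p"],
                 "n_snps": suite["egger"].n_snps})
    return pd.DataFrame(rows)


def _two_sample_stage(cfg: StudyConfig, sim: SimulationConfig, seeds,
                      stage: str, report: StudyReport):
    exp_stats, out_stats, c1, c2 = make_two_sample_pair(sim, seeds,
                                                        return_cohorts=True)
    selected = ins.select_instruments(exp_stats, p_threshold=cfg.p_threshold)
    if selected.empty:
        raise ins.EmptyInstrumentSetError(
            f"{stage}: no genome-wide-significant instruments")
    iset = ins.retained(ins.harmonize(selected, out_stats))
    suite = mrmod.run_estimator_suite(iset, seed=sim.seed, n_boot=cfg.n_boot,
                                      n_simulations=cfg.n_simulations)
    family = []
    table = _method_table("forward", suite, family)

    # experiment-level FDR within this stage's family of method tests
    pvec = [p for (_, _, p) in family]
    qvec = bh_fdr(np.array(pvec))
    qmap = {m: q for (_, m, _), q in zip(family, qvec)}
    egger_q = suite["egger"].extras["intercept_p"]
    verdict = mrmod.triangulate({m: suite[m] for m in mrmod.TRIANGULATION_METHODS},
                                qmap, egger_q)
    table["q"] = table["method"].map(qmap)

    # one-sample companion on the exposure cohort with external truth weights
    grs = ins.compute_grs(c1.dosages[:, c1.truth.exposure_block], c1.truth.gamma)
    one = tsls(c1, "exposure", "outcome", grs, cfg.mr_covariates,
               n_boot=cfg.n_boot, seed=sim.seed + 11)
    obs = observational_assoc(c1, "exposure", "outcome", cfg.obs_covariates)
    extra = pd.DataFrame([
        {"pair": "forward", "method": "one_sample_2sls", "beta": one.beta,
         "se": one.se, "ci_low": one.ci95[0], "ci_high": one.ci95[1],
         "p": one.p, "n_snps": len(iset), "q": np.nan},
        {"pair": "forward", "method": "observational", "beta": obs.estimate,
         "se": obs.se, "ci_low": np.nan, "ci_high": np.nan, "p": obs.p,
         "n_snps": np.nan, "q": np.nan},
    ])
    table = pd.concat([table, extra], ignore_index=True)

    # sensitivity re-runs after exclusion filters
    sens = selected
    if cfg.sensitivity_regions:
        genes = pd.DataFrame([{"chrom": c, "start": s, "end": e}
                              for c, s, e in cfg.sensitivity_regions])
        sens = ins.exclude_by_region(sens, genes)
    if cfg.sensitivity_blocklist:
        sens = ins.exclude_by_id(sens, cfg.sensitivity_blocklist)
    if len(sens) >= 2:
        sens_iset = ins.retained(ins.harmonize(sens, out_stats))
        sens_ivw = mrmod.ivw(sens_iset)
        table = pd.concat([table, pd.DataFrame([{
            "pair": "forward_sensitivity", "method": "ivw", "beta": sens_ivw.beta,
            "se": sens_ivw.se, "ci_low": sens_ivw.ci95[0],
            "ci_high": sens_ivw.ci95[1], "p": sens_ivw.p,
            "n_snps": sens_ivw.n_snps, "q": np.nan}])], ignore_index=True)

    # reverse direction: instrument the outcome trait, estimate outcome->exposure
    rev_sel = ins.select_instruments(out_stats, p_threshold=cfg.p_threshold)
    if len(rev_sel) >= 2:
        rev_iset = ins.retained(ins.harmonize(rev_sel, exp_stats))
        rev = mrmod.ivw(rev_iset)
        rev_row = {"pair": "reverse", "method": "ivw", "beta": rev.beta,
                   "se": rev.se, "ci_low": rev.ci95[0], "ci_high": rev.ci95[1],
                   "p": rev.p, "n_snps": rev.n_snps, "q": np.nan}
    else:
        rev_row = {"pair": "reverse", "method": "ivw", "beta": np.nan,
                   "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "p": np.nan, "n_snps": len(rev_sel), "q": np.nan}
    table = pd.concat([table, pd.DataFrame([rev_row])], ignore_index=True)

    report.tables[stage] = table
    report.verdicts[stage] = {
        "causal": verdict.causal,
        "n_significant_concordant": verdict.n_significant_concordant,
        "egger_intercept_ok": verdict.egger_intercept_ok,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the four-stage synthetic study and collect every table."""
    import renalmr

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    report = StudyReport(config=asdict(config),
                         seeds={f"stage{i + 1}": s
                                for i, s in enumerate(stage_seeds[:4])},
                         versions={"renalmr": renalmr.__version__,
                                   "numpy": np.__version__,
                                   "pandas": pd.__version__})

    base = dict(n_individuals=config.n_per_sample, n_snps=config.n_snps,
                maf_range=config.maf_range, h2_exposure=config.h2_exposure,
                confounder_effects=config.confounder_effects)

    stages = {
        "stage1_biomarker": SimulationConfig(
            **base, beta_causal=config.beta_biomarker, seed=stage_seeds[0]),
        "stage2_index": SimulationConfig(
            **base, beta_causal=config.beta_index, outcome_type="binary",
            baseline_prevalence=config.index_prevalence, seed=stage_seeds[1]),
        "stage3_disease": SimulationConfig(
            **base, beta_causal=config.beta_disease, outcome_type="binary",
            baseline_prevalence=config.disease_prevalence, seed=stage_seeds[2]),
    }
    for name, sim in stages.items():
        try:
            _two_sample_stage(config, sim,
                              (sim.seed + 1, sim.seed + 2), name, report)
        except Exception as exc:
            report.failures[name] = f"{type(exc).__name__}: {exc}"

    # stage 4: mediation of the index effect through BP and a T2D liability
    try:
        a_bp, b_bp = config.mediator_bp
        a_t2d, b_t2d = config.mediator_t2d
        sim4 = SimulationConfig(
            **base, beta_causal=config.mediation_direct,
            mediators=(MediatorSpec("bp", a_bp, b_bp),
                       MediatorSpec("t2d_liability", a_t2d, b_t2d)),
            seed=stage_seeds[3])
        cohort = simulate_cohort(sim4)
        t = cohort.truth
        scores = {"exposure": ins.compute_grs(
            cohort.dosages[:, t.exposure_block], t.gamma)}
        for m in ("bp", "t2d_liability"):
            scores[m] = ins.compute_grs(cohort.dosages[:, t.mediator_blocks[m]],
                                        t.mediator_gammas[m])
        rows = []
        for label, meds in (("bp_only", ["bp"]),
                            ("t2d_only", ["t2d_liability"]),
                            ("bp_and_t2d", ["bp", "t2d_liability"])):
            res = mediation_decompose(cohort, "exposure", meds, "outcome",
                                      scores, cfg_covariates(config),
                                      n_boot=config.n_boot,
                                      seed=stage_seeds[3] + 7)
            rows.append({"mediator_set": label, "total": res.total,
                         "direct": res.direct, "indirect": res.indirect,
                         "proportion": res.proportion,
                         "prop_ci_low": res.bootstrap["ci95"][0],
                         "prop_ci_high": res.bootstrap["ci95"][1],
                         "prop_se": res.bootstrap["se"],
                         "scale": res.outcome_scale})
        report.tables["stage4_mediation"] = pd.DataFrame(rows)
    except Exception as exc:
        report.failures["stage4_mediation"] = f"{type(exc).__name__}: {exc}"

    # phenome scan companion on a biomarker-bearing cohort
    try:
        from .phenotypes import build_index_table

        sim_scan = SimulationConfig(
            n_individuals=min(config.n_per_sample, 3000), n_snps=10,
            maf_range=config.maf_range, h2_exposure=0.1,
            beta_causal=config.beta_biomarker, with_biomarkers=True,
            seed=stage_seeds[4])
        scan_cohort = simulate_cohort(sim_scan)
        index = build_index_table(scan_cohort.biomarkers,
                                  scan_cohort.icd_codes).to_numpy()
        traits = _synthetic_trait_table(scan_cohort, stage_seeds[4] + 1)
        scan = phenome_scan(scan_cohort, index, traits,
                            covariate_names=config.obs_covariates)
        report.tables["phenome_scan"] = scan
    except Exception as exc:
        report.failures["phenome_scan"] = f"{type(exc).__name__}: {exc}"

    return report


def cfg_covariates(config: StudyConfig) -> tuple:
    return config.mr_covariates


def _synthetic_trait_table(cohort, seed: int) -> pd.DataFrame:
    """Binary trait panel: a few tied to renal biomarkers, the rest noise."""
    rng = np.random.default_rng(seed)
    n = cohort.n
    b = cohort.biomarkers
    damage = (np.log(b["uacr"]) - np.log(b["uacr"]).mean()) / np.log(b["uacr"]).std()
    traits = {}
    for i, shift in enumerate((1.2, 0.9)):
        traits[f"renal_trait_{i + 1}"] = (
            rng.random(n) < expit(-1.8 + shift * damage)).astype(int)
    for i in range(6):
        prev = rng.uniform(0.04, 0.25)
        traits[f"independent_trait_{i + 1}"] = (rng.random(n) < prev).astype(int)
    traits["rare_trait"] = (rng.random(n) < 0.01).astype(int)
    return pd.DataFrame(traits)


def main_run_study(config_path: str | None, outdir: str, seed: int | None) -> int:
    """Shell entry: returns process exit code (0 ok, 2 validation, 3 stage)."""
    from .io import load_config

    try:
        cfg = StudyConfig.from_dict(load_config(config_path)) if config_path \
            else StudyConfig()
        if seed is not None:
            cfg.seed = seed
        cfg.validate()
    except (ValueError, TypeError, OSError) as exc:
        print(f"configuration error: {exc}", file=sys.stderr)
        return EXIT_VALIDATION
    report = run_study(cfg)
    report.to_dir(outdir)
    if not report.ok:
        for stage, err in report.failures.items():
            print(f"stage failure [{stage}]: {err}", file=sys.stderr)
        return EXIT_STAGE_FAILURE
    return EXIT_OK
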