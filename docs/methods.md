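# Methods

This note records the models, numerical choices and known limitations of
`renalmr`, in the spirit of the methods documentation that simulation and
statistics packages ship alongside their APIs. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohorts

Genotypes are independent bi-allelic SNPs, `g_j ~ Binomial(2, p_j)` with
`p_j ~ Uniform(maf_range)` (default 0.05–0.5), i.e. Hardy–Weinberg
equilibrium and no LD. This matches the intended use: instrument panels
are LD-pruned by construction (r² < 0.01 in the motivating analyses), so
modelling LD would add cost without changing what the estimators see.
Dosages are centred at their theoretical mean `2p_j` when effects are
applied, so structural intercepts are zero.

Instrument effects `γ_j` are drawn standard-normal and rescaled so that
`Σ γ_j² · 2p_j(1−p_j) = h²`; the exposure is
`X = Σ γ_j g_j + q_x U + ε_x` with residual variance chosen so
`Var(X) = 1`. The confounder is a single standard-normal latent — enough
to induce observational bias, which is all the pipeline needs from it.
`h²` has no default taken from any published panel; it is a user choice
(see "scaling" below).

Each mediator gets its **own** block of instrument SNPs
(`M_k = a_k X + GRS_k + ε`, `Var(M_k) = 1`). Without mediator-specific
instruments the fitted exposures in multivariable models would be
collinear and the direct/indirect decomposition unidentified — the same
reason the motivating design uses separate blood-pressure and diabetes
score GWAS.

Pleiotropic direct effects `α_j` apply to a random invalid subset of the
exposure instruments. `α` is drawn `Normal(mean_direct, sd_direct)` and
**aligned with each SNP's exposure-increasing allele** (multiplied by
`sign(γ_j)`): with signed instrument effects, an orientation-blind
constant-mean `α` cancels in the ratio estimates and is effectively
balanced, which is not what directional pleiotropy means. Under the
InSiDE-violation flag, `α_j` is instead made proportional to `γ_j`, which
is precisely the correlation the Egger intercept test assumes away.

Binary outcomes use a logistic link on the structural linear predictor
with the intercept solved numerically (Brent) to hit the requested
prevalence, so reported effects for binary outcomes are conditional
log-odds (exponentiated to ORs in results). Continuous outcomes receive
residual noise targeting unit variance, floored at variance 0.05 when the
structural part already explains more.

The optional biomarker panel ties serum creatinine, cystatin C, BUN, uACR
and kidney ICD-10 codes to a latent renal-damage variable correlated with
the outcome liability, with log-normal measurement noise and plausible
central values (creatinine ~62 µmol/L, cystatin ~0.85 mg/L, BUN
~5 mmol/L, uACR ~0.8 mg/mmol, sex and age shifts). It gives the index
builder realistic joint structure; it does **not** model assay batch
effects, medication, or longitudinal drift, so index prevalences are
illustrative, not calibrated to any population.

Everything is a pure function of `(config, seed)` via
`numpy.random.SeedSequence` spawning; the two-sample generator shares one
realized truth (MAFs, γ, α) between two disjoint cohorts and rejects
identical seeds as a sample-overlap violation.

## Phenotypes

eGFR uses the CKD-EPI 2009 creatinine and 2012 cystatin/combined
equations without a race term — the standard choice for biobank-era
analyses. Creatinine is stored in µmol/L and converted internally
(÷ 88.4); file readers require an explicit units row and accept mg/dL.

The kidney health index is a conjunction over evaluable components with
reconstructed default thresholds: all three eGFRs ≥ 60 mL/min/1.73 m²,
BUN in 2.5–7.8 mmol/L, uACR < 3 mg/mmol, no ICD-10 code with prefix
N00–N29 (case-insensitive prefix match, dot ignored). All are
configurable; the defaults are conventional clinical cut-offs standing in
for a study-specific supplementary definition and should be treated as
such. Missing components are excluded from the conjunction and recorded;
a strict mode rejects incomplete records instead.

## Instruments

Selection keeps `p < 5e-8` (strict) and prunes greedily from smallest p,
dropping neighbours with r² ≥ 0.01 when an LD provider is supplied, else
within a 1 Mb window on the same chromosome (flagged, since no reference
panel ships with the package). Output is independent of input row order
(p, then SNP id, as the sort key). Gene-region exclusion uses closed
intervals, 1-based, ± 500 kb by default. Harmonization resolves swapped
and strand-complement codings, drops irreconcilable pairs, and aligns
palindromic SNPs by allele frequency, dropping them inside the ambiguity
band (default eaf 0.42–0.58, the common practice). Block jack-knife
scores shuffle individuals with a seeded permutation, split into 10
contiguous blocks by default, and compute each block's per-SNP weights by
GWAS on the complement, so no individual informs their own weights.

## Estimators

Ratio estimates use first-order weights `w_j = β_Xj²/σ_Yj²` throughout;
exposure-side uncertainty is ignored (the no-measurement-error
convention), which is accurate for strong instruments and is the reason
the validation experiments fix per-instrument strength (below).

- **IVW** defaults to multiplicative random effects
  (`se × √max(1, Q/(J−1))`, normal reference); the fixed-effect SE is
  reported alongside. The floor at 1 means homogeneous data are treated
  as fixed-effect.
- **MR-Egger** orients records so all `β_Xj > 0`, fits weighted least
  squares with intercept, uses a t reference with J−2 df and the same
  dispersion floor. The intercept, its SE and p form the
  directional-pleiotropy test.
- **Weighted median** interpolates the inverse-variance-weighted CDF of
  ordered ratios at probability 0.5 using `p_j = (S_j − w_j/2)/S_J`; SE by
  parametric bootstrap (default 1000 draws, seeded).
- **Radial IVW** is the origin regression of `β_j√w_j` on `√w_j`
  (algebraically the IVW slope under these weights); per-SNP
  `Q_j = w_j(β_j − β̂)²` referred to χ²(1) with Bonferroni-adjusted
  outlier flags, and an outlier-excluded re-estimate.
- **Outlier simulation test**: observed global RSS around leave-one-out
  IVW predictions; null distribution from `β*_Yj ~ N(β̂_(−j)β_Xj, σ_Yj)`
  (default 1000 simulations); per-SNP empirical p-values
  Bonferroni-adjusted; distortion p from removing random same-size
  subsets. Empirical p-values have floor `1/(n_sim+1)`, so outlier
  detection requires `n_sim > J/α` — with 30 SNPs at α = 0.05 that means
  at least ~600 simulations; the default 1000 respects this.
- **2SLS / MVMR**: continuous outcomes use the standard IV estimator
  (via statsmodels) with IV-consistent SEs; binary outcomes use predictor
  substitution (logistic on stage-1 fitted exposures) with seeded
  nonparametric bootstrap SEs, and all binary-outcome effects live on the
  log-odds scale — results carry a non-collapsibility note because
  log-odds effects are not collapsible across adjustment sets. First-stage
  F < 10 raises a weak-instrument flag, not an error. MVMR reports a
  conditional instrument-strength F per exposure (instrument F for the
  part of each exposure orthogonal to the other fitted exposures) and
  rejects collinear fitted exposures (condition number > 1e8).
- **Mediation**: total from univariable 2SLS, direct from MVMR including
  the mediators, `indirect = total − direct` (asserted exactly on every
  run), proportion undefined-and-flagged when |total| is below tolerance.
  Percentile bootstrap CIs over individual resamples (default 1000,
  tests use 200). A binary mediator should be supplied as its continuous
  liability proxy; 2SLS on a dichotomized mediator is ill-posed.

The triangulation rule takes experiment-level BH-FDR q-values over the
four estimator p-values within one family of tests (never across
unrelated stages), requires ≥ 3 of 4 significant with sign-concordant
estimates and an Egger-intercept q ≥ 0.05, and returns *undetermined*
(not false) when a method is missing.

## Scaling of the validation experiments

The Monte-Carlo experiments (`renalmr.experiments`, used by both the test
suite and the acceptance script) run at reduced sizes chosen on one
principle: **preserve per-instrument strength** (mean instrument
chi-square `n·h²/J ≈ 120`, the scale of consortium-derived obesity
panels) while shrinking cohorts. Two findings motivate this and are
reproducible with the package:

- With weak instruments the first-order weights understate ratio
  variance: at per-SNP F ≈ 20 the multiplicative-RE IVW null rejection
  rate roughly doubles; at F ≈ 120 it is nominal.
- Equal-sized exposure and outcome samples leave a regression dilution of
  order `J/(n·h²)` in every ratio estimator (estimated exposure betas in
  the denominator). The recovery experiment therefore pairs a
  consortium-scale exposure sample (n = 100 000) with the 20 000-person
  outcome sample, mirroring the asymmetric two-sample designs the method
  is used in; the residual bias is then an order of magnitude below the
  Monte-Carlo resolution of the experiment.

The null-calibration experiment uses balanced pleiotropy on a 30% invalid
subset sized to moderate heterogeneity (Q/df ≈ 2, I² ≈ 50%), the regime
typical of real instrument panels. Two boundary behaviours are worth
knowing: with extreme subset heterogeneity (I² ≳ 90%) the Egger residuals
become a pronounced scale mixture and the intercept p is detectably
non-uniform under a KS test; with balanced pleiotropy on *all*
instruments the additive heterogeneity conflicts with the multiplicative
dispersion model and IVW over-rejects (~8% at nominal 5%). Both are
properties of the standard estimators, not of this implementation.

## What passing tests do and do not show

The generator draws independent SNPs, Gaussian effect sizes, a single
confounder and homoscedastic noise. Passing recovery/coverage/robustness
tests therefore demonstrates correctness of the estimators and pipeline
under the stated structural model — not performance under LD leakage,
population stratification, assortative mating, selection bias,
time-varying exposures or winner's-curse instrument selection (the
experiments feed the full simulated panel as instruments, emulating
externally validated scores; selection-induced bias is deliberately out
of scope). Effect sizes are reported in SD units internally; converting
to "per 5 kg/m²"-style units is a reporting-layer multiplication by
configured trait SDs.

## Degenerate inputs and tie-breaks

Monomorphic SNPs yield NaN GWAS rows and are excluded downstream;
constant traits and constant instruments are rejected; a single
instrument is rejected by IVW unless explicitly allowed (then it reduces
to the Wald ratio); `β_X = 0` rejects the Wald ratio. p-values are
clipped away from zero so FDR machinery never sees p = 0. Selection ties
on p are broken by SNP id to keep pruning order-invariant. Bootstrap
replicates that fail to converge are dropped (counted in `n_valid`);
percentile CIs require at least 50 valid replicates.
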