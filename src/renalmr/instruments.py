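"""Genetic instrument engineering.

Selection of genome-wide-significant, approximately independent SNPs;
exclusion filters (biomarker-metabolism gene regions, blocklisted ids);
exposure/outcome allele harmonization; genetic risk scores; and block
jack-knife internal GWAS weights for one-sample MR without overlap bias.

Summary statistics travel as pandas DataFrames with the tab-separated
header ``snp chr pos ea oa eaf beta se p n``.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "validate_summary_stats",
    "select_instruments",
    "exclude_by_region",
    "exclude_by_id",
    "harmonize",
    "retained",
    "compute_grs",
    "blockjackknife_weights",
    "EmptyInstrumentSetError",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = set("ACGT")


class EmptyInstrumentSetError(ValueError):
    """Raised downstream when instrument selection produced no usable SNPs."""


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    required = {"snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns {sorted(missing)}")
    return stats


def _drop_undefined(stats: pd.DataFrame) -> pd.DataFrame:
    ok = np.isfinite(stats["beta"]) & np.isfinite(stats["se"]) & (stats["se"] > 0)
    dropped = int((~ok).sum())
    if dropped:
        log.info("dropping %d SNPs with undefined beta/se", dropped)
    return stats[ok]


def select_instruments(stats: pd.DataFrame, p_threshold: float = 5e-8,
                       ld_provider: Callable[[str, str], float] | None = None,
                       r2_threshold: float = 0.01,
                       distance_window: int = 1_000_000) -> pd.DataFrame:
    """Genome-wide significance filtering plus greedy LD/distance pruning.

    Keeps SNPs with p < ``p_threshold``; then walks the survivors from
    smallest p upward, retaining each SNP unless it has pairwise r2 >=
    ``r2_threshold`` with an already-retained SNP (via ``ld_provider``), or
    — when no LD provider is available — lies within ``distance_window`` bp
    of one on the same chromosome.  The result is independent of input
    record order (ties broken by snp id).
    """
    validate_summary_stats(stats)
    if stats.empty:
        raise ValueError("empty summary statistics")
    cand = _drop_undefined(stats)
    cand = cand[cand["p"] < p_threshold]
    if cand.empty:
        log.warning("no SNPs pass p < %g; downstream MR will fail", p_threshold)
        return cand.reset_index(drop=True)
    if ld_provider is None:
        log.info("no LD provider: distance-based pruning at %d bp", distance_window)

    cand = cand.sort_values(["p", "snp"], kind="mergesort")
    kept_rows = []
    for _, row in cand.iterrows():
        independent = True
        for kept in kept_rows:
            if ld_provider is not None:
                if ld_provider(kept["snp"], row["snp"]) >= r2_threshold:
                    independent = False
                    break
            elif (kept["chr"] == row["chr"]
                  and abs(int(kept["pos"]) - int(row["pos"])) <= distance_window):
                independent = False
                break
        if independent:
            kept_rows.append(row)
    out = pd.DataFrame(kept_rows).sort_values(["chr", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def exclude_by_region(stats: pd.DataFrame, genes: pd.DataFrame,
                      window: int = 500_000,
                      return_removed: bool = False):
    """Remove SNPs within ``window`` bp of any gene (closed interval, 1-based).

    ``genes`` needs columns ``chrom``, ``start``, ``end`` (and may carry a
    ``build`` column on both tables; a declared mismatch is rejected).
    """
    validate_summary_stats(stats)
    if "build" in stats.columns and "build" in genes.columns:
        b1, b2 = set(stats["build"].unique()), set(genes["build"].unique())
        if b1 != b2:
            raise ValueError(f"genome build mismatch: {sorted(b1)} vs {sorted(b2)}")
    remove = np.zeros(len(stats), dtype=bool)
    chrom = stats["chr"].astype(str).to_numpy()
    pos = stats["pos"].to_numpy()
    for _, g in genes.iterrows():
        lo, hi = int(g["start"]) - window, int(g["end"]) + window
        remove |= (chrom == str(g["chrom"])) & (pos >= lo) & (pos <= hi)
    removed = stats[remove]
    for snp in removed["snp"]:
        log.info("region filter removed %s", snp)
    kept = stats[~remove].reset_index(drop=True)
    if return_removed:
        return kept, removed.reset_index(drop=True)
    return kept


def exclude_by_id(stats: pd.DataFrame, blocklist: Sequence[str]) -> pd.DataFrame:
    """Remove SNPs whose id is blocklisted; unknown ids are logged and ignored."""
    validate_summary_stats(stats)
    block = set(blocklist)
    unknown = block - set(stats["snp"])
    if unknown:
        log.info("blocklist ids not present: %s", sorted(unknown))
    return stats[~stats["snp"].isin(block)].reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Per joined SNP the action is one of ``kept`` (same orientation, possibly
    after an unambiguous strand flip), ``flipped`` (alleles swapped: outcome
    beta negated, eaf complemented), ``dropped_palindromic`` (A/T or C/G SNP
    with exposure or outcome allele frequency inside the ambiguity band) or
    ``dropped_mismatch`` (irreconcilable allele pairs).  All actions are
    recorded in the returned table; use :func:`retained` for the usable rows.
    """
    validate_summary_stats(exposure)
    validate_summary_stats(outcome)
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise EmptyInstrumentSetError("no SNPs shared between exposure and outcome")
    lo, hi = palindrome_eaf_band

    rows = []
    for _, r in merged.iterrows():
        e1, o1 = str(r["ea_exp"]).upper(), str(r["oa_exp"]).upper()
        e2, o2 = str(r["ea_out"]).upper(), str(r["oa_out"]).upper()
        beta_out, eaf_out = r["beta_out"], r["eaf_out"]
        action = None
        if not ({e1, o1} <= _VALID_ALLELES and {e2, o2} <= _VALID_ALLELES):
            action = "dropped_mismatch"
        elif _is_palindromic(e1, o1):
            ambiguous = (lo <= r["eaf_exp"] <= hi) or (lo <= eaf_out <= hi)
            if {e2, o2} != {e1, o1}:
                action = "dropped_mismatch"
            elif ambiguous:
                action = "dropped_palindromic"
            else:
                # strand is unknowable for palindromes, so orient by allele
                # frequency: same side of 0.5 means the same allele is counted
                same_side = (r["eaf_exp"] - 0.5) * (eaf_out - 0.5) > 0
                action = "kept" if same_side else "flipped"
                if action == "flipped":
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        else:
            ce2, co2 = _COMPLEMENT[e2], _COMPLEMENT[o2]
            if (e2, o2) == (e1, o1) or (ce2, co2) == (e1, o1):
                action = "kept"
            elif (e2, o2) == (o1, e1) or (ce2, co2) == (o1, e1):
                action = "flipped"
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            else:
                action = "dropped_mismatch"
        rows.append({
            "snp": r["snp"], "chr": r["chr_exp"], "pos": r["pos_exp"],
            "ea": e1, "oa": o1, "eaf": r["eaf_exp"],
            "beta_exposure": r["beta_exp"], "se_exposure": r["se_exp"],
            "p_exposure": r["p_exp"], "n_exposure": r["n_exp"],
            "beta_outcome": beta_out, "se_outcome": r["se_out"],
            "p_outcome": r["p_out"], "n_outcome": r["n_out"],
            "eaf_outcome": eaf_out,
            "harmonization_action": action,
        })
    out = pd.DataFrame(rows)
    if out["snp"].duplicated().any():
        raise ValueError("duplicate snp ids after join")
    return out


def retained(instrument_set: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized set usable for estimation."""
    keep = instrument_set["harmonization_action"].isin(["kept", "flipped"])
    out = instrument_set[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInstrumentSetError("no instruments retained after harmonization")
    return out


def compute_grs(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted allele score per individual: score_i = sum_j w_j dosage_ij.

    Missing dosages (NaN) are mean-imputed per SNP; an all-missing SNP is
    rejected.
    """
    D = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if D.shape[1] != w.size:
        raise ValueError("weight length does not match number of SNPs")
    if np.isnan(D).any():
        all_missing = np.all(np.isnan(D), axis=0)
        if all_missing.any():
            raise ValueError(f"all-missing dosage column(s) {np.where(all_missing)[0]}")
        col_means = np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D = D.copy()
        D[idx] = np.take(col_means, idx[1])
        log.info("mean-imputed %d missing dosages", len(idx[0]))
    return D @ w


def blockjackknife_weights(cohort, trait: str, n_blocks: int = 10,
                           covariate_names: Sequence[str] = (),
                           seed: int = 0,
                           snp_subset: np.ndarray | None = None) -> np.ndarray:
    """Leave-block-out genetic score: no individual informs their own weights.

    Individuals are shuffled (seeded) and split into ``n_blocks`` contiguous
    blocks; per-SNP GWAS weights for block b come from all individuals NOT
    in b, and b's scores use those weights.
    """
    from .simulate import Cohort

    n = cohort.n
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > n:
        raise ValueError("n_blocks exceeds number of individuals")
    cols = snp_subset if snp_subset is not None else np.arange(cohort.dosages.shape[1])

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blocks = np.array_split(order, n_blocks)

    scores = np.empty(n)
    for block in blocks:
        mask = np.ones(n, dtype=bool)
        mask[block] = False
        sub = Cohort(
            dosages=cohort.dosages[mask][:, cols],
            exposure=cohort.exposure[mask],
            mediators=cohort.mediators.iloc[mask].reset_index(drop=True),
            outcome=np.asarray(cohort.outcome)[mask],
            covariates=cohort.covariates.iloc[mask].reset_index(drop=True),
            truth=cohort.truth,
        )
        y = sub.trait(trait)
        stats = _loo_gwas(sub, y, covariate_names)
        w = np.nan_to_num(stats, nan=0.0)
        scores[block] = cohort.dosages[np.ix_(block, cols)] @ w
    return scores


def _loo_gwas(sub, y, covariate_names) -> np.ndarray:
    """Per-SNP linear GWAS betas on a sub-cohort (weights for scoring)."""
    from .simulate import _residualize

    n, J = sub.dosages.shape
    C = np.column_stack([np.ones(n)] +
                        [sub.covariates[c].to_numpy() for c in covariate_names])
    Gr = _residualize(sub.dosages, C)
    yr = _residualize(y.astype(float), C)
    gtg = np.einsum("ij,ij->j", Gr, Gr)
    beta = np.full(J, np.nan)
    ok = gtg > 0
    beta[ok] = (Gr[:, ok].T @ yr) / gtg[ok]
    return beta
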