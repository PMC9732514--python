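import numpy as np
import pandas as pd
import pytest

from renalmr.simulate import SUMMARY_COLUMNS


def summary_table(snp, chrom, pos, ea, oa, eaf, beta, se, p, n):
    """Hand-built summary-statistics table with the standard header."""
    return pd.DataFrame(dict(zip(SUMMARY_COLUMNS,
                                 [snp, chrom, pos, ea, oa, eaf, beta, se, p, n])))


def instrument_frame(beta_exposure, se_exposure, beta_outcome, se_outcome):
    """Minimal harmonized instrument set for the estimators."""
    J = len(beta_exposure)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(J)],
        "beta_exposure": beta_exposure, "se_exposure": se_exposure,
        "beta_outcome": beta_outcome, "se_outcome": se_outcome,
        "eaf": np.full(J, 0.3),
        "harmonization_action": ["kept"] * J,
    })


def simulate_instrument_summary(rng, J=30, beta=0.3, gamma_mean=0.08,
                                se_x=0.01, se_y=0.015, alpha=None):
    """Summary-level two-sample draw: true gamma, noisy betaX/betaY."""
    gamma = np.abs(rng.normal(gamma_mean, 0.02, size=J)) + 0.01
    direct = np.zeros(J) if alpha is None else alpha
    bx = rng.normal(gamma, se_x)
    by = rng.normal(beta * gamma + direct, se_y)
    return instrument_frame(bx, np.full(J, se_x), by, np.full(J, se_y))


@pytest.fixture(scope="session")
def small_cohort():
    from renalmr.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_individuals=4000, n_snps=30, h2_exposure=0.3,
                           beta_causal=0.3, confounder_effects=(0.3, 0.3),
                           seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def biomarker_cohort():
    from renalmr.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_individuals=3000, n_snps=10, h2_exposure=0.1,
                           beta_causal=-0.3, with_biomarkers=True, seed=21)
    return simulate_cohort(cfg)
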