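"""Two-sample MR estimators against closed-form oracles and planted truths."""

import numpy as np
import pytest
from scipy import stats as sps

from renalmr.mr import (MREstimate, egger, ivw, mr_presso, radial_ivw,
                        triangulate, wald_ratio, weighted_median)

from conftest import instrument_frame, simulate_instrument_summary


class TestWaldRatio:
    def test_direct_ratio(self):
        est = wald_ratio(0.5, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.5, 0.01, 0.0, 0.02).beta == 0.0

    def test_delta_method_oracle(self):
        bx, sx, by, sy = 0.37, 0.02, -0.12, 0.03
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(by / bx)
        assert est.se == pytest.approx(sy / abs(bx))
        assert est.p == pytest.approx(2 * sps.norm.sf(abs(by / bx) / (sy / abs(bx))))

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_degenerate_homogeneity(self):
        bx = np.array([0.1, 0.2, 0.4])
        iset = instrument_frame(bx, 0.01 * np.ones(3), 0.25 * bx,
                                [0.01, 0.02, 0.03])
        est = ivw(iset)
        assert est.beta == pytest.approx(0.25)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_two_instrument_hand_computation(self):
        iset = instrument_frame([0.1, 0.2], [0.01, 0.01], [0.03, 0.05],
                                [0.02, 0.01])
        w = np.array([0.1 ** 2 / 0.02 ** 2, 0.2 ** 2 / 0.01 ** 2])
        ratios = np.array([0.3, 0.25])
        expect = (w * ratios).sum() / w.sum()
        est = ivw(iset, model="fixed")
        assert est.beta == pytest.approx(expect, rel=1e-12)
        assert est.se == pytest.approx(w.sum() ** -0.5, rel=1e-12)

    def test_single_instrument_reduction(self):
        iset = instrument_frame([0.2], [0.01], [0.05], [0.02])
        est = ivw(iset, allow_single=True)
        ref = wald_ratio(0.2, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)
        with pytest.raises(ValueError):
            ivw(iset)

    def test_random_effects_never_tighter_than_fixed(self):
        rng = np.random.default_rng(3)
        iset = simulate_instrument_summary(rng, J=20, beta=0.3,
                                           alpha=rng.normal(0, 0.02, 20))
        fixed, rand = ivw(iset, model="fixed"), ivw(iset)
        assert rand.se >= fixed.se
        assert rand.beta == pytest.approx(fixed.beta)

    def test_matches_wls_oracle_on_random_instances(self):
        """Fixed-effect IVW equals weighted least squares through the origin."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(25):
            J = rng.integers(2, 7)
            bx = rng.normal(0.1, 0.05, J)
            bx[bx == 0] = 0.01
            by = rng.normal(0.0, 0.1, J)
            sy = rng.uniform(0.01, 0.1, J)
            iset = instrument_frame(bx, np.full(J, 0.01), by, sy)
            oracle = sm.WLS(by, bx[:, None], weights=1 / sy ** 2).fit()
            est = ivw(iset, model="fixed")
            assert est.beta == pytest.approx(oracle.params[0], rel=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        iset = instrument_frame(bx, 0.01 * np.ones(4), 0.02 + 0.3 * bx,
                                [0.01, 0.02, 0.03, 0.01])
        est = egger(iset)
        assert est.beta == pytest.approx(0.3, rel=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.02, rel=1e-10)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-18)

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            egger(instrument_frame([0.1, 0.2], [0.01] * 2, [0.03, 0.06],
                                   [0.01] * 2))

    def test_orientation_invariance(self):
        """Flipping an instrument's allele coding leaves Egger unchanged."""
        rng = np.random.default_rng(5)
        iset = simulate_instrument_summary(rng, J=10, beta=0.3)
        flipped = iset.copy()
        flipped.loc[3, "beta_exposure"] *= -1
        flipped.loc[3, "beta_outcome"] *= -1
        a, b = egger(iset), egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"])

    def test_intercept_null_p_uniform_under_balanced_pleiotropy(self):
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(200):
            alpha = rng.normal(0.0, 0.02, 25)       # balanced, InSiDE holds
            iset = simulate_instrument_summary(rng, J=25, beta=0.3, alpha=alpha)
            ps.append(egger(iset).extras["intercept_p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_intercept_power_under_directional_pleiotropy(self):
        rng = np.random.default_rng(23)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            alpha = rng.normal(0.02, 0.005, 50)     # directional mean shift
            iset = simulate_instrument_summary(rng, J=50, beta=0.3, alpha=alpha,
                                               se_y=0.01)
            hits += egger(iset).extras["intercept_p"] < 0.05
        assert hits / n_rep > 0.8


class TestWeightedMedian:
    def test_equal_weight_odd_case(self):
        iset = instrument_frame([0.1, 0.1, 0.1], [0.01] * 3,
                                [0.01, 0.03, 0.09], [0.02] * 3)
        est = weighted_median(iset, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_constant_ratios_any_weights(self):
        iset = instrument_frame([0.1, 0.2, 0.4], [0.01] * 3,
                                [0.04, 0.08, 0.16], [0.05, 0.01, 0.02])
        assert weighted_median(iset, n_boot=200, seed=0).beta == pytest.approx(0.4)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        iset = simulate_instrument_summary(rng, J=15, beta=0.2)
        a = weighted_median(iset, n_boot=300, seed=5)
        b = weighted_median(iset, n_boot=300, seed=5)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_breakdown_resistance_vs_ivw(self):
        """40% invalid instruments: median stays near truth, IVW drifts."""
        rng = np.random.default_rng(13)
        med_err, ivw_err = [], []
        for _ in range(30):
            J = 30
            alpha = np.zeros(J)
            invalid = rng.choice(J, size=12, replace=False)
            alpha[invalid] = rng.normal(0.05, 0.01, 12)
            iset = simulate_instrument_summary(rng, J=J, beta=0.3, alpha=alpha,
                                               se_y=0.005)
            m = weighted_median(iset, n_boot=200, seed=1)
            med_err.append(abs(m.beta - 0.3))
            ivw_err.append(abs(ivw(iset).beta - 0.3))
        assert np.mean(med_err) < np.mean(ivw_err)
        assert np.median(med_err) < 3 * m.se


class TestRadial:
    def test_homogeneous_no_outliers(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        iset = instrument_frame(bx, 0.01 * np.ones(4), 0.3 * bx, [0.01] * 4)
        est = radial_ivw(iset)
        assert np.allclose(est.extras["q_contributions"], 0.0)
        assert est.extras["outlier_indices"] == []

    def test_slope_equals_ivw(self):
        rng = np.random.default_rng(29)
        iset = simulate_instrument_summary(rng, J=20, beta=0.25)
        assert radial_ivw(iset).beta == pytest.approx(ivw(iset).beta, rel=1e-12)

    def test_planted_outlier_recovered(self):
        rng = np.random.default_rng(31)
        iset = simulate_instrument_summary(rng, J=30, beta=0.3, se_y=0.01)
        k = 7
        iset.loc[k, "beta_outcome"] += 10 * iset.loc[k, "se_outcome"]
        est = radial_ivw(iset)
        assert est.extras["outlier_indices"] == [k]
        corrected = est.extras["beta_outlier_corrected"]
        assert abs(corrected - 0.3) < abs(est.beta - 0.3)


class TestPresso:
    def test_null_global_p_rarely_small(self):
        rng = np.random.default_rng(37)
        small = 0
        for rep in range(20):
            iset = simulate_instrument_summary(rng, J=20, beta=0.3)
            res = mr_presso(iset, n_simulations=300, seed=rep)
            small += res.global_p <= 0.05
        assert small <= 1    # >= 95% of seeded runs keep the null

    def test_planted_outlier_detected_and_corrected(self):
        rng = np.random.default_rng(41)
        iset = simulate_instrument_summary(rng, J=30, beta=0.3, se_y=0.01)
        k = 11
        iset.loc[k, "beta_outcome"] += 12 * iset.loc[k, "se_outcome"]
        # the empirical per-SNP p floor is 1/(n_sim+1); Bonferroni over J SNPs
        # needs n_sim > J/alpha for an outlier to be detectable at all
        res = mr_presso(iset, n_simulations=2000, seed=2)
        assert k in res.outlier_indices
        assert abs(res.beta_corrected.beta - 0.3) < abs(res.beta_raw.beta - 0.3)
        assert res.global_p < 0.05

    def test_seeded_determinism(self):
        rng = np.random.default_rng(43)
        iset = simulate_instrument_summary(rng, J=12, beta=0.1)
        a = mr_presso(iset, n_simulations=200, seed=9)
        b = mr_presso(iset, n_simulations=200, seed=9)
        assert a.global_rss == b.global_rss
        assert a.global_p == b.global_p
        assert np.array_equal(a.per_snp_outlier_p, b.per_snp_outlier_p)

    def test_validation(self):
        iset = instrument_frame([0.1, 0.2, 0.3], [0.01] * 3,
                                [0.03, 0.06, 0.09], [0.01] * 3)
        with pytest.raises(ValueError):
            mr_presso(iset)                       # < 4 instruments
        iset4 = instrument_frame([0.1, 0.2, 0.3, 0.4], [0.01] * 4,
                                 [0.03, 0.06, 0.09, 0.12], [0.01] * 4)
        with pytest.raises(ValueError):
            mr_presso(iset4, n_simulations=50)    # too few simulations


def _fake_estimates(signs):
    return {m: MREstimate(m, s * 0.3, 0.05, 1e-4, 10)
            for m, s in signs.items()}


class TestTriangulate:
    def test_all_significant_concordant(self):
        methods = ["ivw", "weighted_median", "radial_ivw", "presso"]
        ests = _fake_estimates({m: 1 for m in methods})
        v = triangulate(ests, {m: 0.001 for m in methods}, 0.5)
        assert v.causal is True

    def test_two_of_four_insufficient(self):
        methods = ["ivw", "weighted_median", "radial_ivw", "presso"]
        ests = _fake_estimates({m: 1 for m in methods})
        q = {"ivw": 0.001, "weighted_median": 0.001,
             "radial_ivw": 0.5, "presso": 0.5}
        assert triangulate(ests, q, 0.5).causal is False

    def test_pleiotropy_vetoes(self):
        methods = ["ivw", "weighted_median", "radial_ivw", "presso"]
        ests = _fake_estimates({m: 1 for m in methods})
        q = {m: 0.001 for m in methods}
        q["presso"] = 0.9
        assert triangulate(ests, q, 0.01).causal is False

    def test_sign_discordance_counts_majority_only(self):
        methods = ["ivw", "weighted_median", "radial_ivw", "presso"]
        ests = _fake_estimates({"ivw": 1, "weighted_median": 1,
                                "radial_ivw": 1, "presso": -1})
        v = triangulate(ests, {m: 0.001 for m in methods}, 0.5)
        assert v.n_significant_concordant == 3
        assert v.causal is True

    def test_missing_method_undetermined(self):
        ests = _fake_estimates({"ivw": 1, "weighted_median": 1})
        v = triangulate(ests, {"ivw": 0.001, "weighted_median": 0.001}, 0.5)
        assert v.causal is None
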