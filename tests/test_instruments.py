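"""Instrument selection, exclusion filters, harmonization, scores, jack-knife."""

import numpy as np
import pandas as pd
import pytest

from renalmr.instruments import (EmptyInstrumentSetError, blockjackknife_weights,
                                 compute_grs, exclude_by_id, exclude_by_region,
                                 harmonize, retained, select_instruments)
from renalmr.simulate import SimulationConfig, simulate_cohort

from conftest import summary_table


def _stats(n=10, p=None, chrom=None, pos=None, ea=None, oa=None, eaf=None):
    p = p if p is not None else np.full(n, 1e-9)
    return summary_table(
        snp=[f"rs{i}" for i in range(n)],
        chrom=chrom if chrom is not None else np.arange(1, n + 1),
        pos=pos if pos is not None else np.full(n, 5_000_000),
        ea=ea if ea is not None else ["A"] * n,
        oa=oa if oa is not None else ["C"] * n,
        eaf=eaf if eaf is not None else np.full(n, 0.3),
        beta=np.linspace(0.05, 0.2, n), se=np.full(n, 0.01),
        p=p, n=np.full(n, 10_000))


class TestSelectInstruments:
    def test_ld_greedy_keeps_smallest_p(self):
        stats = _stats(n=2, p=[1e-8, 1e-9], chrom=[1, 1], pos=[1e6, 9e6])
        out = select_instruments(stats, ld_provider=lambda a, b: 1.0)
        assert out["snp"].tolist() == ["rs1"]   # the 1e-9 SNP

    def test_all_above_threshold_gives_empty(self):
        out = select_instruments(_stats(n=4, p=[1e-5, 1e-6, 0.2, 0.9]))
        assert out.empty

    def test_independent_snps_all_kept_order_invariant(self):
        rng = np.random.default_rng(1)
        stats = _stats(n=10, p=rng.uniform(1e-12, 1e-9, 10))
        ref = select_instruments(stats)
        assert len(ref) == 10
        for seed in range(5):
            shuffled = stats.sample(frac=1, random_state=seed).reset_index(drop=True)
            out = select_instruments(shuffled)
            pd.testing.assert_frame_equal(
                out.sort_values("snp").reset_index(drop=True),
                ref.sort_values("snp").reset_index(drop=True))

    def test_distance_pruning_same_chromosome(self):
        stats = _stats(n=3, p=[1e-10, 1e-9, 1e-9], chrom=[1, 1, 2],
                       pos=[5_000_000, 5_400_000, 5_400_000])
        out = select_instruments(stats, distance_window=1_000_000)
        assert sorted(out["snp"]) == ["rs0", "rs2"]


class TestRegionAndIdFilters:
    def test_closed_interval_boundary_removed(self):
        stats = _stats(n=1, chrom=[7], pos=[4_500_000])
        genes = pd.DataFrame([{"chrom": 7, "start": 5_000_000, "end": 5_100_000}])
        assert exclude_by_region(stats, genes, window=500_000).empty

    def test_other_chromosome_kept(self):
        stats = _stats(n=1, chrom=[8], pos=[5_000_000])
        genes = pd.DataFrame([{"chrom": 7, "start": 5_000_000, "end": 5_100_000}])
        assert len(exclude_by_region(stats, genes, window=500_000)) == 1

    def test_hand_enumerated_survivors(self):
        stats = _stats(n=5, chrom=[1, 1, 1, 2, 1],
                       pos=[1_500_000, 2_000_000, 3_000_000, 2_000_000, 10_000_000])
        genes = pd.DataFrame([{"chrom": 1, "start": 1_900_000, "end": 2_100_000}])
        kept, removed = exclude_by_region(stats, genes, window=500_000,
                                          return_removed=True)
        # padded closed interval [1.4e6, 2.6e6] on chromosome 1
        assert sorted(kept["snp"]) == ["rs2", "rs3", "rs4"]
        assert sorted(removed["snp"]) == ["rs0", "rs1"]

    def test_build_mismatch_rejected(self):
        stats = _stats(n=2).assign(build="GRCh37")
        genes = pd.DataFrame([{"chrom": 1, "start": 1, "end": 2,
                               "build": "GRCh38"}])
        with pytest.raises(ValueError, match="build"):
            exclude_by_region(stats, genes)

    def test_exclude_by_id_variants(self):
        stats = _stats(n=4)
        assert exclude_by_id(stats, ["rs1", "rs3"])["snp"].tolist() == ["rs0", "rs2"]
        pd.testing.assert_frame_equal(exclude_by_id(stats, []), stats)
        pd.testing.assert_frame_equal(exclude_by_id(stats, ["rs1", "rs1"]),
                                      exclude_by_id(stats, ["rs1"]))
        # unknown ids are ignored
        assert len(exclude_by_id(stats, ["rs999"])) == 4

    def test_filters_commute(self):
        stats = _stats(n=6, chrom=[1] * 6,
                       pos=[1e6, 2e6, 3e6, 4e6, 5e6, 6e6])
        genes = pd.DataFrame([{"chrom": 1, "start": 1_900_000, "end": 2_100_000}])
        a = exclude_by_id(exclude_by_region(stats, genes), ["rs4"])
        b = exclude_by_region(exclude_by_id(stats, ["rs4"]), genes)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))


class TestHarmonize:
    def _pair(self, ea2, oa2, beta2=0.1, eaf1=0.3, eaf2=0.3):
        exp = summary_table(["rs1"], [1], [100], ["A"], ["C"], [eaf1],
                            [0.2], [0.01], [1e-9], [10000])
        out = summary_table(["rs1"], [1], [100], [ea2], [oa2], [eaf2],
                            [beta2], [0.02], [1e-4], [20000])
        return harmonize(exp, out)

    def test_swapped_alleles_flip_beta(self):
        h = self._pair("C", "A", beta2=0.1, eaf2=0.7)
        assert h.loc[0, "harmonization_action"] == "flipped"
        assert h.loc[0, "beta_outcome"] == pytest.approx(-0.1)
        assert h.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_palindromic_maximal_ambiguity_dropped(self):
        exp = summary_table(["rs1"], [1], [100], ["A"], ["T"], [0.5],
                            [0.2], [0.01], [1e-9], [10000])
        out = summary_table(["rs1"], [1], [100], ["A"], ["T"], [0.5],
                            [0.1], [0.02], [1e-4], [20000])
        h = harmonize(exp, out)
        assert h.loc[0, "harmonization_action"] == "dropped_palindromic"
        with pytest.raises(EmptyInstrumentSetError):
            retained(h)

    def test_six_snp_enumerated_actions(self):
        exp = summary_table(
            ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"], [1] * 6, range(6),
            ["A", "A", "A", "A", "A", "A"], ["C", "C", "C", "T", "T", "C"],
            [0.3, 0.3, 0.3, 0.2, 0.5, 0.3], [0.2] * 6, [0.01] * 6,
            [1e-9] * 6, [10000] * 6)
        out = summary_table(
            ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"], [1] * 6, range(6),
            ["A", "C", "T", "T", "A", "A"], ["C", "A", "G", "A", "T", "G"],
            [0.3, 0.7, 0.3, 0.8, 0.5, 0.3], [0.1] * 6, [0.02] * 6,
            [1e-4] * 6, [20000] * 6)
        h = harmonize(exp, out)
        assert h["harmonization_action"].tolist() == [
            "kept",                # same orientation
            "flipped",             # swapped alleles
            "kept",                # strand complement, same orientation
            "flipped",             # palindromic, frequencies on opposite sides
            "dropped_palindromic", # palindromic, ambiguous frequency
            "dropped_mismatch",    # A/C vs A/G irreconcilable
        ]
        assert h.loc[1, "beta_outcome"] == pytest.approx(-0.1)
        assert h.loc[3, "beta_outcome"] == pytest.approx(-0.1)

    def test_involution_on_harmonized_set(self):
        exp = summary_table(["rs1", "rs2"], [1, 1], [1, 2], ["A", "G"],
                            ["C", "T"], [0.3, 0.2], [0.2, 0.15], [0.01, 0.01],
                            [1e-9, 1e-9], [10000, 10000])
        out = summary_table(["rs1", "rs2"], [1, 1], [1, 2], ["C", "G"],
                            ["A", "T"], [0.7, 0.2], [0.1, 0.05], [0.02, 0.02],
                            [1e-4, 1e-3], [20000, 20000])
        h1 = retained(harmonize(exp, out))
        # express the harmonized outcome as a summary table and re-harmonize
        out2 = summary_table(h1["snp"], h1["chr"], h1["pos"], h1["ea"], h1["oa"],
                             h1["eaf_outcome"], h1["beta_outcome"],
                             h1["se_outcome"], h1["p_outcome"], h1["n_outcome"])
        h2 = retained(harmonize(exp, out2))
        assert (h2["harmonization_action"] == "kept").all()
        assert np.allclose(h1["beta_outcome"], h2["beta_outcome"])


class TestScores:
    def test_grs_trivial_and_oracle(self):
        D = np.array([[2.0, 0, 1], [0, 1, 1], [1, 2, 0], [0, 0, 0], [2, 2, 2]])
        assert np.allclose(compute_grs(D, np.zeros(3)), 0)
        assert compute_grs(np.array([[2.0]]), np.array([1.0]))[0] == 2.0
        w = np.array([0.1, -0.2, 0.3])
        assert np.allclose(compute_grs(D, w), D @ w)

    def test_grs_mean_imputation(self):
        D = np.array([[2.0, np.nan], [0.0, 1.0], [1.0, 1.0]])
        got = compute_grs(D, np.array([1.0, 1.0]))
        assert got[0] == pytest.approx(2.0 + 1.0)   # column mean of [1, 1]
        with pytest.raises(ValueError, match="all-missing"):
            compute_grs(np.array([[np.nan], [np.nan]]), np.array([1.0]))


class TestBlockJackknife:
    def test_validation(self, small_cohort):
        with pytest.raises(ValueError):
            blockjackknife_weights(small_cohort, "exposure", n_blocks=1)
        with pytest.raises(ValueError):
            blockjackknife_weights(small_cohort, "exposure",
                                   n_blocks=small_cohort.n + 1)

    def test_null_trait_scores_uncorrelated(self):
        cfg = SimulationConfig(n_individuals=3000, n_snps=20, h2_exposure=0.0,
                               seed=31)
        c = simulate_cohort(cfg)
        scores = blockjackknife_weights(c, "exposure", n_blocks=5, seed=1)
        r = np.corrcoef(scores, c.exposure)[0, 1]
        assert abs(r) < 3 / np.sqrt(c.n)

    def test_strong_signal_scores_track_trait(self, small_cohort):
        scores = blockjackknife_weights(small_cohort, "exposure", n_blocks=5,
                                        seed=1)
        r = np.corrcoef(scores, small_cohort.exposure)[0, 1]
        assert r ** 2 > 0.15     # h2 = 0.3 with leave-out estimation noise

    def test_leave_out_contract(self):
        """Perturbing individual i's trait never changes i's own score."""
        import copy

        cfg = SimulationConfig(n_individuals=400, n_snps=10, h2_exposure=0.3,
                               seed=17)
        c = simulate_cohort(cfg)
        base = blockjackknife_weights(c, "exposure", n_blocks=4, seed=3)
        i = 42
        c2 = copy.copy(c)
        c2.exposure = c.exposure.copy()
        c2.exposure[i] += 50.0
        pert = blockjackknife_weights(c2, "exposure", n_blocks=4, seed=3)
        assert pert[i] == pytest.approx(base[i], rel=1e-12)
        assert not np.allclose(pert, base)
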