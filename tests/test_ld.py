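"""EM two-locus haplotype frequency estimation and r²; the phased-count
estimator on the same simulated data serves as the independent oracle."""

import numpy as np
import pytest

from kdrpop.ld import (collapse_to_biallelic, em_haplotype_frequencies,
                       ld_table, phased_r2, two_locus_counts)


def simulate_diploids(freqs, n, seed):
    """Draw 2n haplotypes from (f_AB, f_Ab, f_aB, f_ab); return (A, B) binary
    haplotype columns and the unphased 3x3 genotype counts."""
    rng = np.random.default_rng(seed)
    h = rng.choice(4, size=2 * n, p=freqs)  # 0=AB 1=Ab 2=aB 3=ab
    A = (h < 2).astype(int)
    B = ((h == 0) | (h == 2)).astype(int)
    counts = two_locus_counts(A[0::2] + A[1::2], B[0::2] + B[1::2])
    return A, B, counts


class TestCollapse:
    def test_triallelic_pooling(self):
        calls = np.array([[1, 2], [0, 0], [2, 2], [1, 1], [0, -1]])
        # focal = g>t (index 1): the other mutant pools with ref
        assert collapse_to_biallelic(calls, 1).tolist() == [1, 0, 0, 2, -1]
        assert collapse_to_biallelic(calls, 2).tolist() == [1, 0, 2, 0, -1]

    def test_reference_cannot_be_focal(self):
        with pytest.raises(ValueError, match="mutant"):
            collapse_to_biallelic(np.zeros((2, 2), dtype=int), 0)


class TestEM:
    def test_perfect_coupling_exact(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[2, 2] = 2
        counts[0, 0] = 2
        res = em_haplotype_frequencies(counts)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.D == pytest.approx(0.25, abs=1e-12)
        assert res.converged and res.iterations <= 2

    def test_monomorphic_margin_undefined(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 5
        counts[0, 1] = 3
        res = em_haplotype_frequencies(counts)
        assert not res.defined and np.isnan(res.r2)

    def test_no_double_het_equals_closed_form(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(3, 3))
        counts[1, 1] = 0
        res = em_haplotype_frequencies(counts)
        n = counts.sum()
        cAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
        assert res.f_AB == pytest.approx(cAB / (2 * n), abs=1e-9)

    def test_margins_match_data_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = rng.integers(0, 8, size=(3, 3))
            if counts.sum() == 0:
                continue
            res = em_haplotype_frequencies(counts)
            assert res.f_AB + res.f_Ab == pytest.approx(res.p_A, abs=1e-12)
            assert res.f_AB + res.f_aB == pytest.approx(res.p_B, abs=1e-12)
            assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_loglik_monotone_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            counts = rng.integers(0, 12, size=(3, 3))
            if counts.sum() == 0:
                continue
            res = em_haplotype_frequencies(counts)
            ll = np.array(res.loglik)
            assert np.all(np.diff(ll) >= -1e-9)

    def test_all_double_het_saddle_reported(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 8
        res = em_haplotype_frequencies(counts)
        assert res.saddle and res.converged
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_em_matches_phased_oracle_on_same_data(self):
        freqs = [0.4, 0.1, 0.1, 0.4]
        diffs = []
        for seed in range(20):
            A, B, counts = simulate_diploids(freqs, 1000, 1000 + seed)
            res = em_haplotype_frequencies(counts)
            diffs.append(abs(res.r2 - phased_r2(A, B)))
        assert max(diffs) < 0.05
        assert np.mean(diffs) < 0.02

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            em_haplotype_frequencies(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="non-negative"):
            em_haplotype_frequencies(np.full((3, 3), -1))


class TestLdTable:
    def test_strict_linkage_gives_r2_one(self, panel):
        from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 200,
                                {"FVI": 0.5, "LL1T": 0.5})]
        variants, genotypes, metadata, _ = simulate_kdr_cohort(specs, 3,
                                                               panel=panel)
        wide, long = ld_table(genotypes, variants, panel, metadata)
        pooled = wide[wide.population == "An_coluzzii"].iloc[0]
        assert pooled.r2_402Lgt_vs_1527T == pytest.approx(1.0, abs=1e-9)
        # g>c absent entirely -> monomorphic, rendered NA
        assert np.isnan(pooled.r2_402Lgc_vs_1527T)

    def test_independent_allele_gives_near_zero_r2(self, panel):
        from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort
        # class frequencies chosen so P(L2, T) = p_L2 p_T exactly:
        # p_L2 = 0.3, p_T = 0.5, P(L2 and T) = 0.15
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 5000,
                                {"LL2T": 0.15, "LL2I": 0.15, "LL1T": 0.35,
                                 "LVI": 0.35})]
        variants, genotypes, metadata, truth = simulate_kdr_cohort(
            specs, 9, panel=panel)
        wide, _ = ld_table(genotypes, variants, panel, metadata)
        pooled = wide[wide.population == "An_coluzzii"].iloc[0]
        assert pooled.r2_402Lgc_vs_1527T < 0.05
        # oracle: phased-count r2 on the generator's drawn haplotypes
        expect = truth.pop_r2["p"]["r2_402Lgc_vs_1527T"]
        assert pooled.r2_402Lgc_vs_1527T == pytest.approx(expect, abs=0.02)

    def test_render_undefined_as_zero_switch(self, panel):
        from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 20,
                                {"FVI": 0.5, "LL1T": 0.5})]
        variants, genotypes, metadata, _ = simulate_kdr_cohort(specs, 3,
                                                               panel=panel)
        wide, _ = ld_table(genotypes, variants, panel, metadata,
                           render_undefined_as_zero=True)
        pooled = wide[wide.population == "An_coluzzii"].iloc[0]
        assert pooled.r2_402Lgc_vs_1527T == 0.0
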