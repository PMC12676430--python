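import numpy as np
import pytest

from kdrpop.core_io import GenotypeMatrix, VariantTable
from kdrpop.diversity import group_samples
from kdrpop.variant_effects import (TranscriptModel, add_cumulative_402,
                                    allele_frequencies, annotate_effects,
                                    effect_summary, is_nonsynonymous)


@pytest.fixture
def toy_tx():
    # forward-strand CDS ATG CTG TAA at positions 1-9
    return TranscriptModel("TX1", "2L", "+", [(1, 9)], "ATGCTGTAA")


def _variants(pos_ref_alts):
    return VariantTable(contig=["2L"] * len(pos_ref_alts),
                        pos=np.array([p for p, _, _ in pos_ref_alts]),
                        ref=[r for _, r, _ in pos_ref_alts],
                        alts=[a for _, _, a in pos_ref_alts])


class TestAnnotation:
    def test_missense_by_hand_translation(self, toy_tx):
        # codon 2 CTG (L); pos 5 T>A makes CAG (Q)
        v = annotate_effects(_variants([(5, "T", ("A",))]), toy_tx)
        assert v.effect_labels == [("L2Q",)]

    def test_wobble_synonymous(self, toy_tx):
        # pos 6 G>A: CTG -> CTA, still leucine
        v = annotate_effects(_variants([(6, "G", ("A",))]), toy_tx)
        assert v.effect_labels == [("synonymous",)]

    def test_outside_exons_intronic(self, toy_tx):
        tx = TranscriptModel("TX1", "2L", "+", [(1, 9)],
                             "ATGCTGTAAGGGG")
        v = annotate_effects(_variants([(11, "G", ("A",))]), tx)
        assert v.effect_labels == [("intronic",)]

    def test_multiallelic_annotated_per_alt(self, toy_tx):
        v = annotate_effects(_variants([(5, "T", ("A", "C"))]), toy_tx)
        # CTG->CAG (L2Q) and CTG->CCG (L2P)
        assert v.effect_labels == [("L2Q", "L2P")]

    def test_ref_mismatch_raises_with_position(self, toy_tx):
        with pytest.raises(ValueError, match="2L:5"):
            annotate_effects(_variants([(5, "G", ("A",))]), toy_tx)

    def test_reverse_strand_involution(self):
        # reverse-complement construction of the same toy CDS: the '-'-strand
        # transcript over revcomp(ATGCTGTAA) yields identical labels for the
        # mirrored variants
        fwd = TranscriptModel("TX1", "2L", "+", [(1, 9)], "ATGCTGTAA")
        rev = TranscriptModel("TX1r", "2L", "-", [(1, 9)], "TTACAGCAT")
        v_fwd = annotate_effects(_variants([(5, "T", ("A",))]), fwd)
        # position 5 on the forward toy maps to position 5 of the mirrored
        # sequence with complemented alleles
        v_rev = annotate_effects(_variants([(5, "A", ("T",))]), rev)
        assert v_fwd.effect_labels == v_rev.effect_labels == [("L2Q",)]


class TestFrequencies:
    def test_heterozygote_frequency(self, tiny_variants):
        calls = np.zeros((10, 2, 2), dtype=np.int16)
        calls[0, 0, 1] = 1  # one het among 10 diploids at site 1
        geno = GenotypeMatrix(calls, phased=False)
        df = allele_frequencies(tiny_variants, geno, {"pop": np.arange(10)},
                                min_freq=None)
        row = df[(df.pos == 100) & (df.alt == "T")].iloc[0]
        assert row.frequency == pytest.approx(0.05)
        assert row.total == 20

    def test_all_reference_population_zero(self, tiny_variants):
        calls = np.zeros((4, 2, 2), dtype=np.int16)
        geno = GenotypeMatrix(calls, phased=False)
        df = allele_frequencies(tiny_variants, geno, {"pop": np.arange(4)},
                                min_freq=None)
        assert (df.frequency == 0).all()

    def test_min_freq_uses_max_over_populations(self, tiny_variants):
        calls = np.zeros((8, 2, 2), dtype=np.int16)
        calls[0:4, 0, :] = 1  # alt T at freq 1.0 in pop1, 0.0 in pop2
        geno = GenotypeMatrix(calls, phased=False)
        df = allele_frequencies(tiny_variants, geno,
                                {"pop1": np.arange(4),
                                 "pop2": np.arange(4, 8)}, min_freq=0.05)
        # site kept for BOTH populations because pop1 passes
        assert set(df[df.alt == "T"].population) == {"pop1", "pop2"}
        assert (df.pos == 200).sum() == 0  # monomorphic site dropped

    def test_cumulative_402_row_additive(self, panel, small_cohort):
        variants, genotypes, metadata, truth = small_cohort
        groups = group_samples(metadata, by="site_species")
        df = allele_frequencies(variants, genotypes, groups, min_freq=None)
        df = add_cumulative_402(df, panel)
        locus = panel.locus("402")
        site = df[(df.pos == locus.pos)]
        for pop, sub in site.groupby("population"):
            parts = sub[sub.alt.isin(list(locus.alts))].frequency.sum()
            cum = sub[sub.effect == "V402L_cumulative"].frequency.iloc[0]
            assert cum == pytest.approx(parts, abs=1e-12)

    def test_cumulative_402_equals_1527t_under_strict_linkage(self, panel):
        from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 300,
                                {"FVI": 0.4, "LL1T": 0.4, "LL2T": 0.2})]
        variants, genotypes, metadata, _ = simulate_kdr_cohort(specs, 21,
                                                               panel=panel)
        groups = group_samples(metadata, by="site_species")
        df = allele_frequencies(variants, genotypes, groups, min_freq=None)
        df = add_cumulative_402(df, panel)
        cum = df[df.effect == "V402L_cumulative"].frequency.iloc[0]
        l1527 = panel.locus("1527")
        t_freq = df[(df.pos == l1527.pos) &
                    (df.alt == l1527.alts[0])].frequency.iloc[0]
        assert cum == pytest.approx(t_freq, abs=1e-12)

    def test_panel_frequencies_match_generator_truth(self, panel,
                                                     small_cohort):
        variants, genotypes, metadata, truth = small_cohort
        groups = group_samples(metadata, by="site_species")
        df = allele_frequencies(variants, genotypes, groups, min_freq=None)
        locus995 = panel.locus("995")
        for spec_name, pop in [("popA", "Bana:An_coluzzii"),
                               ("popB", "Gama:An_gambiae_ss")]:
            labels = truth.pop_hap_freqs[spec_name]
            f_true = sum(v for k, v in labels.items() if k.startswith("F"))
            row = df[(df.population == pop) & (df.pos == locus995.pos) &
                     (df.alt == locus995.alts[0])].iloc[0]
            assert row.frequency == pytest.approx(f_true, abs=1e-12)


class TestSummary:
    def test_nonsynonymous_fraction(self):
        labels = [("L995F",), ("synonymous",), ("intronic",), ("A123T",)]
        v = VariantTable(["2L"] * 4, np.array([10, 20, 30, 40]),
                         ["A"] * 4, [("G",)] * 4, effect_labels=labels)
        s = effect_summary(v)
        assert s["n_sites"] == 4 and s["n_non_synonymous"] == 2
        assert s["non_synonymous_fraction"] == pytest.approx(0.5)

    def test_label_classifier(self):
        assert is_nonsynonymous("L995F")
        assert is_nonsynonymous("I1527T")
        assert not is_nonsynonymous("synonymous")
        assert not is_nonsynonymous("intronic")
        assert not is_nonsynonymous("")
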