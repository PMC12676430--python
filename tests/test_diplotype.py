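import numpy as np
import pytest

from kdrpop.diplotype import (classify_cohort, classify_diplotype, cut_tree,
                              cluster_map_order, diplotype_frequencies,
                              dosage_matrix, genotype_clustering,
                              label_haplotype, pca_dosage)
from kdrpop.synthetic_data import PopulationSpec, simulate_kdr_cohort


class TestLabelling:
    @pytest.mark.parametrize("alleles, label", [
        ((0, 0, 0), "LVI"),       # all wild type
        ((1, 0, 0), "FVI"),       # classic kdr background
        ((0, 1, 1), "LL1T"),      # g>t double mutant
        ((0, 2, 1), "LL2T"),      # g>c double mutant
        ((2, 0, 0), "SVI"),       # 995S
        ((1, 1, 1), "FL1T"),
    ])
    def test_label_lookup(self, panel, alleles, label):
        assert label_haplotype(alleles, panel) == label

    def test_unknown_allele_rejected(self, panel):
        with pytest.raises(ValueError, match="allele index"):
            label_haplotype((5, 0, 0), panel)

    def test_label_round_trip(self, panel):
        for label in ("LVI", "FVI", "SVI", "LL1T", "LL2T", "FL1T", "FL2T"):
            assert label_haplotype(panel.parse_label(label), panel) == label


def _phased_calls(panel, hap1, hap2):
    a1 = panel.parse_label(hap1)
    a2 = panel.parse_label(hap2)
    return np.array([[a1[i], a2[i]] for i in range(3)])


class TestClassification:
    @pytest.mark.parametrize("pair, group", [
        (("FVI", "FVI"), "FVI/FVI"),
        (("FL1T", "LVI"), "FL1T/LVI"),
        (("LVI", "FL1T"), "FL1T/LVI"),   # unordered
        (("LL1T", "LL2T"), "LL1T/LL2T"),
        (("FVI", "SVI"), "OD"),          # 995F/995S heterozygote
        (("LVI", "LVI"), "OD"),
    ])
    def test_phased_pairs(self, panel, pair, group):
        call = classify_diplotype("s", _phased_calls(panel, *pair), panel,
                                  phased=True)
        assert call.group == group and not call.ambiguous

    def test_missing_panel_call_is_od_flagged(self, panel):
        calls = _phased_calls(panel, "FVI", "FVI")
        calls[1] = [-1, -1]
        call = classify_diplotype("s", calls, panel, phased=True)
        assert call.group == "OD" and call.missing

    def test_triple_heterozygote_coupling_rule(self, panel):
        # unphased (L/F, V/L1, I/T): both FL1T/LVI and FVI/LL1T resolutions
        # exist; the coupling rule names FL1T/LVI, flagged ambiguous
        calls = np.array([[0, 1], [0, 1], [0, 1]])
        call = classify_diplotype("s", calls, panel, phased=False)
        assert call.group == "FL1T/LVI" and call.ambiguous

    def test_unphased_homozygote_unambiguous(self, panel):
        calls = _phased_calls(panel, "FVI", "FVI")
        call = classify_diplotype("s", calls, panel, phased=False)
        assert call.group == "FVI/FVI" and not call.ambiguous

    def test_unphased_agrees_with_phased_when_unambiguous(self, panel,
                                                          small_cohort):
        variants, genotypes, metadata, _ = small_cohort
        samples = [m.sample_id for m in metadata]
        phased_calls = classify_cohort(variants, genotypes, samples, panel)
        idx = panel.variant_indices(variants)
        for i, c in enumerate(phased_calls):
            un = classify_diplotype(samples[i], genotypes.calls[i, idx],
                                    panel, phased=False)
            if not un.ambiguous:
                assert un.group == c.group

    def test_truth_recovery_on_phased_cohort(self, panel, small_cohort):
        from kdrpop.diplotype import group_of_pair
        variants, genotypes, metadata, truth = small_cohort
        samples = [m.sample_id for m in metadata]
        calls = classify_cohort(variants, genotypes, samples, panel)
        for call, pair in zip(calls, truth.hap_labels):
            assert call.group == group_of_pair(*pair)


class TestFrequencies:
    def test_published_style_fraction(self, panel, tiny_metadata):
        from kdrpop.diplotype import DiplotypeCall
        calls = [DiplotypeCall(f"s{i}", "FVI/FVI") for i in range(112)]
        calls.append(DiplotypeCall("s112", "OD"))
        from kdrpop.core_io import SampleMetadata
        metadata = [SampleMetadata(f"s{i}", "An_gambiae_ss", "Bana",
                                   "Sudanian", "F") for i in range(113)]
        freqs = diplotype_frequencies(calls, metadata)
        fvi = freqs[freqs.group == "FVI/FVI"].iloc[0]
        assert fvi.frequency == pytest.approx(112 / 113)
        assert round(fvi.frequency, 3) == 0.991

    def test_frequencies_partition_to_one(self, panel, small_cohort):
        variants, genotypes, metadata, _ = small_cohort
        calls = classify_cohort(variants, genotypes,
                                [m.sample_id for m in metadata], panel)
        freqs = diplotype_frequencies(calls, metadata)
        sums = freqs.groupby("population").frequency.sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_invariant_to_sample_order(self, panel, small_cohort):
        variants, genotypes, metadata, _ = small_cohort
        calls = classify_cohort(variants, genotypes,
                                [m.sample_id for m in metadata], panel)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(calls))
        a = diplotype_frequencies(calls, metadata)
        b = diplotype_frequencies([calls[i] for i in perm],
                                  [metadata[i] for i in perm])
        key = ["population", "group"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert np.allclose(merged.frequency_a, merged.frequency_b)


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        from kdrpop.core_io import GenotypeMatrix
        calls = np.zeros((3, 4, 2), dtype=np.int16)
        calls[2, :, :] = 1
        geno = GenotypeMatrix(calls, phased=True)
        Z, order, kept = genotype_clustering(geno)
        assert Z[0, 2] == 0.0  # first merge joins the two identical samples

    def test_recovers_three_group_partition(self, panel):
        from sklearn.metrics import rand_score
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 60,
                                {"FVI": 1 / 3, "LL1T": 1 / 3, "SVI": 1 / 3})]
        variants, genotypes, metadata, truth = simulate_kdr_cohort(
            specs, 11, panel=panel, n_private_mutations=3)
        labels_true = ["/".join(sorted(p)) for p in truth.hap_labels]
        # keep only the three homozygous diplotype classes for a clean truth
        keep = [i for i, p in enumerate(truth.hap_labels) if p[0] == p[1]]
        geno = genotypes.take_samples(np.array(keep))
        Z, order, kept = genotype_clustering(geno)
        pred = cut_tree(Z, 3)
        truth_labels = [labels_true[i] for i in keep]
        assert rand_score(truth_labels, pred) >= 0.95

    def test_pca_separates_divergent_classes(self, panel):
        specs = [PopulationSpec("p", "An_coluzzii", "Bana", "Sudanian", 100,
                                {"FVI": 0.5, "LL1T": 0.5})]
        variants, genotypes, metadata, truth = simulate_kdr_cohort(
            specs, 13, panel=panel, n_private_mutations=3)
        X, _ = dosage_matrix(variants, genotypes)
        coords, evr = pca_dosage(X, maf_min=0.01)
        n_res = np.array([sum(h != "FVI" for h in p)
                          for p in truth.hap_labels])
        pc1 = coords[:, 0]
        # the three dosage groups (0, 1, 2 non-FVI haplotypes) are disjoint
        hom_a = pc1[n_res == 0]
        het = pc1[n_res == 1]
        hom_b = pc1[n_res == 2]
        assert hom_a.size and het.size and hom_b.size
        lo, hi = sorted([hom_a.mean(), hom_b.mean()])
        assert np.all((het > lo) & (het < hi))
        assert max(hom_a.max(), -hom_a.min()) is not None
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_pca_identical_samples_all_zero(self):
        X = np.ones((5, 4))  # every sample heterozygous everywhere
        coords, _ = pca_dosage(X, maf_min=0.01)
        assert np.allclose(coords, 0.0)

    def test_pca_no_site_passes_maf_raises(self):
        X = np.zeros((5, 4))  # monomorphic reference
        with pytest.raises(ValueError, match="MAF"):
            pca_dosage(X, maf_min=0.01)

    def test_cluster_map_identity_on_single_row(self):
        rows, cols = cluster_map_order(np.array([[1.0, 2.0, 3.0]]))
        assert rows.tolist() == [0]
        assert len(cols) == 3

    def test_cluster_map_separates_blocks(self):
        # two variant blocks private to two population blocks
        M = np.array([[1.0, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 1.0]])
        rows, cols = cluster_map_order(M)
        r = rows.tolist()
        assert {tuple(sorted(r[:2])), tuple(sorted(r[2:]))} == \
            {(0, 2), (1, 3)}
        c = cols.tolist()
        assert {tuple(sorted(c[:2])), tuple(sorted(c[2:]))} == \
            {(0, 1), (2, 3)}

    def test_duplicated_rows_adjacent(self):
        rng = np.random.default_rng(2)
        M = rng.random((5, 4))
        M[3] = M[0]
        rows, _ = cluster_map_order(M)
        r = rows.tolist()
        assert abs(r.index(0) - r.index(3)) == 1
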