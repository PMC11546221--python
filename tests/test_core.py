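"""Genetic-code tables, codon/pair counting and expression classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonlens as cl

SENSE = sorted(cl.standard_code().sense_codons)

cds_strategy = st.lists(st.sampled_from(SENSE), min_size=1, max_size=150).map(
    lambda cods: cl.CodingSequence("g", "".join(cods))
)


class TestGeneticCode:
    def test_counts_and_coverage(self, code):
        assert code.n_codons == 61
        assert code.n_pairs == 3721
        assert code.stop_codons == {"TAA", "TAG", "TGA"}
        all64 = {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        assert set(code.sense_codons) | code.stop_codons == all64

    def test_synonym_groups_partition_sense_codons(self, code):
        pooled = [c for group in code.synonym_groups.values() for c in group]
        assert sorted(pooled) == sorted(code.sense_codons)
        assert len(pooled) == len(set(pooled))


class TestCounting:
    def test_terminal_stop_stripped(self, code):
        counts = cl.count_codons(cl.CodingSequence("g", "ATGAAAAAATAA"), code)
        assert counts[code.codon_index["ATG"]] == 1
        assert counts[code.codon_index["AAA"]] == 2
        assert counts.sum() == 3

    def test_internal_stop_is_hard_error(self, code):
        with pytest.raises(ValueError, match="codon 2"):
            cl.count_codons(cl.CodingSequence("bad", "ATGTAAAAA"), code)

    def test_non_acgt_codon_skipped_with_warning(self, code, caplog):
        with caplog.at_level("WARNING", logger="codonlens"):
            counts = cl.count_codons(cl.CodingSequence("g", "ATGANAAAA"), code)
        assert counts.sum() == 2
        assert "skipping" in caplog.text

    def test_counts_match_sliding_window_tally(self, code):
        rng = np.random.default_rng(0)
        cods = [SENSE[i] for i in rng.integers(0, 61, size=150)]
        seq = cl.CodingSequence("g", "".join(cods) + "TGA")
        counts = cl.count_codons(seq, code)
        for c in set(cods):
            assert counts[code.codon_index[c]] == cods.count(c)
        assert counts.sum() == 150

    def test_overlapping_pairs(self, code):
        counts = cl.count_codon_pairs(cl.CodingSequence("g", "ATGAAACCC"), code)
        assert counts[code.pair_index["ATGAAA"]] == 1
        assert counts[code.pair_index["AAACCC"]] == 1
        assert counts.sum() == 2

    def test_single_codon_gene_has_no_pairs(self, code):
        assert cl.count_codon_pairs(cl.CodingSequence("g", "ATG"), code).sum() == 0

    @settings(derandomize=True, max_examples=40)
    @given(seq=cds_strategy)
    def test_pair_total_is_codon_total_minus_one(self, seq):
        code = cl.standard_code()
        n_codons = cl.count_codons(seq, code).sum()
        n_pairs = cl.count_codon_pairs(seq, code).sum()
        assert n_codons == n_pairs + 1


class TestFrequencies:
    def test_simple_division(self, code):
        counts = cl.build_count_matrix([cl.CodingSequence("g", "ATGAAAAAA")], code)
        freqs = cl.to_frequencies(counts)
        assert freqs.values[0, code.codon_index["ATG"]] == pytest.approx(1 / 3)
        assert freqs.values[0, code.codon_index["AAA"]] == pytest.approx(2 / 3)

    def test_single_codon_gene_frequency_one(self, code):
        freqs = cl.to_frequencies(cl.build_count_matrix([cl.CodingSequence("g", "AAA" * 5)], code))
        assert freqs.values[0, code.codon_index["AAA"]] == 1.0
        assert freqs.values[0].sum() == 1.0

    def test_rows_sum_to_one(self, planted_matrices):
        _, freqs = planted_matrices
        np.testing.assert_allclose(freqs.values.sum(axis=1), 1.0, atol=1e-9)
        assert ((freqs.values >= 0) & (freqs.values <= 1)).all()

    def test_zero_length_gene_errors(self, code):
        counts = cl.CodonCountMatrix(["g"], "codon", np.zeros((1, 61)), code.sense_codons)
        with pytest.raises(ValueError, match="zero"):
            cl.to_frequencies(counts)


def _tiny_dataset(expressions, length=30, seed=0):
    rng = np.random.default_rng(seed)
    genes = [
        cl.CodingSequence(f"g{i}", "".join(SENSE[j] for j in rng.integers(0, 61, size=length)))
        for i in range(len(expressions))
    ]
    return cl.GeneDataset(genes, np.asarray(expressions, float))


class TestClasses:
    def test_equal_split_of_1688_genes(self):
        ds = _tiny_dataset(np.arange(1688, dtype=float), length=5)
        classes = cl.split_into_classes(ds)
        assert [len(c.gene_ids) for c in classes] == [422] * 4

    def test_remainder_goes_to_highest_classes(self):
        classes = cl.split_into_classes(_tiny_dataset([5, 4, 3, 2, 1]))
        assert [len(c.gene_ids) for c in classes] == [2, 1, 1, 1]

    def test_class_order_statistics_and_partition(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(0, 100, size=37)
        ds = _tiny_dataset(e, seed=4)
        classes = cl.split_into_classes(ds)
        by_id = dict(zip(ds.gene_ids, e))
        mins_maxes = [(min(by_id[g] for g in c.gene_ids), max(by_id[g] for g in c.gene_ids)) for c in classes]
        for (lo1, _), (_, hi2) in zip(mins_maxes, mins_maxes[1:]):
            assert lo1 >= hi2  # class j's worst gene beats class j+1's best
        pooled = [g for c in classes for g in c.gene_ids]
        assert sorted(pooled) == sorted(ds.gene_ids)

    def test_distributions_normalized_and_pool_to_dataset(self, code):
        ds = _tiny_dataset(np.arange(20, dtype=float), length=40, seed=5)
        counts = cl.build_count_matrix(ds.genes, code)
        classes = cl.split_into_classes(ds, counts=counts)
        for c in classes:
            assert c.distribution.sum() == pytest.approx(1.0, abs=1e-9)
        # union of all classes pools back to the dataset-wide distribution
        overall = cl.class_distribution(counts)
        sizes = np.array([len(c.gene_ids) for c in classes])
        totals = counts.row_totals
        # reconstruct pooled counts from per-class distributions
        order = np.argsort(-ds.expressions, kind="stable")
        start, pooled = 0, np.zeros(61)
        for c, s in zip(classes, sizes):
            idx = order[start : start + s]
            start += s
            pooled += c.distribution * totals[idx].sum()
        np.testing.assert_allclose(pooled / pooled.sum(), overall, atol=1e-12)

    def test_pooled_not_averaged(self, code):
        # two genes with disjoint codons and unequal lengths
        g1 = cl.CodingSequence("a", "AAA" * 9)
        g2 = cl.CodingSequence("b", "ATG")
        counts = cl.build_count_matrix([g1, g2], code)
        dist = cl.class_distribution(counts)
        assert dist[code.codon_index["AAA"]] == pytest.approx(0.9)
        assert dist[code.codon_index["ATG"]] == pytest.approx(0.1)

    def test_empty_class_errors(self, code):
        counts = cl.build_count_matrix([cl.CodingSequence("a", "AAA")], code)
        with pytest.raises(ValueError, match="empty"):
            cl.class_distribution(counts, [])

    def test_too_few_classes_errors(self):
        with pytest.raises(ValueError, match="n_classes"):
            cl.split_into_classes(_tiny_dataset([1, 2, 3]), n_classes=1)


class TestDistributionCorrelation:
    def test_identical_distributions(self):
        d = np.random.default_rng(0).dirichlet(np.ones(61))
        assert cl.distribution_correlation(d, d) == pytest.approx(1.0)

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(1)
        d1, d2 = rng.dirichlet(np.ones(61)), rng.dirichlet(np.ones(61))
        assert cl.distribution_correlation(d1, 3 * d1 + 0.2) == pytest.approx(1.0)
        r12 = cl.distribution_correlation(d1, d2)
        assert r12 == pytest.approx(cl.distribution_correlation(d2, d1))
        assert -1 <= r12 <= 1

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        d1, d2 = rng.dirichlet(np.ones(61)), rng.dirichlet(np.ones(61))
        expected = np.cov(d1, d2)[0, 1] / (d1.std(ddof=1) * d2.std(ddof=1))
        assert cl.distribution_correlation(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            cl.distribution_correlation(np.ones(61), np.arange(61.0))
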