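"""Metrics, negative sampling, seen/unseen split, similarity filter."""

import numpy as np
import pytest

from tcrbind import (
    BindingDataset,
    BindingPair,
    compute_metrics,
    negative_sample,
    sequence_similarity,
    similarity_filter,
    split_seen_unseen,
)

from conftest import mann_whitney_auc, random_seq, wagner_fischer


class TestComputeMetrics:
    def test_perfect_separation(self):
        report = compute_metrics([1, 0], [0.9, 0.1])
        assert report.roc_auc == 1.0 and report.accuracy == 1.0
        assert (report.tp, report.fp, report.tn, report.fn) == (1, 0, 1, 0)

    def test_all_tied_scores_give_half_auc(self):
        assert compute_metrics([1, 0], [0.5, 0.5]).roc_auc == 0.5

    def test_six_sample_case_matches_pairwise_count(self):
        labels = [1, 1, 0, 0, 1, 0]
        scores = [0.9, 0.4, 0.6, 0.1, 0.7, 0.3]
        report = compute_metrics(labels, scores)
        assert report.roc_auc == pytest.approx(8 / 9, abs=1e-12)
        assert report.roc_auc == pytest.approx(mann_whitney_auc(labels, scores), abs=1e-12)

    def test_matches_mann_whitney_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            got = compute_metrics(labels, scores).roc_auc
            assert got == pytest.approx(mann_whitney_auc(labels, scores), abs=1e-12)

    def test_confusion_counts_sum_to_n_and_formulas_hold(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        r = compute_metrics(labels, scores, threshold=0.6)
        n = r.tp + r.fp + r.tn + r.fn
        assert n == 40
        assert r.accuracy == pytest.approx((r.tp + r.tn) / n)
        if r.tp + r.fp:
            assert r.precision == pytest.approx(r.tp / (r.tp + r.fp))
        if r.precision + r.recall:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.recall / (r.precision + r.recall))

    def test_single_class_raises_instead_of_half(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics([1, 1, 1], [0.2, 0.5, 0.9])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths"):
            compute_metrics([1, 0], [0.5])


def _positive_set(n_peptides=3, per_peptide=4, seed=0):
    rng = np.random.default_rng(seed)
    peptides = [random_seq(rng, 9, 9) for _ in range(n_peptides)]
    pairs = [BindingPair(random_seq(rng, 10, 14), pep, 1)
             for pep in peptides for _ in range(per_peptide)]
    return BindingDataset(pairs), rng


class TestNegativeSample:
    def test_ratio_one_gives_exact_balance(self):
        positives, rng = _positive_set()
        pool = [random_seq(rng, 10, 14) for _ in range(100)]
        out = negative_sample(positives, pool, ratio=1.0, seed=3)
        assert len(out) == 2 * len(positives)
        assert len(out.positives()) == len(out.negatives()) == len(positives)

    def test_ratio_two_doubles_negatives(self):
        positives, rng = _positive_set()
        pool = [random_seq(rng, 10, 14) for _ in range(200)]
        out = negative_sample(positives, pool, ratio=2.0, seed=3)
        assert len(out.negatives()) == 2 * len(positives)

    def test_never_collides_with_a_positive_pair(self):
        positives, rng = _positive_set(seed=9)
        pool = [p.cdr3b for p in positives] + [random_seq(rng, 10, 14) for _ in range(50)]
        out = negative_sample(positives, pool, seed=1)
        positive_keys = {(p.cdr3b, p.peptide) for p in positives}
        for neg in out.negatives():
            assert (neg.cdr3b, neg.peptide) not in positive_keys

    def test_same_seed_reproduces_exactly(self):
        positives, rng = _positive_set(seed=2)
        pool = [random_seq(rng, 10, 14) for _ in range(60)]
        a = negative_sample(positives, pool, seed=11)
        b = negative_sample(positives, pool, seed=11)
        assert a.pairs == b.pairs

    def test_exhausted_pool_error_names_the_peptide(self):
        pep = "ACDEFGHIK"
        positives = BindingDataset([BindingPair("CASSLGQETQYF", pep, 1)])
        with pytest.raises(ValueError, match=pep):
            negative_sample(positives, ["CASSLGQETQYF"], seed=0)

    def test_rejects_non_positive_input(self):
        ds = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 0)])
        with pytest.raises(ValueError, match="label-1"):
            negative_sample(ds, ["CAWSVGVGQPQHF"], seed=0)


class TestSplitSeenUnseen:
    def test_partition_by_training_peptides(self):
        training = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        validation = BindingDataset([
            BindingPair("CAWSVGVGQPQHF", "ACDEFGHIK", 1),
            BindingPair("CASSIRSSYEQYF", "KLMNPQRST", 1),
        ])
        shared, unique = split_seen_unseen(validation, training)
        assert [p.peptide for p in shared] == ["ACDEFGHIK"]
        assert [p.peptide for p in unique] == ["KLMNPQRST"]

    def test_empty_training_makes_everything_unseen(self):
        validation = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        shared, unique = split_seen_unseen(validation, BindingDataset([]))
        assert len(shared) == 0 and len(unique) == 1

    def test_sizes_partition_the_validation_positives(self):
        rng = np.random.default_rng(8)
        peps = [random_seq(rng, 9, 9) for _ in range(2)]
        validation = BindingDataset(
            [BindingPair(random_seq(rng, 10, 14), peps[i % 2], 1) for i in range(5)])
        training = BindingDataset([BindingPair(random_seq(rng, 10, 14), peps[0], 1)])
        shared, unique = split_seen_unseen(validation, training)
        assert len(shared) + len(unique) == 5


class TestSimilarityFilter:
    def test_threshold_one_only_removes_exact_duplicates(self):
        train = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        valid = BindingDataset([
            BindingPair("CASSLGQETQYF", "KLMNPQRST", 1),   # identical CDR3
            BindingPair("CASSLGQETQYW", "KLMNPQRST", 1),   # similarity 11/12
        ])
        kept = similarity_filter(valid, train, max_similarity=1.0)
        assert len(kept) == 2  # similarity 1.0 is not > 1.0
        kept = similarity_filter(valid, train, max_similarity=0.99)
        assert [p.cdr3b for p in kept] == ["CASSLGQETQYW"]

    def test_identical_cdr3_removed_below_point_nine(self):
        train = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        valid = BindingDataset([BindingPair("CASSLGQETQYF", "KLMNPQRST", 1)])
        assert len(similarity_filter(valid, train, 0.9)) == 0

    def test_distant_sequence_retained(self):
        # closest training CDR3 at edit distance 3 of length 6 -> similarity 0.5
        train = BindingDataset([BindingPair("CAWWLG", "ACDEFGHIK", 1)])
        valid = BindingDataset([BindingPair("CASSLG", "KLMNPQRST", 1)])
        assert wagner_fischer("CASSLG", "CAWWLG") == 2  # sanity: below
        train = BindingDataset([BindingPair("CWWWLG", "ACDEFGHIK", 1)])
        assert wagner_fischer("CASSLG", "CWWWLG") == 3
        assert sequence_similarity("CASSLG", "CWWWLG") == 0.5
        assert len(similarity_filter(valid, train, 0.6)) == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        train = BindingDataset([BindingPair(random_seq(rng, 8, 14),
                                            random_seq(rng, 8, 10), 1) for _ in range(10)])
        valid = BindingDataset([BindingPair(random_seq(rng, 8, 14),
                                            random_seq(rng, 8, 10), 1) for _ in range(30)])
        previous: set = set()
        for t in (0.3, 0.5, 0.7, 0.9, 1.0):
            kept = {(p.cdr3b, p.peptide) for p in similarity_filter(valid, train, t)}
            assert previous <= kept  # raising the cap only admits more pairs
            previous = kept

    def test_invalid_threshold_rejected(self):
        ds = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        for t in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                similarity_filter(ds, ds, t)

    def test_peptide_side_filtering(self):
        train = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)])
        valid = BindingDataset([BindingPair("CAWSVGVGQPQHF", "ACDEFGHIK", 1)])
        assert len(similarity_filter(valid, train, 0.9, side="peptide")) == 0
        assert len(similarity_filter(valid, train, 0.9, side="cdr3b")) == 1
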