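import itertools

import numpy as np
import pytest
from scipy import stats

from mil3d.data_io import label_by_signal
from mil3d.errors import UndefinedStatisticError
from mil3d.evaluation import (
    EvaluationReport,
    TfDataset,
    auc,
    benchmark,
    gc_content,
    paired_ttest,
    pearson,
    top_kmers,
)
from mil3d.synthetic_data import SyntheticSpec, generate


def _brute_force_auc(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_null_expectation(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 4000)
        labels[:2] = [0, 1]
        scores = rng.random(4000)
        assert auc(labels, scores) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.ones(25, dtype=int), np.zeros(25, dtype=int)]
        scores = rng.random(50)
        assert auc(labels, scores) == pytest.approx(_brute_force_auc(labels, scores), abs=1e-12)

    def test_ties_count_half(self):
        assert auc([0, 1], [0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        scores = rng.random(40)
        assert auc(labels, scores) + auc(labels, -scores) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            auc([1, 1], [0.1, 0.2])


class TestTopKmers:
    def _scored(self, triples):
        return [("p", i, kmer, prob) for i, (kmer, prob) in enumerate(triples)]

    def test_filter_count_and_total(self):
        triples = [("AAA", 0.9)] * 3 + [("CCC", 0.9)] + [("GGG", 0.5)] * 9
        table = top_kmers(self._scored(triples), threshold=0.85, top_n=10)
        assert table.rows == [("AAA", 3), ("CCC", 1)]
        assert table.total == 4

    def test_threshold_above_one_gives_empty_table(self):
        table = top_kmers(self._scored([("AAA", 1.0)]), threshold=1.01)
        assert table.rows == [] and table.total == 0

    def test_tie_keeps_lexicographically_smaller(self):
        base = [("TTT", 0.9), ("AAA", 0.9), ("CCC", 0.9)]
        for perm in itertools.permutations(base):
            table = top_kmers(self._scored(list(perm)), top_n=1)
            assert table.rows == [("AAA", 1)]

    def test_threshold_is_inclusive(self):
        table = top_kmers(self._scored([("AAA", 0.85)]), threshold=0.85)
        assert table.rows == [("AAA", 1)]


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10), rng.random(10)
        r, p = pearson(x, y)
        sx, sy = x - x.mean(), y - y.mean()
        r_hand = float((sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum()))
        t_hand = r_hand * np.sqrt(8 / (1 - r_hand ** 2))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=8)
        assert r == pytest.approx(r_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestPairedTtest:
    def test_identical_lists(self):
        assert paired_ttest([0.8, 0.9, 0.7], [0.8, 0.9, 0.7]) == (0.0, 1.0)

    def test_constant_shift_with_tiny_noise(self):
        rng = np.random.default_rng(4)
        b = rng.random(10)
        a = b + 0.2 + rng.normal(0, 1e-3, 10)
        t, p = paired_ttest(a, b)
        assert p < 1e-6 and t > 0

    def test_equals_one_sample_test_on_differences(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(12), rng.random(12)
        t, p = paired_ttest(a, b)
        t1, p1 = stats.ttest_1samp(a - b, 0.0)
        assert t == pytest.approx(float(t1), abs=1e-12)
        assert p == pytest.approx(float(p1), abs=1e-12)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            paired_ttest([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])


def _tiny_datasets(table, n_tf=2, n=60, seed0=60, mutation_rates=None):
    datasets = []
    for t in range(n_tf):
        motifs = ["TGACGTC", "GATTGCA", "ACCACAG"]
        mut = (mutation_rates or [0.0] * n_tf)[t]
        tr, _ = generate(
            SyntheticSpec(n_pos=n, n_neg=n, motif=motifs[t % 3], mutation_rate=mut, seed=seed0 + 2 * t)
        )
        te, _ = generate(
            SyntheticSpec(n_pos=n, n_neg=n, motif=motifs[t % 3], mutation_rate=mut, seed=seed0 + 2 * t + 1)
        )
        datasets.append(
            TfDataset(f"TF{t}", label_by_signal(tr, n, n), label_by_signal(te, n, n))
        )
    return datasets


class TestBenchmark:
    def test_report_contract_and_round_trip(self, table, tmp_path):
        datasets = _tiny_datasets(table)
        report = benchmark(datasets, ["mil3d_k7", "count_5", "sil3d"], table)
        assert not report.errors
        for tf in ("TF0", "TF1"):
            for model in ("mil3d_k7", "count_5", "sil3d"):
                assert 0.0 <= report.per_model_auc[tf][model] <= 1.0
        path = tmp_path / "report.json"
        report.to_json(path)
        again = EvaluationReport.from_json(path)
        assert again.per_model_auc == report.per_model_auc
        assert again.paired_test == report.paired_test
        assert [t.rows for t in again.top_kmer_tables.values()] == [
            t.rows for t in report.top_kmer_tables.values()
        ]

    def test_deterministic_given_data_and_seeds(self, table):
        datasets = _tiny_datasets(table)
        r1 = benchmark(datasets, ["mil3d_k7", "count_5"], table)
        r2 = benchmark(datasets, ["mil3d_k7", "count_5"], table)
        assert r1.per_model_auc == r2.per_model_auc
        assert r1.paired_test == r2.paired_test

    def test_gain_analyses_present_with_three_tfs(self, table):
        # varying motif degeneracy gives the TFs different consensus
        # strength, hence varying top-kmer totals for the correlation
        datasets = _tiny_datasets(table, n_tf=3, n=50, seed0=80, mutation_rates=[0.0, 0.1, 0.25])
        # smoothed leaf probabilities cap below 0.85 at this sample size,
        # so use a threshold the small trees can reach
        report = benchmark(datasets, ["mil3d_k7", "count_5"], table, top_kmer_threshold=0.6)
        names = {(x, y) for x, y, _, _ in report.correlations}
        assert ("top_kmer_total", "gain_mil3d_k7_over_count_5") in names
        assert ("mean_gc_positive_test", "gain_mil3d_k7_over_count_5") in names
        assert report.paired_test is not None

    def test_planted_model_beats_shuffled_label_control(self, table):
        from mil3d.bags import build_bags
        from mil3d.mil_wrapper import predict_bags, train

        margins = []
        for rep in range(5):
            tr, _ = generate(SyntheticSpec(n_pos=80, n_neg=80, seed=300 + 2 * rep))
            te, _ = generate(SyntheticSpec(n_pos=80, n_neg=80, seed=301 + 2 * rep))
            train_bags = build_bags(label_by_signal(tr, 80, 80), 7, table)
            test_bags = build_bags(label_by_signal(te, 80, 80), 7, table)
            y = [1 if b.label == "positive" else 0 for b in test_bags]

            real = train(train_bags)
            rng = np.random.default_rng(1000 + rep)
            shuffled_labels = rng.permutation([b.label for b in train_bags])
            from mil3d.bags import Bag

            shuffled_bags = [
                Bag(b.probe_id, lab, b.instances, b.k) for b, lab in zip(train_bags, shuffled_labels)
            ]
            control = train(shuffled_bags)
            auc_real = auc(y, [p.bag_probability for p in predict_bags(real, test_bags)])
            auc_ctrl = auc(y, [p.bag_probability for p in predict_bags(control, test_bags)])
            margins.append(auc_real - auc_ctrl)
        assert np.mean(margins) > 0.3

    def test_per_model_error_capture(self, table):
        datasets = _tiny_datasets(table, n_tf=1)
        report = benchmark(datasets, ["mil3d_k7"], None)  # structural model without a table
        assert report.per_model_auc["TF0"] == {}
        assert any("table" in msg for msg in report.errors.values())
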