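"""ROC/PR statistics, KL predictability, drift analysis, and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexfp.evaluate import (
    compare_model_rankings,
    contaminated_negatives,
    cross_term_correlation,
    kl_term_divergence,
    ks_right_tailed,
    paired_auc_test,
    pairwise_term_eval,
    pr_convex_hull,
    read_performance_table,
    roc_auc,
    single_gene_auc,
    term_pairs_in_gene_set,
    TermPerformance,
)
from coexfp.goldstd import AnnotationSet, TermSet
from coexfp.neural import NetworkConfig, TrainedFold, TrainingConfig, init_network, predict_pairs
from coexfp.ranking import GeneRanking
from coexfp.synthetic import drift_annotations


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == 1.0
        assert curve.fpr[0] == 0.0 and curve.tpr[-1] == 1.0

    def test_known_value(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 10, size=n) / 10.0  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def hull_envelope(points, xs):
    """Oracle: upper envelope = max over all point-pair segments at each x."""
    best = np.full(len(xs), -np.inf)
    for (x1, y1), (x2, y2) in itertools.combinations(points, 2):
        if x1 == x2:
            continue
        t = (xs - x1) / (x2 - x1)
        seg = y1 + t * (y2 - y1)
        valid = (t >= -1e-12) & (t <= 1 + 1e-12)
        best = np.where(valid, np.maximum(best, seg), best)
    for x, y in points:
        best = np.where(np.isclose(xs, x), np.maximum(best, y), best)
    return best


class TestPrCurve:
    def test_all_positives_first_has_unit_precision(self):
        pr = pr_convex_hull([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert np.all(pr.precision[pr.recall > 0] >= 1.0 - 1e-12)

    def test_hull_dominates_raw_curve(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        raw = pr_convex_hull(scores, labels, hull=False)
        hull = pr_convex_hull(scores, labels, hull=True)
        interp = np.interp(raw.recall, hull.recall, hull.precision)
        assert np.all(interp >= raw.precision - 1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_hull_matches_envelope_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        labels = rng.integers(0, 2, size=12)
        if labels.sum() == 0:
            labels[0] = 1
        raw = pr_convex_hull(scores, labels, hull=False)
        hull = pr_convex_hull(scores, labels, hull=True)
        pts = np.column_stack([raw.recall, raw.precision])
        xs = np.linspace(raw.recall.min(), raw.recall.max(), 101)
        expected = hull_envelope(pts, xs)
        got = np.interp(xs, hull.recall, hull.precision)
        assert np.allclose(got, expected, atol=1e-9)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_convex_hull([0.5, 0.4], [0, 0])


@pytest.fixture(scope="module")
def pair_eval_setting():
    genes = [f"g{i}" for i in range(12)]
    ann = AnnotationSet(
        "s", {g: ({"T"} if i < 4 else {"X"}) for i, g in enumerate(genes)},
        genome_size=100,
    )
    term_set = TermSet(["T", "X"])
    nconf = NetworkConfig(input_size=2, output_size=2, hidden_sizes=(4,))
    fold = TrainedFold(
        0, init_network(nconf, seed=0), np.zeros((1, 2)), nconf,
        TrainingConfig(iterations=1), 0,
    )
    rng = np.random.default_rng(5)

    class FakeFeatures:
        F = {
            tuple(sorted(p)): rng.normal(size=2)
            for p in itertools.combinations(genes, 2)
        }

        def features_for_pairs(self, pairs):
            return np.stack([self.F[tuple(sorted(p))] for p in pairs])

    return genes, ann, term_set, fold, FakeFeatures()


class TestPairwiseTermEval:
    def test_exhaustive_when_sample_covers_all_pairs(self, pair_eval_setting):
        genes, ann, term_set, fold, feats = pair_eval_setting
        auc = pairwise_term_eval(
            fold, "T", genes, ann, term_set, feats, max_pos=10_000, seed=0
        )
        pos, neg = term_pairs_in_gene_set("T", genes, ann)
        X = feats.features_for_pairs(pos + neg)
        preds = predict_pairs(fold, X)[:, term_set.index("T")]
        labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        assert auc == pytest.approx(brute_force_auc(preds, labels), abs=1e-12)

    def test_positive_and_negative_pair_definitions(self, pair_eval_setting):
        genes, ann, _, _, _ = pair_eval_setting
        pos, neg = term_pairs_in_gene_set("T", genes, ann)
        assert len(pos) == math.comb(4, 2)
        assert len(neg) == math.comb(8, 2)
        member = ann.genes_for_term("T")
        assert all(a in member and b in member for a, b in pos)
        assert all(a not in member and b not in member for a, b in neg)

    def test_no_positives_gives_nan(self, pair_eval_setting):
        genes, ann, term_set, fold, feats = pair_eval_setting
        assert math.isnan(
            pairwise_term_eval(fold, "T", genes[6:], ann, term_set, feats)
        )

    def test_deterministic_given_seed(self, pair_eval_setting):
        genes, ann, term_set, fold, feats = pair_eval_setting
        a = pairwise_term_eval(fold, "T", genes, ann, term_set, feats, max_pos=3, seed=4)
        b = pairwise_term_eval(fold, "T", genes, ann, term_set, feats, max_pos=3, seed=4)
        assert a == b


@pytest.fixture(scope="module")
def avgz():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(40)]
    A = rng.normal(size=(40, 40))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    index = {g: i for i, g in enumerate(genes)}
    pairs = list(itertools.combinations(genes, 2))
    return genes, A, index, pairs


class TestKlDivergence:

    def test_same_pool_gives_near_zero(self, avgz):
        genes, A, index, pairs = avgz
        d = kl_term_divergence(genes, A, index, pairs, n_samples=100_000, seed=0)
        assert d.d_kl < 0.01

    def test_nonnegative_always(self, avgz):
        genes, A, index, pairs = avgz
        for seed in range(3):
            d = kl_term_divergence(genes[:10], A, index, pairs, n_samples=5000, seed=seed)
            assert d.d_kl >= 0.0

    def test_histograms_share_edges_and_normalize(self, avgz):
        genes, A, index, pairs = avgz
        d = kl_term_divergence(genes[:8], A, index, pairs, n_samples=5000, seed=1)
        assert d.t_hist.sum() == pytest.approx(1.0)
        assert d.b_hist.sum() == pytest.approx(1.0)
        assert len(d.edges) == len(d.t_hist) + 1

    def test_increases_with_planted_strength(self, demo_run):
        """Stronger co-regulation must diverge more from the background."""
        perfs = read_performance_table(demo_run.output_dir / "performance.csv")
        kl = {p.term_id: p.kl_divergence for p in perfs}
        assert kl["T01"] < kl["T04"] < kl["T07"]  # strengths 0.2 < 0.6 < 0.9

    def test_too_few_genes_rejected(self, avgz):
        genes, A, index, pairs = avgz
        with pytest.raises(ValueError):
            kl_term_divergence(genes[:1], A, index, pairs)


def _ranking_from_scores(genes, scores, labels):
    df = pd.DataFrame({"gene": genes, "score": scores, "label": labels})
    df = df.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneRanking("T", df[["gene", "score", "rank", "label"]])


class TestContaminatedNegatives:
    def test_identical_snapshots_give_empty_set(self):
        ann = AnnotationSet("x", {"a": {"T"}, "b": {"X"}}, genome_size=10)
        ranking = _ranking_from_scores(
            ["a", "b", "c"], [0.9, 0.5, 0.1], ["positive", "negative", "unlabeled"]
        )
        assert len(contaminated_negatives(ranking, ann, ann, "T")) == 0

    def test_recovers_drifted_genes_by_set_algebra(self, tiny_data):
        _, truth = tiny_data
        drifted = drift_annotations(truth, 0.2, seed=3)
        ann_old = drifted.annotation_set("old")
        ann_new = drifted.annotation_set("new")
        term = "T_strong"
        gold_old = ann_old.annotated_genes()
        genes = list(truth.gene_universe)
        rng = np.random.default_rng(0)
        labels = [
            "positive" if g in ann_old.genes_for_term(term)
            else ("negative" if g in gold_old else "unlabeled")
            for g in genes
        ]
        ranking = _ranking_from_scores(genes, rng.random(len(genes)), labels)
        got = set(contaminated_negatives(ranking, ann_old, ann_new, term)["gene"])
        # independent set algebra: new members that were gold-but-negative
        expected = (ann_new.genes_for_term(term) - ann_old.genes_for_term(term)) & gold_old
        assert got == expected


class TestKsRightTailed:
    def test_identical_samples(self):
        a = np.array([0.85, 0.9, 0.95])
        stat, p = ks_right_tailed(a, a.copy())
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_right_tailed([0.99, 0.98, 0.97], [0.82, 0.83, 0.84])
        assert stat == pytest.approx(1.0)

    def test_window_filters_samples(self):
        with pytest.raises(ValueError):
            ks_right_tailed([0.1, 0.2], [0.9, 0.95], window=(0.8, 1.0))

    @pytest.mark.parametrize("seed", range(4))
    def test_statistic_matches_ecdf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.8, 1.0, size=20)
        b = rng.uniform(0.8, 1.0, size=15)
        stat, _ = ks_right_tailed(a, b)
        grid = np.concatenate([a, b])
        fa = (a[:, None] <= grid[None, :]).mean(axis=0)
        fb = (b[:, None] <= grid[None, :]).mean(axis=0)
        assert stat == pytest.approx(np.max(fb - fa), abs=1e-12)


class TestCrossTermCorrelation:
    def _perfs(self, xs, ys):
        return [
            TermPerformance(f"T{i}", train_auc=x, test_auc=y, single_gene_auc=0.5, kl_divergence=0.1)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_identity_and_negation(self):
        xs = [0.5, 0.6, 0.7, 0.8]
        assert cross_term_correlation(self._perfs(xs, xs), "train_auc", "test_auc")[0] == pytest.approx(1.0)
        neg = [1 - x for x in xs]
        assert cross_term_correlation(self._perfs(xs, neg), "train_auc", "test_auc")[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        xs = [0.52, 0.61, 0.77, 0.69, 0.90]
        ys = [0.48, 0.66, 0.70, 0.75, 0.81]
        r, p = cross_term_correlation(self._perfs(xs, ys), "train_auc", "test_auc")
        x, y = np.array(xs), np.array(ys)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)
        t = expected * math.sqrt(3 / (1 - expected**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_term_correlation(self._perfs([0.5] * 4, [0.1, 0.2, 0.3, 0.4]), "train_auc", "test_auc")


class TestPairedAucTest:
    def test_uniform_improvement_is_significant(self):
        rng = np.random.default_rng(1)
        a1 = rng.uniform(0.6, 0.9, size=20)
        a2 = a1 + 0.05 + rng.normal(0, 1e-3, size=20)
        assert paired_auc_test(a1, a2) < 1e-6

    def test_matches_direct_t_statistic(self):
        a1 = np.array([0.6, 0.7, 0.8, 0.75, 0.65])
        a2 = np.array([0.66, 0.69, 0.85, 0.80, 0.70])
        p = paired_auc_test(a1, a2)
        d = a2 - a1
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert p == pytest.approx(float(stats.t.sf(t, df=len(d) - 1)), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_auc_test([0.5, 0.6, 0.7], [0.55, 0.65, 0.75])


class TestModelComparison:
    @pytest.fixture()
    def table(self):
        genes = [f"g{i}" for i in range(10)]
        perfect = np.linspace(1, 0.1, 10)
        noisy = np.random.default_rng(0).random(10)
        old = [1, 1, -1, -1, -1, -1, 0, 0, -1, -1]
        new = [1, 1, 1, -1, -1, -1, 0, 0, -1, 1]
        return pd.DataFrame(
            {"gene": genes, "nn": perfect, "other": noisy, "label_old": old, "label_new": new}
        )

    def test_perfect_model_auc(self, table):
        report = compare_model_rankings(
            table, ["nn", "other"], "label_old", "label_new", window=(0.0, 1.0)
        )
        assert report["models"]["nn"]["auc_old"] == 1.0

    def test_contaminated_count_matches_set_algebra(self, table):
        report = compare_model_rankings(
            table, ["nn"], "label_old", "label_new", window=(0.0, 1.0)
        )
        expected = ((table["label_old"] == -1) & (table["label_new"] == 1)).sum()
        assert report["n_contaminated"] == expected == 2

    def test_identical_labels_no_contamination(self, table):
        t = table.copy()
        t["label_new"] = t["label_old"]
        report = compare_model_rankings(t, ["nn"], "label_old", "label_new", window=(0.0, 1.0))
        assert report["n_contaminated"] == 0

    def test_ks_matches_evaluation_oracle(self, table):
        report = compare_model_rankings(
            table, ["nn", "other"], "label_old", "label_new", window=(0.0, 1.0)
        )
        a = np.array(report["models"]["nn"]["contaminated_relative_ranks"])
        b = np.array(report["models"]["other"]["contaminated_relative_ranks"])
        stat, p = ks_right_tailed(a, b, window=(0.0, 1.0))
        assert report["ks_tests"]["nn_vs_other"]["statistic"] == pytest.approx(stat)
        assert report["ks_tests"]["nn_vs_other"]["p_value"] == pytest.approx(p)


def test_single_gene_auc_ignores_unlabeled():
    ranking = _ranking_from_scores(
        ["a", "b", "c", "d", "e"],
        [0.9, 0.8, 0.7, 0.6, 0.5],
        ["positive", "unlabeled", "positive", "negative", "negative"],
    )
    # among labeled genes the two positives outrank the two negatives
    assert single_gene_auc(ranking) == 1.0


def test_performance_table_recomputation_path(demo_run):
    """The persisted per-term table supports the cross-term analyses."""
    perfs = read_performance_table(demo_run.output_dir / "performance.csv")
    assert len(perfs) == 8
    r, p = cross_term_correlation(perfs, "kl_divergence", "test_auc")
    assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0
    for perf in perfs:
        assert perf.overfitting == pytest.approx(perf.train_auc - perf.test_auc)
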