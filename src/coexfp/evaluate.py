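"""Performance and analysis statistics for pairwise and single-gene predictions.

Covers ROC curves and tie-corrected AUC, convex-hulled precision-recall
curves, per-term pairwise evaluation with sampled positives and 10x negatives,
per-term overfitting (train minus test AUC), KL-divergence predictability of a
term's co-expression distribution against the training background,
contaminated-negative analysis between two annotation snapshots, right-tailed
two-sample Kolmogorov-Smirnov comparisons of relative-rank distributions, and
cross-term correlations of performance statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .goldstd import AnnotationSet, TermSet
from .neural import TrainedFold, predict_pairs
from .ranking import NEGATIVE, POSITIVE, GeneRanking, relative_ranks

DEFAULT_MAX_POS = 10_000
DEFAULT_NEG_FACTOR = 10
DEFAULT_KL_SAMPLES = 200_000
DEFAULT_KL_BINS = 100
DEFAULT_RANK_WINDOW = (0.8, 1.0)


@dataclass(eq=False)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass(eq=False)
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    hulled: bool


@dataclass(frozen=True)
class TermPerformance:
    term_id: str
    train_auc: float
    test_auc: float
    single_gene_auc: float
    kl_divergence: float

    @property
    def overfitting(self) -> float:
        return self.train_auc - self.test_auc


@dataclass(eq=False)
class DivergencePair:
    """Histograms of average pair z-scores: term (T) vs background (B)."""

    t_hist: np.ndarray
    b_hist: np.ndarray
    edges: np.ndarray
    d_kl: float

    def __post_init__(self) -> None:
        if self.d_kl < 0:
            raise ValueError("KL divergence cannot be negative")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC sweep with trapezoidal tie handling; AUC is the Mann-Whitney
    tie-corrected probability of ranking a positive above a negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(labels, scores)))


def _upper_hull(points: np.ndarray) -> np.ndarray:
    """Upper convex hull of 2-D points, by ascending x (monotone chain)."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) >= 0:
                hull.pop()
            else:
                break
        # among duplicate x keep only the highest y
        if hull and hull[-1][0] == p[0]:
            if p[1] > hull[-1][1]:
                hull[-1] = p
            continue
        hull.append(p)
    return np.array(hull)


def pr_convex_hull(scores: np.ndarray, labels: np.ndarray, hull: bool = True) -> PrCurve:
    """Precision-recall curve, optionally replaced by its upper convex hull."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.sum() < 1:
        raise ValueError("need at least one positive")
    precision, recall, _ = precision_recall_curve(labels, scores)
    order = np.argsort(recall, kind="mergesort")
    recall, precision = recall[order], precision[order]
    if not hull:
        return PrCurve(recall=recall, precision=precision, hulled=False)
    pts = _upper_hull(np.column_stack([recall, precision]))
    return PrCurve(recall=pts[:, 0], precision=pts[:, 1], hulled=True)


def _sample_rows(pairs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if len(pairs) <= n:
        return pairs
    return pairs[rng.choice(len(pairs), size=n, replace=False)]


def term_pairs_in_gene_set(
    term: str, gene_set: Sequence[str], ann: AnnotationSet
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positive (co-annotated) and negative (neither annotated) pairs within a set."""
    genes = sorted(gene_set)
    member = ann.genes_for_term(term)
    pos_genes = [g for g in genes if g in member]
    neg_genes = [g for g in genes if g not in member]
    positives = list(itertools.combinations(pos_genes, 2))
    negatives = list(itertools.combinations(neg_genes, 2))
    return positives, negatives


def pairwise_term_eval(
    fold: TrainedFold,
    term: str,
    gene_set: Sequence[str],
    ann: AnnotationSet,
    term_set: TermSet,
    features,
    max_pos: int = DEFAULT_MAX_POS,
    neg_factor: int = DEFAULT_NEG_FACTOR,
    seed: int = 0,
) -> float:
    """Per-term pairwise AUC of one fold over a train or test gene set.

    Samples up to ``max_pos`` co-annotated pairs and ``neg_factor`` times as
    many pairs where neither gene is annotated to the term, scores them with
    the fold's network, and returns the ROC AUC for that term's output.
    Returns NaN (with no exception) when the gene set yields no positive or no
    negative pair, so callers can skip unevaluable terms.
    """
    positives, negatives = term_pairs_in_gene_set(term, gene_set, ann)
    if not positives or not negatives:
        return float("nan")
    rng = np.random.default_rng(seed)
    pos = _sample_rows(np.array(positives, dtype=object), max_pos, rng)
    neg = _sample_rows(
        np.array(negatives, dtype=object), neg_factor * len(pos), rng
    )
    pairs = [tuple(p) for p in pos] + [tuple(p) for p in neg]
    X = features.features_for_pairs(pairs)
    preds = predict_pairs(fold, X)[:, term_set.index(term)]
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return roc_auc(preds, labels).auc


def mean_fold_auc(
    folds: Sequence[TrainedFold],
    term: str,
    gene_sets: Sequence[Sequence[str]],
    ann: AnnotationSet,
    term_set: TermSet,
    features,
    max_pos: int = DEFAULT_MAX_POS,
    neg_factor: int = DEFAULT_NEG_FACTOR,
    seed: int = 0,
) -> float:
    """Unweighted mean per-term AUC across folds (NaN folds skipped)."""
    aucs = [
        pairwise_term_eval(
            fold, term, gene_sets[i], ann, term_set, features,
            max_pos=max_pos, neg_factor=neg_factor, seed=seed + i,
        )
        for i, fold in enumerate(folds)
    ]
    aucs = [a for a in aucs if np.isfinite(a)]
    return float(np.mean(aucs)) if aucs else float("nan")


def kl_term_divergence(
    term_genes: Iterable[str],
    avg_z: np.ndarray,
    gene_index: Mapping[str, int],
    training_pairs: Sequence[tuple[str, str]],
    n_samples: int = DEFAULT_KL_SAMPLES,
    bins: int = DEFAULT_KL_BINS,
    seed: int = 0,
    smoothing: float = 1.0,
) -> DivergencePair:
    """D_KL(T || B) between a term's average-z distribution and the background.

    T is estimated from ``n_samples`` pairs of term genes sampled with
    replacement; B from ``n_samples`` of all training pairs.  Both histograms
    share equal-width bin edges spanning the pooled sample range and receive
    ``smoothing`` pseudo-counts per bin before normalization.
    """
    members = sorted(set(term_genes))
    if len(members) < 2:
        raise ValueError("term needs at least 2 annotated genes")
    rng = np.random.default_rng(seed)
    midx = np.array([gene_index[g] for g in members])
    ti = rng.integers(0, len(members), size=n_samples)
    tj = rng.integers(0, len(members) - 1, size=n_samples)
    tj = np.where(tj >= ti, tj + 1, tj)  # uniform over ordered non-self pairs
    t_vals = avg_z[midx[ti], midx[tj]]
    bg = np.asarray(
        [(gene_index[a], gene_index[b]) for a, b in training_pairs], dtype=int
    )
    bsel = rng.integers(0, len(bg), size=n_samples)
    b_vals = avg_z[bg[bsel, 0], bg[bsel, 1]]
    pooled = np.concatenate([t_vals, b_vals])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        raise ValueError("degenerate samples: all average z-scores identical")
    edges = np.linspace(lo, hi, bins + 1)
    t_hist = np.histogram(t_vals, bins=edges)[0] + smoothing
    b_hist = np.histogram(b_vals, bins=edges)[0] + smoothing
    t_hist = t_hist / t_hist.sum()
    b_hist = b_hist / b_hist.sum()
    d = float(stats.entropy(t_hist, b_hist))
    return DivergencePair(t_hist=t_hist, b_hist=b_hist, edges=edges, d_kl=d)


def contaminated_negatives(
    ranking: GeneRanking,
    ann_old: AnnotationSet,
    ann_new: AnnotationSet,
    term: str,
) -> pd.DataFrame:
    """Genes labeled negative at training time but annotated to the term now.

    Returns a frame (gene, relative_rank) over genes whose evaluation label in
    ``ranking`` (derived from ``ann_old``) is negative and that ``ann_new``
    annotates to the term.
    """
    new_members = ann_new.genes_for_term(term)
    rel = relative_ranks(ranking)
    tab = ranking.table
    mask = (tab["label"] == NEGATIVE) & tab["gene"].isin(new_members)
    genes = tab.loc[mask, "gene"].tolist()
    return pd.DataFrame(
        {"gene": genes, "relative_rank": [rel[g] for g in genes]}
    ).sort_values("gene").reset_index(drop=True)


def ks_right_tailed(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    window: tuple[float, float] | None = DEFAULT_RANK_WINDOW,
) -> tuple[float, float]:
    """One-sided two-sample KS test that ``sample_a`` is stochastically greater.

    Samples are restricted to the high-confidence relative-rank window (top
    20% by default) before testing; pass ``window=None`` to use all values.
    The alternative is that a's empirical CDF lies below b's.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if window is not None:
        lo, hi = window
        a = a[(a >= lo) & (a <= hi)]
        b = b[(b >= lo) & (b <= hi)]
    if a.size == 0 or b.size == 0:
        raise ValueError("no samples fall inside the analysis window")
    res = stats.ks_2samp(a, b, alternative="less")
    return float(res.statistic), float(res.pvalue)


def single_gene_auc(ranking: GeneRanking) -> float:
    """ROC AUC of a single-gene ranking; unlabeled genes are ignored."""
    tab = ranking.table
    labeled = tab[tab["label"].isin([POSITIVE, NEGATIVE])]
    labels = (labeled["label"] == POSITIVE).astype(int).to_numpy()
    return roc_auc(labeled["score"].to_numpy(), labels).auc


def cross_term_correlation(
    performances: Sequence[TermPerformance], field_x: str, field_y: str
) -> tuple[float, float]:
    """Pearson correlation across terms of two performance fields."""
    if len(performances) < 3:
        raise ValueError("need at least 3 terms")
    x = np.array([getattr(p, field_x) for p in performances], dtype=float)
    y = np.array([getattr(p, field_y) for p in performances], dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fewer than 3 terms with finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the fields")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_auc_test(
    auc_model_1: Sequence[float], auc_model_2: Sequence[float]
) -> float:
    """Right-tailed paired t-test that model 2's per-term AUCs exceed model 1's."""
    a1 = np.asarray(auc_model_1, dtype=float)
    a2 = np.asarray(auc_model_2, dtype=float)
    if a1.shape != a2.shape or a1.size < 3:
        raise ValueError("need matching AUC vectors over at least 3 terms")
    if np.ptp(a2 - a1) == 0:
        raise ValueError("zero-variance differences: t-test undefined")
    return float(stats.ttest_rel(a2, a1, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# tables


PERFORMANCE_COLUMNS = [
    "term",
    "train_auc",
    "test_auc",
    "overfitting",
    "single_gene_auc",
    "kl_divergence",
]


def performance_table(performances: Sequence[TermPerformance]) -> pd.DataFrame:
    rows = [
        [p.term_id, p.train_auc, p.test_auc, p.overfitting, p.single_gene_auc, p.kl_divergence]
        for p in performances
    ]
    return pd.DataFrame(rows, columns=PERFORMANCE_COLUMNS)


def read_performance_table(path: str | Path) -> list[TermPerformance]:
    df = pd.read_csv(path, comment="#")
    return [
        TermPerformance(
            term_id=str(r.term),
            train_auc=float(r.train_auc),
            test_auc=float(r.test_auc),
            single_gene_auc=float(r.single_gene_auc),
            kl_divergence=float(r.kl_divergence),
        )
        for r in df.itertuples(index=False)
    ]


def read_model_rankings(path: str | Path) -> pd.DataFrame:
    """Read a cross-model ranking table: gene, per-model score/rank columns,
    and label columns coded 1 / -1 / 0."""
    df = pd.read_csv(path, comment="#")
    if "gene" not in df.columns:
        raise ValueError("ranking table must have a 'gene' column")
    return df


def compare_model_rankings(
    table: pd.DataFrame,
    model_cols: Sequence[str],
    old_label_col: str,
    new_label_col: str,
    window: tuple[float, float] = DEFAULT_RANK_WINDOW,
) -> dict:
    """Cross-model report: AUC under both label sets, contaminated negatives,
    and pairwise right-tailed KS tests of their relative ranks.

    ``model_cols`` are score columns (higher = stronger prediction).  Labels
    are 1 (positive), -1 (negative), 0 (unlabeled).
    """
    for col in (old_label_col, new_label_col, *model_cols):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    report: dict = {"models": {}, "ks_tests": {}}
    n = len(table)
    contaminated_mask = (table[old_label_col] == -1) & (table[new_label_col] == 1)
    report["n_contaminated"] = int(contaminated_mask.sum())
    rel_ranks: dict[str, np.ndarray] = {}
    for col in model_cols:
        scores = table[col].to_numpy(dtype=float)
        order = np.argsort(-scores, kind="mergesort")
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(1, n + 1)
        rel = (n - rank + 1) / n
        entry: dict = {}
        for tag, label_col in (("old", old_label_col), ("new", new_label_col)):
            lab = table[label_col].to_numpy()
            mask = lab != 0
            if len(np.unique(lab[mask])) == 2:
                entry[f"auc_{tag}"] = roc_auc(scores[mask], (lab[mask] == 1)).auc
                pr = pr_convex_hull(scores[mask], (lab[mask] == 1))
                entry[f"pr_{tag}"] = {
                    "recall": pr.recall.tolist(),
                    "precision": pr.precision.tolist(),
                }
        rel_ranks[col] = rel[contaminated_mask.to_numpy()]
        entry["contaminated_relative_ranks"] = sorted(rel_ranks[col].tolist())
        report["models"][col] = entry
    for a, b in itertools.combinations(model_cols, 2):
        try:
            stat, p = ks_right_tailed(rel_ranks[a], rel_ranks[b], window=window)
            report["ks_tests"][f"{a}_vs_{b}"] = {"statistic": stat, "p_value": p}
        except ValueError:
            report["ks_tests"][f"{a}_vs_{b}"] = None
    return report
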