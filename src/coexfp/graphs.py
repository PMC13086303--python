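"""Fold-aware aggregation of pairwise predictions into per-term graphs.

A gene pair's final score averages the outputs of exactly the folds that held
out at least one of its genes, so no fold ever scores a pair it trained on.
Pairs involving uncharacterized genes were held out of every fold's training
data and therefore average all folds.  Per term, the aggregated scores become
edge weights of a complete functional relationship graph over the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .goldstd import TermSet
from .neural import TrainedFold, predict_pairs


def contributing_folds(
    a: str, b: str, fold_of: Mapping[str, int], n_folds: int
) -> frozenset[int]:
    """Folds whose networks may score the pair (a, b).

    Both genes gold: the folds holding out either gene (one fold when they
    share it).  Either gene uncharacterized: all folds.
    """
    fa = fold_of.get(a)
    fb = fold_of.get(b)
    if fa is None or fb is None:
        return frozenset(range(n_folds))
    return frozenset({fa, fb})


def aggregate_scores(
    fold_scores: Mapping[int, np.ndarray], contributing: Iterable[int]
) -> np.ndarray:
    """Unweighted per-term mean over the contributing folds' score vectors."""
    contributing = sorted(set(contributing))
    missing = [f for f in contributing if f not in fold_scores]
    if missing:
        raise KeyError(f"missing predictions for folds {missing}")
    return np.mean([np.asarray(fold_scores[f], dtype=float) for f in contributing], axis=0)


@dataclass(eq=False)
class FunctionalRelationshipGraph:
    """Complete weighted graph over genes for one term; weights in [0, 1]."""

    term_id: str
    genes: tuple[str, ...]
    weights: np.ndarray  # (G, G) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.weights = np.asarray(self.weights, dtype=float)
        G = len(self.genes)
        if self.weights.shape != (G, G):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(self.weights, 0.0)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def weight(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError("no self-edges")
        return float(self.weights[self._index[a], self._index[b]])

    def subgraph(self, genes: Sequence[str]) -> "FunctionalRelationshipGraph":
        idx = np.array([self._index[g] for g in genes])
        return FunctionalRelationshipGraph(
            term_id=self.term_id,
            genes=tuple(genes),
            weights=self.weights[np.ix_(idx, idx)],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        iu, ju = np.triu_indices(len(self.genes), k=1)
        g.add_weighted_edges_from(
            (self.genes[i], self.genes[j], float(self.weights[i, j]))
            for i, j in zip(iu, ju)
        )
        return g

    def edge_dataframe(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in iu],
                "gene_b": [self.genes[j] for j in ju],
                "weight": self.weights[iu, ju],
            }
        )


def build_graphs(
    genes: Sequence[str],
    trained_folds: Sequence[TrainedFold],
    features,
    fold_of: Mapping[str, int],
    term_set: TermSet,
    batch_pairs: int = 8192,
) -> dict[str, FunctionalRelationshipGraph]:
    """Score all unordered gene pairs and assemble one graph per term.

    Pairs are streamed in batches so the all-pairs score table is never
    materialized beyond one batch at a time.  ``features`` is any object with
    ``gene_index`` and ``features_for_index_pairs`` (a
    :class:`~coexfp.compendium.CompendiumFeatures`).
    """
    genes = tuple(genes)
    G = len(genes)
    k = len(trained_folds)
    n_terms = len(term_set)
    fold_arr = np.array([fold_of.get(g, -1) for g in genes])
    uni = np.array([features.gene_index[g] for g in genes])
    W = {t: np.zeros((G, G)) for t in term_set}
    iu, ju = np.triu_indices(G, k=1)
    for lo in range(0, iu.size, batch_pairs):
        hi = lo + batch_pairs
        bi, bj = iu[lo:hi], ju[lo:hi]
        X = features.features_for_index_pairs(uni[bi], uni[bj])
        preds = np.stack([predict_pairs(f, X) for f in trained_folds])  # (k, n, T)
        fa, fb = fold_arr[bi], fold_arr[bj]
        both_gold = (fa >= 0) & (fb >= 0)
        fold_ids = np.arange(k)[:, None]
        contrib = np.where(both_gold, (fa == fold_ids) | (fb == fold_ids), True)
        agg = np.einsum("kn,knt->nt", contrib.astype(float), preds)
        agg /= contrib.sum(axis=0)[:, None]
        for t_idx, term in enumerate(term_set):
            W[term][bi, bj] = agg[:, t_idx]
    graphs = {}
    for term in term_set:
        m = W[term]
        m = m + m.T
        graphs[term] = FunctionalRelationshipGraph(term_id=term, genes=genes, weights=m)
    return graphs


# ---------------------------------------------------------------------------
# on-disk formats: per-term edge lists plus a manifest


def write_graphs(
    graphs: Mapping[str, FunctionalRelationshipGraph],
    outdir: str | Path,
    header_comment: str | None = None,
    prune_below: float | None = None,
) -> Path:
    """Write per-term (gene_a, gene_b, weight) TSV shards and a manifest.

    ``prune_below`` optionally drops edges under a threshold for storage; the
    ranking module treats absent edges as weight 0 only when pruning was used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for term in sorted(graphs):
        frg = graphs[term]
        safe = term.replace(":", "_").replace("/", "_")
        shard = outdir / f"frg_{safe}.tsv"
        df = frg.edge_dataframe()
        if prune_below is not None:
            df = df[df["weight"] >= prune_below]
        with open(shard, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        manifest_rows.append((term, shard.name, len(frg.genes)))
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("term\tshard\tn_genes\n")
        for term, name, n in manifest_rows:
            fh.write(f"{term}\t{name}\t{n}\n")
    return manifest


def read_graphs(
    outdir: str | Path, genes: Sequence[str]
) -> dict[str, FunctionalRelationshipGraph]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t", comment="#")
    genes = tuple(genes)
    index = {g: i for i, g in enumerate(genes)}
    graphs = {}
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(outdir / str(row.shard), sep="\t", comment="#")
        W = np.zeros((len(genes), len(genes)))
        ia = df["gene_a"].map(index).to_numpy()
        ib = df["gene_b"].map(index).to_numpy()
        W[ia, ib] = df["weight"].to_numpy()
        W[ib, ia] = df["weight"].to_numpy()
        graphs[str(row.term)] = FunctionalRelationshipGraph(
            term_id=str(row.term), genes=genes, weights=W
        )
    return graphs
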