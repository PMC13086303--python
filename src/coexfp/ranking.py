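"""Single-gene rankings from functional relationship graphs.

Guilt by association: a gene's score for a term is the mean weight of its
edges to the genes annotated to that term (excluding itself when it is one of
them).  Every genome gene is scored and sorted; genes annotated to the term
are evaluation positives, all other gold genes negatives, and uncharacterized
genes stay unlabeled.  The annotation snapshot used for the averaging is the
training-time snapshot — later snapshots are only ever used to re-label an
existing ranking for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .goldstd import AnnotationSet
from .graphs import FunctionalRelationshipGraph

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

#: numeric label codes used in combined ranking tables
LABEL_CODES = {POSITIVE: 1, NEGATIVE: -1, UNLABELED: 0}


def gene_score(
    gene: str, frg: FunctionalRelationshipGraph, annotated: Iterable[str]
) -> float:
    """Mean edge weight from ``gene`` to the annotated genes, self excluded."""
    others = [a for a in annotated if a != gene]
    if not others:
        raise ValueError(f"no annotated genes other than {gene!r}")
    return float(np.mean([frg.weight(gene, a) for a in others]))


@dataclass(eq=False)
class GeneRanking:
    """Ranked gene list for one term with evaluation labels.

    ``table`` columns: gene, score, rank (1 = best), label.  Scores are
    non-increasing; ties are broken by gene identifier so rankings are
    reproducible.
    """

    term_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        scores = self.table["score"].to_numpy()
        if np.any(np.diff(scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        self._pos = {g: r for g, r in zip(self.table["gene"], self.table["rank"])}

    def __len__(self) -> int:
        return len(self.table)

    def rank_of(self, gene: str) -> int:
        return int(self._pos[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos


def rank_term(
    frg: FunctionalRelationshipGraph,
    ann: AnnotationSet,
    gold_genes: Iterable[str],
    term: str,
) -> GeneRanking:
    """Score and sort every genome gene for one term.

    ``ann`` must be the training-time snapshot; its annotated set drives the
    averaging and the positive labels, gold genes not annotated become
    negatives, and everything else is unlabeled.
    """
    genes = frg.genes
    annotated = sorted(ann.genes_for_term(term) & set(genes))
    if not annotated:
        raise ValueError(f"term {term} has no annotated genes in the graph")
    gold = set(gold_genes)
    idx = {g: i for i, g in enumerate(genes)}
    ann_idx = np.array([idx[g] for g in annotated])
    sums = frg.weights[:, ann_idx].sum(axis=1)  # diagonal is zero: self excluded
    counts = np.full(len(genes), len(annotated), dtype=float)
    is_annotated = np.zeros(len(genes), dtype=bool)
    is_annotated[ann_idx] = True
    counts[is_annotated] -= 1.0
    if np.any(counts == 0):
        raise ValueError(f"term {term} degenerate: a gene has no peers to average over")
    scores = sums / counts
    df = pd.DataFrame({"gene": list(genes), "score": scores})
    df["label"] = [
        POSITIVE if is_annotated[i] else (NEGATIVE if g in gold else UNLABELED)
        for i, g in enumerate(genes)
    ]
    df = df.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneRanking(term_id=term, table=df[["gene", "score", "rank", "label"]])


def relative_rank(ranking: GeneRanking, gene: str) -> float:
    """Relative placement in (0, 1]: 1.0 for the top gene, 1/N for the bottom."""
    if gene not in ranking:
        raise KeyError(f"{gene!r} not in ranking for {ranking.term_id}")
    n = len(ranking)
    return (n - ranking.rank_of(gene) + 1) / n


def relative_ranks(ranking: GeneRanking) -> pd.Series:
    """Relative rank for every gene, indexed by gene."""
    n = len(ranking)
    return pd.Series(
        (n - ranking.table["rank"].to_numpy() + 1) / n,
        index=ranking.table["gene"].to_numpy(),
        name="relative_rank",
    )


# ---------------------------------------------------------------------------
# on-disk formats


def write_ranking(
    ranking: GeneRanking, path: str | Path, header_comment: str | None = None
) -> None:
    with open(Path(path), "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ranking.table.to_csv(fh, index=False, float_format="%.8f")


def read_ranking(path: str | Path, term_id: str | None = None) -> GeneRanking:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    return GeneRanking(term_id=term_id or path.stem, table=df)


def combined_table(rankings: Mapping[str, GeneRanking]) -> pd.DataFrame:
    """Wide table: one row per gene; per-term score, rank, and numeric label.

    Labels use 1 (positive), -1 (negative), 0 (unlabeled), matching the layout
    used for cross-model ranking comparisons.
    """
    out: pd.DataFrame | None = None
    for term in sorted(rankings):
        t = rankings[term].table.set_index("gene")
        block = pd.DataFrame(
            {
                f"{term}_score": t["score"],
                f"{term}_rank": t["rank"],
                f"{term}_label": t["label"].map(LABEL_CODES),
            }
        )
        out = block if out is None else out.join(block)
    assert out is not None
    out = out.sort_index()
    out.index.name = "gene"
    return out.reset_index()
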