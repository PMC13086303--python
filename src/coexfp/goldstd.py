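"""Gold-standard curation: term selection, pair labels, leakage-free CV folds.

Genes annotated to at least one predicted term are the "gold" genes.  A gene
pair is *related* when co-annotated to a predicted term, *unrelated* when both
genes are gold but their functions are known to differ (smallest shared term
covers at least 10% of the genome, or no shared term at all), and *excluded*
otherwise.  Gold genes are split into k random folds; a fold trains only on
pairs whose genes both lie outside the fold and tests only on pairs whose
genes both lie inside it, so no gene ever bridges the train/test divide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

RELATED = "related"
UNRELATED = "unrelated"
EXCLUDED = "excluded"

DEFAULT_MIN_ANNOTATIONS = 10
DEFAULT_GENOME_FRACTION = 0.10
#: fallback genome size when an annotation file declares no gene universe
DEFAULT_GENOME_SIZE = 6000


@dataclass(eq=False)
class AnnotationSet:
    """Gene -> term-set mapping over a declared gene universe."""

    snapshot_id: str
    gene_terms: Mapping[str, frozenset[str]]
    universe: tuple[str, ...] = ()
    genome_size: int | None = None

    def __post_init__(self) -> None:
        self.gene_terms = {g: frozenset(ts) for g, ts in self.gene_terms.items()}
        if not self.universe:
            self.universe = tuple(sorted(self.gene_terms))
        else:
            self.universe = tuple(self.universe)
            missing = set(self.gene_terms) - set(self.universe)
            if missing:
                raise ValueError(f"annotated genes outside universe: {sorted(missing)[:5]}")
        if self.genome_size is None:
            self.genome_size = len(self.universe) or DEFAULT_GENOME_SIZE
        if self.genome_size < len(self.annotated_genes()):
            raise ValueError("genome_size smaller than the number of annotated genes")
        self._term_genes: dict[str, frozenset[str]] = {}
        acc: dict[str, set[str]] = {}
        for g, ts in self.gene_terms.items():
            for t in ts:
                acc.setdefault(t, set()).add(g)
        self._term_genes = {t: frozenset(gs) for t, gs in acc.items()}

    def terms_for_gene(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    def genes_for_term(self, term: str) -> frozenset[str]:
        return self._term_genes.get(term, frozenset())

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._term_genes)

    def annotated_genes(self) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_terms.items() if ts)


class TermSet:
    """Ordered term list fixing the output-neuron order of the networks."""

    def __init__(self, terms: Iterable[str]) -> None:
        self.terms = tuple(terms)
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        self._index = {t: i for i, t in enumerate(self.terms)}

    def index(self, term: str) -> int:
        return self._index[term]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, TermSet) and self.terms == other.terms


def select_terms(
    ann: AnnotationSet,
    slim: Sequence[str],
    min_annotations: int = DEFAULT_MIN_ANNOTATIONS,
) -> TermSet:
    """Keep slim terms with enough annotated genes, in sorted order."""
    if not slim:
        raise ValueError("slim term list is empty")
    kept = sorted(
        t for t in set(slim) if len(ann.genes_for_term(t)) >= min_annotations
    )
    if not kept:
        raise ValueError(
            f"no slim term has >= {min_annotations} annotations in {ann.snapshot_id}"
        )
    return TermSet(kept)


def gold_gene_set(ann: AnnotationSet, term_set: TermSet) -> frozenset[str]:
    """Genes annotated to at least one predicted term."""
    predicted = frozenset(term_set)
    return frozenset(
        g for g, ts in ann.gene_terms.items() if ts & predicted
    )


def classify_pair(
    a: str,
    b: str,
    ann: AnnotationSet,
    term_set: TermSet,
    genome_fraction: float = DEFAULT_GENOME_FRACTION,
    reference_terms: frozenset[str] | None = None,
) -> str:
    """Classify an unordered gene pair as related / unrelated / excluded.

    Related: co-annotated to at least one predicted term.  Unrelated: both
    genes gold, and either they share no term of the reference collection
    (functions known and different) or their smallest shared term covers at
    least ``genome_fraction`` of the genome.  Everything else is excluded.
    The reference collection defaults to the full annotation vocabulary.
    """
    if a == b:
        raise ValueError("self-pairs cannot be classified")
    ta = ann.terms_for_gene(a)
    tb = ann.terms_for_gene(b)
    predicted = frozenset(term_set)
    if ta & tb & predicted:
        return RELATED
    if not (ta & predicted) or not (tb & predicted):
        return EXCLUDED
    shared = ta & tb
    if reference_terms is not None:
        shared &= reference_terms
    if not shared:
        return UNRELATED
    smallest = min(len(ann.genes_for_term(t)) for t in shared)
    if smallest >= genome_fraction * ann.genome_size:
        return UNRELATED
    return EXCLUDED


def make_folds(
    gold_genes: Iterable[str], k: int = 4, seed: int = 0
) -> tuple[frozenset[str], ...]:
    """Random near-equal partition of the gold genes into k folds.

    Seeded shuffle followed by round-robin assignment; fold sizes differ by at
    most one.  Deterministic given the seed.
    """
    genes = sorted(set(gold_genes))
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(genes) < k:
        raise ValueError(f"need at least {k} gold genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, gi in enumerate(order):
        folds[pos % k].append(genes[gi])
    return tuple(frozenset(f) for f in folds)


@dataclass(frozen=True)
class FoldPairs:
    """Classified within-set pairs for one fold's training and testing genes."""

    fold_id: int
    train_related: tuple[tuple[str, str], ...]
    train_unrelated: tuple[tuple[str, str], ...]
    test_related: tuple[tuple[str, str], ...]
    test_unrelated: tuple[tuple[str, str], ...]


def _classified_pairs(
    genes: Sequence[str], ann, term_set, genome_fraction, reference_terms
):
    related, unrelated = [], []
    for a, b in itertools.combinations(sorted(genes), 2):
        kind = classify_pair(
            a, b, ann, term_set,
            genome_fraction=genome_fraction,
            reference_terms=reference_terms,
        )
        if kind == RELATED:
            related.append((a, b))
        elif kind == UNRELATED:
            unrelated.append((a, b))
    return tuple(related), tuple(unrelated)


def enumerate_fold_pairs(
    fold_id: int,
    folds: Sequence[frozenset[str]],
    ann: AnnotationSet,
    term_set: TermSet,
    genome_fraction: float = DEFAULT_GENOME_FRACTION,
    reference_terms: frozenset[str] | None = None,
) -> FoldPairs:
    """Enumerate and classify all train/train and test/test pairs for a fold.

    Training pairs draw both genes from the union of the other folds; testing
    pairs draw both genes from the held-out fold — the leakage control.
    """
    test_genes = folds[fold_id]
    train_genes: set[str] = set()
    for i, f in enumerate(folds):
        if i != fold_id:
            train_genes |= f
    tr_rel, tr_unr = _classified_pairs(
        sorted(train_genes), ann, term_set, genome_fraction, reference_terms
    )
    te_rel, te_unr = _classified_pairs(
        sorted(test_genes), ann, term_set, genome_fraction, reference_terms
    )
    if not tr_rel:
        raise ValueError(f"fold {fold_id} has no related training pairs")
    return FoldPairs(
        fold_id=fold_id,
        train_related=tr_rel,
        train_unrelated=tr_unr,
        test_related=te_rel,
        test_unrelated=te_unr,
    )


def label_vector(
    pair: tuple[str, str], ann: AnnotationSet, term_set: TermSet
) -> np.ndarray:
    """Per-term 0/1 co-annotation vector in term-set order."""
    a, b = pair
    shared = ann.terms_for_gene(a) & ann.terms_for_gene(b)
    out = np.zeros(len(term_set), dtype=float)
    for t in shared:
        if t in term_set:
            out[term_set.index(t)] = 1.0
    return out


def label_matrix(
    pairs: Sequence[tuple[str, str]], ann: AnnotationSet, term_set: TermSet
) -> np.ndarray:
    if not pairs:
        return np.zeros((0, len(term_set)), dtype=float)
    return np.stack([label_vector(p, ann, term_set) for p in pairs])


@dataclass(eq=False)
class GoldStandard:
    """Term set, fold partition, and per-fold classified pair lists."""

    term_set: TermSet
    folds: tuple[frozenset[str], ...]
    fold_pairs: tuple[FoldPairs, ...]
    gold_genes: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        self.fold_of = {g: i for i, f in enumerate(self.folds) for g in f}

    @property
    def k(self) -> int:
        return len(self.folds)


def build_gold_standard(
    ann: AnnotationSet,
    slim: Sequence[str],
    k: int = 4,
    seed: int = 0,
    min_annotations: int = DEFAULT_MIN_ANNOTATIONS,
    genome_fraction: float = DEFAULT_GENOME_FRACTION,
    reference_terms: frozenset[str] | None = None,
) -> GoldStandard:
    term_set = select_terms(ann, slim, min_annotations=min_annotations)
    gold = gold_gene_set(ann, term_set)
    folds = make_folds(gold, k=k, seed=seed)
    fold_pairs = tuple(
        enumerate_fold_pairs(
            i, folds, ann, term_set,
            genome_fraction=genome_fraction,
            reference_terms=reference_terms,
        )
        for i in range(k)
    )
    return GoldStandard(
        term_set=term_set,
        folds=folds,
        fold_pairs=fold_pairs,
        gold_genes=gold,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk formats


def read_annotations(
    path: str | Path,
    snapshot_id: str | None = None,
    universe: Sequence[str] | None = None,
    genome_size: int | None = None,
) -> AnnotationSet:
    """Read GAF 2.x or two-column (gene, term) annotation files.

    GAF rows use the object symbol (column 3, falling back to column 2) and
    the GO ID (column 5); rows with a NOT qualifier are dropped.  Lines
    starting with '!' or '#' are comments.
    """
    path = Path(path)
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) >= 5:
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                gene = fields[2] or fields[1]
                term = fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                continue
            if gene and term:
                gene_terms.setdefault(gene, set()).add(term)
    return AnnotationSet(
        snapshot_id=snapshot_id or path.stem,
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
        universe=tuple(universe) if universe else (),
        genome_size=genome_size,
    )


def read_slim_terms(path: str | Path) -> tuple[str, ...]:
    """One term ID per line; '#' comments and blanks skipped."""
    out = []
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return tuple(out)


def write_term_set(term_set: TermSet, path: str | Path, header_comment: str | None = None) -> None:
    with open(Path(path), "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for t in term_set:
            fh.write(f"{t}\n")


def read_term_set(path: str | Path) -> TermSet:
    return TermSet(read_slim_terms(path))


def write_folds(
    folds: Sequence[frozenset[str]], path: str | Path, header_comment: str | None = None
) -> None:
    with open(Path(path), "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\tfold\n")
        for i, fold in enumerate(folds):
            for g in sorted(fold):
                fh.write(f"{g}\t{i}\n")


def read_folds(path: str | Path) -> tuple[frozenset[str], ...]:
    acc: dict[int, set[str]] = {}
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, fold = line.split("\t")
            acc.setdefault(int(fold), set()).add(gene)
    return tuple(frozenset(acc[i]) for i in sorted(acc))
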