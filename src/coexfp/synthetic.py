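"""Synthetic expression compendia and annotation snapshots with planted structure.

The generator emulates the shape of a curated microarray compendium: several
datasets with differing condition counts, missing entries, and a flat ontology
of terms whose member genes share a term-specific latent expression profile.
Genes annotated to a term follow that term's latent profile scaled by the
term's signal strength, plus independent Gaussian noise; genes in several
terms sum their contributions; genes in no term are pure noise and form the
"uncharacterized" pool.  An annotation-drift operator derives a historical
("old") training snapshot from the generative truth by removing a fraction of
each term's genes (future contaminated negatives) and adding an equal number
of spurious gold genes, emulating how curated annotations improve over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .goldstd import AnnotationSet

#: minimum genes per planted term, mirroring the gold-standard inclusion filter
MIN_TERM_SIZE = 10


@dataclass(frozen=True)
class TermSpec:
    """One planted term: identifier, member count, co-regulation strength."""

    term_id: str
    n_genes: int
    signal_strength: float

    def __post_init__(self) -> None:
        if self.n_genes < MIN_TERM_SIZE:
            raise ValueError(
                f"term {self.term_id}: gene_count must be >= {MIN_TERM_SIZE}"
            )
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError(f"term {self.term_id}: signal_strength must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int
    n_datasets: int
    conditions_per_dataset: tuple[int, ...]
    terms: tuple[TermSpec, ...]
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "conditions_per_dataset", tuple(self.conditions_per_dataset)
        )
        object.__setattr__(
            self,
            "terms",
            tuple(
                t if isinstance(t, TermSpec) else TermSpec(*t) for t in self.terms
            ),
        )
        if len(self.conditions_per_dataset) != self.n_datasets:
            raise ValueError(
                "conditions_per_dataset length must equal n_datasets "
                f"({len(self.conditions_per_dataset)} != {self.n_datasets})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")
        if self.n_genes < max((t.n_genes for t in self.terms), default=0):
            raise ValueError("n_genes smaller than the largest term")
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("term identifiers must be unique")


@dataclass(frozen=True)
class GroundTruth:
    """Planted annotations: the generative truth and a training-time snapshot.

    ``snapshot_new`` is the generative truth (genes actually co-regulated per
    term); ``snapshot_old`` is the snapshot used for training labels.  Before
    drift the two are identical.  After drift, ``moved_out[t]`` lists genes
    truly in term ``t`` but missing from the old snapshot (contaminated
    negatives of the training data) and ``moved_in[t]`` the spurious gold
    genes added in their place.
    """

    snapshot_new: Mapping[str, frozenset[str]]
    snapshot_old: Mapping[str, frozenset[str]]
    strengths: Mapping[str, float]
    gene_universe: tuple[str, ...]
    moved_out: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    moved_in: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.snapshot_new))

    def gold_genes(self, snapshot: str = "new") -> frozenset[str]:
        mapping = self.snapshot_new if snapshot == "new" else self.snapshot_old
        out: set[str] = set()
        for genes in mapping.values():
            out |= genes
        return frozenset(out)

    def annotation_set(self, snapshot: str = "old") -> AnnotationSet:
        """View one snapshot as an :class:`AnnotationSet` over the universe."""
        mapping = self.snapshot_new if snapshot == "new" else self.snapshot_old
        gene_terms: dict[str, set[str]] = {}
        for term, genes in mapping.items():
            for g in genes:
                gene_terms.setdefault(g, set()).add(term)
        return AnnotationSet(
            snapshot_id=snapshot,
            gene_terms={g: frozenset(ts) for g, ts in gene_terms.items()},
            universe=self.gene_universe,
        )


def gene_names(n_genes: int) -> tuple[str, ...]:
    return tuple(f"g{i:04d}" for i in range(n_genes))


def generate_compendium(config: SyntheticConfig):
    """Generate expression datasets and the planted annotation truth.

    Per dataset, each term draws an independent standard-normal latent profile
    over the dataset's conditions; a gene's expression is the sum over its
    terms of signal_strength x profile, plus N(0, noise_sd) noise; entries are
    then masked missing independently at ``missing_rate``.  Deterministic
    given ``config.seed``.

    Returns ``(datasets, truth)`` where ``truth`` has identical old/new
    snapshots (apply :func:`drift_annotations` to derive a drifted training
    snapshot).
    """
    from .compendium import ExpressionDataset  # local import to avoid cycles

    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)

    membership: dict[str, frozenset[str]] = {}
    member_idx: dict[str, np.ndarray] = {}
    for spec in config.terms:
        idx = rng.choice(config.n_genes, size=spec.n_genes, replace=False)
        idx.sort()
        member_idx[spec.term_id] = idx
        membership[spec.term_id] = frozenset(genes[i] for i in idx)

    datasets = []
    for d in range(config.n_datasets):
        n_cond = config.conditions_per_dataset[d]
        dataset_id = f"ds{d:03d}"
        values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_cond))
        for spec in config.terms:
            profile = rng.standard_normal(n_cond)
            values[member_idx[spec.term_id]] += spec.signal_strength * profile
        if config.missing_rate > 0:
            mask = rng.random(values.shape) < config.missing_rate
            values[mask] = np.nan
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_id,
                genes=genes,
                conditions=tuple(f"{dataset_id}_c{j}" for j in range(n_cond)),
                values=values,
            )
        )

    truth = GroundTruth(
        snapshot_new=dict(membership),
        snapshot_old=dict(membership),
        strengths={t.term_id: t.signal_strength for t in config.terms},
        gene_universe=genes,
    )
    return datasets, truth


def drift_annotations(
    truth: GroundTruth, flip_rate: float, seed: int = 0
) -> GroundTruth:
    """Derive a drifted training snapshot from the generative truth.

    Per term, a fraction ``flip_rate`` of the truly annotated genes is removed
    from the old snapshot (they stay co-regulated, so they become contaminated
    negatives of any model trained on the old labels) and an equal number of
    gold genes not annotated to the term is added.  Whole genes move, matching
    how curated annotations change between releases.  Deterministic given seed.
    """
    if not 0.0 <= flip_rate < 1.0:
        raise ValueError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gold = sorted(truth.gold_genes("new"))
    old: dict[str, frozenset[str]] = {}
    moved_out: dict[str, tuple[str, ...]] = {}
    moved_in: dict[str, tuple[str, ...]] = {}
    for term in truth.terms:
        members = sorted(truth.snapshot_new[term])
        n_move = int(round(flip_rate * len(members)))
        if len(members) - n_move < 1:
            raise ValueError(f"flip_rate {flip_rate} would empty term {term}")
        out = sorted(rng.choice(members, size=n_move, replace=False)) if n_move else []
        pool = [g for g in gold if g not in truth.snapshot_new[term]]
        if n_move > len(pool):
            raise ValueError(f"not enough unannotated gold genes to drift {term}")
        into = sorted(rng.choice(pool, size=n_move, replace=False)) if n_move else []
        old[term] = (truth.snapshot_new[term] - set(out)) | set(into)
        moved_out[term] = tuple(out)
        moved_in[term] = tuple(into)
    return GroundTruth(
        snapshot_new=dict(truth.snapshot_new),
        snapshot_old=old,
        strengths=dict(truth.strengths),
        gene_universe=truth.gene_universe,
        moved_out=moved_out,
        moved_in=moved_in,
    )


def write_annotation_file(
    mapping: Mapping[str, frozenset[str]], path: str | Path, header_comment: str | None = None
) -> None:
    """Write a snapshot as a two-column (gene, term) flat file."""
    with open(Path(path), "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for term in sorted(mapping):
            for gene in sorted(mapping[term]):
                fh.write(f"{gene}\t{term}\n")


def write_slim_file(terms: Sequence[str], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for term in sorted(terms):
            fh.write(f"{term}\n")
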