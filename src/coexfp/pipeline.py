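"""End-to-end pipeline: simulate -> normalize -> goldstd -> train -> graphs
-> rank -> evaluate, with every stage idempotent given the configured seeds.

Each stage reads its inputs from the configured directories and writes plain
text artifacts (TSV/CSV, npz checkpoints for weights); downstream stages
reload from disk, so stages can be re-run independently.  Four named seeds
(split / init / sample / calib) control the gold-standard split, weight
initialization, minibatch and evaluation sampling, and normalizer calibration
independently, plus a data seed for the synthetic generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compendium import (
    CompendiumFeatures,
    fit_normalizer,
    read_expression_matrix,
    read_normalizers,
    write_expression_matrix,
    write_normalizers,
)
from .evaluate import (
    TermPerformance,
    contaminated_negatives,
    kl_term_divergence,
    ks_right_tailed,
    mean_fold_auc,
    performance_table,
    single_gene_auc,
)
from .goldstd import (
    AnnotationSet,
    build_gold_standard,
    read_annotations,
    read_folds,
    read_slim_terms,
    read_term_set,
    write_folds,
    write_term_set,
)
from .graphs import build_graphs, read_graphs, write_graphs
from .neural import (
    NetworkConfig,
    TrainedFold,
    TrainingConfig,
    load_checkpoint,
    save_checkpoint,
    train_fold,
    write_loss_trace,
)
from .ranking import combined_table, rank_term, relative_ranks, write_ranking
from .synthetic import (
    SyntheticConfig,
    TermSpec,
    drift_annotations,
    generate_compendium,
    write_annotation_file,
    write_slim_file,
)

logger = logging.getLogger("coexfp")

STAGES = ("normalize", "goldstd", "train", "graphs", "rank", "evaluate")


@dataclass(frozen=True)
class Seeds:
    data: int = 0
    split: int = 1
    init: int = 2
    sample: int = 3
    calib: int = 4


@dataclass
class RunConfig:
    """Full pipeline configuration; serializable to/from YAML."""

    output_dir: Path
    data_dir: Path | None = None  # where simulate writes / real data lives
    synthetic: SyntheticConfig | None = None
    # gold standard
    min_annotations: int = 10
    genome_fraction: float = 0.10
    k_folds: int = 4
    # compendium
    min_overlap: int = 3
    calibration_pairs: int = 200_000
    # network / training
    hidden_sizes: tuple[int, ...] = (500, 200, 100)
    batch_size: int = 50
    positives_per_batch: int = 25
    learning_rate: float = 0.01
    momentum: float = 0.9
    iterations: int = 600_000
    # evaluation
    max_pos: int = 10_000
    neg_factor: int = 10
    kl_samples: int = 200_000
    kl_bins: int = 100
    rank_window: tuple[float, float] = (0.8, 1.0)
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.data_dir is None:
            self.data_dir = self.output_dir / "data"
        self.data_dir = Path(self.data_dir)
        self.hidden_sizes = tuple(self.hidden_sizes)
        self.rank_window = tuple(self.rank_window)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["data_dir"] = str(self.data_dir)
        if self.synthetic is not None:
            d["synthetic"]["terms"] = [
                [t.term_id, t.n_genes, t.signal_strength] for t in self.synthetic.terms
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            syn["terms"] = tuple(TermSpec(str(t), int(n), float(s)) for t, n, s in syn["terms"])
            syn["conditions_per_dataset"] = tuple(syn["conditions_per_dataset"])
            d["synthetic"] = SyntheticConfig(**syn)
        if d.get("seeds"):
            d["seeds"] = Seeds(**d["seeds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded, so moving a
        run directory does not change the hash its outputs carry)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("data_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"coexfp {__version__} config={self.config_hash()}"


#: planted co-regulation strengths of the demo profile's eight terms,
#: spanning weak to strong signal
DEMO_STRENGTHS = (0.1, 0.2, 0.3, 0.45, 0.6, 0.7, 0.8, 0.9)


def demo_config(output_dir: str | Path, seed: int = 0, flip_rate: float = 0.0) -> RunConfig:
    """Desk-scale profile: a small synthetic compendium with varied-strength
    terms, a compact network, and a short iteration budget.

    ``flip_rate`` > 0 additionally drifts the training snapshot so the
    annotation-robustness analysis has contaminated negatives to find.
    """
    seeds = Seeds(
        data=seed, split=seed + 1000, init=seed + 2000,
        sample=seed + 3000, calib=seed + 4000,
    )
    synthetic = SyntheticConfig(
        n_genes=150,
        n_datasets=6,
        conditions_per_dataset=(20, 25, 30, 20, 25, 30),
        terms=tuple(
            TermSpec(f"T{i:02d}", 14, s) for i, s in enumerate(DEMO_STRENGTHS)
        ),
        noise_sd=0.3,
        missing_rate=0.05,
        flip_rate=flip_rate,
        seed=seed,
    )
    return RunConfig(
        output_dir=Path(output_dir),
        synthetic=synthetic,
        hidden_sizes=(32, 16),
        iterations=4000,
        kl_samples=50_000,
        seeds=seeds,
    )


def paper_config(output_dir: str | Path, data_dir: str | Path, seed: int = 0) -> RunConfig:
    """Full-scale profile with the published defaults (113-input architecture
    [500, 200, 100], 600k iterations, 200k calibration pairs)."""
    seeds = Seeds(
        data=seed, split=seed + 1000, init=seed + 2000,
        sample=seed + 3000, calib=seed + 4000,
    )
    return RunConfig(output_dir=Path(output_dir), data_dir=Path(data_dir), seeds=seeds)


# ---------------------------------------------------------------------------
# stages


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def stage_simulate(cfg: RunConfig) -> Path:
    """Generate the synthetic compendium and annotation snapshots on disk."""
    if cfg.synthetic is None:
        raise ValueError("config has no synthetic section")
    t0 = time.time()
    data = cfg.data_dir
    data.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_compendium(cfg.synthetic)
    if cfg.synthetic.flip_rate > 0:
        truth = drift_annotations(truth, cfg.synthetic.flip_rate, seed=cfg.seeds.data + 1)
    for ds in datasets:
        write_expression_matrix(ds, data / f"{ds.dataset_id}.pcl", header_comment=cfg.header())
    write_annotation_file(truth.snapshot_old, data / "annotations_old.tsv", header_comment=cfg.header())
    write_annotation_file(truth.snapshot_new, data / "annotations_new.tsv", header_comment=cfg.header())
    write_slim_file(truth.terms, data / "slim.txt")
    with open(data / "truth.json", "w") as fh:
        json.dump(
            {
                "strengths": dict(truth.strengths),
                "moved_out": {t: list(v) for t, v in truth.moved_out.items()},
                "moved_in": {t: list(v) for t, v in truth.moved_in.items()},
                "gene_universe": list(truth.gene_universe),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    logger.info("simulate: %d datasets in %.1fs config=%s", len(datasets), time.time() - t0, cfg.config_hash())
    return data


def load_compendium(cfg: RunConfig):
    data = Path(cfg.data_dir)
    paths = sorted(data.glob("*.pcl"))
    if not paths:
        raise FileNotFoundError(f"no .pcl expression matrices in {data}")
    return [read_expression_matrix(p) for p in paths]


def load_universe(cfg: RunConfig) -> tuple[str, ...]:
    truth_file = Path(cfg.data_dir) / "truth.json"
    if truth_file.exists():
        with open(truth_file) as fh:
            return tuple(json.load(fh)["gene_universe"])
    datasets = load_compendium(cfg)
    universe: set[str] = set()
    for ds in datasets:
        universe |= set(ds.genes)
    return tuple(sorted(universe))


def load_annotations(cfg: RunConfig, snapshot: str) -> AnnotationSet:
    path = Path(cfg.data_dir) / f"annotations_{snapshot}.tsv"
    _require(path, "simulate")
    return read_annotations(path, snapshot_id=snapshot, universe=load_universe(cfg))


def stage_normalize(cfg: RunConfig) -> Path:
    """Fit per-dataset z-score normalizers from sampled pair correlations."""
    t0 = time.time()
    datasets = load_compendium(cfg)
    normalizers = [
        fit_normalizer(
            ds,
            n_samples=cfg.calibration_pairs,
            seed=cfg.seeds.calib + i,
            min_overlap=cfg.min_overlap,
        )
        for i, ds in enumerate(datasets)
    ]
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    out = cfg.output_dir / "normalizers.tsv"
    write_normalizers(normalizers, out, header_comment=cfg.header())
    logger.info("normalize: %d datasets in %.1fs", len(datasets), time.time() - t0)
    return out


def load_features(cfg: RunConfig) -> CompendiumFeatures:
    normalizers = read_normalizers(_require(cfg.output_dir / "normalizers.tsv", "normalize"))
    return CompendiumFeatures(
        load_compendium(cfg),
        normalizers,
        gene_universe=load_universe(cfg),
        min_overlap=cfg.min_overlap,
    )


def stage_goldstd(cfg: RunConfig) -> Path:
    """Select terms and build the leakage-free cross-validation fold split."""
    ann = load_annotations(cfg, "old")
    slim = read_slim_terms(_require(Path(cfg.data_dir) / "slim.txt", "simulate"))
    gs = build_gold_standard(
        ann,
        slim,
        k=cfg.k_folds,
        seed=cfg.seeds.split,
        min_annotations=cfg.min_annotations,
        genome_fraction=cfg.genome_fraction,
    )
    outdir = cfg.output_dir / "goldstd"
    outdir.mkdir(parents=True, exist_ok=True)
    write_term_set(gs.term_set, outdir / "terms.txt", header_comment=cfg.header())
    write_folds(gs.folds, outdir / "folds.tsv", header_comment=cfg.header())
    logger.info(
        "goldstd: %d terms, %d gold genes, %d folds", len(gs.term_set), len(gs.gold_genes), gs.k
    )
    return outdir


def load_gold(cfg: RunConfig):
    """Reload the gold standard from disk, re-deriving classified pair lists
    (deterministic given annotations and the persisted fold split)."""
    from .goldstd import GoldStandard, TermSet, enumerate_fold_pairs

    ann = load_annotations(cfg, "old")
    outdir = cfg.output_dir / "goldstd"
    term_set = read_term_set(_require(outdir / "terms.txt", "goldstd"))
    folds = read_folds(_require(outdir / "folds.tsv", "goldstd"))
    fold_pairs = tuple(
        enumerate_fold_pairs(
            i, folds, ann, term_set, genome_fraction=cfg.genome_fraction
        )
        for i in range(len(folds))
    )
    gold = frozenset().union(*folds)
    gs = GoldStandard(
        term_set=term_set, folds=folds, fold_pairs=fold_pairs,
        gold_genes=gold, seed=cfg.seeds.split,
    )
    return ann, gs


def stage_train(cfg: RunConfig) -> Path:
    """Train one network per fold on balanced minibatches of labeled pairs."""
    from .goldstd import label_matrix

    t0 = time.time()
    ann, gs = load_gold(cfg)
    features = load_features(cfg)
    nconfig = NetworkConfig(
        input_size=features.n_datasets,
        output_size=len(gs.term_set),
        hidden_sizes=cfg.hidden_sizes,
    )
    outdir = cfg.output_dir / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    for fp in gs.fold_pairs:
        Xr = features.features_for_pairs(fp.train_related)
        Yr = label_matrix(fp.train_related, ann, gs.term_set)
        Xu = features.features_for_pairs(fp.train_unrelated)
        Yu = np.zeros((len(fp.train_unrelated), len(gs.term_set)))
        tconfig = TrainingConfig(
            batch_size=cfg.batch_size,
            positives_per_batch=cfg.positives_per_batch,
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            iterations=cfg.iterations,
            seed=cfg.seeds.sample + fp.fold_id,
        )
        fold = train_fold(
            (Xr, Yr), (Xu, Yu), nconfig, tconfig,
            fold_id=fp.fold_id, init_seed=cfg.seeds.init + fp.fold_id,
        )
        save_checkpoint(fold, outdir / f"fold{fp.fold_id}.npz")
        write_loss_trace(fold, outdir / f"loss_fold{fp.fold_id}.tsv", header_comment=cfg.header())
        logger.info(
            "train fold %d: final loss %.4f (%.1fs elapsed)",
            fp.fold_id, fold.loss_trace[-1, 1], time.time() - t0,
        )
    return outdir

def load_trained_folds(cfg: RunConfig) -> list[TrainedFold]:
    outdir = cfg.output_dir / "models"
    paths = sorted(outdir.glob("fold*.npz"))
    if not paths:
        raise FileNotFoundError(f"no checkpoints in {outdir}; run the 'train' stage first")
    return [load_checkpoint(p) for p in paths]


def stage_graphs(cfg: RunConfig) -> Path:
    """Aggregate fold predictions into per-term functional relationship graphs."""
    t0 = time.time()
    _, gs = load_gold(cfg)
    features = load_features(cfg)
    folds = load_trained_folds(cfg)
    graphs = build_graphs(
        load_universe(cfg), folds, features, gs.fold_of, gs.term_set
    )
    outdir = cfg.output_dir / "graphs"
    write_graphs(graphs, outdir, header_comment=cfg.header())
    logger.info("graphs: %d terms in %.1fs", len(graphs), time.time() - t0)
    return outdir


def stage_rank(cfg: RunConfig) -> Path:
    """Turn each term's graph into a ranked single-gene prediction list."""
    ann, gs = load_gold(cfg)
    universe = load_universe(cfg)
    graphs = read_graphs(_require(cfg.output_dir / "graphs", "graphs"), universe)
    outdir = cfg.output_dir / "rankings"
    outdir.mkdir(parents=True, exist_ok=True)
    rankings = {}
    for term in gs.term_set:
        r = rank_term(graphs[term], ann, gs.gold_genes, term)
        rankings[term] = r
        safe = term.replace(":", "_").replace("/", "_")
        write_ranking(r, outdir / f"ranking_{safe}.csv", header_comment=cfg.header())
    combined = combined_table(rankings)
    with open(outdir / "combined.csv", "w") as fh:
        fh.write(f"# {cfg.header()}\n")
        combined.to_csv(fh, index=False, float_format="%.8f")
    return outdir


def load_rankings(cfg: RunConfig, term_set) -> dict:
    from .ranking import read_ranking

    outdir = _require(cfg.output_dir / "rankings", "rank")
    out = {}
    for term in term_set:
        safe = term.replace(":", "_").replace("/", "_")
        out[term] = read_ranking(outdir / f"ranking_{safe}.csv", term_id=term)
    return out


def stage_evaluate(cfg: RunConfig) -> Path:
    """Per-term performance statistics and the annotation-drift analysis."""
    t0 = time.time()
    ann, gs = load_gold(cfg)
    features = load_features(cfg)
    folds = load_trained_folds(cfg)
    rankings = load_rankings(cfg, gs.term_set)
    avg_z = features.average_z_matrix()
    training_pairs = sorted(
        {p for fp in gs.fold_pairs for p in fp.train_related + fp.train_unrelated}
    )
    performances = []
    for term in gs.term_set:
        train_auc = mean_fold_auc(
            folds, term,
            [sorted(set().union(*(f for j, f in enumerate(gs.folds) if j != i))) for i in range(gs.k)],
            ann, gs.term_set, features,
            max_pos=cfg.max_pos, neg_factor=cfg.neg_factor, seed=cfg.seeds.sample + 101,
        )
        test_auc = mean_fold_auc(
            folds, term,
            [sorted(f) for f in gs.folds],
            ann, gs.term_set, features,
            max_pos=cfg.max_pos, neg_factor=cfg.neg_factor, seed=cfg.seeds.sample + 201,
        )
        kl = kl_term_divergence(
            ann.genes_for_term(term) & gs.gold_genes,
            avg_z, features.gene_index, training_pairs,
            n_samples=cfg.kl_samples, bins=cfg.kl_bins, seed=cfg.seeds.sample + 301,
        ).d_kl
        performances.append(
            TermPerformance(
                term_id=term,
                train_auc=train_auc,
                test_auc=test_auc,
                single_gene_auc=single_gene_auc(rankings[term]),
                kl_divergence=kl,
            )
        )
    out = cfg.output_dir / "performance.csv"
    with open(out, "w") as fh:
        fh.write(f"# {cfg.header()}\n")
        performance_table(performances).to_csv(fh, index=False, float_format="%.6f")

    # annotation-drift analysis when a second snapshot is present
    new_path = Path(cfg.data_dir) / "annotations_new.tsv"
    if new_path.exists():
        ann_new = load_annotations(cfg, "new")
        rows = []
        for term in gs.term_set:
            contam = contaminated_negatives(rankings[term], ann, ann_new, term)
            tab = rankings[term].table
            rel = relative_ranks(rankings[term])
            true_neg = tab.loc[
                (tab["label"] == "negative")
                & ~tab["gene"].isin(ann_new.genes_for_term(term)),
                "gene",
            ]
            ks_stat, ks_p = (float("nan"), float("nan"))
            if len(contam) and len(true_neg):
                try:
                    ks_stat, ks_p = ks_right_tailed(
                        contam["relative_rank"].to_numpy(),
                        rel[true_neg].to_numpy(),
                        window=cfg.rank_window,
                    )
                except ValueError:
                    pass
            rows.append(
                [
                    term,
                    len(contam),
                    contam["relative_rank"].median() if len(contam) else float("nan"),
                    rel[true_neg].median() if len(true_neg) else float("nan"),
                    ks_stat,
                    ks_p,
                ]
            )
        contam_df = pd.DataFrame(
            rows,
            columns=[
                "term", "n_contaminated", "median_rank_contaminated",
                "median_rank_true_negative", "ks_statistic", "ks_p_value",
            ],
        )
        with open(cfg.output_dir / "contamination.csv", "w") as fh:
            fh.write(f"# {cfg.header()}\n")
            contam_df.to_csv(fh, index=False, float_format="%.6f")
    logger.info("evaluate: %d terms in %.1fs", len(performances), time.time() - t0)
    return out


_STAGE_FUNCS = {
    "normalize": stage_normalize,
    "goldstd": stage_goldstd,
    "train": stage_train,
    "graphs": stage_graphs,
    "rank": stage_rank,
    "evaluate": stage_evaluate,
}


def run(cfg: RunConfig, stage: str = "all") -> None:
    """Run one named stage, or every stage in order with ``stage='all'``.

    ``simulate`` is only included in ``all`` when the config has a synthetic
    section; with real data the compendium is expected in ``data_dir``.
    """
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.output_dir / "config.yaml")
    if stage == "simulate":
        stage_simulate(cfg)
        return
    if stage == "all":
        if cfg.synthetic is not None:
            stage_simulate(cfg)
        for name in STAGES:
            _STAGE_FUNCS[name](cfg)
        return
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {('simulate', *STAGES, 'all')}")
    _STAGE_FUNCS[stage](cfg)
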