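"""Per-dataset normalization of pairwise co-expression into z-score features.

Each expression dataset contributes one feature per gene pair: the Pearson
correlation of the two expression profiles over the conditions observed for
both genes, Fisher-transformed, and standardized by moments estimated from a
large random sample of pairs from the same dataset.  Stacking these z-scores
across the compendium yields the fixed-length feature vector a pair carries
into the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: minimum number of conditions observed for *both* genes for a correlation
#: to be considered computable (3 is the smallest non-degenerate overlap).
DEFAULT_MIN_OVERLAP = 3

#: clamp on |rho| before the Fisher transform so identical profiles stay finite.
FISHER_EPS = 1e-6

#: default number of random pairs used to calibrate a dataset's normalizer.
CALIBRATION_PAIRS = 200_000

#: feature value used when a pair is uncomputable in a dataset ("no evidence").
FILL_VALUE = 0.0

_PCL_META_COLUMNS = {"NAME", "GWEIGHT"}
_PCL_META_ROWS = {"EWEIGHT"}


class UncomputablePairError(ValueError):
    """Raised when a correlation cannot be computed and no fill is allowed."""


class DegenerateDatasetError(ValueError):
    """Raised when a dataset yields no usable calibration correlations."""


@dataclass(eq=False)
class ExpressionDataset:
    """One genes x conditions expression matrix; NaN marks a missing entry."""

    dataset_id: str
    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.conditions = tuple(self.conditions)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )
        if len(self.conditions) < 3:
            raise ValueError("a dataset needs at least 3 conditions")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique within a dataset")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_pairs(self) -> int:
        return self.n_genes * (self.n_genes - 1) // 2

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


@dataclass(frozen=True)
class DatasetNormalizer:
    """Moments of Fisher-transformed correlations for one dataset."""

    dataset_id: str
    mu_f: float
    sigma_f: float
    n_calibration_pairs: int
    seed: int

    def __post_init__(self) -> None:
        if not self.sigma_f > 0:
            raise ValueError("sigma_f must be positive")


@dataclass(eq=False)
class PairFeatureVector:
    """Per-pair z-scores, one per dataset, in compendium order.

    The pair is stored in canonical lexicographic order, so the vector is
    symmetric in its gene arguments by construction.
    """

    gene_a: str
    gene_b: str
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-pairs are not allowed")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        self.z = np.asarray(self.z, dtype=float)


def pearson_pairwise(
    x: np.ndarray, y: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Pearson correlation over the conditions observed for both genes.

    Returns NaN when fewer than ``min_overlap`` shared observations remain or
    either restricted vector has zero variance (the "uncomputable" flag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if int(mask.sum()) < min_overlap:
        return float("nan")
    xs = x[mask]
    ys = y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def fisher_transform(rho, eps: float = FISHER_EPS):
    """Fisher z-transform, 0.5*log((1+rho)/(1-rho)), with |rho| clamped below 1."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0 + eps, 1.0 - eps)
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def correlation_matrix(
    dataset: ExpressionDataset, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> np.ndarray:
    """All-pairs pairwise-complete Pearson correlations for one dataset.

    Vectorized masked-moment computation; entry (i, j) is NaN when the pair is
    uncomputable.  Matches :func:`pearson_pairwise` entrywise.
    """
    V = dataset.values
    M = np.isfinite(V).astype(float)
    X = np.where(np.isfinite(V), V, 0.0)
    n = M @ M.T
    Sx = X @ M.T  # sum of x_i over conditions shared with j
    Sxx = (X * X) @ M.T
    Sxy = X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / n
        varx = Sxx - Sx**2 / n
        vary = varx.T
        denom = np.sqrt(np.clip(varx, 0.0, None) * np.clip(vary, 0.0, None))
        r = cov / denom
    # zero-variance tolerance is relative to the magnitude of the data
    tol = 1e-12 * max(1.0, float(np.nanmax(np.abs(V))) ** 2)
    bad = (n < min_overlap) | (varx <= tol) | (vary <= tol)
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    np.fill_diagonal(r, np.nan)
    return r


def _decode_pair_index(k: np.ndarray, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices over the upper triangle (i<j) to (i, j)."""
    counts = np.arange(n_genes - 1, 0, -1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    i = np.searchsorted(offsets, k, side="right") - 1
    j = k - offsets[i] + i + 1
    return i, j


def sample_pair_indices(
    n_genes: int, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample distinct unordered gene pairs, exhaustively when possible."""
    total = n_genes * (n_genes - 1) // 2
    if total <= n_samples:
        k = np.arange(total)
    elif total <= 4 * n_samples:
        k = rng.permutation(total)[:n_samples]
    else:
        # duplicates are rare when the universe dwarfs the sample; top up if not
        k = np.unique(rng.integers(0, total, size=int(n_samples * 1.2)))
        while k.size < n_samples:
            k = np.unique(np.concatenate([k, rng.integers(0, total, size=n_samples)]))
        k = rng.permutation(k)[:n_samples]
        k.sort()
    return _decode_pair_index(k, n_genes)


def _pair_correlations(
    dataset: ExpressionDataset,
    i: np.ndarray,
    j: np.ndarray,
    min_overlap: int,
    chunk: int = 8192,
) -> np.ndarray:
    """Pairwise-complete correlations for explicit index pairs, chunked."""
    V = dataset.values
    out = np.empty(i.shape[0], dtype=float)
    for lo in range(0, i.shape[0], chunk):
        hi = lo + chunk
        x = V[i[lo:hi]]
        y = V[j[lo:hi]]
        m = np.isfinite(x) & np.isfinite(y)
        n = m.sum(axis=1)
        xz = np.where(m, x, 0.0)
        yz = np.where(m, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = xz.sum(axis=1)
            sy = yz.sum(axis=1)
            cov = (xz * yz).sum(axis=1) - sx * sy / n
            vx = (xz * xz).sum(axis=1) - sx**2 / n
            vy = (yz * yz).sum(axis=1) - sy**2 / n
            r = cov / np.sqrt(np.clip(vx, 0.0, None) * np.clip(vy, 0.0, None))
        tol = 1e-12 * max(1.0, float(np.nanmax(np.abs(V))) ** 2)
        r = np.clip(r, -1.0, 1.0)
        r[(n < min_overlap) | (vx <= tol) | (vy <= tol)] = np.nan
        out[lo:hi] = r
    return out


def fit_normalizer(
    dataset: ExpressionDataset,
    n_samples: int = CALIBRATION_PAIRS,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DatasetNormalizer:
    """Estimate mu_f and sigma_f from a random sample of pair correlations.

    When the pair universe is no larger than ``n_samples`` every pair is used,
    so the fit is exhaustive and seed-independent.
    """
    if dataset.n_genes < 2:
        raise DegenerateDatasetError(f"{dataset.dataset_id}: fewer than 2 genes")
    rng = np.random.default_rng(seed)
    i, j = sample_pair_indices(dataset.n_genes, n_samples, rng)
    r = _pair_correlations(dataset, i, j, min_overlap)
    f = fisher_transform(r[np.isfinite(r)])
    if f.size < 2:
        raise DegenerateDatasetError(
            f"{dataset.dataset_id}: no computable calibration pairs"
        )
    sigma = float(np.std(f, ddof=1))
    if sigma == 0:
        raise DegenerateDatasetError(f"{dataset.dataset_id}: sigma_f is zero")
    return DatasetNormalizer(
        dataset_id=dataset.dataset_id,
        mu_f=float(np.mean(f)),
        sigma_f=sigma,
        n_calibration_pairs=int(f.size),
        seed=seed,
    )


def zscore_pair(f: float, norm: DatasetNormalizer) -> float:
    """Standardize one Fisher-transformed correlation with dataset moments."""
    return (f - norm.mu_f) / norm.sigma_f


def zscore_matrix(
    dataset: ExpressionDataset,
    norm: DatasetNormalizer,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    fill: float = FILL_VALUE,
) -> np.ndarray:
    """All-pairs z-score matrix; uncomputable entries and the diagonal get ``fill``."""
    r = correlation_matrix(dataset, min_overlap=min_overlap)
    z = (fisher_transform(r) - norm.mu_f) / norm.sigma_f
    z[~np.isfinite(z)] = fill
    np.fill_diagonal(z, fill)
    return z


def build_pair_features(
    gene_a: str,
    gene_b: str,
    datasets: Sequence[ExpressionDataset],
    normalizers: Mapping[str, DatasetNormalizer],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    fill: float = FILL_VALUE,
) -> PairFeatureVector:
    """Assemble the per-dataset z-score vector for one unordered gene pair.

    Datasets where the pair is uncomputable (either gene absent, overlap below
    ``min_overlap``, or zero variance) contribute ``fill``.
    """
    if gene_a == gene_b:
        raise ValueError("self-pairs are not allowed")
    if gene_a > gene_b:  # canonical order keeps the computation bit-symmetric
        gene_a, gene_b = gene_b, gene_a
    if not any(gene_a in ds for ds in datasets) and not any(
        gene_b in ds for ds in datasets
    ):
        raise KeyError(f"neither {gene_a!r} nor {gene_b!r} occurs in any dataset")
    z = np.full(len(datasets), fill, dtype=float)
    for d, ds in enumerate(datasets):
        if gene_a not in ds or gene_b not in ds:
            continue
        r = pearson_pairwise(ds.row(gene_a), ds.row(gene_b), min_overlap=min_overlap)
        if np.isfinite(r):
            z[d] = zscore_pair(fisher_transform(r), normalizers[ds.dataset_id])
    return PairFeatureVector(gene_a=gene_a, gene_b=gene_b, z=z)


class CompendiumFeatures:
    """Feature source mapping gene pairs to z-score vectors across a compendium.

    By default each dataset's gene x gene z-score matrix over the requested
    universe is computed once and cached, which is the right trade-off up to a
    few thousand genes.  With ``low_memory=True`` nothing is cached and batches
    are computed per dataset on demand, so the all-pairs table never has to be
    materialized.
    """

    def __init__(
        self,
        datasets: Sequence[ExpressionDataset],
        normalizers: Mapping[str, DatasetNormalizer],
        gene_universe: Sequence[str] | None = None,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        fill: float = FILL_VALUE,
        low_memory: bool = False,
    ) -> None:
        self.datasets = list(datasets)
        self.normalizers = dict(normalizers)
        if gene_universe is None:
            gene_universe = sorted(set(itertools.chain(*(d.genes for d in datasets))))
        self.genes = tuple(gene_universe)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.min_overlap = min_overlap
        self.fill = fill
        self.low_memory = low_memory
        self._z: list[np.ndarray] | None = None
        if not low_memory:
            self._z = [self._dataset_matrix(ds) for ds in self.datasets]

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def _dataset_matrix(self, ds: ExpressionDataset) -> np.ndarray:
        present = [g for g in ds.genes if g in self.gene_index]
        sub = ExpressionDataset(
            dataset_id=ds.dataset_id,
            genes=present,
            conditions=ds.conditions,
            values=np.stack([ds.row(g) for g in present])
            if present
            else np.empty((0, ds.n_conditions)),
        ) if len(present) != ds.n_genes else ds
        full = np.full((len(self.genes), len(self.genes)), self.fill)
        if sub.n_genes >= 2:
            z = zscore_matrix(
                sub,
                self.normalizers[ds.dataset_id],
                min_overlap=self.min_overlap,
                fill=self.fill,
            )
            idx = np.array([self.gene_index[g] for g in sub.genes])
            full[np.ix_(idx, idx)] = z
        return full

    def pair_vector(self, gene_a: str, gene_b: str) -> PairFeatureVector:
        if self.low_memory:
            return build_pair_features(
                gene_a,
                gene_b,
                self.datasets,
                self.normalizers,
                min_overlap=self.min_overlap,
                fill=self.fill,
            )
        i = self.gene_index[gene_a]
        j = self.gene_index[gene_b]
        z = np.array([m[i, j] for m in self._z])
        return PairFeatureVector(gene_a=gene_a, gene_b=gene_b, z=z)

    def features_for_pairs(self, pairs: Iterable[tuple[str, str]]) -> np.ndarray:
        """(n_pairs, n_datasets) feature matrix for explicit pairs."""
        pairs = list(pairs)
        if self.low_memory:
            return np.stack([self.pair_vector(a, b).z for a, b in pairs])
        i = np.array([self.gene_index[a] for a, _ in pairs], dtype=int)
        j = np.array([self.gene_index[b] for _, b in pairs], dtype=int)
        return np.stack([m[i, j] for m in self._z], axis=1)

    def features_for_index_pairs(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        if self.low_memory:
            pairs = [(self.genes[a], self.genes[b]) for a, b in zip(i, j)]
            return self.features_for_pairs(pairs)
        return np.stack([m[i, j] for m in self._z], axis=1)

    def average_z_matrix(self) -> np.ndarray:
        """Mean z-score across datasets for every gene pair (fills included)."""
        if self.low_memory:
            raise NotImplementedError("average_z_matrix requires cached matrices")
        return np.mean(np.stack(self._z), axis=0)


# ---------------------------------------------------------------------------
# on-disk formats


def read_expression_matrix(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a tab-separated expression matrix (PCL dialect).

    First column: gene ID; header row: condition names; empty cells: missing.
    NAME/GWEIGHT annotation columns and the EWEIGHT row are skipped when present.
    Lines starting with '#' are treated as comments.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    drop_cols = [c for c in df.columns if str(c).strip().upper() in _PCL_META_COLUMNS]
    df = df.drop(columns=drop_cols)
    df = df[~df.index.astype(str).str.strip().str.upper().isin(_PCL_META_ROWS)]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        genes=tuple(df.index.astype(str)),
        conditions=tuple(str(c) for c in df.columns),
        values=values,
    )


def write_expression_matrix(
    dataset: ExpressionDataset, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    df = pd.DataFrame(dataset.values, index=list(dataset.genes), columns=list(dataset.conditions))
    df.index.name = "GID"
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep="")


NORMALIZER_COLUMNS = ["dataset_id", "mu_f", "sigma_f", "n_calibration_pairs", "seed"]


def write_normalizers(
    normalizers: Iterable[DatasetNormalizer], path: str | Path, header_comment: str | None = None
) -> None:
    rows = [
        [n.dataset_id, n.mu_f, n.sigma_f, n.n_calibration_pairs, n.seed]
        for n in normalizers
    ]
    df = pd.DataFrame(rows, columns=NORMALIZER_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_normalizers(path: str | Path) -> dict[str, DatasetNormalizer]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.dataset_id)] = DatasetNormalizer(
            dataset_id=str(row.dataset_id),
            mu_f=float(row.mu_f),
            sigma_f=float(row.sigma_f),
            n_calibration_pairs=int(row.n_calibration_pairs),
            seed=int(row.seed),
        )
    return out
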