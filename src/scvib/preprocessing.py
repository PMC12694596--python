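"""Per-modality preprocessing into standardized model-ready feature spaces.

RNA counts are depth-normalized to 10,000 per cell, log1p-transformed and
z-scaled per gene.  ATAC peak counts go through a TF-IDF transform and are
z-scaled per peak.  Histone-mark peak counts are summed into fixed 10 kb
genomic bins, log1p-transformed and z-scaled per bin.  Because every
modality ends up standardized, a single augmentation — adding unit-variance
Gaussian noise — serves all of them during contrastive training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data import GenomicInterval, OmicsDataset

__all__ = [
    "StandardizationParams",
    "TfidfIntermediate",
    "normalize_rna",
    "tfidf_transform",
    "bin_histone_features",
    "select_hvg",
    "augment",
    "standardize_columns",
]

RNA_TARGET_SUM = 10_000.0
DEFAULT_BIN_BP = 10_000
DEFAULT_N_HVG = 2000


@dataclass
class StandardizationParams:
    """Per-feature location/scale; zero-variance features get scale 1."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if np.any(self.scale <= 0):
            raise ValueError("scale must be strictly positive")


@dataclass
class TfidfIntermediate:
    """Intermediates of the TF-IDF transform, kept for inspection/tests."""

    tf: np.ndarray
    idf: np.ndarray
    t: np.ndarray
    n_cells_with_peak: np.ndarray


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def standardize_columns(x: np.ndarray) -> tuple[np.ndarray, StandardizationParams]:
    """Remove per-column mean, scale to unit variance (population sd).

    Columns with zero variance fall back to scale 1 so they standardize to
    exactly zero instead of dividing by zero.
    """
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    return (x - mean) / scale, StandardizationParams(mean=mean, scale=scale)


def normalize_rna(counts) -> tuple[np.ndarray, StandardizationParams]:
    """Standard RNA pipeline: CP10K -> log1p -> per-gene z-scaling.

    Cells with zero total counts are left as all-zero rows (a warning is
    emitted); negative entries are rejected.
    """
    x = _dense(counts)
    if np.any(x < 0):
        raise ValueError("RNA counts must be nonnegative")
    totals = x.sum(axis=1, keepdims=True)
    zero_cells = totals[:, 0] == 0
    if np.any(zero_cells):
        warnings.warn(f"{int(zero_cells.sum())} cells have zero total counts")
    safe = np.where(totals > 0, totals, 1.0)
    cp10k = x / safe * RNA_TARGET_SUM
    logged = np.log1p(cp10k)
    return standardize_columns(logged)


def tfidf_transform(
    peak_counts, idf_dialect: str = "smoothed_plus1"
) -> tuple[np.ndarray, TfidfIntermediate]:
    """TF-IDF transform of an accessibility matrix, then per-peak z-scaling.

    For peak p in cell n with raw count x_np over N cells:

        TF(p, n) = x_np / sum_p' x_np'
        N_p      = #{n : x_np > 0}
        IDF(p)   = log((1 + N) / (1 + N_p)) + 1     (dialect "smoothed_plus1")
                 = log(1 + N / N_p)                  (dialect "log1p_ratio")
        t_np     = TF(p, n) * IDF(p)

    Both dialects keep weights finite for peaks observed in every cell and
    give rarer peaks strictly larger weights; the smoothed form is the
    default.
    """
    x = _dense(peak_counts)
    if np.any(x < 0):
        raise ValueError("peak counts must be nonnegative")
    if not np.any(x > 0):
        raise ValueError("accessibility matrix is all zero")
    n_cells = x.shape[0]
    totals = x.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    tf = x / safe
    n_p = (x > 0).sum(axis=0)
    if idf_dialect == "smoothed_plus1":
        idf = np.log((1.0 + n_cells) / (1.0 + n_p)) + 1.0
    elif idf_dialect == "log1p_ratio":
        idf = np.log1p(n_cells / np.maximum(n_p, 1))
    else:
        raise ValueError(f"unknown IDF dialect {idf_dialect!r}")
    t = tf * idf
    standardized, _ = standardize_columns(t)
    return standardized, TfidfIntermediate(tf=tf, idf=idf, t=t, n_cells_with_peak=n_p)


def bin_histone_features(
    peak_counts,
    peak_intervals: Sequence[GenomicInterval],
    bin_bp: int = DEFAULT_BIN_BP,
) -> tuple[np.ndarray, list[str]]:
    """Aggregate histone-mark peak counts into fixed genomic bins.

    Each peak is assigned to the half-open ``bin_bp`` window containing its
    midpoint; bin counts are log1p-transformed and z-scaled per bin.  Returns
    the standardized matrix and the ``chrom:start-end`` bin ids (sorted by
    chromosome then coordinate).
    """
    x = _dense(peak_counts)
    peak_intervals = list(peak_intervals)
    if x.shape[1] != len(peak_intervals):
        raise ValueError(
            f"matrix has {x.shape[1]} peaks but {len(peak_intervals)} intervals"
        )
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    assignments = [
        (pk.chrom, (pk.midpoint // bin_bp) * bin_bp) for pk in peak_intervals
    ]
    bins = sorted(set(assignments))
    bin_index = {b: i for i, b in enumerate(bins)}
    binned = np.zeros((x.shape[0], len(bins)))
    for j, b in enumerate(assignments):
        binned[:, bin_index[b]] += x[:, j]
    standardized, _ = standardize_columns(np.log1p(binned))
    bin_ids = [f"{chrom}:{start}-{start + bin_bp}" for chrom, start in bins]
    return standardized, bin_ids


def _dispersion_ranks(counts) -> np.ndarray:
    """Rank genes by variance/mean dispersion of CP10K counts (1 = most variable)."""
    x = _dense(counts)
    totals = x.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    cp10k = x / safe * RNA_TARGET_SUM
    mean = cp10k.mean(axis=0)
    var = cp10k.var(axis=0)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # stable ranking: higher dispersion -> lower rank number; ties by column order
    order = np.lexsort((np.arange(len(disp)), -disp))
    ranks = np.empty(len(disp))
    ranks[order] = np.arange(1, len(disp) + 1)
    return ranks


def select_hvg(rna_datasets: Sequence[OmicsDataset], n_genes: int = DEFAULT_N_HVG) -> list[str]:
    """Select the shared highly-variable-gene space from raw RNA datasets.

    Genes are ranked per dataset by a dispersion statistic (variance/mean of
    CP10K counts) and, with multiple datasets, combined by median rank over
    the gene union (genes absent from a dataset get the worst rank there).
    Deterministic: ties break by position in the gene union.
    """
    if len(rna_datasets) == 0:
        raise ValueError("at least one RNA dataset is required")
    union: list[str] = []
    seen = set()
    for ds in rna_datasets:
        for g in ds.feature_ids:
            if g not in seen:
                seen.add(g)
                union.append(g)
    worst = float(len(union) + 1)
    rank_table = np.full((len(rna_datasets), len(union)), worst)
    pos = {g: i for i, g in enumerate(union)}
    for d, ds in enumerate(rna_datasets):
        ranks = _dispersion_ranks(ds.matrix)
        for g, r in zip(ds.feature_ids, ranks):
            rank_table[d, pos[g]] = r
    combined = np.median(rank_table, axis=0)
    if n_genes >= len(union):
        if n_genes > len(union):
            warnings.warn(
                f"requested {n_genes} HVGs but only {len(union)} genes available"
            )
        n_genes = len(union)
    order = np.lexsort((np.arange(len(union)), combined))
    return [union[i] for i in order[:n_genes]]


def augment(X: np.ndarray, seed: int) -> np.ndarray:
    """Return a noisy view: X + eps with eps ~ N(0, 1) i.i.d. per entry.

    All modalities are standardized, so unit-variance noise is a comparable
    perturbation everywhere.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix must be finite")
    rng = np.random.default_rng(seed)
    return X + rng.standard_normal(X.shape)
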