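"""Evaluation metrics for integrated embeddings.

Covers entropy-based batch/modality mixing, the two silhouette variants
(cell-type preservation and within-type modality mixing), the local
annotation enrichment score (LAES), k-NN label transfer and cell querying,
NMI/ARI, and the weighted rank aggregation used to compare methods.  All
distances are Euclidean in the latent space; cosine similarity is used only
inside the training losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .data import EmbeddingTable

__all__ = [
    "MetricResult",
    "RankWeights",
    "LabelTransferResult",
    "mixing_score",
    "asw_cell_type",
    "asw_modality",
    "laes",
    "transfer_labels",
    "query_neighbors",
    "nmi",
    "ari",
    "rank_methods",
]


@dataclass
class MetricResult:
    """A metric value plus the parameters that produced it."""

    name: str
    value: float
    parameters: dict = field(default_factory=dict)
    per_group: Optional[dict] = None

    def __post_init__(self):
        self.value = float(self.value)
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.name} is non-finite")


@dataclass
class RankWeights:
    """Category weights for the final ranking index.

    BCS = batch correction, MAS = modality alignment, CPS = cell-type
    preservation, CMS = cross-modality mapping.  Biology-facing categories
    (CPS, CMS) carry more weight.
    """

    w_BCS: float = 0.2
    w_MAS: float = 0.2
    w_CPS: float = 0.3
    w_CMS: float = 0.3

    def __post_init__(self):
        total = self.w_BCS + self.w_MAS + self.w_CPS + self.w_CMS
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rank weights must sum to 1, got {total}")

    def as_dict(self) -> dict:
        return {"BCS": self.w_BCS, "MAS": self.w_MAS, "CPS": self.w_CPS, "CMS": self.w_CMS}


def _group_labels(emb: EmbeddingTable, group_label) -> np.ndarray:
    if isinstance(group_label, str):
        if emb.covariates is None or group_label not in emb.covariates.columns:
            raise ValueError(f"covariate column {group_label!r} not present")
        return emb.covariates[group_label].to_numpy(dtype=object)
    return np.asarray(group_label, dtype=object)


def mixing_score(
    emb: EmbeddingTable,
    group_label,
    n_neighbors: int = 100,
    n_samples: int = 100,
    reps: int = 100,
    seed: int = 0,
) -> MetricResult:
    """Entropy-based regional mixing of batches or modalities.

    Per repetition: sample `n_samples` cells from every group, find each
    sampled cell's `n_neighbors` nearest neighbors within the pooled sample,
    and average the Shannon entropy (natural log) of the neighborhood group
    proportions; the score is the mean over `reps` repetitions.  0 means
    purely one-group neighborhoods; ln(#groups) is perfect mixing.
    """
    labels = _group_labels(emb, group_label)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("mixing score needs at least 2 groups")
    for g in groups:
        if (labels == g).sum() < n_samples:
            raise ValueError(
                f"group {g!r} has fewer than n_samples={n_samples} cells"
            )
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(reps):
        idx = np.concatenate(
            [rng.choice(np.flatnonzero(labels == g), n_samples, replace=False) for g in groups]
        )
        X = emb.z[idx]
        lab = labels[idx]
        k = min(n_neighbors, len(idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, nbrs = nn.kneighbors(X)
        nbrs = nbrs[:, 1:]  # drop self
        ent = np.empty(len(idx))
        for i in range(len(idx)):
            _, counts = np.unique(lab[nbrs[i]], return_counts=True)
            p = counts / k
            ent[i] = -(p * np.log(p)).sum()
        scores.append(ent.mean())
    return MetricResult(
        name="mixing_score",
        value=float(np.mean(scores)),
        parameters={
            "group_label": str(group_label),
            "n_neighbors": n_neighbors,
            "n_samples": n_samples,
            "reps": reps,
            "seed": seed,
        },
    )


def asw_cell_type(emb: EmbeddingTable, labels=None) -> MetricResult:
    """Cell-type preservation: (ASW_c + 1) / 2 in [0, 1] on cell-type labels."""
    if labels is None:
        if emb.cell_type_labels is None:
            raise ValueError("no cell-type labels available")
        labels = emb.cell_type_labels.iloc[:, 0]
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise ValueError("ASW needs at least 2 label classes")
    asw_c = silhouette_score(emb.z, labels)
    return MetricResult(name="asw_cell_type", value=(asw_c + 1.0) / 2.0,
                        parameters={"raw_asw": float(asw_c)})


def asw_modality(emb: EmbeddingTable, cell_type_labels, modality_labels) -> MetricResult:
    """Within-type modality mixing: mean over cell types of 1 - |ASW_m(j)|.

    1 means modalities are indistinguishable within every cell type; 0 means
    they separate perfectly.  Cell types observed in a single modality are
    skipped with a warning.
    """
    cts = np.asarray(cell_type_labels, dtype=object)
    mods = np.asarray(modality_labels, dtype=object)
    per_type = {}
    for ct in np.unique(cts):
        sel = cts == ct
        sub_mods = mods[sel]
        uniq = np.unique(sub_mods)
        if len(uniq) < 2 or min((sub_mods == m).sum() for m in uniq) < 2:
            warnings.warn(f"cell type {ct!r} lacks >=2 modalities with >=2 cells; skipped")
            continue
        asw_m = silhouette_score(emb.z[sel], sub_mods)
        per_type[str(ct)] = 1.0 - abs(float(asw_m))
    if not per_type:
        raise ValueError("no cell type had at least 2 modalities")
    return MetricResult(
        name="asw_modality",
        value=float(np.mean(list(per_type.values()))),
        per_group=per_type,
    )


def laes(
    emb: EmbeddingTable,
    modality_labels,
    cell_type: Optional[str] = None,
    k_neighbors: int = 15,
    cell_type_mask=None,
) -> MetricResult:
    """Local annotation enrichment score for one cell type.

    Restricted to the cells of the given type (all modalities pooled, N
    cells total), each cell n of modality A scores

        LAES_n = (N_A(k)/N_A - N_nonA(k)/N_nonA) * N / k

    over its k nearest in-type neighbors (self excluded).  0 indicates the
    modalities are locally interchangeable; positive values indicate
    same-modality enrichment.  The pooled value averages over all cells of
    the type; per-modality means are reported in ``per_group``.
    """
    mods = np.asarray(modality_labels, dtype=object)
    if cell_type_mask is None:
        if cell_type is None:
            raise ValueError("provide cell_type or cell_type_mask")
        if emb.cell_type_labels is None:
            raise ValueError("no cell-type labels available")
        cell_type_mask = (
            emb.cell_type_labels.iloc[:, 0].to_numpy(dtype=object) == cell_type
        )
    sel = np.flatnonzero(np.asarray(cell_type_mask, dtype=bool))
    sub_mods = mods[sel]
    uniq = np.unique(sub_mods)
    if len(uniq) < 2:
        raise ValueError("cell type must be present in at least 2 modalities")
    N = len(sel)
    if k_neighbors >= N:
        raise ValueError(f"k_neighbors={k_neighbors} must be < type population {N}")
    X = emb.z[sel]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, nbrs = nn.kneighbors(X)
    nbrs = nbrs[:, 1:]
    counts = {m: int((sub_mods == m).sum()) for m in uniq}
    per_cell = np.empty(N)
    for i in range(N):
        m = sub_mods[i]
        n_a = counts[m]
        n_non = N - n_a
        k_a = int((sub_mods[nbrs[i]] == m).sum())
        k_non = k_neighbors - k_a
        per_cell[i] = (k_a / n_a - k_non / n_non) * N / k_neighbors
    per_group = {str(m): float(per_cell[sub_mods == m].mean()) for m in uniq}
    return MetricResult(
        name="laes",
        value=float(per_cell.mean()),
        parameters={"k_neighbors": k_neighbors, "n_cells": N},
        per_group=per_group,
    )


@dataclass
class LabelTransferResult:
    predictions: np.ndarray
    accuracy: Optional[float]
    macro_f1: Optional[float]


def transfer_labels(
    ref: EmbeddingTable, query: EmbeddingTable, k: int = 15
) -> LabelTransferResult:
    """k-NN majority-vote label transfer from a labeled reference.

    Euclidean distances in the shared latent space; vote ties are broken by
    the summed inverse distance of each tied class's neighbors.  Accuracy
    and macro F1 are computed when the query carries truth labels.
    """
    if ref.n_cells == 0:
        raise ValueError("reference embedding is empty")
    if ref.cell_type_labels is None:
        raise ValueError("reference must carry cell-type labels")
    ref_labels = ref.cell_type_labels.iloc[:, 0].to_numpy(dtype=object)
    k = min(k, ref.n_cells)
    nn = NearestNeighbors(n_neighbors=k).fit(ref.z)
    dist, nbrs = nn.kneighbors(query.z)
    preds = np.empty(query.n_cells, dtype=object)
    eps = 1e-12
    for i in range(query.n_cells):
        lab = ref_labels[nbrs[i]]
        classes, counts = np.unique(lab, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if len(tied) == 1:
            preds[i] = tied[0]
        else:
            weights = {
                c: (1.0 / (dist[i][lab == c] + eps)).sum() for c in tied
            }
            preds[i] = max(tied, key=lambda c: weights[c])
    accuracy = macro_f1 = None
    if query.cell_type_labels is not None:
        truth = query.cell_type_labels.iloc[:, 0].to_numpy(dtype=object)
        accuracy = float((preds == truth).mean())
        macro_f1 = float(
            f1_score(truth.astype(str), preds.astype(str), average="macro")
        )
    return LabelTransferResult(predictions=preds, accuracy=accuracy, macro_f1=macro_f1)


def query_neighbors(
    query: EmbeddingTable, reference: EmbeddingTable, k: int = 15
) -> list:
    """For each query cell, its k nearest reference cells with source tags.

    Returns a list (one entry per query cell) of lists of
    ``(reference_cell_id, source_dataset_tag)`` sorted by distance.
    """
    if reference.n_cells == 0:
        raise ValueError("reference embedding is empty")
    if k > reference.n_cells:
        warnings.warn(
            f"k={k} exceeds reference size {reference.n_cells}; clamping"
        )
        k = reference.n_cells
    nn = NearestNeighbors(n_neighbors=k).fit(reference.z)
    _, nbrs = nn.kneighbors(query.z)
    src = reference.source_dataset or [""] * reference.n_cells
    return [
        [(reference.cell_ids[j], src[j]) for j in row] for row in nbrs
    ]


def _check_lengths(a, b):
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty labelings")
    return a, b


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization), in [0, 1]."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(
        normalized_mutual_info_score(a.astype(str), b.astype(str), average_method="arithmetic")
    )


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (chance-corrected), in [-1, 1]."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a.astype(str), b.astype(str)))


def rank_methods(
    per_metric_scores: pd.DataFrame,
    category_map: dict,
    weights: RankWeights = RankWeights(),
    lower_is_better: Sequence[str] = (),
) -> pd.Series:
    """Weighted rank aggregation across metric categories.

    `per_metric_scores` is methods x metrics (higher = better unless the
    metric is listed in `lower_is_better`); `category_map` assigns each
    metric to one of BCS / MAS / CPS / CMS.  Within each metric, methods are
    ranked 1 = best with average ranks on ties; ranks are averaged within
    each category and combined as

        R_i = R_BCS * w_BCS + R_MAS * w_MAS + R_CPS * w_CPS + R_CMS * w_CMS.

    Lower R is better; a method that wins every metric gets R = 1.
    """
    scores = pd.DataFrame(per_metric_scores)
    if scores.isna().any().any():
        missing = scores.columns[scores.isna().any()].tolist()
        raise ValueError(f"missing scores in metrics: {missing}")
    unknown = set(scores.columns) - set(category_map)
    if unknown:
        raise ValueError(f"metrics without a category: {sorted(unknown)}")
    cats = set(category_map.values())
    valid = {"BCS", "MAS", "CPS", "CMS"}
    if not cats <= valid:
        raise ValueError(f"unknown categories: {sorted(cats - valid)}")
    ranks = pd.DataFrame(index=scores.index)
    for metric in scores.columns:
        ascending = metric in lower_is_better
        ranks[metric] = scores[metric].rank(ascending=ascending, method="average")
    w = weights.as_dict()
    result = pd.Series(0.0, index=scores.index)
    for cat in valid:
        cat_metrics = [m for m in scores.columns if category_map[m] == cat]
        if not cat_metrics:
            raise ValueError(f"no metric mapped to category {cat}")
        result += ranks[cat_metrics].mean(axis=1) * w[cat]
    result.name = "ranking_index"
    return result
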