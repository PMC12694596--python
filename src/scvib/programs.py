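"""Conserved and species-specific gene programs from trained translators.

After phase-2 training of a cross-species integration, each species owns a
low-rank translator A_fd (species genes -> compressed space) while a common
B_dg maps the compressed space onto shared homologous genes.  Shared genes
are clustered from their B columns and tied to cell types by expression;
multiplying A_fd @ B_dg reconstructs each species' gene-to-shared-gene map
w_fg, whose weights are z-scored to call species genes significantly linked
to the shared genes of a cell-type program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GeneEmbedding",
    "GeneProgramCall",
    "significance_cutoff",
    "build_gene_embedding",
    "cluster_shared_genes",
    "categorize_clusters_by_celltype",
    "reconstruct_species_map",
    "zscore_weights",
    "call_species_specific_genes",
    "classify_program_speciesness",
]

DEFAULT_Z_THRESHOLD = 2.3263
DEFAULT_MIN_LINKS = 5


def significance_cutoff(p: float = 0.01) -> float:
    """One-sided standard-normal quantile used as the significance cutoff.

    At p = 0.01 this is 2.3263 (to 4 decimals), the default z threshold for
    calling species-specific gene links.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return float(norm.ppf(1.0 - p))


@dataclass
class GeneEmbedding:
    """Per-gene coordinates in the compressed translator space.

    Species genes live in rows of their species' A_fd; shared genes live in
    columns of the common B_dg.  Co-embedding them makes cross-species gene
    neighborhoods comparable.
    """

    vectors: np.ndarray
    gene_ids: Sequence[str]
    species: Sequence[str]

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.gene_ids = list(map(str, self.gene_ids))
        self.species = list(map(str, self.species))
        if self.vectors.shape[0] != len(self.gene_ids) or len(self.gene_ids) != len(self.species):
            raise ValueError("vectors, gene_ids and species must align")
        pairs = list(zip(self.species, self.gene_ids))
        if len(set(pairs)) != len(pairs):
            raise ValueError("gene ids must be unique within each species")


@dataclass
class GeneProgramCall:
    """One species gene scored against a shared-gene program."""

    species: str
    gene: str
    z_score: float
    n_shared_links: int
    significant: bool
    linked_genes: tuple = ()
    cell_type_context: Optional[str] = None


def build_gene_embedding(A_by_species: dict, B: np.ndarray, shared_gene_ids) -> GeneEmbedding:
    """Co-embed genes of all species in the compressed translator space.

    Rows of each species' A_fd give species-gene vectors; columns of the
    common B_dg give shared-gene vectors (tagged species ``"shared"``).
    """
    vectors, ids, species = [], [], []
    for sp, (A, gene_ids) in A_by_species.items():
        A = np.asarray(A, dtype=np.float64)
        if A.shape[0] != len(gene_ids):
            raise ValueError(f"species {sp!r}: {A.shape[0]} rows vs {len(gene_ids)} ids")
        vectors.append(A)
        ids.extend(map(str, gene_ids))
        species.extend([sp] * A.shape[0])
    B = np.asarray(B, dtype=np.float64)
    vectors.append(B.T)
    ids.extend(map(str, shared_gene_ids))
    species.extend(["shared"] * B.shape[1])
    return GeneEmbedding(
        vectors=np.vstack(vectors), gene_ids=ids, species=species
    )


def cluster_shared_genes(
    B: np.ndarray,
    resolution: float = 1.0,
    k_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Louvain communities of shared genes from their B_dg column vectors.

    Builds a k-NN graph (cosine similarity, negative similarities dropped)
    over the g shared genes and runs multilevel modularity optimization.
    Deterministic given `seed`.
    """
    import random

    import igraph as ig

    B = np.asarray(B, dtype=np.float64)
    g = B.shape[1]
    if g == 1:
        return np.zeros(1, dtype=int)
    cols = B.T
    norms = np.linalg.norm(cols, axis=1, keepdims=True)
    if np.allclose(cols, cols[0]):
        warnings.warn("all shared-gene vectors identical; returning one cluster")
        return np.zeros(g, dtype=int)
    unit = cols / np.where(norms > 0, norms, 1.0)
    sim = unit @ unit.T
    np.fill_diagonal(sim, -np.inf)
    k = min(k_neighbors, g - 1)
    edges = set()
    weights = {}
    for i in range(g):
        nbrs = np.argpartition(-sim[i], k - 1)[:k]
        for j in nbrs:
            w = sim[i, j]
            if w <= 0:
                continue
            e = (min(i, int(j)), max(i, int(j)))
            edges.add(e)
            weights[e] = max(weights.get(e, 0.0), float(w))
    graph = ig.Graph(n=g, edges=sorted(edges))
    ew = [weights[e] for e in sorted(edges)]
    ig.set_random_number_generator(random.Random(seed))
    try:
        part = graph.community_multilevel(weights=ew, resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    return np.asarray(part.membership, dtype=int)


def categorize_clusters_by_celltype(
    clusters: np.ndarray,
    expression: pd.DataFrame,
    z_threshold: float = 1.0,
) -> dict:
    """Assign each gene cluster the cell types it is enriched in.

    `expression` is cell types x genes (scaled mean expression).  Per
    cluster, gene means are averaged per cell type and z-scored across cell
    types; types above `z_threshold` are marked enriched.  Genes absent from
    the expression table are dropped with a warning.
    """
    clusters = np.asarray(clusters)
    genes = list(expression.columns)
    if len(genes) < len(clusters):
        warnings.warn(
            f"{len(clusters) - len(genes)} clustered genes missing from expression table"
        )
    out = {}
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        cols = [i for i in members if i < len(genes)]
        if not cols:
            out[int(c)] = {"enriched": [], "profile": None}
            continue
        profile = expression.iloc[:, cols].mean(axis=1)
        sd = profile.std(ddof=0)
        zs = (profile - profile.mean()) / (sd if sd > 0 else 1.0)
        out[int(c)] = {
            "enriched": list(profile.index[zs > z_threshold]),
            "profile": profile,
        }
    return out


def reconstruct_species_map(A_s: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Recover one species' gene-to-shared-gene map: w = A_fd @ B_dg."""
    A_s = np.asarray(A_s, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A_s.shape[1] != B.shape[0]:
        raise ValueError(
            f"inner dimensions differ: A is {A_s.shape}, B is {B.shape}"
        )
    return A_s @ B


def zscore_weights(w: np.ndarray, col_idx: np.ndarray) -> np.ndarray:
    """z-score the weights restricted to the columns of interest.

    The population is *all* (species gene, shared gene of interest) weights
    within one species; the returned matrix has mean 0 and sd 1 over that
    population.
    """
    sub = np.asarray(w, dtype=np.float64)[:, col_idx]
    sd = sub.std(ddof=0)
    if sd == 0:
        raise ValueError("weight population has zero variance")
    return (sub - sub.mean()) / sd


def call_species_specific_genes(
    w,
    shared_genes_of_interest: Sequence[str],
    species: str = "species",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_links: int = DEFAULT_MIN_LINKS,
    cell_type_context: Optional[str] = None,
) -> list[GeneProgramCall]:
    """Call species genes significantly linked to a shared-gene program.

    `w` is the reconstructed f_s x g map as a DataFrame (index = species
    gene ids, columns = shared gene ids) or a bare array with implicit ids.
    Weights restricted to the columns of interest are z-scored over that
    whole population; a species gene is significant iff at least `min_links`
    of its links exceed `z_threshold` (one-sided: strong negative weights
    never qualify).  One call per species gene is returned, carrying its max
    z and the linked shared genes.
    """
    if isinstance(w, pd.DataFrame):
        wdf = w
    else:
        w = np.asarray(w, dtype=np.float64)
        wdf = pd.DataFrame(
            w,
            index=[f"f{i}" for i in range(w.shape[0])],
            columns=[f"g{j}" for j in range(w.shape[1])],
        )
    interest = [str(g) for g in shared_genes_of_interest]
    if len(interest) == 0:
        raise ValueError("shared_genes_of_interest is empty")
    missing = set(interest) - set(map(str, wdf.columns))
    if missing:
        raise ValueError(f"shared genes absent from w columns: {sorted(missing)}")
    col_idx = np.array([list(map(str, wdf.columns)).index(g) for g in interest])
    z = zscore_weights(wdf.to_numpy(dtype=np.float64), col_idx)
    calls = []
    cols = np.array(interest)
    for row, gene in enumerate(wdf.index):
        hits = z[row] > z_threshold
        n_links = int(hits.sum())
        calls.append(
            GeneProgramCall(
                species=species,
                gene=str(gene),
                z_score=float(z[row].max()),
                n_shared_links=n_links,
                significant=n_links >= min_links,
                linked_genes=tuple(cols[hits]),
                cell_type_context=cell_type_context,
            )
        )
    return calls


def classify_program_speciesness(
    significant_by_species: dict,
    clades: Optional[dict] = None,
) -> str:
    """Label a gene module by the species in which it is significant.

    `significant_by_species` maps species -> bool (or a truthy call set).
    Significant in every species -> ``conserved``; in exactly one ->
    ``species_specific:<s>``; in a named clade (e.g. NHP = {macaque,
    marmoset}) -> ``clade_specific:<name>``; otherwise ``mixed`` (or
    ``none`` when nowhere significant).
    """
    if len(significant_by_species) < 2:
        raise ValueError("classification needs calls for at least 2 species")
    sig = {s for s, v in significant_by_species.items() if bool(v)}
    all_species = set(significant_by_species)
    if not sig:
        return "none"
    if sig == all_species:
        return "conserved"
    if len(sig) == 1:
        return f"species_specific:{next(iter(sig))}"
    for name, members in (clades or {}).items():
        if sig == set(members):
            return f"clade_specific:{name}"
    return "mixed"
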