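"""Core data containers and standard-format I/O.

Conventions used throughout the package:

* matrices are cells x features;
* genomic coordinates are 0-based half-open (BED convention); GTF/GFF3
  inputs (1-based, closed) are converted on read;
* peak/bin feature identifiers are encoded as ``chrom:start-end`` strings so
  they round-trip through plain-text formats without a sidecar file.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "OmicsDataset",
    "GenomicInterval",
    "MaskMatrix",
    "EmbeddingTable",
    "read_dataset",
    "write_dataset",
    "read_gene_annotation",
    "build_gene_proximity_mask",
    "write_embedding",
    "read_embedding",
    "interval_from_feature_id",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def feature_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_FEATURE_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def interval_from_feature_id(fid: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` feature id back into an interval."""
    m = _FEATURE_ID_RE.match(fid)
    if m is None:
        raise ValueError(f"not an interval-encoded feature id: {fid!r}")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass
class OmicsDataset:
    """One modality's cell-by-feature matrix plus per-cell metadata.

    Parameters
    ----------
    matrix
        cells x features, dense ndarray or scipy sparse.
    feature_ids, cell_ids
        Ordered identifiers matching the matrix axes.
    modality
        Tag such as ``rna``, ``atac``, ``histone:H3K4me1``, ``methyl:CG``.
    covariates
        Per-cell categorical table (batch / species / modality, ...).
    cell_type_labels
        Optional per-cell annotations, one column per resolution.
    pairing
        Optional map from local cell index to a global joint-cell identifier
        for jointly-profiled cells.
    """

    matrix: np.ndarray | sp.spmatrix
    feature_ids: Sequence[str]
    cell_ids: Sequence[str]
    modality: str = "other"
    covariates: Optional[pd.DataFrame] = None
    cell_type_labels: Optional[pd.DataFrame] = None
    pairing: Optional[dict] = None

    def __post_init__(self):
        self.feature_ids = list(map(str, self.feature_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        n, f = self.matrix.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if f != len(self.feature_ids):
            raise ValueError(
                f"matrix has {f} columns but {len(self.feature_ids)} feature ids"
            )
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError("covariates must have one row per cell")
            self.covariates = self.covariates.reset_index(drop=True)
        if self.cell_type_labels is not None:
            if isinstance(self.cell_type_labels, (pd.Series, list, np.ndarray)):
                self.cell_type_labels = pd.DataFrame(
                    {"cell_type": list(self.cell_type_labels)}
                )
            if len(self.cell_type_labels) != n:
                raise ValueError("cell_type_labels must have one row per cell")
            self.cell_type_labels = self.cell_type_labels.reset_index(drop=True)
        if self.pairing is not None:
            ids = list(self.pairing.values())
            if len(set(ids)) != len(ids):
                raise ValueError("pairing identifiers must be unique within a dataset")
            for idx in self.pairing:
                if not (0 <= idx < n):
                    raise ValueError(f"pairing index {idx} out of range")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=np.float64)
        return np.asarray(self.matrix, dtype=np.float64)


@dataclass
class MaskMatrix:
    """Binary features x shared-genes mask constraining a translator."""

    mask: np.ndarray
    feature_ids: Sequence[str]
    shared_gene_ids: Sequence[str]

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        self.feature_ids = list(map(str, self.feature_ids))
        self.shared_gene_ids = list(map(str, self.shared_gene_ids))
        if self.mask.shape != (len(self.feature_ids), len(self.shared_gene_ids)):
            raise ValueError("mask shape does not match id lists")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask entries must be 0 or 1")


@dataclass
class EmbeddingTable:
    """Integrated latent coordinates plus provenance — the unit of evaluation."""

    z: np.ndarray
    cell_ids: Sequence[str]
    covariates: Optional[pd.DataFrame] = None
    cell_type_labels: Optional[pd.DataFrame] = None
    source_dataset: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.cell_ids = list(map(str, self.cell_ids))
        if self.z.ndim != 2 or self.z.shape[0] != len(self.cell_ids):
            raise ValueError("z row count inconsistent with cell_ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("embedding contains non-finite entries")
        if self.covariates is not None:
            if len(self.covariates) != len(self.cell_ids):
                raise ValueError("covariates must have one row per cell")
            self.covariates = self.covariates.reset_index(drop=True)
        if self.cell_type_labels is not None:
            if isinstance(self.cell_type_labels, (pd.Series, list, np.ndarray)):
                self.cell_type_labels = pd.DataFrame(
                    {"cell_type": list(self.cell_type_labels)}
                )
            self.cell_type_labels = self.cell_type_labels.reset_index(drop=True)
        if self.source_dataset is not None:
            self.source_dataset = list(map(str, self.source_dataset))
            if len(self.source_dataset) != len(self.cell_ids):
                raise ValueError("source_dataset must have one tag per cell")

    @property
    def n_cells(self) -> int:
        return self.z.shape[0]

    def subset(self, idx) -> "EmbeddingTable":
        idx = np.asarray(idx)
        return EmbeddingTable(
            z=self.z[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            covariates=None if self.covariates is None else self.covariates.iloc[idx],
            cell_type_labels=(
                None
                if self.cell_type_labels is None
                else self.cell_type_labels.iloc[idx]
            ),
            source_dataset=(
                None
                if self.source_dataset is None
                else [self.source_dataset[i] for i in idx]
            ),
        )


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

_COVARIATE_PREFIX = "cov_"
_LABEL_PREFIX = "label_"
_PAIRING_COL = "joint_id"


def read_dataset(path: str, format: str, modality: Optional[str] = None) -> OmicsDataset:
    """Read an :class:`OmicsDataset` from disk.

    Formats
    -------
    ``mtx``
        `path` is a directory holding ``matrix.mtx`` (features x cells,
        MatrixMarket), ``features.tsv``, ``barcodes.tsv`` and optionally
        ``covariates.tsv``, ``cell_types.tsv``, ``pairing.tsv``.
    ``h5ad``
        AnnData file as written by :func:`write_dataset`.
    ``tsv``
        Dense matrix, cells as rows (index = barcodes), genes as columns.
    """
    if format == "mtx":
        return _read_mtx_dir(path, modality)
    if format == "h5ad":
        return _read_h5ad(path, modality)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return OmicsDataset(
            matrix=df.to_numpy(dtype=np.float64),
            feature_ids=list(df.columns),
            cell_ids=list(df.index.astype(str)),
            modality=modality or "other",
        )
    raise ValueError(f"unknown format {format!r}")


def _read_mtx_dir(path: str, modality: Optional[str]) -> OmicsDataset:
    from scipy.io import mmread

    mtx_path = os.path.join(path, "matrix.mtx")
    feat_path = os.path.join(path, "features.tsv")
    bc_path = os.path.join(path, "barcodes.tsv")
    for p in (mtx_path, feat_path, bc_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"required companion file missing: {p}")
    mat = sp.csr_matrix(mmread(mtx_path)).T  # stored features x cells
    features = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    covariates = None
    cov_path = os.path.join(path, "covariates.tsv")
    if os.path.exists(cov_path):
        covariates = pd.read_csv(cov_path, sep="\t").astype(str)
    labels = None
    lbl_path = os.path.join(path, "cell_types.tsv")
    if os.path.exists(lbl_path):
        labels = pd.read_csv(lbl_path, sep="\t").astype(str)
    pairing = None
    pair_path = os.path.join(path, "pairing.tsv")
    if os.path.exists(pair_path):
        pdf = pd.read_csv(pair_path, sep="\t")
        pairing = dict(zip(pdf["cell_index"].astype(int), pdf[_PAIRING_COL].astype(str)))
    meta_path = os.path.join(path, "modality.txt")
    if modality is None and os.path.exists(meta_path):
        with open(meta_path) as fh:
            modality = fh.read().strip()
    return OmicsDataset(
        matrix=mat,
        feature_ids=features,
        cell_ids=barcodes,
        modality=modality or "other",
        covariates=covariates,
        cell_type_labels=labels,
        pairing=pairing,
    )


def _read_h5ad(path: str, modality: Optional[str]) -> OmicsDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    cov_cols = [c for c in adata.obs.columns if c.startswith(_COVARIATE_PREFIX)]
    lbl_cols = [c for c in adata.obs.columns if c.startswith(_LABEL_PREFIX)]
    covariates = None
    if cov_cols:
        covariates = adata.obs[cov_cols].astype(str).reset_index(drop=True)
        covariates.columns = [c[len(_COVARIATE_PREFIX):] for c in cov_cols]
    labels = None
    if lbl_cols:
        labels = adata.obs[lbl_cols].astype(str).reset_index(drop=True)
        labels.columns = [c[len(_LABEL_PREFIX):] for c in lbl_cols]
    pairing = None
    if _PAIRING_COL in adata.obs.columns:
        col = adata.obs[_PAIRING_COL].astype(str).reset_index(drop=True)
        pairing = {i: v for i, v in col.items() if v not in ("", "nan")}
    X = adata.X
    if sp.issparse(X):
        X = sp.csr_matrix(X)
    else:
        X = np.asarray(X, dtype=np.float64)
    return OmicsDataset(
        matrix=X,
        feature_ids=list(adata.var_names.astype(str)),
        cell_ids=list(adata.obs_names.astype(str)),
        modality=modality or str(adata.uns.get("modality", "other")),
        covariates=covariates,
        cell_type_labels=labels,
        pairing=pairing,
    )


def write_dataset(ds: OmicsDataset, path: str, format: str) -> None:
    """Write an :class:`OmicsDataset`; inverse of :func:`read_dataset`."""
    if format == "mtx":
        from scipy.io import mmwrite

        os.makedirs(path, exist_ok=True)
        mat = ds.matrix.T if sp.issparse(ds.matrix) else sp.csr_matrix(ds.matrix).T
        mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(mat))
        pd.Series(ds.feature_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        with open(os.path.join(path, "modality.txt"), "w") as fh:
            fh.write(ds.modality + "\n")
        if ds.covariates is not None:
            ds.covariates.to_csv(os.path.join(path, "covariates.tsv"), sep="\t", index=False)
        if ds.cell_type_labels is not None:
            ds.cell_type_labels.to_csv(
                os.path.join(path, "cell_types.tsv"), sep="\t", index=False
            )
        if ds.pairing is not None:
            pd.DataFrame(
                {"cell_index": list(ds.pairing.keys()), _PAIRING_COL: list(ds.pairing.values())}
            ).to_csv(os.path.join(path, "pairing.tsv"), sep="\t", index=False)
        return
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id").astype(str))
        if ds.covariates is not None:
            for c in ds.covariates.columns:
                obs[_COVARIATE_PREFIX + c] = ds.covariates[c].to_numpy()
        if ds.cell_type_labels is not None:
            for c in ds.cell_type_labels.columns:
                obs[_LABEL_PREFIX + c] = ds.cell_type_labels[c].to_numpy()
        if ds.pairing is not None:
            col = np.array([""] * ds.n_cells, dtype=object)
            for i, v in ds.pairing.items():
                col[i] = v
            obs[_PAIRING_COL] = col
        adata = ad.AnnData(
            X=ds.matrix if sp.issparse(ds.matrix) else np.asarray(ds.matrix),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(ds.feature_ids, name="feature_id")),
        )
        adata.uns["modality"] = ds.modality
        adata.write_h5ad(path)
        return
    if format == "tsv":
        pd.DataFrame(ds.dense(), index=ds.cell_ids, columns=ds.feature_ids).to_csv(
            path, sep="\t"
        )
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene annotation + translator mask
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str) -> pd.DataFrame:
    """Read gene intervals from BED or GTF/GFF3 into a 0-based half-open table.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand``.
    """
    lower = path.lower()
    if lower.endswith(".bed"):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame(
            {
                "gene_id": df[3].astype(str) if df.shape[1] > 3 else df.index.astype(str),
                "chrom": df[0].astype(str),
                "start": df[1].astype(int),
                "end": df[2].astype(int),
                "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
            }
        )
        return out
    if lower.endswith((".gtf", ".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        rows = []
        feats = list(db.features_of_type("gene"))
        if not feats:  # annotations without explicit gene features
            feats = list(db.all_features())
        for f in feats:
            gid = (
                f.attributes.get("gene_id", [None])[0]
                or f.attributes.get("ID", [None])[0]
                or f.attributes.get("Name", [f.id])[0]
            )
            rows.append(
                # GTF/GFF is 1-based closed; convert to 0-based half-open
                {"gene_id": gid, "chrom": f.seqid, "start": f.start - 1, "end": f.end,
                 "strand": f.strand or "."}
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unrecognized annotation format for {path!r}")


def build_gene_proximity_mask(
    peaks: Sequence[GenomicInterval],
    genes: pd.DataFrame,
    window_bp: int = 2000,
) -> MaskMatrix:
    """Build the biological-prior translator mask from genomic proximity.

    ``mask[f, g] = 1`` iff peak *f* overlaps the interval
    ``[gene_start - window_bp, gene_end + window_bp)`` of gene *g*
    (half-open overlap, strand ignored).  The rationale is that chromatin
    regions near a gene body are the ones plausibly coupled to its
    transcription; distal regions are masked out during phase-1 training.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if genes is None or len(genes) == 0:
        raise ValueError("gene annotation is empty")
    peaks = list(peaks)
    n_peaks, n_genes = len(peaks), len(genes)
    mask = np.zeros((n_peaks, n_genes), dtype=np.uint8)
    gene_chroms = set(genes["chrom"].astype(str))
    gstart = genes["start"].to_numpy(dtype=np.int64) - window_bp
    gend = genes["end"].to_numpy(dtype=np.int64) + window_bp
    gchrom = genes["chrom"].astype(str).to_numpy()
    warned: set[str] = set()
    for i, pk in enumerate(peaks):
        if pk.chrom not in gene_chroms:
            if pk.chrom not in warned:
                warnings.warn(
                    f"peak chromosome {pk.chrom!r} absent from gene annotation; "
                    "mask rows left empty"
                )
                warned.add(pk.chrom)
            continue
        same = gchrom == pk.chrom
        # half-open overlap of [pk.start, pk.end) with [gstart, gend)
        hit = same & (pk.start < gend) & (gstart < pk.end)
        mask[i, hit] = 1
    return MaskMatrix(
        mask=mask,
        feature_ids=[p.feature_id() for p in peaks],
        shared_gene_ids=genes["gene_id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# embedding I/O
# ---------------------------------------------------------------------------


def write_embedding(table: EmbeddingTable, path: str, format: str) -> None:
    """Write an :class:`EmbeddingTable` as h5ad or full-precision TSV."""
    if table.n_cells == 0:
        raise ValueError("refusing to write an empty embedding table")
    if format == "h5ad":
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(table.cell_ids, name="cell_id").astype(str))
        if table.covariates is not None:
            for c in table.covariates.columns:
                obs[_COVARIATE_PREFIX + c] = table.covariates[c].to_numpy()
        if table.cell_type_labels is not None:
            for c in table.cell_type_labels.columns:
                obs[_LABEL_PREFIX + c] = table.cell_type_labels[c].to_numpy()
        if table.source_dataset is not None:
            obs["source_dataset"] = list(table.source_dataset)
        adata = ad.AnnData(X=np.asarray(table.z), obs=obs)
        adata.write_h5ad(path)
        return
    if format == "tsv":
        df = pd.DataFrame(
            table.z,
            index=pd.Index(table.cell_ids, name="cell_id"),
            columns=[f"z{i}" for i in range(table.z.shape[1])],
        )
        if table.covariates is not None:
            for c in table.covariates.columns:
                df[_COVARIATE_PREFIX + c] = table.covariates[c].to_numpy()
        if table.cell_type_labels is not None:
            for c in table.cell_type_labels.columns:
                df[_LABEL_PREFIX + c] = table.cell_type_labels[c].to_numpy()
        if table.source_dataset is not None:
            df["source_dataset"] = list(table.source_dataset)
        # repr round-trips float64 exactly
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    raise ValueError(f"unknown format {format!r}")


def read_embedding(path: str, format: str) -> EmbeddingTable:
    """Read an embedding written by :func:`write_embedding`."""
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        cov_cols = [c for c in adata.obs.columns if c.startswith(_COVARIATE_PREFIX)]
        lbl_cols = [c for c in adata.obs.columns if c.startswith(_LABEL_PREFIX)]
        covariates = None
        if cov_cols:
            covariates = adata.obs[cov_cols].astype(str).reset_index(drop=True)
            covariates.columns = [c[len(_COVARIATE_PREFIX):] for c in cov_cols]
        labels = None
        if lbl_cols:
            labels = adata.obs[lbl_cols].astype(str).reset_index(drop=True)
            labels.columns = [c[len(_LABEL_PREFIX):] for c in lbl_cols]
        source = None
        if "source_dataset" in adata.obs.columns:
            source = adata.obs["source_dataset"].astype(str).tolist()
        return EmbeddingTable(
            z=np.asarray(adata.X, dtype=np.float64),
            cell_ids=list(adata.obs_names.astype(str)),
            covariates=covariates,
            cell_type_labels=labels,
            source_dataset=source,
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        zcols = [c for c in df.columns if re.fullmatch(r"z\d+", c)]
        cov_cols = [c for c in df.columns if c.startswith(_COVARIATE_PREFIX)]
        lbl_cols = [c for c in df.columns if c.startswith(_LABEL_PREFIX)]
        covariates = None
        if cov_cols:
            covariates = df[cov_cols].astype(str).reset_index(drop=True)
            covariates.columns = [c[len(_COVARIATE_PREFIX):] for c in cov_cols]
        labels = None
        if lbl_cols:
            labels = df[lbl_cols].astype(str).reset_index(drop=True)
            labels.columns = [c[len(_LABEL_PREFIX):] for c in lbl_cols]
        source = df["source_dataset"].astype(str).tolist() if "source_dataset" in df else None
        return EmbeddingTable(
            z=df[zcols].to_numpy(dtype=np.float64),
            cell_ids=list(df.index.astype(str)),
            covariates=covariates,
            cell_type_labels=labels,
            source_dataset=source,
        )
    raise ValueError(f"unknown format {format!r}")
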