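"""Training orchestration for horizontal, vertical and mosaic integration.

Horizontal integration (datasets sharing gene-centric features) trains in
two phases: phase 1 with biologically masked dense translators and the
two-augmented-view contrastive loss on covariate-conditioned projector
outputs, then phase 2 after SVD conversion of each translator to its
low-rank form with the mask lifted.  Vertical integration (jointly-profiled
cells) skips phase 1: the non-gene-space translator is initialized by
ordinary least squares on the paired cells, converted to low-rank form, and
trained with the paired-modality contrastive loss on the latent z.  Mosaic
integration runs an ordered schedule of such stages; the shared encoder and
projector always inherit their weights from the previous stage, and
translators are warm-started from the registry when their modality was seen
before.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import EmbeddingTable, MaskMatrix, OmicsDataset
from .losses import (
    LossConfig,
    dc_loss_paired_modalities,
    dc_loss_two_views,
    kl_to_standard_normal,
    total_vib_loss,
)
from .model import (
    EncoderParams,
    ProjectorParams,
    TranslatorParams,
    decompose_translator,
    encode,
    init_translator_by_regression,
    new_masked_dense_translator,
    sample_latent,
    translate,
)
from .nn import Adam, Tensor
from .preprocessing import (
    bin_histone_features,
    normalize_rna,
    select_hvg,
    standardize_columns,
    tfidf_transform,
)

__all__ = [
    "TrainConfig",
    "ModelState",
    "Stage",
    "preprocess_for_integration",
    "split_by_covariate",
    "train_horizontal",
    "train_vertical",
    "train_mosaic",
    "embed",
    "save_state",
    "load_state",
]


def split_by_covariate(ds: OmicsDataset, column: str = "batch") -> list[OmicsDataset]:
    """Split one dataset into per-category datasets on a covariate column.

    Horizontal integration treats every batch (or study, or species) as its
    own dataset so that contrastive minibatches — and hence the negative
    pool — never span the covariate being integrated out.
    """
    if ds.covariates is None or column not in ds.covariates.columns:
        raise ValueError(f"covariate column {column!r} not present")
    out = []
    for val in pd.unique(ds.covariates[column].astype(str)):
        idx = np.flatnonzero(ds.covariates[column].astype(str) == val)
        out.append(
            OmicsDataset(
                matrix=ds.dense()[idx],
                feature_ids=ds.feature_ids,
                cell_ids=[ds.cell_ids[i] for i in idx],
                modality=ds.modality,
                covariates=ds.covariates.iloc[idx],
                cell_type_labels=(
                    None if ds.cell_type_labels is None else ds.cell_type_labels.iloc[idx]
                ),
                pairing=(
                    None
                    if ds.pairing is None
                    else {
                        int(np.searchsorted(idx, i)): j
                        for i, j in ds.pairing.items()
                        if i in set(idx)
                    }
                ),
            )
        )
    return out


@dataclass
class TrainConfig:
    """Hyperparameters for one integration run.

    phase1/phase2 epoch counts default to the 100/200 schedule; vertical
    integration trains for ``phase2_epochs`` (it skips phase 1 by design).
    ``holdout_fraction`` cells (per dataset, or per joint cell in vertical
    mode) are excluded from every gradient step and serve as the test set.
    One seed drives splits, initialization, dropout, augmentation and
    latent sampling.
    """

    phase1_epochs: int = 100
    phase2_epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 3e-3
    seed: int = 0
    mode: str = "horizontal"
    holdout_fraction: float = 0.0
    latent_dim: int = 32
    projection_dim: Optional[int] = None
    hidden_sizes: tuple = (512, 256, 128)
    feature_dropout: float = 0.25
    low_rank_dim: int = 128
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.mode not in ("horizontal", "vertical", "mosaic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.projection_dim is not None and self.projection_dim <= self.latent_dim:
            raise ValueError("projection_dim must exceed latent_dim")

    @property
    def p(self) -> int:
        return self.projection_dim or self.latent_dim + 16


@dataclass
class ModelState:
    """Everything learned: translator registry, encoder, projector, history."""

    translators: dict
    encoder: EncoderParams
    projector: Optional[ProjectorParams]
    covariate_vocab: list            # ordered (column, category) pairs
    shared_genes: list
    history: list = field(default_factory=list)
    holdout: dict = field(default_factory=dict)
    trained_indices: dict = field(default_factory=dict)
    stage_records: list = field(default_factory=list)

    def check_dimensions(self) -> None:
        g = self.encoder.n_inputs
        for mod, tr in self.translators.items():
            out = None
            if tr.form == "masked_dense":
                out = tr.W.shape[1]
            elif tr.form == "low_rank":
                out = tr.B.shape[1]
            if out is not None and out != g:
                raise ValueError(
                    f"translator {mod!r} outputs {out} features, encoder expects {g}"
                )

    def encoder_snapshot(self) -> list:
        return [p.data.copy() for p in self.encoder.params]


@dataclass
class Stage:
    """One mosaic stage: a set of datasets integrated in one mode."""

    datasets: Sequence[OmicsDataset]
    mode: str
    masks: Optional[dict] = None


# ---------------------------------------------------------------------------
# preprocessing glue
# ---------------------------------------------------------------------------


def preprocess_for_integration(
    datasets: Sequence[OmicsDataset], n_hvg: int = 2000
) -> tuple[list[OmicsDataset], list[str]]:
    """Run the per-modality preprocessing pipeline on raw datasets.

    RNA datasets define the shared HVG gene space and are subset to it, then
    CP10K/log1p/z-scaled; ATAC goes through TF-IDF; histone marks are binned
    into 10 kb windows; anything else is accepted as a pre-standardized
    gene-level matrix and only z-scaled.  Returns the standardized datasets
    and the ordered shared gene list.
    """
    rna = [ds for ds in datasets if ds.modality.split(":")[0] == "rna"]
    if rna:
        shared = select_hvg(rna, n_genes=min(n_hvg, min(len(d.feature_ids) for d in rna)))
    else:
        shared = list(datasets[0].feature_ids)
    out = []
    for ds in datasets:
        kind = ds.modality.split(":")[0]
        feature_ids = list(ds.feature_ids)
        if kind == "rna":
            pos = {g: i for i, g in enumerate(ds.feature_ids)}
            cols = [pos[g] for g in shared if g in pos]
            sub = ds.dense()[:, cols]
            X, _ = normalize_rna(sub)
            feature_ids = [g for g in shared if g in pos]
        elif kind == "atac":
            X, _ = tfidf_transform(ds.matrix)
        elif kind == "histone":
            from .data import interval_from_feature_id

            intervals = [interval_from_feature_id(f) for f in ds.feature_ids]
            X, feature_ids = bin_histone_features(ds.matrix, intervals)
        else:
            X, _ = standardize_columns(ds.dense())
        out.append(
            OmicsDataset(
                matrix=X,
                feature_ids=feature_ids,
                cell_ids=ds.cell_ids,
                modality=ds.modality,
                covariates=ds.covariates,
                cell_type_labels=ds.cell_type_labels,
                pairing=ds.pairing,
            )
        )
    return out, shared


# ---------------------------------------------------------------------------
# covariate vocabulary
# ---------------------------------------------------------------------------


def _extend_vocab(vocab: list, datasets: Sequence[OmicsDataset]) -> list:
    """Freeze covariate categories in order of first sight; append new ones."""
    vocab = list(vocab)
    seen = set(vocab)
    for ds in datasets:
        if ds.covariates is None:
            continue
        for col in ds.covariates.columns:
            for val in ds.covariates[col].astype(str):
                key = (col, val)
                if key not in seen:
                    seen.add(key)
                    vocab.append(key)
    return vocab


def _flat_one_hot(covariates: Optional[pd.DataFrame], n_cells: int, vocab: list) -> np.ndarray:
    C = np.zeros((n_cells, len(vocab)))
    if covariates is None:
        return C
    for j, (col, val) in enumerate(vocab):
        if col in covariates.columns:
            C[:, j] = (covariates[col].astype(str) == val).to_numpy(dtype=float)
    # unseen category check
    for col in covariates.columns:
        known = {v for c, v in vocab if c == col}
        if not known:
            continue
        present = set(covariates[col].astype(str))
        unseen = present - known
        if unseen:
            raise ValueError(
                f"unseen covariate category {sorted(unseen)[0]!r} in column {col!r}"
            )
    return C


# ---------------------------------------------------------------------------
# shared internals
# ---------------------------------------------------------------------------


def _split_holdout(n: int, fraction: float, rng: np.random.Generator):
    n_hold = int(np.floor(fraction * n))
    perm = rng.permutation(n)
    return np.sort(perm[n_hold:]), np.sort(perm[:n_hold])


def _minibatches(idx: np.ndarray, batch_size: int, rng: np.random.Generator):
    idx = idx.copy()
    rng.shuffle(idx)
    out = []
    for s in range(0, len(idx), batch_size):
        b = idx[s : s + batch_size]
        if len(b) >= 2:
            out.append(b)
    return out


def _collect_params(state: ModelState) -> list[Tensor]:
    params = list(state.encoder.params)
    if state.projector is not None:
        params += state.projector.params
    for tr in state.translators.values():
        params += tr.params
    return params


def _dataset_key(stage: int, i: int, ds: OmicsDataset) -> str:
    # stage prefix keeps holdout/instrumentation keys distinct across mosaic
    # stages that reuse dataset positions
    return f"s{stage}:{i}:{ds.modality}"


# ---------------------------------------------------------------------------
# horizontal integration
# ---------------------------------------------------------------------------


def train_horizontal(
    datasets: Sequence[OmicsDataset],
    masks: Optional[dict],
    config: TrainConfig,
    state: Optional[ModelState] = None,
) -> ModelState:
    """Two-phase horizontal integration over gene-centric datasets.

    `masks` maps modality tags to :class:`MaskMatrix` for datasets whose
    features are not already the shared genes.  Phase 1 trains masked dense
    translators; phase 2 converts them to low-rank form (mask lifted) and
    continues.  An existing `state` warm-starts the encoder, projector and
    translator registry (mosaic continuation).
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets provided")
    for ds in datasets:
        if ds.n_cells == 0:
            raise ValueError("empty dataset")
    masks = dict(masks or {})
    rng = np.random.default_rng(config.seed)

    # shared gene space
    if state is not None:
        shared = state.shared_genes
    elif masks:
        shared = list(next(iter(masks.values())).shared_gene_ids)
    else:
        shared = list(datasets[0].feature_ids)

    vocab = _extend_vocab(state.covariate_vocab if state else [], datasets)

    if state is None:
        encoder = EncoderParams(
            n_inputs=len(shared),
            k=config.latent_dim,
            rng=rng,
            hidden_sizes=config.hidden_sizes,
            feature_dropout_rate=config.feature_dropout,
        )
        projector = ProjectorParams(
            k=config.latent_dim, n_covariates=len(vocab), p=config.p, rng=rng
        )
        state = ModelState(
            translators={},
            encoder=encoder,
            projector=projector,
            covariate_vocab=vocab,
            shared_genes=shared,
        )
    else:
        if state.projector is None:
            state.projector = ProjectorParams(
                k=state.encoder.k, n_covariates=len(vocab), p=config.p, rng=rng
            )
        else:
            state.projector.extend_covariates(len(vocab) - len(state.covariate_vocab))
        state.covariate_vocab = vocab

    # translators
    for ds in datasets:
        mod = ds.modality
        if mod in state.translators:
            continue
        if mod in masks:
            mask = masks[mod]
            if list(mask.shared_gene_ids) != list(shared):
                raise ValueError(f"mask for {mod!r} targets a different shared gene list")
            state.translators[mod] = new_masked_dense_translator(mask, mod, rng)
        elif list(ds.feature_ids) == list(shared):
            state.translators[mod] = TranslatorParams(form="identity", modality=mod)
        else:
            raise ValueError(
                f"dataset of modality {mod!r} is not in the shared gene space and has no mask"
            )
    state.check_dimensions()

    # holdout + matrices + one-hot covariates
    infos = []
    for i, ds in enumerate(datasets):
        key = _dataset_key(len(state.stage_records), i, ds)
        train_idx, hold_idx = _split_holdout(ds.n_cells, config.holdout_fraction, rng)
        state.holdout[key] = hold_idx
        state.trained_indices.setdefault(key, set())
        infos.append(
            {
                "key": key,
                "X": ds.dense(),
                "C": _flat_one_hot(ds.covariates, ds.n_cells, vocab),
                "translator": state.translators[ds.modality],
                "train_idx": train_idx,
            }
        )

    start_snapshot = state.encoder_snapshot()

    def run_phase(phase: int, n_epochs: int):
        if n_epochs == 0:
            return
        opt = Adam(_collect_params(state), lr=config.learning_rate)
        for epoch in range(n_epochs):
            batch_lists = [
                _minibatches(info["train_idx"], config.batch_size, rng) for info in infos
            ]
            # round-robin interleave across datasets
            schedule = []
            for r in range(max(len(b) for b in batch_lists)):
                for d, blist in enumerate(batch_lists):
                    if r < len(blist):
                        schedule.append((d, blist[r]))
            totals = {"loss": 0.0, "contrastive": 0.0, "kl": 0.0}
            for d, batch in schedule:
                info = infos[d]
                x = info["X"][batch]
                v1 = x + rng.standard_normal(x.shape)
                v2 = x + rng.standard_normal(x.shape)
                tr = info["translator"]
                h1 = translate(Tensor(v1), tr)
                h2 = translate(Tensor(v2), tr)
                post1 = encode(h1, state.encoder, training=True, rng=rng)
                post2 = encode(h2, state.encoder, training=True, rng=rng)
                z1 = sample_latent(post1, rng)
                z2 = sample_latent(post2, rng)
                C = Tensor(info["C"][batch])
                y1 = state.projector.linear(_concat_zc(z1, C))
                y2 = state.projector.linear(_concat_zc(z2, C))
                dc = dc_loss_two_views(y1, y2, config.loss.tau, config.loss.reduction)
                kl = (kl_to_standard_normal(post1) + kl_to_standard_normal(post2)) * 0.5
                loss = total_vib_loss(dc, kl, config.loss)
                opt.zero_grad()
                loss.backward()
                opt.step()
                for t in state.translators.values():
                    t.apply_mask()
                state.trained_indices[info["key"]].update(int(i) for i in batch)
                totals["loss"] += float(loss)
                totals["contrastive"] += float(dc)
                totals["kl"] += float(kl)
            nb = max(len(schedule), 1)
            state.history.append(
                {
                    "stage": len(state.stage_records),
                    "phase": phase,
                    "epoch": epoch,
                    "loss": totals["loss"] / nb,
                    "contrastive": totals["contrastive"] / nb,
                    "kl": totals["kl"] / nb,
                }
            )

    run_phase(1, config.phase1_epochs)

    # phase transition: lift the mask by SVD conversion to low-rank form
    if config.phase2_epochs > 0:
        for mod, tr in list(state.translators.items()):
            if tr.form == "masked_dense" and tr.mask is not None:
                d = min(config.low_rank_dim, *tr.W.shape)
                state.translators[mod] = decompose_translator(tr, d=d)
        for info, ds in zip(infos, datasets):
            info["translator"] = state.translators[ds.modality]
        run_phase(2, config.phase2_epochs)

    state.stage_records.append(
        {"mode": "horizontal", "encoder_start": start_snapshot,
         "encoder_end": state.encoder_snapshot()}
    )
    return state


def _concat_zc(z: Tensor, C: Tensor) -> Tensor:
    from .nn import concat

    return concat([z, C], axis=1)


# ---------------------------------------------------------------------------
# vertical integration
# ---------------------------------------------------------------------------


def train_vertical(
    paired: Sequence[OmicsDataset],
    config: TrainConfig,
    state: Optional[ModelState] = None,
) -> ModelState:
    """Vertical integration of two jointly-profiled modalities.

    The gene-space dataset (features equal to the shared genes) anchors the
    shared space; the other modality's translator is initialized by OLS on
    the paired training cells and converted to low-rank form.  Training
    minimizes the paired-modality contrastive loss on sampled latents plus
    the KL bottleneck averaged over both views; cells without a visible
    pairing contribute KL only.  Runs for ``config.phase2_epochs`` epochs
    (phase 1 is skipped by design).
    """
    paired = list(paired)
    if len(paired) != 2:
        raise ValueError("vertical integration expects exactly two datasets")
    rng = np.random.default_rng(config.seed)

    shared = state.shared_genes if state is not None else None
    if shared is None:
        gene_space = [
            ds for ds in paired if ds.modality.split(":")[0] == "rna"
        ] or [paired[0]]
        shared = list(gene_space[0].feature_ids)
    anchor_i = next(
        (i for i, ds in enumerate(paired) if list(ds.feature_ids) == list(shared)), None
    )
    if anchor_i is None:
        raise ValueError("neither dataset lives in the shared gene space")
    other_i = 1 - anchor_i
    ds_a, ds_b = paired[anchor_i], paired[other_i]

    if ds_a.pairing is None or ds_b.pairing is None:
        raise ValueError("both datasets need pairing maps for vertical integration")
    inv_a = {jid: i for i, jid in ds_a.pairing.items()}
    inv_b = {jid: i for i, jid in ds_b.pairing.items()}
    joint = sorted(set(inv_a) & set(inv_b))
    if len(joint) < 2:
        raise ValueError("vertical integration needs at least 2 joint cells")

    train_pos, hold_pos = _split_holdout(len(joint), config.holdout_fraction, rng)
    idx_a = np.array([inv_a[j] for j in joint])
    idx_b = np.array([inv_b[j] for j in joint])

    X_a, X_b = ds_a.dense(), ds_b.dense()
    vocab = _extend_vocab(state.covariate_vocab if state else [], paired)

    if state is None:
        encoder = EncoderParams(
            n_inputs=len(shared),
            k=config.latent_dim,
            rng=rng,
            hidden_sizes=config.hidden_sizes,
            feature_dropout_rate=config.feature_dropout,
        )
        state = ModelState(
            translators={},
            encoder=encoder,
            projector=None,
            covariate_vocab=vocab,
            shared_genes=shared,
        )
    else:
        if state.projector is not None:
            state.projector.extend_covariates(len(vocab) - len(state.covariate_vocab))
        state.covariate_vocab = vocab

    if ds_a.modality not in state.translators:
        state.translators[ds_a.modality] = TranslatorParams(
            form="identity", modality=ds_a.modality
        )
    if ds_b.modality not in state.translators:
        # regression init on paired *training* cells, then low-rank conversion
        tr_rows = idx_b[train_pos]
        tgt_rows = idx_a[train_pos]
        ols = init_translator_by_regression(
            X_b[tr_rows], X_a[tgt_rows], modality=ds_b.modality
        )
        d = min(config.low_rank_dim, *ols.W.shape)
        state.translators[ds_b.modality] = decompose_translator(ols, d=d)
    state.check_dimensions()

    key_a = _dataset_key(len(state.stage_records), anchor_i, ds_a)
    key_b = _dataset_key(len(state.stage_records), other_i, ds_b)
    state.holdout[key_a] = idx_a[hold_pos]
    state.holdout[key_b] = idx_b[hold_pos]
    state.trained_indices.setdefault(key_a, set())
    state.trained_indices.setdefault(key_b, set())

    # cells without a visible joint identity contribute only KL; holdout
    # joint cells contribute nothing at all
    unpaired_a = np.setdiff1d(np.arange(ds_a.n_cells), idx_a)
    unpaired_b = np.setdiff1d(np.arange(ds_b.n_cells), idx_b)

    start_snapshot = state.encoder_snapshot()
    tr_a = state.translators[ds_a.modality]
    tr_b = state.translators[ds_b.modality]
    opt = Adam(_collect_params(state), lr=config.learning_rate)

    for epoch in range(config.phase2_epochs):
        totals = {"loss": 0.0, "contrastive": 0.0, "kl": 0.0}
        nb = 0
        for batch in _minibatches(train_pos.copy(), config.batch_size, rng):
            rows_a, rows_b = idx_a[batch], idx_b[batch]
            # universal augmentation: unit Gaussian noise on the standardized
            # inputs (all modalities share the same scale), regularizing the
            # encoder beyond the anchored cell states
            x_a = X_a[rows_a] + rng.standard_normal((len(rows_a), X_a.shape[1]))
            x_b = X_b[rows_b] + rng.standard_normal((len(rows_b), X_b.shape[1]))
            h_a = translate(Tensor(x_a), tr_a)
            h_b = translate(Tensor(x_b), tr_b)
            post_a = encode(h_a, state.encoder, training=True, rng=rng)
            post_b = encode(h_b, state.encoder, training=True, rng=rng)
            z_a = sample_latent(post_a, rng)
            z_b = sample_latent(post_b, rng)
            dc = dc_loss_paired_modalities(z_a, z_b, config.loss.tau, config.loss.reduction)
            kl = (kl_to_standard_normal(post_a) + kl_to_standard_normal(post_b)) * 0.5
            loss = total_vib_loss(dc, kl, config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.trained_indices[key_a].update(int(i) for i in rows_a)
            state.trained_indices[key_b].update(int(i) for i in rows_b)
            totals["loss"] += float(loss)
            totals["contrastive"] += float(dc)
            totals["kl"] += float(kl)
            nb += 1
        # KL-only pass over unpaired cells
        for X, tr, key, unpaired in (
            (X_a, tr_a, key_a, unpaired_a),
            (X_b, tr_b, key_b, unpaired_b),
        ):
            for batch in _minibatches(unpaired.copy(), config.batch_size, rng):
                x = X[batch] + rng.standard_normal((len(batch), X.shape[1]))
                h = translate(Tensor(x), tr)
                post = encode(h, state.encoder, training=True, rng=rng)
                kl = kl_to_standard_normal(post)
                loss = kl * config.loss.beta
                opt.zero_grad()
                loss.backward()
                opt.step()
                state.trained_indices[key].update(int(i) for i in batch)
                totals["loss"] += float(loss)
                totals["kl"] += float(kl)
                nb += 1
        state.history.append(
            {
                "stage": len(state.stage_records),
                "phase": 2,
                "epoch": epoch,
                "loss": totals["loss"] / max(nb, 1),
                "contrastive": totals["contrastive"] / max(nb, 1),
                "kl": totals["kl"] / max(nb, 1),
            }
        )

    state.stage_records.append(
        {"mode": "vertical", "encoder_start": start_snapshot,
         "encoder_end": state.encoder_snapshot()}
    )
    return state


# ---------------------------------------------------------------------------
# mosaic integration
# ---------------------------------------------------------------------------


def train_mosaic(schedule: Sequence[Stage], config: TrainConfig) -> ModelState:
    """Run an ordered schedule of horizontal/vertical stages.

    The encoder (and projector, once created) carry their weights across
    stages; translators for previously seen modalities are warm-started from
    the registry, new modalities get a fresh translator per their stage's
    mode.  The returned state holds the union registry and the concatenated
    history; ``stage_records`` documents the encoder weights at each stage
    boundary (the inheritance contract).
    """
    state: Optional[ModelState] = None
    for stage in schedule:
        if stage.mode == "horizontal":
            state = train_horizontal(stage.datasets, stage.masks, config, state=state)
        elif stage.mode == "vertical":
            state = train_vertical(stage.datasets, config, state=state)
        else:
            raise ValueError(f"unknown stage mode {stage.mode!r}")
    if state is None:
        raise ValueError("empty schedule")
    return state


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def embed(
    datasets: Sequence[OmicsDataset],
    state: ModelState,
    use_mean: bool = True,
    seed: int = 0,
) -> EmbeddingTable:
    """Embed datasets with the trained model (eval mode, no augmentation).

    Returns posterior means by default; with ``use_mean=False`` a single
    seeded reparameterized sample per cell.
    """
    zs, ids, covs, labels, sources = [], [], [], [], []
    rng = np.random.default_rng(seed)
    have_labels = all(ds.cell_type_labels is not None for ds in datasets)
    for ds in datasets:
        if ds.modality not in state.translators:
            raise ValueError(f"modality {ds.modality!r} is not registered")
        tr = state.translators[ds.modality]
        h = translate(Tensor(ds.dense()), tr)
        post = encode(h, state.encoder, training=False)
        z = post.mean if use_mean else sample_latent(post, rng).data
        zs.append(z)
        ids.extend(ds.cell_ids)
        covs.append(
            ds.covariates
            if ds.covariates is not None
            else pd.DataFrame(index=range(ds.n_cells))
        )
        if have_labels:
            labels.append(ds.cell_type_labels)
        sources.extend([ds.modality] * ds.n_cells)
    return EmbeddingTable(
        z=np.vstack(zs),
        cell_ids=ids,
        covariates=pd.concat(covs, ignore_index=True).fillna(""),
        cell_type_labels=pd.concat(labels, ignore_index=True) if have_labels else None,
        source_dataset=sources,
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_state(state: ModelState, path: str) -> None:
    """Save a trained model as one archive: parameter arrays + JSON config.

    The archive holds every tensor of the translator registry, encoder and
    projector plus the covariate vocabulary, shared gene list and layer
    sizes, so :func:`load_state` reconstructs a state whose embeddings are
    bit-identical.
    """
    import json as _json

    arrays: dict = {}
    for i, p in enumerate(state.encoder.params):
        arrays[f"enc:{i}"] = p.data
    meta = {
        "shared_genes": list(state.shared_genes),
        "covariate_vocab": [list(kv) for kv in state.covariate_vocab],
        "encoder": {
            "n_inputs": state.encoder.n_inputs,
            "k": state.encoder.k,
            "hidden_sizes": list(state.encoder.hidden_sizes),
            "feature_dropout_rate": state.encoder.feature_dropout_rate,
        },
        "projector": None,
        "translators": {},
    }
    if state.projector is not None:
        meta["projector"] = {
            "k": state.projector.k,
            "n_covariates": state.projector.n_covariates,
            "p": state.projector.p,
        }
        for i, p in enumerate(state.projector.params):
            arrays[f"proj:{i}"] = p.data
    for mod, tr in state.translators.items():
        info = {"form": tr.form, "has_mask": tr.mask is not None}
        meta["translators"][mod] = info
        if tr.form == "masked_dense":
            arrays[f"tr:{mod}:W"] = tr.W.data
            arrays[f"tr:{mod}:b"] = tr.b.data
            if tr.mask is not None:
                arrays[f"tr:{mod}:mask"] = tr.mask.mask
                arrays[f"tr:{mod}:mask_features"] = np.array(tr.mask.feature_ids)
        elif tr.form == "low_rank":
            arrays[f"tr:{mod}:A"] = tr.A.data
            arrays[f"tr:{mod}:B"] = tr.B.data
            arrays[f"tr:{mod}:b"] = tr.b.data
    np.savez(path, meta=np.array(_json.dumps(meta)), **arrays)


def load_state(path: str) -> ModelState:
    """Load a model archive written by :func:`save_state`."""
    import json as _json

    from .data import MaskMatrix

    with np.load(path, allow_pickle=False) as npz:
        meta = _json.loads(str(npz["meta"]))
        rng = np.random.default_rng(0)  # placeholder init, overwritten below
        enc_cfg = meta["encoder"]
        encoder = EncoderParams(
            n_inputs=enc_cfg["n_inputs"],
            k=enc_cfg["k"],
            rng=rng,
            hidden_sizes=tuple(enc_cfg["hidden_sizes"]),
            feature_dropout_rate=enc_cfg["feature_dropout_rate"],
        )
        for i, p in enumerate(encoder.params):
            p.data = np.array(npz[f"enc:{i}"])
        projector = None
        if meta["projector"] is not None:
            pc = meta["projector"]
            projector = ProjectorParams(
                k=pc["k"], n_covariates=pc["n_covariates"], p=pc["p"], rng=rng
            )
            for i, p in enumerate(projector.params):
                p.data = np.array(npz[f"proj:{i}"])
        translators: dict = {}
        for mod, info in meta["translators"].items():
            if info["form"] == "identity":
                translators[mod] = TranslatorParams(form="identity", modality=mod)
            elif info["form"] == "masked_dense":
                mask = None
                if info["has_mask"]:
                    mask = MaskMatrix(
                        mask=np.array(npz[f"tr:{mod}:mask"]),
                        feature_ids=list(npz[f"tr:{mod}:mask_features"]),
                        shared_gene_ids=meta["shared_genes"],
                    )
                translators[mod] = TranslatorParams(
                    form="masked_dense",
                    modality=mod,
                    W=Tensor(np.array(npz[f"tr:{mod}:W"]), requires_grad=True),
                    mask=mask,
                    b=Tensor(np.array(npz[f"tr:{mod}:b"]), requires_grad=True),
                )
            else:
                translators[mod] = TranslatorParams(
                    form="low_rank",
                    modality=mod,
                    A=Tensor(np.array(npz[f"tr:{mod}:A"]), requires_grad=True),
                    B=Tensor(np.array(npz[f"tr:{mod}:B"]), requires_grad=True),
                    b=Tensor(np.array(npz[f"tr:{mod}:b"]), requires_grad=True),
                )
    state = ModelState(
        translators=translators,
        encoder=encoder,
        projector=projector,
        covariate_vocab=[tuple(kv) for kv in meta["covariate_vocab"]],
        shared_genes=list(meta["shared_genes"]),
    )
    state.check_dimensions()
    return state
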