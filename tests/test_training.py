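"""Training orchestration: schedules, holdout discipline, continuity, mosaic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestNeighbors

from scvib import evaluation as ev
from scvib.data import EmbeddingTable
from scvib.model import decompose_translator, translate
from scvib.simulate import SimulationConfig, simulate_multiome
from scvib.training import (
    Stage,
    TrainConfig,
    embed,
    preprocess_for_integration,
    split_by_covariate,
    train_horizontal,
    train_mosaic,
    train_vertical,
)

SMALL = dict(hidden_sizes=(32, 32, 16), latent_dim=8)


def small_config(**kw):
    base = dict(
        phase1_epochs=5,
        phase2_epochs=5,
        batch_size=64,
        seed=0,
        **SMALL,
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def horizontal_data():
    """Two-batch, 3-type RNA data, one dataset per batch."""
    cfg = SimulationConfig(
        seed=21, n_cell_types=3, cells_per_type=80, latent_dim_true=8,
        modalities=(("rna", 60, "shared_genes"),), n_batches=2,
        batch_effect_scale=3.0,
    )
    datasets, truth = simulate_multiome(cfg)
    prepped, shared = preprocess_for_integration(datasets, n_hvg=60)
    return split_by_covariate(prepped[0], "batch"), truth


@pytest.fixture(scope="module")
def vertical_data():
    cfg = SimulationConfig(
        seed=22, n_cell_types=4, cells_per_type=90, latent_dim_true=8,
        modalities=(("rna", 60, "shared_genes"), ("atac", 90, "linear_map")),
    )
    datasets, truth = simulate_multiome(cfg)
    prepped, shared = preprocess_for_integration(datasets, n_hvg=60)
    return prepped, truth


class TestHorizontal:
    def test_zero_epoch_schedule_returns_initialized_state(self, horizontal_data):
        prepped, _ = horizontal_data
        state = train_horizontal(prepped, None, small_config(phase1_epochs=0, phase2_epochs=0))
        assert state.history == []
        assert "rna" in state.translators
        assert state.encoder.n_inputs == 60

    def test_loss_nonincreasing_over_smoothed_window(self, horizontal_data):
        prepped, _ = horizontal_data
        state = train_horizontal(
            prepped, None, small_config(phase1_epochs=0, phase2_epochs=30)
        )
        losses = np.array([h["loss"] for h in state.history])
        smooth = np.convolve(losses, np.ones(5) / 5, mode="valid")
        assert smooth[-1] <= smooth[0]
        # no long stretch of increase
        assert np.mean(np.diff(smooth) <= 1e-6) > 0.6

    def test_integration_improves_batch_mixing_on_holdout(self, horizontal_data):
        prepped, truth = horizontal_data
        config = small_config(
            phase1_epochs=0, phase2_epochs=60, holdout_fraction=0.2, seed=3
        )
        state = train_horizontal(prepped, None, config)
        table = embed(prepped, state)
        holds = [state.holdout["s0:0:rna"], state.holdout["s0:1:rna"]]
        idx = np.concatenate([holds[0], prepped[0].n_cells + holds[1]])
        held_table = table.subset(idx)
        raw = EmbeddingTable(
            z=np.vstack([prepped[0].dense()[holds[0]], prepped[1].dense()[holds[1]]]),
            cell_ids=held_table.cell_ids,
            covariates=held_table.covariates,
        )
        kw = dict(n_neighbors=15, n_samples=20, reps=10, seed=0)
        mixed = ev.mixing_score(held_table, "batch", **kw).value
        raw_mix = ev.mixing_score(raw, "batch", **kw).value
        assert mixed > raw_mix

    def test_missing_mask_for_foreign_feature_space_rejected(self, vertical_data):
        prepped, _ = vertical_data
        with pytest.raises(ValueError, match="no mask"):
            train_horizontal(prepped, None, small_config())


class TestVertical:
    def test_holdout_count_exact_and_disjoint_from_steps(self, vertical_data):
        prepped, _ = vertical_data
        n_joint = len(prepped[0].pairing)
        config = small_config(phase1_epochs=0, phase2_epochs=3, holdout_fraction=0.2)
        state = train_vertical(prepped, config)
        for key in state.holdout:
            held = set(int(i) for i in state.holdout[key])
            assert len(held) == int(np.floor(0.2 * n_joint))
            assert held.isdisjoint(state.trained_indices[key])

    def test_alignment_improves_modality_mixing(self, vertical_data):
        prepped, truth = vertical_data
        config = small_config(phase1_epochs=0, phase2_epochs=30, seed=5)
        state = train_vertical(prepped, config)
        table = embed(prepped, state)
        kw = dict(n_neighbors=15, n_samples=50, reps=10, seed=0)
        mixed = ev.mixing_score(table, "modality", **kw).value
        assert mixed > 0.8 * np.log(2)

    def test_trained_map_correlates_with_simulator_truth(self):
        cfg = SimulationConfig(
            seed=23, n_cell_types=3, cells_per_type=100, latent_dim_true=6,
            modalities=(("ga", 30, "shared_genes"), ("gb", 40, "linear_map")),
            noise_scale=0.5, render_counts=False,
        )
        datasets, truth = simulate_multiome(cfg)
        prepped, _ = preprocess_for_integration(datasets)
        config = small_config(phase1_epochs=0, phase2_epochs=20, seed=1)
        state = train_vertical(prepped, config)
        W_eff = state.translators["gb"].effective_weights()
        # simulator truth composed through the latent space, rescaled to the
        # standardized feature spaces
        Ma, Mb = truth.modality_maps["ga"], truth.modality_maps["gb"]
        sd_a = datasets[0].dense().std(axis=0)
        sd_b = datasets[1].dense().std(axis=0)
        W_true = np.diag(sd_b) @ np.linalg.pinv(Mb) @ Ma @ np.diag(1.0 / sd_a)
        cosines = [
            W_eff[:, j]
            @ W_true[:, j]
            / (np.linalg.norm(W_eff[:, j]) * np.linalg.norm(W_true[:, j]))
            for j in range(W_true.shape[1])
        ]
        assert np.mean(cosines) >= 0.5

    def test_no_pairing_rejected(self, vertical_data):
        prepped, _ = vertical_data
        stripped = [
            type(ds)(
                matrix=ds.matrix,
                feature_ids=ds.feature_ids,
                cell_ids=ds.cell_ids,
                modality=ds.modality,
                covariates=ds.covariates,
            )
            for ds in prepped
        ]
        with pytest.raises(ValueError, match="pairing"):
            train_vertical(stripped, small_config())


class TestTwoPhaseMasked:
    def _masked_inputs(self):
        cfg = SimulationConfig(
            seed=25, n_cell_types=3, cells_per_type=50, latent_dim_true=8,
            modalities=(("rna", 40, "shared_genes"), ("atac", 60, "linear_map")),
        )
        datasets, truth = simulate_multiome(cfg)
        prepped, shared = preprocess_for_integration(datasets, n_hvg=40)
        from scvib.data import build_gene_proximity_mask, interval_from_feature_id

        peaks = [interval_from_feature_id(f) for f in prepped[1].feature_ids]
        genes = pd.DataFrame(
            {
                "gene_id": shared,
                "chrom": ["chr1"] * len(shared),
                "start": [j * 1500 for j in range(len(shared))],
                "end": [j * 1500 + 1000 for j in range(len(shared))],
                "strand": ["."] * len(shared),
            }
        )
        mask = build_gene_proximity_mask(peaks, genes, window_bp=2000)
        return prepped, mask

    def test_mask_discipline_through_phase1_and_conversion(self):
        prepped, mask = self._masked_inputs()
        config = small_config(phase1_epochs=4, phase2_epochs=0, seed=7)
        state = train_horizontal(prepped, {"atac": mask}, config)
        tr = state.translators["atac"]
        assert tr.form == "masked_dense"
        off_support = tr.W.data * (1 - mask.mask)
        np.testing.assert_array_equal(off_support, np.zeros_like(off_support))
        # continue into phase 2: translator becomes low rank, training proceeds
        config2 = small_config(phase1_epochs=2, phase2_epochs=3, seed=7)
        state2 = train_horizontal(prepped, {"atac": mask}, config2)
        assert state2.translators["atac"].form == "low_rank"
        phases = [h["phase"] for h in state2.history]
        assert phases == [1, 1, 2, 2, 2]


class TestPhaseContinuity:
    def test_full_rank_conversion_matches_on_probe_batch(self, rng):
        from scvib.data import MaskMatrix
        from scvib.model import new_masked_dense_translator

        m = (rng.random((30, 20)) > 0.4).astype(int)
        mask = MaskMatrix(
            mask=m,
            feature_ids=[f"f{i}" for i in range(30)],
            shared_gene_ids=[f"g{j}" for j in range(20)],
        )
        tr = new_masked_dense_translator(mask, "atac", rng)
        tr.W.data += rng.standard_normal((30, 20))
        tr.apply_mask()
        low = decompose_translator(tr, d=20)
        probe = rng.standard_normal((16, 30))
        h_dense = translate(probe, tr)
        h_low = translate(probe, low)
        rel = np.linalg.norm(h_low - h_dense) / np.linalg.norm(h_dense)
        assert rel < 1e-4


class TestMosaic:
    def _schedule(self):
        cfg = SimulationConfig(
            seed=31, n_cell_types=3, cells_per_type=60, latent_dim_true=8,
            modalities=(("rna", 50, "shared_genes"), ("atac", 70, "linear_map")),
            n_batches=2, batch_effect_scale=1.0,
        )
        datasets, truth = simulate_multiome(cfg)
        prepped, _ = preprocess_for_integration(datasets, n_hvg=50)
        return prepped, truth

    def test_encoder_inherited_bitwise_between_stages(self):
        prepped, _ = self._schedule()
        schedule = [
            Stage(datasets=[prepped[0]], mode="horizontal"),
            Stage(datasets=prepped, mode="vertical"),
        ]
        state = train_mosaic(schedule, small_config(phase1_epochs=0, phase2_epochs=3))
        assert len(state.stage_records) == 2
        for w_end, w_start in zip(
            state.stage_records[0]["encoder_end"], state.stage_records[1]["encoder_start"]
        ):
            np.testing.assert_array_equal(w_end, w_start)

    def test_one_stage_schedule_deterministic(self):
        prepped, _ = self._schedule()
        config = small_config(phase1_epochs=0, phase2_epochs=4, seed=9)
        h1 = train_mosaic([Stage(datasets=[prepped[0]], mode="horizontal")], config).history
        h2 = train_mosaic([Stage(datasets=[prepped[0]], mode="horizontal")], config).history
        assert h1 == h2

    def test_later_stages_preserve_stage1_structure(self):
        prepped, truth = self._schedule()
        config = small_config(
            phase1_epochs=0, phase2_epochs=15, holdout_fraction=0.2, seed=2
        )
        schedule = [
            Stage(datasets=[prepped[0]], mode="horizontal"),
            Stage(datasets=prepped, mode="vertical"),
        ]
        state = train_mosaic(schedule, config)
        table = embed([prepped[0]], state)
        hold = state.holdout["s0:0:rna"]
        types = truth.cell_types[hold]
        nn = NearestNeighbors(n_neighbors=2).fit(table.z[hold])
        _, nbrs = nn.kneighbors(table.z[hold])
        acc = (truth.cell_types[hold][nbrs[:, 1]] == types).mean()
        assert acc >= 0.8


class TestCheckpoint:
    def test_roundtrip_reproduces_embedding_bitwise(self, vertical_data, tmp_path):
        from scvib.training import load_state, save_state

        prepped, _ = vertical_data
        state = train_vertical(prepped, small_config(phase1_epochs=0, phase2_epochs=2))
        path = str(tmp_path / "ckpt.npz")
        save_state(state, path)
        back = load_state(path)
        np.testing.assert_array_equal(
            embed(prepped, state).z, embed(prepped, back).z
        )
        assert back.shared_genes == state.shared_genes
        assert back.covariate_vocab == state.covariate_vocab


class TestEmbed:
    def test_mean_embedding_deterministic(self, vertical_data):
        prepped, _ = vertical_data
        state = train_vertical(prepped, small_config(phase1_epochs=0, phase2_epochs=2))
        t1 = embed(prepped, state, use_mean=True)
        t2 = embed(prepped, state, use_mean=True)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_sampled_embedding_seeded(self, vertical_data):
        prepped, _ = vertical_data
        state = train_vertical(prepped, small_config(phase1_epochs=0, phase2_epochs=2))
        t1 = embed(prepped, state, use_mean=False, seed=4)
        t2 = embed(prepped, state, use_mean=False, seed=4)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_mean_is_monte_carlo_limit_of_samples(self, vertical_data):
        prepped, _ = vertical_data
        state = train_vertical(prepped, small_config(phase1_epochs=0, phase2_epochs=2))
        # a handful of cells keeps the per-coordinate 3-sigma band meaningful
        sub = [
            type(prepped[0])(
                matrix=prepped[0].dense()[:5],
                feature_ids=prepped[0].feature_ids,
                cell_ids=prepped[0].cell_ids[:5],
                modality=prepped[0].modality,
            )
        ]
        mean_table = embed(sub, state, use_mean=True)
        draws = np.stack(
            [embed(sub, state, use_mean=False, seed=s).z for s in range(1000)]
        )
        from scvib.model import encode
        from scvib.nn import Tensor
        from scvib.model import translate as tr_fn

        post = encode(
            tr_fn(Tensor(sub[0].dense()), state.translators[sub[0].modality]),
            state.encoder,
            training=False,
        )
        dev = np.abs(draws.mean(axis=0) - mean_table.z)
        tol3 = 3 * post.scale / np.sqrt(1000)
        # per-coordinate 3-sigma holds for the vast majority; the extremes of
        # 40 coordinates stay within 5 sigma
        assert (dev <= tol3 + 1e-12).mean() >= 0.9
        assert np.all(dev <= (5 / 3) * tol3 + 1e-12)

    def test_unregistered_modality_rejected(self, vertical_data):
        prepped, _ = vertical_data
        state = train_vertical(prepped, small_config(phase1_epochs=0, phase2_epochs=1))
        foreign = type(prepped[0])(
            matrix=prepped[0].matrix,
            feature_ids=prepped[0].feature_ids,
            cell_ids=prepped[0].cell_ids,
            modality="methyl:CG",
        )
        with pytest.raises(ValueError, match="not registered"):
            embed([foreign], state)
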