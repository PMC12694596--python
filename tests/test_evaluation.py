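"""Metric suite against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from scvib.data import EmbeddingTable
from scvib.evaluation import (
    RankWeights,
    ari,
    asw_cell_type,
    asw_modality,
    laes,
    mixing_score,
    nmi,
    query_neighbors,
    rank_methods,
    transfer_labels,
)


def table(z, batch=None, modality=None, cell_type=None):
    n = len(z)
    cov = {}
    if batch is not None:
        cov["batch"] = batch
    if modality is not None:
        cov["modality"] = modality
    return EmbeddingTable(
        z=np.asarray(z, dtype=float),
        cell_ids=[f"c{i}" for i in range(n)],
        covariates=pd.DataFrame(cov) if cov else None,
        cell_type_labels=(
            pd.DataFrame({"cell_type": list(cell_type)}) if cell_type is not None else None
        ),
    )


class TestMixingScore:
    def test_pure_neighborhoods_score_zero(self, rng):
        # two groups at huge separation: every neighborhood is one group
        z = np.vstack([rng.standard_normal((30, 2)), rng.standard_normal((30, 2)) + 1000])
        t = table(z, batch=["a"] * 30 + ["b"] * 30)
        res = mixing_score(t, "batch", n_neighbors=10, n_samples=20, reps=5, seed=0)
        assert res.value == pytest.approx(0.0)

    def test_identical_distributions_approach_ln2(self, rng):
        z = rng.standard_normal((400, 3))
        groups = np.array(["a", "b"])[rng.integers(0, 2, 400)]
        # ensure both groups large enough
        t = table(z, batch=groups)
        res = mixing_score(t, "batch", n_neighbors=50, n_samples=100, reps=10, seed=1)
        assert res.value == pytest.approx(np.log(2), abs=0.05)

    def test_matches_naive_loop_with_same_seed(self, rng):
        z = rng.standard_normal((60, 2))
        groups = np.array(["a"] * 30 + ["b"] * 30)
        t = table(z, batch=groups)
        n_nb, n_s, reps, seed = 8, 15, 4, 42
        res = mixing_score(t, "batch", n_neighbors=n_nb, n_samples=n_s, reps=reps, seed=seed)
        # independent reimplementation with the identical sampling protocol
        r = np.random.default_rng(seed)
        scores = []
        for _ in range(reps):
            idx = np.concatenate(
                [r.choice(np.flatnonzero(groups == g), n_s, replace=False) for g in ["a", "b"]]
            )
            ents = []
            for i in idx:
                d = np.linalg.norm(z[idx] - z[i], axis=1)
                order = [j for j in np.argsort(d, kind="stable") if idx[j] != i][:n_nb]
                lab = groups[idx][order]
                e = 0.0
                for g in set(lab):
                    p = (lab == g).mean()
                    e -= p * np.log(p)
                ents.append(e)
            scores.append(np.mean(ents))
        assert res.value == pytest.approx(np.mean(scores), abs=1e-10)

    def test_single_group_rejected(self, rng):
        t = table(rng.standard_normal((10, 2)), batch=["a"] * 10)
        with pytest.raises(ValueError, match="2 groups"):
            mixing_score(t, "batch", n_samples=5)

    def test_invariant_to_group_renaming(self, rng):
        z = rng.standard_normal((40, 2))
        g1 = np.array(["a"] * 20 + ["b"] * 20)
        g2 = np.array(["x"] * 20 + ["y"] * 20)
        r1 = mixing_score(table(z, batch=g1), "batch", n_neighbors=5, n_samples=10, reps=3, seed=0)
        r2 = mixing_score(table(z, batch=g2), "batch", n_neighbors=5, n_samples=10, reps=3, seed=0)
        assert r1.value == pytest.approx(r2.value, abs=1e-12)


def naive_silhouette(z, labels):
    n = len(z)
    d = np.linalg.norm(z[:, None] - z[None, :], axis=2)
    svals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = d[i][same].mean()
        b = min(
            d[i][labels == other].mean() for other in set(labels) if other != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


class TestASW:
    def test_separated_tight_clusters_score_one(self, rng):
        z = np.vstack([np.zeros((10, 2)), np.full((10, 2), 1e6)])
        z += rng.standard_normal(z.shape) * 1e-9
        res = asw_cell_type(table(z, cell_type=["A"] * 10 + ["B"] * 10))
        assert res.value == pytest.approx(1.0, abs=1e-6)

    def test_random_labels_on_structureless_cloud_near_half(self, rng):
        z = rng.standard_normal((300, 5))
        labels = np.array(["A", "B"])[rng.integers(0, 2, 300)]
        res = asw_cell_type(table(z, cell_type=labels))
        assert res.value == pytest.approx(0.5, abs=0.05)

    def test_matches_bruteforce_silhouette(self, rng):
        z = rng.standard_normal((20, 3))
        labels = np.array(["A"] * 7 + ["B"] * 6 + ["C"] * 7)
        res = asw_cell_type(table(z, cell_type=labels))
        assert res.value == pytest.approx((naive_silhouette(z, labels) + 1) / 2, abs=1e-8)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 label classes"):
            asw_cell_type(table(rng.standard_normal((5, 2)), cell_type=["A"] * 5))


class TestASWModality:
    def test_perfectly_mixed_modalities_score_one(self, rng):
        # both modalities drawn from the identical distribution
        z = rng.standard_normal((400, 3))
        mods = ["m1"] * 200 + ["m2"] * 200
        cts = ["X"] * 400
        res = asw_modality(table(z), cts, mods)
        assert res.value == pytest.approx(1.0, abs=0.05)

    def test_perfectly_separated_modalities_score_zero(self, rng):
        z = np.vstack([np.zeros((10, 2)), np.full((10, 2), 1e6)])
        z += rng.standard_normal(z.shape) * 1e-9
        res = asw_modality(table(z), ["X"] * 20, ["m1"] * 10 + ["m2"] * 10)
        assert res.value == pytest.approx(0.0, abs=1e-6)

    def test_matches_per_type_bruteforce(self, rng):
        z = rng.standard_normal((24, 3))
        cts = np.array(["X"] * 12 + ["Y"] * 12)
        mods = np.array((["m1"] * 6 + ["m2"] * 6) * 2)
        res = asw_modality(table(z), cts, mods)
        expected = np.mean(
            [1 - abs(naive_silhouette(z[cts == ct], mods[cts == ct])) for ct in ["X", "Y"]]
        )
        assert res.value == pytest.approx(expected, abs=1e-8)

    def test_single_modality_type_skipped_with_warning(self, rng):
        z = rng.standard_normal((30, 2))
        cts = ["X"] * 20 + ["Y"] * 10
        mods = ["m1"] * 10 + ["m2"] * 10 + ["m1"] * 10
        with pytest.warns(UserWarning, match="'Y'"):
            res = asw_modality(table(z), cts, mods)
        assert set(res.per_group) == {"X"}


class TestLAES:
    def test_balanced_neighborhoods_cancel_to_zero(self):
        # interleaved duplicated coordinates: every k=2 neighborhood is one
        # cell from each modality
        z = np.repeat(np.arange(10)[:, None] * 100.0, 2, axis=0)
        mods = np.array(["A", "B"] * 10)
        t = table(z, cell_type=["X"] * 20)
        res = laes(t, mods, cell_type="X", k_neighbors=2)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_pure_modality_neighborhoods_score_two(self, rng):
        z = np.vstack([rng.standard_normal((10, 2)), 1e6 + rng.standard_normal((10, 2))])
        mods = np.array(["A"] * 10 + ["B"] * 10)
        t = table(z, cell_type=["X"] * 20)
        res = laes(t, mods, cell_type="X", k_neighbors=5)
        assert res.value == pytest.approx(2.0)

    def test_matches_naive_loop(self, rng):
        z = rng.standard_normal((30, 3))
        mods = np.array(["A"] * 12 + ["B"] * 18)
        t = table(z, cell_type=["X"] * 30)
        k = 7
        res = laes(t, mods, cell_type="X", k_neighbors=k)
        vals = []
        for i in range(30):
            d = np.linalg.norm(z - z[i], axis=1)
            order = [j for j in np.argsort(d, kind="stable") if j != i][:k]
            n_a = (mods == mods[i]).sum()
            k_a = sum(mods[j] == mods[i] for j in order)
            vals.append((k_a / n_a - (k - k_a) / (30 - n_a)) * 30 / k)
        assert res.value == pytest.approx(np.mean(vals), abs=1e-10)

    def test_k_exceeding_population_rejected(self, rng):
        t = table(rng.standard_normal((6, 2)), cell_type=["X"] * 6)
        with pytest.raises(ValueError, match="population"):
            laes(t, ["A", "B"] * 3, cell_type="X", k_neighbors=6)


class TestTransferAndQuery:
    def test_self_transfer_is_perfect(self, rng):
        z = rng.standard_normal((12, 3))
        labels = ["A"] * 6 + ["B"] * 6
        t = table(z, cell_type=labels)
        res = transfer_labels(t, t, k=1)
        assert res.accuracy == 1.0 and res.macro_f1 == 1.0

    def test_single_class_reference_predicts_that_class(self, rng):
        ref = table(rng.standard_normal((5, 2)), cell_type=["A"] * 5)
        qry = table(rng.standard_normal((4, 2)), cell_type=["A", "A", "B", "B"])
        res = transfer_labels(ref, qry, k=3)
        assert set(res.predictions) == {"A"}
        assert res.accuracy == 0.5

    def test_matches_exhaustive_knn_oracle(self, rng):
        ref_z = np.vstack(
            [rng.standard_normal((8, 2)) + c for c in ([0, 0], [6, 0], [0, 6])]
        )
        labels = np.array(["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        qry_z = rng.standard_normal((10, 2)) * 3
        ref = table(ref_z, cell_type=labels)
        qry = table(qry_z)
        res = transfer_labels(ref, qry, k=5)
        for i in range(10):
            d = np.linalg.norm(ref_z - qry_z[i], axis=1)
            nbrs = np.argsort(d, kind="stable")[:5]
            vals, counts = np.unique(labels[nbrs], return_counts=True)
            best = counts.max()
            tied = vals[counts == best]
            if len(tied) == 1:
                assert res.predictions[i] == tied[0]
            else:
                assert res.predictions[i] in tied

    def test_accuracy_invariant_to_joint_rotation(self, rng):
        ref_z = rng.standard_normal((20, 4))
        qry_z = rng.standard_normal((10, 4))
        labels = ["A"] * 10 + ["B"] * 10
        truth = ["A"] * 5 + ["B"] * 5
        R = ortho_group.rvs(4, random_state=1)
        r1 = transfer_labels(table(ref_z, cell_type=labels), table(qry_z, cell_type=truth), k=3)
        r2 = transfer_labels(
            table(ref_z @ R, cell_type=labels), table(qry_z @ R, cell_type=truth), k=3
        )
        assert r1.accuracy == r2.accuracy

    def test_query_neighbors_coincident_point_first(self, rng):
        ref_z = rng.standard_normal((9, 2))
        ref = EmbeddingTable(
            z=ref_z,
            cell_ids=[f"r{i}" for i in range(9)],
            source_dataset=["ds"] * 9,
        )
        qry = table(ref_z[[4]])
        out = query_neighbors(qry, ref, k=3)
        assert out[0][0] == ("r4", "ds")

    def test_query_k_clamped_with_warning(self, rng):
        ref = EmbeddingTable(z=rng.standard_normal((4, 2)), cell_ids=list("abcd"))
        qry = table(rng.standard_normal((2, 2)))
        with pytest.warns(UserWarning, match="clamping"):
            out = query_neighbors(qry, ref, k=10)
        assert len(out[0]) == 4


class TestNmiAri:
    def test_identical_labelings(self):
        a = ["x", "x", "y", "y", "z"]
        assert nmi(a, a) == pytest.approx(1.0)
        assert ari(a, a) == pytest.approx(1.0)

    def test_constant_labeling_is_chance_level(self):
        a = ["x", "y", "x", "y"]
        b = ["c"] * 4
        assert nmi(a, b) == pytest.approx(0.0)
        assert ari(a, b) == pytest.approx(0.0)

    def test_2x2_contingency_closed_form(self):
        # contingency [[2,0],[0,2]] swapped names: still perfect agreement
        a = ["p", "p", "q", "q"]
        b = ["q", "q", "p", "p"]
        assert nmi(a, b) == pytest.approx(1.0)
        assert ari(a, b) == pytest.approx(1.0)
        # hand-computed partial agreement: a=[p,p,q,q], b=[p,q,p,q]
        b2 = ["p", "q", "p", "q"]
        # contingency [[1,1],[1,1]]: MI = 0; ARI = (0 - 2/3)/(2 - 2/3) = -1/2
        assert nmi(a, b2) == pytest.approx(0.0, abs=1e-12)
        assert ari(a, b2) == pytest.approx(-0.5, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            nmi(["a"], ["a", "b"])


class TestRankAggregation:
    def _scores(self):
        return pd.DataFrame(
            {
                "mix_batch": [0.9, 0.5, 0.7],
                "asw_mod": [0.8, 0.6, 0.7],
                "asw_ct": [0.95, 0.9, 0.8],
                "f1": [0.7, 0.6, 0.5],
            },
            index=["m1", "m2", "m3"],
        )

    _cats = {"mix_batch": "BCS", "asw_mod": "MAS", "asw_ct": "CPS", "f1": "CMS"}

    def test_dominating_method_gets_R_one(self):
        r = rank_methods(self._scores(), self._cats)
        assert r["m1"] == pytest.approx(1.0)

    def test_ties_get_equal_R(self):
        scores = pd.DataFrame(
            {"mix_batch": [1, 1], "asw_mod": [2, 2], "asw_ct": [3, 3], "f1": [4, 4]},
            index=["m1", "m2"],
        )
        r = rank_methods(scores, self._cats)
        assert r["m1"] == r["m2"] == pytest.approx(1.5)

    def test_matches_hand_computed_spreadsheet(self):
        # hand computation: ranks per metric (higher better, best=1)
        # mix_batch: m1=1 m3=2 m2=3 ; asw_mod: m1=1 m3=2 m2=3
        # asw_ct:    m1=1 m2=2 m3=3 ; f1:     m1=1 m2=2 m3=3
        # R(m2) = 3*.2 + 3*.2 + 2*.3 + 2*.3 = 2.4
        # R(m3) = 2*.2 + 2*.2 + 3*.3 + 3*.3 = 2.6
        r = rank_methods(self._scores(), self._cats)
        assert r["m2"] == pytest.approx(2.4)
        assert r["m3"] == pytest.approx(2.6)

    def test_missing_score_rejected(self):
        scores = self._scores()
        scores.loc["m2", "f1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rank_methods(scores, self._cats)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RankWeights(w_BCS=0.5, w_MAS=0.5, w_CPS=0.5, w_CMS=0.5)
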