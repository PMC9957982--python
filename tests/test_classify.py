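"""Two-step classification: splits, MLPs, voting, post-processing."""

import math

import numpy as np
import pandas as pd
import pytest

from arterylabel import (
    anatomical_postprocess,
    binomial_vote_accuracy,
    predict_branch,
    predict_chunk,
    split_subjects,
    train_branch_models,
    train_chunk_model,
    vote_labels,
)
from arterylabel.classify import SplitSpec
from arterylabel.config import MLPConfig
from arterylabel.features import PREDICTOR_COLUMNS


class TestSplit:
    def test_42_subjects_split_29_13(self):
        subjects = [f"s{i:02d}" for i in range(42)]
        split = split_subjects(subjects, 0.70, seed=0)
        assert len(split.train) == 29
        assert len(split.test) == 13
        assert set(split.train) | set(split.test) == set(subjects)
        assert not set(split.train) & set(split.test)

    def test_deterministic(self):
        subjects = [f"s{i}" for i in range(20)]
        a = split_subjects(subjects, 0.7, seed=3)
        b = split_subjects(subjects, 0.7, seed=3)
        assert a.train == b.train and a.test == b.test

    def test_stratified_by_cohort(self):
        subjects = [f"c{i}" for i in range(10)] + [f"p{i}" for i in range(10)]
        cohorts = {s: s[0] for s in subjects}
        split = split_subjects(subjects, 0.7, seed=1, cohort_of=cohorts)
        for prefix in "cp":
            n_train = sum(1 for s in split.train if s.startswith(prefix))
            assert n_train == 7

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_subjects(["a", "b"], 0.7, 0)


def _toy_table(nmap, n_per_class=1000, classes=("A1", "P0"), sep=6.0, seed=0,
               n_subjects=6):
    """Two (or more) well-separated Gaussian chunk clouds in feature space."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, chunk in enumerate(classes):
        centre = np.zeros(12)
        centre[0] = ci * sep
        X = rng.normal(centre, 1.0, size=(n_per_class, 12))
        branch = nmap.branches_of(chunk)[0]
        for k in range(n_per_class):
            rows.append(
                dict(zip(PREDICTOR_COLUMNS, X[k]))
                | {
                    "subject_id": f"s{k % n_subjects}",
                    "spot_id": len(rows),
                    "segment_id": k % 40,
                    "segment_key": f"s{k % n_subjects}/{k % 40}",
                    "true_chunk": chunk,
                    "true_branch": branch,
                }
            )
    return pd.DataFrame(rows)


class TestChunkModel:
    def test_separable_two_chunk_toy(self, nmap):
        table = _toy_table(nmap)
        subjects = sorted(table["subject_id"].unique())
        split = split_subjects(subjects, 0.7, seed=0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=60),
                                seed=0)
        test = table[table["subject_id"].isin(split.test)]
        proba, labels = predict_chunk(ens, test)
        acc = (labels == test["true_chunk"].to_numpy()).mean()
        assert acc >= 0.99

    def test_probability_rows_sum_to_one(self, nmap):
        table = _toy_table(nmap, n_per_class=300)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=30))
        proba, _ = predict_chunk(ens, table)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_shuffled_labels_give_chance_accuracy(self, nmap):
        rng = np.random.default_rng(1)
        table = _toy_table(nmap, n_per_class=800, seed=1)
        table["true_chunk"] = rng.permutation(table["true_chunk"].to_numpy())
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=40),
                                seed=1)
        test = table[table["subject_id"].isin(split.test)]
        _, labels = predict_chunk(ens, test)
        acc = (labels == test["true_chunk"].to_numpy()).mean()
        n = len(test)
        # permutation null: accuracy ~ 1/K with sd sqrt(p(1-p)/n)
        assert abs(acc - 0.5) <= 3 * math.sqrt(0.25 / n) + 0.05

    def test_nan_feature_rejected(self, nmap):
        table = _toy_table(nmap, n_per_class=200)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=20))
        bad = table.head(10).copy()
        bad.loc[bad.index[0], "curvature"] = np.nan
        with pytest.raises(ValueError):
            predict_chunk(ens, bad)

    def test_row_order_invariance(self, nmap):
        table = _toy_table(nmap, n_per_class=300)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=30))
        _, l1 = predict_chunk(ens, table)
        perm = np.random.default_rng(0).permutation(len(table))
        _, l2 = predict_chunk(ens, table.iloc[perm].reset_index(drop=True))
        assert np.array_equal(l1[perm], l2)


class TestVoting:
    def test_majority_wins(self):
        labels = np.array(["A7", "A7", "A3"], dtype=object)
        voted = vote_labels(labels, np.array(["s/0"] * 3))
        assert list(voted) == ["A7", "A7", "A7"]

    def test_tie_breaks_by_probability_sum(self):
        labels = np.array(["A7", "A3"], dtype=object)
        proba = pd.DataFrame({"A3": [0.4, 0.8], "A7": [0.6, 0.2]})
        voted = vote_labels(labels, np.array(["s/0", "s/0"]), proba)
        assert list(voted) == ["A3", "A3"]

    def test_tie_without_proba_breaks_lexicographically(self):
        labels = np.array(["A7", "A3"], dtype=object)
        voted = vote_labels(labels, np.array(["s/0", "s/0"]))
        assert list(voted) == ["A3", "A3"]

    def test_voting_matches_binomial_oracle(self):
        """10,000 simulated 15-spot segments with iid per-spot accuracy 0.7:
        post-voting accuracy equals the exact binomial majority tail."""
        rng = np.random.default_rng(42)
        n_seg, n_spot, p = 10_000, 15, 0.7
        correct = rng.random((n_seg, n_spot)) < p
        labels = np.where(correct, "T", "F").astype(object).ravel()
        segments = np.repeat(np.arange(n_seg), n_spot).astype(object)
        voted = vote_labels(labels, segments)
        seg_correct = voted.reshape(n_seg, n_spot)[:, 0] == "T"
        oracle = binomial_vote_accuracy(n_spot, p)
        assert oracle == pytest.approx(
            sum(math.comb(15, k) * 0.7**k * 0.3 ** (15 - k)
                for k in range(8, 16)),
            abs=1e-12,
        )
        assert abs(seg_correct.mean() - oracle) <= 0.01

    def test_voting_never_hurts_when_spots_above_half(self):
        """Segment-level accuracy after voting dominates the per-spot rate
        for iid errors with accuracy > 0.5 (binomial oracle check)."""
        for p in (0.55, 0.7, 0.9):
            for n in (5, 15, 31):
                assert binomial_vote_accuracy(n, p) >= p - 1e-12


class TestBranchModels:
    def test_single_branch_chunk_deterministic(self, nmap):
        table = _toy_table(nmap, classes=("P0", "A1"))
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=30))
        ens = train_branch_models(ens, table)
        chunks = np.array(["P0"] * 5, dtype=object)
        out = predict_branch(ens, table.head(5), chunks, vote=False)
        assert set(out) == {"P0"}

    def test_separable_three_branch_chunk(self, nmap):
        rng = np.random.default_rng(0)
        branches = nmap.branches_of("A7")[:3]
        rows = []
        for bi, br in enumerate(branches):
            X = rng.normal(np.eye(12)[bi] * 8.0, 1.0, size=(600, 12))
            for k in range(600):
                rows.append(
                    dict(zip(PREDICTOR_COLUMNS, X[k]))
                    | {
                        "subject_id": f"s{k % 6}",
                        "segment_id": k % 30,
                        "segment_key": f"s{k % 6}/{bi}-{k % 30}",
                        "true_chunk": "A7",
                        "true_branch": br,
                    }
                )
        table = pd.DataFrame(rows)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=60))
        ens = train_branch_models(ens, table)
        test = table[table["subject_id"].isin(split.test)].reset_index(drop=True)
        out = predict_branch(
            ens, test, np.array(["A7"] * len(test), dtype=object),
            vote=True, segment_keys=test["segment_key"].to_numpy(),
        )
        acc = (out == test["true_branch"].to_numpy()).mean()
        assert acc >= 0.99

    def test_branch_always_inside_assigned_chunk(self, nmap):
        table = _toy_table(nmap, classes=("A1", "A7"), n_per_class=600)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=40))
        ens = train_branch_models(ens, table)
        chunks = table["true_chunk"].to_numpy(dtype=object)
        out = predict_branch(ens, table, chunks, vote=False)
        assert all(nmap.chunk_of(b) == c for b, c in zip(out, chunks))


class TestPersistence:
    def test_ensemble_roundtrip(self, nmap, tmp_path):
        from arterylabel import load_ensemble, save_ensemble

        table = _toy_table(nmap, classes=("A1", "P0"), n_per_class=400)
        split = split_subjects(sorted(table["subject_id"].unique()), 0.7, 0)
        ens = train_chunk_model(table, split, nmap, MLPConfig(max_iter=30))
        ens = train_branch_models(ens, table)
        save_ensemble(ens, tmp_path / "model")
        back = load_ensemble(tmp_path / "model", nmap)
        _, l1 = predict_chunk(ens, table)
        _, l2 = predict_chunk(back, table)
        assert np.array_equal(l1, l2)
        assert isinstance(back.branch_models["P0"], str)


class TestPostprocess:
    def _table(self, seg_chunks, xs=None, terminal=None, nmap=None):
        rows = []
        for i, chunk in enumerate(seg_chunks):
            branch = nmap.branches_of(chunk)[0]
            for k in range(5):
                rows.append(
                    {
                        "segment_key": f"s/{i}",
                        "pred_chunk": chunk,
                        "pred_branch": branch,
                        "x_mm": (xs[i] if xs else 0.0) + 0.01 * k,
                        "terminal": terminal[i] if terminal else False,
                    }
                )
        return pd.DataFrame(rows)

    def test_consistent_labelling_is_fixed_point(self, nmap):
        table = self._table(["A7", "A7", "A3"], xs=[20, 21, 19], nmap=nmap)
        adjacency = {"s/0": {"s/1", "s/2"}, "s/1": {"s/0"}, "s/2": {"s/0"}}
        out = anatomical_postprocess(table, adjacency, nmap,
                                     rules=("connectivity",))
        assert out["pred_chunk"].tolist() == table["pred_chunk"].tolist()

    def test_isolated_segment_adopts_neighbour_chunk(self, nmap):
        # an A3-labelled segment wedged between A7 segments, with the A3
        # body connected elsewhere
        chunks = ["A7", "A3", "A7", "A3", "A3"]
        adjacency = {
            "s/0": {"s/1"},
            "s/1": {"s/0", "s/2"},
            "s/2": {"s/1"},
            "s/3": {"s/4"},
            "s/4": {"s/3"},
        }
        table = self._table(chunks, xs=[20] * 5, nmap=nmap)
        out = anatomical_postprocess(table, adjacency, nmap,
                                     rules=("connectivity",))
        assert set(out[out["segment_key"] == "s/1"]["pred_chunk"]) == {"A7"}

    def test_laterality_flip(self, nmap):
        # a right-chunk segment sitting far on the left of the midline
        table = self._table(["A7", "A8", "A7"], xs=[25.0, -25.0, -25.0],
                            nmap=nmap)
        out = anatomical_postprocess(table, {}, nmap, rules=("laterality",),
                                     midline_x=0.0)
        flipped = out[out["segment_key"] == "s/2"]
        assert set(flipped["pred_chunk"]) == {"A8"}
        assert set(out[out["segment_key"] == "s/0"]["pred_chunk"]) == {"A7"}

    def test_idempotent(self, nmap):
        chunks = ["A7", "A3", "A7", "A3", "A3"]
        adjacency = {
            "s/0": {"s/1"},
            "s/1": {"s/0", "s/2"},
            "s/2": {"s/1"},
            "s/3": {"s/4"},
            "s/4": {"s/3"},
        }
        table = self._table(chunks, xs=[25, 25, 25, -25, -25], nmap=nmap)
        once = anatomical_postprocess(table, adjacency, nmap)
        twice = anatomical_postprocess(once, adjacency, nmap)
        pd.testing.assert_frame_equal(once, twice)

    def test_terminal_segments_protected(self, nmap):
        # the singleton P7 leaf would qualify for adoption (a connected P7
        # body exists elsewhere) but terminal segments are left alone
        chunks = ["P0", "P7", "P0", "P7", "P7"]
        adjacency = {
            "s/0": {"s/1", "s/2"},
            "s/1": {"s/0"},
            "s/2": {"s/0"},
            "s/3": {"s/4"},
            "s/4": {"s/3"},
        }
        table = self._table(chunks, xs=[20] * 5,
                            terminal=[False, True, False, False, False],
                            nmap=nmap)
        out = anatomical_postprocess(table, adjacency, nmap,
                                     rules=("connectivity",))
        assert set(out[out["segment_key"] == "s/1"]["pred_chunk"]) == {"P7"}
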