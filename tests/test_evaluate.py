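"""Metric routines against independent hand/brute-force computations."""

import numpy as np
import pandas as pd
import pytest

from arterylabel import (
    groupwise_feature_stats,
    per_class_metrics,
    roc_pr,
    separability_check,
)
from arterylabel.evaluate import paired_permutation_pvalue


def brute_force_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney pair counting: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


class TestPerClassMetrics:
    def test_perfect_predictions_are_100(self):
        y = ["A", "B", "C"] * 10
        rep = per_class_metrics(y, y)
        assert (rep.per_class[["precision", "recall", "f1"]] == 100.0).all().all()
        assert rep.micro_accuracy == 1.0

    def test_hand_computed_confusion_matrix(self):
        """Confusion matrix [[8,2],[1,9]]: class-1 precision 8/9, recall
        8/10, F1 = 2 p r / (p + r) — hand-derived values to 1e-9."""
        y_true = ["c1"] * 10 + ["c2"] * 10
        y_pred = ["c1"] * 8 + ["c2"] * 2 + ["c1"] * 1 + ["c2"] * 9
        rep = per_class_metrics(y_true, y_pred)
        p = 100 * 8 / 9
        r = 100 * 8 / 10
        f1 = 2 * p * r / (p + r)
        assert rep.per_class.loc["c1", "precision"] == pytest.approx(p, abs=1e-9)
        assert rep.per_class.loc["c1", "recall"] == pytest.approx(r, abs=1e-9)
        assert rep.per_class.loc["c1", "f1"] == pytest.approx(f1, abs=1e-9)
        assert rep.micro_accuracy == pytest.approx(17 / 20, abs=1e-12)

    def test_random_10_class_matrix_matches_brute_force(self):
        """Every per-class metric on a random 10-class problem agrees with
        a from-scratch confusion-matrix computation to 1e-9."""
        rng = np.random.default_rng(0)
        classes = [f"k{i}" for i in range(10)]
        y_true = rng.choice(classes, 500)
        y_pred = rng.choice(classes, 500)
        rep = per_class_metrics(y_true, y_pred)
        for c in classes:
            tp = np.sum((y_true == c) & (y_pred == c))
            fp = np.sum((y_true != c) & (y_pred == c))
            fn = np.sum((y_true == c) & (y_pred != c))
            tn = 500 - tp - fp - fn
            prec = 100 * tp / (tp + fp) if tp + fp else 0.0
            rec = 100 * tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            row = rep.per_class.loc[c]
            assert row["precision"] == pytest.approx(prec, abs=1e-9)
            assert row["recall"] == pytest.approx(rec, abs=1e-9)
            assert row["f1"] == pytest.approx(f1, abs=1e-9)
            assert row["accuracy"] == pytest.approx(
                100 * (tp + tn) / 500, abs=1e-9
            )

    def test_micro_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(["a", "b", "c"], 200)
        y_pred = rng.choice(["a", "b", "c"], 200)
        rep = per_class_metrics(y_true, y_pred)
        assert rep.micro_accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / rep.confusion.to_numpy().sum()
        )

    def test_zero_support_class_excluded(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 4 + ["c"] + ["b"] * 5
        rep = per_class_metrics(y_true, y_pred)
        assert rep.excluded_classes == ["c"]
        assert "c" not in rep.per_class.index

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_class_metrics(["a"], ["a", "b"])


class TestRocPr:
    def test_perfect_separation_gives_1(self):
        y = ["p"] * 20 + ["n"] * 20
        proba = pd.DataFrame(
            {"p": [0.9] * 20 + [0.1] * 20, "n": [0.1] * 20 + [0.9] * 20}
        )
        out = roc_pr(y, proba)
        assert out["auroc_micro"] == pytest.approx(1.0)
        assert out["auroc_macro"] == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        n = 10_000
        y = rng.choice(["a", "b"], n)
        p = rng.random(n)
        proba = pd.DataFrame({"a": p, "b": 1 - p})
        out = roc_pr(y, proba)
        assert out["auroc_micro"] == pytest.approx(0.5, abs=0.02)

    def test_auroc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.choice(["a", "b", "c"], n)
        raw = rng.random((n, 3))
        raw /= raw.sum(axis=1, keepdims=True)
        proba = pd.DataFrame(raw, columns=["a", "b", "c"])
        out = roc_pr(y, proba)
        per_class = []
        for c in ["a", "b", "c"]:
            per_class.append(
                brute_force_auroc(proba[c].to_numpy(), y == c)
            )
            assert out["per_class_auroc"][c] == pytest.approx(
                per_class[-1], abs=1e-9
            )
        assert out["auroc_macro"] == pytest.approx(np.mean(per_class), abs=1e-9)

    def test_bootstrap_ci_covers_point_estimate(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.choice(["a", "b"], n)
        p = np.clip(rng.normal(0.7, 0.2, n) * (y == "a")
                    + rng.normal(0.3, 0.2, n) * (y == "b"), 0, 1)
        proba = pd.DataFrame({"a": p, "b": 1 - p})
        out = roc_pr(y, proba, n_bootstrap=200, seed=1)
        lo, hi = out["auroc_micro_ci95"]
        assert lo <= out["auroc_micro"] <= hi
        assert 0 < hi - lo < 0.2

    def test_unnormalised_probabilities_rejected(self):
        with pytest.raises(ValueError):
            roc_pr(["a", "b"], pd.DataFrame({"a": [0.9, 0.9], "b": [0.3, 0.3]}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr(["a", "a"], pd.DataFrame({"a": [0.6, 0.7], "b": [0.4, 0.3]}))


def _cohort_table(rng, n_subjects, shift=0.0, chunk="A1"):
    rows = []
    for s in range(n_subjects):
        for chunk_code in (chunk, "P0"):
            base = rng.normal(2.0, 0.2, size=30)
            if chunk_code == chunk:
                base = base + shift
            for v in base:
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "true_chunk": chunk_code,
                        "inscribed_radius": v,
                        "curvature": rng.normal(0.1, 0.02),
                    }
                )
    return pd.DataFrame(rows)


class TestGroupwiseStats:
    def test_identical_cohorts_all_masked(self):
        rng = np.random.default_rng(0)
        a = _cohort_table(rng, 10)
        b = _cohort_table(rng, 10)
        out = groupwise_feature_stats(
            {"control": a, "icas": b}, ["inscribed_radius", "curvature"]
        )
        assert not out.filter(like="sig_").any().any()

    def test_planted_shift_detected(self):
        """A +3 SD radius shift in one chunk at n=20/20 subjects passes the
        p < 0.001 gate (power is essentially 1 at this effect size)."""
        rng = np.random.default_rng(1)
        a = _cohort_table(rng, 20)
        b = _cohort_table(rng, 20, shift=0.6)  # 3 x the 0.2 SD
        out = groupwise_feature_stats(
            {"control": a, "icas": b}, ["inscribed_radius"]
        )
        cell = out[(out["chunk"] == "A1") & (out["feature"] == "inscribed_radius")]
        assert bool(cell["sig_control_vs_icas"].iloc[0])
        other = out[(out["chunk"] == "P0")]
        assert not bool(other["sig_control_vs_icas"].iloc[0])

    def test_t_statistic_matches_closed_form(self):
        """Two hand-entered 5-value samples against the pooled-variance
        two-sample t formula."""
        x = np.array([2.1, 2.3, 1.9, 2.2, 2.0])
        y = np.array([2.6, 2.8, 2.5, 2.9, 2.7])
        rows = []
        for cohort, vals in (("control", x), ("icas", y)):
            for i, v in enumerate(vals):
                rows.append(
                    {"subject_id": f"{cohort}{i}", "true_chunk": "A1",
                     "inscribed_radius": v}
                )
        tables = {
            c: pd.DataFrame([r for r in rows if r["subject_id"].startswith(c)])
            for c in ("control", "icas")
        }
        out = groupwise_feature_stats(tables, ["inscribed_radius"])
        sp = np.sqrt(((4 * x.var(ddof=1)) + (4 * y.var(ddof=1))) / 8)
        t_manual = (x.mean() - y.mean()) / (sp * np.sqrt(2 / 5))
        assert out["t_control_vs_icas"].iloc[0] == pytest.approx(
            t_manual, abs=1e-9
        )

    def test_single_cohort_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            groupwise_feature_stats({"control": _cohort_table(rng, 5)}, ["curvature"])


class TestSeparability:
    @pytest.fixture(scope="class")
    def gaussian_table(self):
        rng = np.random.default_rng(0)
        from arterylabel.features import PREDICTOR_COLUMNS

        rows = []
        for ci, chunk in enumerate(["A1", "P0"]):
            X = rng.normal(ci * 10.0, 1.0, size=(400, 12))
            for k in range(400):
                rows.append(
                    dict(zip(PREDICTOR_COLUMNS, X[k]))
                    | {"true_chunk": chunk, "true_branch": f"{chunk}.0{k % 2 + 1}"}
                )
        return pd.DataFrame(rows)

    def test_separated_chunks_high_silhouette(self, gaussian_table):
        from arterylabel.features import PREDICTOR_COLUMNS

        out = separability_check(gaussian_table, PREDICTOR_COLUMNS, seed=0,
                                 subsample=800)
        assert out["silhouette_chunk"] > 0.5

    def test_shuffled_labels_near_zero(self, gaussian_table):
        from arterylabel.features import PREDICTOR_COLUMNS

        rng = np.random.default_rng(5)
        tab = gaussian_table.copy()
        tab["true_chunk"] = rng.permutation(tab["true_chunk"].to_numpy())
        tab["true_branch"] = tab["true_chunk"]
        out = separability_check(tab, PREDICTOR_COLUMNS, seed=0, subsample=800)
        assert abs(out["silhouette_chunk"]) <= 0.05

    def test_single_class_rejected(self, gaussian_table):
        from arterylabel.features import PREDICTOR_COLUMNS

        tab = gaussian_table.copy()
        tab["true_chunk"] = "A1"
        tab["true_branch"] = "A1.01"
        with pytest.raises(ValueError):
            separability_check(tab, PREDICTOR_COLUMNS, seed=0, subsample=400)


class TestPairedPermutation:
    def test_clear_improvement_is_significant(self):
        rng = np.random.default_rng(0)
        b = rng.random(300) < 0.7
        a = b | (rng.random(300) < 0.5)  # strictly better
        p = paired_permutation_pvalue(a.astype(float), b.astype(float),
                                      rounds=2000, seed=1)
        assert p < 0.001

    def test_no_difference_is_insignificant(self):
        rng = np.random.default_rng(2)
        a = (rng.random(300) < 0.7).astype(float)
        b = (rng.random(300) < 0.7).astype(float)
        p = paired_permutation_pvalue(a, b, rounds=2000, seed=1)
        assert p > 0.01
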