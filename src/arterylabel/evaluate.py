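"""Evaluation surface: per-class metrics, ROC/PR areas, groupwise feature
statistics and cluster-separability checks.

Per-class "accuracy" is reported in two conventions because the field uses
both: one-vs-rest accuracy ((TP+TN)/N) and within-class recall; precision,
recall and F1 are one-vs-rest.  AUROC/AUPRC come in micro (pooled) and
macro (unweighted class mean) averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    silhouette_score,
)
from sklearn.preprocessing import StandardScaler, label_binarize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-class metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_class: pd.DataFrame          # index: class; columns in percent
    confusion: pd.DataFrame
    micro_accuracy: float            # trace / total, in [0, 1]
    excluded_classes: list[str] = field(default_factory=list)
    level: str = "chunk"
    stage: str = "raw"
    auroc_micro: float | None = None
    auroc_macro: float | None = None
    auprc_micro: float | None = None
    auprc_macro: float | None = None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "stage": self.stage,
            "micro_accuracy": self.micro_accuracy,
            "auroc_micro": self.auroc_micro,
            "auroc_macro": self.auroc_macro,
            "auprc_micro": self.auprc_micro,
            "auprc_macro": self.auprc_macro,
            "excluded_classes": self.excluded_classes,
            "per_class": self.per_class.round(4).to_dict(orient="index"),
        }


def per_class_metrics(
    true_labels,
    pred_labels,
    level: str = "chunk",
    stage: str = "raw",
) -> MetricsReport:
    """One-vs-rest precision/recall/F1 and per-class accuracy (percent).

    Classes with zero test support are excluded from the per-class table
    and listed in ``excluded_classes``.
    """
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(pred_labels, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    support = cm.sum(axis=1)
    kept = [c for c, s in zip(classes, support) if s > 0]
    excluded = [c for c, s in zip(classes, support) if s == 0]
    if excluded:
        logger.info("classes with no test support excluded: %s", excluded)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=kept, zero_division=0
    )
    n = len(y_true)
    rows = {}
    for i, c in enumerate(kept):
        ci = classes.index(c)
        tp = cm[ci, ci]
        fp = cm[:, ci].sum() - tp
        fn = cm[ci, :].sum() - tp
        tn = n - tp - fp - fn
        rows[c] = {
            "support": int(cm[ci, :].sum()),
            "accuracy": 100.0 * (tp + tn) / n,
            "recall_accuracy": 100.0 * rec[i],
            "precision": 100.0 * prec[i],
            "recall": 100.0 * rec[i],
            "f1": 100.0 * f1[i],
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return MetricsReport(
        per_class=per_class,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        micro_accuracy=float(np.trace(cm)) / n,
        excluded_classes=excluded,
        level=level,
        stage=stage,
    )


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------


def roc_pr(
    true_labels,
    probability_frame: pd.DataFrame,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> dict:
    """Micro/macro AUROC and AUPRC from one-vs-rest curves.

    ``probability_frame`` columns are class codes; rows must sum to 1.
    Macro averages run over classes with positive test support; micro pools
    all decisions.  With ``n_bootstrap`` > 0 a stratified bootstrap
    (resampling within each true class) yields a 95% CI for the micro
    AUROC.
    """
    y_true = np.asarray(true_labels, dtype=object)
    classes = list(probability_frame.columns)
    P = probability_frame.to_numpy(dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        raise ValueError("need at least two classes present for ROC analysis")
    Y = label_binarize(y_true, classes=classes)
    if Y.shape[1] == 1:  # sklearn collapses the binary case
        Y = np.column_stack([1 - Y[:, 0], Y[:, 0]])
    keep = [classes.index(c) for c in present]
    per_class_auroc = {
        classes[i]: float(roc_auc_score(Y[:, i], P[:, i])) for i in keep
    }
    per_class_auprc = {
        classes[i]: float(average_precision_score(Y[:, i], P[:, i])) for i in keep
    }
    out = {
        "auroc_micro": float(roc_auc_score(Y.ravel(), P.ravel())),
        "auroc_macro": float(np.mean(list(per_class_auroc.values()))),
        "auprc_micro": float(average_precision_score(Y.ravel(), P.ravel())),
        "auprc_macro": float(np.mean(list(per_class_auprc.values()))),
        "per_class_auroc": per_class_auroc,
        "per_class_auprc": per_class_auprc,
    }
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        class_idx = {c: np.nonzero(y_true == c)[0] for c in present}
        stats_boot = []
        for _ in range(n_bootstrap):
            idx = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True)
                 for ix in class_idx.values()]
            )
            stats_boot.append(
                float(roc_auc_score(Y[idx].ravel(), P[idx].ravel()))
            )
        lo, hi = np.percentile(stats_boot, [2.5, 97.5])
        out["auroc_micro_ci95"] = [float(lo), float(hi)]
    return out


# ---------------------------------------------------------------------------
# groupwise statistics
# ---------------------------------------------------------------------------


def groupwise_feature_stats(
    tables: dict[str, pd.DataFrame],
    features: list[str],
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Two-sample t between cohort pairs and one-way F across cohorts on
    subject-level feature means, per (chunk, feature).

    Entries with p above ``alpha`` are masked (significant=False); the
    t/F values themselves are retained for inspection.
    """
    cohorts = sorted(tables)
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    means = {}
    for cohort, tab in tables.items():
        g = tab.groupby(["subject_id", "true_chunk"])[features].mean()
        if g.index.get_level_values(0).nunique() < 2:
            raise ValueError(f"cohort {cohort} has fewer than 2 subjects")
        means[cohort] = g
    rows = []
    chunks = sorted(
        set().union(*(m.index.get_level_values(1).unique() for m in means.values()))
    )
    for chunk in chunks:
        for feat in features:
            samples = {}
            for cohort in cohorts:
                m = means[cohort]
                sel = m.xs(chunk, level=1)[feat].dropna() if chunk in (
                    m.index.get_level_values(1)
                ) else pd.Series(dtype=float)
                samples[cohort] = sel.to_numpy()
            valid = {c: s for c, s in samples.items() if len(s) >= 2}
            if len(valid) < 2:
                continue
            row = {"chunk": chunk, "feature": feat}
            if len(valid) >= 2:
                f_stat, f_p = stats.f_oneway(*valid.values())
                row["F"] = float(f_stat)
                row["F_p"] = float(f_p)
                row["F_significant"] = bool(f_p <= alpha)
            for i, a in enumerate(cohorts):
                for b in cohorts[i + 1:]:
                    if a not in valid or b not in valid:
                        continue
                    t_stat, t_p = stats.ttest_ind(valid[a], valid[b])
                    row[f"t_{a}_vs_{b}"] = float(t_stat)
                    row[f"p_{a}_vs_{b}"] = float(t_p)
                    row[f"sig_{a}_vs_{b}"] = bool(t_p <= alpha)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# separability
# ---------------------------------------------------------------------------


def separability_check(
    table: pd.DataFrame,
    predictor_columns: list[str],
    seed: int = 0,
    subsample: int = 6000,
    min_class_size: int = 5,
) -> dict:
    """Mean silhouette of a 2-D nonlinear neighbour embedding (UMAP),
    scored separately with chunk and with branch colouring.

    The contract mirrored from real cohorts: the chunk level separates
    better than the branch level on the same embedding.
    """
    import umap  # deferred: numba compilation is slow to import

    rng = np.random.default_rng(seed)
    tab = table.dropna(subset=["true_chunk", "true_branch"])
    if len(tab) > subsample:
        idx = rng.choice(len(tab), size=subsample, replace=False)
        tab = tab.iloc[np.sort(idx)]
    for level, col in (("chunk", "true_chunk"), ("branch", "true_branch")):
        counts = tab[col].value_counts()
        if (counts >= min_class_size).sum() < 2:
            raise ValueError(f"need at least two {level} classes")
    X = StandardScaler().fit_transform(tab[predictor_columns].to_numpy(float))
    reducer = umap.UMAP(n_components=2, random_state=int(seed) % (2**31))
    emb = reducer.fit_transform(X)
    result = {}
    for level, col in (("chunk", "true_chunk"), ("branch", "true_branch")):
        y = tab[col].to_numpy()
        counts = pd.Series(y).value_counts()
        keep = counts[counts >= min_class_size].index
        mask = np.isin(y, keep)
        if len(keep) < 2:
            raise ValueError(f"need at least two {level} classes")
        result[f"silhouette_{level}"] = float(
            silhouette_score(emb[mask], y[mask])
        )
        result[f"n_classes_{level}"] = int(len(keep))
    return result


# ---------------------------------------------------------------------------
# paired permutation test
# ---------------------------------------------------------------------------


def paired_permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    rounds: int = 10000,
    seed: int = 0,
) -> float:
    """One-sided sign-flip permutation p-value for mean(a - b) > 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    observed = d.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(rounds, len(d)))
    null = (signs * d).mean(axis=1)
    return float((np.sum(null >= observed) + 1) / (rounds + 1))
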