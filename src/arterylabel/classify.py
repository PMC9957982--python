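"""Two-step supervised labelling of vascular spots.

Step 1 allocates every spot of the whole brain to one of the 20 chunks with
a multilayer perceptron over 12 predictors (3 normalised coordinates + 9
geometric features); segment-wise majority voting then smooths the spot
labels.  Step 2 repeats the process within each chunk, allocating spots to
that chunk's branches with a per-chunk MLP followed by another round of
voting.  An optional anatomical post-processing pass repairs segments whose
labels are inconsistent with the centerline tree (connectivity) or with the
mid-sagittal plane (laterality).

The split is always by subject, never by spot; the feature scaler is
fitted on training subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .config import MLPConfig
from .features import PREDICTOR_COLUMNS
from .hierarchy import NomenclatureMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# subject-level split
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    train: list[str]
    test: list[str]
    train_fraction: float
    seed: int


def split_subjects(
    subjects: list[str],
    train_fraction: float = 0.70,
    seed: int = 0,
    cohort_of: dict[str, str] | None = None,
) -> SplitSpec:
    """Disjoint subject-level train/test partition, stratified by cohort.

    Within each cohort ``round(train_fraction * n)`` subjects train and the
    rest test; deterministic under ``seed``.
    """
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    cohort_of = cohort_of or {}
    by_cohort: dict[str, list[str]] = {}
    for s in subjects:
        by_cohort.setdefault(cohort_of.get(s, "all"), []).append(s)
    train, test = [], []
    for cohort in sorted(by_cohort):
        group = sorted(by_cohort[cohort])
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        train += [group[i] for i in order[:n_train]]
        test += [group[i] for i in order[n_train:]]
    return SplitSpec(sorted(train), sorted(test), train_fraction, seed)


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------


@dataclass
class ClassifierEnsemble:
    """Step-1 chunk model plus per-chunk step-2 branch models.

    ``branch_models`` maps a chunk code to either a fitted classifier (for
    chunks owning several branches with training support) or directly to a
    branch-code string (single-branch chunks, assigned deterministically).
    """

    nmap: NomenclatureMap
    scaler: StandardScaler | None = None
    chunk_model: MLPClassifier | None = None
    branch_models: dict = field(default_factory=dict)
    split: SplitSpec | None = None
    seed: int = 0
    config: MLPConfig = field(default_factory=MLPConfig)

    def predictors(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in PREDICTOR_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks predictor columns {missing}")
        X = table[PREDICTOR_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in predictor columns")
        return self.scaler.transform(X)


def _balanced_indices(
    y: np.ndarray, rng: np.random.Generator, cap: float
) -> np.ndarray:
    """Bounded inverse-frequency oversampling: each class is duplicated up
    to ``cap`` times toward the median class count."""
    idx = np.arange(len(y))
    classes, counts = np.unique(y, return_counts=True)
    median = float(np.median(counts))
    extra = []
    for cls, count in zip(classes, counts):
        factor = min(cap, median / count)
        n_extra = int(round((factor - 1.0) * count))
        if n_extra > 0:
            pool = idx[y == cls]
            extra.append(rng.choice(pool, size=n_extra, replace=True))
    if extra:
        idx = np.concatenate([idx] + extra)
    return np.sort(idx)


def _make_mlp(config: MLPConfig, seed: int, n_samples: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layer_sizes),
        activation=config.activation,
        solver=config.solver,
        max_iter=config.max_iter,
        early_stopping=config.early_stopping and n_samples >= 100,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.n_iter_no_change,
        random_state=seed,
    )


# ---------------------------------------------------------------------------
# step 1: chunk model
# ---------------------------------------------------------------------------


def train_chunk_model(
    table: pd.DataFrame,
    split: SplitSpec,
    nmap: NomenclatureMap,
    config: MLPConfig | None = None,
    seed: int = 0,
) -> ClassifierEnsemble:
    """Standardise the 12 predictors on training subjects and fit the
    spot-to-chunk MLP."""
    config = config or MLPConfig()
    ens = ClassifierEnsemble(nmap=nmap, split=split, seed=seed, config=config)
    train_rows = table[table["subject_id"].isin(split.train)]
    if train_rows.empty:
        raise ValueError("no training rows after split")
    X = train_rows[PREDICTOR_COLUMNS].to_numpy(dtype=float)
    y = train_rows["true_chunk"].to_numpy()
    missing = set(nmap.chunk_codes) - set(np.unique(y))
    if missing:
        logger.warning("chunks absent from training and dropped from the "
                       "model: %s", sorted(missing))
    ens.scaler = StandardScaler().fit(X)
    Xs = ens.scaler.transform(X)
    rng = np.random.default_rng(seed)
    if config.balance_classes:
        idx = _balanced_indices(y, rng, config.balance_cap)
        Xs, y = Xs[idx], y[idx]
    ens.chunk_model = _make_mlp(config, seed, len(y))
    with np.errstate(all="ignore"):
        ens.chunk_model.fit(Xs, y)
    return ens


def predict_chunk(
    ensemble: ClassifierEnsemble, table: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-spot chunk probability vectors and argmax labels."""
    Xs = ensemble.predictors(table)
    proba = ensemble.chunk_model.predict_proba(Xs)
    classes = ensemble.chunk_model.classes_
    labels = classes[np.argmax(proba, axis=1)]
    return pd.DataFrame(proba, columns=classes, index=table.index), labels


# ---------------------------------------------------------------------------
# segment-wise voting
# ---------------------------------------------------------------------------


def vote_labels(
    labels: np.ndarray,
    segment_keys: np.ndarray,
    proba: pd.DataFrame | None = None,
) -> np.ndarray:
    """Broadcast each segment's modal label back onto its spots.

    Ties break by the highest summed predicted probability over the
    segment, then lexicographically — fully deterministic.
    """
    labels = np.asarray(labels, dtype=object)
    out = labels.copy()
    df = pd.DataFrame({"label": labels, "segment": segment_keys})
    if df["segment"].isna().any():
        raise ValueError("every spot must carry a segment key")
    for seg, grp in df.groupby("segment", sort=False):
        counts = grp["label"].value_counts()
        top = counts[counts == counts.iloc[0]].index.tolist()
        if len(top) > 1 and proba is not None:
            sums = {}
            for cand in top:
                if cand in proba.columns:
                    sums[cand] = float(proba.loc[grp.index, cand].sum())
                else:
                    sums[cand] = -np.inf
            best = max(sums.values())
            top = [c for c in top if sums[c] == best]
        out[grp.index.to_numpy()] = sorted(top)[0]
    return out


def binomial_vote_accuracy(n: int, p: float) -> float:
    """Exact probability that a majority of n iid spots (accuracy p) votes
    the correct label (closed form used as the voting oracle)."""
    from math import comb

    k_min = n // 2 + 1
    total = sum(comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(k_min, n + 1))
    if n % 2 == 0:  # even splits break ties at random between two labels
        total += 0.5 * comb(n, n // 2) * p ** (n // 2) * (1 - p) ** (n // 2)
    return total


# ---------------------------------------------------------------------------
# step 2: branch models
# ---------------------------------------------------------------------------


def train_branch_models(
    ensemble: ClassifierEnsemble,
    table: pd.DataFrame,
) -> ClassifierEnsemble:
    """Fit one spot-to-branch MLP per chunk owning several branches.

    Single-branch chunks map deterministically; chunks without training
    spots are skipped (and logged).
    """
    split = ensemble.split
    config = ensemble.config
    train_rows = table[table["subject_id"].isin(split.train)]
    rng = np.random.default_rng(ensemble.seed + 1)
    for chunk in ensemble.nmap.chunk_codes:
        branches = ensemble.nmap.branches_of(chunk)
        if len(branches) == 1:
            ensemble.branch_models[chunk] = branches[0]
            continue
        rows = train_rows[train_rows["true_chunk"] == chunk]
        if rows.empty:
            logger.warning("chunk %s has no training spots; branch model "
                           "skipped", chunk)
            continue
        y = rows["true_branch"].to_numpy()
        present = np.unique(y)
        if len(present) == 1:
            ensemble.branch_models[chunk] = str(present[0])
            continue
        Xs = ensemble.scaler.transform(
            rows[PREDICTOR_COLUMNS].to_numpy(dtype=float)
        )
        if config.balance_classes:
            idx = _balanced_indices(y, rng, config.balance_cap)
            Xs, y = Xs[idx], y[idx]
        model = _make_mlp(config, ensemble.seed + 1, len(y))
        with np.errstate(all="ignore"):
            model.fit(Xs, y)
        ensemble.branch_models[chunk] = model
    return ensemble


def predict_branch(
    ensemble: ClassifierEnsemble,
    table: pd.DataFrame,
    chunk_assignments: np.ndarray,
    vote: bool = True,
    segment_keys: np.ndarray | None = None,
) -> np.ndarray:
    """Step-2 branch labels given (voted) step-1 chunk assignments.

    The emitted branch always satisfies ``chunk_of(branch) == chunk``.
    """
    chunk_assignments = np.asarray(chunk_assignments, dtype=object)
    out = np.empty(len(table), dtype=object)
    proba_cols: dict[str, pd.DataFrame] = {}
    Xs = ensemble.predictors(table)
    positions = np.arange(len(table))
    for chunk in pd.unique(chunk_assignments):
        mask = chunk_assignments == chunk
        model = ensemble.branch_models.get(chunk)
        if model is None:
            fallback = ensemble.nmap.branches_of(chunk)
            out[mask] = fallback[0] if fallback else chunk
            logger.warning("no branch model for chunk %s; first branch code "
                           "assigned", chunk)
            continue
        if isinstance(model, str):
            out[mask] = model
            continue
        proba = model.predict_proba(Xs[mask])
        out[mask] = model.classes_[np.argmax(proba, axis=1)]
        proba_cols[chunk] = pd.DataFrame(
            proba, columns=model.classes_, index=positions[mask]
        )
    if vote:
        if segment_keys is None:
            raise ValueError("segment keys required for branch voting")
        for chunk, proba in proba_cols.items():
            mask = chunk_assignments == chunk
            voted = vote_labels(
                out[mask],
                np.asarray(segment_keys, dtype=object)[mask],
                proba.set_axis(np.arange(int(mask.sum()))),
            )
            out[mask] = voted
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_ensemble(ensemble: ClassifierEnsemble, directory) -> None:
    """Persist the model bundle: per-model weights plus JSON metadata
    (seed, split, scaler statistics, nomenclature version)."""
    import dataclasses
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(ensemble.chunk_model, directory / "chunk_model.joblib")
    joblib.dump(ensemble.scaler, directory / "scaler.joblib")
    branch_meta = {}
    for chunk, model in ensemble.branch_models.items():
        if isinstance(model, str):
            branch_meta[chunk] = {"kind": "constant", "branch": model}
        else:
            fname = f"branch_{chunk}.joblib"
            joblib.dump(model, directory / fname)
            branch_meta[chunk] = {"kind": "mlp", "file": fname}
    meta = {
        "seed": ensemble.seed,
        "split": dataclasses.asdict(ensemble.split) if ensemble.split else None,
        "mlp_config": dataclasses.asdict(ensemble.config),
        "nomenclature_version": ensemble.nmap.version,
        "branch_models": branch_meta,
        "predictor_columns": PREDICTOR_COLUMNS,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_ensemble(directory, nmap: NomenclatureMap | None = None) -> ClassifierEnsemble:
    """Load a model bundle written by :func:`save_ensemble`."""
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    nmap = nmap or NomenclatureMap.default()
    if meta["nomenclature_version"] != nmap.version:
        logger.warning(
            "model was trained with nomenclature %s but %s is active",
            meta["nomenclature_version"], nmap.version,
        )
    mlp_cfg = dict(meta["mlp_config"])
    mlp_cfg["hidden_layer_sizes"] = tuple(mlp_cfg["hidden_layer_sizes"])
    split = SplitSpec(**meta["split"]) if meta.get("split") else None
    ens = ClassifierEnsemble(
        nmap=nmap,
        scaler=joblib.load(directory / "scaler.joblib"),
        chunk_model=joblib.load(directory / "chunk_model.joblib"),
        split=split,
        seed=meta["seed"],
        config=MLPConfig(**mlp_cfg),
    )
    for chunk, bm in meta["branch_models"].items():
        if bm["kind"] == "constant":
            ens.branch_models[chunk] = bm["branch"]
        else:
            ens.branch_models[chunk] = joblib.load(directory / bm["file"])
    return ens


# ---------------------------------------------------------------------------
# anatomical post-processing
# ---------------------------------------------------------------------------


def _segment_frame(table: pd.DataFrame, chunk_col: str, branch_col: str):
    agg = dict(
        chunk=(chunk_col, "first"),
        branch=(branch_col, "first"),
        mean_x=("x_mm", "mean"),
        n=("segment_key", "size"),
    )
    if "terminal" in table.columns:
        agg["terminal"] = ("terminal", "first")
    return table.groupby("segment_key").agg(**agg)


def anatomical_postprocess(
    table: pd.DataFrame,
    adjacency: dict[str, set[str]],
    nmap: NomenclatureMap,
    rules: tuple[str, ...] = ("connectivity", "laterality"),
    midline_x: float | None = None,
    right_is_positive_x: bool = True,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Rule-based repair of voted labels; idempotent.

    connectivity — a segment whose predicted chunk also occurs elsewhere in
    the subject but is connected (through the centerline tree) to no other
    segment of that chunk adopts its neighbours' modal chunk.
    laterality — a segment labelled with a sided chunk whose spots lie on
    the opposite side of the subject's mid-sagittal plane is flipped to the
    mirror chunk (and mirror branch).  Every relabel is logged.

    ``table`` needs columns segment_key, pred_chunk, pred_branch, x_mm.
    """
    out = table.copy()
    if midline_x is None:
        midline_x = float(out["x_mm"].mean())
    for _ in range(max_iter):
        changed = False
        seg = _segment_frame(out, "pred_chunk", "pred_branch")
        if "connectivity" in rules:
            # connected groups of same-chunk segments (within this table)
            group_sizes: dict[str, list[int]] = {}
            seen: set[str] = set()
            for seg_key in seg.index:
                if seg_key in seen:
                    continue
                chunk = seg.loc[seg_key, "chunk"]
                stack, group = [seg_key], set()
                while stack:
                    cur = stack.pop()
                    if cur in group:
                        continue
                    group.add(cur)
                    for n in adjacency.get(cur, set()):
                        if n in seg.index and n not in group and (
                            seg.loc[n, "chunk"] == chunk
                        ):
                            stack.append(n)
                seen |= group
                group_sizes.setdefault(chunk, []).append(len(group))
                for m in group:
                    seg.loc[m, "group_size"] = len(group)
            for seg_key, row in seg.iterrows():
                chunk = row["chunk"]
                # only repair a singleton cut off from a larger connected
                # body of its own chunk; chunks that legitimately occur as
                # scattered single segments are left alone, and so are
                # terminal segments, which may dangle into foreign territory
                if row.get("group_size", 1) != 1:
                    continue
                if bool(row.get("terminal", False)):
                    continue
                if max(group_sizes.get(chunk, [1])) < 2:
                    continue
                nbrs = adjacency.get(seg_key, set())
                nbr_chunks = [seg.loc[n, "chunk"] for n in nbrs if n in seg.index]
                if not nbr_chunks or chunk in nbr_chunks:
                    continue
                new_chunk = sorted(
                    pd.Series(nbr_chunks).value_counts().pipe(
                        lambda c: c[c == c.iloc[0]].index.tolist()
                    )
                )[0]
                branches = nmap.branches_of(new_chunk)
                nbr_branches = [
                    seg.loc[n, "branch"]
                    for n in nbrs
                    if n in seg.index and seg.loc[n, "chunk"] == new_chunk
                ]
                new_branch = nbr_branches[0] if nbr_branches else branches[0]
                mask = out["segment_key"] == seg_key
                out.loc[mask, "pred_chunk"] = new_chunk
                out.loc[mask, "pred_branch"] = new_branch
                logger.info("connectivity rule: segment %s %s -> %s",
                            seg_key, chunk, new_chunk)
                changed = True
        if "laterality" in rules:
            seg = _segment_frame(out, "pred_chunk", "pred_branch")
            for seg_key, row in seg.iterrows():
                side = nmap.chunk_sides.get(row["chunk"], "midline")
                if side == "midline":
                    continue
                dx = row["mean_x"] - midline_x
                if abs(dx) < 12.0:
                    continue  # parasagittal vessels are left alone; the
                    # rule targets gross lateral misassignments only
                on_right = (dx > 0) == right_is_positive_x
                if (side == "right") == on_right:
                    continue
                mirror = nmap.mirror_chunk(row["chunk"])
                if mirror is None:
                    continue
                mbranch = nmap.mirror_branch(row["branch"])
                mask = out["segment_key"] == seg_key
                out.loc[mask, "pred_chunk"] = mirror
                out.loc[mask, "pred_branch"] = (
                    mbranch if mbranch else nmap.branches_of(mirror)[0]
                )
                logger.info("laterality rule: segment %s %s -> %s",
                            seg_key, row["chunk"], mirror)
                changed = True
        if not changed:
            break
    return out
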