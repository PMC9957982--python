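"""End-to-end orchestration of the labelling experiment.

simulate → extract → features → hierarchy → train → label → vote →
post-process → evaluate, with per-subject caching, one root seed feeding
named substreams, and every artefact stamped with the resolved config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, features, geometry, hierarchy, synthetic
from .config import RunConfig
from .features import FEATURE_COLUMNS, PREDICTOR_COLUMNS
from .hierarchy import NomenclatureMap

logger = logging.getLogger(__name__)


def subseed(root_seed: int, *tags) -> int:
    """Deterministic substream seed derived from the root seed and a tag
    path (kept below 2**31)."""
    h = hashlib.sha256(repr((int(root_seed),) + tags).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# per-subject processing
# ---------------------------------------------------------------------------


def process_subject(
    nmap: NomenclatureMap,
    cohort: str,
    seed: int,
    config: RunConfig,
    subject_id: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one subject and run the full geometric characterisation.

    Returns the per-spot feature table (with ground-truth labels, raw mm
    coordinates and segment keys) and a topology summary comparing the
    skeleton-derived endpoint/junction counts against the generating tree.
    """
    subject_id = subject_id or f"{cohort}-{seed:05d}"
    spec = synthetic.sample_tree(nmap, cohort, seed, subject_id=subject_id)
    truth_lines = synthetic.realize_centerlines(spec)
    volume, labels = synthetic.voxelize(truth_lines, config.spacing_mm)
    volume = geometry.resample_isovoxel(volume)

    skel = geometry.skeletonize(volume)
    skel = geometry.prune_skeleton(skel, config.prune_mm)
    tree = geometry.build_tree(skel)
    tree = geometry.prune_skeleton(tree, config.prune_mm)
    centerlines = geometry.extract_centerlines(
        tree, volume, smooth_window=config.smooth_window
    )

    spots = features.sample_spots(centerlines, config.spot_interval_mm)
    spots = features.compute_all_features(
        volume,
        centerlines,
        spots,
        window_mm=config.distortion_window_mm,
        curvature_window_mm=config.curvature_window_mm,
        circularity_mode=config.circularity_mode,
        pitch_factor=config.section_pitch_factor,
    )
    spots = hierarchy.label_spots_from_volume(spots, labels, nmap)
    segments = hierarchy.segment_spots(centerlines, spots)

    table = features.assemble_feature_table(
        spots, volume=volume, subject_id=subject_id
    )
    pos = {s.spot_id: s.position for s in spots}
    coords = np.array([pos[i] for i in table["spot_id"]])
    table["x_mm"], table["y_mm"], table["z_mm"] = coords.T
    table["segment_key"] = [
        f"{subject_id}/{seg}" for seg in table["segment_id"]
    ]
    terminal = {
        i: (p.start_kind != "junction" or p.end_kind != "junction")
        for i, p in enumerate(centerlines)
    }
    table["terminal"] = table["segment_id"].map(terminal)
    table["cohort"] = cohort

    detected = geometry.topology_summary(tree)
    expected = spec.expected_topology()
    adjacency = {}
    for i, poly in enumerate(centerlines):
        key = f"{subject_id}/{i}"
        for j, other in enumerate(centerlines):
            if i == j:
                continue
            shared = {poly.start_node, poly.end_node} & {
                other.start_node, other.end_node
            }
            if shared - {None}:
                adjacency.setdefault(key, []).append(f"{subject_id}/{j}")
    topo = {
        "subject_id": subject_id,
        "cohort": cohort,
        "seed": seed,
        "detected": detected,
        "expected": expected,
        "topology_match": bool(
            detected["n_endpoints"] == expected["n_endpoints"]
            and detected["n_junctions"] == expected["n_junctions"]
            and detected["n_components"] == expected["n_components"]
        ),
        "n_spots": int(len(table)),
        "n_segments": int(table["segment_id"].nunique()),
        "n_present_chunks": len(spec.present_chunks(nmap)),
        "n_present_branches": len(spec.present_branches()),
        "adjacency": adjacency,
    }
    return table, topo


def _cached_subject(
    nmap, cohort, seed, config, cache_dir: Path | None
) -> tuple[pd.DataFrame, dict]:
    subject_id = f"{cohort}-{seed:05d}"
    if cache_dir is not None:
        csv = cache_dir / f"{subject_id}.csv"
        meta = cache_dir / f"{subject_id}.json"
        if csv.exists() and meta.exists():
            topo = json.loads(meta.read_text())
            if topo.get("config_hash") == config.config_hash:
                logger.info("cache hit for %s", subject_id)
                return pd.read_csv(csv), topo
    table, topo = process_subject(nmap, cohort, seed, config, subject_id)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        topo["config_hash"] = config.config_hash
        table.to_csv(cache_dir / f"{subject_id}.csv", index=False)
        (cache_dir / f"{subject_id}.json").write_text(json.dumps(topo, indent=1))
    return table, topo


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------


def _segment_accuracy(table: pd.DataFrame, pred_col: str, true_col: str) -> float:
    seg = table.groupby("segment_key").agg(
        pred=(pred_col, lambda s: s.mode().iloc[0]),
        true=(true_col, lambda s: s.mode().sort_values().iloc[0]),
    )
    return float((seg["pred"] == seg["true"]).mean())


def label_cohort(
    ensemble: classify.ClassifierEnsemble,
    table: pd.DataFrame,
    adjacency: dict[str, set[str]],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run steps 1 + 2 (with voting and post-processing) on a feature
    table; returns the table with prediction columns added, plus the raw
    step-1 probability frame."""
    table = table.reset_index(drop=True)
    proba, raw_chunk = classify.predict_chunk(ensemble, table)
    table["pred_chunk_raw"] = raw_chunk
    seg_keys = table["segment_key"].to_numpy()
    if config.vote_chunks:
        table["pred_chunk"] = classify.vote_labels(raw_chunk, seg_keys, proba)
    else:
        table["pred_chunk"] = raw_chunk
    table["pred_chunk_voted"] = table["pred_chunk"]
    table["pred_branch_raw"] = classify.predict_branch(
        ensemble, table, table["pred_chunk"].to_numpy(), vote=False
    )
    if config.vote_branches:
        table["pred_branch"] = classify.predict_branch(
            ensemble,
            table,
            table["pred_chunk"].to_numpy(),
            vote=True,
            segment_keys=seg_keys,
        )
    else:
        table["pred_branch"] = table["pred_branch_raw"]
    table["pred_branch_voted"] = table["pred_branch"]
    if config.postprocess:
        # rules reason about one subject's tree and mid-sagittal plane
        parts = []
        for _, sub in table.groupby("subject_id", sort=False):
            parts.append(
                classify.anatomical_postprocess(
                    sub, adjacency, ensemble.nmap,
                    rules=config.postprocess_rules,
                )
            )
        table = pd.concat(parts).sort_index()
        # keep the hierarchy consistent after any relabelling
        table["pred_chunk"] = [
            ensemble.nmap.chunk_of(b) for b in table["pred_branch"]
        ]
    return table, proba


def run_experiment(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-cohort experiment and write reports.

    Deterministic under ``config.seed``: subject simulation, the 70/30
    subject split, network initialisation, the embedding and the
    permutation test each draw from a named substream of the root seed.
    """
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nmap = NomenclatureMap.default()
    config.to_json(outdir / "run_config.json")

    # ---- simulate + extract + features --------------------------------
    cache_dir = outdir / "subjects"
    cohort_tables: dict[str, list[pd.DataFrame]] = {}
    topologies: list[dict] = []
    adjacency: dict[str, set[str]] = {}
    n_by_cohort = {"control": config.n_control, "icas": config.n_icas}
    for cohort in config.cohorts:
        for k in range(n_by_cohort.get(cohort, 0)):
            seed = subseed(config.seed, "simulate", cohort, k)
            table, topo = _cached_subject(nmap, cohort, seed, config, cache_dir)
            cohort_tables.setdefault(cohort, []).append(table)
            topologies.append(topo)
            for key, nbrs in topo["adjacency"].items():
                adjacency[key] = set(nbrs)
    control = pd.concat(cohort_tables["control"], ignore_index=True)

    # ---- hierarchy consistency (ground truth) --------------------------
    assert control["true_chunk"].notna().all()

    # ---- split + train --------------------------------------------------
    subjects = sorted(control["subject_id"].unique())
    split = classify.split_subjects(
        subjects, config.train_fraction, subseed(config.seed, "split")
    )
    mlp_seed = subseed(config.seed, "mlp")
    ensemble = classify.train_chunk_model(
        control, split, nmap, config.mlp, seed=mlp_seed
    )
    ensemble = classify.train_branch_models(ensemble, control)

    # ---- label the held-out control subjects ----------------------------
    test_table = control[control["subject_id"].isin(split.test)]
    test_table, test_proba = label_cohort(ensemble, test_table, adjacency, config)

    results: dict = {"config_hash": config.config_hash, "seed": config.seed}
    chunk_raw = evaluate.per_class_metrics(
        test_table["true_chunk"], test_table["pred_chunk_raw"], "chunk", "raw"
    )
    chunk_voted = evaluate.per_class_metrics(
        test_table["true_chunk"], test_table["pred_chunk_voted"], "chunk", "voted"
    )
    chunk_final = evaluate.per_class_metrics(
        test_table["true_chunk"], test_table["pred_chunk"], "chunk",
        "postprocessed",
    )
    branch_final = evaluate.per_class_metrics(
        test_table["true_branch"], test_table["pred_branch"], "branch",
        "postprocessed",
    )
    rocpr = evaluate.roc_pr(test_table["true_chunk"], test_proba)
    for key, value in rocpr.items():
        if not key.startswith("per_class"):
            chunk_raw.__setattr__(key, value)

    seg_acc_voted = _segment_accuracy(test_table, "pred_chunk_voted",
                                      "true_chunk")
    seg_acc_final = _segment_accuracy(test_table, "pred_chunk", "true_chunk")

    # voting significance: per-segment mean spot correctness, raw vs voted,
    # one-sided sign-flip permutation over test segments
    per_seg = test_table.assign(
        raw_ok=(test_table["pred_chunk_raw"] == test_table["true_chunk"]),
        voted_ok=(test_table["pred_chunk_voted"] == test_table["true_chunk"]),
    ).groupby("segment_key")[["raw_ok", "voted_ok"]].mean()
    p_voting = evaluate.paired_permutation_pvalue(
        per_seg["voted_ok"].to_numpy(),
        per_seg["raw_ok"].to_numpy(),
        rounds=config.permutation_rounds,
        seed=subseed(config.seed, "permutation"),
    )

    results["control"] = {
        "n_subjects": len(subjects),
        "split": {"train": split.train, "test": split.test},
        "chunk_spot_accuracy_raw": chunk_raw.micro_accuracy,
        "chunk_spot_accuracy_voted": chunk_voted.micro_accuracy,
        "chunk_spot_accuracy_final": chunk_final.micro_accuracy,
        "branch_spot_accuracy_final": branch_final.micro_accuracy,
        "segment_accuracy_voted": seg_acc_voted,
        "segment_accuracy_final": seg_acc_final,
        "voting_improvement_pvalue": p_voting,
        "auroc_micro": rocpr["auroc_micro"],
        "auroc_macro": rocpr["auroc_macro"],
        "auprc_micro": rocpr["auprc_micro"],
        "auprc_macro": rocpr["auprc_macro"],
        "hierarchy_consistent_fraction": float(
            np.mean(
                [
                    nmap.chunk_of(b) == c
                    for b, c in zip(
                        test_table["pred_branch"], test_table["pred_chunk"]
                    )
                ]
            )
        ),
    }

    # ---- external ICAS validation --------------------------------------
    if "icas" in cohort_tables:
        icas = pd.concat(cohort_tables["icas"], ignore_index=True)
        icas, icas_proba = label_cohort(ensemble, icas, adjacency, config)
        icas_metrics = evaluate.per_class_metrics(
            icas["true_chunk"], icas["pred_chunk"], "chunk", "voted"
        )
        results["icas_external"] = {
            "n_subjects": int(icas["subject_id"].nunique()),
            "chunk_spot_accuracy_voted": icas_metrics.micro_accuracy,
            "chunk_accuracy_drop": results["control"][
                "chunk_spot_accuracy_final"
            ]
            - icas_metrics.micro_accuracy,
            "segment_accuracy_voted": _segment_accuracy(
                icas, "pred_chunk", "true_chunk"
            ),
        }
        stats_table = evaluate.groupwise_feature_stats(
            {"control": control, "icas": icas.drop(
                columns=[c for c in icas.columns if c.startswith("pred_")]
            )},
            FEATURE_COLUMNS,
        )
        stats_table.to_csv(outdir / "groupwise_stats.csv", index=False)
        results["groupwise"] = {
            "n_cells": int(len(stats_table)),
            "n_significant_t": int(
                stats_table.filter(like="sig_").sum(numeric_only=True).sum()
            ),
        }

    # ---- separability ---------------------------------------------------
    sep = evaluate.separability_check(
        test_table,
        PREDICTOR_COLUMNS,
        seed=subseed(config.seed, "umap"),
        subsample=config.silhouette_subsample,
    )
    results["separability"] = sep

    # ---- component profile ----------------------------------------------
    control_topos = [t for t in topologies if t["cohort"] == "control"]
    results["profile"] = {
        "mean_spots_control": float(
            np.mean([t["n_spots"] for t in control_topos])
        ),
        "mean_segments_control": float(
            np.mean([t["n_segments"] for t in control_topos])
        ),
        "mean_chunks_control": float(
            np.mean([t["n_present_chunks"] for t in control_topos])
        ),
        "topology_match_fraction": float(
            np.mean([t["topology_match"] for t in control_topos])
        ),
    }
    if "icas" in cohort_tables:
        icas_topos = [t for t in topologies if t["cohort"] == "icas"]
        results["profile"]["mean_chunks_icas"] = float(
            np.mean([t["n_present_chunks"] for t in icas_topos])
        )

    (outdir / "report.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    results["runtime_s"] = round(time.time() - t_start, 1)
    (outdir / "timing.json").write_text(
        json.dumps({"runtime_s": results["runtime_s"]})
    )
    chunk_final.per_class.to_csv(outdir / "per_class_chunk.csv")
    branch_final.per_class.to_csv(outdir / "per_class_branch.csv")
    chunk_final.confusion.to_csv(outdir / "confusion_chunk.csv")
    test_table.to_csv(outdir / "labelled_test_spots.csv", index=False)
    logger.info("experiment complete in %.1fs", results["runtime_s"])
    results["_test_table"] = test_table
    results["_topologies"] = topologies
    return results
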