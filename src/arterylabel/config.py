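"""Run configuration for the labelling pipeline.

All tunable parameters of the pipeline live here so that an experiment is
fully described by one serialisable object.  Every artefact written by
:mod:`arterylabel.pipeline` carries the MD5 hash of the resolved
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class MLPConfig:
    """Hyper-parameters of the multilayer-perceptron point classifiers."""

    hidden_layer_sizes: tuple[int, ...] = (64, 32)
    activation: str = "relu"
    solver: str = "adam"
    max_iter: int = 120
    early_stopping: bool = True
    validation_fraction: float = 0.1
    n_iter_no_change: int = 10
    # inverse-frequency rebalancing by bounded oversampling of rare classes;
    # a class is duplicated at most this many times
    balance_classes: bool = True
    balance_cap: float = 4.0


@dataclass
class RunConfig:
    """Full configuration of a synthetic-cohort labelling experiment."""

    # -- imaging / sampling geometry -------------------------------------
    spacing_mm: float = 0.284          # isotropic voxel edge
    spot_interval_mm: float = 0.2801   # centerline spot sampling interval
    prune_mm: float = 2.0              # skeleton leaf-branch pruning length
    smooth_window: int = 7             # centerline moving-average (points)
    section_pitch_factor: float = 0.5  # cross-section pitch = spacing * factor
    distortion_window_mm: float = 5.0
    curvature_window_mm: float = 5.0
    circularity_mode: str = "isoperimetric"   # or "hydraulic"

    # -- cohorts ----------------------------------------------------------
    n_control: int = 30
    n_icas: int = 8                    # external-validation subjects
    cohorts: tuple[str, ...] = ("control", "icas")

    # -- modelling --------------------------------------------------------
    train_fraction: float = 0.70
    mlp: MLPConfig = field(default_factory=MLPConfig)
    vote_chunks: bool = True
    vote_branches: bool = True
    postprocess: bool = True
    postprocess_rules: tuple[str, ...] = ("connectivity", "laterality")

    # -- evaluation -------------------------------------------------------
    silhouette_subsample: int = 6000
    permutation_rounds: int = 10000

    # -- bookkeeping ------------------------------------------------------
    seed: int = 0
    save_volumes: bool = False

    # ---------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mlp" in d and isinstance(d["mlp"], dict):
            mlp = dict(d["mlp"])
            if "hidden_layer_sizes" in mlp:
                mlp["hidden_layer_sizes"] = tuple(mlp["hidden_layer_sizes"])
            d["mlp"] = MLPConfig(**mlp)
        for key in ("cohorts", "postprocess_rules"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.md5(self.to_json().encode()).hexdigest()[:12]
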