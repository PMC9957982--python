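"""Synthetic labelled cerebral-arterial-tree phantoms.

Generates per-subject Circle-of-Willis-like arterial forests over the full
62-branch nomenclature, realises them as radius-annotated centerlines, and
voxelises them into paired binary occupancy and ground-truth label volumes.

The topology template hard-codes a stylised three-root forest (right ICA,
left ICA, right vertebral carrying the vertebrobasilar system) in which the
communicating arteries are represented as terminal branches of one side, so
the structure remains a forest.  Geometry is schematic rather than
anatomically exact: each branch is a gently curving, mildly tortuous tube
whose direction fans away from its parent, which keeps sibling subtrees
spatially separated while reproducing realistic per-subject unit counts
(thousands of spots, tens of segments, up to 20 chunks).  Cohort-specific
presence probabilities, length/radius jitter and pathology events emulate
control, stroke and ICAS-like (intracranial-stenosis) subjects.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CenterlinePolyline, polyline_tangents
from .hierarchy import NomenclatureMap
from .volume import BACKGROUND, LabelVolume, VoxelVolume

logger = logging.getLogger(__name__)

COHORTS = ("control", "stroke", "icas")

#: global multiplier on template branch lengths, calibrated so control
#: subjects carry on the order of 5,000 spots at the 0.2801 mm interval
LENGTH_SCALE = 1.62


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class BranchSpec:
    """One branch of a subject's arterial tree."""

    code: str
    parent_code: str | None
    attach_fraction: float
    length_mm: float
    proximal_radius_mm: float
    distal_radius_mm: float
    tortuosity_amp_mm: float = 0.0
    tortuosity_freq: float = 1.0
    present: bool = True
    # geometric realisation parameters (template-driven)
    theta_deg: float = 0.0        # polar branching angle off the parent
    phi_deg: float = 0.0          # azimuth of the branching plane
    curve_deg: float = 0.0        # in-plane direction drift along the branch
    root_start: tuple | None = None
    root_dir: tuple | None = None
    # stenosis window (arc-length fractions) and severity, if any
    stenosis_severity: float = 0.0
    stenosis_window: tuple = (0.35, 0.65)

    def validate(self) -> None:
        if self.proximal_radius_mm <= 0 or self.distal_radius_mm <= 0:
            raise ValueError(f"{self.code}: radii must be positive")
        if self.distal_radius_mm > self.proximal_radius_mm + 1e-9:
            raise ValueError(f"{self.code}: distal radius exceeds proximal")
        if not 0.0 <= self.attach_fraction <= 1.0:
            raise ValueError(f"{self.code}: attach_fraction outside [0, 1]")
        if self.length_mm <= 0:
            raise ValueError(f"{self.code}: length must be positive")


@dataclass
class TreeSpec:
    """A subject's arterial tree: branch collection + identity metadata."""

    branches: list[BranchSpec]
    subject_id: str = "subject"
    cohort: str = "control"
    rng_seed: int = 0
    rotation_z_deg: float = 0.0

    def __post_init__(self):
        codes = [b.code for b in self.branches]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate branch codes in tree")
        self._by_code = {b.code: b for b in self.branches}
        self._check_forest()

    def _check_forest(self) -> None:
        for b in self.branches:
            seen = {b.code}
            cur = b
            while cur.parent_code is not None:
                if cur.parent_code in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(cur.parent_code)
                cur = self._by_code[cur.parent_code]
        for b in self.branches:
            if b.present and b.parent_code is not None:
                if not self._by_code[b.parent_code].present:
                    raise ValueError(
                        f"{b.code} present but parent {b.parent_code} absent"
                    )

    # ------------------------------------------------------------------
    def branch(self, code: str) -> BranchSpec:
        return self._by_code[code]

    def present_branches(self) -> list[BranchSpec]:
        return [b for b in self.branches if b.present]

    def present_codes(self) -> list[str]:
        return [b.code for b in self.branches if b.present]

    def present_chunks(self, nmap: NomenclatureMap) -> set[str]:
        return {nmap.chunk_of(b.code) for b in self.present_branches()}

    def children_of(self, code: str) -> list[BranchSpec]:
        return [b for b in self.branches if b.parent_code == code]

    def descendants(self, code: str) -> list[str]:
        out, stack = [], [code]
        while stack:
            cur = stack.pop()
            for child in self.children_of(cur):
                out.append(child.code)
                stack.append(child.code)
        return out

    def roots(self) -> list[BranchSpec]:
        return [b for b in self.branches if b.parent_code is None]

    # ------------------------------------------------------------------
    def expected_topology(self) -> dict:
        """Endpoint / junction / component counts implied by the spec.

        A junction is a distinct (parent, attachment-point) with at least
        one present child; an endpoint is a root's proximal tip or the
        distal tip of a present branch with no child attached at its end.
        """
        present = {b.code for b in self.present_branches()}
        groups: dict[tuple[str, float], int] = {}
        tip_blocked: set[str] = set()
        for b in self.branches:
            if not b.present or b.parent_code is None:
                continue
            key = (b.parent_code, round(b.attach_fraction, 6))
            groups[key] = groups.get(key, 0) + 1
            if b.attach_fraction >= 1.0 - 1e-9:
                tip_blocked.add(b.parent_code)
        # a lone child at the parent's distal tip merely continues the
        # parent (no bifurcation); interior attachments always branch
        n_junctions = sum(
            1
            for (parent, frac), n in groups.items()
            if n >= 2 or frac < 1.0 - 1e-9
        )
        roots_present = [b for b in self.roots() if b.present]
        n_endpoints = len(roots_present) + sum(
            1 for c in present if c not in tip_blocked
        )
        return {
            "n_endpoints": n_endpoints,
            "n_junctions": n_junctions,
            "n_components": len(roots_present),
        }

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "subject_id": self.subject_id,
            "cohort": self.cohort,
            "rng_seed": self.rng_seed,
            "rotation_z_deg": self.rotation_z_deg,
            "branches": [dataclasses.asdict(b) for b in self.branches],
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TreeSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        branches = []
        for bd in d["branches"]:
            for key in ("root_start", "root_dir", "stenosis_window"):
                if bd.get(key) is not None:
                    bd[key] = tuple(bd[key])
            branches.append(BranchSpec(**bd))
        return cls(
            branches=branches,
            subject_id=d["subject_id"],
            cohort=d["cohort"],
            rng_seed=d["rng_seed"],
            rotation_z_deg=d.get("rotation_z_deg", 0.0),
        )


# ---------------------------------------------------------------------------
# topology template
# ---------------------------------------------------------------------------

# fields: code, parent, attach_fraction, length, r_prox, r_dist,
#         theta, phi, curve, tort_amp, tort_freq, presence p (control)
# Lengths are design units scaled by LENGTH_SCALE at sampling time.
# Left-side counterparts are generated by mirroring (phi -> 180 - phi).
_RIGHT_TEMPLATE = [
    # --- right internal carotid system -------------------------------
    ("A1.01", None,    0.00, 20.0, 2.0, 1.75, 0,  180,  30, 1.8, 2.0, 1.00),
    ("A1.02", "A1.01", 0.55, 11.0, 0.70, 0.50, 55,  60,  15, 0.5, 1.0, 0.60),
    ("A1.03", "A1.01", 0.65, 5.0, 0.60, 0.45, 50, 270,  15, 0.5, 1.0, 0.60),
    # --- right MCA ----------------------------------------------------
    ("A3.01", "A1.01", 1.00, 16.0, 1.5, 1.25, 48,   0,  25, 1.0, 1.5, 1.00),
    ("A3.02", "A3.01", 1.00, 15.0, 1.1, 0.85, 35,  90,  25, 0.8, 1.5, 0.90),
    ("A3.03", "A3.01", 1.00, 15.0, 1.1, 0.85, 35, 270,  25, 0.8, 1.5, 0.90),
    ("A7.01", "A3.02", 1.00, 15.0, 0.85, 0.60, 40,  60,  35, 1.4, 1.5, 1.0),
    ("A7.02", "A3.02", 1.00, 16.0, 0.90, 0.60, 35, 240,  30, 1.4, 1.5, 1.0),
    ("A7.03", "A7.02", 1.00, 14.0, 0.80, 0.55, 38,  60,  35, 1.4, 1.5, 0.70),
    ("A7.04", "A7.02", 1.00, 16.0, 0.80, 0.55, 35, 240,  30, 1.4, 1.5, 0.70),
    ("A7.05", "A7.04", 1.00, 14.0, 0.75, 0.55, 38,  90,  35, 1.4, 1.5, 0.70),
    ("A7.06", "A7.04", 1.00, 14.0, 0.75, 0.55, 35, 270,  35, 1.4, 1.5, 0.80),
    ("A7.07", "A3.03", 1.00, 13.0, 0.85, 0.60, 40, 250, 25, 1.4, 1.5, 1.0),
    ("A7.08", "A3.03", 1.00, 15.0, 0.85, 0.60, 35,  90,  30, 1.4, 1.5, 1.0),
    ("A7.09", "A7.08", 0.60, 14.0, 0.70, 0.50, 45, 180,  30, 1.4, 1.5, 0.60),
    # --- right ACA ----------------------------------------------------
    ("A5.01", "A1.01", 1.00, 9.0, 1.0, 0.85, 25, 140,  15, 0.8, 1.5, 1.00),
    ("A5.02", "A5.01", 1.00, 16.0, 0.90, 0.70, 25, 340, 18, 1.5, 2.0, 1.00),
    ("A5.03", "A5.01", 0.50, 8.0, 0.70, 0.55, 40, 120,  20, 0.5, 1.0, 0.30),
    ("A0",    "A5.01", 1.00, 5.5, 0.50, 0.40, 70, 205,  10, 0.3, 1.0, 0.60),
    ("A9.01", "A5.02", 1.00, 11.0, 0.75, 0.55, 40, 310, 20, 1.4, 1.5, 1.0),
    ("A9.02", "A5.02", 1.00, 13.0, 0.80, 0.55, 25, 70, 18, 1.4, 1.5, 1.0),
    # --- vertebrobasilar system (right root; midline/left explicit) ---
    ("P1",    None,    0.00, 14.0, 1.3, 1.15, 0,  180,  15, 1.2, 1.5, 1.00),
    ("P7.02", "P1",    0.50, 11.0, 0.70, 0.50, 45, 300, 25, 1.0, 1.5, 0.65),
    ("P0",    "P1",    1.00, 16.0, 1.6, 1.35, 18, 260, 8, 1.0, 1.5, 1.00),
    ("P2",    "P1",    1.00, 17.0, 1.3, 1.15, 140, 190, 15, 1.2, 1.5, 1.00),
    ("P8.02", "P2",    0.50, 11.0, 0.70, 0.50, 45, 120, 25, 1.0, 1.5, 0.65),
    ("P7.01", "P0", 0.6, 6.5, 0.70, 0.50, 95,   0,  25, 0.8, 1.5, 0.65),
    ("P8.01", "P0", 0.72, 6.5, 0.70, 0.50, 95, 180,  25, 0.8, 1.5, 0.65),
    # --- right PCA ----------------------------------------------------
    ("P3.01", "P0",    1.00, 16.0, 1.15, 0.95, 60, 325, 30, 1.5, 2.0, 1.00),
    ("P3.02", "P3.01", 0.35, 10.0, 0.60, 0.50, 55, 130,  20, 0.5, 1.0, 0.45),
    ("P5.01", "P3.01", 0.68, 14.0, 1.00, 0.80, 40, 300, -15, 1.4, 1.5, 1.00),
    ("P5.02", "P5.01", 1.00, 12.0, 0.80, 0.55, 35, 300, 10, 1.4, 1.5, 0.65),
    ("P5.03", "P5.01", 1.00, 11.0, 0.80, 0.55, 30, 100, 15, 1.4, 1.5, 0.7),
    ("P5.04", "P5.03", 1.00, 10.0, 0.65, 0.50, 35, 160,  30, 1.4, 1.5, 0.60),
    ("P5.05", "P5.03", 1.00, 10.0, 0.70, 0.50, 35, 10,  30, 1.4, 1.5, 0.65),
]

_ROOT_GEOMETRY = {
    "A1.01": ((15.0, -2.0, -24.0), (-0.05, 0.12, 0.99)),
    "A2.01": ((-15.0, -2.0, -24.0), (0.05, 0.12, 0.99)),
    "P1": ((5.0, -18.0, -28.0), (-0.22, 0.15, 0.96)),
}


# branches that never auto-mirror (midline or explicitly defined left units)
_NO_MIRROR = {"A0", "P0", "P1", "P2", "P8.01", "P8.02"}


def build_template(nmap: NomenclatureMap | None = None) -> list[dict]:
    """Expand the right-side template into the full 62-branch table."""
    nmap = nmap or NomenclatureMap.default()
    entries = []
    index = {}
    for row in _RIGHT_TEMPLATE:
        e = dict(
            zip(
                ["code", "parent", "frac", "length", "rp", "rd", "theta",
                 "phi", "curve", "amp", "freq", "p"],
                row,
            )
        )
        entries.append(e)
        index[e["code"]] = e
    mirrored = []
    for e in entries:
        code = e["code"]
        if code in _NO_MIRROR:
            continue
        mcode = nmap.mirror_branch(code)
        if mcode is None or mcode in index:
            continue
        parent = e["parent"]
        if parent is not None:
            mparent = nmap.mirror_branch(parent)
            parent = mparent if mparent is not None else parent
        m = dict(e)
        m["code"] = mcode
        m["parent"] = parent
        # branch azimuths mirror as 180 - phi; root curl axes as -phi
        if e["parent"] is None:
            m["phi"] = (-e["phi"]) % 360.0
        else:
            m["phi"] = (180.0 - e["phi"]) % 360.0
        mirrored.append(m)
        index[mcode] = m
    full = entries + mirrored
    codes = {e["code"] for e in full}
    missing = set(nmap.branch_codes) - codes
    if missing:
        raise RuntimeError(f"template incomplete, missing {sorted(missing)}")
    return full


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _trunc_normal(rng: np.random.Generator, mean: float, rel_sd: float,
                  rel_bound: float = 0.2) -> float:
    lo, hi = mean * (1 - rel_bound), mean * (1 + rel_bound)
    for _ in range(16):
        v = rng.normal(mean, rel_sd * mean)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(v, lo, hi))


_MAJOR_TARGETS = ["A1.01", "A2.01", "A3.01", "A4.01", "P0", "A5.01", "A6.01",
                  "P3.01", "P4.01"]


def sample_tree(
    template: NomenclatureMap,
    cohort: str,
    seed: int,
    subject_id: str | None = None,
) -> TreeSpec:
    """Draw one subject's TreeSpec from the cohort distribution.

    Presence, lengths, radii and branching geometry are jittered per
    subject from truncated Gaussians around the template; ICAS subjects
    additionally receive stenosis/occlusion events on major arteries and a
    reduced distal presence rate, stroke subjects a milder version of the
    same.  Identical (cohort, seed) reproduces an identical TreeSpec.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    rows = build_template(template)
    roots = [e["code"] for e in rows if e["parent"] is None]
    for root in ("A1.01", "A2.01", "P1"):
        if root not in [e["code"] for e in rows]:
            raise ValueError(f"template missing root branch {root}")
    rng = np.random.default_rng([int(seed), COHORTS.index(cohort)])

    distal_factor = {"control": 1.0, "stroke": 0.92, "icas": 0.85}[cohort]
    scale = _trunc_normal(rng, 1.0, 0.04, 0.12)
    rotation = float(rng.uniform(-5.0, 5.0))

    present: dict[str, bool] = {}
    branches: list[BranchSpec] = []
    by_code = {e["code"]: e for e in rows}

    def presence(e) -> bool:
        p = e["p"]
        if p < 1.0:
            p *= distal_factor
        parent_ok = e["parent"] is None or present.get(e["parent"], False)
        return bool(parent_ok and rng.random() < p)

    # topological order: parents precede children in the template
    ordered = []
    placed = set()
    pending = list(rows)
    while pending:
        progressed = False
        for e in list(pending):
            if e["parent"] is None or e["parent"] in placed:
                ordered.append(e)
                placed.add(e["code"])
                pending.remove(e)
                progressed = True
        if not progressed:  # pragma: no cover
            raise RuntimeError("template parent links are inconsistent")

    for e in ordered:
        is_present = presence(e)
        present[e["code"]] = is_present
        length = _trunc_normal(rng, e["length"] * LENGTH_SCALE * scale, 0.08)
        rp = _trunc_normal(rng, e["rp"], 0.06, 0.15)
        rd = min(_trunc_normal(rng, e["rd"], 0.06, 0.15), rp)
        root_geom = _ROOT_GEOMETRY.get(e["code"])
        branches.append(
            BranchSpec(
                code=e["code"],
                parent_code=e["parent"],
                attach_fraction=e["frac"],
                length_mm=length,
                proximal_radius_mm=rp,
                distal_radius_mm=rd,
                tortuosity_amp_mm=max(0.0, rng.normal(e["amp"], 0.15 * e["amp"] + 1e-12)),
                tortuosity_freq=e["freq"],
                present=is_present,
                theta_deg=e["theta"] + rng.uniform(-5, 5),
                phi_deg=e["phi"] + rng.uniform(-8, 8),
                curve_deg=e["curve"] + rng.uniform(-10, 10),
                root_start=None if root_geom is None else tuple(
                    np.array(root_geom[0]) * scale + rng.uniform(-1.5, 1.5, 3)
                ),
                root_dir=None if root_geom is None else root_geom[1],
            )
        )

    spec = TreeSpec(
        branches=branches,
        subject_id=subject_id or f"{cohort}-{seed}",
        cohort=cohort,
        rng_seed=int(seed),
        rotation_z_deg=rotation,
    )

    # pathology events for the clinical cohorts
    if cohort in ("icas", "stroke"):
        n_events = 1 + int(rng.random() < (0.4 if cohort == "icas" else 0.0))
        if cohort == "stroke" and rng.random() < 0.5:
            n_events = 0
        for _ in range(n_events):
            candidates = [c for c in _MAJOR_TARGETS
                          if spec.branch(c).present]
            if not candidates:
                break
            target = candidates[int(rng.integers(len(candidates)))]
            if cohort == "icas" and rng.random() < 0.45:
                spec = apply_pathology(spec, "occlusion", target, 1.0,
                                       int(rng.integers(2**31)))
            else:
                lo, hi = (0.55, 0.9) if cohort == "icas" else (0.3, 0.6)
                spec = apply_pathology(spec, "stenosis", target,
                                       float(rng.uniform(lo, hi)),
                                       int(rng.integers(2**31)))
    return spec


def apply_pathology(
    spec: TreeSpec,
    kind: str,
    target_code: str,
    severity: float,
    seed: int = 0,
) -> TreeSpec:
    """Stenose (multiply a contiguous radius window by 1 - severity) or
    occlude (remove with all descendants) a present branch."""
    if kind not in ("stenosis", "occlusion"):
        raise ValueError(f"unknown pathology kind {kind!r}")
    if not 0.0 < severity <= 1.0:
        raise ValueError("severity must be in (0, 1]")
    target = spec.branch(target_code)  # KeyError for unknown codes
    if not target.present:
        raise ValueError(f"target branch {target_code} is absent")
    rng = np.random.default_rng(seed)
    branches = [dataclasses.replace(b) for b in spec.branches]
    by_code = {b.code: b for b in branches}
    if kind == "occlusion":
        by_code[target_code].present = False
        for code in spec.descendants(target_code):
            by_code[code].present = False
    else:
        centre = float(rng.uniform(0.3, 0.7))
        half = float(rng.uniform(0.08, 0.18))
        b = by_code[target_code]
        b.stenosis_severity = severity
        b.stenosis_window = (max(0.0, centre - half), min(1.0, centre + half))
    return TreeSpec(
        branches=branches,
        subject_id=spec.subject_id,
        cohort=spec.cohort,
        rng_seed=spec.rng_seed,
        rotation_z_deg=spec.rotation_z_deg,
    )


# ---------------------------------------------------------------------------
# centerline realisation
# ---------------------------------------------------------------------------


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _initial_frame(d: np.ndarray) -> np.ndarray:
    """Frame vector u0 perpendicular to d: the global +x axis projected
    off d (azimuth 0 = subject right, 90 = anterior for a vertical d)."""
    d = d / np.linalg.norm(d)
    u = np.array([1.0, 0.0, 0.0]) - d[0] * d
    n = np.linalg.norm(u)
    if n < 1e-6:  # vessel running along x: fall back to anterior reference
        u = np.array([0.0, 1.0, 0.0]) - d[1] * d
        n = np.linalg.norm(u)
    return u / n


def _transport_frames(points: np.ndarray, u0: np.ndarray) -> np.ndarray:
    """Parallel-transport u0 along a polyline (project-and-renormalise),
    giving a twist-free azimuth reference at every point."""
    tans = polyline_tangents(points)
    frames = np.empty_like(points)
    u = u0 / np.linalg.norm(u0)
    for i, t in enumerate(tans):
        u = u - (u @ t) * t
        n = np.linalg.norm(u)
        if n < 1e-9:
            u = _initial_frame(t)
        else:
            u = u / n
        frames[i] = u
    return frames


def _branch_curve(
    start: np.ndarray,
    dir0: np.ndarray,
    curve_axis: np.ndarray,
    length_mm: float,
    curve_deg: float,
    amp: float,
    freq: float,
    step: float = 0.4,
) -> np.ndarray:
    """Generate a branch centerline: a circular-arc drift of the direction
    about ``curve_axis`` plus an out-of-plane sinusoidal perturbation,
    rescaled so the realised arc length matches ``length_mm`` within 1%%."""
    n = max(int(np.ceil(length_mm / step)), 8)
    t = np.linspace(0.0, 1.0, n + 1)
    axial = length_mm

    def generate(axial_len: float) -> np.ndarray:
        angles = np.deg2rad(curve_deg) * t
        dirs = np.array([_rotation_matrix(curve_axis, a) @ dir0 for a in angles])
        steps = dirs[:-1] * (axial_len / n)
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        offset = amp * np.sin(2 * np.pi * freq * t)[:, None] * curve_axis[None, :]
        return pts + offset

    for _ in range(4):
        pts = generate(axial)
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if abs(arc - length_mm) <= 0.002 * length_mm:
            break
        axial *= length_mm / arc
    return pts


def realize_centerlines(spec: TreeSpec) -> list[CenterlinePolyline]:
    """Realise every present branch as a radius-annotated polyline.

    Children attach to the parent polyline at their arc-length fraction;
    the branch direction is the parent tangent rotated by the branching
    angle, at an azimuth measured in the parent's parallel-transported
    frame (stable along curved vessels, mirror-consistent across sides);
    per-point radius tapers linearly from proximal to distal, with any
    stenosis window applied multiplicatively.
    """
    rot = _rotation_matrix(np.array([0.0, 0.0, 1.0]),
                           np.deg2rad(spec.rotation_z_deg))
    realised: dict[str, CenterlinePolyline] = {}
    frames: dict[str, np.ndarray] = {}
    polylines: list[CenterlinePolyline] = []
    pending = list(spec.present_branches())
    while pending:
        progressed = False
        for b in list(pending):
            phi = np.deg2rad(b.phi_deg)
            if b.parent_code is None:
                start = rot @ np.asarray(b.root_start, dtype=float)
                dir0 = rot @ np.asarray(b.root_dir, dtype=float)
                dir0 = dir0 / np.linalg.norm(dir0)
                u0 = _initial_frame(dir0)
                v0 = np.cross(dir0, u0)
                # for roots phi selects the curl axis in the root frame
                curve_axis = np.cos(phi) * u0 + np.sin(phi) * v0
            elif b.parent_code in realised:
                parent = realised[b.parent_code]
                arc = parent.arc_params
                s = b.attach_fraction * parent.arc_length
                i = int(np.searchsorted(arc, s))
                i = min(max(i, 0), len(arc) - 1)
                start = parent.points[i]
                ptan = parent.tangents[i]
                u = frames[b.parent_code][i]
                v = np.cross(ptan, u)
                theta = np.deg2rad(b.theta_deg)
                dir0 = (
                    np.cos(theta) * ptan
                    + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
                )
                dir0 = dir0 / np.linalg.norm(dir0)
                axis = np.cross(ptan, dir0)
                nrm = np.linalg.norm(axis)
                curve_axis = axis / nrm if nrm > 1e-9 else u
            elif b.parent_code in {x.code for x in pending}:
                continue
            else:
                raise ValueError(
                    f"branch {b.code} attaches to absent parent {b.parent_code}"
                )
            pts = _branch_curve(
                start, dir0, curve_axis, b.length_mm, b.curve_deg,
                b.tortuosity_amp_mm, b.tortuosity_freq,
            )
            arc = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
            )
            frac = arc / arc[-1]
            radius = b.proximal_radius_mm + frac * (
                b.distal_radius_mm - b.proximal_radius_mm
            )
            if b.stenosis_severity > 0:
                w0, w1 = b.stenosis_window
                inside = (frac >= w0) & (frac <= w1)
                radius = radius.copy()
                radius[inside] *= 1.0 - b.stenosis_severity
            poly = CenterlinePolyline(
                points=pts,
                inscribed_radius=radius,
                tangents=polyline_tangents(pts),
                start_kind="junction" if b.parent_code else "root",
                end_kind="endpoint",
                branch_code=b.code,
            )
            realised[b.code] = poly
            frames[b.code] = _transport_frames(pts, dir0_frame_seed(dir0))
            polylines.append(poly)
            pending.remove(b)
            progressed = True
        if not progressed:  # pragma: no cover
            raise RuntimeError("unresolvable parent links during realisation")
    return polylines


def dir0_frame_seed(dir0: np.ndarray) -> np.ndarray:
    return _initial_frame(dir0)


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------


def voxelize(
    centerlines: list[CenterlinePolyline],
    spacing_mm: float | tuple = 0.284,
    margin_mm: float = 1.5,
) -> tuple[VoxelVolume, LabelVolume]:
    """Rasterise tube centerlines into paired occupancy and label volumes.

    A voxel is foreground iff its centre lies within the local tube radius
    of some centerline point; its label is the branch code of the nearest
    such point.  Branches thinner than half the voxel size are reported
    (they may vanish from the raster) but processing continues.
    """
    if not centerlines:
        raise ValueError("empty centerline set")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")

    codes = sorted({p.branch_code or f"segment-{i}" for i, p in enumerate(centerlines)})
    code_index = {c: i for i, c in enumerate(codes)}

    for poly in centerlines:
        if poly.inscribed_radius.max() < spacing.max() / 2:
            warnings.warn(
                f"branch {poly.branch_code}: radius below half the voxel size; "
                "it may vanish from the raster",
                stacklevel=2,
            )

    all_pts = np.vstack([p.points for p in centerlines])
    rmax = max(float(p.inscribed_radius.max()) for p in centerlines)
    lo = all_pts.min(axis=0) - rmax - margin_mm
    hi = all_pts.max(axis=0) + rmax + margin_mm
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    dist2 = np.full(shape, np.inf, dtype=np.float32)
    labels = np.full(shape, BACKGROUND, dtype=np.int16)

    step = float(spacing.min()) / 2.0
    for poly in centerlines:
        ci = code_index[poly.branch_code or ""] if poly.branch_code else 0
        L = poly.arc_length
        n = max(int(np.ceil(L / step)), 1)
        s = np.linspace(0.0, L, n + 1)
        pts, rad, _ = poly.interpolate(s)
        piece = 24
        for a in range(0, len(pts), piece):
            p = pts[a : a + piece]
            r = rad[a : a + piece]
            rmaxp = r.max()
            plo = np.maximum(
                np.floor((p.min(axis=0) - rmaxp - origin) / spacing).astype(int), 0
            )
            phi_ = np.minimum(
                np.ceil((p.max(axis=0) + rmaxp - origin) / spacing).astype(int) + 1,
                shape,
            )
            if np.any(plo >= phi_):
                continue
            sl = tuple(slice(lo_, hi_) for lo_, hi_ in zip(plo, phi_))
            gx = origin[0] + np.arange(plo[0], phi_[0]) * spacing[0]
            gy = origin[1] + np.arange(plo[1], phi_[1]) * spacing[1]
            gz = origin[2] + np.arange(plo[2], phi_[2]) * spacing[2]
            G = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1)
            diff = G[..., None, :] - p[None, None, None, :, :]
            d2 = np.einsum("...k,...k->...", diff, diff).astype(np.float32)
            covered = d2 <= (r * r)[None, None, None, :]
            d2 = np.where(covered, d2, np.inf)
            j = np.argmin(d2, axis=-1)
            dmin = np.take_along_axis(d2, j[..., None], axis=-1)[..., 0]
            improve = dmin < dist2[sl]
            if improve.any():
                dist2[sl][improve] = dmin[improve]
                labels[sl][improve] = ci
    occupancy = np.isfinite(dist2)
    vol = VoxelVolume(occupancy, spacing, origin)
    lab = LabelVolume(labels, codes, spacing, origin)
    return vol, lab


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------


def simulate_subject(
    template: NomenclatureMap,
    cohort: str,
    seed: int,
    spacing_mm: float = 0.284,
    subject_id: str | None = None,
):
    """Sample, realise and voxelise one subject; returns
    ``(spec, centerlines, volume, labels)``."""
    spec = sample_tree(template, cohort, seed, subject_id=subject_id)
    centerlines = realize_centerlines(spec)
    vol, lab = voxelize(centerlines, spacing_mm)
    return spec, centerlines, vol, lab
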