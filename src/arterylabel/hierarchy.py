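"""Hierarchical vascular unit system: spots → segments → branches → chunks.

The cerebrovasculature is reframed into four levels: *spots* (centerline
points sampled at a fixed interval), *segments* (contiguous spot runs
between bifurcations), 62 *branches* (conventionally named arteries) and 20
*chunks* (functional-anatomical groupings such as "right anterior pial
MCA").  Branch identifiers follow the grammar ``<chunk>.<2-digit>`` —
``"A7.09"`` is the ninth branch of chunk ``A7``; chunks owning exactly one
branch (ACOA, basilar, the two vertebrals) use their bare chunk code.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .volume import BACKGROUND, LabelVolume

if TYPE_CHECKING:  # pragma: no cover
    from .features import Spot
    from .geometry import CenterlinePolyline

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^([AP]\d+)(?:\.(\d{2}))?$")


def parse_branch_code(code: str) -> tuple[str, int]:
    """Split a branch identifier into ``(chunk_code, segment_index)``.

    Bare chunk codes (single-branch chunks) parse to index 0.
    """
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"malformed branch code: {code!r}")
    chunk, idx = m.group(1), m.group(2)
    return chunk, (0 if idx is None else int(idx))


def format_branch_code(chunk_code: str, segment_index: int) -> str:
    if segment_index == 0:
        return chunk_code
    return f"{chunk_code}.{segment_index:02d}"


@dataclass
class NomenclatureMap:
    """The 62-branch → 20-chunk hierarchy with identifier grammar."""

    chunk_codes: list[str]
    branch_codes: list[str]
    branch_to_chunk: dict[str, str]
    chunk_names: dict[str, str] = field(default_factory=dict)
    branch_names: dict[str, str] = field(default_factory=dict)
    chunk_sides: dict[str, str] = field(default_factory=dict)
    mirror_pairs: list[tuple[str, str]] = field(default_factory=list)
    version: str = "unversioned"

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "NomenclatureMap":
        chunks = [c["code"] for c in d["chunks"]]
        branches = [b["code"] for b in d["branches"]]
        mapping = {}
        for b in branches:
            chunk, _ = parse_branch_code(b)
            if chunk not in chunks:
                raise ValueError(f"branch {b} references unknown chunk {chunk}")
            mapping[b] = chunk
        return cls(
            chunk_codes=chunks,
            branch_codes=branches,
            branch_to_chunk=mapping,
            chunk_names={c["code"]: c.get("name", "") for c in d["chunks"]},
            branch_names={b["code"]: b.get("name", "") for b in d["branches"]},
            chunk_sides={c["code"]: c.get("side", "midline") for c in d["chunks"]},
            mirror_pairs=[tuple(p) for p in d.get("mirror_pairs", [])],
            version=d.get("version", "unversioned"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NomenclatureMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "NomenclatureMap":
        text = resources.files("arterylabel.data").joinpath("nomenclature.json").read_text()
        return cls.from_dict(json.loads(text))

    def __post_init__(self):
        if len(set(self.chunk_codes)) != len(self.chunk_codes):
            raise ValueError("duplicate chunk codes")
        if len(set(self.branch_codes)) != len(self.branch_codes):
            raise ValueError("duplicate branch codes")
        owned = set(self.branch_to_chunk.values())
        if not owned <= set(self.chunk_codes):
            raise ValueError("branch mapped onto unknown chunk")

    # ------------------------------------------------------------------
    def chunk_of(self, branch_code: str) -> str:
        try:
            return self.branch_to_chunk[branch_code]
        except KeyError:
            raise KeyError(f"unknown branch code: {branch_code!r}") from None

    def branches_of(self, chunk_code: str) -> list[str]:
        return [b for b in self.branch_codes if self.branch_to_chunk[b] == chunk_code]

    def mirror_chunk(self, chunk_code: str) -> str | None:
        """Contralateral chunk for sided chunks; None for midline chunks."""
        for a, b in self.mirror_pairs:
            if chunk_code == a:
                return b
            if chunk_code == b:
                return a
        return None

    def mirror_branch(self, branch_code: str) -> str | None:
        chunk, idx = parse_branch_code(branch_code)
        other = self.mirror_chunk(chunk)
        if other is None:
            return None
        candidate = format_branch_code(other, idx)
        return candidate if candidate in self.branch_to_chunk else None

    @property
    def n_chunks(self) -> int:
        return len(self.chunk_codes)

    @property
    def n_branches(self) -> int:
        return len(self.branch_codes)


def chunk_of(branch_code: str, nmap: NomenclatureMap) -> str:
    """Owning chunk of a branch code (total over the map's 62 codes)."""
    return nmap.chunk_of(branch_code)


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


@dataclass
class SegmentRecord:
    """A contiguous run of spots on one junction-to-junction centerline."""

    segment_id: int
    spot_ids: list[int]
    start_kind: str = "junction"
    end_kind: str = "junction"


def segment_spots(
    centerlines: Sequence["CenterlinePolyline"], spots: Sequence["Spot"]
) -> list[SegmentRecord]:
    """Group spots into segments, one per junction-to-junction polyline.

    Spots carry the index of their source polyline (``segment_id``); the
    segments partition the spot set exactly.
    """
    by_segment: dict[int, list] = {}
    for s in spots:
        by_segment.setdefault(s.segment_id, []).append(s)
    records = []
    for seg_id in sorted(by_segment):
        members = sorted(by_segment[seg_id], key=lambda s: s.arc_pos)
        poly = centerlines[seg_id] if seg_id < len(centerlines) else None
        records.append(
            SegmentRecord(
                segment_id=seg_id,
                spot_ids=[s.spot_id for s in members],
                start_kind=getattr(poly, "start_kind", "junction") or "junction",
                end_kind=getattr(poly, "end_kind", "junction") or "junction",
            )
        )
    return records


# ---------------------------------------------------------------------------
# ground-truth labelling
# ---------------------------------------------------------------------------

_NEIGHBOURHOOD = None


def _neighbourhood_offsets(max_dist_voxels: int) -> np.ndarray:
    r = int(np.ceil(max_dist_voxels))
    off = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    d = np.linalg.norm(off, axis=1)
    keep = d <= max_dist_voxels + 1e-9
    off, d = off[keep], d[keep]
    order = np.lexsort((off[:, 2], off[:, 1], off[:, 0], d))
    return off[order]


def label_spots_from_volume(
    spots: Iterable["Spot"],
    labels: LabelVolume,
    nmap: NomenclatureMap,
    max_dist_voxels: float = 2.0,
) -> list["Spot"]:
    """Assign each spot its ground-truth branch (and chunk) from a label map.

    The spot adopts the label of the nearest labelled voxel within
    ``max_dist_voxels``; distance ties break lexicographically on the code.
    Spots with no labelled voxel in range are dropped (and counted in the
    log).
    """
    offsets = _neighbourhood_offsets(max_dist_voxels)
    lab = labels.labels
    shape = np.array(lab.shape)
    retained, dropped = [], 0
    for spot in spots:
        idx = np.rint(labels.world_to_voxel(spot.position)).astype(int)
        best = None  # (dist, code)
        prev_d = -1.0
        for off in offsets:
            p = idx + off
            if np.any(p < 0) or np.any(p >= shape):
                continue
            d = float(np.linalg.norm(off))
            if best is not None and d > best[0] + 1e-9:
                break
            v = lab[tuple(p)]
            if v == BACKGROUND:
                continue
            code = labels.codes[v]
            cand = (d, code)
            if best is None or cand[0] < best[0] - 1e-9 or (
                abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]
            ):
                best = cand
            prev_d = d
        if best is None:
            dropped += 1
            continue
        spot.true_branch = best[1]
        spot.true_chunk = nmap.chunk_of(best[1])
        retained.append(spot)
    if dropped:
        logger.info("label_spots_from_volume: dropped %d unresolvable spots", dropped)
    return retained
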