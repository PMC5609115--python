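"""Compartmental trees: segments, geometry, SWC I/O and reduced archetypes.

A morphology is an ordered collection of cylindrical segments connected in a
tree.  Each segment knows its parent, its dimensions and a coarse region tag
(soma, axon initial segment, node of Ranvier, ...) that mechanism presets key
their densities on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RegionTag",
    "Segment",
    "Morphology",
    "InvalidGeometryError",
    "SWCFormatError",
    "segment_geometry",
    "load_swc",
    "write_swc",
    "build_archetype",
    "ARCHETYPE_KINDS",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive segment dimensions or malformed trees."""


class SWCFormatError(ValueError):
    """Raised on malformed SWC files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RegionTag(str, Enum):
    SOMA = "soma"
    AIS = "AIS"
    AXON_NODE = "axon_node"
    AXON_MYELIN = "axon_myelin"
    DENDRITE_PROXIMAL = "dendrite_proximal"
    DENDRITE_DISTAL = "dendrite_distal"
    TUFT = "tuft"


@dataclass(frozen=True)
class Segment:
    """A cylindrical compartment.

    Lengths and diameters are in um.  ``parent_id is None`` marks the root.
    """

    id: int
    parent_id: int | None
    length: float
    diameter: float
    region: RegionTag
    name: str = ""

    def __post_init__(self):
        if not (self.length > 0 and self.diameter > 0):
            raise InvalidGeometryError(
                f"segment {self.id}: length and diameter must be positive "
                f"(got L={self.length}, d={self.diameter})"
            )


def segment_geometry(seg: Segment) -> tuple[float, float, float]:
    """Return (lateral_area um^2, volume um^3, cross_section um^2)."""
    lateral = math.pi * seg.diameter * seg.length
    cross = math.pi * seg.diameter**2 / 4.0
    return lateral, cross * seg.length, cross


class Morphology:
    """An ordered, validated tree of :class:`Segment`.

    ``spatial_resolution`` records how many subdivisions per original section
    were applied (see :meth:`subdivide`).
    """

    def __init__(self, segments: Sequence[Segment], spatial_resolution: int = 1):
        segs = list(segments)
        if not segs:
            raise InvalidGeometryError("morphology must contain at least one segment")
        ids = [s.id for s in segs]
        if len(set(ids)) != len(ids):
            raise InvalidGeometryError("segment ids are not unique")
        byid = {s.id: s for s in segs}
        roots = [s for s in segs if s.parent_id is None]
        if len(roots) != 1:
            raise InvalidGeometryError(f"expected exactly one root, found {len(roots)}")
        for s in segs:
            if s.parent_id is not None and s.parent_id not in byid:
                raise InvalidGeometryError(
                    f"segment {s.id} references missing parent {s.parent_id}"
                )
        # cycle / connectivity check by walking to the root from every node
        for s in segs:
            seen = set()
            cur = s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise InvalidGeometryError(f"cycle detected at segment {s.id}")
                seen.add(cur.id)
                cur = byid[cur.parent_id]
        self.segments: list[Segment] = segs
        self.spatial_resolution = spatial_resolution
        self._byid = byid

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, seg_id: int) -> Segment:
        return self._byid[seg_id]

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent_id is None)

    def children(self, seg_id: int) -> list[Segment]:
        return [s for s in self.segments if s.parent_id == seg_id]

    def by_region(self, region: RegionTag) -> list[Segment]:
        return [s for s in self.segments if s.region == region]

    def total_area(self) -> float:
        return sum(segment_geometry(s)[0] for s in self.segments)

    def total_volume(self) -> float:
        return sum(segment_geometry(s)[1] for s in self.segments)

    def path_distance(self, seg_id: int) -> float:
        """Path distance (um) from the root center to the center of *seg_id*."""
        seg = self._byid[seg_id]
        dist = seg.length / 2.0
        while seg.parent_id is not None:
            seg = self._byid[seg.parent_id]
            dist += seg.length
        return dist - self.root.length / 2.0

    def nearest_segment(
        self, distance: float, regions: Iterable[RegionTag] | None = None
    ) -> Segment:
        """Segment (optionally restricted by region) nearest a path distance."""
        pool = (
            self.segments
            if regions is None
            else [s for s in self.segments if s.region in set(regions)]
        )
        if not pool:
            raise KeyError("no segment matches the requested regions")
        return min(pool, key=lambda s: abs(self.path_distance(s.id) - distance))

    # -- transforms --------------------------------------------------------
    def subdivide(self, n: int) -> "Morphology":
        """Split every segment into *n* serial pieces of equal length.

        Total membrane area and volume are preserved exactly; the tree
        topology is preserved with children re-attached to the distal piece.
        """
        if n < 1:
            raise ValueError("subdivision factor must be >= 1")
        if n == 1:
            return self
        new_segs: list[Segment] = []
        next_id = 0
        distal_of: dict[int, int] = {}  # original id -> id of its distal piece
        for s in self.segments:  # parents precede children (validated tree)
            parent = distal_of[s.parent_id] if s.parent_id is not None else None
            for k in range(n):
                new_segs.append(
                    Segment(
                        id=next_id,
                        parent_id=parent,
                        length=s.length / n,
                        diameter=s.diameter,
                        region=s.region,
                        name=f"{s.name}.{k}" if s.name else "",
                    )
                )
                parent = next_id
                next_id += 1
            distal_of[s.id] = parent  # type: ignore[assignment]
        return Morphology(new_segs, spatial_resolution=self.spatial_resolution * n)

    def remove_regions(self, regions: Iterable[RegionTag]) -> "Morphology":
        """Drop whole subtrees rooted in the given regions (e.g. dendrites)."""
        drop = set(regions)
        keep: dict[int, Segment] = {}
        for s in self.segments:
            if s.region in drop:
                continue
            if s.parent_id is not None and s.parent_id not in keep:
                continue  # parent was dropped -> drop subtree
            keep[s.id] = s
        return Morphology(list(keep.values()), self.spatial_resolution)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_TYPE_TO_REGION = {
    1: RegionTag.SOMA,
    2: RegionTag.AXON_NODE,
    3: RegionTag.DENDRITE_PROXIMAL,
    4: RegionTag.DENDRITE_DISTAL,
    5: RegionTag.TUFT,
}
_REGION_TO_SWC_TYPE = {
    RegionTag.SOMA: 1,
    RegionTag.AIS: 2,
    RegionTag.AXON_NODE: 2,
    RegionTag.AXON_MYELIN: 2,
    RegionTag.DENDRITE_PROXIMAL: 3,
    RegionTag.DENDRITE_DISTAL: 4,
    RegionTag.TUFT: 5,
}


def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Segment lengths are inter-sample Euclidean distances and diameters are
    twice the distal sample radius.  All type-1 (soma) samples are collapsed
    into a single equivalent cylinder with L = d = 2 * mean radius, whose
    lateral area equals the area of the sphere of that radius.
    """
    samples: dict[int, tuple[int, float, float, float, float, int, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCFormatError(
                    f"expected 7 columns, got {len(parts)}", lineno
                )
            try:
                sid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCFormatError(f"unparsable field ({exc})", lineno) from None
            if sid in samples:
                raise SWCFormatError(f"duplicate sample id {sid}", lineno)
            if r <= 0:
                raise SWCFormatError(f"non-positive radius for sample {sid}", lineno)
            samples[sid] = (stype, x, y, z, r, parent, lineno)
            order.append(sid)
    if not samples:
        raise SWCFormatError("empty SWC file (no samples)")

    # validate parent references and check for cycles
    for sid in order:
        stype, x, y, z, r, parent, lineno = samples[sid]
        if parent != -1 and parent not in samples:
            raise SWCFormatError(
                f"sample {sid} references absent parent {parent}", lineno
            )
        seen = {sid}
        cur = parent
        while cur != -1:
            if cur in seen:
                raise SWCFormatError(f"cyclic parent chain at sample {sid}", lineno)
            seen.add(cur)
            cur = samples[cur][5]

    soma_ids = [sid for sid in order if samples[sid][0] == 1]
    segs: list[Segment] = []
    sample_to_seg: dict[int, int] = {}
    next_id = 0

    if soma_ids:
        r_mean = float(np.mean([samples[sid][4] for sid in soma_ids]))
        segs.append(
            Segment(next_id, None, 2 * r_mean, 2 * r_mean, RegionTag.SOMA, "soma")
        )
        for sid in soma_ids:
            sample_to_seg[sid] = next_id
        next_id += 1

    for sid in order:
        stype, x, y, z, r, parent, lineno = samples[sid]
        if stype == 1:
            continue
        if parent == -1:
            if not soma_ids and next_id == 0:
                # rootless non-soma file: first sample becomes a stub root
                segs.append(
                    Segment(
                        next_id,
                        None,
                        2 * r,
                        2 * r,
                        _SWC_TYPE_TO_REGION.get(stype, RegionTag.DENDRITE_PROXIMAL),
                    )
                )
                sample_to_seg[sid] = next_id
                next_id += 1
                continue
            raise SWCFormatError(f"multiple root samples (sample {sid})", lineno)
        px, py, pz = samples[parent][1:4]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            raise SWCFormatError(
                f"zero distance between sample {sid} and its parent", lineno
            )
        if parent not in sample_to_seg:
            raise SWCFormatError(
                f"sample {sid} attaches to unprocessed parent {parent}", lineno
            )
        segs.append(
            Segment(
                next_id,
                sample_to_seg[parent],
                length,
                2 * r,
                _SWC_TYPE_TO_REGION.get(stype, RegionTag.DENDRITE_PROXIMAL),
            )
        )
        sample_to_seg[sid] = next_id
        next_id += 1
    return Morphology(segs)


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as SWC, embedding the tree in 3-D with exact lengths.

    Each segment becomes one sample placed at its parent's position plus its
    length along a per-branch direction, so a re-read reproduces lengths and
    diameters exactly (the soma cylinder round-trips through its equivalent
    sphere radius).
    """
    pos: dict[int, tuple[float, float, float]] = {}
    lines = ["# generated by nadyn"]
    swc_id_of: dict[int, int] = {}
    golden = math.pi * (3 - math.sqrt(5))
    for k, seg in enumerate(morph.segments, start=1):
        swc_id_of[seg.id] = k
        if seg.parent_id is None:
            pos[seg.id] = (0.0, 0.0, 0.0)
            radius = seg.diameter / 2.0
            lines.append(f"{k} 1 0.0 0.0 0.0 {radius!r} -1")
            continue
        px, py, pz = pos[seg.parent_id]
        theta = golden * k
        dx = seg.length * math.cos(theta)
        dy = seg.length * math.sin(theta)
        x, y, z = px + dx, py + dy, pz
        pos[seg.id] = (x, y, z)
        stype = _REGION_TO_SWC_TYPE[seg.region]
        lines.append(
            f"{k} {stype} {x!r} {y!r} {z!r} "
            f"{seg.diameter / 2.0!r} {swc_id_of[seg.parent_id]}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reduced archetypes
# ---------------------------------------------------------------------------

ARCHETYPE_KINDS = ("mitral_like", "pyramidal_like", "purkinje_like")


@dataclass
class _Section:
    """Builder shorthand: a serial run of identical segments."""

    name: str
    region: RegionTag
    length: float
    diameter: float
    n: int = 1
    parent: str | None = None  # name of parent section


# Free geometric parameters of the reduced cells.  The lumped geometries of
# the source models are not published as plain numbers; these presets are
# hand-chosen to give each archetype the qualitative structure it needs
# (thin AIS, large somatic volume, thin distal dendrites, nodes of Ranvier
# for the purkinje-like cell, a thick proximal dendrite, ...).
_ARCHETYPES: dict[str, list[_Section]] = {
    "mitral_like": [
        _Section("soma", RegionTag.SOMA, 20.0, 20.0),
        _Section("ais", RegionTag.AIS, 30.0, 1.5, n=3, parent="soma"),
        _Section("axon", RegionTag.AXON_NODE, 300.0, 1.0, n=3, parent="ais"),
        _Section("prox", RegionTag.DENDRITE_PROXIMAL, 100.0, 3.5, n=5, parent="soma"),
        _Section("distal", RegionTag.DENDRITE_DISTAL, 300.0, 1.2, n=15, parent="prox"),
        _Section("tuft", RegionTag.TUFT, 100.0, 1.0, n=5, parent="distal"),
    ],
    "pyramidal_like": [
        _Section("soma", RegionTag.SOMA, 25.0, 20.0),
        _Section("ais", RegionTag.AIS, 40.0, 1.2, n=2, parent="soma"),
        _Section("axon", RegionTag.AXON_NODE, 300.0, 1.0, n=3, parent="ais"),
        _Section("basal", RegionTag.DENDRITE_PROXIMAL, 150.0, 2.0, n=8, parent="soma"),
        _Section("trunk", RegionTag.DENDRITE_PROXIMAL, 200.0, 4.0, n=5, parent="soma"),
        _Section("apical", RegionTag.DENDRITE_DISTAL, 400.0, 1.2, n=20, parent="trunk"),
        _Section("tuft", RegionTag.TUFT, 200.0, 0.9, n=10, parent="apical"),
    ],
    "purkinje_like": [
        _Section("soma", RegionTag.SOMA, 22.0, 22.0),
        _Section("ais", RegionTag.AIS, 20.0, 1.2, n=2, parent="soma"),
        _Section("myelin1", RegionTag.AXON_MYELIN, 100.0, 1.0, parent="ais"),
        _Section("node1", RegionTag.AXON_NODE, 2.0, 1.0, parent="myelin1"),
        _Section("myelin2", RegionTag.AXON_MYELIN, 100.0, 1.0, parent="node1"),
        _Section("node2", RegionTag.AXON_NODE, 2.0, 1.0, parent="myelin2"),
        _Section("myelin3", RegionTag.AXON_MYELIN, 100.0, 1.0, parent="node2"),
        _Section("node3", RegionTag.AXON_NODE, 2.0, 1.0, parent="myelin3"),
        _Section("main", RegionTag.DENDRITE_PROXIMAL, 60.0, 4.0, n=3, parent="soma"),
        # thick smooth branches (> 2.2 um: climbing-fiber targets)
        _Section("thick", RegionTag.DENDRITE_DISTAL, 120.0, 3.0, n=6, parent="main"),
        # thin spiny branchlets (parallel-fiber targets)
        _Section("spiny", RegionTag.DENDRITE_DISTAL, 150.0, 1.2, n=8, parent="thick"),
    ],
}


def build_archetype(kind: str, params: dict | None = None) -> Morphology:
    """Build a reduced soma + AIS + axon + dendrite morphology.

    *params* may override section dimensions with entries of the form
    ``{"<section>_length": float, "<section>_diameter": float,
    "<section>_n": int}`` and may request finer spatial resolution with
    ``{"subdivide": int}``.
    """
    if kind not in _ARCHETYPES:
        raise ValueError(
            f"unknown archetype kind {kind!r}; expected one of {ARCHETYPE_KINDS}"
        )
    params = dict(params or {})
    subdivide = int(params.pop("subdivide", 1))
    sections = []
    for sec in _ARCHETYPES[kind]:
        sections.append(
            replace(
                sec,
                length=float(params.pop(f"{sec.name}_length", sec.length)),
                diameter=float(params.pop(f"{sec.name}_diameter", sec.diameter)),
                n=int(params.pop(f"{sec.name}_n", sec.n)),
            )
        )
    if params:
        raise ValueError(f"unknown archetype parameters: {sorted(params)}")

    segs: list[Segment] = []
    next_id = 0
    tip_of: dict[str, int] = {}
    for sec in sections:
        parent = tip_of[sec.parent] if sec.parent is not None else None
        for k in range(sec.n):
            segs.append(
                Segment(
                    id=next_id,
                    parent_id=parent,
                    length=sec.length / sec.n,
                    diameter=sec.diameter,
                    region=sec.region,
                    name=f"{sec.name}{k}",
                )
            )
            parent = next_id
            next_id += 1
        tip_of[sec.name] = parent  # type: ignore[assignment]
    morph = Morphology(segs)
    if subdivide > 1:
        morph = morph.subdivide(subdivide)
    return morph
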