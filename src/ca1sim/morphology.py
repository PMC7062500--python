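"""Neuronal morphologies: SWC I/O, section trees, regions, path distances.

A morphology is a rooted tree of cable *sections*.  Each section carries an
ordered list of 3D sample points with radii; the first point of a non-root
section coincides with its attachment point on the parent, so geometry is
contiguous across branch points.  A multi-point SWC soma is collapsed to a
single cylinder of equivalent membrane area (length = diameter), which is the
root section of the tree.

Apical sections are partitioned into three regions:

* ``apical_primary`` -- the trunk path from the soma,
* ``apical_oblique`` -- side branches leaving the trunk,
* ``apical_tuft``    -- everything distal to the trunk's terminal bifurcation.

The trunk is found by walking from the apical root, at every branch point
following the child with the greatest total subtree length; the walk stops at
the first branch point where the two largest child subtrees each hold more
than 30% of the remaining apical length (the "terminal bifurcation").  On an
unbranched apical cable the whole cable is primary and tuft/oblique are empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ClassificationError, MorphologyStructureError, SWCFormatError

__all__ = [
    "SWCPoint",
    "Section",
    "Morphology",
    "RegionMap",
    "read_swc",
    "write_swc",
    "classify_apical_regions",
    "path_distance",
    "APICAL_REGIONS",
    "ALL_REGIONS",
]

# SWC structure codes -> labels
_SWC_STRUCTURE = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
_STRUCTURE_SWC = {v: k for k, v in _SWC_STRUCTURE.items()}

APICAL_REGIONS = ("apical_primary", "apical_oblique", "apical_tuft")
ALL_REGIONS = ("soma", "axon", "basal") + APICAL_REGIONS


@dataclass(frozen=True)
class SWCPoint:
    """One row of an SWC file (1-based ids, parent −1 for the root)."""

    id: int
    structure: str
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class Section:
    """An unbranched cable between branch points / structure changes.

    ``points`` is an (N, 4) float array of x, y, z, radius in μm whose first
    row coincides with the attachment point on the parent section.
    """

    name: str
    structure: str
    points: np.ndarray
    parent: int = -1          # index into Morphology.sections, -1 for root
    parent_pos: float = 1.0   # attachment position on the parent, in [0, 1]

    @property
    def length(self) -> float:
        d = np.diff(self.points[:, :3], axis=0)
        return float(np.sqrt((d ** 2).sum(axis=1)).sum())

    @property
    def mean_diameter(self) -> float:
        return float(2.0 * self.points[:, 3].mean())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length (μm) at each sample point, starting at 0."""
        d = np.diff(self.points[:, :3], axis=0)
        seg = np.sqrt((d ** 2).sum(axis=1))
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Morphology:
    """A validated tree of sections; section 0 is the soma root."""

    sections: List[Section]
    region_map: Optional["RegionMap"] = None

    def __post_init__(self):
        self._validate()

    def _validate(self):
        if not self.sections:
            raise MorphologyStructureError("morphology has no sections")
        if self.sections[0].parent != -1:
            raise MorphologyStructureError("section 0 must be the root")
        for i, sec in enumerate(self.sections):
            if i > 0 and not (0 <= sec.parent < i):
                raise MorphologyStructureError(
                    f"section {sec.name!r}: parent index {sec.parent} does not "
                    f"precede it (Hines order violated)"
                )
            if sec.length <= 0:
                raise MorphologyStructureError(f"section {sec.name!r} has zero length")
            if np.any(sec.points[:, 3] <= 0):
                raise MorphologyStructureError(f"section {sec.name!r} has non-positive radius")

    # -- tree queries -----------------------------------------------------

    def children(self, index: int) -> List[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == index]

    def section_index(self, name: str) -> int:
        for i, s in enumerate(self.sections):
            if s.name == name:
                return i
        raise KeyError(name)

    def section_start_distances(self) -> np.ndarray:
        """Path distance (μm) from the soma to the start of each section.

        The soma's own extent does not count toward path distance: sections
        attached to the soma start at distance 0.
        """
        d0 = np.zeros(len(self.sections))
        for i, sec in enumerate(self.sections):
            if sec.parent < 0:
                d0[i] = 0.0
                continue
            parent = self.sections[sec.parent]
            if parent.structure == "soma":
                d0[i] = d0[sec.parent]
            else:
                d0[i] = d0[sec.parent] + parent.length * sec.parent_pos
        return d0

    def total_length(self, structure: Optional[str] = None) -> float:
        return sum(s.length for s in self.sections
                   if structure is None or s.structure == structure)

    def subtree_indices(self, index: int) -> List[int]:
        out = [index]
        for c in self.children(index):
            out.extend(self.subtree_indices(c))
        return out

    def subtree_length(self, index: int) -> float:
        return sum(self.sections[i].length for i in self.subtree_indices(index))

    # -- summaries --------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Tidy summary: one row per section (section, region, length, mean diameter)."""
        regions = (self.region_map.assignment if self.region_map
                   else classify_apical_regions(self).assignment)
        rows = [
            dict(section=s.name, region=regions[s.name],
                 length_um=s.length, mean_diameter_um=s.mean_diameter)
            for s in self.sections
        ]
        return pd.DataFrame(rows)


@dataclass
class RegionMap:
    """Section name -> region label; apical sections get exactly one of the
    three apical classes."""

    assignment: Dict[str, str] = field(default_factory=dict)

    def sections_in(self, *regions: str) -> List[str]:
        return [name for name, r in self.assignment.items() if r in regions]

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.assignment.values():
            out[r] = out.get(r, 0) + 1
        return out


# ---------------------------------------------------------------------------
# SWC reading / writing
# ---------------------------------------------------------------------------

def _parse_swc_rows(text: str) -> List[SWCPoint]:
    points: List[SWCPoint] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            pid, stype = int(cols[0]), int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCFormatError(f"line {lineno}: {exc}") from exc
        if r <= 0:
            raise SWCFormatError(f"line {lineno}: non-positive radius {r}")
        points.append(SWCPoint(pid, _SWC_STRUCTURE.get(stype, "other"),
                               x, y, z, r, parent))
    if not points:
        raise SWCFormatError("no data rows in SWC input")
    return points


def _validate_points(points: Sequence[SWCPoint]) -> Dict[int, SWCPoint]:
    by_id: Dict[int, SWCPoint] = {}
    for p in points:
        if p.id in by_id:
            raise SWCFormatError(f"duplicate point id {p.id}")
        if p.parent_id != -1 and p.parent_id not in by_id:
            # parent must precede child (also catches forward references)
            raise SWCFormatError(
                f"point {p.id}: parent id {p.parent_id} not defined before it")
        if p.parent_id == p.id:
            raise MorphologyStructureError(f"point {p.id} is its own parent (cycle)")
        by_id[p.id] = p
    roots = [p for p in points if p.parent_id == -1]
    if len(roots) != 1:
        raise MorphologyStructureError(f"expected exactly 1 root point, found {len(roots)}")
    return by_id


def _equivalent_soma_cylinder(soma_points: List[SWCPoint]) -> Tuple[np.ndarray, float]:
    """Collapse soma sample points to one cylinder with the same membrane area.

    A single-point soma is treated as a sphere (area 4πr²); a multi-point soma
    as a chain of frusta.  The cylinder has length = diameter so a 1-point
    write/read round trip is exact.
    """
    if len(soma_points) == 1:
        r = soma_points[0].radius
        area = 4.0 * math.pi * r * r
        cx, cy, cz = soma_points[0].x, soma_points[0].y, soma_points[0].z
    else:
        area = 0.0
        for a, b in zip(soma_points[:-1], soma_points[1:]):
            dl = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            slant = math.hypot(dl, a.radius - b.radius)
            area += math.pi * (a.radius + b.radius) * slant
        cx = float(np.mean([p.x for p in soma_points]))
        cy = float(np.mean([p.y for p in soma_points]))
        cz = float(np.mean([p.z for p in soma_points]))
    diam = math.sqrt(area / math.pi)  # solves π·d·L = area with L = d
    half = diam / 2.0
    pts = np.array([[cx - half, cy, cz, diam / 2.0],
                    [cx + half, cy, cz, diam / 2.0]])
    return pts, area


def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Sections are cut at branch points and at structure-type changes.  All
    soma points become a single equivalent-area cylinder (the root section).
    """
    with open(path) as fh:
        text = fh.read()
    points = _parse_swc_rows(text)
    by_id = _validate_points(points)

    children: Dict[int, List[int]] = {p.id: [] for p in points}
    for p in points:
        if p.parent_id != -1:
            children[p.parent_id].append(p.id)

    soma_pts = [p for p in points if p.structure == "soma"]
    root = next(p for p in points if p.parent_id == -1)
    if not soma_pts:
        # tolerate soma-less files by rooting at the root point's structure
        soma_pts = [root]
    soma_ids = {p.id for p in soma_pts}
    soma_xyz, _ = _equivalent_soma_cylinder(soma_pts)
    sections: List[Section] = [Section("soma", "soma", soma_xyz, parent=-1)]

    # Section seeds: non-soma points whose parent is soma or absent, plus
    # points starting a new section after a branch point or structure change.
    counters: Dict[str, int] = {}

    def _new_name(structure: str) -> str:
        n = counters.get(structure, 0)
        counters[structure] = n + 1
        return f"{structure}[{n}]"

    # map from point id -> (section index, position in [0,1]) for attachment
    end_of: Dict[int, Tuple[int, float]] = {pid: (0, 0.5) for pid in soma_ids}

    stack: List[int] = []
    for pid in sorted(soma_ids):
        stack.extend(c for c in children[pid] if c not in soma_ids)
    if root.id not in soma_ids:
        stack.append(root.id)
    # depth-first, building maximal unbranched runs
    seen = set()
    queue = list(dict.fromkeys(stack))
    while queue:
        start_id = queue.pop(0)
        if start_id in seen:
            continue
        p = by_id[start_id]
        parent_sec, parent_pos = end_of.get(p.parent_id, (0, 0.5))
        if p.parent_id in by_id and p.parent_id not in soma_ids:
            pp = by_id[p.parent_id]
            first = [pp.x, pp.y, pp.z, pp.radius]
        else:
            # attach to soma cylinder center; geometry starts at the point itself
            first = [p.x, p.y, p.z, p.radius]
        run = [first]
        cur = p
        while True:
            seen.add(cur.id)
            run.append([cur.x, cur.y, cur.z, cur.radius])
            kids = [c for c in children[cur.id] if c not in soma_ids]
            if len(kids) == 1 and by_id[kids[0]].structure == cur.structure:
                cur = by_id[kids[0]]
            else:
                break
        pts = np.asarray(run, dtype=float)
        if len(pts) >= 2 and np.allclose(pts[0], pts[1]):
            pts = pts[1:]
        if len(pts) < 2 or np.sqrt(np.diff(pts[:, :3], axis=0) ** 2
                                   @ np.ones(3)).sum() <= 0:
            raise MorphologyStructureError(
                f"zero-length section at SWC point {start_id}")
        sec = Section(_new_name(p.structure), p.structure, pts,
                      parent=parent_sec, parent_pos=parent_pos)
        sections.append(sec)
        idx = len(sections) - 1
        end_of[cur.id] = (idx, 1.0)
        for k in children[cur.id]:
            if k not in soma_ids and k not in seen:
                queue.append(k)
    return Morphology(sections)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard SWC (1-based ids, soma as one point)."""
    lines = ["# generated by ca1sim"]
    next_id = 1
    soma = m.sections[0]
    cx = float(soma.points[:, 0].mean())
    cy, cz = float(soma.points[0, 1]), float(soma.points[0, 2])
    soma_r = soma.length / 2.0  # cylinder with L = d; sphere of same area has r = d/2
    lines.append(f"1 1 {cx:.17g} {cy:.17g} {cz:.17g} {soma_r:.17g} -1")
    last_id_of = {0: 1}
    next_id = 2
    for i, sec in enumerate(m.sections[1:], start=1):
        parent_last = last_id_of[sec.parent]
        code = _STRUCTURE_SWC.get(sec.structure, 5)
        pts = sec.points[1:] if m.sections[sec.parent].structure != "soma" else sec.points
        prev = parent_last
        for row in pts:
            lines.append(
                f"{next_id} {code} {row[0]:.17g} {row[1]:.17g} {row[2]:.17g} "
                f"{row[3]:.17g} {prev}")
            prev = next_id
            next_id += 1
        last_id_of[i] = prev
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regions and distances
# ---------------------------------------------------------------------------

_TERMINAL_BIFURCATION_SHARE = 0.30


def classify_apical_regions(m: Morphology) -> RegionMap:
    """Partition sections into soma/axon/basal and the three apical regions."""
    apical = [i for i, s in enumerate(m.sections) if s.structure == "apical"]
    if not apical:
        raise ClassificationError("morphology has no apical sections")

    assignment: Dict[str, str] = {}
    for i, s in enumerate(m.sections):
        if s.structure == "soma":
            assignment[s.name] = "soma"
        elif s.structure == "axon":
            assignment[s.name] = "axon"
        elif s.structure in ("basal", "other"):
            assignment[s.name] = "basal"

    # apical roots: apical sections whose parent is not apical
    roots = [i for i in apical if m.sections[m.sections[i].parent].structure != "apical"]
    main_root = max(roots, key=m.subtree_length)

    subtree_len = {i: m.subtree_length(i) for i in apical}
    trunk: List[int] = []
    cur = main_root
    tuft_roots: List[int] = []
    while True:
        trunk.append(cur)
        kids = [c for c in m.children(cur) if m.sections[c].structure == "apical"]
        if not kids:
            break
        remaining = sum(subtree_len[k] for k in kids)
        ranked = sorted(kids, key=lambda k: subtree_len[k], reverse=True)
        if (len(ranked) >= 2
                and subtree_len[ranked[0]] > _TERMINAL_BIFURCATION_SHARE * remaining
                and subtree_len[ranked[1]] > _TERMINAL_BIFURCATION_SHARE * remaining):
            tuft_roots = kids
            break
        # continue down the heaviest child; siblings become obliques
        cur = ranked[0]

    trunk_set = set(trunk)
    tuft_set = set()
    for r in tuft_roots:
        tuft_set.update(m.subtree_indices(r))
    for i in apical:
        sec = m.sections[i]
        if i in trunk_set:
            assignment[sec.name] = "apical_primary"
        elif i in tuft_set:
            assignment[sec.name] = "apical_tuft"
        else:
            assignment[sec.name] = "apical_oblique"
    # secondary apical roots (rare) fall into oblique via the loop above
    rm = RegionMap(assignment)
    m.region_map = rm
    return rm


def path_distance(m: Morphology, location: Tuple[int, float]) -> float:
    """Arc-length distance (μm) from the soma to ``(section index, pos in [0,1])``.

    The soma's own extent contributes zero, so any location on the soma is at
    distance 0 and sections attached to the soma start at 0.
    """
    idx, pos = location
    if not (0 <= idx < len(m.sections)):
        raise LookupError(f"invalid section index {idx}")
    if not (0.0 <= pos <= 1.0):
        raise LookupError(f"position {pos} outside [0, 1]")
    sec = m.sections[idx]
    if sec.structure == "soma":
        return 0.0
    d0 = m.section_start_distances()
    return float(d0[idx] + pos * sec.length)
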