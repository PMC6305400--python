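"""Quantitative features of neuron morphologies.

Covers the quantities a circular dendrogram can encode or sort by: neurite,
bifurcation and terminal counts; path lengths; radial (soma-centered)
distances; length-weighted mean diameters; lateral surface areas and volumes
of the conical frusta between consecutive tracing samples; angles between
sibling branches at a bifurcation; dendritic-spine densities; Sholl
intersection profiles; and population summary statistics.

Conventions
-----------
* Radial distances are measured from the *soma centroid* (mean of soma
  samples), which makes them deterministic across SWC dialects with
  multi-point somas.
* A tracing point with ``k >= 2`` children counts as ``k - 1`` binary
  bifurcations by default (the binary-tree idealization); pass
  ``binary=False`` to count each branch point once.
* A Sholl sphere of radius ``r`` is crossed by the tracing edge ``(p, c)``
  (``c`` non-soma) when ``min(d) < r <= max(d)`` for the two endpoint radial
  distances — a half-open rule, so a crossing exactly at ``r`` is counted
  once and never twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, SpineError
from .io_swc import ROOT_PARENT, SOMA, NeuronMorphology


@dataclass(frozen=True)
class Branch:
    """A straightened inter-bifurcation neurite fragment.

    ``point_ids`` run from the attachment (the first tracing point of the
    neurite for a stem, the parent bifurcation point otherwise) to a
    bifurcation point or a terminal tip.  The id of the last point is unique
    across the cell and is used as the branch key everywhere a table or a
    spine record needs to reference a branch.
    """

    point_ids: tuple[int, ...]
    neurite_index: int
    branch_order: int
    is_terminal: bool

    @property
    def key(self) -> int:
        return self.point_ids[-1]


@dataclass(frozen=True)
class BranchGeometry:
    path_length: float
    mean_diameter: float
    lateral_area: float
    volume: float


@dataclass
class MorphometrySummary:
    neurite_count: int
    bifurcation_count: int
    terminal_count: int
    endings_per_neurite: list[int]
    bifurcations_per_neurite: list[int]
    points_per_neurite: list[int]
    total_path_length: float
    branch_table: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class SpineRecord:
    """A dendritic spine annotation: which branch, where along it, how big."""

    branch_key: int
    arc_position: float
    volume: float


@dataclass(frozen=True)
class ShollProfile:
    radii: tuple[float, ...]
    intersection_counts: tuple[int, ...]


# ---------------------------------------------------------------------------
# branch decomposition


def extract_branches(morph: NeuronMorphology, binary: bool = True) -> list[Branch]:
    """Decompose the tracing into inter-bifurcation branches, depth-first,
    neurites in tracing order.  ``binary`` has no effect on the decomposition
    itself (an n-ary branch point simply has n child branches)."""
    branches: list[Branch] = []
    for ni, root in enumerate(morph.neurite_root_ids()):
        # stack of (start point id, branch order, id of attachment point or None)
        stack: list[tuple[int, int, int | None]] = [(root, 1, None)]
        while stack:
            start, order, attach = stack.pop()
            ids: list[int] = [] if attach is None else [attach]
            cur = start
            ids.append(cur)
            kids = morph.children(cur)
            while len(kids) == 1:
                cur = kids[0]
                ids.append(cur)
                kids = morph.children(cur)
            branches.append(
                Branch(tuple(ids), ni, order, is_terminal=not kids)
            )
            for kid in reversed(kids):
                stack.append((kid, order + 1, cur))
    return branches


# ---------------------------------------------------------------------------
# geometry


def _positions(morph: NeuronMorphology, ids: Sequence[int]) -> np.ndarray:
    return np.array([morph.point(i).position for i in ids], dtype=float)


def branch_geometry(branch: Branch, morph: NeuronMorphology) -> BranchGeometry:
    """Path length, length-weighted mean diameter, and the frustum lateral
    area / volume of a branch modelled as a chain of conical frusta."""
    if len(branch.point_ids) < 2:
        raise DegenerateGeometryError(
            f"branch ending at point {branch.key} has a single point"
        )
    pos = _positions(morph, branch.point_ids)
    radii = np.array([morph.point(i).radius for i in branch.point_ids], dtype=float)
    deltas = np.diff(pos, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    r1, r2 = radii[:-1], radii[1:]
    slant = np.sqrt(seg_len**2 + (r1 - r2) ** 2)
    lateral = float(np.sum(math.pi * (r1 + r2) * slant))
    volume = float(np.sum(math.pi * seg_len / 3.0 * (r1**2 + r1 * r2 + r2**2)))
    total = float(np.sum(seg_len))
    if total > 0:
        mean_diam = float(np.sum(seg_len * (r1 + r2)) / total)  # (d1+d2)/2 = r1+r2
    else:
        mean_diam = float(np.mean(radii) * 2.0)
    return BranchGeometry(total, mean_diam, lateral, volume)


def radial_distance(point_id: int, morph: NeuronMorphology) -> float:
    """Euclidean distance from a tracing point to the soma centroid."""
    p = morph.point(point_id)
    c = morph.soma_centroid
    return math.dist(p.position, c)


def bifurcation_angle(node_id: int, morph: NeuronMorphology) -> list[float]:
    """Pairwise angles (degrees) between the child directions at a branch
    point — a single angle at a binary node, the full pairwise list at an
    n-ary one.  The direction to a child is taken to its first tracing point
    at a nonzero offset from the node."""
    kids = morph.children(node_id)
    if len(kids) < 2:
        raise ValueError(f"point {node_id} has {len(kids)} children; need >= 2")
    origin = np.array(morph.point(node_id).position)
    dirs = []
    for kid in kids:
        cur = kid
        v = np.array(morph.point(cur).position) - origin
        while np.linalg.norm(v) == 0.0:
            nxt = morph.children(cur)
            if not nxt:
                raise DegenerateGeometryError(
                    f"child {kid} of point {node_id} never leaves the node position"
                )
            cur = nxt[0]
            v = np.array(morph.point(cur).position) - origin
        dirs.append(v / np.linalg.norm(v))
    angles = []
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            u, v = dirs[i], dirs[j]
            ang = math.atan2(float(np.linalg.norm(np.cross(u, v))), float(np.dot(u, v)))
            angles.append(math.degrees(ang))
    return angles


# ---------------------------------------------------------------------------
# counts


def count_summary(morph: NeuronMorphology, binary: bool = True) -> MorphometrySummary:
    """Neurite / bifurcation / terminal counts plus a per-branch feature table.

    Neurites are the stems attached to the soma (or tree roots in a soma-less
    tracing).  With ``binary=True`` a point with ``k`` children contributes
    ``k - 1`` bifurcations; with ``binary=False`` it contributes one.
    """
    roots = morph.neurite_root_ids()
    endings: list[int] = []
    bifs: list[int] = []
    npoints: list[int] = []
    for root in roots:
        e = b = n = 0
        stack = [root]
        while stack:
            pid = stack.pop()
            n += 1
            kids = morph.children(pid)
            if not kids:
                e += 1
            elif len(kids) >= 2:
                b += (len(kids) - 1) if binary else 1
            stack.extend(kids)
        endings.append(e)
        bifs.append(b)
        npoints.append(n)

    branches = extract_branches(morph)
    table = []
    total_len = 0.0
    for br in branches:
        if len(br.point_ids) >= 2:
            geom = branch_geometry(br, morph)
        else:
            # a stem whose first point is already a branch point; tolerated
            # here and reported by validate_morphology as degenerate
            r = morph.point(br.key).radius
            geom = BranchGeometry(0.0, 2.0 * r, 0.0, 0.0)
        total_len += geom.path_length
        table.append(
            {
                "branch_key": br.key,
                "neurite_index": br.neurite_index,
                "branch_order": br.branch_order,
                "is_terminal": br.is_terminal,
                "path_length": geom.path_length,
                "mean_diameter": geom.mean_diameter,
                "lateral_area": geom.lateral_area,
                "volume": geom.volume,
                "radial_distance_end": radial_distance(br.key, morph),
            }
        )
    return MorphometrySummary(
        neurite_count=len(roots),
        bifurcation_count=sum(bifs),
        terminal_count=sum(endings),
        endings_per_neurite=endings,
        bifurcations_per_neurite=bifs,
        points_per_neurite=npoints,
        total_path_length=total_len,
        branch_table=table,
    )


# ---------------------------------------------------------------------------
# spines


def spine_density(
    branch: Branch, morph: NeuronMorphology, spines: Sequence[SpineRecord]
) -> float:
    """Spines assigned to the branch per micron of its path length."""
    geom = branch_geometry(branch, morph)
    count = 0
    for rec in spines:
        if rec.branch_key != branch.key:
            continue
        if not (0.0 <= rec.arc_position <= geom.path_length + 1e-9):
            raise SpineError(
                f"spine at arc position {rec.arc_position} lies beyond branch "
                f"{branch.key} (length {geom.path_length:.3f})"
            )
        count += 1
    return count / geom.path_length


# ---------------------------------------------------------------------------
# Sholl


def sholl_profile(morph: NeuronMorphology, radii: Sequence[float]) -> ShollProfile:
    """Count tracing-segment crossings of concentric spheres centered on the
    soma centroid."""
    radii = list(radii)
    if not radii or any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    dist = {p.id: radial_distance(p.id, morph) for p in morph.points}
    crossings = []
    for p in morph.points:
        if p.structure_type == SOMA or p.parent_id == ROOT_PARENT:
            continue
        d_child = dist[p.id]
        d_parent = dist[p.parent_id]
        crossings.append((min(d_parent, d_child), max(d_parent, d_child)))
    counts = [sum(1 for lo, hi in crossings if lo < r <= hi) for r in radii]
    return ShollProfile(tuple(radii), tuple(counts))


# ---------------------------------------------------------------------------
# populations


POPULATION_METRICS = ("neurites", "bifurcations", "endings", "total_length")


def _metric_values(summaries: Sequence[MorphometrySummary], metric: str) -> np.ndarray:
    attr = {
        "neurites": "neurite_count",
        "bifurcations": "bifurcation_count",
        "endings": "terminal_count",
        "total_length": "total_path_length",
    }[metric]
    return np.array([getattr(s, attr) for s in summaries], dtype=float)


def population_stats(
    summaries: Sequence[MorphometrySummary],
) -> dict[str, dict[str, float]]:
    """Mean and standard deviation of the count metrics across cells.

    Both SD conventions are reported: ``sd_population`` divides by ``n`` and
    ``sd_sample`` by ``n - 1`` (0 for a single cell).
    """
    if not summaries:
        raise ValueError("population_stats needs at least one summary")
    out: dict[str, dict[str, float]] = {}
    n = len(summaries)
    for metric in POPULATION_METRICS:
        vals = _metric_values(summaries, metric)
        mean = float(np.mean(vals))
        sd_pop = float(np.std(vals, ddof=0))
        sd_sam = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out[metric] = {"mean": mean, "sd_population": sd_pop, "sd_sample": sd_sam}
    return out


# ---------------------------------------------------------------------------
# projection


def principal_projection(morph: NeuronMorphology) -> np.ndarray:
    """Project all tracing points onto the plane of the two leading principal
    axes of the point cloud — the area-maximizing projection heuristic.

    Returns an ``(n_points, 2)`` array in point order; within-plane distances
    are preserved.  Raises :class:`DegenerateGeometryError` for collinear or
    too-small clouds.
    """
    pts = _positions(morph, [p.id for p in morph.points])
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points to fit a plane")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0.0 or s[1] <= 1e-12 * s[0]:
        raise DegenerateGeometryError("point cloud is collinear or degenerate")
    return centered @ vt[:2].T
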