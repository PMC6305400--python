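"""Reading, validating and writing neuron morphologies in SWC format.

The SWC dialect accepted here is the common 7-column one::

    id  structure_type  x  y  z  radius  parent_id

with ``#`` comment lines, blank lines, arbitrary whitespace between fields,
and ``parent_id == -1`` marking a root.  Ids need not be contiguous or
sorted on input; :func:`write_swc` canonicalizes (parent-before-child order,
ids renumbered ``1..n``) and produces byte-deterministic output.

Structure-type codes follow the NeuroMorpho convention (1 soma, 2 axon,
3 basal dendrite, 4 apical dendrite); unknown codes are preserved and treated
as their own neurite class, so non-neuronal branching structures such as
vasculature trees pass through unchanged.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import (
    EmptyMorphologyError,
    SWCConnectivityError,
    SWCFormatError,
)

ROOT_PARENT = -1

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

STRUCTURE_NAMES = {
    0: "undefined",
    SOMA: "soma",
    AXON: "axon",
    BASAL_DENDRITE: "basal dendrite",
    APICAL_DENDRITE: "apical dendrite",
}


@dataclass(frozen=True)
class MorphPoint:
    """One tracing sample: position, radius and parent link."""

    id: int
    structure_type: int
    position: tuple[float, float, float]
    radius: float
    parent_id: int

    @property
    def x(self) -> float:
        return self.position[0]

    @property
    def y(self) -> float:
        return self.position[1]

    @property
    def z(self) -> float:
        return self.position[2]


@dataclass(frozen=True)
class ValidationIssue:
    """A coded, point-addressed problem found by :func:`validate_morphology`."""

    code: str
    point_id: int | None
    message: str


class NeuronMorphology:
    """A validated tracing tree (or forest rooted at the soma).

    Structural invariants (unique ids, resolvable parents, acyclicity) are
    enforced at construction; value-level problems (negative radii,
    zero-length segments, disconnected somas) are soft and reported by
    :func:`validate_morphology` instead.
    """

    def __init__(
        self,
        points: Iterable[MorphPoint],
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.points: list[MorphPoint] = list(points)
        self.metadata: dict[str, object] = dict(metadata or {})
        self._index: dict[int, MorphPoint] = {}
        for p in self.points:
            if p.id in self._index:
                raise SWCFormatError(f"duplicate point id {p.id}")
            if p.id <= 0:
                raise SWCFormatError(f"point id must be positive, got {p.id}")
            self._index[p.id] = p
        self._children: dict[int, list[int]] = {p.id: [] for p in self.points}
        for p in self.points:
            if p.parent_id == ROOT_PARENT:
                continue
            if p.parent_id not in self._index:
                raise SWCConnectivityError(
                    f"point {p.id} references undefined parent {p.parent_id}"
                )
            self._children[p.parent_id].append(p.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}  # 0 visiting, 1 done
        for p in self.points:
            pid = p.id
            chain = []
            while pid != ROOT_PARENT and state.get(pid) != 1:
                if state.get(pid) == 0:
                    raise SWCConnectivityError(f"cycle detected at point {pid}")
                state[pid] = 0
                chain.append(pid)
                pid = self._index[pid].parent_id
            for c in chain:
                state[c] = 1

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[MorphPoint]:
        return iter(self.points)

    def point(self, point_id: int) -> MorphPoint:
        try:
            return self._index[point_id]
        except KeyError:
            raise KeyError(f"no point with id {point_id}") from None

    def __contains__(self, point_id: int) -> bool:
        return point_id in self._index

    def children(self, point_id: int) -> list[int]:
        """Child point ids in tracing order."""
        return list(self._children[point_id])

    # -- soma and neurite structure -----------------------------------------

    @property
    def soma_ids(self) -> list[int]:
        return [p.id for p in self.points if p.structure_type == SOMA]

    @property
    def soma_centroid(self) -> tuple[float, float, float]:
        """Mean position of soma points; falls back to the mean of the tree
        roots when the tracing carries no soma samples."""
        pts = [self._index[i] for i in self.soma_ids]
        if not pts:
            pts = [p for p in self.points if p.parent_id == ROOT_PARENT]
        if not pts:
            raise EmptyMorphologyError("morphology has no points")
        n = float(len(pts))
        return (
            sum(p.x for p in pts) / n,
            sum(p.y for p in pts) / n,
            sum(p.z for p in pts) / n,
        )

    @property
    def soma_mean_radius(self) -> float:
        pts = [self._index[i] for i in self.soma_ids]
        if not pts:
            return 1.0
        return sum(p.radius for p in pts) / len(pts)

    def neurite_root_ids(self) -> list[int]:
        """Ids of the first point of each neurite, in tracing order.

        A neurite root is a non-soma point whose parent is a soma point or
        the root marker (the latter covers soma-less tracings such as
        vasculature exports).
        """
        soma = set(self.soma_ids)
        roots = []
        for p in self.points:
            if p.structure_type == SOMA:
                continue
            if p.parent_id == ROOT_PARENT or p.parent_id in soma:
                roots.append(p.id)
        return roots


# ---------------------------------------------------------------------------
# reading


def _parse_line(line: str, lineno: int) -> MorphPoint:
    fields = line.split()
    if len(fields) != 7:
        raise SWCFormatError(
            f"line {lineno}: expected 7 fields, got {len(fields)}"
        )
    try:
        pid = int(fields[0])
        stype = int(fields[1])
        x, y, z, radius = (float(v) for v in fields[2:6])
        parent = int(fields[6])
    except ValueError as exc:
        raise SWCFormatError(f"line {lineno}: non-numeric field ({exc})") from None
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not math.isfinite(v):
            raise SWCFormatError(f"line {lineno}: non-finite coordinate {name}={v}")
    return MorphPoint(pid, stype, (x, y, z), radius, parent)


def read_swc(stream: Iterable[str] | str) -> NeuronMorphology:
    """Parse SWC text into a :class:`NeuronMorphology`.

    ``stream`` may be an open text file, any iterable of lines, or a string
    holding the whole file content.  Point order is preserved; comment lines
    are retained in ``metadata["comments"]``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    points: list[MorphPoint] = []
    seen: set[int] = set()
    comments: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line.lstrip("#").strip())
            continue
        pt = _parse_line(line, lineno)
        if pt.id in seen:
            raise SWCFormatError(f"line {lineno}: duplicate point id {pt.id}")
        seen.add(pt.id)
        points.append(pt)
    if not points:
        raise EmptyMorphologyError("SWC stream contains no data lines")
    return NeuronMorphology(points, metadata={"comments": comments})


def load_swc(path) -> NeuronMorphology:
    with open(path, "r", encoding="utf-8") as fh:
        morph = read_swc(fh)
    morph.metadata["source"] = str(path)
    return morph


# ---------------------------------------------------------------------------
# writing


def _fmt_coord(v: float) -> str:
    s = f"{v:.6f}"
    return "0.000000" if s == "-0.000000" else s


def _fmt_radius(v: float) -> str:
    return f"{v:.6g}"


def write_swc(morph: NeuronMorphology) -> str:
    """Serialize to canonical SWC text.

    Points are emitted parent-before-child (depth-first, tracing order of
    siblings, roots in original point order) and renumbered ``1..n``; output
    is byte-deterministic for a given morphology.
    """
    if len(morph) == 0:
        raise EmptyMorphologyError("cannot write an empty morphology")
    lines: list[str] = []
    comments = morph.metadata.get("comments") or []
    if comments:
        lines.extend(f"# {c}" if c else "#" for c in comments)
    else:
        lines.append("# SWC export (circdendro)")
    new_id: dict[int, int] = {}
    order: list[MorphPoint] = []
    roots = [p.id for p in morph.points if p.parent_id == ROOT_PARENT]
    for root in roots:
        stack = [root]
        while stack:
            pid = stack.pop()
            pt = morph.point(pid)
            new_id[pid] = len(order) + 1
            order.append(pt)
            stack.extend(reversed(morph.children(pid)))
    if len(order) != len(morph):
        # only reachable if some point is in a parent cycle, which the
        # constructor forbids; kept as a guard for hand-built instances
        raise SWCConnectivityError("morphology contains unreachable points")
    for pt in order:
        parent = ROOT_PARENT if pt.parent_id == ROOT_PARENT else new_id[pt.parent_id]
        lines.append(
            f"{new_id[pt.id]} {pt.structure_type} "
            f"{_fmt_coord(pt.x)} {_fmt_coord(pt.y)} {_fmt_coord(pt.z)} "
            f"{_fmt_radius(pt.radius)} {parent}"
        )
    return "\n".join(lines) + "\n"


def save_swc(morph: NeuronMorphology, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(write_swc(morph))


# ---------------------------------------------------------------------------
# validation report


def validate_morphology(morph: NeuronMorphology) -> list[ValidationIssue]:
    """Report soft inconsistencies; an empty list means the morphology meets
    all value-level invariants (structural ones are already guaranteed)."""
    issues: list[ValidationIssue] = []
    soma = set(morph.soma_ids)
    for p in morph.points:
        if p.radius < 0:
            issues.append(
                ValidationIssue("negative-radius", p.id, f"point {p.id} has radius {p.radius}")
            )
        if not all(math.isfinite(c) for c in p.position):
            issues.append(
                ValidationIssue("non-finite-coordinate", p.id, f"point {p.id} at {p.position}")
            )
        if p.parent_id != ROOT_PARENT:
            q = morph.point(p.parent_id)
            if q.position == p.position:
                issues.append(
                    ValidationIssue(
                        "zero-length-segment",
                        p.id,
                        f"points {q.id} and {p.id} share position {p.position}",
                    )
                )
    # duplicate coordinates among non-adjacent points
    seen_pos: dict[tuple[float, float, float], int] = {}
    for p in morph.points:
        if p.position in seen_pos:
            other = seen_pos[p.position]
            if morph.point(p.id).parent_id != other and morph.point(other).parent_id != p.id:
                issues.append(
                    ValidationIssue(
                        "duplicate-coordinates",
                        p.id,
                        f"points {other} and {p.id} share position {p.position}",
                    )
                )
        else:
            seen_pos[p.position] = p.id
    # soma connectivity: every soma point should belong to one component
    soma_roots = [
        i for i in soma
        if morph.point(i).parent_id == ROOT_PARENT or morph.point(i).parent_id not in soma
    ]
    if len(soma_roots) > 1:
        issues.append(
            ValidationIssue(
                "multiple-soma-components",
                None,
                f"soma points form {len(soma_roots)} components",
            )
        )
    # orphan subtree: a non-soma root while a soma exists
    if soma:
        for p in morph.points:
            if p.parent_id == ROOT_PARENT and p.structure_type != SOMA:
                issues.append(
                    ValidationIssue(
                        "orphan-subtree",
                        p.id,
                        f"non-soma point {p.id} is a root although a soma exists",
                    )
                )
    return issues
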