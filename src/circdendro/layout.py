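"""Radial layout of circular dendrograms.

A morphology is first abstracted into one branch tree per neurite
(:func:`build_branch_tree`): every inter-bifurcation fragment becomes a
single :class:`DendrogramNode`, curvature is discarded, and sibling order is
the tracing order.  Layout then happens in two independent passes:

* :func:`assign_lengths` gives every node a radial start ``r0`` and extent
  ``length`` under one of four length modes — real path length (RLM),
  radial soma distance (RM), unitary fixed length (UM), or an arbitrary
  feature affinely mapped into a length range (LMM);
* :func:`assign_angles` gives every node a half-open angular span and a ray
  angle under one of three angle modes — equal wedge per terminal (ENDM,
  β = 360/E), equal sector per neurite (NDM, α = 360/N with ENDM inside
  each sector), or weight-proportional wedges (WDM, spans ∝ C).

Sibling spans partition their parent's span contiguously, so Σ α_i = 360°
holds in every mode by construction.  Neurite and sibling order can be
rearranged beforehand with :func:`order_neurites` / :func:`order_siblings`
(stable sorts by any morphometric key), and subtrees can be replaced by a
summary glyph with :func:`collapse_subtree`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

from .errors import FeatureError, LayoutError
from .io_swc import NeuronMorphology
from . import morphometry
from .morphometry import Branch, SpineRecord, branch_geometry, extract_branches


class AngleMode(str, Enum):
    ENDM = "endm"  # equal wedge per branch ending
    NDM = "ndm"    # equal sector per neurite
    WDM = "wdm"    # wedges proportional to correction weights


class LengthMode(str, Enum):
    REAL = "rlm"     # real path length
    RADIAL = "rm"    # radial distance from node to soma
    UNITARY = "um"   # fixed length L0 per node
    MAPPED = "lmm"   # arbitrary feature mapped to a length range


@dataclass
class DendrogramNode:
    branch: Branch
    children: list["DendrogramNode"] = field(default_factory=list)
    e_sub: int = 1
    theta_start: float | None = None
    theta_end: float | None = None
    ray_angle: float | None = None
    r0: float | None = None
    length: float | None = None
    collapsed: bool = False
    collapse_label: str = ""

    @property
    def key(self) -> int:
        return self.branch.key

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def span(self) -> tuple[float, float]:
        if self.theta_start is None or self.theta_end is None:
            raise LayoutError("angles not assigned yet")
        return (self.theta_start, self.theta_end)


@dataclass
class LayoutConfig:
    """All knobs of the radial layout.

    ``unit_length`` is the UM segment length L0 (drawing units; default 20).
    ``weights`` maps leaf node keys to positive correction weights C (WDM);
    missing entries default to 1 so a partial weighting is valid.
    ``mapped_range`` is the (min, max) length a feature is rescaled into
    under LMM.  ``start_angle`` is where the first wedge begins (degrees,
    counterclockwise positive, 0° at the positive x-axis).
    """

    angle_mode: AngleMode = AngleMode.ENDM
    length_mode: LengthMode = LengthMode.REAL
    unit_length: float = 20.0
    weights: Mapping[int, float] | None = None
    mapped_feature: str | None = None
    mapped_range: tuple[float, float] = (5.0, 50.0)
    start_angle: float = 90.0
    clockwise: bool = False
    anchor: bool = False
    ray_style: str = "midpoint"  # or "weighted" (endings-weighted centroid)
    soma_radius: float | None = None

    def __post_init__(self):
        self.angle_mode = AngleMode(self.angle_mode)
        self.length_mode = LengthMode(self.length_mode)
        if self.unit_length <= 0:
            raise LayoutError("unit_length must be > 0")
        lo, hi = self.mapped_range
        if lo >= hi:
            raise LayoutError("mapped_range must be increasing")
        if self.ray_style not in ("midpoint", "weighted"):
            raise LayoutError(f"unknown ray_style {self.ray_style!r}")


# ---------------------------------------------------------------------------
# tree construction


def build_branch_tree(morph: NeuronMorphology) -> list[DendrogramNode]:
    """One DendrogramNode tree per neurite, in tracing order; subtree ending
    counts ``e_sub`` are filled bottom-up."""
    branches = extract_branches(morph)
    if not branches:
        warnings.warn("morphology has no neurites", stacklevel=2)
        return []
    by_start: dict[int, list[Branch]] = {}
    roots: list[Branch] = []
    for br in branches:
        if br.branch_order == 1:
            roots.append(br)
        else:
            by_start.setdefault(br.point_ids[0], []).append(br)

    def build(br: Branch) -> DendrogramNode:
        node = DendrogramNode(branch=br)
        for child in by_start.get(br.key, []):
            node.children.append(build(child))
        node.e_sub = sum(c.e_sub for c in node.children) if node.children else 1
        return node

    return [build(br) for br in roots]


def iter_nodes(trees: Sequence[DendrogramNode]) -> Iterator[DendrogramNode]:
    """Depth-first, siblings in current order."""
    stack = list(reversed(trees))
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def iter_visible(trees: Sequence[DendrogramNode]) -> Iterator[DendrogramNode]:
    """Like :func:`iter_nodes` but never descends below a collapsed node."""
    stack = list(reversed(trees))
    while stack:
        node = stack.pop()
        yield node
        if not node.collapsed:
            stack.extend(reversed(node.children))


def _leaves(node: DendrogramNode) -> list[DendrogramNode]:
    return [n for n in iter_nodes([node]) if n.is_leaf]


# ---------------------------------------------------------------------------
# feature keys (ordering, LMM, encodings)


ORDER_KEYS = (
    "endings",
    "nodes",
    "total_length",
    "length",
    "volume",
    "lateral_area",
    "mean_diameter",
    "spine_density",
)


def subtree_feature(
    node: DendrogramNode,
    morph: NeuronMorphology,
    key: str,
    spines: Sequence[SpineRecord] | None = None,
) -> float:
    """Scalar feature of a node's subtree, used as a sort key or glyph label.

    ``endings``/``nodes`` are subtree counts; ``total_length`` and
    ``mean_diameter`` aggregate over the subtree; ``length``, ``volume`` and
    ``lateral_area`` are properties of the node's own branch;
    ``spine_density`` is subtree spine count over subtree length.
    """
    if key == "endings":
        return float(node.e_sub)
    if key == "nodes":
        return float(sum(1 for n in iter_nodes([node]) if not n.is_leaf))
    geoms = None
    if key in ("total_length", "mean_diameter", "spine_density"):
        geoms = [branch_geometry(n.branch, morph) for n in iter_nodes([node])]
    if key == "total_length":
        return sum(g.path_length for g in geoms)
    if key == "mean_diameter":
        total = sum(g.path_length for g in geoms)
        if total == 0:
            return float(sum(g.mean_diameter for g in geoms) / len(geoms))
        return sum(g.mean_diameter * g.path_length for g in geoms) / total
    if key == "spine_density":
        if spines is None:
            raise FeatureError("spine_density ordering requires spine records")
        keys = {n.key for n in iter_nodes([node])}
        count = sum(1 for rec in spines if rec.branch_key in keys)
        total = sum(g.path_length for g in geoms)
        return count / total if total > 0 else 0.0
    if key in ("length", "volume", "lateral_area"):
        g = branch_geometry(node.branch, morph)
        return {
            "length": g.path_length,
            "volume": g.volume,
            "lateral_area": g.lateral_area,
        }[key]
    raise FeatureError(f"unknown ordering key {key!r}; known: {', '.join(ORDER_KEYS)}")


# ---------------------------------------------------------------------------
# ordering


def order_neurites(
    trees: Sequence[DendrogramNode],
    morph: NeuronMorphology,
    key: str,
    descending: bool = False,
    spines: Sequence[SpineRecord] | None = None,
) -> list[DendrogramNode]:
    """Stable sort of whole neurites by a subtree feature; ties keep tracing
    order and subtree topology is untouched."""
    return sorted(
        trees,
        key=lambda t: subtree_feature(t, morph, key, spines),
        reverse=descending,
    )


def order_siblings(
    tree: DendrogramNode,
    morph: NeuronMorphology,
    key: str,
    descending: bool = False,
    spines: Sequence[SpineRecord] | None = None,
) -> DendrogramNode:
    """Recursively stable-sort the children at every internal node (in
    place); returns the tree for chaining."""
    for node in iter_nodes([tree]):
        if node.children:
            node.children = sorted(
                node.children,
                key=lambda c: subtree_feature(c, morph, key, spines),
                reverse=descending,
            )
    return tree


# ---------------------------------------------------------------------------
# lengths


def assign_lengths(
    trees: Sequence[DendrogramNode],
    morph: NeuronMorphology,
    config: LayoutConfig,
    feature_values: Mapping[int, float] | None = None,
) -> None:
    """Set ``r0`` and ``length`` on every node (in place).

    Roots start at the soma circle (``config.soma_radius`` or the mean soma
    sample radius); each child starts at its parent's outer radius.  Under RM
    a curved neurite can place a child end point nearer the soma than its
    parent's; the extent is then clamped to ``1e-6 * unit_length`` with a
    warning, since a radial segment cannot point inward.
    """
    mode = config.length_mode
    soma_r = config.soma_radius if config.soma_radius is not None else morph.soma_mean_radius

    if mode is LengthMode.MAPPED:
        if feature_values is None:
            raise FeatureError("MAPPED length mode requires feature values per branch")
        missing = [n.key for n in iter_nodes(trees) if n.key not in feature_values]
        if missing:
            raise FeatureError(
                f"feature not defined for branches {missing[:5]} "
                f"({len(missing)} missing in total)"
            )
        vals = [feature_values[n.key] for n in iter_nodes(trees)]
        vlo, vhi = min(vals), max(vals)
        llo, lhi = config.mapped_range

    clamp_floor = 1e-6 * config.unit_length
    for root in trees:
        stack = [(root, float(soma_r))]
        while stack:
            node, r0 = stack.pop()
            node.r0 = r0
            if mode is LengthMode.REAL:
                node.length = branch_geometry(node.branch, morph).path_length
            elif mode is LengthMode.UNITARY:
                node.length = config.unit_length
            elif mode is LengthMode.RADIAL:
                outer = morphometry.radial_distance(node.key, morph)
                ell = outer - r0
                if ell <= 0:
                    warnings.warn(
                        f"radial mode: branch {node.key} ends no farther from the "
                        "soma than its parent; extent clamped",
                        stacklevel=2,
                    )
                    ell = clamp_floor
                node.length = ell
            else:  # MAPPED
                v = feature_values[node.key]
                if vhi == vlo:
                    node.length = 0.5 * (llo + lhi)
                else:
                    node.length = llo + (v - vlo) / (vhi - vlo) * (lhi - llo)
            for child in node.children:
                stack.append((child, node.r0 + node.length))


# ---------------------------------------------------------------------------
# angles


def _leaf_spans(
    trees: Sequence[DendrogramNode], config: LayoutConfig
) -> dict[int, float]:
    """Angular wedge width per leaf key, according to the angle mode."""
    all_leaves = [leaf for tree in trees for leaf in _leaves(tree)]
    E = len(all_leaves)
    if E == 0:
        raise LayoutError("layout needs at least one terminal")
    if config.angle_mode is AngleMode.ENDM:
        beta = 360.0 / E
        return {leaf.key: beta for leaf in all_leaves}
    if config.angle_mode is AngleMode.NDM:
        alpha = 360.0 / len(trees)
        spans: dict[int, float] = {}
        for tree in trees:
            beta_i = alpha / tree.e_sub
            for leaf in _leaves(tree):
                spans[leaf.key] = beta_i
        return spans
    # WDM
    weights = dict(config.weights or {})
    w = {}
    for leaf in all_leaves:
        c = float(weights.get(leaf.key, 1.0))
        if c <= 0:
            raise LayoutError(f"WDM weight for leaf {leaf.key} must be > 0, got {c}")
        w[leaf.key] = c
    total = sum(w.values())
    return {k: 360.0 * c / total for k, c in w.items()}


def _assign_spans(node: DendrogramNode, spans: dict[int, float], cursor: float, sign: float) -> float:
    """Lay out the subtree's leaf wedges from ``cursor``; returns new cursor."""
    if node.is_leaf:
        width = spans[node.key]
        a, b = cursor, cursor + sign * width
        node.theta_start, node.theta_end = (a, b) if sign > 0 else (b, a)
        node.ray_angle = 0.5 * (a + b)
        return b
    for child in node.children:
        cursor = _assign_spans(child, spans, cursor, sign)
    node.theta_start = min(c.theta_start for c in node.children)
    node.theta_end = max(c.theta_end for c in node.children)
    node.ray_angle = 0.5 * (node.theta_start + node.theta_end)
    return cursor


def _apply_weighted_rays(node: DendrogramNode) -> float:
    """Endings-weighted centroid ray angles (alternative ray style)."""
    if node.is_leaf:
        return node.ray_angle
    rays = [_apply_weighted_rays(c) for c in node.children]
    node.ray_angle = sum(r * c.e_sub for r, c in zip(rays, node.children)) / node.e_sub
    return node.ray_angle


def _rotate(trees: Sequence[DendrogramNode], delta: float) -> None:
    for node in iter_nodes(trees):
        node.theta_start += delta
        node.theta_end += delta
        node.ray_angle += delta


def _anchor_order(trees: Sequence[DendrogramNode], morph: NeuronMorphology) -> list[DendrogramNode]:
    """Apical neurites first, then basal/other, then axons (stable)."""
    def rank(tree: DendrogramNode) -> int:
        stype = morph.point(tree.branch.point_ids[0]).structure_type
        if stype == 4:   # apical dendrite
            return 0
        if stype == 2:   # axon
            return 2
        return 1
    return sorted(trees, key=rank)


def assign_angles(
    trees: Sequence[DendrogramNode],
    config: LayoutConfig,
    morph: NeuronMorphology | None = None,
) -> list[DendrogramNode]:
    """Set spans and ray angles on every node (in place); returns the trees
    in the order they were laid out.

    With ``config.anchor`` (requires ``morph`` for structure types) neurites
    are reordered apical → basal/other → axon and the whole layout is rotated
    so the apical sector is centered on 90° (or, with no apical neurite, the
    axon sector on 270°) — the conventional apical-up / axon-down view.
    """
    trees = list(trees)
    if not trees:
        raise LayoutError("no neurite trees to lay out")
    if config.anchor:
        if morph is None:
            raise LayoutError("anchoring requires the morphology for structure types")
        trees = _anchor_order(trees, morph)
    spans = _leaf_spans(trees, config)
    sign = -1.0 if config.clockwise else 1.0
    cursor = config.start_angle
    for tree in trees:
        cursor = _assign_spans(tree, spans, cursor, sign)
    if config.ray_style == "weighted":
        for tree in trees:
            _apply_weighted_rays(tree)
    if config.anchor:
        def stype(t):
            return morph.point(t.branch.point_ids[0]).structure_type
        apicals = [t for t in trees if stype(t) == 4]
        axons = [t for t in trees if stype(t) == 2]
        if apicals:
            mid = 0.5 * (apicals[0].theta_start + apicals[0].theta_end)
            _rotate(trees, 90.0 - mid)
        elif axons:
            mid = 0.5 * (axons[0].theta_start + axons[0].theta_end)
            _rotate(trees, 270.0 - mid)
    return trees


# ---------------------------------------------------------------------------
# collapse


def collapse_subtree(
    node: DendrogramNode,
    morph: NeuronMorphology | None = None,
    feature_key: str = "endings",
    spines: Sequence[SpineRecord] | None = None,
) -> DendrogramNode:
    """Replace an internal node's subtree with a summary glyph.

    The node keeps its full angular span; its children are hidden from
    rendering; the glyph label is the formatted feature value (subtree ending
    count by default).
    """
    if node.is_leaf:
        raise LayoutError(f"cannot collapse leaf node {node.key}")
    if feature_key == "endings":
        value: float = node.e_sub
    else:
        if morph is None:
            raise FeatureError(f"collapse by {feature_key!r} requires the morphology")
        value = subtree_feature(node, morph, feature_key, spines)
    node.collapsed = True
    node.collapse_label = f"{int(value)}" if float(value).is_integer() else f"{value:.3g}"
    return node


def expand_subtree(node: DendrogramNode) -> DendrogramNode:
    node.collapsed = False
    node.collapse_label = ""
    return node


# ---------------------------------------------------------------------------
# table export


LAYOUT_TABLE_COLUMNS = (
    "node",
    "parent",
    "neurite",
    "order",
    "theta_start",
    "theta_end",
    "ray_angle",
    "r0",
    "length",
    "endings",
    "collapsed",
)


def layout_table(trees: Sequence[DendrogramNode]) -> str:
    """Dump the laid-out trees as a deterministic TSV (one row per node)."""
    parent_of: dict[int, int] = {}
    for node in iter_nodes(trees):
        for child in node.children:
            parent_of[child.key] = node.key
    rows = ["\t".join(LAYOUT_TABLE_COLUMNS)]
    for node in iter_nodes(trees):
        rows.append(
            "\t".join(
                [
                    str(node.key),
                    str(parent_of.get(node.key, -1)),
                    str(node.branch.neurite_index),
                    str(node.branch.branch_order),
                    f"{node.theta_start:.6f}",
                    f"{node.theta_end:.6f}",
                    f"{node.ray_angle:.6f}",
                    f"{node.r0:.6f}",
                    f"{node.length:.6f}",
                    str(node.e_sub),
                    "1" if node.collapsed else "0",
                ]
            )
        )
    return "\n".join(rows) + "\n"
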