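"""Feature-to-visual-channel encodings and deterministic SVG rendering.

A laid-out dendrogram resolves into a :class:`SceneGraph` — an ordered list
of drawable primitives in world (polar) coordinates: the soma circle, one
colored origin dot per neurite, one radial segment per visible node, one
connecting arc per visible bifurcation, spine markers, and collapse glyphs.
:func:`render_svg` turns the scene into an SVG 1.1 document with an
isotropic world-to-canvas transform and fixed 4-decimal number formatting,
so identical inputs produce identical bytes on any platform.

Encodings follow the scheme the diagrams are built around: a power-law
width channel ``w = clamp(w_ref * (v / v_ref)**gain, w_min, w_max)`` (gain 1
gives widths proportional to the feature, e.g. true neurite calibre; larger
gains exaggerate differences), a colormap channel over a fixed domain, and
three spine modes (per-branch count tags, uniform dots at true arc
positions, or disks whose radius and color encode spine volume, with a
minimum-volume filter applied before placement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from matplotlib import colormaps
from matplotlib.colors import to_hex

from .errors import FeatureError, LayoutError, SpineError
from .io_swc import APICAL_DENDRITE, AXON, BASAL_DENDRITE, NeuronMorphology
from .layout import DendrogramNode, iter_visible
from .morphometry import SpineRecord, branch_geometry


@dataclass(frozen=True)
class FeatureMap:
    """Named scalar feature per branch key."""

    key: str
    values: Mapping[int, float]
    units: str = ""


@dataclass
class WidthChannel:
    feature: str | None = None
    v_ref: float = 1.0
    gain: float = 1.0
    w_ref: float = 1.2
    w_min: float = 0.2
    w_max: float = 12.0

    def __post_init__(self):
        if self.v_ref <= 0:
            raise FeatureError("width reference value v_ref must be > 0")
        if self.gain < 0:
            raise FeatureError("width gain must be >= 0")
        if not (0 < self.w_min <= self.w_ref <= self.w_max):
            raise FeatureError("need 0 < w_min <= w_ref <= w_max")


@dataclass
class ColorChannel:
    feature: str | None = None
    cmap: str = "viridis"
    domain: tuple[float, float] | None = None  # None -> observed range
    clamp: bool = True


class SpineMode(str, Enum):
    NONE = "none"
    COUNT_TAGS = "count_tags"
    UNIFORM_DOTS = "uniform_dots"
    SCALED_DISKS = "scaled_disks"


DEFAULT_ORIGIN_COLORS = {
    AXON: "#ff0000",            # red
    APICAL_DENDRITE: "#0000ff", # blue
    BASAL_DENDRITE: "#00ffff",  # cyan
}


@dataclass
class StyleSpec:
    width: WidthChannel = field(default_factory=WidthChannel)
    color: ColorChannel = field(default_factory=ColorChannel)
    spine_mode: SpineMode = SpineMode.NONE
    spine_min_volume: float = 0.0
    spine_dot_radius: float = 1.5
    spine_disk_radius_range: tuple[float, float] = (1.0, 5.0)
    spine_cmap: str = "plasma"
    soma_radius: float | None = None  # None -> layout root r0
    origin_dot_colors: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_COLORS)
    )
    origin_dot_radius: float = 2.0
    default_stroke: str = "#000000"
    missing_color: str = "#808080"
    full_span_arcs: bool = False
    label_size: float = 6.0

    def __post_init__(self):
        self.spine_mode = SpineMode(self.spine_mode)


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class CirclePrim:
    radius: float
    stroke: str
    stroke_width: float
    node_key: int = -1


@dataclass(frozen=True)
class RadialSegment:
    node_key: int
    angle: float
    r0: float
    r1: float
    width: float
    color: str


@dataclass(frozen=True)
class ArcPrim:
    node_key: int
    radius: float
    theta_start: float
    theta_end: float
    width: float
    color: str


@dataclass(frozen=True)
class DiskMarker:
    node_key: int
    angle: float
    radius_pos: float
    disk_radius: float
    color: str


@dataclass(frozen=True)
class GlyphPrim:
    """Collapse glyph: small triangle pointing outward at the branch tip."""

    node_key: int
    angle: float
    radius_pos: float
    size: float
    color: str


@dataclass(frozen=True)
class TextLabel:
    node_key: int
    angle: float
    radius_pos: float
    text: str
    size: float
    color: str


Primitive = CirclePrim | RadialSegment | ArcPrim | DiskMarker | GlyphPrim | TextLabel


@dataclass
class SceneGraph:
    primitives: list[Primitive] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.primitives:
            name = type(p).__name__
            out[name] = out.get(name, 0) + 1
        return out


# ---------------------------------------------------------------------------
# channels


def width_map(values: FeatureMap, style: StyleSpec) -> dict[int, float]:
    """Power-law width per branch: ``clamp(w_ref * (v/v_ref)**gain)``.

    Gain 0 gives uniform widths; gain 1 is proportional (and scale-
    equivariant: rescaling all values together with ``v_ref`` changes
    nothing).  Non-positive values cannot enter the power law and are mapped
    to the minimum width with a warning.
    """
    ch = style.width
    out: dict[int, float] = {}
    for key, v in values.values.items():
        if v <= 0 and ch.gain > 0:
            warnings.warn(
                f"width feature {values.key!r} is non-positive on branch {key}; "
                "using minimum width",
                stacklevel=2,
            )
            out[key] = ch.w_min
            continue
        w = ch.w_ref * (v / ch.v_ref) ** ch.gain
        out[key] = min(max(w, ch.w_min), ch.w_max)
    return out


def color_map(values: FeatureMap, style: StyleSpec) -> dict[int, str]:
    """Colormap lookup after an affine map of the value into [0, 1] over the
    channel domain; out-of-range values are clamped (default) and missing
    branches get the neutral gray at lookup time in :func:`build_scene`."""
    ch = style.color
    try:
        cmap = colormaps[ch.cmap]
    except KeyError:
        raise FeatureError(f"unknown colormap {ch.cmap!r}") from None
    if ch.domain is not None:
        lo, hi = ch.domain
    elif values.values:
        lo, hi = min(values.values.values()), max(values.values.values())
    else:
        lo, hi = 0.0, 1.0
    if lo >= hi:
        hi = lo + 1.0
    out: dict[int, str] = {}
    for key, v in values.values.items():
        t = (v - lo) / (hi - lo)
        if ch.clamp:
            t = min(max(t, 0.0), 1.0)
        out[key] = to_hex(cmap(t))
    return out


# ---------------------------------------------------------------------------
# spines


def _node_index(trees: Sequence[DendrogramNode]) -> dict[int, DendrogramNode]:
    return {n.key: n for t in trees for n in iter_visible([t])}


def spine_markers(
    spines: Sequence[SpineRecord],
    trees: Sequence[DendrogramNode],
    morph: NeuronMorphology,
    style: StyleSpec,
) -> list[Primitive]:
    """Resolve spine records into marker primitives per the style's mode.

    Records below ``spine_min_volume`` are dropped before placement.  Dots
    and disks sit at radial position ``r0 + length * (arc / path_length)``
    along the branch ray — the true arc position in real-length mode, the
    proportional position otherwise.
    """
    nodes = _node_index(trees)
    survivors = [s for s in spines if s.volume >= style.spine_min_volume]
    for s in survivors:
        if s.branch_key not in nodes:
            raise SpineError(f"spine references unknown or hidden branch {s.branch_key}")
    prims: list[Primitive] = []
    if style.spine_mode is SpineMode.NONE:
        return prims
    if style.spine_mode is SpineMode.COUNT_TAGS:
        counts: dict[int, int] = {}
        for s in survivors:
            counts[s.branch_key] = counts.get(s.branch_key, 0) + 1
        for key in sorted(counts):
            node = nodes[key]
            prims.append(
                TextLabel(
                    key,
                    node.ray_angle,
                    node.r0 + 0.5 * node.length,
                    str(counts[key]),
                    style.label_size,
                    style.default_stroke,
                )
            )
        return prims
    vols = [s.volume for s in survivors]
    vlo, vhi = (min(vols), max(vols)) if vols else (0.0, 1.0)
    rlo, rhi = style.spine_disk_radius_range
    cmap = colormaps[style.spine_cmap]
    for s in survivors:
        node = nodes[s.branch_key]
        path_len = branch_geometry(node.branch, morph).path_length
        if not (0.0 <= s.arc_position <= path_len + 1e-9):
            raise SpineError(
                f"spine at arc {s.arc_position} beyond branch {s.branch_key} "
                f"(length {path_len:.3f})"
            )
        frac = s.arc_position / path_len if path_len > 0 else 0.0
        r = node.r0 + node.length * frac
        if style.spine_mode is SpineMode.UNIFORM_DOTS:
            prims.append(
                DiskMarker(s.branch_key, node.ray_angle, r, style.spine_dot_radius, style.default_stroke)
            )
        else:  # SCALED_DISKS
            t = 0.5 if vhi == vlo else (s.volume - vlo) / (vhi - vlo)
            prims.append(
                DiskMarker(
                    s.branch_key,
                    node.ray_angle,
                    r,
                    rlo + t * (rhi - rlo),
                    to_hex(cmap(t)),
                )
            )
    return prims


# ---------------------------------------------------------------------------
# scene


def build_scene(
    trees: Sequence[DendrogramNode],
    morph: NeuronMorphology,
    style: StyleSpec | None = None,
    features: Mapping[str, FeatureMap] | None = None,
    spines: Sequence[SpineRecord] | None = None,
) -> SceneGraph:
    """Resolve a laid-out dendrogram into drawable primitives.

    Order is stable: soma circle, then per neurite (layout order) an origin
    dot followed by its subtree depth-first (segment, arc, glyph per node),
    then spine markers.
    """
    style = style or StyleSpec()
    if not trees:
        raise LayoutError("empty layout")
    for t in trees:
        if t.theta_start is None or t.r0 is None:
            raise LayoutError("layout incomplete: assign lengths and angles first")

    widths: dict[int, float] = {}
    if style.width.feature and features and style.width.feature in features:
        widths = width_map(features[style.width.feature], style)
    colors: dict[int, str] = {}
    if style.color.feature and features and style.color.feature in features:
        colors = color_map(features[style.color.feature], style)

    def node_width(key: int) -> float:
        if style.width.feature:
            return widths.get(key, style.width.w_min)
        return style.width.w_ref

    def node_color(key: int) -> str:
        if style.color.feature:
            return colors.get(key, style.missing_color)
        return style.default_stroke

    scene = SceneGraph()
    soma_r = style.soma_radius if style.soma_radius is not None else min(t.r0 for t in trees)
    scene.primitives.append(CirclePrim(soma_r, style.default_stroke, 1.0))
    for tree in trees:
        stype = morph.point(tree.branch.point_ids[0]).structure_type
        scene.primitives.append(
            DiskMarker(
                tree.key,
                tree.ray_angle,
                tree.r0,
                style.origin_dot_radius,
                style.origin_dot_colors.get(stype, style.missing_color),
            )
        )
        for node in iter_visible([tree]):
            scene.primitives.append(
                RadialSegment(
                    node.key,
                    node.ray_angle,
                    node.r0,
                    node.r0 + node.length,
                    node_width(node.key),
                    node_color(node.key),
                )
            )
            if node.collapsed:
                tip = node.r0 + node.length
                scene.primitives.append(
                    GlyphPrim(node.key, node.ray_angle, tip, 4.0, node_color(node.key))
                )
                scene.primitives.append(
                    TextLabel(
                        node.key,
                        node.ray_angle,
                        tip + 6.0,
                        node.collapse_label,
                        style.label_size,
                        style.default_stroke,
                    )
                )
            elif node.children:
                if style.full_span_arcs:
                    a, b = node.theta_start, node.theta_end
                else:
                    rays = [c.ray_angle for c in node.children]
                    a, b = min(rays), max(rays)
                scene.primitives.append(
                    ArcPrim(node.key, node.r0 + node.length, a, b, node_width(node.key), node_color(node.key))
                )
    if spines:
        scene.primitives.extend(spine_markers(spines, trees, morph, style))
    return scene


# ---------------------------------------------------------------------------
# SVG


def _fmt(v: float) -> str:
    s = f"{v:.4f}"
    return "0.0000" if s == "-0.0000" else s


def _scene_extent(scene: SceneGraph) -> float:
    r = 1.0
    for p in scene.primitives:
        if isinstance(p, CirclePrim):
            r = max(r, p.radius)
        elif isinstance(p, RadialSegment):
            r = max(r, p.r1)
        elif isinstance(p, ArcPrim):
            r = max(r, p.radius)
        elif isinstance(p, DiskMarker):
            r = max(r, p.radius_pos + p.disk_radius)
        elif isinstance(p, (GlyphPrim, TextLabel)):
            r = max(r, p.radius_pos + 8.0)
    return r


def render_svg(
    scene: SceneGraph,
    size: tuple[float, float] = (800.0, 800.0),
    margin: float = 24.0,
) -> bytes:
    """Render the scene to SVG 1.1 bytes.

    The transform is isotropic (one world-to-pixel scale for both axes), the
    world origin (soma center) maps to the canvas center, and the world y
    axis points up on screen.  All numbers are written with 4 decimals and no
    timestamps or environment-dependent content is emitted, so output is
    byte-deterministic.
    """
    if not scene.primitives:
        raise ValueError("cannot render an empty scene")
    w, h = size
    if w <= 0 or h <= 0:
        raise ValueError(f"canvas size must be positive, got {size}")
    extent = _scene_extent(scene)
    scale = (min(w, h) / 2.0 - margin) / extent
    if scale <= 0:
        raise ValueError("margin leaves no drawable area")
    cx, cy = w / 2.0, h / 2.0

    def xy(angle_deg: float, r: float) -> tuple[float, float]:
        a = math.radians(angle_deg)
        return (cx + scale * r * math.cos(a), cy - scale * r * math.sin(a))

    parts: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
    ]
    for p in scene.primitives:
        if isinstance(p, CirclePrim):
            parts.append(
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(scale * p.radius)}" '
                f'fill="none" stroke="{p.stroke}" stroke-width="{_fmt(p.stroke_width)}"/>'
            )
        elif isinstance(p, RadialSegment):
            x1, y1 = xy(p.angle, p.r0)
            x2, y2 = xy(p.angle, p.r1)
            parts.append(
                f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                f'stroke="{p.color}" stroke-width="{_fmt(p.width)}" stroke-linecap="round"/>'
            )
        elif isinstance(p, ArcPrim):
            if abs(p.theta_end - p.theta_start) < 1e-12:
                continue
            x1, y1 = xy(p.theta_start, p.radius)
            x2, y2 = xy(p.theta_end, p.radius)
            rr = scale * p.radius
            large = 1 if (p.theta_end - p.theta_start) > 180.0 else 0
            # increasing world angle is counterclockwise on screen -> sweep 0
            parts.append(
                f'<path d="M {_fmt(x1)} {_fmt(y1)} A {_fmt(rr)} {_fmt(rr)} 0 {large} 0 '
                f'{_fmt(x2)} {_fmt(y2)}" fill="none" stroke="{p.color}" '
                f'stroke-width="{_fmt(p.width)}" stroke-linecap="round"/>'
            )
        elif isinstance(p, DiskMarker):
            x, y = xy(p.angle, p.radius_pos)
            parts.append(
                f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(scale * p.disk_radius)}" '
                f'fill="{p.color}" stroke="none"/>'
            )
        elif isinstance(p, GlyphPrim):
            x, y = xy(p.angle, p.radius_pos)
            s = scale * p.size
            a = math.radians(p.angle)
            ux, uy = math.cos(a), -math.sin(a)   # outward on screen
            px, py = -uy, ux                      # perpendicular
            tip = (x + s * ux, y + s * uy)
            b1 = (x + 0.6 * s * px, y + 0.6 * s * py)
            b2 = (x - 0.6 * s * px, y - 0.6 * s * py)
            pts = " ".join(f"{_fmt(a_)},{_fmt(b_)}" for a_, b_ in (tip, b1, b2))
            parts.append(f'<polygon points="{pts}" fill="{p.color}" stroke="none"/>')
        elif isinstance(p, TextLabel):
            x, y = xy(p.angle, p.radius_pos)
            # rotate along the ray, flipped on the left half for readability
            rot = -p.angle % 360.0
            if 90.0 < rot <= 270.0:
                rot = (rot + 180.0) % 360.0
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(p.size)}" '
                f'font-family="sans-serif" fill="{p.color}" text-anchor="middle" '
                f'transform="rotate({_fmt(rot)} {_fmt(x)} {_fmt(y)})">{p.text}</text>'
            )
    parts.append("</svg>")
    return ("\n".join(parts) + "\n").encode("utf-8")
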