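"""Parameterized synthetic neuron morphologies with known ground truth.

Trees are grown to an exact per-neurite terminal count by repeatedly
bifurcating the tip of the currently shallowest path, which yields both
balanced and unbalanced shapes across seeds.  Branch trajectories are 3D
polylines with jittered directions, branch lengths are drawn from a
truncated normal, and diameters taper multiplicatively with branch order —
enough geometric structure to exercise length modes, width/color encodings
and mean-diameter orderings, without pretending to be a biophysical growth
model.

Every neurite consumes its own random substream (a child of the spec seed),
so adding or removing a neurite never perturbs the geometry of the others.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_swc import (
    BASAL_DENDRITE,
    ROOT_PARENT,
    SOMA,
    MorphPoint,
    NeuronMorphology,
)

# Default scale parameters: branch lengths of a few tens of microns, five
# tracing samples per branch, ~20% diameter loss per branch order and a
# 2 µm stem — typical orders of magnitude for cortical dendritic arbors.
DEFAULT_SEGMENT_LENGTH = (40.0, 12.0)
DEFAULT_POINTS_PER_BRANCH = 5
DEFAULT_TAPER = 0.8
DEFAULT_ROOT_DIAMETER = 2.0
DEFAULT_SOMA_RADIUS = 8.0


@dataclass(frozen=True)
class TreeSpec:
    """Ground-truth description of one synthetic cell.

    ``neurite_specs`` lists ``(structure_type, ending_count)`` pairs; the
    generated tree has exactly that many terminals per neurite and, being
    strictly binary, ``ending_count - 1`` bifurcations per neurite.
    """

    neurite_specs: tuple[tuple[int, int], ...]
    segment_length: tuple[float, float] = DEFAULT_SEGMENT_LENGTH
    points_per_branch: int = DEFAULT_POINTS_PER_BRANCH
    taper_ratio: float = DEFAULT_TAPER
    root_diameter: float = DEFAULT_ROOT_DIAMETER
    soma_radius: float = DEFAULT_SOMA_RADIUS
    seed: int = 0

    def __post_init__(self):
        if not self.neurite_specs:
            raise ValueError("at least one neurite is required")
        for stype, endings in self.neurite_specs:
            if endings < 1:
                raise ValueError(f"ending count must be >= 1, got {endings}")
        if self.segment_length[0] <= 0 or self.segment_length[1] < 0:
            raise ValueError("segment length mean must be > 0 and sd >= 0")
        if self.points_per_branch < 2:
            raise ValueError("points_per_branch must be >= 2")
        if not (0 < self.taper_ratio <= 1):
            raise ValueError("taper_ratio must be in (0, 1]")
        if self.root_diameter <= 0 or self.soma_radius <= 0:
            raise ValueError("scale parameters must be > 0")

    @property
    def total_endings(self) -> int:
        return sum(e for _, e in self.neurite_specs)

    @property
    def total_bifurcations(self) -> int:
        return sum(e - 1 for _, e in self.neurite_specs)


def tree_spec(endings: Sequence[int], types: Sequence[int] | None = None, **kw) -> TreeSpec:
    """Convenience constructor: ``tree_spec([2, 3, 4, 8])`` makes four basal
    dendrites with those terminal counts."""
    if types is None:
        types = [BASAL_DENDRITE] * len(endings)
    if len(types) != len(endings):
        raise ValueError("types and endings must have equal length")
    return TreeSpec(tuple(zip(types, endings)), **kw)


# ---------------------------------------------------------------------------
# topology


def _grow_topology(n_leaves: int, rng: np.random.Generator) -> dict[int, list[int]]:
    """Binary topology with exactly ``n_leaves`` leaves, as node->children.

    Node 0 is the neurite root.  The tip of the shallowest current path is
    split first; ties are broken randomly so different seeds explore both
    balanced and comb-like shapes.
    """
    children: dict[int, list[int]] = {0: []}
    # heap of (depth, tiebreak, node)
    heap: list[tuple[int, float, int]] = [(0, 0.0, 0)]
    next_id = 1
    leaves = 1
    while leaves < n_leaves:
        depth, _, node = heapq.heappop(heap)
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = [a, b]
        children[a] = []
        children[b] = []
        heapq.heappush(heap, (depth + 1, float(rng.random()), a))
        heapq.heappush(heap, (depth + 1, float(rng.random()), b))
        leaves += 1
    return children


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _branch_length(spec: TreeSpec, rng: np.random.Generator) -> float:
    mean, sd = spec.segment_length
    for _ in range(100):
        val = rng.normal(mean, sd)
        if val > 0:
            return float(val)
    return max(mean, 1e-3)  # pragma: no cover - sd << mean in practice


# ---------------------------------------------------------------------------
# generation


def generate_tree(spec: TreeSpec) -> NeuronMorphology:
    """Generate one morphology matching ``spec`` exactly and deterministically.

    The soma is a single point at the origin; each neurite departs in a
    direction drawn uniformly on the sphere from its own substream.
    """
    root_seq = np.random.SeedSequence(spec.seed)
    points: list[MorphPoint] = [
        MorphPoint(1, SOMA, (0.0, 0.0, 0.0), spec.soma_radius, ROOT_PARENT)
    ]
    next_pid = 2

    for ni, (stype, n_endings) in enumerate(spec.neurite_specs):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(ni,)))
        topo = _grow_topology(n_endings, rng)
        # uniform direction on the sphere for the stem
        v = rng.normal(size=3)
        stem_dir = _unit(v)
        # DFS embedding: (topo node, parent point id, entry position, direction, order)
        stack = [(0, 1, np.zeros(3), stem_dir, 1)]
        while stack:
            node, parent_pid, pos, direction, order = stack.pop()
            radius = 0.5 * spec.root_diameter * spec.taper_ratio ** (order - 1)
            length = _branch_length(spec, rng)
            step = length / spec.points_per_branch
            cur = pos.copy()
            d = direction.copy()
            pid = parent_pid
            for _ in range(spec.points_per_branch):
                d = _unit(d + 0.15 * rng.normal(size=3))  # gentle wiggle
                cur = cur + step * d
                points.append(
                    MorphPoint(next_pid, stype, (float(cur[0]), float(cur[1]), float(cur[2])), radius, pid)
                )
                pid = next_pid
                next_pid += 1
            kids = topo[node]
            for kid in reversed(kids):
                kd = _unit(d + 0.6 * rng.normal(size=3))
                stack.append((kid, pid, cur.copy(), kd, order + 1))
    return NeuronMorphology(points, metadata={"comments": [f"synthetic tree seed={spec.seed}"]})


def generate_population(
    n: int,
    spec_sampler: Callable[[np.random.Generator], TreeSpec] | None = None,
    seed: int = 0,
) -> list[NeuronMorphology]:
    """Generate ``n`` independent trees, reproducible per ``(seed, index)``.

    ``spec_sampler`` receives the per-cell generator and returns the
    :class:`TreeSpec` to use (its ``seed`` field is overridden with a value
    drawn from that stream).  The default sampler draws 3–8 basal dendrites
    with 1–12 endings each.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        if spec_sampler is None:
            n_neurites = int(rng.integers(3, 9))
            endings = [int(rng.integers(1, 13)) for _ in range(n_neurites)]
            spec = tree_spec(endings)
        else:
            spec = spec_sampler(rng)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        spec = TreeSpec(
            spec.neurite_specs,
            spec.segment_length,
            spec.points_per_branch,
            spec.taper_ratio,
            spec.root_diameter,
            spec.soma_radius,
            cell_seed,
        )
        out.append(generate_tree(spec))
    return out


def population_from_counts(
    dendrite_counts: Sequence[int],
    node_counts: Sequence[int],
    seed: int = 0,
) -> list[NeuronMorphology]:
    """Build a population whose per-cell dendrite and bifurcation-node counts
    are prescribed exactly.

    For a strictly binary cell, terminals = bifurcations + neurites, so the
    required total ending count per cell is ``nodes + dendrites``; endings
    are distributed across dendrites as evenly as the remainder allows.
    """
    if len(dendrite_counts) != len(node_counts):
        raise ValueError("dendrite_counts and node_counts must align")
    cells = []
    for i, (nd, nn) in enumerate(zip(dendrite_counts, node_counts)):
        if nd < 1 or nn < 0:
            raise ValueError("counts must be positive")
        total_endings = nd + nn
        base, rem = divmod(total_endings, nd)
        endings = [base + (1 if j < rem else 0) for j in range(nd)]
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        spec = tree_spec(endings, seed=int(rng.integers(0, 2**31 - 1)))
        cells.append(generate_tree(spec))
    return cells
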