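"""Shared fixtures: tiny hand-built morphologies and random-spec helpers."""

import numpy as np
import pytest

from circdendro import MorphPoint, NeuronMorphology, tree_spec
from circdendro.io_swc import BASAL_DENDRITE, ROOT_PARENT, SOMA


def mp(pid, stype, x, y, z, r, parent):
    return MorphPoint(pid, stype, (float(x), float(y), float(z)), float(r), parent)


@pytest.fixture
def straight_neurite():
    """Soma at the origin, one unbranched 100 um dendrite along +x."""
    pts = [mp(1, SOMA, 0, 0, 0, 5.0, ROOT_PARENT)]
    for i in range(1, 11):
        pts.append(mp(i + 1, BASAL_DENDRITE, 10.0 * i, 0, 0, 1.0, i))
    return NeuronMorphology(pts)


@pytest.fixture
def y_neuron():
    """One dendrite bifurcating at radial 20 um; both terminals at radial 60 um."""
    yend = float(np.sqrt(60.0**2 - 20.0**2))
    pts = [
        mp(1, SOMA, 0, 0, 0, 5.0, ROOT_PARENT),
        mp(2, BASAL_DENDRITE, 10, 0, 0, 1.0, 1),
        mp(3, BASAL_DENDRITE, 20, 0, 0, 1.0, 2),       # bifurcation
        mp(4, BASAL_DENDRITE, 40, 0, 0, 1.0, 3),
        mp(5, BASAL_DENDRITE, 60, 0, 0, 1.0, 4),       # terminal A, radial 60
        mp(6, BASAL_DENDRITE, 20, yend / 2, 0, 1.0, 3),
        mp(7, BASAL_DENDRITE, 20, yend, 0, 1.0, 6),    # terminal B, radial 60
    ]
    return NeuronMorphology(pts)


def random_spec(rng: np.random.Generator, max_neurites=6, max_endings=9):
    """A random small TreeSpec with its own derived seed."""
    n = int(rng.integers(1, max_neurites + 1))
    endings = [int(rng.integers(1, max_endings + 1)) for _ in range(n)]
    return tree_spec(endings, seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# independent oracles (deliberately written against the raw parent table,
# not against the package's branch/tree structures)


def oracle_counts(morph):
    """Leaf/branch-point enumeration by scanning the child-count histogram."""
    soma = set(morph.soma_ids)
    child_count = {p.id: 0 for p in morph.points}
    for p in morph.points:
        if p.parent_id != ROOT_PARENT:
            child_count[p.parent_id] += 1
    neurites = sum(
        1
        for p in morph.points
        if p.structure_type != SOMA
        and (p.parent_id == ROOT_PARENT or p.parent_id in soma)
    )
    terminals = sum(
        1
        for p in morph.points
        if p.structure_type != SOMA and child_count[p.id] == 0
    )
    bifurcations = sum(
        max(0, child_count[p.id] - 1)
        for p in morph.points
        if p.id not in soma
    )
    return neurites, terminals, bifurcations


def oracle_sholl(morph, radii):
    """Sphere-segment crossing test over every tracing edge."""
    import math

    cx, cy, cz = morph.soma_centroid

    def dist(p):
        return math.sqrt((p.x - cx) ** 2 + (p.y - cy) ** 2 + (p.z - cz) ** 2)

    counts = []
    for r in radii:
        c = 0
        for p in morph.points:
            if p.structure_type == SOMA or p.parent_id == ROOT_PARENT:
                continue
            d1 = dist(morph.point(p.parent_id))
            d2 = dist(p)
            if min(d1, d2) < r <= max(d1, d2):
                c += 1
        counts.append(c)
    return counts
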