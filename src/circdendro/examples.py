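"""Small example morphologies used in the documentation and golden tests.

Three synthetic cells of increasing complexity: a pyramidal-like cell with
apical/basal dendrites and an axon, a minimal two-dendrite cell, and a
bushier multipolar cell.  They are fixed specs (types, terminal counts,
seeds), so every call regenerates byte-identical SWC.
"""

from __future__ import annotations

from .io_swc import APICAL_DENDRITE, AXON, BASAL_DENDRITE
from .synthetic import TreeSpec, generate_tree


EXAMPLE_SPECS: dict[str, TreeSpec] = {
    "pyramidal": TreeSpec(
        (
            (APICAL_DENDRITE, 5),
            (BASAL_DENDRITE, 3),
            (BASAL_DENDRITE, 2),
            (AXON, 4),
        ),
        seed=101,
    ),
    "bipolar": TreeSpec(
        (
            (BASAL_DENDRITE, 1),
            (BASAL_DENDRITE, 5),
        ),
        seed=202,
    ),
    "multipolar": TreeSpec(
        (
            (APICAL_DENDRITE, 8),
            (BASAL_DENDRITE, 4),
            (BASAL_DENDRITE, 6),
            (BASAL_DENDRITE, 5),
            (AXON, 7),
        ),
        seed=303,
    ),
}


def example_morphology(name: str):
    """Regenerate one of the named example cells."""
    try:
        spec = EXAMPLE_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown example {name!r}; available: {', '.join(EXAMPLE_SPECS)}"
        ) from None
    return generate_tree(spec)
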