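"""Regenerate the frozen golden SVGs under tests/golden/.

Run from the repository root after an intentional change to layout or
rendering, then review the diffs before committing:

    python scripts/regenerate_golden.py
"""

from pathlib import Path

from circdendro.examples import EXAMPLE_SPECS
from circdendro.layout import (
    LayoutConfig,
    assign_angles,
    assign_lengths,
    build_branch_tree,
)
from circdendro.render import build_scene, render_svg
from circdendro.synthetic import generate_tree

GOLDEN_DIR = Path(__file__).resolve().parent.parent / "tests" / "golden"

ANGLE_MODES = ("endm", "ndm")
LENGTH_MODES = ("rlm", "um")


def golden_bytes(name: str, angle_mode: str, length_mode: str) -> bytes:
    morph = generate_tree(EXAMPLE_SPECS[name])
    config = LayoutConfig(angle_mode=angle_mode, length_mode=length_mode)
    trees = build_branch_tree(morph)
    assign_lengths(trees, morph, config)
    trees = assign_angles(trees, config, morph)
    return render_svg(build_scene(trees, morph))


def main() -> None:
    GOLDEN_DIR.mkdir(parents=True, exist_ok=True)
    for name in EXAMPLE_SPECS:
        for am in ANGLE_MODES:
            for lm in LENGTH_MODES:
                path = GOLDEN_DIR / f"{name}_{am}_{lm}.svg"
                path.write_bytes(golden_bytes(name, am, lm))
                print(f"wrote {path}")


if __name__ == "__main__":
    main()
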