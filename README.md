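# circdendro

Circular dendrograms and morphometry for neuron morphologies in SWC format.

3D reconstructions of neurons are hard to read: projections to 2D overlap
branches, hide bifurcations, and depend on whoever picked the viewing
direction. `circdendro` replaces the projection with a *symbolic* 2D
representation: each neurite is straightened into its branch tree and drawn
radially around an idealized soma circle, with bifurcations shown as
connecting arcs. The diagram is computed deterministically from the tracing —
no operator choices — and morphometric features (diameter, length, surface
area, volume, spine density, …) can be encoded onto segment width, color,
length, angular allocation, markers and labels.

The package is aimed at neuroanatomists and neuroinformatics developers who
need unambiguous per-cell overviews — counting dendrites and bifurcation
nodes, comparing arborization patterns, browsing repositories — and at anyone
analysing SWC-format branching structures (the pipeline makes no
neuron-specific assumption beyond optional structure-type labels, so
vascular trees work too).

## The model

A tracing is abstracted into one branch tree per neurite: every fragment
between consecutive bifurcations (or between soma/bifurcation and a terminal
tip) becomes a single node. With `E` terminal endings in total, `N` neurites
and `E_i` endings in neurite `i`, angular space is allocated by one of three
modes:

* **ENDM** (end-node distribution): every ending gets the same wedge
  `β = 360°/E`; neurite `i` spans `α_i = E_i · β`.
* **NDM** (neurite distribution): every neurite gets the same sector
  `α = 360°/N`; within neurite `i` endings get `β_i = α/E_i`.
* **WDM** (weighted distribution): ending wedges proportional to positive
  correction weights `C`, normalized so the total is 360°.

Sibling spans partition their parent's span contiguously, so sectors always
sum to 360° and never overlap. Radial extents come from one of four length
modes: **RLM** (real path length), **RM** (radial node-to-soma distance,
which makes the diagram directly usable for Sholl analysis), **UM** (fixed
unit length `L0`, emphasizing topology), or **LMM** (any branch feature
affinely mapped into a length range). Neurites and siblings can be reordered
by any morphometric key (ending count, node count, total length, mean
diameter, spine density, …), subtrees can be collapsed into a glyph
annotated with a summary value, and dendritic-spine tables can be drawn as
per-branch count tags, position-true dots, or volume-scaled disks with a
minimum-volume filter.

The morphometry module computes everything the diagrams encode: counts
(neurites, bifurcations, terminals), path lengths, radial distances,
length-weighted mean diameters, lateral areas and volumes of conical
frusta, angles between sibling branches, spine densities, Sholl
intersection profiles, population means/SDs, and the PCA projection that
maximizes the projected area of the cell.

## Worked example

Generate a synthetic cell with four dendrites carrying 2, 3, 4 and 8
terminal endings, then measure and render it:

```sh
$ circdendro generate -o demo.swc --endings 2,3,4,8 --seed 1
wrote demo.swc: neurites=4 endings=17 bifurcations=13 points=151

$ circdendro stats demo.swc -o demo_stats.tsv && cat demo_stats.tsv
cell        neurites  bifurcations  endings  total_length_um
demo.swc    4         13            17       1161.448
mean        4.000     13.000        17.000   1161.448
sd_population  0.000  0.000         0.000    0.000
sd_sample      0.000  0.000         0.000    0.000

$ circdendro sholl demo.swc -o demo_sholl.tsv --step 60 && cat demo_sholl.tsv
cell        radius_um  intersections
demo.swc    60         7
demo.swc    120        6
demo.swc    180        1
demo.swc    240        0

$ circdendro render demo.swc -o demo.svg --angle-mode ndm --length-mode um \
      --sort-neurites endings --descending
wrote demo.svg
```

The counts confirm the binary-tree identity `terminals = bifurcations +
neurites` (17 = 13 + 4). The Sholl rows say that spheres of radius 60 and
120 µm around the soma are crossed 7 and 6 times and the arbor ends before
240 µm. The SVG shows the four dendrites in equal 90° sectors (NDM), unit
segment lengths (UM), ordered by arbor complexity — every invocation yields
byte-identical output.

The same pipeline is available as a library:

```python
from circdendro import (load_swc, build_branch_tree, LayoutConfig,
                        assign_lengths, assign_angles, build_scene, render_svg)

morph = load_swc("demo.swc")
trees = build_branch_tree(morph)
config = LayoutConfig(angle_mode="endm", length_mode="rlm")
assign_lengths(trees, morph, config)
trees = assign_angles(trees, config, morph)
svg = render_svg(build_scene(trees, morph))
```

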