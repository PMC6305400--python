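# Methods

## Representation model

A neuron tracing (SWC: points with position, radius, structure type, parent
link) is reduced to one rooted branch tree per neurite. A *branch* is the
maximal fragment between consecutive bifurcations, or between the
soma/bifurcation and a terminal tip; its curvature is discarded and only its
scalar features (path length, mean diameter, area, volume) and its place in
the topology survive into the diagram. Branches always attach at their
parent's last tracing point, so geometry is continuous; a stem branch starts
at the neurite's first traced point.

The diagram places the soma as a circle at the origin, draws one radial
segment per branch, and joins the children of a bifurcation with a circular
arc at the parent's outer radius (by default spanning from the first to the
last child ray; a flag extends it to the node's full angular span). Neurite
origins are marked with dots colored by structure type (axon red, apical
dendrite blue, basal dendrite cyan; unknown types gray and treated as their
own neurite class, which is what lets non-neuronal trees such as vasculature
pass through unchanged).

## Angular allocation

Let `E` be the total number of terminals, `N` the number of neurites, `E_i`
the terminals of neurite `i`.

* **ENDM** — each leaf gets `β = 360/E` degrees; `α_i = E_i β`.
* **NDM** — each neurite gets `α = 360/N`; leaves of neurite `i` get
  `β_i = α/E_i`.
* **WDM** — leaf wedges proportional to positive weights `C`, normalized to
  360°. Weights are interpreted *relatively* (any positive weighting is
  valid); unspecified leaves default to weight 1, so the all-default case
  coincides with ENDM.

Wedges are laid out leaf-by-leaf in depth-first order from `start_angle`
(default 90°, counterclockwise; a flag flips direction). An internal node's
span is the union of its children's; its ray angle is the span midpoint by
default (an endings-weighted centroid is available, `ray_style="weighted"`).
Because sibling spans are contiguous by construction, `Σ α_i = 360°` holds
to floating-point accuracy in every mode, and in exact arithmetic ENDM leaf
spans are all equal (the implementation stays within ~1e-13 of it).

Sibling order inside a neurite defaults to tracing order; both neurites and
siblings can be stable-sorted by any of: ending count, internal-node count,
subtree total length, branch length, branch volume, lateral area,
length-weighted mean diameter, or spine density. Stability means ties
preserve tracing order and repeated sorting is idempotent.

**Anchoring.** Users of pyramidal-cell data conventionally expect the apical
dendrite pointing up and the axon down. With `anchor=True` the neurites are
reordered apical → basal/other → axon and the finished layout is rigidly
rotated so the apical sector's midpoint sits at 90° (with no apical neurite,
the axon's at 270°). A rigid rotation was chosen over per-neurite pinning
because it preserves the conservation and nesting invariants exactly; with
both an apical tree and an axon present, only the apical constraint is
honored exactly.

## Segment lengths

* **RLM** — the node's radial extent *is* its branch path length (the same
  float, not a recomputation), so distances in the diagram are true
  arc-lengths and spine positions can be placed exactly.
* **RM** — the node's outer radius equals the radial (Euclidean) distance of
  the branch's end point from the soma centroid. Concentric circles over an
  RM diagram are exactly the spheres of a Sholl analysis. A curved neurite
  can end a child branch *nearer* the soma than its parent's outer radius;
  the extent is then clamped to `1e-6·L0` with a warning, since a radial
  segment cannot point inward.
* **UM** — every node has length `L0` (default 20 drawing units), which
  emphasizes pure topology (branch order, ending counts).
* **LMM** — any per-branch feature is affinely rescaled from its observed
  range into `(ℓ_min, ℓ_max)` (default 5–50); a constant feature maps to the
  midpoint. Missing values are an error rather than silently defaulted.

Roots start at the soma circle radius (mean soma-sample radius unless
overridden); each child starts at its parent's outer radius.

## Morphometry conventions

* **Soma centroid.** Radial distances and the Sholl center use the mean
  position of soma-labeled points (falling back to tree roots for soma-less
  files). Centroid reduction keeps results independent of how a given
  repository encodes multi-point somas.
* **Binary counting.** A point with `k ≥ 2` children counts as `k − 1`
  bifurcations by default, so a trifurcation equals two binary nodes —
  consistent with the binary-tree idealization under which
  `terminals = bifurcations + neurites`; `binary=False` counts each branch
  point once.
* **Frusta.** Between consecutive samples the neurite is a conical frustum:
  lateral area `π(r1+r2)·slant` with `slant = sqrt(h² + (r1−r2)²)`, volume
  `πh/3·(r1²+r1r2+r2²)`. The mean diameter of a branch is the
  length-weighted mean of per-segment mean diameters.
* **Sholl.** A sphere of radius `r` is crossed by edge `(p, c)` (`c`
  non-soma) when `min(d) < r ≤ max(d)` of the endpoint distances — half-open,
  so a crossing exactly at `r` counts once and a tangent path through two
  edges counts twice only if it genuinely crosses twice. Counts at `r → 0⁺`
  equal the number of stems.
* **Bifurcation angles** are measured between unit vectors from the node to
  each child's first tracing point at a nonzero offset, via
  `atan2(‖u×v‖, u·v)` (numerically robust near 0° and 180°); n-ary nodes
  yield the full pairwise list.
* **Population statistics** report the mean and *both* SD conventions
  (divide by `n` and by `n − 1`), labeled, because published tables are often
  ambiguous about which was used.
* **Maximum-area projection** uses the two leading principal axes of the
  centered point cloud (SVD); collinear clouds raise a degeneracy error
  rather than returning an arbitrary plane.

## Visual channels

Width: `w = clamp(w_ref · (v/v_ref)^gain, w_min, w_max)`. Gain 1 is
proportional and scale-equivariant; gain 0 uniform; larger gains exaggerate
relative differences. Non-positive values cannot enter the power law and map
to the minimum width with a warning. Color: affine map of the value into
[0, 1] over a fixed or observed domain, then a named matplotlib colormap
(default `viridis`, a perceptually uniform sequential map); out-of-range
values clamp and missing branches render neutral gray. Spines: records are
`(branch key, arc position µm, volume µm³)`; after dropping records below
the minimum volume, they render as per-branch count labels, equally sized
dots, or disks whose radius and color encode volume through an affine scale
over the observed volume range (the disk scale is a design choice; no
canonical scale exists). Dots sit at `r0 + ℓ·(arc/path_length)` — the true
position under RLM, the proportional position otherwise.

## Rendering determinism

The SVG writer formats every number with exactly 4 decimals (normalizing
`-0.0000`), emits primitives in a stable depth-first order, and contains no
timestamps or environment-dependent content, so a given scene renders to
identical bytes on any platform. The world-to-canvas transform is isotropic
and the scene is auto-scaled to fit the canvas with a fixed margin.

## Synthetic morphologies

The generator emulates the inputs the method is designed for — multi-neurite
cells with tens of branches, branch lengths of a few tens of microns, and
diameters tapering with branch order — with exact, known ground truth.
Topology is grown by bifurcating the tip of the currently shallowest path
until the requested per-neurite terminal count is reached (random
tie-breaking yields both balanced and comb-like shapes); trajectories are 3D
polylines with direction jitter; branch lengths draw from a truncated normal
(default mean 40 µm, sd 12 µm, 5 samples per branch); radii follow
`(root_diameter/2)·taper^(order−1)` (default 2 µm stems, taper 0.8); the
soma is a single 8 µm point at the origin. Each neurite consumes its own
seeded substream, so adding a neurite never perturbs the others, and
generation is byte-deterministic per seed.

What this does *not* emulate: realistic branch-angle statistics, space
filling and tropism, within-branch tapering, multi-point somas, or tracing
noise (gaps, zero-length segments, duplicated points — though the validator
detects these when present in real files). Passing tests therefore certify
the counting, geometry and layout machinery on well-formed tracings, not
robustness to every artifact found in repository data.

`population_from_counts` builds a cohort with prescribed per-cell dendrite
and bifurcation counts by using the binary identity
`endings = nodes + dendrites` and distributing endings as evenly as possible
across dendrites; it backs the seven-cell validation cohort (dendrite counts
4–8, node counts 12–34) whose count means — 5.714 dendrites and 19.714 nodes
at three decimals — the acceptance script recomputes. The corresponding
printed SDs in the source table (1.285 / 7.561) match neither the
population-SD (1.278 / 7.516) nor the sample-SD (1.380 / 8.118) of those
counts, so only the means serve as checked values; `population_stats`
reports both conventions.

## Numerical and degenerate-input choices

* Zero-length branches (a stem that bifurcates at its first point) get zero
  length/area/volume in the branch table instead of failing whole-cell
  summaries; `branch_geometry` itself raises on a single-point branch, and
  the validator reports such files.
* Angular invariant tolerances in tests: 1e-9 on span sums and partitions,
  1e-12 on ENDM leaf-span uniformity.
* The SWC writer renumbers ids 1..n parent-before-child, emits coordinates
  with 6 decimals and radii with 6 significant digits; written files
  round-trip read→write byte-identically.
* Problem sizes in tests and the acceptance script (trees of up to ~10
  endings per neurite, cohorts of ≤100 cells) were chosen as the smallest
  sizes at which every identity and oracle comparison is non-trivial; all
  quantities checked are exact combinatorial or closed-form values, so size
  does not affect the outcome.

## Known limitations

* No Neurolucida (.dat/.asc) or NeuroML input; SWC only.
* No edge-crossing optimization or label de-overlap; very unbalanced WDM
  weightings can crowd labels.
* Interactive/dynamic dendrograms and multi-panel composites are out of
  scope; the SVG is a static document.
* RM mode's inward-branch clamping is a pragmatic convention, not a claim
  about the right visualization of re-entrant neurites.
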