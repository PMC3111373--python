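# Methods

This note documents the recognition model, its parameters and numerical
choices, what the synthetic generator does and does not emulate, and the
known limits of the approach.

## Problem statement and assumptions

The input is a raster of a *rectangular, left-rooted phylogram*: the root at
the left edge, branches drawn as horizontal lines whose x-extent encodes
branch length, children of a node joined by a single vertical connector,
taxon labels printed to the right of the tips. The drawing must be dark ink
on a light, homogeneous background; the tree must be bi- or multifurcating
(a tree, not a network); internal nodes are bare junctions (no inscribed
circles or boxes); and every tip branch has strictly positive length. Inputs
violating these prerequisites are *rejected with a diagnosis*, never
repaired: the pipeline's failure status names the stage and reason.

## Pipeline

### Binarization

Luminance conversion uses the standard ITU-R 601 weights; alpha is
composited over white; only the first frame of an animated GIF is read. The
foreground test is `intensity < threshold` with the threshold chosen by
Otsu's criterion on the global histogram (a fixed threshold can be forced
via configuration). A global threshold is sufficient because the
prerequisites guarantee a homogeneous light background.

### Thickness normalization

All later tolerances assume lines ~2 px thick, so the raster is rescaled by
`2 / m` where *m* is the measured thickness. *m* is the **median of vertical
foreground run lengths**, sampled at one sample per (column, vertical run)
over columns interior to maximal horizontal runs of at least `min_run = 15`
px. The per-run deduplication makes a k-thick bar contribute one sample per
column rather than k; the median is robust against junction columns, where
the vertical connector inflates the run. On crisp renders the estimate is
exact for thickness 1–8. Downscaling uses center-aligned nearest-neighbor
sampling on the binary raster; upscaling goes through a bilinear gray
resample re-binarized at 128, so no gray halo re-enters the binary domain.
Because the output extent of a k-thick line is exactly `k · (2/k) = 2`
pixels, re-measuring after rescale yields 2.0 under any phase alignment.

### Cleaning

Order: despeckle → remove unattached horizontals → keep largest component →
patch lines and corners. Deletion precedes bridging so patching cannot weld
noise into the tree. Defaults (rescaled-pixel units): `speckle_box = 4`,
`min_horizontal_len = 6`, `max_gap = 3`; 8-connectivity throughout, so
antialiased corner pixels cannot disconnect a junction.

* **Despeckle** deletes blobs whose bounding box fits in `speckle_box²` and
  whose one-pixel surrounding ring is entirely background.
* **Unattached horizontals**: a maximal horizontal run survives if it
  touches a vertical run ≥ 2× line thickness; otherwise it is deleted when
  it is short (< `min_horizontal_len`) or its component contains no such
  vertical at all. This removes dashes, underscores and glyph residue while
  keeping every branch (branches always meet a connector).
* **Largest component**: with labels and support numerals being separate
  ink blobs, the tree is the single largest 8-connected component;
  everything else is deleted. Ties break toward the leftmost-topmost
  bounding box.
* **Patching** bridges collinear run pairs separated by ≤ `max_gap`
  background pixels (row- and column-wise) and closes residual corner
  notches with a `max_gap`-sized box closing. Only background→foreground
  flips occur.

One subtlety connects the deletion stages to patching: a small line break
can sever a whole subtree (or a tip fragment) from the main component
*before* the patcher would have re-attached it. Both deletion stages
therefore judge connectivity on a *virtually gap-bridged* copy of the
raster — a fragment within `max_gap` of the tree counts as attached, while
a genuinely lone dash far from everything is still removed. Without this,
every break on a tip branch would delete the tip.

### Segments and topology

Run-length maps classify pixels: a pixel lies on a horizontal (vertical)
segment when its horizontal (vertical) run exceeds 4× the line thickness.
The 4× threshold is deliberately above the naive 2×: speckle welded onto a
line by patching can form spurious runs up to a few pixels, while true
branches and connectors (bounded below by the minimum drawn branch length
and leaf spacing) are far longer. Junction pixels satisfying both tests are
assigned to the vertical, which splits a parent branch from a collinear
middle child (odd multifurcations draw both at the same row) at their
shared connector. Segments are the 8-connected components of each mask,
taken by bounding box; fragments shorter than `2×thickness + 1` are
discarded as noise.

The segment graph maps onto the tree directly: each vertical is an internal
node, its children the horizontals touching its right side ordered by row
center, its parent the horizontal at its left side. Touch tolerance is 1 px
beyond exact adjacency (junction columns are carved from the horizontal
mask, so a true attachment sits exactly one pixel away). The root is the
unique horizontal with no vertical on its left; if none exists (no root
stem drawn), the leftmost parent-free vertical becomes the root with length
0. Cycles (a connector claimed by two parents, or reached twice) raise a
network error; a connector with fewer than two children raises a malformed-
junction error; leftover unreachable segments are reported as a
disconnected skeleton. Zero-length internal stems collapse implicitly:
stacked connectors form one 8-connected vertical, i.e. one multifurcation.

Branch length is the horizontal segment's x-extent plus the carved junction
columns; on clean renders recovered lengths agree with drawn extents within
±(thickness + 1) px. The outer boundary of every component is traced by
Moore-neighbor following with Jacob's stopping criterion, clockwise from
the topmost-then-leftmost pixel; on 2-px-thick line drawings the contour
visits each boundary pixel exactly once. The contour feeds the SVG overlay
only — topology is read from the segment graph, which is the testable
equivalent of walking the edge contour.

### Labels and OCR

Tip coordinates are mapped back to the *original* image (OCR quality
degrades under rescaling) via the inverse scale factor. Each label box
starts at the first ink column right of the tip end, grows rightward until
a background gap of ≥ max(3, 1.5× the estimated glyph height) — adaptive,
since fixed pixel gaps fail across font sizes — and is clamped vertically
to the midlines toward the neighboring tips, so boxes never overlap. OCR
sits behind a three-binding contract: external tesseract-compatible
subprocess, injected fake (tests), and placeholder `tip_<k>` (no-OCR mode,
fully deterministic and dependency-free). OCR accuracy is logged but never
asserted; it is a property of the engine, not of the recognizer. Labels are
sanitized for Newick: whitespace → underscore, unsafe labels single-quoted
with internal quotes doubled, a lone punctuation character or empty result
→ `tip_<k>`. Underscores in unquoted output labels mean literal
underscores.

### Serialization

Newick, NEXUS (TAXA + TREES blocks) and phyloXML (nested `clade` elements
with `branch_length` children, name omitted when empty) all encode the same
topology, labels and lengths; serialization is deterministic. Branch
lengths are raw rescaled-image pixels by default; an optional normalization
divides by the root-to-farthest-tip pixel depth. The SVG overlay has the
original image's dimensions, one polyline per traced contour (coordinates
mapped back through the scale factor) and one rectangle per label box.

## Synthetic generator

`random_tree` grows a topology by iterative leaf attachment: each step
either splits a random leaf into a cherry or, with probability
`multifurcation_prob` (default 0.15 — published trees are mostly
bifurcating with occasional polytomies), widens the parent into a
multifurcation. Branch lengths are uniform integers in 18–80 px (root stem
12–40 px); labels come from a seeded pronounceable genus_species generator.
Rendering uses 2-px lines, 14-px leaf spacing, 11-px label text and a 20-px
margin by default. With a minimum branch length well above the junction
tolerance and leaf spacing above the glyph height, unrelated lines keep
comfortable clearance by construction (x grows monotonically with depth,
and row spans nest with subtrees) — a property real published phylograms
share.

Degradations are seeded and recorded: Bernoulli speckle (density ≤ 0.01),
line breaks of ≤ 4 px cut at branch interiors, two-digit support numerals
placed near internal nodes with ≥ 4 px clearance (more than `max_gap`, so
patching can never weld them to the tree), and lossy JPEG re-encoding.
The standard degraded condition used in the tests is speckle density 0.001,
two 2-px breaks and numerals on.

What the generator does **not** emulate: scanned-page artifacts (skew,
curvature, bleed-through), fonts other than the bundled one, italic or
two-line labels, dashed/dotted branch styles, and numerals touching
branches. Passing the round-trip suite therefore demonstrates correctness
of the recognition algorithm under the stated image model, not performance
on arbitrary wild figures, where layout diversity dominates the error rate.

## Problem sizes in the test suite

Round-trip suites use 50 renders spanning 2–115 leaves (clean) and 50
degraded renders, plus a dedicated 115-leaf case — 115 leaves being the
upper end of what single-figure phylograms realistically contain. Cross-
format agreement is checked on 20 recognized trees against independent
reference parsers (dendropy for Newick/NEXUS, Bio.Phylo for phyloXML). The
benchmark generator writes 100 image/tree pairs by default.

## Known limitations

* Labels that physically touch branch lines become part of the tree
  component and corrupt the skeleton; prerequisites exclude such figures.
* Two-line or italic tip labels are boxed as a single line; the second line
  is attributed to the nearest tip band.
* Very tight leaf spacing (< ~5 px after rescaling) can merge adjacent
  structures; in practice the 2-px normalization keeps published figures
  well clear of this.
* Branch lengths are reported in pixels; calibrating them against a printed
  scale bar is out of scope.
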