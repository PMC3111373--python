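# phylopix

Optical recognition of phylogenetic tree figures. Given a raster image
(PNG, JPG/JPEG or GIF) of a left-rooted, rectangular phylogram — dark lines
on a light background, horizontal branches, bi- or multifurcating —
`phylopix` recovers the tree topology, branch lengths in pixels and tip
labels, and writes the result as Newick, NEXUS and phyloXML plus a
diagnostic SVG overlay of the traced contours.

Decades of published phylogenies exist only as figures embedded in journal
pages. Turning those figures back into machine-readable trees ("defrosting"
them) is what this package automates, for the common rectangular figure
style. It is aimed at anyone curating legacy phylogenies: comparative
biologists, tree-database maintainers, and methodologists who need large
sets of published topologies.

## How it works

The recognizer is a fixed pipeline over the binary raster:

1. **Decode and binarize** — luminance conversion, then a global threshold
   (Otsu's criterion by default, or a fixed override).
2. **Thickness normalization** — the median vertical thickness *m* of the
   horizontal lines is measured from run lengths, and the image is rescaled
   by 2/*m* so lines are on average 2 px thick; every later tolerance is
   expressed in these units.
3. **Cleaning** — speckle blobs fully ringed by background are deleted;
   horizontal runs not anchored to any vertical line (glyph residue, dashes)
   are deleted; all components except the largest (the tree) are deleted,
   which strips node-support numerals and labels; finally small line breaks
   and corners are patched (gaps ≤ 3 px bridged).
4. **Skeleton → tree** — maximal horizontal and vertical segments are
   extracted from run-length maps. Every vertical segment is an internal
   node; the horizontals leaving its right side (top to bottom) are its
   children, the horizontal arriving at its left side is its parent branch;
   horizontal pixel extent is the branch length. A horizontal whose right
   end touches no vertical is a tip. The Moore-neighbor contour of the tree
   is traced for the SVG overlay.
5. **Labels** — tip positions are mapped back to the original image, a label
   box is grown rightward from each tip end, and the crop is passed to a
   pluggable OCR engine (an external tesseract-compatible program, an
   injected fake for tests, or placeholder `tip_<k>` labels with `--no-ocr`).

A bundled synthetic renderer (`phylopix.synth`) generates random
multifurcating trees, draws them as rectangular phylograms with exactly
known geometry, and can degrade them (speckle noise, line breaks, support
numerals, lossy JPEG re-encoding). It is the ground truth for the entire
test suite: recognition is scored by Robinson–Foulds distance against the
source topology, with leaves matched by their top-to-bottom drawing order.

## Worked example

```sh
# draw a known 5-leaf phylogram, then recognize it
python -c "
from phylopix import random_tree, render_tree
render_tree(random_tree(5, multifurcation_prob=0.0, seed=11)).save('example.png')"
phylopix recognize example.png --no-ocr --out out/
```

prints

```
example.png: recognized 5 leaves
```

and `out/example.nwk` contains

```
(((tip_1:54,tip_2:29):55,tip_3:57):26,(tip_4:28,tip_5:54):68):15;
```

The source tree was `(((A:52,B:27):55,C:55):26,(D:26,E:52):68):15` (labels
abbreviated): the topology is identical and every branch length is within
2 px of the drawn extent — pixel lengths, not time units, since a raster
carries no scale. `out/example.svg` overlays the traced contour and label
boxes on the original image dimensions; `out/example.log` records per-stage
diagnostics (threshold, measured thickness, cleaning counts, segment and
tip counts).

Batch a directory and score a synthetic benchmark:

```sh
phylopix benchmark make --out bench/ -n 100 --seed 1
phylopix benchmark score bench/
phylopix batch images/ --no-ocr --out results/
```

Exit codes: 0 success, 2 recognition failure, 3 configuration error.

## Scope and limits

The recognizer deliberately rejects what it cannot interpret instead of
guessing: radial/polar/sloped layouts, light-on-dark or shaded images,
networks, and zero-length tip branches all yield a failed status naming the
stage and reason. See `docs/methods.md` for the method's assumptions,
parameters and known limitations.
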