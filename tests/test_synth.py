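"""Ground-truth generator: random trees, renders, degradations, benchmark."""

import numpy as np
import pytest
from scipy import ndimage

from phylopix.cleaning import EIGHT
from phylopix.errors import ParameterError
from phylopix.synth import (
    DegradationSpec,
    RenderSpec,
    degrade,
    make_benchmark,
    random_tree,
    render_tree,
)


class TestRandomTree:
    def test_two_leaves_is_a_cherry(self):
        root = random_tree(2, seed=0)
        assert len(root.children) == 2
        assert all(c.is_leaf for c in root.children)

    def test_bifurcating_internal_node_count(self):
        root = random_tree(5, multifurcation_prob=0.0, seed=3)
        internals = [n for n in root.walk() if not n.is_leaf]
        assert len(internals) == 4  # n-1 for a rooted binary tree

    def test_same_seed_reproduces(self):
        from phylopix.serialize import to_newick
        from phylopix.tree import RecognizedTree

        a = random_tree(12, multifurcation_prob=0.3, seed=9)
        b = random_tree(12, multifurcation_prob=0.3, seed=9)
        assert to_newick(RecognizedTree(root=a)) == to_newick(RecognizedTree(root=b))

    def test_multifurcations_appear(self):
        root = random_tree(30, multifurcation_prob=0.8, seed=1)
        assert any(len(n.children) >= 3 for n in root.walk() if not n.is_leaf)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ParameterError):
            random_tree(1)

    def test_labels_unique_and_positive_lengths(self):
        root = random_tree(40, seed=5)
        labels = [l.label for l in root.leaves()]
        assert len(set(labels)) == 40
        assert all(l.branch_length >= 1 for l in root.leaves())


class TestRenderTree:
    def test_cherry_line_list(self):
        root = random_tree(2, seed=0)
        truth = render_tree(root)
        horizontals = [l for l in truth.line_list if l.orientation == "horizontal"]
        verticals = [l for l in truth.line_list if l.orientation == "vertical"]
        assert len(horizontals) == 3 and len(verticals) == 1
        for leaf, line in zip(truth.root.leaves(), horizontals[1:]):
            assert line.x1 - line.x0 == leaf.branch_length + truth.spec.line_thickness - 1

    def test_single_component_without_labels(self):
        truth = render_tree(random_tree(9, seed=2), RenderSpec(draw_labels=False))
        _, n = ndimage.label(truth.image < 128, structure=EIGHT)
        assert n == 1

    def test_prerequisites_hold_mechanically(self):
        truth = render_tree(random_tree(14, multifurcation_prob=0.3, seed=6))
        # dark foreground on light background
        assert truth.image.min() == 0 and truth.image.max() == 255
        # leftmost foreground is the root stem
        mask = truth.image < 128
        leftmost_col = int(mask.any(axis=0).argmax())
        root_line = truth.line_list[0]
        assert root_line.role == "root" and root_line.x0 == leftmost_col
        # all tips drawn with positive horizontal extent
        assert all(l.branch_length >= 1 for l in truth.root.leaves())
        # tip label boxes pairwise disjoint
        boxes = truth.tip_boxes
        for a, b in zip(boxes, boxes[1:]):
            assert a[3] < b[1]

    def test_height_formula(self):
        spec = RenderSpec(leaf_spacing=14, margin=20)
        truth = render_tree(random_tree(115, seed=7), spec)
        assert truth.image.shape[0] == 115 * 14 + 2 * 20

    def test_oversized_layout_rejected(self):
        with pytest.raises(ParameterError):
            render_tree(random_tree(40, seed=1), RenderSpec(max_dim=300))


class TestDegrade:
    def test_identity_degradation_is_noop(self):
        truth = render_tree(random_tree(6, seed=3))
        out = degrade(truth, DegradationSpec(seed=1))
        assert (out.image == truth.image).all()

    def test_gaps_reproducible_and_counted(self):
        truth = render_tree(random_tree(8, seed=4))
        deg = DegradationSpec(gap_count=3, gap_width=2, seed=11)
        a, b = degrade(truth, deg), degrade(truth, deg)
        assert (a.image == b.image).all()
        diff = (a.image != truth.image)
        _, n = ndimage.label(diff, structure=EIGHT)
        assert n == 3

    def test_speckle_count_within_binomial_band(self):
        # Mean flipped-pixel count over 100 seeds vs the binomial expectation
        density = 0.002
        truth = render_tree(random_tree(12, seed=1))
        n_bg = int((truth.image != 0).sum())  # a flip is visible iff not already ink
        counts = []
        for seed in range(100):
            out = degrade(truth, DegradationSpec(speckle_density=density, seed=seed))
            counts.append(int((out.image != truth.image).sum()))
        expect = n_bg * density
        sem = np.sqrt(n_bg * density * (1 - density)) / np.sqrt(100)
        assert abs(np.mean(counts) - expect) <= 3 * sem

    def test_numerals_never_touch_tree(self):
        truth = render_tree(random_tree(10, seed=9))
        out = degrade(truth, DegradationSpec(node_numerals=True, seed=2))
        assert out.numeral_pixel_sets
        line_mask = np.zeros_like(truth.image, dtype=bool)
        for ln in truth.line_list:
            line_mask[ln.y0 : ln.y1 + 1, ln.x0 : ln.x1 + 1] = True
        grown = ndimage.binary_dilation(line_mask, structure=EIGHT, iterations=3)
        for coords in out.numeral_pixel_sets:
            assert not grown[coords[:, 0], coords[:, 1]].any()

    def test_jpeg_reencode_keeps_recognizability(self):
        from phylopix.compare import topology_match
        from phylopix.pipeline import recognize_gray

        truth = render_tree(random_tree(12, seed=15))
        out = degrade(truth, DegradationSpec(jpeg_quality=75, seed=3))
        assert (out.image != truth.image).any()
        res = recognize_gray(out.image)
        assert res.ok and topology_match(truth.root, res.tree)


class TestMakeBenchmark:
    def test_unit_batch(self, tmp_path):
        manifest = make_benchmark(tmp_path / "bench", n_images=1, seed=4)
        files = sorted(p.name for p in (tmp_path / "bench").iterdir())
        assert files == ["manifest.tsv", "tree_000.nwk", "tree_000.png"]
        rows = manifest.read_text().splitlines()
        assert len(rows) == 2 and rows[0].startswith("filename\t")

    def test_manifest_deterministic(self, tmp_path):
        m1 = make_benchmark(tmp_path / "a", n_images=3, seed=9)
        m2 = make_benchmark(tmp_path / "b", n_images=3, seed=9)
        assert m1.read_text() == m2.read_text()
        img1 = (tmp_path / "a" / "tree_001.png").read_bytes()
        img2 = (tmp_path / "b" / "tree_001.png").read_bytes()
        assert img1 == img2

    def test_leaf_counts_within_range(self, tmp_path):
        manifest = make_benchmark(
            tmp_path / "c", n_images=5, leaf_range=(4, 9), seed=1
        )
        for row in manifest.read_text().splitlines()[1:]:
            n = int(row.split("\t")[1])
            assert 4 <= n <= 9
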