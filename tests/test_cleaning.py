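"""Speckle/glyph removal and line patching."""

import numpy as np
import pytest

from phylopix.cleaning import (
    CleaningConfig,
    clean,
    despeckle,
    patch_lines_and_corners,
    remove_nonmain_components,
    remove_unattached_horizontals,
)
from phylopix.errors import RecognitionError
from phylopix.pipeline import recognize_gray
from phylopix.compare import topology_match
from phylopix.synth import DegradationSpec, degrade, random_tree, render_tree


class TestDespeckle:
    def test_isolated_pixel_removed(self, blank):
        mask = blank()
        mask[10, 10] = True
        out, n = despeckle(mask, 3)
        assert n == 1 and not out.any()

    def test_long_bar_untouched(self, blank):
        mask = blank()
        mask[10:12, 5:105] = True
        out, n = despeckle(mask, 3)
        assert n == 0 and (out == mask).all()

    def test_small_blob_removed_bar_kept(self, blank):
        mask = blank(80, 120)
        mask[5:7, 5:7] = True        # 2x2 blob, fully ringed by background
        mask[40:42, 10:60] = True    # 50x2 bar
        out, n = despeckle(mask, 3)
        assert n == 1
        assert not out[5:7, 5:7].any()
        assert out[40:42, 10:60].all()

    def test_foreground_in_ring_blocks_removal(self, blank):
        mask = blank()
        # diagonal 2-px blob; the stray pixel sits inside its bounding-box
        # ring but is not 8-adjacent, so it is a separate component
        mask[10, 10] = mask[11, 11] = True
        mask[9, 12] = True
        out, n = despeckle(mask, 3)
        assert out[10, 10] and out[11, 11]  # dirty ring: blob kept
        assert not out[9, 12] and n == 1    # the stray pixel itself is speckle

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(3)
        mask = rng.random((60, 80)) < 0.02
        once, _ = despeckle(mask, 4)
        twice, n2 = despeckle(once, 4)
        assert n2 == 0 and (once == twice).all()
        assert once.sum() <= mask.sum()


class TestRemoveUnattachedHorizontals:
    def test_lone_dash_removed(self, blank):
        mask = blank()
        mask[10:12, 20:50] = True
        out, n = remove_unattached_horizontals(mask, CleaningConfig())
        assert not out.any() and n > 0

    def test_l_shape_kept(self, blank):
        mask = blank()
        mask[10:12, 10:40] = True
        mask[10:40, 10:12] = True
        out, n = remove_unattached_horizontals(mask, CleaningConfig())
        assert n == 0 and (out == mask).all()

    def test_injected_dashes_removed_and_topology_survives(self):
        from phylopix.synth import RenderSpec

        root = random_tree(6, seed=2)

        def with_dashes(truth):
            img = truth.image.copy()
            h = img.shape[0]
            for k in range(3):  # three 8-px dashes in the bottom margin
                img[h - 8 : h - 6, 10 + 30 * k : 18 + 30 * k] = 0
            return img

        bare = render_tree(root, RenderSpec(draw_labels=False))
        out, n = remove_unattached_horizontals(
            with_dashes(bare) < 128, CleaningConfig()
        )
        assert n == 3  # one removal per dash blob
        assert not out[bare.image.shape[0] - 8 :, :].any()

        labeled = render_tree(root)
        res = recognize_gray(with_dashes(labeled))
        assert res.ok and topology_match(labeled.root, res.tree)


class TestRemoveNonmainComponents:
    def test_numeral_blob_removed(self, blank):
        mask = blank(120, 200)
        mask[50:52, 10:180] = True
        mask[50:110, 10:12] = True
        mask[10:17, 100:106] = True  # glyph-sized blob
        out, n = remove_nonmain_components(mask, CleaningConfig())
        assert n == 1
        assert not out[10:17, 100:106].any()
        assert out[50:52, 10:180].all()

    def test_single_component_unchanged(self, blank):
        mask = blank()
        mask[10:12, 5:60] = True
        out, n = remove_nonmain_components(mask, CleaningConfig())
        assert n == 0 and (out == mask).all()

    def test_empty_raster_errors(self, blank):
        with pytest.raises(RecognitionError):
            remove_nonmain_components(blank(), CleaningConfig())

    def test_rendered_numerals_vanish_exactly(self):
        root = random_tree(8, seed=13)
        truth = render_tree(root)
        deg = degrade(truth, DegradationSpec(node_numerals=True, seed=5))
        assert deg.numeral_pixel_sets, "no numerals placed"
        cleaned, _ = clean(deg.image < 128)
        for coords in deg.numeral_pixel_sets:
            assert not cleaned[coords[:, 0], coords[:, 1]].any()
        res = recognize_gray(deg.image)
        assert res.ok and topology_match(truth.root, res.tree)


class TestPatchLinesAndCorners:
    def test_small_gap_bridged(self, blank):
        mask = blank()
        mask[10:12, 5:50] = True
        mask[10:12, 52:105] = True  # 2-px gap at col 50
        out, report = patch_lines_and_corners(mask, CleaningConfig())
        assert report.gaps_patched >= 1
        assert out[10:12, 5:105].all()

    def test_wide_gap_left_alone(self, blank):
        mask = blank()
        mask[10:12, 5:45] = True
        mask[10:12, 55:105] = True  # 10-px gap
        out, _ = patch_lines_and_corners(mask, CleaningConfig())
        assert not out[10:12, 45:55].any()

    def test_only_background_becomes_foreground(self):
        rng = np.random.default_rng(9)
        mask = rng.random((50, 70)) < 0.1
        out, _ = patch_lines_and_corners(mask, CleaningConfig())
        assert (out | mask == out).all()  # monotone increasing
        assert out[mask].all()

    def test_gap_knocked_into_each_branch_recovers(self):
        root = random_tree(7, seed=21)
        truth = render_tree(root)
        deg = degrade(
            truth, DegradationSpec(gap_count=5, gap_width=2, seed=8)
        )
        res = recognize_gray(deg.image)
        assert res.ok and topology_match(truth.root, res.tree)


class TestFullChain:
    def test_clean_render_tree_pixels_untouched(self, five_leaf_truth):
        mask = five_leaf_truth.image < 128
        cleaned, report = clean(mask)
        # the labels disappear but every drawn line pixel survives
        for ln in five_leaf_truth.line_list:
            assert cleaned[ln.y0 : ln.y1 + 1, ln.x0 : ln.x1 + 1].all()
        assert report.components_removed > 0  # the label glyphs

    def test_deletion_stages_monotone_decreasing(self):
        rng = np.random.default_rng(17)
        mask = rng.random((80, 100)) < 0.05
        cfg = CleaningConfig()
        a, _ = despeckle(mask, cfg.speckle_box)
        b, _ = remove_unattached_horizontals(a, cfg)
        assert a.sum() <= mask.sum() >= 0
        assert b.sum() <= a.sum()
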