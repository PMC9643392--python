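"""Tile grids, block pooling, quantization brackets, heatmaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleoscore.detection import DetectionSet, NoTumorError, detect_cells
from pleoscore.slide import (
    BlockScoreMap,
    QuantizationScheme,
    quantize,
    render_heatmap,
    score_slide,
    severity_to_rgb,
    tile_grid,
)
from pleoscore.synthetic import generate_slide

from conftest import StubNet


def _full_tumor_dets(size, step=16):
    xs, ys = np.meshgrid(np.arange(step // 2, size, step),
                         np.arange(step // 2, size, step))
    n = xs.size
    return DetectionSet(xs.ravel().astype(float), ys.ravel().astype(float),
                        np.array(["tumor"] * n, object), np.ones(n),
                        (size, size), 1.0)


class TestTileGrid:
    def test_single_tile(self):
        grid = tile_grid((512, 512), 512, 448)
        assert list(grid.tiles()) == [(0, 0)]

    def test_stride_arithmetic(self):
        grid = tile_grid((576, 512), 512, 448)
        assert list(grid.xs) == [0, 64]
        assert list(grid.ys) == [0]

    def test_coverage_completion_shifted_tile(self):
        grid = tile_grid((600, 512), 512, 448)
        assert list(grid.xs) == [0, 64, 88]   # last tile ends at 600

    def test_full_coverage(self):
        grid = tile_grid((600, 520), 512, 448)
        covered = np.zeros((520, 600), bool)
        for x0, y0 in grid.tiles():
            covered[y0:y0 + 512, x0:x0 + 512] = True
        assert covered.all()

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            tile_grid((512, 512), 512, 512)


class TestScoreSlide:
    def test_conservation_constant_model(self):
        """Constant tile scores pool to the same constant everywhere."""
        net = StubNet(2.0, input_size=512)
        img = np.zeros((1024, 1024, 3), np.uint8)
        dets = _full_tumor_dets(1024)
        bmap, slide_score = score_slide(net, img, dets, tile_size=512,
                                        overlap=448, block=64)
        assert slide_score == 2.0
        scored = bmap.scores[bmap.defined]
        assert (scored == 2.0).all()

    def test_interior_block_covering_count(self):
        """Tile 512 / overlap 448: interior blocks see (512/64)^2 tiles."""
        net = StubNet(2.0, input_size=512)
        img = np.zeros((1024, 1024, 3), np.uint8)
        bmap, _ = score_slide(net, img, _full_tumor_dets(1024),
                              tile_size=512, overlap=448, block=64)
        assert bmap.counts[8, 8] == 64

    def test_block_scores_bounded_by_tile_scores(self, desk_model):
        slide = generate_slide([((8, 8, 120, 248), "invasive", 1.0),
                                ((136, 8, 248, 248), "invasive", 3.0)],
                               256, 1.0, seed=5)
        dets = detect_cells(slide.image, "oracle", slide.nuclei)
        bmap, score = score_slide(desk_model.net_, slide.image, dets,
                                  tile_size=64, overlap=48, block=16)
        scored = bmap.scores[bmap.defined]
        assert scored.min() >= 1.0 and scored.max() <= 3.0
        assert 1.0 <= score <= 3.0

    def test_two_region_separation(self, desk_model):
        """Blocks over an s=3 region score >= 1 higher than over s=1."""
        slide = generate_slide([((8, 8, 120, 248), "invasive", 1.0),
                                ((136, 8, 248, 248), "invasive", 3.0)],
                               256, 1.0, seed=6)
        dets = detect_cells(slide.image, "oracle", slide.nuclei)
        bmap, _ = score_slide(desk_model.net_, slide.image, dets,
                              tile_size=64, overlap=48, block=16)
        bx = np.arange(bmap.scores.shape[1]) * 16
        left = bmap.defined & (bx[None, :] + 16 <= 120)
        right = bmap.defined & (bx[None, :] >= 136)
        lo = bmap.scores[left].mean()
        hi = bmap.scores[right].mean()
        assert hi - lo >= 1.0 and lo < hi

    def test_no_tumor_errors(self):
        net = StubNet(2.0, input_size=64)
        img = np.zeros((128, 128, 3), np.uint8)
        dets = DetectionSet(np.array([64.0]), np.array([64.0]),
                            np.array(["normal"], object), np.ones(1),
                            (128, 128), 1.0)
        with pytest.raises(NoTumorError):
            score_slide(net, img, dets, tile_size=64, overlap=48, block=16)

    def test_benign_inclusion_pulls_score_down(self, desk_model):
        """A large benign region lowers the slide score only when the
        tumor mask erroneously includes it."""
        layout_tumor = [((136, 8, 248, 248), "invasive", 3.0)]
        layout_mixed = [((8, 8, 120, 248), "benign", 1.0)] + layout_tumor
        slide = generate_slide(layout_mixed, 256, 1.0, seed=7)
        dets = detect_cells(slide.image, "oracle", slide.nuclei)
        net = desk_model.net_
        _, correct = score_slide(net, slide.image, dets,
                                 tile_size=64, overlap=48, block=16)
        # corrupt the detector: benign epithelium mislabeled as tumor
        bad = DetectionSet(dets.x, dets.y,
                           np.array(["tumor"] * len(dets), object),
                           dets.confidence, dets.image_size, dets.spacing)
        _, polluted = score_slide(net, slide.image, bad,
                                  tile_size=64, overlap=48, block=16)
        assert polluted < correct - 0.3
        # excluding the benign area leaves the tumor-only score intact
        tumor_only = generate_slide(layout_tumor, 256, 1.0, seed=7)
        d2 = detect_cells(tumor_only.image, "oracle", tumor_only.nuclei)
        _, ref = score_slide(net, tumor_only.image, d2,
                             tile_size=64, overlap=48, block=16)
        assert correct == pytest.approx(ref, abs=0.15)

    def test_block_map_invariants(self):
        with pytest.raises(ValueError):
            BlockScoreMap(np.array([[0.0, np.nan]]),
                          np.array([[0, 1]]),
                          np.ones((1, 2), bool), 16, (32, 16))


class TestQuantize:
    def test_worked_examples(self):
        assert quantize(1.50) == 1      # [1, 5/3)
        assert quantize(2.00) == 2      # [5/3, 7/3)
        assert quantize(3.00) == 3      # closed upper endpoint

    def test_printed_boundary_two_decimals(self):
        edges = QuantizationScheme(3).edges
        assert round(float(edges[2]), 2) == 2.33
        assert round(float(edges[1]), 2) == 1.67   # exact 5/3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize(3.01)
        with pytest.raises(ValueError):
            quantize(0.99)

    @pytest.mark.parametrize("p", [2, 3, 5])
    def test_monotone_and_surjective(self, p):
        scores = np.linspace(1, 3, 301)
        cats = quantize(scores, p)
        assert (np.diff(cats) >= 0).all()
        assert set(cats) == set(range(1, p + 1))

    @given(st.floats(1.0, 3.0), st.integers(1, 8))
    @settings(max_examples=200, deadline=None)
    def test_bracket_membership(self, score, p):
        scheme = QuantizationScheme(p)
        cat = scheme.category(score)
        edges = scheme.edges
        assert 1 <= cat <= p
        assert edges[cat - 1] - 1e-9 <= score <= edges[cat] + 1e-9


class TestHeatmap:
    def _bmap(self, scores):
        scores = np.asarray(scores, float)
        counts = np.where(np.isnan(scores), 0, 1).astype(int)
        return BlockScoreMap(scores, counts, counts > 0, 4,
                             (scores.shape[1] * 4, scores.shape[0] * 4))

    def test_anchor_colors(self):
        rgb = severity_to_rgb(np.array([1.0, 2.0, 3.0]))
        assert rgb.tolist() == [[0, 255, 0], [255, 255, 0], [255, 0, 0]]

    def test_uniform_yellow(self):
        img = render_heatmap(self._bmap([[2.0, 2.0]]), upscale=False)
        assert (img == [255, 255, 0]).all()

    def test_missing_blocks_neutral(self):
        img = render_heatmap(self._bmap([[1.0, np.nan]]), upscale=False)
        assert img[0, 0].tolist() == [0, 255, 0]
        assert img[0, 1].tolist() == [235, 235, 235]

    def test_monotone_ramp_hue(self):
        ramp = np.linspace(1, 3, 21)
        rgb = severity_to_rgb(ramp).astype(int)
        assert (np.diff(rgb[:, 0]) >= 0).all()   # red rises
        assert (np.diff(rgb[:, 1]) <= 0).all() or \
            (rgb[:11, 1] == 255).all()           # green holds then falls
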