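"""Whole-slide scoring: overlapping tiles, block pooling, quantization.

A slide is processed as overlapping fixed-size tiles (default 512 px with
448 px overlap, i.e. stride 64).  Each tile intersecting detected tumor
is scored once by the patch regressor; every block (default 64 px)
averages the scores of all tiles covering it, and the slide score is the
unweighted mean over tumor-masked blocks.  Continuous scores are
quantized into ``p`` even brackets of [1, 3] for comparison with the
traditional three-tier grading, and block maps render as a
green-yellow-red severity heatmap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .config import SEVERITY_MAX, SEVERITY_MIN
from .detection import DetectionSet, NoTumorError, tumor_block_mask
from .regressor import crop_patch, predict_batch

__all__ = [
    "TileGrid",
    "BlockScoreMap",
    "QuantizationScheme",
    "tile_grid",
    "score_slide",
    "quantize",
    "render_heatmap",
]


@dataclass
class TileGrid:
    """Half-open tile origins covering an image completely."""

    xs: np.ndarray          # tile origin x values
    ys: np.ndarray
    tile_size: int
    overlap: int
    image_size: tuple[int, int]

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap

    def tiles(self):
        """Iterate (x0, y0) origins, row-major."""
        for y0 in self.ys:
            for x0 in self.xs:
                yield int(x0), int(y0)

    def __len__(self) -> int:
        return len(self.xs) * len(self.ys)


def _axis_origins(extent: int, tile: int, stride: int) -> np.ndarray:
    """Origins at stride multiples plus a final shifted tile if needed."""
    last = extent - tile
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)   # coverage-completion: clamp to image edge
    return np.asarray(origins, int)


def tile_grid(image_size, tile_size: int = 512,
              overlap: int = 448) -> TileGrid:
    """Overlapping tile grid with coverage-completion at the far edges.

    ``image_size`` is (width, height).  Origins run at multiples of
    ``stride = tile_size - overlap``; when the last stride step does not
    land flush with the image edge an extra tile shifted to end exactly
    at the edge is appended (no padding, no partial tiles).
    """
    if not (0 <= overlap < tile_size):
        raise ValueError("need 0 <= overlap < tile_size")
    w, h = int(image_size[0]), int(image_size[1])
    if tile_size > w or tile_size > h:
        raise ValueError("tile larger than image")
    stride = tile_size - overlap
    return TileGrid(_axis_origins(w, tile_size, stride),
                    _axis_origins(h, tile_size, stride),
                    tile_size, overlap, (w, h))


@dataclass
class BlockScoreMap:
    """Per-block pooled scores; blocks without any covering tile are NaN."""

    scores: np.ndarray       # (nby, nbx) float, NaN = missing
    counts: np.ndarray       # contributing-tile count per block
    tumor_mask: np.ndarray   # (nby, nbx) bool
    block_size: int
    image_size: tuple[int, int]

    def __post_init__(self):
        have = self.counts > 0
        if np.isnan(self.scores[have]).any():
            raise ValueError("covered blocks must have scores")
        if not np.isnan(self.scores[~have]).all():
            raise ValueError("blocks with count 0 must be missing (NaN)")

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self):
        import pandas as pd
        nby, nbx = self.scores.shape
        by, bx = np.mgrid[0:nby, 0:nbx]
        return pd.DataFrame({
            "block_x": bx.ravel(), "block_y": by.ravel(),
            "score": self.scores.ravel(),
            "n_tiles": self.counts.ravel(),
            "is_tumor": self.tumor_mask.ravel(),
        })


def score_slide(
    model,
    slide_image: np.ndarray,
    dets: DetectionSet,
    tile_size: int | None = None,
    overlap: int | None = None,
    block: int = 64,
    min_tumor_count: int = 1,
    tumor_blocks_only: bool = True,
    batch: int = 64,
) -> tuple[BlockScoreMap, float]:
    """Score a slide through the overlapping-tile / block-pooling scheme.

    Each tile that intersects the tumor block mask is scored once by the
    patch regressor; a block's score is the unweighted mean of all scored
    tiles covering it, and the slide score is the unweighted mean over
    tumor-masked blocks with at least one contributing tile (set
    ``tumor_blocks_only=False`` to average all scored blocks instead).
    Raises :class:`NoTumorError` when no tumor blocks exist — a slide
    without detected tumor has no fabricated score.
    """
    cfg = model.config
    tile_size = cfg.input_size if tile_size is None else int(tile_size)
    if overlap is None:
        # default geometry: stride = block, the production 512/448 ratio
        overlap = tile_size - block if tile_size > block else 0
    h, w = slide_image.shape[:2]
    grid = tile_grid((w, h), tile_size, overlap)
    mask = tumor_block_mask(dets, block, min_tumor_count)
    nby, nbx = mask.shape
    if not mask.any():
        raise NoTumorError("no tumor blocks on this slide")

    # pick tiles intersecting >= 1 tumor block
    origins = []
    for x0, y0 in grid.tiles():
        bx0, by0 = x0 // block, y0 // block
        bx1 = int(np.ceil((x0 + tile_size) / block))
        by1 = int(np.ceil((y0 + tile_size) / block))
        if mask[by0:by1, bx0:bx1].any():
            origins.append((x0, y0))

    acc = np.zeros((nby, nbx))
    counts = np.zeros((nby, nbx), int)
    for i in range(0, len(origins), batch):
        chunk = origins[i:i + batch]
        tiles = np.stack([
            slide_image[y0:y0 + tile_size, x0:x0 + tile_size]
            for x0, y0 in chunk])
        preds = predict_batch(model, tiles, batch=batch)
        for (x0, y0), score in zip(chunk, preds):
            bx0, by0 = x0 // block, y0 // block
            bx1 = int(np.ceil((x0 + tile_size) / block))
            by1 = int(np.ceil((y0 + tile_size) / block))
            acc[by0:by1, bx0:bx1] += score
            counts[by0:by1, bx0:bx1] += 1

    scores = np.full((nby, nbx), np.nan)
    have = counts > 0
    scores[have] = acc[have] / counts[have]
    bmap = BlockScoreMap(scores, counts, mask, block, (w, h))
    pool = mask & have if tumor_blocks_only else have
    slide_score = float(scores[pool].mean())
    return bmap, slide_score


# ---------------------------------------------------------------------------
# quantization


@dataclass(frozen=True)
class QuantizationScheme:
    """Even partition of [1, 3] into ``p`` integer-labeled brackets.

    Bracket edges sit at ``1 + 2k/p``; brackets are left-closed /
    right-open with the final bracket right-closed, so for p = 3 the
    exact edges are 5/3 and 7/3 (printed as 1.66 / 2.33 at two decimals):
    [1, 5/3) -> 1, [5/3, 7/3) -> 2, [7/3, 3] -> 3.
    """

    p: int = 3

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")

    @property
    def edges(self) -> np.ndarray:
        k = np.arange(self.p + 1)
        return SEVERITY_MIN + (SEVERITY_MAX - SEVERITY_MIN) * k / self.p

    def category(self, score: float) -> int:
        if not (SEVERITY_MIN <= score <= SEVERITY_MAX):
            raise ValueError(f"score {score} outside [1, 3]; clamp upstream")
        cat = int(np.floor((score - SEVERITY_MIN)
                           / (SEVERITY_MAX - SEVERITY_MIN) * self.p)) + 1
        return min(cat, self.p)   # right-closed final bracket


def quantize(score, scheme: QuantizationScheme | int = 3):
    """Map continuous score(s) in [1, 3] to categories 1..p."""
    if isinstance(scheme, int):
        scheme = QuantizationScheme(scheme)
    arr = np.asarray(score, float)
    if arr.ndim == 0:
        return scheme.category(float(arr))
    return np.asarray([scheme.category(float(v)) for v in arr.ravel()]
                      ).reshape(arr.shape)


# ---------------------------------------------------------------------------
# heatmap


_ANCHORS = np.array([
    [0, 255, 0],     # severity 1: green
    [255, 255, 0],   # severity 2: yellow
    [255, 0, 0],     # severity 3: red
], float)


def severity_to_rgb(scores: np.ndarray) -> np.ndarray:
    """Linear green->yellow->red colormap over [1, 3] (uint8)."""
    s = np.clip(np.asarray(scores, float), SEVERITY_MIN, SEVERITY_MAX)
    t = (s - SEVERITY_MIN)  # 0..2; 0..1 green->yellow, 1..2 yellow->red
    lo = np.clip(t, 0.0, 1.0)[..., None]
    hi = np.clip(t - 1.0, 0.0, 1.0)[..., None]
    rgb = (_ANCHORS[0] * (1 - lo) + _ANCHORS[1] * lo) * (hi == 0) \
        + ((_ANCHORS[1] * (1 - hi) + _ANCHORS[2] * hi) * (hi > 0))
    return rgb.round().astype(np.uint8)


def render_heatmap(
    bmap: BlockScoreMap,
    upscale: bool = True,
    missing_color=(235, 235, 235),
    overlay: np.ndarray | None = None,
    alpha: float = 0.55,
) -> np.ndarray:
    """Render the pleomorphism spectrum of a block map as RGB.

    Severity 1 maps to pure green, 2 to yellow, 3 to red with linear
    interpolation; blocks without scores take ``missing_color``.  With
    ``overlay`` the heatmap is alpha-blended onto the slide raster.
    """
    if not bmap.defined.any():
        raise ValueError("empty block map")
    rgb = np.empty(bmap.scores.shape + (3,), np.uint8)
    rgb[...] = np.asarray(missing_color, np.uint8)
    have = bmap.defined
    rgb[have] = severity_to_rgb(bmap.scores[have])
    if upscale:
        rgb = np.repeat(np.repeat(rgb, bmap.block_size, 0),
                        bmap.block_size, 1)
        w, h = bmap.image_size
        rgb = rgb[:h, :w]
    if overlay is not None:
        if overlay.shape[:2] != rgb.shape[:2]:
            raise ValueError("overlay raster does not match heatmap size")
        mixed = (1 - alpha) * overlay.astype(float) + alpha * rgb
        rgb = np.clip(mixed, 0, 255).round().astype(np.uint8)
    return rgb


def heatmap_legend() -> dict:
    """JSON-ready legend sidecar for rendered heatmaps."""
    return {
        "colormap": "green->yellow->red over severity [1, 3]",
        "anchors": {"1.0": [0, 255, 0], "2.0": [255, 255, 0],
                    "3.0": [255, 0, 0]},
        "missing": "blocks without tile scores are neutral gray",
    }


def save_slide_report(path_prefix, bmap: BlockScoreMap,
                      slide_score: float) -> None:
    """Write block CSV + slide-score JSON + heatmap PNG."""
    import imageio.v3 as iio
    bmap.to_frame().to_csv(str(path_prefix) + "_blocks.csv", index=False)
    with open(str(path_prefix) + "_score.json", "w") as fh:
        json.dump({"slide_score": slide_score,
                   "quantized": quantize(slide_score),
                   "legend": heatmap_legend()}, fh, indent=2)
    iio.imwrite(str(path_prefix) + "_heatmap.png", render_heatmap(bmap))
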