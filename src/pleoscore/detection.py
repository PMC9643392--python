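"""Epithelial-cell detection stand-in, density maps, patch sampling.

The production system uses a frozen anchor-based detection network whose
only role downstream is its output contract: labeled point detections of
tumor and normal epithelial cells.  This module keeps that contract with
two desk-scale modes — an *oracle* that reads the synthetic generator's
ground truth, and a *blob* detector (multi-scale Laplacian of Gaussian on
the hematoxylin channel) with a size-threshold tumor/normal classifier.
Detections drive Gaussian nuclear-density maps, density-proportional
patch sampling ("areas with high nuclear composition") and the tumor
block mask that restricts slide scoring to invasive tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.color import rgb2hed
from skimage.feature import blob_log

from .config import DetectionConfig, GeneratorConfig
from .synthetic import NucleusRecord

__all__ = [
    "DetectionSet",
    "DensityMap",
    "NoTumorError",
    "detect_cells",
    "density_map",
    "sample_patch_centers",
    "tumor_block_mask",
    "match_detections",
    "detections_to_frame",
    "detections_from_frame",
]


class NoTumorError(RuntimeError):
    """No tumor detections / zero sampling mass: nothing to score."""


@dataclass
class DetectionSet:
    """Labeled point detections; the contract between the two stages."""

    x: np.ndarray            # float px
    y: np.ndarray
    label: np.ndarray        # "tumor" | "normal"
    confidence: np.ndarray   # in [0, 1]
    image_size: tuple[int, int]   # (width, height) px
    spacing: float                # um/px
    source_image_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.label = np.asarray(self.label, object)
        self.confidence = np.asarray(self.confidence, float)
        n = len(self.x)
        if not (len(self.y) == len(self.label) == len(self.confidence) == n):
            raise ValueError("ragged detection arrays")
        if n:
            w, h = self.image_size
            if (self.x < 0).any() or (self.x >= w).any() or \
               (self.y < 0).any() or (self.y >= h).any():
                raise ValueError("detection centers outside image bounds")
            if not np.isin(self.label, ("tumor", "normal")).all():
                raise ValueError("labels restricted to tumor/normal")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, mask: np.ndarray) -> "DetectionSet":
        return DetectionSet(self.x[mask], self.y[mask], self.label[mask],
                            self.confidence[mask], self.image_size,
                            self.spacing, self.source_image_id)

    @property
    def tumor(self) -> "DetectionSet":
        return self.subset(self.label == "tumor")


@dataclass
class DensityMap:
    """Nuclear density sampled on a stride grid; values >= 0."""

    values: np.ndarray       # (ny, nx)
    stride: int              # px between grid samples
    sigma: float             # px, Gaussian kernel scale
    label_filter: str        # "tumor" | "normal" | "all"
    image_size: tuple[int, int]

    def grid_to_pixel(self, iy: np.ndarray, ix: np.ndarray):
        """Pixel coordinates of grid cell centers."""
        return ix * self.stride + self.stride / 2.0, \
            iy * self.stride + self.stride / 2.0


def detect_cells(
    image: np.ndarray,
    mode: str = "blob",
    truth: list[NucleusRecord] | None = None,
    spacing: float = 1.0,
    config: DetectionConfig | None = None,
    source_image_id: str = "",
) -> DetectionSet:
    """Detect epithelial cells and label them tumor/normal.

    ``oracle`` mode passes the generator's ground truth through with
    confidence 1.0 (for isolating downstream behavior from detector
    error).  ``blob`` mode deconvolves the image into HED space, runs a
    multi-scale LoG blob detector on the hematoxylin channel and labels
    each blob by a radius threshold calibrated on the severity-1
    morphology: nuclei distinctly larger than resting epithelium are
    called tumor.  Confidence is the normalized LoG response.
    """
    cfg = config or DetectionConfig()
    h, w = image.shape[:2] if image is not None and image.size else (0, 0)
    if mode == "oracle":
        if truth is None:
            raise ValueError("oracle mode requires ground-truth records")
        inside = [nuc for nuc in truth
                  if 0 <= nuc.x < w and 0 <= nuc.y < h]
        return DetectionSet(
            np.array([n.x for n in inside]),
            np.array([n.y for n in inside]),
            np.array([n.label for n in inside], object),
            np.ones(len(inside)),
            (w, h), spacing, source_image_id)
    if mode != "blob":
        raise ValueError(f"unknown detection mode {mode!r}")
    if h == 0 or w == 0:
        return DetectionSet(np.empty(0), np.empty(0),
                            np.empty(0, object), np.empty(0),
                            (0, 0), spacing, source_image_id)

    hed = rgb2hed(image)
    hema = hed[..., 0]
    hema = hema - np.median(hema)          # background ~ 0
    hema = np.clip(hema, 0.0, None)
    # absolute OD floor: a nucleus-free image must stay empty instead of
    # having its read noise normalized up to full range
    if hema.max() < cfg.min_hema_od:
        return DetectionSet(np.empty(0), np.empty(0),
                            np.empty(0, object), np.empty(0),
                            (w, h), spacing, source_image_id)
    hema = hema / hema.max()
    sig_min = cfg.min_radius_um / spacing / np.sqrt(2.0)
    sig_max = cfg.max_radius_um / spacing / np.sqrt(2.0)
    blobs = blob_log(hema, min_sigma=sig_min, max_sigma=sig_max,
                     num_sigma=cfg.n_scales, threshold=cfg.log_threshold)
    if blobs.size == 0:
        return DetectionSet(np.empty(0), np.empty(0),
                            np.empty(0, object), np.empty(0),
                            (w, h), spacing, source_image_id)
    ys, xs, sigmas = blobs[:, 0], blobs[:, 1], blobs[:, 2]
    radii_um = sigmas * np.sqrt(2.0) * spacing
    gen = GeneratorConfig()
    r1 = gen.morphology.radius_mean_um[0]
    labels = np.where(radii_um > cfg.tumor_radius_factor * r1,
                      "tumor", "normal").astype(object)
    # response at the blob center as a crude confidence
    conf = hema[ys.astype(int), xs.astype(int)]
    conf = np.clip(conf, 0.0, 1.0)
    keep = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    return DetectionSet(xs[keep], ys[keep], labels[keep], conf[keep],
                        (w, h), spacing, source_image_id)


def density_map(
    dets: DetectionSet,
    sigma: float,
    stride: int = 1,
    label_filter: str = "all",
    truncate: float = 4.0,
) -> DensityMap:
    """Sum of isotropic Gaussians at detections, sampled on a stride grid.

    Mass is conserved up to kernel truncation at the image boundary:
    ``values.sum() * stride**2`` approximates the number of detections.
    Linear in the detection set.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    w, h = dets.image_size
    if label_filter == "all":
        sel = dets
    elif label_filter in ("tumor", "normal"):
        sel = dets.subset(dets.label == label_filter)
    else:
        raise ValueError(f"unknown label filter {label_filter!r}")
    canvas = np.zeros((h, w))
    if len(sel):
        np.add.at(canvas,
                  (sel.y.astype(int), sel.x.astype(int)), 1.0)
        canvas = ndimage.gaussian_filter(canvas, sigma, truncate=truncate,
                                         mode="constant")
    values = canvas[stride // 2::stride, stride // 2::stride].copy()
    return DensityMap(values, stride, sigma, label_filter, (w, h))


def sample_patch_centers(
    dmap: DensityMap,
    n: int,
    patch_size: int,
    seed=0,
) -> np.ndarray:
    """Draw patch centers with probability proportional to density.

    Implements "sample from areas with high nuclear composition" as
    proportional sampling (no hard threshold).  Centers are restricted so
    the patch lies fully inside the image; raises :class:`NoTumorError`
    when no admissible cell carries mass.  Returns an (n, 2) array of
    (x, y) pixel centers.
    """
    w, h = dmap.image_size
    half = patch_size / 2.0
    if patch_size > w or patch_size > h:
        raise ValueError("patch larger than image")
    rng = np.random.default_rng(seed)
    ny, nx = dmap.values.shape
    iy, ix = np.mgrid[0:ny, 0:nx]
    cx, cy = dmap.grid_to_pixel(iy, ix)
    admissible = ((cx >= half) & (cx <= w - half)
                  & (cy >= half) & (cy <= h - half))
    weights = np.where(admissible, dmap.values, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise NoTumorError("density map has zero admissible mass")
    probs = weights / total
    flat = rng.choice(weights.size, size=n, p=probs)
    jitter = rng.uniform(-dmap.stride / 2.0, dmap.stride / 2.0, (n, 2))
    xs = cx.ravel()[flat] + jitter[:, 0]
    ys = cy.ravel()[flat] + jitter[:, 1]
    xs = np.clip(xs, half, w - half)
    ys = np.clip(ys, half, h - half)
    return np.column_stack([xs, ys])


def tumor_block_mask(
    dets: DetectionSet,
    block: int,
    min_count: int = 1,
) -> np.ndarray:
    """Boolean block grid: True where >= ``min_count`` tumor detections.

    Monotone non-increasing in ``min_count``; restricts slide scoring to
    blocks with detected invasive tumor.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    w, h = dets.image_size
    nby = int(np.ceil(h / block))
    nbx = int(np.ceil(w / block))
    counts = np.zeros((nby, nbx), int)
    tum = dets.tumor
    if len(tum):
        bx = (tum.x // block).astype(int)
        by = (tum.y // block).astype(int)
        np.add.at(counts, (by, bx), 1)
    return counts >= min_count


def match_detections(
    dets: DetectionSet,
    truth: list[NucleusRecord],
    radius_px: float,
) -> tuple[int, int, int]:
    """Greedy-by-confidence matching of detections to ground truth.

    Returns (true positives, false positives, false negatives) at the
    given matching radius; each truth nucleus matches at most once.
    """
    order = np.argsort(-dets.confidence)
    tx = np.array([n.x for n in truth])
    ty = np.array([n.y for n in truth])
    used = np.zeros(len(truth), bool)
    tp = 0
    for i in order:
        if not len(truth):
            break
        d = np.hypot(tx - dets.x[i], ty - dets.y[i])
        d[used] = np.inf
        j = int(np.argmin(d)) if d.size else -1
        if j >= 0 and d[j] <= radius_px:
            used[j] = True
            tp += 1
    fp = len(dets) - tp
    fn = len(truth) - tp
    return tp, fp, fn


# ---------------------------------------------------------------------------
# external interfaces

_DET_COLUMNS = ["x", "y", "label", "confidence"]


def detections_to_frame(dets: DetectionSet) -> pd.DataFrame:
    return pd.DataFrame({"x": dets.x, "y": dets.y,
                         "label": dets.label.astype(str),
                         "confidence": dets.confidence})


def detections_from_frame(df: pd.DataFrame, image_size, spacing,
                          source_image_id="") -> DetectionSet:
    return DetectionSet(df["x"].to_numpy(), df["y"].to_numpy(),
                        df["label"].to_numpy(object),
                        df["confidence"].to_numpy(),
                        tuple(image_size), spacing, source_image_id)


def save_density_tiff(path, dmap: DensityMap) -> None:
    tifffile.imwrite(str(path), dmap.values.astype(np.float32))
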