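"""Synthetic H&E-like histology with known pleomorphism ground truth.

Generates seeded patches, tumor/normal ROI pairs and mosaic "slides" whose
nuclear morphology is a monotone function of a continuous severity
parameter ``s`` in [1, 3].  Every rendered nucleus is backed by exactly one
:class:`NucleusRecord`, so detection and regression stages can be validated
against exact ground truth.  Images are additive optical-density renderings
of two chromogens (hematoxylin-like nuclei on an eosin-like background)
with Gaussian read noise; they are deliberately schematic, not
photorealistic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .config import (
    SEVERITY_MAX,
    SEVERITY_MIN,
    GeneratorConfig,
    MorphologyMap,
    StainParams,
)

__all__ = [
    "NucleusRecord",
    "SeverityField",
    "SyntheticSlide",
    "RoiPair",
    "SmallRegionWarning",
    "LayoutError",
    "generate_nucleus_field",
    "render_patch",
    "generate_roi_pair",
    "generate_slide",
    "nuclei_to_frame",
    "nuclei_from_frame",
    "save_image",
    "save_slide",
]


class SmallRegionWarning(UserWarning):
    """Region too small to place any nucleus."""


class LayoutError(ValueError):
    """Slide layout regions overlap or fall outside the slide bounds."""


@dataclass(frozen=True)
class NucleusRecord:
    """One rendered nucleus; coordinates in pixels of the parent image."""

    x: float
    y: float
    major: float            # semi-axis, px
    minor: float            # semi-axis, px
    orientation: float      # radians, CCW from +x
    label: str              # "tumor" | "normal"
    chromatin_contrast: float  # hematoxylin OD contrast in [0, 1]

    def __post_init__(self):
        if not (self.major >= self.minor > 0):
            raise ValueError("semi-axes must satisfy major >= minor > 0")
        if self.label not in ("tumor", "normal"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.minor / self.major) ** 2))

    @property
    def area(self) -> float:
        """Ellipse area in px^2."""
        return float(np.pi * self.major * self.minor)


@dataclass
class SeverityField:
    """Per-block ground-truth severity; ``defined`` masks covered blocks."""

    values: np.ndarray        # (ny, nx) float in [1, 3]
    defined: np.ndarray       # (ny, nx) bool
    block_size: int           # px per block side
    spacing: float            # um/px of the parent image

    def __post_init__(self):
        v = self.values[self.defined]
        if v.size and (v.min() < SEVERITY_MIN or v.max() > SEVERITY_MAX):
            raise ValueError("severity values outside [1, 3]")


@dataclass
class SyntheticSlide:
    """Raster mosaic standing in for a whole-slide image."""

    image: np.ndarray                     # (H, W, 3) uint8
    spacing: float                        # um/px
    nuclei: list[NucleusRecord]
    severity: SeverityField
    region_labels: list[tuple[tuple[int, int, int, int], str, float]]
    seed: int

    @property
    def size(self) -> tuple[int, int]:
        return self.image.shape[1], self.image.shape[0]


@dataclass
class RoiPair:
    """A tumor ROI paired with a normal-epithelium ROI (same 'patient')."""

    tumor_image: np.ndarray
    normal_image: np.ndarray
    tumor_nuclei: list[NucleusRecord]
    normal_nuclei: list[NucleusRecord]
    severity: float
    spacing: float


# ---------------------------------------------------------------------------
# nucleus fields


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled normal; falls back to clipping after 20 rounds."""
    out = rng.normal(mean, sd, size)
    for _ in range(20):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, high)


def generate_nucleus_field(
    severity: float,
    target_density: float,
    region_bounds: tuple[float, float, float, float],
    label: str,
    seed,
    spacing: float = 1.0,
    morphology: MorphologyMap | None = None,
    hardcore_factor: float = 0.8,
) -> list[NucleusRecord]:
    """Place nuclei in a half-open pixel rectangle ``(x0, y0, x1, y1)``.

    The expected count is ``target_density`` (nuclei/mm^2) times the region
    area; realized counts are Poisson, thinned by a hard-core repulsion
    (minimum center distance = ``hardcore_factor`` x the sum of the two
    minor semi-axes) that keeps nuclei resolvable by a blob detector.
    Mean nuclear area, area variance and mean eccentricity all increase
    strictly with ``severity`` through :class:`MorphologyMap`.
    """
    if not (SEVERITY_MIN <= severity <= SEVERITY_MAX):
        raise ValueError("severity must lie in [1, 3]")
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    x0, y0, x1, y1 = region_bounds
    if x1 <= x0 or y1 <= y0:
        raise ValueError("region area must be > 0")
    morphology = morphology or MorphologyMap()
    rng = np.random.default_rng(seed)

    area_mm2 = (x1 - x0) * (y1 - y0) * (spacing * 1e-3) ** 2
    expected = target_density * area_mm2
    n = int(rng.poisson(expected))
    if n == 0:
        warnings.warn(
            f"region of {area_mm2:.2e} mm^2 too small for density "
            f"{target_density}/mm^2 (expected count {expected:.2f})",
            SmallRegionWarning,
        )
        return []

    m = morphology.at(severity)
    r_mean_px = m["radius_mean_um"] / spacing
    r_sd_px = m["radius_cv"] * r_mean_px

    radii = _truncated_normal(rng, r_mean_px, r_sd_px,
                              0.35 * r_mean_px, 2.5 * r_mean_px, n)
    ratios = _truncated_normal(rng, m["axis_ratio_mean"], m["axis_ratio_sd"],
                               0.30, 1.0, n)
    contrasts = np.clip(
        rng.normal(m["chromatin_contrast"], 0.05, n), 0.05, 1.0)
    orientations = rng.uniform(0.0, np.pi, n)

    # hard-core dart throwing; keeps as many of the n candidates as fit
    records: list[NucleusRecord] = []
    centers = np.empty((0, 2))
    minors: list[float] = []
    max_attempts = 40
    for i in range(n):
        major = radii[i] / np.sqrt(ratios[i])
        minor = radii[i] * np.sqrt(ratios[i])
        placed = False
        for _ in range(max_attempts):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            if centers.size:
                d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
                limit = hardcore_factor * (np.asarray(minors) + minor)
                if (d < limit).any():
                    continue
            centers = np.vstack([centers, (cx, cy)])
            minors.append(minor)
            records.append(NucleusRecord(
                x=cx, y=cy, major=float(major), minor=float(minor),
                orientation=float(orientations[i]), label=label,
                chromatin_contrast=float(contrasts[i]),
            ))
            placed = True
            break
        if not placed:
            continue
    if not records:
        warnings.warn("hard-core packing placed no nuclei",
                      SmallRegionWarning)
    return records


# ---------------------------------------------------------------------------
# rendering


def _paint_hematoxylin(od: np.ndarray, nuclei, rng) -> None:
    """Accumulate nuclear hematoxylin OD into ``od`` (H, W) in place."""
    h, w = od.shape
    for nuc in nuclei:
        r = nuc.major
        x_lo = max(int(np.floor(nuc.x - r - 2)), 0)
        x_hi = min(int(np.ceil(nuc.x + r + 2)) + 1, w)
        y_lo = max(int(np.floor(nuc.y - r - 2)), 0)
        y_hi = min(int(np.ceil(nuc.y + r + 2)) + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue  # entirely outside: silently clipped
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        dx = xx - nuc.x
        dy = yy - nuc.y
        c, s = np.cos(nuc.orientation), np.sin(nuc.orientation)
        u = (c * dx + s * dy) / nuc.major
        v = (-s * dx + c * dy) / nuc.minor
        rho2 = u * u + v * v
        # soft-edged ellipse profile: ~1 inside, sigmoid rolloff at rho=1
        profile = 1.0 / (1.0 + np.exp((np.sqrt(rho2) - 1.0) / 0.07))
        # chromatin texture: smooth multiplicative noise
        tex_amp = 0.35 * nuc.chromatin_contrast
        tex = ndimage.gaussian_filter(
            rng.standard_normal(profile.shape), 1.2)
        od[y_lo:y_hi, x_lo:x_hi] += (
            nuc.chromatin_contrast * profile * (1.0 + tex_amp * tex)
        ).clip(0.0)


def render_patch(
    nuclei: list[NucleusRecord],
    size: int | tuple[int, int],
    spacing: float = 1.0,
    stain_params: StainParams | None = None,
    seed=0,
) -> np.ndarray:
    """Render nuclei as shaded ellipses on an eosin-like background.

    Returns an (H, W, 3) uint8 raster.  Nuclei partly or fully outside the
    canvas are silently clipped.  Bit-identical for identical arguments and
    seed.
    """
    if isinstance(size, (int, np.integer)):
        size = (int(size), int(size))
    w, h = int(size[0]), int(size[1])
    if w <= 0 or h <= 0:
        raise ValueError("size must be positive")
    sp = stain_params or StainParams()
    rng = np.random.default_rng(seed)

    # background eosin with slow texture (stroma/cytoplasm)
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), 12.0)
    tex = (tex - tex.mean()) / (tex.std() or 1.0)   # zero-mean per patch
    od_e = sp.background_eosin_od * (
        1.0 + sp.background_texture_sd / sp.background_eosin_od * tex)
    od_h = np.full((h, w), sp.background_hema_od)
    _paint_hematoxylin(od_h, nuclei, rng)

    h_col = np.asarray(sp.h_color)
    e_col = np.asarray(sp.e_color)
    od = od_h[..., None] * h_col + od_e[..., None] * e_col
    img = np.exp(-od)
    img += rng.normal(0.0, sp.read_noise_sd, img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def background_mean_rgb(stain_params: StainParams | None = None) -> np.ndarray:
    """Expected background color (0..255 floats) of the stain model."""
    sp = stain_params or StainParams()
    od = (np.asarray(sp.h_color) * sp.background_hema_od
          + np.asarray(sp.e_color) * sp.background_eosin_od)
    return np.exp(-od) * 255.0


# ---------------------------------------------------------------------------
# ROI pairs and slides


def generate_roi_pair(
    severity: float,
    seed: int,
    size: int | None = None,
    spacing: float | None = None,
    config: GeneratorConfig | None = None,
) -> RoiPair:
    """Generate a (tumor ROI, normal ROI) query pair.

    The tumor ROI is generated at ``severity``; the normal ROI uses the
    severity-1 morphology with normal labels, mirroring how normal
    epithelium serves as the visual reference for grading.  Defaults are
    2560 x 2560 px at 0.25 um/px.
    """
    cfg = config or GeneratorConfig()
    size = cfg.roi_size_px if size is None else int(size)
    spacing = cfg.roi_spacing_um if spacing is None else float(spacing)
    bounds = (0.0, 0.0, float(size), float(size))
    seq = np.random.SeedSequence(seed).spawn(4)

    tumor_nuclei = generate_nucleus_field(
        severity, cfg.tumor_density_per_mm2, bounds, "tumor", seq[0],
        spacing=spacing, morphology=cfg.morphology,
        hardcore_factor=cfg.hardcore_factor)
    normal_nuclei = generate_nucleus_field(
        SEVERITY_MIN, cfg.tumor_density_per_mm2, bounds, "normal", seq[1],
        spacing=spacing, morphology=cfg.morphology,
        hardcore_factor=cfg.hardcore_factor)
    tumor_image = render_patch(tumor_nuclei, size, spacing, cfg.stain, seq[2])
    normal_image = render_patch(normal_nuclei, size, spacing, cfg.stain,
                                seq[3])
    return RoiPair(tumor_image, normal_image, tumor_nuclei, normal_nuclei,
                   float(severity), spacing)


def _rects_overlap(a, b) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def generate_slide(
    layout: list[tuple[tuple[int, int, int, int], str, float]],
    size: int | tuple[int, int] = 768,
    spacing: float = 1.0,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    severity_block: int = 32,
) -> SyntheticSlide:
    """Compose a mosaic slide from non-overlapping labeled regions.

    ``layout`` entries are ``(bounds, label, severity)`` with half-open
    pixel bounds, label in {"invasive", "benign"} and severity in [1, 3].
    Benign regions are forced to severity-1 morphology and normal labels
    (their stated severity is ignored); the rest of the canvas is bare
    background.  The ground-truth severity field is piecewise constant.
    """
    cfg = config or GeneratorConfig()
    if isinstance(size, (int, np.integer)):
        size = (int(size), int(size))
    w, h = size
    for i, (bounds, label, sev) in enumerate(layout):
        x0, y0, x1, y1 = bounds
        if label not in ("invasive", "benign"):
            raise LayoutError(f"unknown region label {label!r}")
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h or x1 <= x0 or y1 <= y0:
            raise LayoutError(f"region {i} outside slide bounds")
        for j in range(i):
            if _rects_overlap(bounds, layout[j][0]):
                raise LayoutError(f"regions {j} and {i} overlap")

    seq = np.random.SeedSequence(seed).spawn(len(layout) + 1)
    nuclei: list[NucleusRecord] = []
    resolved: list[tuple[tuple[int, int, int, int], str, float]] = []
    for k, (bounds, label, sev) in enumerate(layout):
        if label == "benign":
            sev_eff, nuc_label = SEVERITY_MIN, "normal"
        else:
            sev_eff, nuc_label = float(sev), "tumor"
        nuclei.extend(generate_nucleus_field(
            sev_eff, cfg.tumor_density_per_mm2, bounds, nuc_label, seq[k],
            spacing=spacing, morphology=cfg.morphology,
            hardcore_factor=cfg.hardcore_factor))
        resolved.append((tuple(bounds), label, sev_eff))

    image = render_patch(nuclei, (w, h), spacing, cfg.stain, seq[-1])

    nby = int(np.ceil(h / severity_block))
    nbx = int(np.ceil(w / severity_block))
    values = np.full((nby, nbx), SEVERITY_MIN)
    defined = np.zeros((nby, nbx), bool)
    for bounds, label, sev_eff in resolved:
        x0, y0, x1, y1 = bounds
        bx0, by0 = x0 // severity_block, y0 // severity_block
        bx1 = int(np.ceil(x1 / severity_block))
        by1 = int(np.ceil(y1 / severity_block))
        values[by0:by1, bx0:bx1] = sev_eff
        defined[by0:by1, bx0:bx1] = True
    field_ = SeverityField(values, defined, severity_block, spacing)
    return SyntheticSlide(image, spacing, nuclei, field_, resolved, seed)


# ---------------------------------------------------------------------------
# external interfaces (writers)


_NUCLEUS_COLUMNS = ["x", "y", "major", "minor", "orientation_rad", "label",
                    "chromatin_contrast"]


def nuclei_to_frame(nuclei: list[NucleusRecord]) -> pd.DataFrame:
    rows = [(n.x, n.y, n.major, n.minor, n.orientation, n.label,
             n.chromatin_contrast) for n in nuclei]
    return pd.DataFrame(rows, columns=_NUCLEUS_COLUMNS)


def nuclei_from_frame(df: pd.DataFrame) -> list[NucleusRecord]:
    return [
        NucleusRecord(x=r.x, y=r.y, major=r.major, minor=r.minor,
                      orientation=r.orientation_rad, label=r.label,
                      chromatin_contrast=r.chromatin_contrast)
        for r in df.itertuples()
    ]


def save_image(path, image: np.ndarray) -> None:
    """Write a raster as PNG or TIFF based on the file extension."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def save_slide(slide: SyntheticSlide, prefix) -> None:
    """Write image + nuclei CSV + severity CSV + JSON sidecar."""
    prefix = str(prefix)
    save_image(prefix + ".png", slide.image)
    nuclei_to_frame(slide.nuclei).to_csv(prefix + "_nuclei.csv", index=False)
    pd.DataFrame(slide.severity.values).to_csv(
        prefix + "_severity.csv", index=False, header=False)
    sidecar = {
        "spacing_um_per_px": slide.spacing,
        "seed": slide.seed,
        "severity_block_px": slide.severity.block_size,
        "regions": [
            {"bounds": list(map(int, b)), "label": lab, "severity": sev}
            for b, lab, sev in slide.region_labels
        ],
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
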