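"""Central configuration objects and documented default constants.

Conventions used throughout the package:

* 0-based pixel coordinates, x to the right, y down; rectangles are
  half-open ``[x0, x1) x [y0, y1)``.
* All physical spacings are micrometres per pixel (um/px); 0.25 um/px
  corresponds to a 40x scan, 0.5 um/px to 20x.
* Severity ``s`` is the continuous nuclear-pleomorphism score in [1, 3]:
  1 resembles normal breast epithelium, 3 the most aberrant morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


SEVERITY_MIN = 1.0
SEVERITY_MAX = 3.0


@dataclass(frozen=True)
class MorphologyMap:
    """Linear map from severity ``s`` in [1, 3] to nuclear morphology.

    No quantitative morphology is standardized for the 1/2/3 grades
    (grading is qualitative in routine practice), so this map is an
    explicit modeling choice: every cue a pathologist uses informally --
    nuclear size, size variation, shape irregularity, chromatin density --
    increases linearly with ``s``.  Radii are in micrometres so rendered
    nuclei keep their physical size at any pixel spacing.

    For a parameter with pair ``(v1, v3)`` the value at severity ``s`` is
    ``v1 + (v3 - v1) * (s - 1) / 2``.
    """

    #: mean equivalent nuclear radius (um): ~3.5 um for resting epithelium,
    #: up to ~6.5 um for the most pleomorphic nuclei.
    radius_mean_um: tuple[float, float] = (3.5, 6.5)
    #: coefficient of variation of the radius (anisokaryosis).
    radius_cv: tuple[float, float] = (0.08, 0.22)
    #: mean minor/major axis ratio; lower ratio = more elongated/irregular.
    axis_ratio_mean: tuple[float, float] = (0.90, 0.62)
    #: spread of the axis ratio.
    axis_ratio_sd: tuple[float, float] = (0.04, 0.10)
    #: hematoxylin optical-density contrast of the nucleus (hyperchromasia).
    chromatin_contrast: tuple[float, float] = (0.45, 0.78)
    #: within-nucleus chromatin texture (SD of the OD multiplier).
    chromatin_texture: tuple[float, float] = (0.06, 0.18)

    def at(self, s: float) -> dict[str, float]:
        """Evaluate every morphology parameter at severity ``s``."""
        t = (s - SEVERITY_MIN) / (SEVERITY_MAX - SEVERITY_MIN)
        out = {}
        for name, (v1, v3) in asdict(self).items():
            out[name] = v1 + (v3 - v1) * t
        return out


@dataclass(frozen=True)
class StainParams:
    """Two-chromogen (hematoxylin / eosin) optical-density rendering model.

    RGB = 255 * exp(-(OD_h * h_color + OD_e * e_color)); the unit color
    vectors are the standard Ruifrok-Johnston H and E absorbance vectors,
    so scikit-image's HED deconvolution recovers the hematoxylin channel.
    """

    h_color: tuple[float, float, float] = (0.650, 0.704, 0.286)
    e_color: tuple[float, float, float] = (0.072, 0.990, 0.105)
    #: background (cytoplasm/stroma) eosin OD and its slow spatial texture SD
    background_eosin_od: float = 0.28
    background_texture_sd: float = 0.035
    #: faint diffuse hematoxylin in cytoplasm
    background_hema_od: float = 0.02
    #: Gaussian read noise SD on the 0..1 intensity scale (default 4/255)
    read_noise_sd: float = 4.0 / 255.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults for the synthetic-histology generator (the stated world)."""

    morphology: MorphologyMap = field(default_factory=MorphologyMap)
    stain: StainParams = field(default_factory=StainParams)
    #: epithelial nuclear density inside generated regions (nuclei / mm^2)
    tumor_density_per_mm2: float = 4000.0
    #: hard-core repulsion: min center distance = factor * (minor_i + minor_j)
    hardcore_factor: float = 0.8
    #: default pixel spacings: ROI-study rasters at 40x, desk work at 1 um/px
    roi_spacing_um: float = 0.25
    desk_spacing_um: float = 1.0
    roi_size_px: int = 2560


@dataclass
class RegressorConfig:
    """Hyper-parameters of the dense-block patch regressor.

    The reference (production-scale) settings are a 512-px input at
    0.5 um/px, batch 12, 200 training / 500 validation iterations per
    epoch, Adam at 1e-4 with decoupled weight decay, LR decreased by 30%
    (new_lr = 0.7 * lr) after 10 epochs without validation improvement,
    and early stop after 10 such epochs.  ``desk()`` scales the layout
    down to what a single CPU trains in minutes while keeping every
    mechanism identical.
    """

    input_size: int = 512
    input_spacing_um: float = 0.5
    stem_channels: int = 16
    dense_block_layout: tuple[int, ...] = (4, 4, 4)
    growth_rate: int = 12
    compression: float = 0.5
    batch_size: int = 12
    train_iters_per_epoch: int = 200
    val_iters_per_epoch: int = 500
    max_epochs: int = 200
    lr_init: float = 1e-4
    lr_decay_factor: float = 0.30      # new_lr = (1 - 0.30) * lr
    lr_patience: int = 10
    early_stop_patience: int = 10
    weight_decay: float = 1e-4
    smooth_l1_beta: float = 1.0
    #: fixed input normalization (applied after scaling to [0, 1])
    norm_mean: float = 0.7
    norm_sd: float = 0.25
    #: dense block index whose output feeds Grad-CAM (negative = from end)
    saliency_block: int = -1
    seed: int = 0

    @staticmethod
    def desk(**overrides) -> "RegressorConfig":
        """CPU-trainable desk configuration (64-px patches at 1 um/px)."""
        cfg = RegressorConfig(
            input_size=64,
            input_spacing_um=1.0,
            stem_channels=12,
            dense_block_layout=(2, 2, 2),
            growth_rate=8,
            batch_size=12,
            train_iters_per_epoch=60,
            val_iters_per_epoch=20,
            max_epochs=60,
            lr_init=1e-3,
            lr_patience=4,
            early_stop_patience=8,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges for the training-time augmentation stack.

    Dihedral: one of the 8 flip/rotation symmetries of the square.
    Stain: multiplicative scale and additive offset in HED space
    (a light-weight stand-in for full stain augmentation).
    Blur: Gaussian sigma drawn uniformly from [0, blur_sigma_max].
    All ranges at zero make ``augment`` the identity.
    """

    dihedral: bool = True
    stain_scale: float = 0.15     # per-channel scale in [1 - a, 1 + a]
    stain_offset: float = 0.02    # per-channel additive OD offset
    blur_sigma_max: float = 1.0

    @staticmethod
    def off() -> "AugmentConfig":
        return AugmentConfig(dihedral=False, stain_scale=0.0,
                             stain_offset=0.0, blur_sigma_max=0.0)


@dataclass(frozen=True)
class DetectionConfig:
    """Desk-scale nucleus detector and density-map defaults."""

    #: LoG blob detection on the hematoxylin channel
    min_radius_um: float = 2.0
    max_radius_um: float = 9.0
    n_scales: int = 8
    log_threshold: float = 0.05
    #: minimum peak hematoxylin OD (log10 units after background
    #: subtraction) for an image to be considered stained; read noise
    #: alone peaks near 0.01, the faintest severity-1 nuclei near 0.08
    min_hema_od: float = 0.03
    #: tumor/normal size classifier: tumor if estimated radius exceeds the
    #: generator's severity-1 mean radius by this factor
    tumor_radius_factor: float = 1.15
    #: density map: Gaussian sigma 16 px at 0.5 um/px (um below), 4-sigma
    #: truncation, stride 8 px
    sigma_um: float = 8.0
    stride_px: int = 8
    truncate: float = 4.0
    #: detection-evaluation matching radius: 10 px at 0.5 um/px
    match_radius_um: float = 5.0
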