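"""Continuous pleomorphism regression: loss, augmentation, training, CAM.

The regressor learns the continuous severity spectrum from patches and
panel-mean reference scores with a smooth-L1 loss, Adam with decoupled
weight decay, plateau LR decay (new_lr = 0.7 * lr after ``lr_patience``
stagnant epochs) and early stopping, returning the snapshot of the best
validation epoch.  A scikit-learn style estimator wraps the machinery;
Grad-CAM saliency exposes which image regions drive a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hed2rgb, rgb2hed
from skimage.filters import gaussian as _gaussian_blur
from skimage.transform import resize
from sklearn.base import BaseEstimator, RegressorMixin

from .config import (
    SEVERITY_MAX,
    SEVERITY_MIN,
    AugmentConfig,
    DetectionConfig,
    RegressorConfig,
)
from .detection import DetectionSet, NoTumorError, density_map, \
    sample_patch_centers
from .nn import AdamW, DenseRegressorNet

__all__ = [
    "smooth_l1",
    "smooth_l1_grad",
    "augment",
    "dihedral",
    "normalize_patches",
    "ArraySource",
    "TrainHistory",
    "TrainController",
    "train",
    "predict_patch",
    "score_roi",
    "saliency",
    "PleomorphismRegressor",
]


# ---------------------------------------------------------------------------
# loss


def smooth_l1(prediction, target, beta: float = 1.0):
    """Smooth-L1 (Huber-style) loss, elementwise.

    ``0.5 d^2 / beta`` for ``|d| < beta`` else ``|d| - 0.5 beta`` with
    ``d = prediction - target``; continuous and once-differentiable at
    ``|d| = beta``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    d = np.asarray(prediction, float) - np.asarray(target, float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite loss inputs")
    ad = np.abs(d)
    out = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    return out if out.ndim else float(out)


def smooth_l1_grad(prediction, target, beta: float = 1.0):
    """d(loss)/d(prediction), elementwise."""
    d = np.asarray(prediction, float) - np.asarray(target, float)
    return np.where(np.abs(d) < beta, d / beta, np.sign(d))


# ---------------------------------------------------------------------------
# augmentation


def dihedral(patch: np.ndarray, k: int) -> np.ndarray:
    """One of the 8 symmetries of the square (k in 0..7; 0 = identity)."""
    if not 0 <= k < 8:
        raise ValueError("k must be in 0..7")
    out = np.rot90(patch, k % 4)
    if k >= 4:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(patch: np.ndarray, seed,
            config: AugmentConfig | None = None) -> np.ndarray:
    """Seeded appearance/orientation augmentation of a square patch.

    Composition of: a random dihedral transform; HED stain-space
    channel scale/offset (robustness to staining variation across labs);
    Gaussian blur with sigma ~ U[0, sigma_max] (out-of-focus regions).
    With every range at zero and dihedral disabled this is the identity.
    """
    cfg = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    out = patch
    if cfg.dihedral:
        out = dihedral(out, int(rng.integers(8)))
    if cfg.stain_scale > 0 or cfg.stain_offset > 0:
        hed = rgb2hed(out)
        scale = rng.uniform(1.0 - cfg.stain_scale, 1.0 + cfg.stain_scale, 3)
        offset = rng.uniform(-cfg.stain_offset, cfg.stain_offset, 3)
        rgb = hed2rgb(hed * scale + offset)
        out = (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    if cfg.blur_sigma_max > 0:
        sig = rng.uniform(0.0, cfg.blur_sigma_max)
        if sig > 1e-3:
            blurred = _gaussian_blur(out.astype(float) / 255.0, sigma=sig,
                                     channel_axis=-1)
            out = (np.clip(blurred, 0.0, 1.0) * 255.0).round().astype(
                np.uint8)
    return out


def normalize_patches(X: np.ndarray, config: RegressorConfig) -> np.ndarray:
    """uint8 (N, H, W, 3) -> normalized float32 for the network."""
    x = np.asarray(X, np.float32) / 255.0
    return (x - config.norm_mean) / config.norm_sd


# ---------------------------------------------------------------------------
# training


class ArraySource:
    """Patch source over in-memory arrays; samples with replacement."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        self.X = X
        self.y = np.asarray(y, float)

    def sample(self, rng: np.random.Generator, n: int):
        idx = rng.integers(0, len(self.X), n)
        return self.X[idx], self.y[idx]


@dataclass
class TrainHistory:
    """Per-epoch log; ``lr`` is the rate in effect during the epoch."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": self.epoch,
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss, "lr": self.lr})


@dataclass
class TrainController:
    """Plateau LR decay + early stopping, testable in isolation.

    After each epoch call :meth:`update` with the validation loss.  A
    strict improvement resets both counters; after ``lr_patience``
    stagnant epochs the LR is multiplied by ``1 - lr_decay_factor`` (the
    "decreased by 30%" reading: new_lr = 0.7 * lr) and the LR counter
    resets; after ``early_stop_patience`` stagnant epochs training stops.
    """

    lr: float
    lr_decay_factor: float = 0.30
    lr_patience: int = 10
    early_stop_patience: int = 10
    best_val: float = np.inf
    best_epoch: int = -1
    since_best: int = 0
    since_lr_event: int = 0

    def update(self, epoch: int, val_loss: float):
        """Returns (improved, decayed, stop)."""
        improved = val_loss < self.best_val
        decayed = False
        if improved:
            self.best_val = val_loss
            self.best_epoch = epoch
            self.since_best = 0
            self.since_lr_event = 0
        else:
            self.since_best += 1
            self.since_lr_event += 1
            if self.since_lr_event >= self.lr_patience:
                self.lr *= (1.0 - self.lr_decay_factor)
                self.since_lr_event = 0
                decayed = True
        stop = self.since_best >= self.early_stop_patience
        return improved, decayed, stop


def _draw_val_pool(val_source, config: RegressorConfig,
                   rng: np.random.Generator,
                   augment_cfg: AugmentConfig | None):
    """Fixed validation pool with frozen spatial (dihedral) augmentation."""
    n = config.val_iters_per_epoch * config.batch_size
    X, y = val_source.sample(rng, n)
    if augment_cfg is not None and augment_cfg.dihedral:
        X = np.stack([dihedral(p, int(rng.integers(8))) for p in X])
    return X, np.asarray(y, float)


def train(model: DenseRegressorNet, train_source, val_source,
          config: RegressorConfig,
          augment_cfg: AugmentConfig | None = None,
          verbose: bool = False):
    """Train to convergence; returns (best-epoch model, TrainHistory).

    One epoch = ``train_iters_per_epoch`` batches of ``batch_size``
    followed by a full pass over the fixed validation pool.  Deterministic
    given the sources and ``config.seed`` (single-threaded numpy).
    Raises on NaN loss rather than training through it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    opt = AdamW(model.param_layers(), lr=config.lr_init,
                weight_decay=config.weight_decay)
    ctrl = TrainController(config.lr_init, config.lr_decay_factor,
                           config.lr_patience, config.early_stop_patience)
    Xv, yv = _draw_val_pool(val_source, config, rng, augment_cfg)
    Xv_n = normalize_patches(Xv, config)
    history = TrainHistory()
    best_weights = model.get_weights()
    beta = config.smooth_l1_beta

    for epoch in range(1, config.max_epochs + 1):
        lr_in_effect = ctrl.lr
        opt.lr = lr_in_effect
        losses = []
        for _ in range(config.train_iters_per_epoch):
            X, y = train_source.sample(rng, config.batch_size)
            if augment_cfg is not None:
                X = np.stack([augment(p, rng.integers(2 ** 31), augment_cfg)
                              for p in X])
            pred = model.forward(normalize_patches(X, config))
            loss = float(np.mean(smooth_l1(pred, y, beta)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}")
            losses.append(loss)
            grad = smooth_l1_grad(pred, y, beta) / len(y)
            model.zero_grad()
            model.backward(grad)
            opt.step()

        val_losses = []
        for i in range(0, len(Xv_n), config.batch_size):
            pv = model.forward(Xv_n[i:i + config.batch_size])
            val_losses.append(
                np.sum(smooth_l1(pv, yv[i:i + config.batch_size], beta)))
        val_loss = float(np.sum(val_losses) / len(Xv_n))
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"NaN/inf val loss at epoch {epoch}")

        improved, decayed, stop = ctrl.update(epoch, val_loss)
        if improved:
            best_weights = model.get_weights()
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.lr.append(lr_in_effect)
        if verbose:
            print(f"epoch {epoch:3d} train {np.mean(losses):.4f} "
                  f"val {val_loss:.4f} lr {lr_in_effect:.2e}"
                  + (" *" if improved else ""))
        if stop:
            break
    history.best_epoch = ctrl.best_epoch
    model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# inference


def predict_patch(model: DenseRegressorNet, patch: np.ndarray) -> float:
    """Score one patch; raw output clamped to [1, 3]."""
    cfg = model.config
    if patch.shape[:2] != (cfg.input_size, cfg.input_size) or \
       patch.shape[-1] != 3:
        raise ValueError(
            f"patch shape {patch.shape} != configured input "
            f"{cfg.input_size}")
    out = model.forward(normalize_patches(patch[None], cfg))[0]
    return float(np.clip(out, SEVERITY_MIN, SEVERITY_MAX))


def predict_batch(model: DenseRegressorNet, patches: np.ndarray,
                  batch: int = 64) -> np.ndarray:
    cfg = model.config
    out = []
    for i in range(0, len(patches), batch):
        out.append(model.forward(
            normalize_patches(patches[i:i + batch], cfg)))
    return np.clip(np.concatenate(out), SEVERITY_MIN, SEVERITY_MAX)


def crop_patch(image: np.ndarray, cx: float, cy: float,
               size: int) -> np.ndarray:
    half = size // 2
    x0 = int(round(cx)) - half
    y0 = int(round(cy)) - half
    x0 = min(max(x0, 0), image.shape[1] - size)
    y0 = min(max(y0, 0), image.shape[0] - size)
    return image[y0:y0 + size, x0:x0 + size]


def score_roi(model: DenseRegressorNet, roi: np.ndarray,
              dets: DetectionSet, n_patches: int = 32, seed=0,
              det_config: DetectionConfig | None = None) -> float:
    """ROI score: mean over density-sampled overlapping patches.

    Multiple overlapping patches with small displacements are scored and
    averaged, which damps the rare failure where a single patch's
    prediction keys on non-nuclear tissue.
    """
    cfg = model.config
    dcfg = det_config or DetectionConfig()
    tum = dets.tumor
    if not len(tum):
        raise NoTumorError("no tumor detections in ROI")
    sigma_px = dcfg.sigma_um / dets.spacing
    dmap = density_map(dets, sigma_px, dcfg.stride_px, "tumor",
                       dcfg.truncate)
    centers = sample_patch_centers(dmap, n_patches, cfg.input_size, seed)
    patches = np.stack([crop_patch(roi, cx, cy, cfg.input_size)
                        for cx, cy in centers])
    return float(np.mean(predict_batch(model, patches)))


def saliency(model: DenseRegressorNet, patch: np.ndarray
             ) -> tuple[np.ndarray, bool]:
    """Grad-CAM for the scalar regression output.

    Channel gradients at the designated dense block are global-average-
    pooled into weights; the weighted feature-map sum is rectified,
    upsampled to the patch size and max-normalized to [0, 1].  Returns
    ``(map, flagged)`` with ``flagged`` True when gradients vanish and
    the map is identically zero.
    """
    cfg = model.config
    x = normalize_patches(patch[None], cfg)
    model.forward(x)
    model.zero_grad()
    grads = model.backward(np.ones(1), capture_block=cfg.saliency_block)
    acts = model.block_activation(cfg.saliency_block)
    weights = grads.mean(axis=(1, 2))              # (1, C)
    cam = np.maximum((acts * weights[:, None, None, :]).sum(axis=-1), 0.0)[0]
    flagged = bool(cam.max() <= 0.0)
    if flagged:
        return np.zeros(patch.shape[:2]), True
    cam = resize(cam, patch.shape[:2], order=1, mode="edge",
                 anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    return cam / cam.max(), False


# ---------------------------------------------------------------------------
# estimator


class PleomorphismRegressor(BaseEstimator, RegressorMixin):
    """Dense-block convolutional regressor for continuous severity.

    scikit-learn estimator interface: ``fit(X, y)`` on uint8 patches
    ``(n, H, W, 3)`` with continuous references in [1, 3]; ``predict``
    returns clamped continuous scores.  Defaults to the desk-scale
    configuration (64-px patches), trainable on one CPU in minutes.

    Parameters
    ----------
    config : RegressorConfig or None
        Architecture/schedule; None selects ``RegressorConfig.desk()``.
    augment_config : AugmentConfig or None
        Training-time augmentation; None selects package defaults.
    val_fraction : float
        Fraction of fit data held out for the validation pool when no
        explicit validation set is passed.
    """

    def __init__(self, config: RegressorConfig | None = None,
                 augment_config: AugmentConfig | None = None,
                 val_fraction: float = 0.2, verbose: bool = False):
        self.config = config
        self.augment_config = augment_config
        self.val_fraction = val_fraction
        self.verbose = verbose

    def _resolve(self) -> RegressorConfig:
        return self.config if self.config is not None \
            else RegressorConfig.desk()

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X)
        y = np.asarray(y, float)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n, H, W, 3) patches")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if ((y < SEVERITY_MIN) | (y > SEVERITY_MAX)).any():
            raise ValueError("targets must lie in [1, 3]")
        cfg = self._resolve()
        if X.shape[1] != cfg.input_size or X.shape[2] != cfg.input_size:
            raise ValueError(
                f"patches are {X.shape[1]}x{X.shape[2]}, configured input "
                f"is {cfg.input_size}")
        aug = self.augment_config if self.augment_config is not None \
            else AugmentConfig()
        if X_val is None:
            rng = np.random.default_rng(cfg.seed)
            perm = rng.permutation(len(X))
            n_val = max(1, int(len(X) * self.val_fraction))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        net = DenseRegressorNet(cfg)
        net, history = train(net, ArraySource(X, y),
                             ArraySource(np.asarray(X_val),
                                         np.asarray(y_val, float)),
                             cfg, augment_cfg=aug, verbose=self.verbose)
        self.net_ = net
        self.history_ = history
        self.config_ = cfg
        self.n_params_ = net.n_params
        return self

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        return predict_batch(self.net_, X)

    def predict_patch(self, patch) -> float:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        return predict_patch(self.net_, patch)

    def saliency(self, patch) -> tuple[np.ndarray, bool]:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        return saliency(self.net_, patch)

    def score_roi(self, roi, dets, n_patches: int = 32, seed=0) -> float:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        return score_roi(self.net_, roi, dets, n_patches, seed)
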