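# Methods

`pleoscore` implements, at desk scale, a fully automated pipeline for
scoring nuclear pleomorphism in breast-cancer histology as a *continuous
spectrum* rather than the traditional three discrete grades. This note
documents the model, the synthetic world it is validated in, the
numerical choices, and what the tests do and do not establish.

## The scoring model

Pleomorphism grading assigns 1 (nuclei resembling normal epithelium) to
3 (severe abnormality). Because the grading criteria are qualitative,
inter-observer agreement is poor; averaging the discrete grades of a
rater panel yields a continuous *reference score* in [1, 3] that
preserves the information in the panel's spread. The pipeline has two
stages:

1. **Epithelial cell detection** produces labeled point detections
   (tumor / normal epithelial cells, with confidences). Downstream code
   depends only on this output contract. Detections drive (a) Gaussian
   nuclear-density maps from which training/scoring patches are sampled
   proportionally to density ("areas of high nuclear composition") and
   (b) the tumor block mask that restricts scoring to invasive tumor.
2. **Dense-block regression** maps a fixed-size patch to a continuous
   severity. The network is a small DenseNet-style CNN: a stem
   convolution, dense blocks (each 3×3 conv layer sees the concatenation
   of the block input and all earlier layer outputs), 1×1
   channel-compressing transition layers with 2×2 average pooling,
   global average pooling and a linear scalar head. Training minimizes
   smooth-L1 loss between prediction and reference score with Adam plus
   decoupled weight decay.

Whole-slide scores come from overlapping tiles (production geometry:
512-px tiles, 448-px overlap, i.e. stride 64): each tile intersecting
the tumor mask is scored once; each 64-px block averages all covering
tile scores; the slide score is the unweighted mean over tumor blocks.
Continuous scores are quantized into `p` even brackets of [1, 3]
(left-closed, final bracket closed; exact edges `1 + 2k/p`, so the
three-category boundaries are 5/3 and 7/3 — the familiar 1.67 / 2.33
when printed at two decimals). Block maps render as a green→yellow→red
heatmap anchored at severities 1 / 2 / 3.

## Backend

No deep-learning framework is assumed: the network, backprop, AdamW,
and Grad-CAM are implemented directly on numpy (NHWC float32,
convolutions as nine shifted matmuls). This keeps the package
dependency-light and fully deterministic on a single CPU thread;
backprop is validated against central differences in the test suite.
The reference *desk configuration* (64-px input at 1 µm/px, 3 blocks × 2
layers, growth 8, ≈9k parameters) trains in about a minute on one CPU;
the production-scale layout (512-px input at 0.5 µm/px) is expressible
in the same config but is not trained in tests.

## Training schedule

Batch size 12; 200 training / 500 validation iterations per epoch at
production scale (desk: 60 / 20). Initial learning rate 1e-4
(desk: 1e-3 — the tiny net tolerates and needs a larger step). When the
validation loss fails to improve for `lr_patience` epochs the LR is
*decreased by 30%* (new_lr = 0.7·lr — not "decayed to 30%", the rival
reading); after `early_stop_patience` stagnant epochs training stops and
the weights of the best validation epoch are restored. The validation
pool is drawn once per run (with its spatial augmentation frozen), so
epoch-to-epoch validation losses are comparable. A NaN loss aborts with
a diagnostic rather than training on.

Augmentation: one of the 8 dihedral symmetries; stain jitter as
per-channel scale/offset in HED (hematoxylin–eosin–DAB) absorbance
space; Gaussian blur with σ ~ U[0, 1]. Ranges are chosen to keep
augmented images in valid intensity range; every range at zero gives the
identity. Inputs are scaled to [0, 1] then normalized with fixed
mean 0.7 / SD 0.25 (roughly the brightness of an H&E field).

## Synthetic world

The generator states the conditions under which every quantitative claim
in the tests holds. Nuclei are soft-edged ellipses with multiplicative
chromatin texture, rendered through a two-chromogen Beer–Lambert model
using the standard Ruifrok–Johnston H and E absorbance vectors (so
scikit-image's HED deconvolution recovers the hematoxylin channel), plus
Gaussian read noise (SD 4/255). Placement is a hard-core Poisson process
(expected count = density × area at 4000 nuclei/mm²; minimum center
distance 0.8 × the sum of minor semi-axes).

No quantitative morphology is standardized for grades 1/2/3, so the
severity→morphology map is an explicit modeling stand-in, linear in
`s`: mean equivalent radius 3.5→6.5 µm, radius CV 0.08→0.22, minor/major
axis ratio 0.90→0.62, chromatin contrast 0.45→0.78, chromatin texture
0.06→0.18. Every cue increases with `s`, making mean nuclear area, area
variance and eccentricity strictly increasing — verified by Monte-Carlo
in the tests. ROI query pairs follow the reader-study geometry
(2560×2560 px at 0.25 µm/px; the normal ROI uses the severity-1
morphology). Mosaic "slides" are non-overlapping labeled regions;
benign regions are forced to severity-1 morphology with normal labels,
which reproduces the known failure mode where a detector that mislabels
benign epithelium as tumor pulls the slide score down.

What the generator does *not* emulate: real chromatin texture, nucleoli,
mitoses, overlapping/clustered nuclei, stroma and fat architecture,
scanner artifacts, stain variability between labs. A green test
therefore establishes that the *pipeline mechanics* (sampling, loss,
schedule, pooling, quantization, agreement statistics) are correct and
that the regressor can recover a morphology-encoded severity signal —
not that it grades clinical slides at pathologist level.

## Observer panel

Simulated rater `g` grades item `i` as the 3-category quantization of
`clamp(s_i + bias_g + ε, 1, 3)`, `ε ~ N(0, σ_g)`; the default ROI panel
uses biases ~ N(0, 0.15) and σ ~ U[0.15, 0.35], which lands pairwise
kappas in the moderate range typical of this task. Confidence falls
with distance of the perceived score to the nearest bracket edge
(< 0.10 → not certain, < 0.25 → fairly certain, else certain).

Majority votes break ties by summed ordinal confidence (1/2/3); residual
ties go to the category nearest the panel mean, then to the lower
category — the sources state only that confidence breaks ties, so the
rest is a documented convention of this package. Kappa is Cohen's
weighted kappa with quadratic weights `(i−j)²/(k−1)²`; when the
chance-expected disagreement is zero (both raters constant) it is an
explicit `UndefinedKappaError`, never a silent 0, because silent zeros
would corrupt average-kappa summaries. Note that one constant rater
against a varying one is *defined* and equals 0 exactly.

## Numerical choices and degenerate inputs

* Coordinates are 0-based pixels, x right / y down, half-open
  rectangles; spacings in µm/px.
* Tile grids complete coverage by appending a final tile shifted to end
  flush with the image edge (no padding, no partial tiles), so every
  tile sees full-size input statistics.
* Blocks with no covering tile are missing (NaN), never 0-valued; a
  slide without tumor blocks raises `NoTumorError` instead of
  fabricating a score.
* Quantization requires scores inside [1, 3]; inference clamps before
  quantizing. Bracket edges use exact thirds, not the printed
  two-decimal roundings; the measure-zero boundary goes to the upper
  bracket except at 3.0.
* Explained variance is `1 − Var(error)/Var(reference)` (flagged
  undefined at zero reference variance).
* The LoG blob detector runs on the deconvolved hematoxylin channel
  with an absolute OD floor (0.03 in log10 units) so nucleus-free
  images yield empty detection sets instead of normalized noise.
* Density-map mass is conserved up to Gaussian truncation at image
  boundaries.
* Grad-CAM uses the final dense block's output; with a constant model
  the gradients vanish and the saliency map is all-zero with an
  explicit flag.

## Known limitations

* The desk detector's tumor/normal size-threshold classifier cannot
  separate tumor at severity 1 from normal epithelium (they share the
  morphology map by construction); oracle mode exists precisely to
  isolate downstream behavior from detector error.
* Parameter-recovery results are specific to the stated synthetic
  world; the severity signal there (size + chromatin) is easier than
  clinical pleomorphism.
* Training determinism assumes single-threaded numpy BLAS order;
  histories are reproducible under a fixed seed on the same platform.
* Slide inference scores one prediction per tile (no sub-tile
  granularity); block/tile alignment assumes stride is a multiple of
  the block size, which the default geometries satisfy.
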