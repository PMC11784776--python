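# Methods

This note documents the models implemented in `pulmoseg`, the choices
made where the design was genuinely open, and what the synthetic
phantoms can and cannot show.

## Pipeline overview

Four feed-forward stages: median-filter preprocessing → transformer-CNN
hybrid segmentation → four-family feature extraction → hybrid
LinkNet/MLSTM classification with probability-averaged fusion. Every
stage is a pure function of its inputs and a seed.

## Synthetic phantoms

Real chest-CT datasets are replaced by synthetic phantoms designed to
be *sufficient* for exercising every stage, not anatomically
realistic. A phantom is a grayscale image in [0, 1] with a bright
elliptical thorax (intensity 0.70), two dark elliptical lung fields
(0.18), a mild vertical intensity gradient, and pixelwise background
noise (sd 0.015). Diseased classes place 1–3 elliptical lesion blobs
inside the lung fields, blended in with a Gaussian-smoothed edge
(σ = 1.2 px):

| class | role      | base intensity | speckle sd | stripes |
|-------|-----------|----------------|------------|---------|
| 0     | normal    | — (no lesions) | —          | —       |
| 1     | smooth    | 0.80           | 0.03       | none    |
| 2     | textured  | 0.55           | 0.14       | freq 0.35 cyc/px, amp 0.12 |

These parameters were chosen once so that (a) a trivial rule on
lesion-region statistics separates the classes with >90% accuracy
(verified in the test suite), making downstream accuracy targets
attainable in principle, and (b) the classes still differ by texture
and intensity rather than by trivial geometry. The default image size
is 128×128 (512×512 available via config); lesion radii default to
7–16 px at that size.

Determinism: per-sample seeds are SHA-256 digests of
`(master seed, index)`, so extending a dataset never changes existing
samples. Noise injection supports salt-and-pepper (an exact
`round(level·N)` pixel count flipped to 0/1, half each) and white
Gaussian noise with sd = level × dynamic range, clipped to [0, 1].

What phantoms do **not** emulate: Hounsfield calibration, anatomy,
partial-volume effects, scanner artefacts, inter-patient variability.
A passing benchmark here shows the pipeline's machinery is correct and
trainable, not that it reaches any particular accuracy on clinical CT.

## Preprocessing

Median filter with a square window (default 3×3), reflect border
padding (configurable: edge, constant). The even-window median is the
average of the two middle values. Mean and Gaussian filters are
provided as comparison baselines. PSNR uses 10·log₁₀(MAX²/MSE) with a
+∞ sentinel at zero MSE; SSIM uses the standard 11×11
Gaussian-weighted window (σ = 1.5) with stabilisers (0.01·L)² and
(0.03·L)², averaged over the interior where the window fits. The
border mode defaults to reflect because dark constant frames corrupt
the texture codes downstream.

## Segmentation (ITCNN)

Two parallel encoder branches over the filtered image, four stages
each (default embedding widths 16/32/64/128, patch size 4, internal
working resolution 64×64):

* **Transformer branch** — pairs of improved Swin-transformer blocks
  per stage. Pre-norm residual placement is used
  (`u + Attn(LN(u))`, `· + MLP(LN(·))`): the alternative form with the
  residual folded inside the attention argument would double-count
  the input and break the zero-weight identity property. Window
  attention uses 4×4 token windows; the shifted variant rolls the
  grid by 2 tokens (no cross-window masking — at these window counts
  the roll alone suffices for inter-window mixing). The blocks add
  batch normalisation after each block and 2×2 average pooling
  between stages as the downsampling operator.
* **Improved attention logits** — the query-key logit matrix is
  squared elementwise before scaling:
  `softmax(σ·((qkᵀ ⊙ qkᵀ)/√D + B))`, with σ = exp(s) a learnable
  positive scalar (init 1) and B a relative-position bias gathered
  from a (2p−1)×(2p+1) table (the asymmetric second axis is kept as
  specified; one column pair is simply never addressed). A
  `standard` mode restores `softmax(qkᵀ/√D + B)`.
* **CNN branch** — one MBConv block per stage: 1×1 expansion (×2),
  depthwise 3×3, squeeze-and-excitation gating (reduction 0.25,
  Swish activations), 1×1 projection, residual where shapes match.
* **Fusion (STCF)** — per stage: CBAM-style spatial attention
  (sigmoid of a 7×7 conv over channelwise max/mean) gates each
  branch; concurrent spatial+channel squeeze-and-excitation (additive
  combination) recalibrates the cross-branch concatenations; a
  Hadamard-product bridge of 1×1-projected branch maps passes through
  a 3×3 conv; the three results are concatenated and merged by a 3×3
  conv + BN + ReLU.

The decoder upsamples the deepest fused map, concatenating each
shallower fused map as a skip connection (3×3 conv + BN + ReLU per
step) and ends in a sigmoid 1×1 head thresholded at 0.5. Images of
other sizes are resized bilinearly to the working resolution and the
probability map is resized back before thresholding.

Training: binary cross-entropy plus (1 − soft Dice) with Adam
(lr 3e-3, batch 8), fully seeded. After optimisation, every batch-norm
layer's running statistics are recomputed exactly from one sweep over
the training data in class-mixed batches ("BN refresh"); with runs of
only a few epochs the standard EMA update is still dominated by its
initial values, and class-sorted refresh batches would distort deeper
layers' statistics.

## Feature extraction

All mask-restricted blocks use the zero-vector convention for empty
masks. F = [Tex, Sha, Col, De]:

* **Modified LGIP** (256 bins): eight 3×3 Sobel-style masks M0..M7,
  M0 the horizontal Sobel and each subsequent mask the previous one's
  outer ring rotated 45°; bit i is set when the response is strictly
  positive (with a ~1e−9·scale tolerance absorbing float
  cancellation), so constant regions map to code 0. Rotating a patch
  by 90° permutes the response vector by two mask positions.
* **Improved LBP** (256 bins): for each ring pixel pᵢ (clockwise from
  top-left), gᵢ = (pᵢ² − adj(pᵢ)/max(|pᵢ|, ε))·((L+R)/max(T, ε)),
  where adj(pᵢ) is the sum of the two ring-adjacent neighbours and
  L/R/T the left/right/top grid neighbours of pᵢ (reflect padding,
  ε = 1e−6 keeps the operator total); bit i = 1 iff gᵢ − g_c ≥ 0
  against the raw centre intensity. This comparison deliberately
  mixes a transformed quantity with a raw intensity and therefore
  breaks constant-image symmetry (a constant patch of value 2 maps to
  code 255); it is implemented as stated.
* **Multi-texton** (7 bins): Otsu binarisation, then the six classic
  2×2 binary micro-patterns (all-ones, all-zeros, horizontal pair,
  vertical pair, two diagonals) counted on a stride-2 grid, plus a
  no-texton bin; computed over the mask's bounding box so constant
  background borders cannot change the block.
* **Shape** (6): area, perimeter, circularity 4πA/P², bounding-box
  aspect ratio, ellipse eccentricity and solidity of the largest
  connected component. Perimeter is the convex-hull boundary length
  of the pixel-box support: exactly 4n for an axis-aligned n×n square
  and within a few percent of 2πr for rasterised disks. It
  underestimates strongly concave supports; lesion blobs here are
  near-convex.
* **Colour** (32): normalised intensity histogram over mask pixels on
  [0, 1] (per-channel for RGB).
* **Deep** (128): penultimate (global-average-pool) activations of
  two small from-scratch encoders — a 4-block residual net (widths
  16→64) and a VGG-style stack of four conv-pool blocks — applied to
  the masked image resized to 32×32, trained briefly on the phantom
  classification task (or left at seeded-random weights via config).
  Pretrained ImageNet encoders are out of scope.

## Classification (L-MLSTM)

**ScReLU**: identity for x ≥ 0; sigmoid(x) + sinh(βx) + comb(βx) for
−1 ≤ x < 0; αx below −1 (α = 0.01; β defaults to 1, it is not
otherwise pinned down). The comb term defaults to arcsinh(βx), which
keeps the middle branch bounded and trainable; the literal 1/sinh(βx)
mode is retained and diverges as x → 0⁻ (|sinh| floored at 1e−6). In
both modes the activation is discontinuous at 0⁻ (the middle branch
tends to 0.5 in arcsinh mode); the test suite asserts rather than
hides this.

**MLSTM**: an LSTM cell whose four gate/candidate nonlinearities are
all ScReLU. Gates are therefore unbounded above and the cell state
can grow; this literal behaviour is kept, stabilised in training by
small gate-weight initialisation (×0.3), feature standardisation, and
global-norm gradient clipping (max norm 1). The flat feature vector
is zero-padded to a multiple of T = 16 and consumed as T timesteps;
the final hidden state (128 units) feeds a dense softmax.

**LinkNet head**: four encoder blocks (two 3×3 conv + BN + ReLU each,
filters 32/64/128/256, 2×2 max-pool), global average pooling and a
dense softmax, consuming the masked segmented image. The conv head
needs spatial input, so it takes the image while the MLSTM takes the
feature vector. The API default input side is 64 (64 → 4×4 after the
four pools); the end-to-end benchmark uses side 32 as its documented
problem size.

**Fusion**: elementwise mean of the two branch probability vectors
(a convex combination of distributions needs no renormalisation).
Both branches train independently with Adam on (sparse) categorical
cross-entropy; reference recipes are 25 epochs (batch 50 MLSTM,
batch 64 LinkNet), configurable down for desk-scale runs.

## Evaluation machinery

Dice 2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| with the empty-mask
conventions 1.0 (both empty) / 0.0 (one empty). The confusion-matrix
bundle (accuracy, sensitivity, specificity, precision, F, F2, NPV,
FPR, FNR, MCC, Cohen's κ) returns 0 with an `undefined` flag for
zero-denominator ratios; multi-class metrics are macro-averaged
one-vs-rest. Learning-percentage partitioning sets
train = round(lp/100·n) and treats test and validation as two views
of the same held-out remainder (equal sizes; a disjoint-halves flag
exists) — the only reading consistent with split tables where
test + validation exceeds n − train. k-fold uses stratified folds
with a fresh seeded model per fold. AUC is the rank-based
Mann–Whitney statistic (ties counted half). Model comparison uses the
Friedman test across ≥3 models (signed-rank for 2) plus pairwise
Wilcoxon signed-rank tests; degenerate all-equal inputs short-circuit
to p = 1 with a flag.

## The standard benchmark

`pulmoseg.pipeline.run_phantom_benchmark(seed)`: 300 phantoms
(3 × 100, 128×128), learning percentage 70 (210 train / 90 held out,
test = validation). The segmenter trains 5 epochs on 120 training
images at working resolution 64; deep encoders train 3 epochs at
32×32; the MLSTM trains 10 epochs and the LinkNet head 8 epochs at
side 32. Robustness re-runs the *entire* pipeline (filter → segment →
extract → classify) on the held-out images corrupted with white noise
at levels 0.10/0.20/0.30. These problem sizes are the package's
canonical desk-scale experiment; all are configurable upward.

## Numerical and engineering choices

* All neural components run on a small in-package reverse-mode
  autodiff engine over float64 numpy arrays (`pulmoseg.nn`), with
  im2col convolutions; every layer is verified against central-
  difference gradients in the test suite. Training is single-threaded
  and bit-reproducible for a fixed seed.
* BN refresh (above) replaces EMA statistics with exact pooled
  moments after every training run.
* Thresholds/tie-breaks: mask threshold 0.5; LGIP bits strict `> 0`;
  improved-LBP bits `≥ 0` at ties; max-pool gradient goes to the
  first maximal element.
* Degenerate inputs: empty masks → zero feature vectors and the
  overlap conventions above; constant images → all-zero Otsu
  binarisation; 1–2 pixel supports use a 4·area perimeter fallback.

## Known limitations

* Phantom realism (above); accuracies measured here do not transfer
  to clinical data.
* The windowed attention omits the cross-boundary attention mask in
  the shifted variant.
* The literal reciprocal comb mode is not recommended for training
  (divergence at 0⁻); it exists for fidelity and for studying the
  activation.
* The convex-hull perimeter underestimates concave shapes.
* CPU-scale only: the default architectures are deliberately tiny;
  full-size configurations exist but are not exercised by the tests.
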