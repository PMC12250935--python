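# Methods

`glandseg` implements an instance segmentation network for glandular
structures in H&E-stained pathology tiles, built around the idea of
*cross-scale guidance*: the coarsest, largest field-of-view features
steer the finer-scale features that the query decoder actually reads.
This note documents the model, the numerical choices, the synthetic
data the package trains on at desk scale, and the limits of what the
tests demonstrate.

## Model

**Encoder.** A pathology tile `I ∈ R^{H×W×C}` (padded so `H, W` are
divisible by 32) is reduced to a 1/4-scale patch embedding `f0` by two
stride-2 3×3 projections, then passed through four stages of
pre-norm transformer blocks whose attention is *neighborhood
attention*: each position attends to a k×k window around itself,
alternating dilation 1 with the stage's maximum feasible dilation to
enlarge the field of view. Between stages the spatial size halves and
channels double, giving `f4, f8, f16, f32` at 1/4 … 1/32 scale with
`embed_dim·{1,2,4,8}` channels. Windows are clamped (shifted inward)
at borders so every query sees exactly k² valid keys; keys are never
zero-padded. When a deep-stage map is smaller than the window span the
window shrinks to the map extent, which degenerates gracefully to full
attention — this only occurs on maps of a few dozen positions.

**Pixel decoder.** Six (tiny preset: one) multi-scale deformable
attention layers run over the 1/8, 1/16 and 1/32 features projected to
`decoder_dim` channels: every position samples `n_points` learned
offset locations per head from *every* level by bilinear interpolation
and combines them with softmax weights over (levels × points).
Sinusoidal 2-D positional encodings and a learned per-level embedding
are added to the queries. The 1/4-scale output is formed laterally:
`p4 = conv3×3(proj(f4) + up×2(p8))`. All four `p` levels carry
`decoder_dim` channels.

**Cross-scale guidance.** Block 1 upsamples `p32` bicubically by
factors 2, 4, 8 and fuses it into each finer level through a single
1×1 convolution whose weights are shared across scales:
`v_k = conv¹(U^j(p32) ⊕_cat p_k)`, `k = 32/j`. Block 2 uses `v16` as a
raw multiplicative weight map on the finer levels with a residual:
`g_k = U^j(v16) ⊗ v_k ⊕ v_k` for `k ∈ {8, 4}`, and `g16 = v16` by
definition. The weight map is deliberately not squashed — plain
multiply-then-add — because the residual guarantees the identity
behaviour at zero guidance; a `gated_guidance` switch applying a
sigmoid exists but is off by default. No nonlinearity or normalization
follows the 1×1 projection, and the projection carries a bias. The
`p32` consumed by block 1 is the pixel-decoder output (not the raw
encoder `f32` projected); the alternative reading exists but the
pixel-decoder feature is the one already refined by cross-level
attention, which is what the guidance is meant to spread.

**Query decoder.** N learned queries (X₀ is a learnable N×C parameter
initialized to zeros) pass through nine decoder layers that consume
`g16 → g8 → g4` and repeat that cycle three times. Cross-attention is
*masked*: `X_l = softmax(M_{l-1} + Q_l K_lᵀ) V_l + X_{l-1}`, where
`M_{l-1}` is 0 inside the previous layer's binarized mask prediction
(resized to the current scale) and −∞ outside, so each query keeps its
focus on its own object while climbing scales. A row that binarizes to
all −∞ falls back to all zeros (attend everywhere); without the
fallback the softmax would produce NaNs. Each layer then runs
self-attention over the queries and a feed-forward sublayer (pre-norm,
8 heads full / 2 tiny). Logits are scaled by `1/√d_head`; sinusoidal
encodings are added to K and a learned query embedding to Q (both
switchable off). Mask predictions exist for layer 0 through 9:
`mask_logits[n, y, x] = ⟨MLP₃(X_l)[n], p4[·, y, x]⟩` at 1/4 scale; the
attention mask is recomputed from *detached* logits, so gradients flow
through the attention equation, not the binarization. Class logits
come from a shared MLP head with one foreground class plus no-object.

**Instance assembly.** Queries with foreground probability above 0.5
are kept; masks are bilinearly upsampled to full resolution,
binarized at 0.5, conflicting pixels go to the highest-scoring query,
empty instances are dropped, and labels are renumbered contiguously in
descending score order. The instance count is reported alongside
per-instance scores and areas.

## Training

Set-prediction training: per decoder layer (deep supervision,
including layer 0) a Hungarian assignment matches queries to ground
truth objects under the cost
`λ_cls·(−p(class)) + λ_bce·BCE + λ_dice·(1 − softDice)` with
λ = (2, 5, 5); matched queries are supervised toward their object mask
and class, unmatched queries toward no-object with weight 0.1. Ground
truth masks are compared at 1/4 scale via nearest-neighbour
downsampling with half-pixel centers. Losses use full mask grids;
point sampling is a GPU-memory optimization that buys nothing at these
sizes. Soft Dice uses +1 smoothing in numerator and denominator.

Optimizer: AdamW (β = 0.9/0.999, weight decay 0.05), backbone learning
rate multiplier 0.1, global gradient-norm clipping at 1.0, linear
warmup over the first 100 iterations and a ×0.1 step decay at 85% of
the run. The full preset uses base lr 1e-4 (the conventional
large-batch setting); the tiny preset trains on single-tile batches
and uses 5e-4 — the usual batch-size scaling argument, and small-batch
noise is already tempered by clipping and warmup. Training iterates
one tile per step; all randomness (data order, augmentation draws,
initialization) derives from one seed, and two runs with the same seed
produce bit-identical loss traces.

## Synthetic data

Real gland ground truth requires external downloads, so the package
ships a generator that emulates the *geometry* of the problem: rotated
elliptical rings — dark purple epithelial borders around pale lumina —
on pink stroma, with per-object color jitter, smooth background
texture and speckle noise. Radii are drawn log-uniformly from
8–28 px in 96 px tiles (a 3.5× span; the central difficulty the
architecture targets is exactly this size variation), eccentricity
0.55–1.0, 2–6 glands per tile, touching allowed with probability 0.3
(contested border pixels go to the earlier-drawn object — draw order
is the tie-break, since real gland labels are mutually exclusive).
Objects are placed by rejection sampling; after bounded retries a tile
may carry fewer objects than drawn, with a warning.

What the generator does **not** emulate: nuclei and subcellular
texture, stain variability between slides and scanners, malignant
gland morphology (cribriform patterns, fused glands), tissue folds and
artifacts. Passing the learning check therefore shows the
architecture, losses and evaluation loop work end-to-end on
variant-size ring-shaped objects — it says nothing about accuracy on
real slides, which requires the real datasets and full-scale training.

Training augmentations follow the standard recipe: random crop,
horizontal/vertical flips, rotations restricted to {90°, 180°, 270°}
(exact array permutations — label maps are never interpolated), and
photometric jitter (±0.2 brightness/contrast/saturation, ±0.05 hue,
clipped to [0,1]); jitter ranges and crop size are declared defaults.
The desk-scale learning benchmark uses the geometric subset only,
because color is the dominant discriminative cue in the synthetic
tiles and hue jitter would degrade the toy task without making it more
realistic.

## Evaluation metrics

The gland-challenge object-level trio plus pixel F1 (formulas restated
in `glandseg.metrics`): detection F1 with the greedy 50 %-of-gt-area
claiming rule (descending overlap, smaller label on ties), the
area-weighted symmetrized object Dice, and the area-weighted
symmetrized object Hausdorff over 8-connectivity boundary pixels.
Conventions that vary between published implementations are fixed here
as follows: an object with zero overlap is paired with the *nearest*
object of the other map by minimal boundary distance; if the other map
is entirely empty the image diagonal is charged (so prediction against
an empty ground truth scores half the diagonal — the gt-side sum of
the symmetrization is empty). Dataset aggregates are unweighted means
of per-image values. Pixel F1 of two empty maps is defined as 1.

## Numerical and implementation choices

* The network runs on a small reverse-mode autodiff tape over float32
  numpy arrays written for this package (`glandseg._autodiff`);
  gradient correctness of every primitive is pinned by finite
  differences and the attention paths by per-element loop oracles.
* All fixed-ratio resizing (bicubic ×2/4/8 guidance upsampling,
  bilinear lateral ×2, mask resizing) is expressed as separable dense
  interpolation matrices with half-pixel centers and replicate
  borders; constants are reproduced exactly and rows always sum to 1.
  Bicubic uses the Keys kernel (a = −1/2).
* Deformable sampling clamps normalized coordinates to [0, 1];
  bilinear corner weights give piecewise-linear gradients in the
  offsets. Offset projections start at zero weight with the standard
  directional grid bias; attention-weight projections start at zero
  (uniform weights).
* Attention masks threshold sigmoid probability at 0.5 after bilinear
  resizing; the all-masked fallback row is mandatory.
* Initialization is truncated normal (σ = 0.02, clipped at 2σ) from a
  generator seeded by `RunConfig.seed`; X₀ starts at zero.
* AdamW runs on one flat parameter buffer (parameters are views into
  it) so the update cost is independent of the number of parameter
  arrays.

## Desk-scale benchmark protocol

The tiny preset (embed_dim 32, depths 1/1/1/1, kernel 3, decoder_dim
64, N = 20 queries, one deformable layer, nine decoder layers) is
sized so the whole pipeline trains in minutes on one CPU core:

* **Overfit check** — 8 fixed synthetic tiles, 300 iterations: the
  mean loss of the last 10 iterations must fall below half the mean of
  the first 10.
* **Learning check** — 64 training tiles with geometric augmentation,
  3500 iterations, 16 held-out tiles: object Dice ≥ 0.6 and object
  F1 ≥ 0.5. These bars are this artifact's own, chosen to demonstrate
  better-than-chance instance segmentation of variant-size glands with
  the full train → predict → evaluate loop.

`scripts/acceptance.py` reruns both protocols from scratch for a given
seed and writes the measured quantities to JSON.

## Known limitations

* The full preset mirrors published large-backbone hyperparameters but
  is never exercised end-to-end here; only the tiny preset is tested.
* Pretrained encoder weights are out of scope; everything trains from
  random initialization, which is the main reason desk-scale absolute
  numbers are far below published full-scale results.
* The object F1 at the desk-scale bar is limited by duplicate query
  detections that survive pixel-conflict resolution as small fragments
  and by merged predictions on touching glands — both shrink with
  longer training rather than with any post-hoc suppression, which the
  assembly rule deliberately omits.
* Tiling large images for inference stitches by score without overlap
  blending; boundary effects on very large tiles are untested.
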