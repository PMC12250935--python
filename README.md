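# glandseg

Instance segmentation of glands in H&E-stained pathology tiles with a
cross-scale guidance transformer — implemented, trained and evaluated
entirely at desk scale (one CPU, minutes, no downloads).

## The problem

Grading colorectal adenocarcinoma requires delineating *each* gland in
a histology section as a separate object and quantifying its shape.
Glands in the same tile vary enormously in size, which defeats
fixed-receptive-field segmenters: small glands need fine local detail,
large ones need global context. This package implements a set-prediction
transformer built around that problem:

* a **dilated neighborhood-attention encoder** producing features
  `f4, f8, f16, f32` at 1/4 … 1/32 of the input resolution with
  doubled channels per stage;
* a **multi-scale deformable-attention pixel decoder** producing
  `p4 … p32` (256 channels in the full preset);
* a **cross-scale guidance module** — the architectural core — that
  injects the largest field-of-view feature into every finer scale,

  ```
  v_k = conv¹( U^j(p32) ⊚ p_k ),      k = 32/j,  j ∈ {2,4,8}
  g_k = U^j(v16) ⊗ v_k ⊕ v_k,         k = 16/j,  j ∈ {2,4},   g16 = v16
  ```

  with bicubic upsampling `U^j`, channel concatenation `⊚`, a single
  1×1 convolution shared across the three scales, and elementwise
  multiply/add;
* a **masked-attention query decoder**: N learned queries refine
  masks over nine layers cycling `g16 → g8 → g4` three times, with
  `X_l = softmax(M_{l-1} + Q_l K_lᵀ) V_l + X_{l-1}` and attention
  masked to each query's previous mask prediction; final masks come
  from `X9 · p4` and classes from an MLP head;
* Hungarian-matched mask + classification losses with deep
  supervision, and the gland-challenge metrics: **object-level F1**
  (50 %-overlap rule), **object-level Dice**, **object-level
  Hausdorff**, plus pixel F1.

Because the real datasets (CRAG, GlaS) need external downloads and
GPU-scale training, the package ships a synthetic generator producing
H&E-like tiles of ring-shaped glands with a 3.5× size span and exact
instance ground truth; every component is testable against it.
Adapters for the CRAG/GlaS directory layouts are included for users
with the real data. The network runs on a small numpy autodiff engine
written for this package — see `docs/methods.md` for the model,
assumptions and numerical choices.

## Worked example

```python
from glandseg import GlandSegmentationModel, RunConfig

model = GlandSegmentationModel.from_synthetic(
    n_tiles=8, config=RunConfig.tiny(), seed=0)
res = model.fit(iterations=300)

tile, gt = model.dataset[0]
inst = res.predict(tile)
print(res.summary(eval_pairs=model.dataset[:4]))
print(f"tile 0: {inst.count} instances, gt {gt.n_objects}")
```

prints (run on one CPU core):

```
Gland instance segmentation — fit summary
=================================================
preset:            tiny
embed_dim:         32
decoder_dim:       64
queries (N):       20
decoder layers:    9 (cycling 1/16 -> 1/8 -> 1/4, three rounds)
parameters:        1,671,214
iterations:        300
loss first 10:     94.1367
loss last 10:      36.0094
fit time:          113.0s
-------------------------------------------------
object F1:         0.2826
object Dice:       0.5048
object Hausdorff:  44.46 px
pixel F1:          0.8599

tile 0: 5 instances, gt 6
```

After 300 iterations on 8 tiles the loss has fallen to ~38 % of its
starting value and the model already finds most glands on its own
training tiles (here 5 of 6 on tile 0); the object-level scores are
evaluated *on the training tiles* and keep improving with longer
training — the held-out benchmark below trains 3500 iterations on 64
tiles. `Instances.scores` carries each surviving query's foreground
probability, and the label map is a 16-bit PNG-serializable instance
map (0 = background).

## Command line

```bash
glandseg synth    --n 64 --seed 0 --out data/           # tiles + GT + manifest
glandseg train    --data data --iterations 3500 --out runs/a
glandseg predict  --checkpoint runs/a/checkpoint.npz img1.png img2.png
glandseg evaluate --pred runs/predict --gt data --out report.json
glandseg selftest                                       # oracle suites
```

Every command takes `--seed` and is bit-reproducible given it.

## Layout

```
src/glandseg/
  core_io.py        tiles, instance maps, 16-bit PNG I/O, RunConfig
  synthetic.py      H&E-like ring-gland generator + augmentations
  _autodiff.py      reverse-mode autodiff on float32 numpy arrays
  nn.py             layers, AdamW, interpolation matrices
  encoder.py        patch embed + dilated neighborhood attention
  pixel_decoder.py  multi-scale deformable attention + lateral path
  csgi.py           cross-scale guidance integration (the core module)
  mask_decoder.py   masked-attention query decoder + instance assembly
  training.py       Hungarian matching, losses, training loop
  metrics.py        object F1 / Dice / Hausdorff, pixel F1, reports
  model.py          GlandSegmentationModel / GlandSegmentationResults
  benchmarks.py     the overfit / learning experiment protocols
  cli.py            synth, train, predict, evaluate, selftest
  data_adapters.py  optional CRAG / GlaS directory readers
```
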