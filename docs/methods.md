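# Methods

`wavemri` implements a three-stage pipeline for binary triage of 2D brain MR
slices into *normal* vs *abnormal*, plus a synthetic phantom generator that
makes the whole chain testable without clinical data.

## Pipeline

1. **Median filtering.** MR magnitude images suffer impulsive
   (salt-and-pepper) corruption; a 3×3 median filter removes it while
   preserving edges. Borders use edge replication so the output keeps the
   input's shape (the standard choice for small masks; larger windows both
   blur edges and cost more). The filter is applied before RGB conversion.
2. **RGB replication.** The grayscale plane is replicated into three
   channels. Replication is information-preserving — any colormap would
   inject arbitrary structure — and gives the network a fixed `H×W×3`
   input contract.
3. **3-level Haar reduction.** One orthonormal 2D Haar analysis level maps
   each disjoint 2×2 block `[[a,b],[c,d]]` to

       LL = (a+b+c+d)/2   LH = (a−b+c−d)/2
       HL = (a+b−c−d)/2   HH = (a−b−c+d)/2

   Repeating the split on LL three times reduces a 512×512 slice to its
   64×64 *approximate image* — a 64-fold reduction of the network's input
   (786,432 → 12,288 scalars) that keeps anatomy-scale structure and
   discards pixel-scale detail. Only LL is consumed downstream; the detail
   bands exist in the `WaveletPyramid` for inspection.
4. **Block-wise CNN.** Four blocks of {3×3 conv, batch norm, ReLU, 2×2
   stride-2 max-pool, 50% dropout} with 8/16/32/64 channels, then two tanh
   fully-connected layers (512, 1024) and a single sigmoid unit trained
   with binary cross-entropy. Abnormal is the positive class; the decision
   threshold is 0.5.

## Conventions and numerical choices

- **Wavelet normalization** is orthonormal (`1/√2` taps), so energy
  conservation is an exact invariant (tested at 1e−9 relative) and the
  level-k LL equals `2^k ×` the mean of each disjoint `2^k×2^k` block.
  The `2^k·255` gain is divided out before the network, landing inputs in
  [0, 1]. Sub-band naming: LH carries column-difference (horizontal)
  detail, HL row-difference (vertical), HH diagonal; the test suite pins
  the mapping against a separable matrix-filtering oracle.
- **Odd dimensions are rejected**, not padded: the canonical input is
  512×512 and silent padding would alter the 64×64 contract.
- **Convolution stride is 1 with 'same' padding**; all spatial reduction
  happens in the pools (64→32→16→8→4). Stride-2 convolutions *and* four
  stride-2 pools together would collapse a 64×64 input below 1×1, so they
  cannot coexist; both the stride and the set of pooling blocks are
  configurable, and `pool_blocks=(0, 1, 2)` reproduces the variant that
  reaches the FC stack with an 8×8 map.
- **Optimizer** is Adam at the stated learning rate 0.001 (the community
  default for small CNNs; the source method names no optimizer). Epochs
  default to 35 (the dedicated hyperparameter table; prose elsewhere says
  40), validation every 31 iterations when a validation set is supplied.
- **Batch size 16.** Unstated upstream. At desk scale (hundreds of
  images) batch 32 leaves ~175 optimizer steps in 35 epochs: the network
  then ranks perfectly (AUC ≈ 1) but the output bias cannot migrate to
  the 0.5 threshold, while batch 8 degrades batch-norm statistics. 16
  keeps mini-batch statistics stable and the step budget proportionate.
- **Zero-initialized classification head.** The final dense layer starts
  at exactly zero, so an untrained network predicts 0.5 for every input
  and no seed-dependent logit offset has to be unlearned during a short
  run. Hidden layers use He (conv) / Glorot (dense) initialization.
- **Dropout/batch-norm variance shift.** Inverted dropout preserves means
  but inflates the second moments that downstream batch-norm layers
  record during training; inference activations (dropout off) are then
  mis-standardized and the error compounds across blocks. After the last
  epoch the running statistics are therefore re-estimated from clean
  forward passes over the training images with dropout inactive.
- **Augmentation** is uniform random rotation in [−15°, +15°] with
  reflect fill on every training batch (angles unstated upstream; small
  rotations match axial-slice pose variation), seeded.
- **ReLU** is `max(0, x)`; the source's printed sign layout for it is a
  typographical error. The output layer is a single sigmoid unit (its
  printed softmax-like ratio contradicts the named sigmoid layer and the
  binary task).
- **Layer counting** is reported under two conventions, because published
  counts are ambiguous: `n_layers_table` (grouped table rows: input + 5
  per block + FC/activations/classification/loss = 25 for the default)
  and `n_weight_layers` (trainable layers: 4 conv + 3 dense = 7).
- **Metrics.** Kappa is `(po − pe)/(1 − pe)` with marginal-product chance
  agreement, implemented directly so that *fractional* confusion cells
  are allowed: rebuilding a matrix from printed rates (`tp = TPR·n_pos`)
  yields non-integers, and rounding destroys 4-decimal agreement with
  published kappa values. AUC uses the Mann–Whitney rank-sum identity
  with average ranks (half-credit ties), equal to the trapezoidal area
  under the ROC curve. Brute-force re-derivations (longhand po/pe; all
  positive–negative pairs) serve as oracles in the tests, with
  scikit-learn as an extra cross-check.
- **The no-wavelet ablation arm** bilinearly downscales to the same
  64×64×3 target (the stated FC sizes make raw 512×512 input impossible),
  so architecture, seeds and splits are held fixed and only the reduction
  method varies.
- **Splits** are stratified by label, disjoint, and deterministic given
  the seed; sweeps carve 15% of the training split as validation (no
  validation split is defined upstream) and report the mean over 3 seeds.

## The phantom generator

Each phantom is a 512×512 8-bit slice: a dark background, an elliptical
brain (semi-axes 0.42/0.34 of the image side), tissue texture made of
white noise blurred with a σ = 12 px Gaussian (scaled so ±35 gray levels
≈ 3σ) around a mean of 120, and salt-and-pepper corruption at 2%. An
abnormal slice adds one bright disc of radius 30 px (a few-cm focal
lesion at this resolution) offset by 80 gray levels at a uniformly random
fully-in-brain location. Per-sample seeds derive from the dataset seed by
index, so datasets are bit-reproducible and extensible; class balance
defaults to 50/50.

What the generator does *not* emulate: skull/CSF anatomy, bias fields,
partial-volume effects, disease-specific lesion morphology, or
multi-focal disease. A green end-to-end test therefore establishes that
the pipeline detects a bright focal abnormality on correlated texture
through the full preprocessing chain — not clinical performance. The
zero-contrast control (abnormal slices generated identically to normal
ones) checks the complement: with no signal the pipeline's AUC must stay
at chance, i.e. nothing in preprocessing leaks the label.

## Scaled-down evaluation

Desk-scale runs use 200 phantoms (70/30 stratified split, 35 epochs,
≈ 1 minute on one CPU). At this scale the synthetic task is easy by
construction; the interesting guarantees are the exact transform/metric
identities, determinism of the whole chain from its seeds, the chance-
level null, and that the with/without-wavelet comparison differs by
exactly one flag.

## Known limitations

- The CNN is a from-scratch numpy implementation: single-threaded,
  float32, no GPU; it is sized for 64×64 inputs and hundreds of images,
  not for clinical-scale training.
- Binary output only; no multi-class disease taxonomy, no 3D volumes,
  no CT/PET modalities.
- Median filter, Haar transform and phantoms assume 8-bit intensity
  ranges; other bit depths must be rescaled by the caller.
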