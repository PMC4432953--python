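# Methods note

This note records the modelling and numerical choices behind `ishannot`,
the rationale for the default parameters, and the known limits of the
synthetic data generator.

## 1. Problem statement and model

Input: for each gene, a stack of grayscale sagittal ISH section images with
scalar section positions, plus a hierarchical ontology of brain structures.
Output: for every structure at a chosen ontology level, a score for whether
the gene is expressed there, evaluated against curated annotations.

Annotations carry three metrics — `pattern` (undetected / regional /
full / gradient), `intensity` and `density` (undetected / low / median /
high). For classification all three are binarised identically:
`undetected` → −1, everything else → +1, so each (structure, metric) task is
a binary "expressed here?" problem. The model per structure is linear:

    f(x) = wᵀx + b,
    min_{w,b}  Σ_i softplus(−y_i f(x_i)) + λ‖w‖²,   λ = 1, b unpenalised.

The squared-norm penalty is a deliberate design decision (the classical
presentation uses an unsquared norm); it keeps the objective smooth and
strongly convex, which L-BFGS handles robustly. With p ≫ n (10 521 or
147 456 features vs. tens–hundreds of genes) regularisation, not model
capacity, is the binding constraint, and λ = 1 works across both
representations on the synthetic data without tuning.

## 2. Bag-of-words representation

- **Dense SIFT.** Images are reduced by local 4×4 mean-pooling (downsample
  factor 4), gradients taken with central differences, orientations
  hard-assigned to 8 bins, and cell sums computed with integral images.
  Descriptors are L2-normalised, clamped at 0.2, and renormalised. A
  descriptor whose norm is below 1e-12 (flat patch) is not discarded: it is
  counted in a dedicated "zero" word per scale, so histogram mass is
  conserved — Σ(word counts) + zero count = number of grid positions, a
  property the tests check exactly.
- **Scales and step.** Bin sizes 4/8/16 px with step 4 on the downsampled
  image are conventional dense-SIFT defaults; the method's description
  leaves them open. Descriptor footprint is 4×bin px, so a 256×256 image
  (64×64 after downsampling) yields 169/81/1 descriptors at the three
  scales. Images smaller than 256 px per side would produce *zero*
  descriptors at scale 16, which is why 256×256 is the generator default.
- **Codebooks.** One K-means codebook per scale, K = 500, learned on a pool
  of up to 100 000 descriptors sampled uniformly per image (with leftover
  top-up so the pool is exact when the corpus suffices). K-means uses
  random initialisation with `n_init=1` per restart and 5 restarts; restart
  seeds are drawn in order from one seed sequence, so using more restarts
  can only keep or improve the selected within-cluster distance (a tested
  monotonicity invariant). The winning restart minimises within-cluster
  distance.
- **Global vector.** Sections are binned into 7 equal-width intervals of
  the position range, `floor((p − lo)/(hi − lo) · 7)` clamped so the
  maximum position maps to the last interval; a degenerate (single-
  position) range maps everything to interval 0. Histograms are averaged
  within an interval (empty intervals contribute zeros) and concatenated:
  1503 × 7 = 10 521 dimensions. Averaging makes the representation
  invariant to section order, another tested invariant.

## 3. Convolutional representation

- **Topology.** OverFeat-"fast"-style feature extractor, 231×231×3 input,
  18 feature layers where ZeroPad modules count toward the layer index:
  conv/relu/pool (1–3), conv/relu/pool (4–6, tap), pad/conv/relu (7–9,
  tap), pad/conv/relu (10–12, tap), pad/conv/relu/pool (13–16, tap),
  linear/relu (17–18, tap). Tap shapes (256,12,12), (512,12,12),
  (1024,12,12), (1024,6,6), (3072,1,1); flattened lengths 36 864, 73 728,
  147 456, 36 864, 3072. The architecture object propagates shapes
  symbolically at construction and refuses to build if any tap disagrees
  with this contract, so empirical and symbolic shapes cannot drift apart.
- **Weights.** Training is out of scope; weights are He-initialised
  (N(0, √(2/fan_in)), zero biases) from a seed by default, and can be
  loaded from a JSON-header + raw little-endian float32 file. Random-weight
  convolutional features are a known-strong baseline, and on the synthetic
  data they separate the classes perfectly (see §6).
- **Forward pass.** float32, im2col (via `sliding_window_view`) plus a
  single BLAS sgemm per conv layer, all sections of a stack batched into
  one GEMM. The forward stops at the deepest requested tap. Preprocessing:
  integer images scaled by their dtype maximum, grayscale replicated to 3
  channels, bilinear resize to 231×231, centred by subtracting 0.5.
- **Pooling across sections.** Element-wise max (default) or mean over the
  per-section tap vectors, with map-major flattening. Max pooling is
  idempotent under section duplication and invariant to section order
  (both tested).

## 4. Train/test split and evaluation

The balance-maximising split draws random 2/3–1/3 gene partitions and
accepts the first draw whose minority-class fraction exceeds the current
threshold for every structure *in both halves* — the conservative reading;
checking both halves prevents accepting a test half with (say) a single
positive. Schedule: threshold starts at ⅓, decays by 0.8 after each round
of 5000 failed attempts, floors at 0.01; if the floor is reached the
best-seen draw is returned. Structures that are single-class overall can
never satisfy any threshold and are excluded up front with a warning;
structures that become single-class after the split are skipped at
evaluation time, also with a warning. AUC is computed with
`sklearn.roc_auc_score` (ties counted half), validated in the tests against
an O(n₊·n₋) pairwise counting oracle; the per-level summary is the
unweighted mean over structures.

## 5. Synthetic generator: what it emulates, and what it does not

Each structure is an axis-aligned rectangle nested inside its parent
(margin 6 px at the root, 2 px insets per level, recursive splits along the
longer axis). Expression in a structure adds an oriented sinusoidal grating
(orientations on the golden angle, spatial frequencies 0.18/0.26/0.34
cycles/px, contrast 0.4) scaled by intensity amplitude (low 0.2, median
0.4, high 0.6) over a 0.10 background, with pattern semantics full (whole
rectangle), regional (half), gradient (linear ramp). Gaussian pixel noise
σ = 0.05 (easy preset: σ = 0.02, full/high only). `density` annotations
mirror `intensity` — the generator has no independent density process, so
the two metrics induce identical tasks by construction.

The structure-specific textures are the load-bearing realism compromise:
a bag of visual words has no spatial information inside a sagittal
interval, so spatially disjoint structures must differ in local appearance
to be distinguishable — a stand-in for genuine cytoarchitectural
differences between brain regions. The generator does **not** emulate real
anatomy (no curved boundaries, no per-section shape change — masks are
identical across sections), staining artefacts, section damage, or
registration error. Consequently recovery AUCs near 1.0 on the easy
setting indicate the pipeline is wired correctly, not that the problem is
solved at atlas scale; the label-permutation control (mean AUC ≈ 0.5) shows
the evaluation itself is honest.

## 6. Problem sizes and numerical choices

Sizes used by the tests and the acceptance script are this package's own
choices, made for single-CPU runtimes:

| context | genes | sections | codebook | notes |
|---|---|---|---|---|
| unit tests | 2–40 | 1–7 | K ≤ 64, ≤ 2 restarts | seconds each |
| acceptance test (recovery) | 200 | 17 | K = 500, pool 20 000, 2 restarts, 50 iters | ≈ 8 min incl. CNN |
| `scripts/acceptance.py` | 80 | 17 | same scaled codebook settings | ≈ 7 min |

Production-style defaults (pool 100 000, 5 restarts) live in
`PipelineConfig` and the library function signatures; the scaled settings
only shrink codebook estimation cost — vector dimensions and every
downstream contract are unchanged.

Other numerics: zero-descriptor threshold 1e-12; L-BFGS-B with gtol 1e-6,
at most 1000 iterations, objective trace recorded (monotone, tested);
softplus computed stably as `max(z,0) + log1p(exp(−|z|))`; all stochastic
components seeded through `numpy.random.SeedSequence` spawning so every
artefact is a pure function of one integer seed.

## 7. Known limitations

- Trained CNN weights are not included; random-weight features are a
  baseline, and the weight-file format is the extension point.
- The generator's identical masks across sections make the 7-interval
  spatial binning less informative than it would be on real stacks.
- λ and the split schedule are fixed defaults, not tuned per task; at
  atlas scale (1071 structures, sparse positives at deep levels) many
  structures will be excluded as single-class, which the report surfaces
  explicitly rather than silently skipping.
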