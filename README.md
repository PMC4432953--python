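# ishannot — annotating gene expression patterns in mouse brain section images

`ishannot` is a pipeline for automated annotation of gene expression in
stacks of in situ hybridisation (ISH) brain section images. Given a set of
genes, each imaged as a series of sagittal sections through the developing
mouse brain, the task is to predict — for every anatomical structure in a
hierarchical brain ontology — whether the gene is expressed there and how
(pattern, intensity, density). Manual curation of such atlases is the
bottleneck; this package reproduces the classical machine-learning approach
to automating it, and ships a synthetic data generator so the whole pipeline
can be exercised and validated without access to a real atlas.

The package is aimed at computational-biology and machine-learning
practitioners who want a transparent, dependency-light reference
implementation of the method with every numeric kernel testable against an
independent oracle.

## Method

**Representations.** Each gene's section stack is summarised by one fixed-
length vector, in one of two ways:

1. *Bag of visual words (BOW).* Dense SIFT descriptors (128-D: 4×4 spatial
   cells × 8 orientation bins) are computed on a 4× downsampled image at
   three patch scales (bin sizes 4, 8, 16 px, step 4). A codebook of
   K = 500 visual words per scale is learned by K-means on a pool of up to
   100 000 descriptors; flat (zero-gradient) patches get an extra "zero"
   word, so each section yields a (500+1)×3 = 1503-dimensional word
   histogram. Sections are assigned to 7 equal-width sagittal intervals by
   position; histograms are averaged within an interval and concatenated,
   giving a global vector of 1503 × 7 = **10 521** dimensions.

2. *Convolutional features (CNN).* A forward-only OverFeat-fast-style
   network takes 231×231×3 inputs and exposes five tap layers with
   flattened lengths 36 864 / 73 728 / 147 456 / 36 864 / 3072 (layers 6, 9,
   12, 16, 18; ZeroPad modules count as layers). Per-section activations
   are pooled across a stack with an element-wise max (or average). Weights
   are seeded random (He initialisation) by default; trained weights can be
   plugged in from a simple JSON-header + raw-float32 file.

**Annotation.** For every structure s at an ontology level, labels are
binarised (undetected → −1, anything else → +1) and one linear classifier
is trained by minimising the L2-regularised logistic loss

    min_{w,b}  Σ_i log(1 + exp(−y_i (wᵀx_i + b)))  +  λ ‖w‖²

with λ = 1 and an unpenalised bias, via L-BFGS. Genes are divided 2/3–1/3
into train and test sets by a balance-maximising rejection-sampling split:
random splits are drawn until the minority-class fraction in *both* halves
exceeds a threshold (start ⅓) for every structure; after 5000 failed draws
the threshold decays by 0.8, down to a floor of 0.01. Performance is the
area under the ROC curve (AUC) on held-out genes; the per-level summary is
the unweighted mean over structures. For the reference atlas level counts
[3, 6, 19, 14, 81, 46, 123, 40, 307, 432] the pipeline defines **1071**
classifiers.

**Synthetic generator.** Stacks are rendered as nested axis-aligned
rectangles (one per ontology structure) filled with structure-specific
oriented sinusoidal textures over a 0.10 background, with expression
semantics *full* / *regional* / *gradient*, intensities *low* / *median* /
*high* (amplitudes 0.2 / 0.4 / 0.6), and Gaussian pixel noise (σ = 0.05;
"easy" preset σ = 0.02 with full/high expression only). Detection of each
(gene, structure) pair is an independent Bernoulli draw. See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

`examples/04_annotate.py` runs the full pipeline on a small synthetic
dataset (40 genes, 17 sections each, 30 % of (gene, structure) pairs
detected, reduced codebook K = 64):

```
$ python examples/04_annotate.py
features: 40 genes x 1365 dims (bow)
split balance threshold achieved: 0.267
structure_id  level  n_train  n_test  n_pos_test  auc
      S1_000      1       27      13           3  1.0
      S1_001      1       27      13           3  1.0
      S1_002      1       27      13           7  1.0
      S1_003      1       27      13           5  1.0
overall level-1 AUC (unweighted mean): 1.000
```

On the easy synthetic setting the representations separate expressing from
non-expressing genes perfectly; a label-permutation control collapses the
mean AUC to chance (0.53 over 20 measurements in the run below), confirming
the signal is carried by the features and not by an artefact of the
evaluation.

The other examples show each stage in isolation. `examples/02_bow_features.py`:

```
scale  4:  169 textured descriptors (128-D), 0 flat ones -> zero slot
scale  8:   81 textured descriptors (128-D), 0 flat ones -> zero slot
scale 16:    1 textured descriptors (128-D), 0 flat ones -> zero slot
codebooks: K=16 words per scale, within-cluster distance at scale 4 = 534.0
per-section histogram length: 51 = (16 + 1) words x 3 scales
sections fall into intervals [0, 1, 2, 3, 4, 5, 6]
global vector length: 357 = 51 x 7 intervals (10521 with the production K=500)
```

and `examples/03_cnn_features.py`:

```
tap layer -> (maps, h, w), flattened length:
  layer  6: (256, 12, 12), 36864
  layer  9: (512, 12, 12), 73728
  layer 12: (1024, 12, 12), 147456
  layer 16: (1024, 6, 6), 36864
  layer 18: (3072, 1, 1), 3072

processed 5 sections (231x231 input after resizing) in 0.20 s
per-section vector length at tap 12: 147456
pooled gene vector: length 147456, mean activation 0.2546, 52.6% positive after ReLU+max
```

## Command-line interface

The same stages are available as a CLI:

```
ishannot simulate    --out ds --genes 60 --seed 1        # synthetic dataset
ishannot extract-bow --dataset ds --out feats --seed 1   # BOW features
ishannot extract-cnn --dataset ds --out feats --tap 12   # CNN features
ishannot train-eval  --dataset ds --features feats --out report
ishannot report      --summary report.json
```

Each command writes a JSON reproducibility record (full command, package and
numpy versions, configuration) next to its output.

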