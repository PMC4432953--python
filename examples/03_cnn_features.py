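"""Extract convolutional features from a section stack.

A forward-only OverFeat-style network (seeded random weights by default,
trained weights pluggable from file) exposes five tap layers; per-section
activations are pooled across sections with an element-wise maximum.
"""

import time

import numpy as np

from ishannot import (
    build_extractor,
    easy_config,
    extract,
    generate_dataset,
    pool_sections,
    preprocess,
)
from ishannot.cnn import TAP_LENGTHS

extractor = build_extractor(weights_source=0)
print("tap layer -> (maps, h, w), flattened length:")
for tap in sorted(TAP_LENGTHS):
    print(f"  layer {tap:>2}: {extractor.shapes[tap]}, {TAP_LENGTHS[tap]}")

stacks, _, _ = generate_dataset(
    n_genes=2, undetected_fraction=0.5, config=easy_config(n_sections=5),
    seed=5,
)
stack = stacks[0]

t0 = time.time()
vectors = [extract(extractor, im, tap=12) for im in stack.images]
pooled = pool_sections(vectors, mode="max", gene_id=stack.gene_id)
dt = time.time() - t0

print(f"\nprocessed {len(vectors)} sections "
      f"(231x231 input after resizing) in {dt:.2f} s")
print(f"per-section vector length at tap 12: {len(vectors[0].values)}")
print(f"pooled gene vector: length {len(pooled.values)}, "
      f"mean activation {np.mean(pooled.values):.4f}, "
      f"{np.mean(pooled.values > 0) * 100:.1f}% positive after ReLU+max")
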