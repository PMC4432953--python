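"""Compute the bag-of-words representation of one gene's section stack.

Dense SIFT descriptors at three scales are quantised against per-scale
codebooks (plus a zero-descriptor slot), averaged within 7 sagittal
intervals, and concatenated into one global vector per gene.
"""

from ishannot import (
    assign_intervals,
    build_codebooks,
    build_global_bow,
    dense_descriptors,
    easy_config,
    generate_dataset,
    quantize,
)

stacks, _, _ = generate_dataset(
    n_genes=4, undetected_fraction=0.5, config=easy_config(n_sections=7),
    seed=7,
)

# Descriptors from a single section, per scale
ds = dense_descriptors(stacks[0].images[3])
for scale, kept, zero in zip(ds.scales, ds.descriptors, ds.zero_counts):
    print(f"scale {scale:>2}: {kept.shape[0]:>4} textured descriptors "
          f"(128-D), {zero} flat ones -> zero slot")

# Small codebooks learned from all four stacks (K=500 in production)
all_sets = [dense_descriptors(im) for s in stacks for im in s.images]
books = build_codebooks(all_sets, K=16, pool_size=3000, restarts=2, seed=7)
print(f"codebooks: K={books[4].K} words per scale, "
      f"within-cluster distance at scale 4 = "
      f"{books[4].within_cluster_distance:.1f}")

stack = stacks[0]
vecs = [quantize(dense_descriptors(im), books) for im in stack.images]
print(f"per-section histogram length: {vecs[0].shape[0]} "
      f"= (16 + 1) words x 3 scales")

idx = assign_intervals(stack.positions, n_intervals=7)
global_vec = build_global_bow(vecs, idx, n_intervals=7)
print(f"sections fall into intervals {idx.tolist()}")
print(f"global vector length: {global_vec.shape[0]} = 51 x 7 intervals "
      f"(10521 with the production K=500)")
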