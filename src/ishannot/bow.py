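"""Bag-of-visual-words representation of ISH section stacks.

Pipeline: each section image is downsampled, dense gradient-orientation
descriptors (SIFT layout: 4x4 spatial cells x 8 orientation bins = 128 dims)
are computed on a regular grid at several spatial scales, nonzero
descriptors are pooled across the corpus and clustered per scale into a
K-word visual codebook (K-means, best of several restarts), each section
becomes a histogram of visual-word occurrences plus one extra slot counting
its zero (gradient-free) descriptors, sections are grouped into equal-width
sagittal intervals whose histograms are averaged, and the interval vectors
are concatenated into one global per-gene vector.

With the defaults (K = 500 words, 3 scales, 7 sagittal intervals) the
per-section vector has (500 + 1) x 3 = 1503 entries and the global per-gene
vector has 1503 x 7 = 10521.

Mass conservation holds throughout: per section and scale, word counts plus
the zero-descriptor slot equal the number of descriptor grid positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin_min

from .features import FeatureMatrix
from .stack import SectionStack

DEFAULT_SCALES = (4, 8, 16)  # SIFT spatial-bin sizes in px on the downsampled image
DEFAULT_STEP = 4
DEFAULT_DOWNSAMPLE = 4
DEFAULT_K = 500
DEFAULT_POOL_SIZE = 100_000
DEFAULT_RESTARTS = 5
DEFAULT_INTERVALS = 7

_ZERO_NORM_EPS = 1e-12


# ---------------------------------------------------------------------------
# dense descriptors
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSet:
    """Per-scale dense descriptors for one image.

    ``descriptors[s]`` is an (n_s, 128) array of kept (nonzero-norm)
    descriptors; ``zero_counts[s]`` counts grid positions whose descriptor
    had zero norm (no gradient energy anywhere in the footprint); their sum
    equals ``grid_counts[s]``.
    """

    scales: tuple
    descriptors: list = field(default_factory=list)
    zero_counts: list = field(default_factory=list)
    grid_counts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for d, z, g in zip(self.descriptors, self.zero_counts, self.grid_counts):
            if d.shape[0] + z != g:
                raise ValueError("kept + zero descriptor counts must equal grid size")


def grid_count(height: int, width: int, bin_size: int, step: int) -> int:
    """Number of dense-descriptor grid positions (closed form).

    The descriptor footprint is 4 spatial cells of ``bin_size`` px; anchors
    start at the top-left corner and advance by ``step`` while the footprint
    fits inside the image.
    """
    fp = 4 * bin_size
    ny = (height - fp) // step + 1 if height >= fp else 0
    nx = (width - fp) // step + 1 if width >= fp else 0
    return ny * nx


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D or 3-channel image, got shape {image.shape}")
    return img


def _downsample_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Local-mean (area) downsampling; trailing rows/cols that do not fill a
    full block are dropped."""
    if factor == 1:
        return img
    h, w = img.shape
    h2, w2 = h // factor, w // factor
    if h2 == 0 or w2 == 0:
        return img[:0, :0]
    cropped = img[: h2 * factor, : w2 * factor]
    return cropped.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def dense_descriptors(
    image: np.ndarray,
    scales: tuple = DEFAULT_SCALES,
    step: int = DEFAULT_STEP,
    downsample: int = DEFAULT_DOWNSAMPLE,
) -> DescriptorSet:
    """Dense 128-D gradient-orientation descriptors on a regular grid.

    Gradients are central differences on the (local-mean) downsampled image;
    each grid cell accumulates gradient magnitude into 8 orientation bins;
    the 16-cell descriptor is L2-normalised, clamped at 0.2 and renormalised
    (the standard SIFT contrast normalisation).  Descriptors with zero norm
    (flat footprints) are discarded but counted.
    """
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")
    if not scales:
        raise ValueError("at least one scale is required")
    img = _downsample_mean(_to_gray(image), downsample)
    h, w = img.shape

    if h >= 2 and w >= 2:
        gy, gx = np.gradient(img)
        mag = np.hypot(gx, gy)
        ori = np.arctan2(gy, gx)  # [-pi, pi]
        obin = np.floor((ori + math.pi) / (2 * math.pi) * 8).astype(int) % 8
        channels = np.zeros((8, h, w))
        for k in range(8):
            channels[k][obin == k] = mag[obin == k]
        # integral images per orientation channel
        integ = np.zeros((8, h + 1, w + 1))
        integ[:, 1:, 1:] = channels.cumsum(axis=1).cumsum(axis=2)
    else:
        integ = None

    descriptors, zero_counts, grid_counts = [], [], []
    for bs in scales:
        g = grid_count(h, w, bs, step)
        grid_counts.append(g)
        if g == 0 or integ is None:
            descriptors.append(np.empty((0, 128), dtype=np.float32))
            zero_counts.append(g if integ is not None else g)
            continue
        fp = 4 * bs
        ys = np.arange(0, h - fp + 1, step)
        xs = np.arange(0, w - fp + 1, step)
        # cell sums from the integral image for every window start
        cs = (
            integ[:, bs:, bs:] - integ[:, :-bs, bs:]
            - integ[:, bs:, :-bs] + integ[:, :-bs, :-bs]
        )  # (8, h-bs+1, w-bs+1)
        rows = (ys[:, None] + np.arange(4)[None, :] * bs).ravel()  # (ny*4,)
        cols = (xs[:, None] + np.arange(4)[None, :] * bs).ravel()
        sub = cs[:, rows][:, :, cols]  # (8, ny*4, nx*4)
        sub = sub.reshape(8, len(ys), 4, len(xs), 4)
        # layout: cells row-major (i, j), then 8 orientations per cell
        desc = sub.transpose(1, 3, 2, 4, 0).reshape(g, 128)
        norms = np.linalg.norm(desc, axis=1)
        keep = norms > _ZERO_NORM_EPS
        kept = desc[keep] / norms[keep, None]
        kept = np.minimum(kept, 0.2)
        kept /= np.linalg.norm(kept, axis=1, keepdims=True)
        descriptors.append(kept.astype(np.float32))
        zero_counts.append(int((~keep).sum()))
    return DescriptorSet(tuple(scales), descriptors, zero_counts, grid_counts)


# ---------------------------------------------------------------------------
# descriptor pool and codebook
# ---------------------------------------------------------------------------

def sample_pool(
    descriptor_sets: list[DescriptorSet],
    pool_size: int = DEFAULT_POOL_SIZE,
    per_image_quota: int | None = None,
    seed: int = 0,
    return_provenance: bool = False,
):
    """Randomly sample nonzero descriptors per image into per-scale pools.

    Each image contributes up to ``per_image_quota`` descriptors (default:
    ``ceil(pool_size / n_images)``); if the quota-limited draw falls short of
    ``pool_size`` while the corpus holds more, the deficit is topped up
    uniformly from the remaining descriptors.  The pool therefore has
    exactly ``pool_size`` members whenever the corpus supplies that many.
    """
    if not descriptor_sets:
        raise ValueError("empty descriptor corpus")
    scales = descriptor_sets[0].scales
    n_images = len(descriptor_sets)
    quota = per_image_quota or max(1, math.ceil(pool_size / n_images))
    root = np.random.SeedSequence(seed)
    pools: dict[int, np.ndarray] = {}
    provenance: dict[int, np.ndarray] = {}
    for s, scale in enumerate(scales):
        counts = [ds.descriptors[s].shape[0] for ds in descriptor_sets]
        total = sum(counts)
        if total == 0:
            raise ValueError(f"no nonzero descriptors anywhere at scale {scale}")
        rng = np.random.default_rng(root.spawn(1)[0])
        chosen: list[np.ndarray] = []
        owners: list[np.ndarray] = []
        left_desc: list[np.ndarray] = []
        left_owner: list[np.ndarray] = []
        for i, ds in enumerate(descriptor_sets):
            n = counts[i]
            if n == 0:
                continue
            take = min(quota, n)
            idx = rng.choice(n, size=take, replace=False)
            chosen.append(ds.descriptors[s][idx])
            owners.append(np.full(take, i))
            if take < n:
                rest = np.setdiff1d(np.arange(n), idx, assume_unique=False)
                left_desc.append(ds.descriptors[s][rest])
                left_owner.append(np.full(len(rest), i))
        pool = np.concatenate(chosen, axis=0)
        owner = np.concatenate(owners)
        if pool.shape[0] > pool_size:
            idx = rng.choice(pool.shape[0], size=pool_size, replace=False)
            pool, owner = pool[idx], owner[idx]
        elif pool.shape[0] < pool_size and left_desc:
            deficit = pool_size - pool.shape[0]
            extra = np.concatenate(left_desc, axis=0)
            extra_owner = np.concatenate(left_owner)
            pick = rng.choice(extra.shape[0], size=min(deficit, extra.shape[0]),
                              replace=False)
            pool = np.concatenate([pool, extra[pick]], axis=0)
            owner = np.concatenate([owner, extra_owner[pick]])
        pools[scale] = pool
        provenance[scale] = owner
    if return_provenance:
        return pools, provenance
    return pools


@dataclass
class Codebook:
    """Visual-word centroids for one descriptor scale."""

    scale: int
    centroids: np.ndarray
    within_cluster_distance: float
    n_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids)
        if self.centroids.ndim != 2:
            raise ValueError("centroids must be a K x D matrix")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


def build_codebook(
    pool: np.ndarray,
    K: int = DEFAULT_K,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    scale: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> Codebook:
    """K-means codebook; best of ``restarts`` random initialisations.

    Each restart runs Lloyd's algorithm from K descriptors drawn uniformly
    from the pool; the restart with the smallest within-cluster distance
    (sum of squared distances of pool members to their centroid) wins.
    Restart seeds derive from ``seed`` in order, so increasing ``restarts``
    can only keep or improve the selected distance.
    """
    pool = np.asarray(pool, dtype=np.float64)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if pool.shape[0] < K:
        raise ValueError(
            f"pool of {pool.shape[0]} descriptors cannot support K={K} words"
        )
    children = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for child in children:
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        km = KMeans(
            n_clusters=K, init="random", n_init=1, algorithm="lloyd",
            max_iter=max_iter, tol=tol, random_state=rs,
        ).fit(pool)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    return Codebook(
        scale=scale,
        centroids=best.cluster_centers_,
        within_cluster_distance=float(best.inertia_),
        n_restarts=restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# quantisation and aggregation
# ---------------------------------------------------------------------------

def quantize(
    descriptor_set: DescriptorSet,
    codebooks: dict[int, Codebook],
    normalize: str | None = None,
) -> np.ndarray:
    """Per-image bag-of-words vector: per scale, K word counts (nearest
    centroid by Euclidean distance) followed by the zero-descriptor slot;
    scales concatenated in order.  Length = (K + 1) x n_scales.

    ``normalize='l1'`` rescales each scale block to unit sum (empty blocks
    stay zero); default is raw counts.
    """
    if tuple(sorted(codebooks)) != tuple(sorted(descriptor_set.scales)):
        raise ValueError(
            f"codebook scales {sorted(codebooks)} do not match descriptor "
            f"scales {sorted(descriptor_set.scales)}"
        )
    blocks = []
    for s, scale in enumerate(descriptor_set.scales):
        cb = codebooks[scale]
        desc = descriptor_set.descriptors[s]
        counts = np.zeros(cb.K, dtype=np.float64)
        if desc.shape[0]:
            assign, _ = pairwise_distances_argmin_min(
                desc.astype(np.float64), cb.centroids
            )
            counts = np.bincount(assign, minlength=cb.K).astype(np.float64)
        block = np.concatenate([counts, [float(descriptor_set.zero_counts[s])]])
        if normalize == "l1" and block.sum() > 0:
            block = block / block.sum()
        blocks.append(block)
    return np.concatenate(blocks)


def assign_intervals(positions, n_intervals: int = DEFAULT_INTERVALS) -> np.ndarray:
    """Equal-width sagittal intervals over [min(pos), max(pos)].

    The maximum position is clamped into the last interval; a degenerate
    range (single section or identical positions) maps everything to
    interval 0.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no section positions given")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite section position")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    lo, hi = positions.min(), positions.max()
    if hi == lo:
        return np.zeros(positions.shape, dtype=int)
    idx = np.floor((positions - lo) / (hi - lo) * n_intervals).astype(int)
    return np.clip(idx, 0, n_intervals - 1)


def build_global_bow(
    per_image_vectors: list[np.ndarray],
    interval_assignment,
    n_intervals: int = DEFAULT_INTERVALS,
) -> np.ndarray:
    """Average per-section vectors within each sagittal interval and
    concatenate the interval means in order; empty intervals contribute
    zeros.  Global length = per-section length x n_intervals."""
    if not per_image_vectors:
        raise ValueError("no per-image vectors")
    vecs = np.asarray(per_image_vectors, dtype=np.float64)
    if vecs.ndim != 2:
        raise ValueError("per-image vectors must share one length")
    assignment = np.asarray(interval_assignment, dtype=int)
    if assignment.shape[0] != vecs.shape[0]:
        raise ValueError("one interval index per section is required")
    p = vecs.shape[1]
    out = np.zeros(p * n_intervals)
    for k in range(n_intervals):
        members = vecs[assignment == k]
        if members.shape[0]:
            out[k * p: (k + 1) * p] = members.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------

def build_codebooks(
    descriptor_sets: list[DescriptorSet],
    K: int = DEFAULT_K,
    pool_size: int = DEFAULT_POOL_SIZE,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    per_image_quota: int | None = None,
    max_iter: int = 300,
) -> dict[int, Codebook]:
    """Sample the descriptor pool and fit one codebook per scale."""
    pools = sample_pool(descriptor_sets, pool_size, per_image_quota, seed=seed)
    children = np.random.SeedSequence(seed).spawn(len(pools))
    books = {}
    for (scale, pool), child in zip(sorted(pools.items()), children):
        books[scale] = build_codebook(
            pool, K=K, restarts=restarts,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            scale=scale, max_iter=max_iter,
        )
    return books


def bow_feature_matrix(
    stacks: list[SectionStack],
    scales: tuple = DEFAULT_SCALES,
    step: int = DEFAULT_STEP,
    downsample: int = DEFAULT_DOWNSAMPLE,
    K: int = DEFAULT_K,
    pool_size: int = DEFAULT_POOL_SIZE,
    restarts: int = DEFAULT_RESTARTS,
    n_intervals: int = DEFAULT_INTERVALS,
    seed: int = 0,
    normalize: str | None = None,
    codebooks: dict[int, Codebook] | None = None,
    kmeans_max_iter: int = 300,
) -> FeatureMatrix:
    """Full bag-of-words pipeline over a corpus of section stacks.

    One codebook per scale is learned from the whole corpus (all sections of
    all genes, mirroring per-stage codebook construction) unless pre-built
    ``codebooks`` are supplied; every section is quantised, grouped into
    sagittal intervals and aggregated into the per-gene global vector.
    """
    per_stack_sets: list[list[DescriptorSet]] = []
    flat: list[DescriptorSet] = []
    for stack in stacks:
        sets = [dense_descriptors(im, scales, step, downsample) for im in stack.images]
        per_stack_sets.append(sets)
        flat.extend(sets)
    if codebooks is None:
        codebooks = build_codebooks(
            flat, K=K, pool_size=pool_size, restarts=restarts, seed=seed,
            max_iter=kmeans_max_iter,
        )
    rows = []
    for stack, sets in zip(stacks, per_stack_sets):
        vectors = [quantize(ds, codebooks, normalize=normalize) for ds in sets]
        assignment = assign_intervals(stack.positions, n_intervals)
        rows.append(build_global_bow(vectors, assignment, n_intervals))
    values = np.asarray(rows)
    meta = {
        "scales": list(scales), "step": step, "downsample": downsample,
        "K": K, "pool_size": pool_size, "restarts": restarts,
        "n_intervals": n_intervals, "seed": seed, "normalize": normalize,
    }
    return FeatureMatrix(values, [s.gene_id for s in stacks], "bow", meta)
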