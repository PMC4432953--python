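"""Synthetic ISH section stacks with exact ground-truth annotations.

Real developing-brain ISH data couples three artefacts: a stack of sagittal
section images per gene, a level-tagged structure ontology, and a manual
annotation table (pattern / intensity / density per structure).  This module
generates all three with known ground truth so the whole annotation pipeline
can be exercised and validated without any atlas download.

The model is deliberately minimal rather than anatomically realistic:

* Structures are nested axis-aligned rectangles (children strictly inside
  parents), so every structure mask is available in closed form.
* A detected gene paints a structure-specific oriented sinusoidal grating
  into the structure's rectangle.  Giving each structure its own texture
  signature emulates the fact that brain structures differ in
  cytoarchitecture, and makes expression identifiable from global
  (location-free) texture statistics — which is what both downstream
  representations consume.
* The three pattern classes follow atlas semantics: ``full`` fills the
  structure mask, ``regional`` fills a contiguous half of it, ``gradient``
  ramps the amplitude linearly across it.  ``undetected`` paints nothing.
* Intensity categories low/median/high map to three fixed foreground
  amplitudes above background; sections carry i.i.d. additive Gaussian noise.

Sections within a stack share the painted pattern (the stack samples one
brain) and differ only in noise; positions are section index scaled to
[0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ontology import (
    AnnotationTable,
    LEVEL_CATEGORIES,
    PATTERN_CATEGORIES,
    StructureNode,
    StructureOntology,
    MAX_LEVEL,
)
from .stack import SectionStack

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


# ---------------------------------------------------------------------------
# ontology generation
# ---------------------------------------------------------------------------

def generate_ontology(depth: int, branching: list[int], seed: int = 0) -> StructureOntology:
    """Balanced ontology: level k has prod(branching[:k]) structures.

    ``branching[k-1]`` children hang under every level-(k-1) structure.  The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity and reserved for future stochastic variants.
    """
    if not 1 <= depth <= MAX_LEVEL:
        raise ValueError(f"depth must be in [1, {MAX_LEVEL}], got {depth}")
    if len(branching) != depth:
        raise ValueError(
            f"branching must list one factor per level: expected {depth}, "
            f"got {len(branching)}"
        )
    if any(b < 1 for b in branching):
        raise ValueError(f"branching factors must be positive, got {branching}")
    nodes: list[StructureNode] = []
    prev: list[str] = []
    for level in range(1, depth + 1):
        current: list[str] = []
        if level == 1:
            for i in range(branching[0]):
                sid = f"S1_{i:03d}"
                nodes.append(StructureNode(sid, None, 1))
                current.append(sid)
        else:
            for parent in prev:
                for j in range(branching[level - 1]):
                    sid = f"{parent}.{j}"
                    nodes.append(StructureNode(sid, parent, level))
                    current.append(sid)
        prev = current
    return StructureOntology(nodes)


# ---------------------------------------------------------------------------
# geometry: closed-form nested rectangles
# ---------------------------------------------------------------------------

def structure_rects(
    ontology: StructureOntology, image_size: tuple[int, int], margin: int = 6
) -> dict[str, tuple[int, int, int, int]]:
    """Assign each structure an axis-aligned rectangle (r0, r1, c0, c1).

    Level-1 structures partition the canvas (inset by ``margin``); children
    partition their parent's rectangle (inset by 2 px), splitting along the
    longer axis.  Purely deterministic.
    """
    h, w = image_size
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"image size {image_size} too small for margin {margin}")
    rects: dict[str, tuple[int, int, int, int]] = {}

    def split(rect, n):
        r0, r1, c0, c1 = rect
        out = []
        if (r1 - r0) >= (c1 - c0):  # split rows
            edges = np.linspace(r0, r1, n + 1).round().astype(int)
            for i in range(n):
                out.append((edges[i], edges[i + 1], c0, c1))
        else:
            edges = np.linspace(c0, c1, n + 1).round().astype(int)
            for i in range(n):
                out.append((r0, r1, edges[i], edges[i + 1]))
        return out

    roots = ontology.structures_at(1)
    for node, rect in zip(roots, split((margin, h - margin, margin, w - margin), len(roots))):
        rects[node.structure_id] = rect
    for level in range(2, ontology.depth + 1):
        for parent in ontology.structures_at(level - 1):
            kids = ontology.children(parent.structure_id)
            if not kids:
                continue
            r0, r1, c0, c1 = rects[parent.structure_id]
            inner = (r0 + 2, r1 - 2, c0 + 2, c1 - 2)
            if inner[1] <= inner[0] or inner[3] <= inner[2]:
                raise ValueError(
                    f"structure {parent.structure_id!r} rectangle too small to "
                    f"hold {len(kids)} children; enlarge the image"
                )
            for kid, rect in zip(kids, split(inner, len(kids))):
                rects[kid.structure_id] = rect
    return rects


def structure_masks(
    ontology: StructureOntology, image_size: tuple[int, int], margin: int = 6
) -> dict[str, np.ndarray]:
    """Boolean mask per structure (the ground truth used by the painter)."""
    h, w = image_size
    masks = {}
    for sid, (r0, r1, c0, c1) in structure_rects(ontology, image_size, margin).items():
        m = np.zeros((h, w), dtype=bool)
        m[r0:r1, c0:c1] = True
        masks[sid] = m
    return masks


def structure_texture_params(ontology: StructureOntology) -> dict[str, tuple[float, float]]:
    """(orientation, spatial frequency) of each structure's grating.

    Orientations follow the golden-angle sequence and frequencies cycle over
    a small set, so any two structures differ in at least one texture
    attribute — the property that makes per-structure annotation learnable
    from location-free features.
    """
    freqs = (0.18, 0.26, 0.34)
    out = {}
    for i, sid in enumerate(ontology.ids()):
        theta = (i * _GOLDEN_ANGLE) % math.pi
        out[sid] = (theta, freqs[i % len(freqs)])
    return out


# ---------------------------------------------------------------------------
# rendering parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Photometric model of the synthetic sections (intensities in [0, 1])."""

    background: float = 0.10
    amplitudes: dict = field(
        default_factory=lambda: {"low": 0.20, "median": 0.40, "high": 0.60}
    )
    noise_sigma: float = 0.05
    texture_contrast: float = 0.4  # fraction of amplitude modulated by the grating
    margin: int = 6

    def easy(self) -> "RenderParams":
        """Low-noise variant for detectability / recovery experiments."""
        return replace(self, noise_sigma=0.02)


# ---------------------------------------------------------------------------
# stack generation
# ---------------------------------------------------------------------------

def _pattern_weight(pattern: str, mask: np.ndarray, rect, rng: np.random.Generator) -> np.ndarray:
    """Spatial weight in [0, 1] realising the pattern class on the mask."""
    r0, r1, c0, c1 = rect
    w = np.zeros(mask.shape, dtype=np.float32)
    if pattern == "full":
        w[mask] = 1.0
    elif pattern == "regional":
        # contiguous half of the rectangle, side chosen per gene
        half = np.zeros_like(mask)
        if (r1 - r0) >= (c1 - c0):
            mid = (r0 + r1) // 2
            sl = (slice(r0, mid), slice(c0, c1)) if rng.random() < 0.5 else (
                slice(mid, r1), slice(c0, c1))
        else:
            mid = (c0 + c1) // 2
            sl = (slice(r0, r1), slice(c0, mid)) if rng.random() < 0.5 else (
                slice(r0, r1), slice(mid, c1))
        half[sl] = True
        w[mask & half] = 1.0
    elif pattern == "gradient":
        rows = np.arange(mask.shape[0], dtype=np.float32)
        cols = np.arange(mask.shape[1], dtype=np.float32)
        if rng.random() < 0.5:
            ramp = np.clip((rows[:, None] - r0) / max(r1 - 1 - r0, 1), 0, 1)
            ramp = np.broadcast_to(ramp, mask.shape)
        else:
            ramp = np.clip((cols[None, :] - c0) / max(c1 - 1 - c0, 1), 0, 1)
            ramp = np.broadcast_to(ramp, mask.shape)
        if rng.random() < 0.5:
            ramp = 1.0 - ramp
        w = np.where(mask, ramp, 0.0).astype(np.float32)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown pattern {pattern!r}")
    return w


def _validate_gene_spec(gene_spec: dict, ontology: StructureOntology) -> None:
    for sid, (pattern, intensity) in gene_spec.items():
        if sid not in ontology:
            raise ValueError(f"gene_spec references unknown structure {sid!r}")
        if pattern not in PATTERN_CATEGORIES:
            raise ValueError(f"unknown pattern category {pattern!r}")
        if intensity not in LEVEL_CATEGORIES:
            raise ValueError(f"unknown intensity category {intensity!r}")
        if (pattern == "undetected") != (intensity == "undetected"):
            raise ValueError(
                f"structure {sid!r}: pattern and intensity must be undetected together"
            )


def generate_stack(
    gene_spec: dict,
    ontology: StructureOntology,
    n_sections: int = 17,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    params: RenderParams | None = None,
    gene_id: str = "gene",
    stage: str = "E13.5",
) -> tuple[SectionStack, list[tuple[str, str, str, str]]]:
    """Render one gene's stack and return it with its annotation rows.

    ``gene_spec`` maps structure IDs to ``(pattern, intensity)``; density in
    the emitted rows mirrors intensity (the generator models one expression
    strength per structure).  The returned rows are exactly the ground truth
    painted into the images.  Deterministic under ``seed``.
    """
    params = params or RenderParams()
    if n_sections < 1:
        raise ValueError(f"n_sections must be >= 1, got {n_sections}")
    h, w = image_size
    if h < 1 or w < 1:
        raise ValueError(f"image size must be positive, got {image_size}")
    _validate_gene_spec(gene_spec, ontology)

    rng = np.random.default_rng(seed)
    rects = structure_rects(ontology, image_size, params.margin)
    textures = structure_texture_params(ontology)
    rows_grid, cols_grid = np.mgrid[0:h, 0:w].astype(np.float32)

    # gene-level (section-independent) painted signal
    signal = np.zeros((h, w), dtype=np.float32)
    rows: list[tuple[str, str, str, str]] = []
    for sid in sorted(gene_spec):
        pattern, intensity = gene_spec[sid]
        if pattern == "undetected":
            for metric in ("pattern", "intensity", "density"):
                rows.append((gene_id, sid, metric, "undetected"))
            continue
        rect = rects[sid]
        mask = np.zeros((h, w), dtype=bool)
        mask[rect[0]:rect[1], rect[2]:rect[3]] = True
        amp = params.amplitudes[intensity]
        theta, freq = textures[sid]
        phase = rng.uniform(0, 2 * math.pi)
        grating = 0.5 + 0.5 * np.sin(
            2 * math.pi * freq * (cols_grid * math.cos(theta) + rows_grid * math.sin(theta))
            + phase
        )
        weight = _pattern_weight(pattern, mask, rect, rng)
        tc = params.texture_contrast
        signal += amp * weight * ((1.0 - tc) + tc * grating.astype(np.float32))
        rows.append((gene_id, sid, "pattern", pattern))
        rows.append((gene_id, sid, "intensity", intensity))
        rows.append((gene_id, sid, "density", intensity))

    positions = (
        np.linspace(0.0, 1.0, n_sections) if n_sections > 1 else np.zeros(1)
    )
    images = []
    for _ in range(n_sections):
        noise = rng.normal(0.0, params.noise_sigma, size=(h, w)).astype(np.float32)
        img = np.clip(params.background + signal + noise, 0.0, 1.0)
        images.append(img.astype(np.float32))
    stack = SectionStack(gene_id, stage, images, positions)
    return stack, rows


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated dataset.

    Defaults model one developmental stage with four disjoint level-1
    structures, 17 sections per gene (ISH experiments produce 15-20) and the
    rendering model above.
    """

    depth: int = 1
    branching: tuple = (4,)
    n_sections: int = 17
    image_size: tuple = (256, 256)
    params: RenderParams = field(default_factory=RenderParams)
    detected_patterns: tuple = ("full", "regional", "gradient")
    detected_intensities: tuple = ("low", "median", "high")


def easy_config(**overrides) -> SyntheticConfig:
    """High-signal, low-noise conditions: detected genes express at high
    intensity over the full structure, noise sigma is small."""
    base = SyntheticConfig(
        params=RenderParams().easy(),
        detected_patterns=("full",),
        detected_intensities=("high",),
    )
    return replace(base, **overrides)


def generate_dataset(
    n_genes: int,
    undetected_fraction: float,
    stage_label: str = "E13.5",
    config: SyntheticConfig | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Generate a cohort of genes with the atlas's class imbalance.

    Each (gene, structure) is undetected independently with probability
    ``undetected_fraction`` — manual annotation of the real atlas is
    dominated by the undetected class, and this knob reproduces that
    imbalance at any strength.  Detected structures draw pattern and
    intensity uniformly from the configured category sets.

    Returns ``(stacks, ontology, table)``; when ``out_dir`` is given the
    dataset is also written to disk (PNG sections, ``ontology.json``,
    ``annotations.csv``, ``manifest.csv``) via :mod:`ishannot.io`.
    """
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    if not 0.0 < undetected_fraction <= 1.0:
        raise ValueError("undetected_fraction must be in (0, 1]")
    config = config or SyntheticConfig()
    ontology = generate_ontology(config.depth, list(config.branching), seed=seed)
    root = np.random.SeedSequence(seed)
    gene_seeds = root.spawn(n_genes)

    stacks: list[SectionStack] = []
    all_rows: list[tuple[str, str, str, str]] = []
    for g, gseq in enumerate(gene_seeds):
        rng = np.random.default_rng(gseq)
        gene_id = f"gene{g:04d}"
        spec = {}
        for sid in ontology.ids():
            if rng.random() < undetected_fraction:
                spec[sid] = ("undetected", "undetected")
            else:
                pattern = config.detected_patterns[
                    rng.integers(len(config.detected_patterns))
                ]
                intensity = config.detected_intensities[
                    rng.integers(len(config.detected_intensities))
                ]
                spec[sid] = (pattern, intensity)
        stack_seed = int(rng.integers(0, 2**31 - 1))
        stack, rows = generate_stack(
            spec, ontology, config.n_sections, tuple(config.image_size),
            seed=stack_seed, params=config.params, gene_id=gene_id,
            stage=stage_label,
        )
        stacks.append(stack)
        all_rows.extend(rows)

    table = AnnotationTable.from_records(all_rows)
    if out_dir is not None:
        from .io import write_dataset

        write_dataset(out_dir, stacks, ontology, table)
    return stacks, ontology, table
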