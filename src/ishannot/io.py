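"""Readers and writers for every on-disk artifact, plus pipeline config.

Dataset layout::

    <root>/
      ontology.json          # {"nodes": [{"id", "parent", "level"}, ...]}
      annotations.csv        # gene_id,structure_id,metric,category
      manifest.csv           # gene_id,section_index,position,stage,path
      <gene_id>/section_<k>.png   # 8-bit grayscale sections

Feature matrices are stored as ``<base>.npy`` (values) with a ``<base>.json``
sidecar carrying gene IDs, the representation tag and the extraction-config
fingerprint.  Evaluation reports are plain CSV plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .annotate import EvaluationReport
from .features import FeatureMatrix
from .ontology import AnnotationTable, OntologyError, StructureOntology
from .stack import SectionStack

log = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Missing or inconsistent dataset artefact."""


class FeatureTagError(ValueError):
    """Feature file holds a different representation than requested."""


# ---------------------------------------------------------------------------
# dataset write / read
# ---------------------------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    return np.round(arr * 255).astype(np.uint8)


def write_dataset(root, stacks: list[SectionStack], ontology: StructureOntology,
                  table: AnnotationTable) -> None:
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
        probe = root / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DatasetError(f"output directory {root} is not writable: {exc}") from exc

    (root / "ontology.json").write_text(
        json.dumps({"nodes": ontology.to_records()}, indent=1)
    )
    table.frame.to_csv(root / "annotations.csv", index=False)
    manifest = []
    for stack in stacks:
        gene_dir = root / stack.gene_id
        gene_dir.mkdir(exist_ok=True)
        for k, (img, pos) in enumerate(zip(stack.images, stack.positions)):
            rel = f"{stack.gene_id}/section_{k:02d}.png"
            iio.imwrite(root / rel, _to_uint8(img))
            manifest.append({
                "gene_id": stack.gene_id, "section_index": k,
                "position": float(pos), "stage": stack.stage, "path": rel,
            })
    pd.DataFrame(manifest).to_csv(root / "manifest.csv", index=False)


def read_image(path) -> np.ndarray:
    """PNG/TIFF, 8- or 16-bit, grayscale or RGB, as float in [0, 1]."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float32)
    return arr


def read_dataset(root) -> tuple[list[SectionStack], StructureOntology, AnnotationTable]:
    """Load a dataset, cross-checking gene and structure IDs.

    Hard errors: missing files, a manifest path with no image, an annotation
    referencing a structure absent from the ontology, a malformed ontology
    node.  Genes annotated but without any section image are dropped with a
    warning.
    """
    root = Path(root)
    for name in ("ontology.json", "annotations.csv", "manifest.csv"):
        if not (root / name).exists():
            raise DatasetError(f"missing dataset file: {root / name}")

    try:
        records = json.loads((root / "ontology.json").read_text())["nodes"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise OntologyError(f"malformed ontology file {root / 'ontology.json'}") from exc
    ontology = StructureOntology.from_records(records)

    table = AnnotationTable(pd.read_csv(root / "annotations.csv", dtype=str))
    unknown = set(table.frame["structure_id"]) - set(ontology.ids())
    if unknown:
        raise DatasetError(
            f"annotations reference structures absent from the ontology: "
            f"{sorted(unknown)}"
        )

    manifest = pd.read_csv(root / "manifest.csv")
    stacks: list[SectionStack] = []
    for gene_id, group in manifest.groupby("gene_id", sort=True):
        group = group.sort_values("position", kind="stable")
        images, positions = [], []
        for _, row in group.iterrows():
            path = root / row["path"]
            if not path.exists():
                raise DatasetError(f"manifest references a missing image: {path}")
            images.append(read_image(path))
            positions.append(float(row["position"]))
        stacks.append(SectionStack(str(gene_id), str(group["stage"].iloc[0]),
                                   images, np.asarray(positions)))

    imaged = {s.gene_id for s in stacks}
    orphans = sorted(set(table.frame["gene_id"]) - imaged)
    if orphans:
        log.warning("annotated genes without images dropped: %s", orphans)
        table = AnnotationTable(
            table.frame[~table.frame["gene_id"].isin(orphans)].reset_index(drop=True)
        )
    return stacks, ontology, table


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, base_path) -> None:
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), fm.values)
    sidecar = {
        "gene_ids": fm.gene_ids,
        "tag": fm.tag,
        "n_features": fm.n_features,
        "meta": fm.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(base_path, expect_tag: str | None = None) -> FeatureMatrix:
    base = Path(base_path)
    values = np.load(base.with_suffix(".npy"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if expect_tag is not None and sidecar["tag"] != expect_tag:
        raise FeatureTagError(
            f"{base}: holds representation {sidecar['tag']!r}, "
            f"but {expect_tag!r} was requested"
        )
    return FeatureMatrix(values, list(sidecar["gene_ids"]), sidecar["tag"],
                         dict(sidecar.get("meta", {})))


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

def write_report(reports: list[EvaluationReport], csv_path, json_path,
                 config: dict | None = None) -> None:
    frames = [r.rows for r in reports if len(r.rows)]
    combined = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=list(EvaluationReport.ROW_COLUMNS)))
    Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
    combined.to_csv(csv_path, index=False)
    summary = {
        "per_level_overall_auc": {str(r.level): r.overall_auc for r in reports},
        "achieved_thresholds": {str(r.level): r.achieved_threshold for r in reports},
        "excluded_structures": {str(r.level): r.excluded_structures for r in reports},
        "representation": reports[0].representation if reports else None,
        "stage": reports[0].stage if reports else None,
        "config": config or {},
    }
    Path(json_path).write_text(json.dumps(summary, indent=1))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Single source of truth for the pipeline's constants.

    Defaults: images downsampled by 4 for descriptor extraction, K = 500
    visual words from a 100,000-descriptor pool, 7 sagittal intervals,
    231x231 network input, balance-maximising split with 2/3 training
    fraction and up to 5,000 attempts per threshold.
    """

    stage: str = "E13.5"
    representation: str = "bow"  # "bow" or "cnn:L<tap>"
    # bag-of-words
    scales: tuple = (4, 8, 16)
    step: int = 4
    downsample: int = 4
    K: int = 500
    pool_size: int = 100_000
    restarts: int = 5
    n_intervals: int = 7
    normalize: str | None = None
    # cnn
    tap: int = 12
    pooling: str = "max"
    input_size: int = 231
    weights_source: str | None = None  # None -> seeded random
    # split + classifier
    train_fraction: float = 2.0 / 3.0
    max_attempts: int = 5000
    threshold_start: float = 1.0 / 3.0
    threshold_decay: float = 0.8
    threshold_floor: float = 0.01
    lam: float = 1.0
    metric: str = "pattern"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in data:
            data["scales"] = tuple(data["scales"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
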