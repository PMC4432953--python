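"""Hierarchical brain-structure ontology and categorical annotation tables.

The developing-brain reference atlas organises anatomical structures in a
tree whose depth runs from level 1 (coarsest, e.g. forebrain/midbrain/
hindbrain) down to level 10 (finest subdivisions).  Expression of each gene
is described per structure by three categorical metrics:

* ``pattern``   — ``undetected`` / ``full`` / ``regional`` / ``gradient``
* ``intensity`` — ``undetected`` / ``low`` / ``median`` / ``high``
* ``density``   — ``undetected`` / ``low`` / ``median`` / ``high``

A gene that is undetected in a structure is undetected under all three
metrics; that constraint is validated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MAX_LEVEL = 10

METRICS = ("pattern", "intensity", "density")
PATTERN_CATEGORIES = ("undetected", "full", "regional", "gradient")
LEVEL_CATEGORIES = ("undetected", "low", "median", "high")

_VALID_CATEGORIES = {
    "pattern": set(PATTERN_CATEGORIES),
    "intensity": set(LEVEL_CATEGORIES),
    "density": set(LEVEL_CATEGORIES),
}


class OntologyError(ValueError):
    """Malformed ontology: duplicate IDs, bad parent levels, gaps in levels."""


@dataclass(frozen=True)
class StructureNode:
    structure_id: str
    parent_id: str | None  # None for level-1 structures
    level: int


@dataclass
class StructureOntology:
    """Level-tagged structure hierarchy.

    Invariants (checked in ``validate``): structure IDs are unique; every
    non-root node's parent exists and sits exactly one level above it; levels
    are contiguous from 1 to the maximum present.
    """

    nodes: list[StructureNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------
    @property
    def depth(self) -> int:
        return max((n.level for n in self.nodes), default=0)

    def ids(self) -> list[str]:
        return [n.structure_id for n in self.nodes]

    def structures_at(self, level: int) -> list[StructureNode]:
        return [n for n in self.nodes if n.level == level]

    def level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for n in self.nodes:
            counts[n.level] = counts.get(n.level, 0) + 1
        return counts

    def children(self, structure_id: str) -> list[StructureNode]:
        return [n for n in self.nodes if n.parent_id == structure_id]

    def node(self, structure_id: str) -> StructureNode:
        for n in self.nodes:
            if n.structure_id == structure_id:
                return n
        raise KeyError(structure_id)

    def __contains__(self, structure_id: str) -> bool:
        return any(n.structure_id == structure_id for n in self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen: dict[str, StructureNode] = {}
        for n in self.nodes:
            if n.structure_id in seen:
                raise OntologyError(f"duplicate structure ID {n.structure_id!r}")
            seen[n.structure_id] = n
        levels = {n.level for n in self.nodes}
        if levels and levels != set(range(1, max(levels) + 1)):
            raise OntologyError(f"levels not contiguous from 1: {sorted(levels)}")
        for n in self.nodes:
            if n.level == 1:
                if n.parent_id is not None:
                    raise OntologyError(
                        f"level-1 structure {n.structure_id!r} must be a root node"
                    )
                continue
            if n.parent_id not in seen:
                raise OntologyError(
                    f"structure {n.structure_id!r} has unknown parent {n.parent_id!r}"
                )
            parent = seen[n.parent_id]
            if parent.level != n.level - 1:
                raise OntologyError(
                    f"structure {n.structure_id!r} at level {n.level} has parent "
                    f"{n.parent_id!r} at level {parent.level}; expected level {n.level - 1}"
                )

    # -- (de)serialisation ----------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {"id": n.structure_id, "parent": n.parent_id, "level": n.level}
            for n in self.nodes
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "StructureOntology":
        nodes = []
        for r in records:
            try:
                nodes.append(
                    StructureNode(str(r["id"]),
                                  None if r["parent"] in (None, "") else str(r["parent"]),
                                  int(r["level"]))
                )
            except (KeyError, TypeError) as exc:
                raise OntologyError(f"malformed ontology record {r!r}") from exc
        return cls(nodes)


def ontology_from_level_counts(counts: list[int]) -> StructureOntology:
    """Build an ontology with a prescribed number of structures per level.

    Children at level ``k`` are distributed round-robin over the level
    ``k-1`` structures, which allows arbitrary per-level counts (the atlas
    hierarchy is not a uniform tree).  Deterministic.
    """
    if not counts or any(c < 1 for c in counts):
        raise ValueError("level counts must be positive")
    if len(counts) > MAX_LEVEL:
        raise ValueError(f"at most {MAX_LEVEL} levels supported")
    nodes: list[StructureNode] = []
    prev: list[str] = []
    for level, count in enumerate(counts, start=1):
        current = []
        for i in range(count):
            sid = f"L{level}_{i:03d}"
            parent = None if level == 1 else prev[i % len(prev)]
            nodes.append(StructureNode(sid, parent, level))
            current.append(sid)
        prev = current
    return StructureOntology(nodes)


class AnnotationError(ValueError):
    """Annotation table violates a categorical or consistency constraint."""


@dataclass
class AnnotationTable:
    """Per-gene, per-structure categorical annotations.

    Backed by a DataFrame with columns ``gene_id``, ``structure_id``,
    ``metric``, ``category``.  Each (gene, structure, metric) appears at most
    once, categories are drawn from the metric's vocabulary, and an
    undetected pattern forces intensity and density to be undetected.
    """

    frame: pd.DataFrame

    COLUMNS = ("gene_id", "structure_id", "metric", "category")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise AnnotationError(f"annotation table missing columns {sorted(missing)}")
        self.frame = self.frame[list(self.COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        bad_metric = set(df["metric"]) - set(METRICS)
        if bad_metric:
            raise AnnotationError(f"unknown metrics {sorted(bad_metric)}")
        for metric, valid in _VALID_CATEGORIES.items():
            cats = set(df.loc[df["metric"] == metric, "category"])
            if cats - valid:
                raise AnnotationError(
                    f"invalid {metric} categories {sorted(cats - valid)}"
                )
        dup = df.duplicated(subset=["gene_id", "structure_id", "metric"])
        if dup.any():
            first = df[dup].iloc[0]
            raise AnnotationError(
                f"duplicate record for ({first.gene_id}, {first.structure_id}, "
                f"{first.metric})"
            )
        # undetected pattern implies undetected intensity and density
        wide = df.pivot_table(
            index=["gene_id", "structure_id"], columns="metric",
            values="category", aggfunc="first",
        )
        if "pattern" in wide.columns:
            undet = wide["pattern"] == "undetected"
            for metric in ("intensity", "density"):
                if metric in wide.columns:
                    clash = undet & wide[metric].notna() & (wide[metric] != "undetected")
                    if clash.any():
                        gene, struct = wide.index[clash.to_numpy()][0]
                        raise AnnotationError(
                            f"gene {gene!r} undetected in {struct!r} for pattern "
                            f"but not for {metric}"
                        )

    def genes(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique())

    def structures(self) -> list[str]:
        return sorted(self.frame["structure_id"].unique())

    def subset_metric(self, metric: str) -> pd.DataFrame:
        if metric not in METRICS:
            raise AnnotationError(f"unknown metric {metric!r}")
        return self.frame[self.frame["metric"] == metric]

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))
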