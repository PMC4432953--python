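"""Gene-level feature matrices shared by both representations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureMatrix:
    """Genes x feature-dimension array with IDs and a representation tag.

    ``tag`` is ``"bow"`` for the bag-of-visual-words representation or
    ``"cnn:L<tap>"`` for convolutional features tapped at a given layer.
    ``meta`` echoes the extraction configuration (a reproducibility
    fingerprint carried through serialisation).
    """

    values: np.ndarray
    gene_ids: list[str]
    tag: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (genes x features)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene IDs"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def reorder(self, gene_ids: list[str]) -> "FeatureMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return FeatureMatrix(self.values[idx], list(gene_ids), self.tag, dict(self.meta))
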