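"""Section stacks: one gene's ordered sagittal ISH images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SectionStack:
    """Ordered sagittal sections for one gene at one developmental stage.

    ``images`` holds 2-D (grayscale) or 3-channel float arrays in [0, 1];
    ``positions`` are sagittal coordinates in arbitrary units, ascending.
    An ISH experiment typically yields 15-20 sections per gene.
    """

    gene_id: str
    stage: str
    images: list[np.ndarray] = field(default_factory=list)
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.images) == 0:
            raise ValueError(f"stack for gene {self.gene_id!r} has no sections")
        if len(self.images) != len(self.positions):
            raise ValueError("images and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite section position")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("sections must be sorted by ascending position")
        dtypes = {im.dtype for im in self.images}
        if len(dtypes) > 1:
            raise ValueError(f"mixed image dtypes in stack: {dtypes}")

    def __len__(self) -> int:
        return len(self.images)
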