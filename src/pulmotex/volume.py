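"""In-memory containers for volumes of interest (VOIs) and labeled datasets.

A VOI is a small cube of CT intensities — in the pipeline always 32x32x32
voxels — that is classified as one of six pulmonary texture patterns:
consolidation (CON), ground-glass opacity (GGO), honeycombing (HCM),
emphysema (EMP), nodule (NOD) or normal parenchyma (NOR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six-class vocabulary, in the fixed order used everywhere (this order
#: also breaks classifier vote ties, so it is part of the public contract).
PATTERN_LABELS: tuple[str, ...] = ("CON", "GGO", "HCM", "EMP", "NOD", "NOR")

#: Edge length of a pipeline VOI, in voxels.
VOI_SHAPE: tuple[int, int, int] = (32, 32, 32)


def check_label(label: str) -> str:
    """Validate a pattern label, returning it unchanged.

    Raises
    ------
    ValueError
        If ``label`` is not one of the six known patterns; the message lists
        the valid vocabulary.
    """
    if label not in PATTERN_LABELS:
        raise ValueError(
            f"unknown pattern label {label!r}; valid labels are "
            f"{', '.join(PATTERN_LABELS)}"
        )
    return label


@dataclass
class Volume:
    """One VOI: a 3D scalar grid with optional physical spacing.

    Axes are treated as abstract (x, y, z) — the features downstream are
    orientation-agnostic patch moments, so no anatomical meaning is attached.
    Voxels are stored as float64 regardless of any on-disk integer type.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"volume must be a 3D grid, got ndim={self.voxels.ndim}"
            )
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def require_finite(self) -> "Volume":
        """Raise if any voxel is NaN/inf, naming the first offending index."""
        finite = np.isfinite(self.voxels)
        if not finite.all():
            idx = tuple(int(i) for i in np.argwhere(~finite)[0])
            raise ValueError(
                f"volume {self.identifier!r} contains a non-finite voxel, "
                f"first at index {idx}"
            )
        return self

    def require_shape(self, shape: tuple[int, int, int] = VOI_SHAPE) -> "Volume":
        """Raise unless the volume has exactly the given shape (pipeline gate)."""
        if tuple(self.voxels.shape) != tuple(shape):
            raise ValueError(
                f"volume {self.identifier!r} has shape {self.voxels.shape}, "
                f"pipeline requires {tuple(shape)}"
            )
        return self


@dataclass
class LabeledDataset:
    """A list of VOIs with class labels and optional train/test split tags."""

    volumes: list[Volume] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    split_tags: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.labels):
            raise ValueError(
                f"{len(self.volumes)} volumes but {len(self.labels)} labels"
            )
        for label in self.labels:
            check_label(label)
        if self.split_tags is not None and len(self.split_tags) != len(self.labels):
            raise ValueError("split_tags length does not match dataset size")

    def __len__(self) -> int:
        return len(self.volumes)

    def subset(self, indices) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            volumes=[self.volumes[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            split_tags=None
            if self.split_tags is None
            else [self.split_tags[i] for i in idx],
        )
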