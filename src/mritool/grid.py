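"""Image container used throughout the toolkit.

Arrays are indexed (row, column[, slice]), 0-based, half-open ranges.
Intensity images are non-negative and finite; spacing is physical voxel
size in millimetres along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class ImageGrid:
    """A 2-D or 3-D grid of non-negative intensities plus geometry metadata.

    Parameters
    ----------
    values : ndarray
        Intensities, shape ``(rows, cols)`` or ``(rows, cols, slices)``.
    spacing : tuple of float
        Physical size of a voxel along each axis, in mm. Defaults to 1 mm.
    modality_tag : str
        Free-text acquisition tag, e.g. ``"T1WI"``, ``"T2WI"``, ``"synthetic"``.
    metadata : dict
        Opaque acquisition metadata (TR/TE/FOV strings and the like),
        preserved through I/O round trips where the format allows.
    """

    values: np.ndarray
    spacing: tuple[float, ...] = ()
    modality_tag: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise InputError(
                f"ImageGrid requires a 2-D or 3-D array, got ndim={self.values.ndim}"
            )
        if any(s < 1 for s in self.values.shape):
            raise InputError(f"degenerate image shape {self.values.shape}")
        if not self.spacing:
            self.spacing = (1.0,) * self.values.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise InputError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.values.ndim}-D image"
            )
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing entries must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("intensity image contains non-finite values")
        if np.any(self.values < 0):
            raise InputError("intensity image contains negative values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def like(self, values: np.ndarray) -> "ImageGrid":
        """New grid with the same geometry/metadata but different values."""
        return ImageGrid(
            values=np.asarray(values, dtype=float),
            spacing=self.spacing,
            modality_tag=self.modality_tag,
            metadata=dict(self.metadata),
        )


def as_image(values, spacing=(), modality_tag="synthetic") -> ImageGrid:
    """Convenience wrapper building an :class:`ImageGrid` from an array."""
    return ImageGrid(np.asarray(values, dtype=float), spacing, modality_tag)
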