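"""In-memory containers for co-registered multi-contrast volumes.

Conventions: arrays are indexed ``(x, y, z)`` for scalar volumes and
``(x, y, z, c)`` for multi-channel volumes.  The slicing axis used for
patch work defaults to axis 0 (the "coronal" axis of the phantom);
in-plane then means the remaining two axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class MultiContrastVolume:
    """A 3D grid with C signal channels (shape ``(x, y, z, c)``)."""

    data: np.ndarray
    channel_labels: list[str]
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,c) array, got {self.data.ndim}D")
        if len(self.channel_labels) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[3]} channels"
            )
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    def channel(self, index: int) -> np.ndarray:
        return self.data[..., index]

    def with_data(self, data: np.ndarray) -> "MultiContrastVolume":
        return MultiContrastVolume(
            data, list(self.channel_labels), self.voxel_size, self.affine.copy()
        )


@dataclass
class TargetVolume:
    """A 3D scalar grid of stain-like intensity."""

    data: np.ndarray
    name: str = "target"
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got {self.data.ndim}D")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "TargetVolume":
        return TargetVolume(data, self.name, self.voxel_size, self.affine.copy())


def check_same_grid(*shapes) -> None:
    """Raise if the 3D grids of the given arrays/volumes differ."""
    dims = []
    for s in shapes:
        if hasattr(s, "shape"):
            s = s.shape
        dims.append(tuple(s[:3]))
    if len(set(dims)) > 1:
        raise ValueError(f"grid mismatch: {dims}")
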