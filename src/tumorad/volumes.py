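"""Core in-memory containers: 3D intensity volumes and binary VOI masks.

An :class:`ImageVolume` is one subject / timepoint / contrast; a
:class:`VOIMask` is a binary tumor volume of interest congruent with it.
Both carry physical voxel spacing in mm and a NIfTI-style affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "VOIMask", "GeometryError"]


class GeometryError(ValueError):
    """Image/mask grids or affines do not match."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass(eq=False)
class ImageVolume:
    """3D scalar intensity grid with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))


@dataclass(eq=False)
class VOIMask:
    """Binary tumor mask congruent with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be binary {{0,1}}, found {uniq[:5]}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def check_aligned(image: ImageVolume, mask: VOIMask, atol: float = 1e-6) -> None:
    """Raise :class:`GeometryError` unless image and mask share grid and affine."""
    if image.shape != mask.shape:
        raise GeometryError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    if not np.allclose(image.affine, mask.affine, atol=atol):
        raise GeometryError("image and mask affines differ")
    if not np.allclose(image.spacing, mask.spacing, atol=atol):
        raise GeometryError(
            f"image spacing {image.spacing} != mask spacing {mask.spacing}"
        )
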