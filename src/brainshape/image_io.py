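"""NIfTI I/O and the voxel-grid contract.

Every downstream measurement (surface area in mm^2, volume in mm^3) relies on
knowing the per-axis voxel edge length. This module is the single place where
volumes enter and leave the package, so the spacing contract is enforced here:
three spatial dimensions, each at least two voxels, strictly positive finite
spacing read from the NIfTI header. Only voxel spacing is consumed from the
header; the rotation part of the affine is ignored because surface area and
volume are rotation-invariant, which avoids a resampling step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Provenance", "VoxelVolume", "read_volume", "write_volume"]


class Provenance(str, enum.Enum):
    """What a volume represents; controls load-time handling."""

    PET = "pet"
    TISSUE_PROB = "tissue_prob"
    MASK = "mask"


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar field with per-axis voxel spacing in millimetres.

    Parameters
    ----------
    data
        3-D array of intensities. Units are arbitrary: the PET threshold is
        fractional, so relative intensities suffice.
    spacing
        Per-axis voxel edge length (mm), strictly positive and finite.
    provenance
        ``pet``, ``tissue_prob`` or ``mask``. Tissue-probability volumes are
        clamped to [0, 1] on construction (segmentation outputs commonly
        contain small numerical excursions).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: Provenance = Provenance.PET

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {data.ndim}-D")
        if min(data.shape) < 2:
            raise ValueError(f"each axis needs >= 2 voxels, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValueError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be finite and > 0, got {spacing}")
        provenance = Provenance(self.provenance)
        if provenance is Provenance.TISSUE_PROB:
            data = np.clip(data, 0.0, 1.0)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "provenance", provenance)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_volume(path: str | Path, expected_provenance: Provenance | str = Provenance.PET) -> VoxelVolume:
    """Read a NIfTI-1/2 file as a :class:`VoxelVolume`.

    4-D images with a singleton last axis are squeezed (multi-frame PET has
    already been averaged upstream and is rejected here). Spacing comes from
    the header zooms; the affine rotation is deliberately ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim > 3:
        extra = data.shape[3:]
        if all(n == 1 for n in extra):
            data = data.reshape(data.shape[:3])
        else:
            raise ValueError(
                f"{path.name}: expected a 3-D image, got shape {data.shape} with "
                "non-singleton extra axes (multi-frame inputs are rejected, not averaged)"
            )
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"{path.name}: non-positive voxel spacing in header: {zooms}")
    return VoxelVolume(data=data, spacing=tuple(float(z) for z in zooms), provenance=Provenance(expected_provenance))


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a :class:`VoxelVolume` to a NIfTI-1 file.

    ``read_volume(write_volume(v))`` is the identity on (data, spacing).
    Masks are stored as unsigned 8-bit; everything else as float64 (lossless
    for the values this package produces).
    """
    path = Path(path)
    data = volume.data
    if volume.provenance is Provenance.MASK:
        data = data.astype(np.uint8)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
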