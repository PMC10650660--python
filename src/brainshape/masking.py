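"""Construction of the measured objects.

Two masks feed the shape scores: the MR brain mask, built by summing the
gray- and white-matter probability maps and thresholding at 50%, and the PET
volume of interest (VOI), built by thresholding at a fraction of the maximum
intensity (the "SUV threshold of 50%": fractional, so absolute calibration of
the tracer signal never matters). After thresholding, only the largest
connected component is kept — stray suprathreshold islands (scalp uptake,
segmentation specks) must not contribute surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import Provenance, VoxelVolume

__all__ = [
    "BinaryMask",
    "brain_mask_from_tissue_maps",
    "threshold_pet_voi",
    "largest_component",
    "fill_holes",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class BinaryMask:
    """A 3-D occupancy grid on a :class:`~brainshape.image_io.VoxelVolume` grid."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid).astype(bool)
        if grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        spacing = tuple(float(s) for s in self.spacing)
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be finite and > 0, got {spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def to_volume(self) -> VoxelVolume:
        """View the mask as a volume (for writing through image_io)."""
        return VoxelVolume(self.grid.astype(np.uint8), self.spacing, Provenance.MASK)


def brain_mask_from_tissue_maps(
    gm: VoxelVolume, wm: VoxelVolume, threshold: float = 0.5
) -> BinaryMask:
    """Binarize the summed gray+white tissue-probability maps.

    Foreground is where clip(gm + wm, 0, 1) >= ``threshold``. Monotone in the
    threshold: a higher threshold always yields a subset mask.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if gm.shape != wm.shape:
        raise ValueError(f"gm/wm shape mismatch: {gm.shape} vs {wm.shape}")
    if not np.allclose(gm.spacing, wm.spacing):
        raise ValueError(f"gm/wm spacing mismatch: {gm.spacing} vs {wm.spacing}")
    summed = np.clip(gm.data + wm.data, 0.0, 1.0)
    grid = summed >= threshold
    if not grid.any():
        raise ValueError("brain mask is empty at this threshold")
    return BinaryMask(grid, gm.spacing)


def threshold_pet_voi(
    pet: VoxelVolume, fraction: float = 0.5, head_mask: BinaryMask | None = None
) -> BinaryMask:
    """Segment the PET VOI at a fraction of the maximum intensity.

    Foreground is where ``intensity / I_max >= fraction`` with I_max the
    maximum inside ``head_mask`` (or globally if absent). Because the
    threshold is relative, rescaling all intensities by any k > 0 leaves the
    VOI unchanged — SUV calibration never changes the downstream scores.
    The default fraction 0.5 is the value at which conversion-prediction AUC
    peaked in the threshold sweep (see ``cohort_stats.threshold_sweep``).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    data = pet.data
    if not np.isfinite(data).all():
        raise ValueError("PET intensities must be finite")
    if head_mask is not None:
        if head_mask.grid.shape != data.shape:
            raise ValueError("head_mask grid does not match the PET grid")
        search = np.where(head_mask.grid, data, -np.inf)
    else:
        search = data
    i_max = float(search.max())
    if i_max <= 0:
        raise ValueError(f"maximum intensity must be positive, got {i_max}")
    grid = (data / i_max) >= fraction
    if head_mask is not None:
        grid &= head_mask.grid
    if not grid.any():
        raise ValueError(f"empty VOI at fraction {fraction}")
    return BinaryMask(grid, pet.spacing)


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the connected component with the greatest voxel count.

    Ties are broken deterministically toward the component whose first voxel
    (array scan order) has the smallest lexicographic coordinate, which is
    the order ``scipy.ndimage.label`` assigns labels in.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if mask.n_foreground < 1:
        raise ValueError("mask has no foreground voxels")
    labels, n = ndimage.label(mask.grid, structure=_STRUCTURES[connectivity])
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns the first (lowest-label) max
    return BinaryMask(labels == best, mask.spacing)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill internal cavities: background not 6-connected to the grid boundary.

    Off by default in every pipeline — hole filling changes surface area and
    therefore BASS/BAI; it is provided for masks with segmentation cavities.
    """
    filled = ndimage.binary_fill_holes(mask.grid, structure=_STRUCTURES[6])
    return BinaryMask(filled, mask.spacing)
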