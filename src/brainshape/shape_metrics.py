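"""Surface/volume measurement and the sphericity scores.

The scores are ratios against the sphere, the solid with the smallest
surface area for a given volume:

    BASS          = A_sphere(V) / A        (sphericity of the PET VOI;
                                            high = smooth, blob-like uptake)
    BAI           = A / A_sphere(V)        (1/sphericity of the brain mask;
                                            high = irregular, atrophic surface)
    shape feature = BASS x BAI             (fused PET+MRI biomarker)

where A_sphere(V) = (36 pi V^2)^(1/3). Volume is always exact
(foreground-voxel count x voxel volume); only the surface area A is
estimated, by one of three methods:

``mesh`` (default)
    Triangulated 0.5 iso-surface (marching cubes) of the binary grid,
    zero-padded so boundary-touching objects close, after a fixed Gaussian
    anti-alias filter of sigma = 1 voxel. The filter matters: meshing the raw
    binary grid carries a staircase overestimate of ~8–9% on smooth objects
    that does not vanish with resolution, while the filtered estimator is
    accurate to well under 1% for balls of radius >= 20 voxels.
``crofton``
    Directional-intercept estimator: 2/3 of the total exposed-face area
    (the isotropic Cauchy–Crofton correction for three orthogonal line
    directions). Unbiased for spheres, useful as a mesh cross-check.
``face_count``
    Raw exposed-voxel-face area. Deliberately biased (+~50% on smooth
    objects); exact for axis-aligned boxes, so it serves as an analytic
    oracle, never as the default.

Absolute scores depend on the estimator, so values are comparable only
within one method; rankings and group contrasts are the robust surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure

from .image_io import VoxelVolume
from .masking import BinaryMask, brain_mask_from_tissue_maps, largest_component, threshold_pet_voi

__all__ = [
    "SurfaceMethod",
    "ShapeMeasurement",
    "ShapeScores",
    "measure_surface_and_volume",
    "sphere_equivalent_area",
    "compute_bass",
    "compute_bai",
    "compute_shape_feature",
    "shape_feature_from_images",
]

SurfaceMethod = str  # "mesh" | "crofton" | "face_count"

#: Anti-alias smoothing (in voxels) applied before marching cubes. Fixed by a
#: calibration sweep on analytic solids; not a user dial, because changing it
#: recalibrates every absolute score.
MESH_SMOOTHING_SIGMA = 1.0


@dataclass(frozen=True)
class ShapeMeasurement:
    """Surface area (mm^2), volume (mm^3) and sphere-equivalent area of one mask."""

    surface_area: float
    volume: float
    sphere_equiv_area: float
    method: str

    def __post_init__(self) -> None:
        if not self.surface_area > 0:
            raise ValueError(f"surface_area must be > 0, got {self.surface_area}")
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")


@dataclass(frozen=True)
class ShapeScores:
    """Per-subject sphericity scores; shape_feature == bass * bai exactly."""

    bass: float
    bai: float
    shape_feature: float


def sphere_equivalent_area(volume: float) -> float:
    """Surface area of the sphere with the given volume: (36 pi)^(1/3) V^(2/3).

    This is the minimal surface area any solid of that volume can have, which
    is what makes the ratios below well-defined sphericity measures.
    """
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return float((36.0 * np.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0))


def _exposed_face_area(grid: np.ndarray, spacing: tuple[float, float, float]) -> float:
    padded = np.pad(grid, 1).astype(np.int8)
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        total += float(np.abs(np.diff(padded, axis=axis)).sum()) * fa
    return total


def _mesh_area(grid: np.ndarray, spacing: tuple[float, float, float]) -> float:
    # Pad by 2 so the smoothed field decays to 0 before the boundary and the
    # iso-surface is always closed, even for masks touching the grid edge.
    field = np.pad(grid, 2).astype(np.float64)
    field = ndimage.gaussian_filter(field, MESH_SMOOTHING_SIGMA)
    verts, faces, _, _ = _skmeasure.marching_cubes(field, level=0.5, spacing=spacing)
    return float(_skmeasure.mesh_surface_area(verts, faces))


def measure_surface_and_volume(mask: BinaryMask, method: SurfaceMethod = "mesh") -> ShapeMeasurement:
    """Measure one mask on its (possibly anisotropic) grid.

    Volume is exact and method-independent: n_foreground x voxel volume.
    Surface area is estimated per the module docstring. Spacing is applied to
    mesh vertex coordinates / face areas directly; nothing is resampled.
    """
    if mask.n_foreground < 1:
        raise ValueError("cannot measure an empty mask")
    volume = mask.n_foreground * mask.voxel_volume_mm3
    if method == "mesh":
        area = _mesh_area(mask.grid, mask.spacing)
    elif method == "crofton":
        area = (2.0 / 3.0) * _exposed_face_area(mask.grid, mask.spacing)
    elif method == "face_count":
        area = _exposed_face_area(mask.grid, mask.spacing)
    else:
        raise ValueError(f"unknown surface method {method!r}")
    return ShapeMeasurement(
        surface_area=area,
        volume=volume,
        sphere_equiv_area=sphere_equivalent_area(volume),
        method=method,
    )


def compute_bass(m: ShapeMeasurement) -> float:
    """Brain amyloid smoothing score: sphere-equivalent area over actual area.

    Equals 1 for a perfect sphere and decreases as the surface grows more
    convoluted; continuum BASS <= 1, though discrete estimators may cross 1
    by a fraction of a percent on near-spherical objects.
    """
    if not m.surface_area > 0:
        raise ValueError("surface area must be > 0")
    return m.sphere_equiv_area / m.surface_area


def compute_bai(m: ShapeMeasurement) -> float:
    """Brain atrophic index: actual area over sphere-equivalent area (1/sphericity)."""
    if not m.volume > 0:
        raise ValueError("volume must be > 0")
    return m.surface_area / m.sphere_equiv_area


def compute_shape_feature(bass: float, bai: float) -> float:
    """The fused biomarker: one multiplication, BASS x BAI."""
    if not (bass > 0 and bai > 0):
        raise ValueError(f"bass and bai must be > 0, got {bass}, {bai}")
    return bass * bai


def shape_feature_from_images(
    pet: VoxelVolume,
    gm: VoxelVolume,
    wm: VoxelVolume,
    pet_fraction: float = 0.5,
    tissue_threshold: float = 0.5,
    method: SurfaceMethod = "mesh",
    head_mask: BinaryMask | None = None,
    connectivity: int = 26,
) -> ShapeScores:
    """End-to-end per-subject pipeline.

    PET:  threshold at ``pet_fraction`` of max -> largest component ->
    measure -> BASS. MRI: gm+wm >= ``tissue_threshold`` -> largest
    component -> measure -> BAI. The two modalities are treated on their own
    grids; no co-registration is performed (the scores are per-image ratios).
    Deterministic for fixed inputs and settings.
    """
    voi = largest_component(threshold_pet_voi(pet, pet_fraction, head_mask), connectivity)
    brain = largest_component(brain_mask_from_tissue_maps(gm, wm, tissue_threshold), connectivity)
    bass = compute_bass(measure_surface_and_volume(voi, method))
    bai = compute_bai(measure_surface_and_volume(brain, method))
    return ShapeScores(bass=bass, bai=bai, shape_feature=compute_shape_feature(bass, bai))
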