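"""Synthetic ground truth: solids, PET fields, and score cohorts.

Nothing in this package requires the original multi-site imaging cohort.
Every metric and statistic is validated against phantoms with known answers:

* analytic solids (ball, ellipsoid, cuboid) for surface/volume calibration;
* a "gyrified" family — a ball whose radius is modulated by a separable
  sinusoid in the spherical angles — whose corrugation amplitude is the
  ground-truth ordering BAI must recover (more corrugation = more surface at
  nearly constant volume);
* simulated amyloid-PET fields: uniform uptake over a solid (the smooth,
  amyloid-positive appearance in which gray–white differentiation is lost)
  versus uptake confined to a cortical rim (amyloid-negative appearance),
  both blurred by an isotropic Gaussian PSF with multiplicative noise;
* two-group score cohorts matching the published converter/non-converter
  means and SDs, with event times for survival analysis.

All randomness is seeded; identical spec + seed is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import Provenance, VoxelVolume
from .masking import BinaryMask, largest_component

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroupMoments",
    "TABLE1_CONVERTERS",
    "TABLE1_NONCONVERTERS",
    "make_solid_mask",
    "simulate_pet_pair",
    "make_level_corrugated_pet",
    "make_sweep_cohort",
    "simulate_cohort",
    "simulate_hazard_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic solid.

    ``size_mm`` is per-family: radius for ``ball`` and ``gyrified_brain``,
    three semi-axes for ``ellipsoid``, three edge lengths for ``cuboid``.
    Corrugation for the gyrified family modulates the radius as
    r(theta, phi) = R * (1 + eps * sin(k theta) * sin(k phi)); ``eps`` must
    stay below 0.5 so the surface remains a radial graph.
    """

    family: str = "ball"
    size_mm: tuple[float, ...] = (20.0,)
    corrugation_amplitude: float = 0.0
    corrugation_frequency: int = 6
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in {"ball", "ellipsoid", "cuboid", "gyrified_brain"}:
            raise ValueError(f"unknown phantom family {self.family!r}")
        if not 0 <= self.corrugation_amplitude < 0.5:
            raise ValueError("corrugation amplitude must be in [0, 0.5)")
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("sizes must be positive")


def _centered_coords(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def make_solid_mask(spec: PhantomSpec) -> BinaryMask:
    """Voxelize the analytic solid: foreground iff the voxel center is inside.

    The grid is sized to hold the object plus ``margin_voxels`` on every
    side, so nothing is clipped. Deterministic given the spec.
    """
    eps, k = spec.corrugation_amplitude, spec.corrugation_frequency
    if spec.family in ("ball", "gyrified_brain"):
        (radius,) = spec.size_mm
        half_extent = (radius * (1 + eps),) * 3
    elif spec.family == "ellipsoid":
        half_extent = tuple(spec.size_mm)
    if spec.family == "cuboid":
        # grid parity must match the edge's voxel count so that centers fall
        # symmetrically inside: a W-mm edge then contains exactly round(W/s) voxels
        shape = tuple(
            int(round(e / s)) + 2 * spec.margin_voxels
            for e, s in zip(spec.size_mm, spec.spacing)
        )
    else:
        shape = tuple(
            2 * (int(np.ceil(h / s)) + spec.margin_voxels) + 1
            for h, s in zip(half_extent, spec.spacing)
        )
    x, y, z = _centered_coords(shape, spec.spacing)

    if spec.family == "cuboid":
        a, b, c = spec.size_mm
        grid = (np.abs(x) < a / 2) & (np.abs(y) < b / 2) & (np.abs(z) < c / 2)
    elif spec.family == "ellipsoid":
        a, b, c = spec.size_mm
        grid = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    else:
        (radius,) = spec.size_mm
        r = np.sqrt(x**2 + y**2 + z**2)
        if eps == 0.0 or spec.family == "ball":
            grid = r <= radius
        else:
            cos_theta = np.divide(z, r, out=np.zeros_like(r), where=r > 0)
            theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
            phi = np.arctan2(y, x)
            r_surface = radius * (1.0 + eps * np.sin(k * theta) * np.sin(k * phi))
            grid = r <= r_surface
    if not grid.any():
        raise ValueError("phantom produced an empty mask (grid too coarse?)")
    return largest_component(BinaryMask(grid, spec.spacing))


def _fwhm_to_sigma_voxels(fwhm_mm: float, spacing: tuple[float, float, float]) -> tuple[float, ...]:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return tuple(sigma_mm / s for s in spacing)


def simulate_pet_pair(
    mask: BinaryMask,
    pattern: str = "amyloid_positive",
    psf_fwhm_mm: float = 6.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    rim_voxels: int = 3,
    interior_uptake: float = 0.25,
) -> VoxelVolume:
    """Simulate an amyloid-PET field over a solid.

    ``amyloid_positive``: uniform uptake over the whole solid — after PSF
    blur its 50%-of-max isocontour is smooth (high BASS). ``amyloid_negative``:
    uptake confined to a ``rim_voxels``-thick outer shell ("cortex") with
    ``interior_uptake`` inside — its isocontour is a shell with a much larger
    area-to-volume ratio (low BASS). Blur is an isotropic Gaussian PSF of the
    given FWHM (default 6 mm, typical reconstructed PET resolution); noise is
    multiplicative Gaussian with fractional SD ``noise_sd`` (count-scaled PET
    noise without Poisson physics). ``noise_sd = 0`` and ``psf_fwhm_mm = 0``
    with the positive pattern reproduce the mask exactly at fraction 0.5.
    """
    if pattern not in ("amyloid_positive", "amyloid_negative"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    field = mask.grid.astype(np.float64)
    if pattern == "amyloid_negative":
        core = ndimage.binary_erosion(mask.grid, iterations=rim_voxels)
        field = np.where(core, interior_uptake, field)
    if psf_fwhm_mm > 0:
        field = ndimage.gaussian_filter(field, _fwhm_to_sigma_voxels(psf_fwhm_mm, mask.spacing))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        field = field * (1.0 + noise_sd * rng.standard_normal(field.shape))
        field = np.clip(field, 0.0, None)
    return VoxelVolume(field, mask.spacing, Provenance.PET)


def make_level_corrugated_pet(
    radius_mm: float = 12.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    amplitude: float = 0.15,
    frequency: int = 6,
    bump_width_frac: float = 0.12,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> VoxelVolume:
    """A PET field whose corrugation lives only at the 50%-of-max iso-level.

    The intensity is a linear radial ramp I(r) = max(0, 1 - r / 2R), whose
    50% isocontour sits at r = R. The radius is perturbed by a sinusoidal
    corrugation windowed by a Gaussian bump centred at R (width
    ``bump_width_frac * R``), so isocontours at 30% or 70% of max (r = 1.4R
    and 0.6R) are nearly unperturbed while the 50% contour carries the full
    corrugation. With ``amplitude = 0`` the field is perfectly smooth at all
    levels. Used to build sweep cohorts whose separability peaks at 0.5.
    """
    half = radius_mm * 2.2
    shape = tuple(2 * int(np.ceil(half / s)) + 1 for s in spacing)
    x, y, z = _centered_coords(shape, spacing)
    r = np.sqrt(x**2 + y**2 + z**2)
    if amplitude > 0:
        cos_theta = np.divide(z, r, out=np.zeros_like(r), where=r > 0)
        theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
        phi = np.arctan2(y, x)
        bump = np.exp(-(((r - radius_mm) / (bump_width_frac * radius_mm)) ** 2))
        r_eff = r - amplitude * radius_mm * bump * np.sin(frequency * theta) * np.sin(frequency * phi)
    else:
        r_eff = r
    field = np.clip(1.0 - r_eff / (2.0 * radius_mm), 0.0, None)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        field = np.clip(field * (1.0 + noise_sd * rng.standard_normal(field.shape)), 0.0, None)
    return VoxelVolume(field, spacing, Provenance.PET)


def make_sweep_cohort(
    n_per_group: int = 60,
    radius_mm: float = 12.0,
    amplitude_mean: float = 0.12,
    amplitude_sd: float = 0.03,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[VoxelVolume], np.ndarray]:
    """PET volumes and labels for threshold-sweep validation.

    Cases (label 1) are smooth fields; controls carry level-localized
    corrugation (:func:`make_level_corrugated_pet`) with a per-subject random
    amplitude, so the 50%-of-max threshold separates the groups maximally by
    construction — mirroring that converters' amyloid-positive scans are the
    smooth, high-BASS ones. Returns ``(volumes, labels)``.
    """
    rng = np.random.default_rng(seed)
    volumes, labels = [], []
    for i in range(2 * n_per_group):
        smooth = i < n_per_group
        amp = 0.0 if smooth else float(np.clip(rng.normal(amplitude_mean, amplitude_sd), 0.04, 0.2))
        volumes.append(
            make_level_corrugated_pet(
                radius_mm=radius_mm, amplitude=amp, noise_sd=noise_sd, seed=seed * 10_000 + i
            )
        )
        labels.append(1 if smooth else 0)
    return volumes, np.array(labels)


@dataclass(frozen=True)
class GroupMoments:
    """Per-group marker means and SDs."""

    bass_mean: float
    bass_sd: float
    bai_mean: float
    bai_sd: float
    suvr_mean: float
    suvr_sd: float


# Published converter / non-converter marker moments (48-month follow-up,
# n = 226 non-converters vs 108 converters).
TABLE1_NONCONVERTERS = GroupMoments(0.38, 0.06, 3.86, 0.51, 1.14, 0.18)
TABLE1_CONVERTERS = GroupMoments(0.44, 0.07, 4.23, 0.52, 1.39, 0.22)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated two-group score cohort.

    Defaults reproduce the published cohort structure: 226 non-converters and
    108 converters with the group marker moments above. Within each group,
    (bass, bai, suvr) are multivariate normal; ``corr_bass_bai`` (default
    0.3) and ``corr_suvr`` (SUVR with each shape marker, default 0.5) are
    assumptions — the study reports only a pooled shape-feature–SUVR rank
    correlation, not a within-group covariance. Converters receive Weibull
    event times (median 24 months, shape 1.5) truncated at the follow-up
    horizon; non-converters are censored at the horizon (48 months).
    """

    n_nonconverters: int = 226
    n_converters: int = 108
    nonconverters: GroupMoments = TABLE1_NONCONVERTERS
    converters: GroupMoments = TABLE1_CONVERTERS
    corr_bass_bai: float = 0.3
    corr_suvr: float = 0.5
    horizon_months: float = 48.0
    event_median_months: float = 24.0
    event_weibull_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nonconverters, self.n_converters) < 2:
            raise ValueError("each group needs >= 2 subjects")
        if not -1 < self.corr_bass_bai < 1 or not -1 < self.corr_suvr < 1:
            raise ValueError("correlations must be in (-1, 1)")
        for g in (self.nonconverters, self.converters):
            if min(g.bass_sd, g.bai_sd, g.suvr_sd) <= 0:
                raise ValueError("group SDs must be > 0")


def _draw_group_scores(rng: np.random.Generator, g: GroupMoments, n: int, spec: CohortSpec) -> np.ndarray:
    corr = np.array(
        [
            [1.0, spec.corr_bass_bai, spec.corr_suvr],
            [spec.corr_bass_bai, 1.0, spec.corr_suvr],
            [spec.corr_suvr, spec.corr_suvr, 1.0],
        ]
    )
    sds = np.array([g.bass_sd, g.bai_sd, g.suvr_sd])
    cov = corr * np.outer(sds, sds)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("invalid covariance (not positive definite)") from exc
    means = np.array([g.bass_mean, g.bai_mean, g.suvr_mean])
    return means + rng.standard_normal((n, 3)) @ chol.T


def _truncated_weibull(rng: np.random.Generator, n: int, median: float, shape: float, horizon: float) -> np.ndarray:
    scale = median / np.log(2.0) ** (1.0 / shape)
    f_horizon = 1.0 - np.exp(-((horizon / scale) ** shape))
    u = rng.uniform(0.0, f_horizon, size=n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a cohort table with columns
    ``subject_id, group, bass, bai, shape_feature, suvr, event, time_months``.

    ``group`` is "converter"/"nonconverter"; ``event`` is 1 for converters
    (conversion observed within the horizon) and 0 for censored
    non-converters. shape_feature is the per-subject product bass * bai.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, g, n, event in (
        ("nonconverter", spec.nonconverters, spec.n_nonconverters, 0),
        ("converter", spec.converters, spec.n_converters, 1),
    ):
        scores = _draw_group_scores(rng, g, n, spec)
        if event:
            times = _truncated_weibull(
                rng, n, spec.event_median_months, spec.event_weibull_shape, spec.horizon_months
            )
        else:
            times = np.full(n, spec.horizon_months)
        for i in range(n):
            rows.append((group, *scores[i], event, times[i]))
    df = pd.DataFrame(rows, columns=["group", "bass", "bai", "suvr", "event", "time_months"])
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    df["shape_feature"] = df["bass"] * df["bai"]
    return df[["subject_id", "group", "bass", "bai", "shape_feature", "suvr", "event", "time_months"]]


def simulate_hazard_cohort(
    n: int = 334,
    true_hr: float = 5.0,
    cutoff: float = 1.54,
    baseline_median_months: float = 120.0,
    horizon_months: float = 48.0,
    p_converter_moments: float = 108.0 / 334.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A cohort obeying exact proportional hazards for HR-recovery tests.

    Scores are drawn from the two-group mixture of the published moments
    (each subject's group chosen Bernoulli(``p_converter_moments``)), then
    event times are exponential with hazard multiplied by ``true_hr`` for
    subjects whose shape feature exceeds ``cutoff`` (the study's reported
    optimal cutoff, 1.54, splits the mixture near its middle). Events beyond
    ``horizon_months`` are censored there. Unlike :func:`simulate_cohort`,
    this generator has a well-defined true hazard ratio.
    """
    spec = CohortSpec(seed=seed)
    rng = np.random.default_rng(seed)
    from_converters = rng.random(n) < p_converter_moments
    scores = np.empty((n, 3))
    n_c = int(from_converters.sum())
    scores[from_converters] = _draw_group_scores(rng, spec.converters, n_c, spec)
    scores[~from_converters] = _draw_group_scores(rng, spec.nonconverters, n - n_c, spec)
    shape_feature = scores[:, 0] * scores[:, 1]
    high = shape_feature > cutoff
    rate = (np.log(2.0) / baseline_median_months) * np.where(high, true_hr, 1.0)
    t = rng.exponential(1.0 / rate)
    event = (t <= horizon_months).astype(int)
    df = pd.DataFrame(
        {
            "subject_id": [f"H{i:04d}" for i in range(n)],
            "group": np.where(high, "high", "low"),
            "bass": scores[:, 0],
            "bai": scores[:, 1],
            "shape_feature": shape_feature,
            "suvr": scores[:, 2],
            "event": event,
            "time_months": np.minimum(t, horizon_months),
        }
    )
    return df
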