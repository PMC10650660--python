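# Methods

## Scores

All three scores are ratios built from the surface area `A` (mm²) and
volume `V` (mm³) of a binary voxel mask, via the sphere-equivalent area
`A_sphere(V) = (36π V²)^(1/3)` — the minimum surface area of any solid of
volume `V` (isoperimetric inequality), which bounds continuum BASS ≤ 1 and
BAI ≥ 1. Discrete estimators may cross 1 by a fraction of a percent on
near-spherical objects, so tests use tolerance bands rather than the
continuum bounds.

- `BASS = A_sphere(V_VOI) / A_VOI` on the PET volume of interest,
- `BAI = A_brain / A_sphere(V_brain)` on the MR brain mask,
- `shape feature = BASS × BAI` (one multiplication, exact).

## Mask construction

**PET VOI.** The "50% SUV threshold" is interpreted as a relative
threshold: foreground where `intensity / I_max ≥ fraction`, with `I_max`
the global maximum (or the maximum inside an optional head mask). This
makes every score invariant to PET intensity calibration — rescaling all
voxels by any `k > 0` changes nothing. The comparison is closed (`≥`), so a
two-level field thresholds to exactly its upper level. The default fraction
0.5 is the value at which conversion-prediction AUC peaks in the threshold
sweep (`cohort_stats.threshold_sweep` reproduces this calibration on
synthetic cohorts over fractions 0.3–0.7).

**Brain mask.** Foreground where `clip(gm + wm, 0, 1) ≥ 0.5`. Tissue
probabilities are clamped to [0, 1] at load time rather than rejected,
because segmentation outputs routinely contain small excursions.

**Largest component.** After thresholding, only the largest 26-connected
component is retained (ties broken toward the component encountered first
in array scan order — deterministic). Hole filling (6-connected background)
is available but off by default: it changes surface area and therefore the
scores, and nothing in the measurement model calls for it.

Both modalities are processed on their own grids; no co-registration or
resampling is performed, since the scores are per-image ratios and surface
area/volume are rotation-invariant. Only voxel spacing is consumed from the
NIfTI header.

## Surface-area estimation

Volume is always exact: foreground-voxel count × voxel volume, identical
across estimators. Three area estimators are provided:

- **mesh** (default): marching-cubes triangulation at level 0.5 of the
  binary grid, zero-padded by two voxels (so boundary-touching masks close)
  and smoothed with a fixed Gaussian of σ = 1 voxel per axis before
  extraction. The smoothing is essential: meshing the raw binary grid
  overestimates the area of smooth objects by ~8–9% (a staircase artifact
  that does not vanish with resolution), while the smoothed estimator is
  accurate to under 1% for balls of radius ≥ 20 voxels and to ~2% for a
  20×15×10 mm ellipsoid against the Thomsen closed form. σ was fixed by a
  calibration sweep on analytic solids (0.8–1.5 voxels) and is deliberately
  not a user parameter — changing it recalibrates every absolute score.
- **crofton**: 2/3 of the total exposed-voxel-face area, the isotropic
  Cauchy–Crofton correction for three orthogonal intercept directions.
  Essentially unbiased on spheres; used as an independent cross-check.
- **face_count**: raw exposed-face area. Exact for axis-aligned boxes,
  ~+50% biased on smooth objects; retained only as an analytic oracle.

Anisotropic spacing enters through the mesh vertex coordinates and the
per-axis face areas; nothing is resampled. Absolute BASS/BAI values are
estimator-dependent (the original measurements used a different, unpublished
region-property routine), so cross-study comparisons of raw values carry a
method-dependent calibration factor; within-method rankings and group
contrasts are the reproducible quantities.

## Phantoms

- **Solids**: balls, ellipsoids and cuboids voxelized by the
  center-inside-solid rule on a grid sized to hold the object plus a
  2-voxel margin. A cuboid's grid parity matches its edge voxel count, so a
  10×20×40 mm cuboid at 1 mm spacing contains exactly 8000 voxels.
- **Gyrified family**: radius modulated as
  `r(θ, φ) = R (1 + ε sin kθ sin kφ)`, ε < 0.5. A separable sinusoid is
  crude near the poles but gives the property the scores must detect:
  across ε at fixed R the volume is stable within ~3% while surface area
  strictly increases. Not anatomically realistic cortical folding.
- **PET fields**: amyloid-positive = uniform uptake over the solid;
  amyloid-negative = uptake confined to a 3-voxel cortical rim with 0.25
  relative interior uptake. Both are blurred by an isotropic Gaussian PSF
  (default FWHM 6 mm, typical reconstructed PET resolution) and carry
  multiplicative Gaussian noise (default 5% — count-scaled PET noise
  without Poisson physics, scatter or scanner anisotropy). In the noise- and
  blur-free limit the positive pattern thresholds back to its generating
  mask exactly.
- **Sweep cohorts**: a radial-ramp field whose corrugation is windowed by a
  Gaussian bump at the 50%-of-max radius, so separability between smooth
  (case) and corrugated (control) subjects peaks at fraction 0.5 by
  construction — the ground truth for validating the threshold sweep.

**Simulated cohorts.** The default `CohortSpec` reproduces the published
two-group structure: 226 non-converters vs 108 converters with group means
± SD of BASS 0.38 ± 0.06 / 0.44 ± 0.07, BAI 3.86 ± 0.51 / 4.23 ± 0.52 and
SUVR 1.14 ± 0.18 / 1.39 ± 0.22. Within groups, (bass, bai, suvr) are
multivariate normal; the bass–bai correlation (0.3) and the SUVR–shape
coupling (0.5) are assumptions — only a pooled shape-feature–SUVR rank
correlation is reported in the literature, not a within-group covariance.
Conversion times are not published beyond 48-month status, so converters
draw Weibull times (shape 1.5, median 24 months) truncated at the 48-month
horizon and non-converters are censored at 48 — a stated model chosen so
survival-recovery tests have ground truth. A second generator,
`simulate_hazard_cohort`, provides an exact proportional-hazards world
(exponential baseline with 120-month median in the low stratum, hazard
multiplied by a configurable true HR above the shape-feature cutoff 1.54)
because the group-structure generator has no single true hazard ratio to
recover. What a green test establishes is therefore statistical and
geometric correctness of the machinery — not anatomical realism: the
phantoms have no cortical topology, no PET physics beyond Gaussian
blur+noise, and the cohort model assumes normal scores and proportional
hazards.

## Statistics

- **AUC**: Mann–Whitney rank formulation, ties counted ½; 95% CI is Wald on
  the DeLong structural-component variance, clipped to [0, 1].
- **Paired ROC comparison**: DeLong's test with the full structural
  covariance; identical inputs give p = 1 by convention (zero variance and
  zero difference). Two-sided normal p-values.
- **Youden cutoff**: classification rule is `score > cutoff`; the curve is
  evaluated at every unique score value (plus one value below the minimum),
  and ties in `J = sens + spec − 1` resolve toward the lowest cutoff — the
  more sensitive rule — since no tie rule is published with the reported
  cutoffs. The chosen cutoff applied back to its own cohort reproduces the
  reported sensitivity/specificity pair exactly.
- **Log-rank**: observed-minus-expected events over hypergeometric variance
  across the per-event-time risk tables, 1 df.
- **Hazard ratio**: Newton maximization of the partial likelihood for a
  single binary covariate with Breslow tie handling; Wald CI from the
  observed information. Chosen over a general-purpose fitter because the
  closed-form derivatives make the fit deterministic and transparent; it
  agrees with an independent Efron-ties fitter to <0.1% on
  continuous-time cohorts (asserted in tests). Monotone-likelihood cases
  (all events in one stratum) are capped at |log HR| = 30 with an infinite
  CI rather than failing. Multivariate/stepwise model selection is out of
  scope; the pipeline reports univariate tables only.
- **Welch t / Pearson χ² (no continuity correction) / Spearman** are
  delegated to scipy.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; phantom generation is fully deterministic given
its spec. Demo and report outputs embed the resolved configuration and
package version and contain no timestamps, so identical seeds produce
byte-identical files.

## Known limitations

- Absolute scores are calibrated to this package's mesh estimator; values
  from other surface-area routines differ by a systematic factor.
- The relative-threshold reading of the "50% SUV threshold" (fraction of
  the in-volume maximum) is the simplest reproducible choice; an absolute
  SUV reading would require calibrated tracer data the pipeline does not
  assume.
- The MRI tissue threshold is assumed equal to the PET mask threshold
  (0.5); both are configurable.
- Phantom corrugation degenerates near the poles of the spherical
  parameterization; monotonicity properties hold across the tested
  amplitude grid but amplitudes approaching 0.5 are untested territory.
- Survival machinery assumes right-censoring at a common horizon and
  proportional hazards between strata; no competing risks or
  time-dependent covariates.
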