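# Methods

## Scope and data model

The package analyses gamma-camera phantom measurements of the
²⁰³Pb/²¹²Pb theragnostic pair: count-rate series (activity, counts,
duration), planar count images, and reconstructed SPECT count volumes, one
per energy window. No scanner data ship with the package; a synthetic
generator (below) produces statistically matched inputs with known ground
truth. Units are keV for energies, MBq for activities, kBq/ml for fill
concentrations (Bq/ml in voxel maps), hours for decay intervals, seconds
for acquisitions, mm for geometry.

## Nuclides, windows, collimators

Emission tables (photon lines with probability > 1%) are packaged for
²⁰³Pb and for ²¹²Pb including its daughters ²¹²Bi and ²⁰⁸Tl, whose
high-energy lines drive dead time and septal penetration. Multi-line X-ray
bands are stored at the band midpoint with the total probability — the
individual sub-lines are never resolved by a NaI camera and nothing
downstream consumes them separately.

Energy windows follow the camera convention: a photopeak window of a given
percentage width about its center, and two flanking scatter windows whose
percentage widths are taken **relative to the photopeak center** (so the
5% scatter windows of the 239 keV peak are 11.95 keV wide wherever they
sit). Four window sets are packaged: 279/72 keV for ²⁰³Pb and 239/79 keV
for ²¹²Pb.

Collimator geometry (MELP: 40.64/1.14/2.94 mm, HE: 59.7/2.0/4.0 mm hole
length/septum/hole diameter) is packaged with an acceptance-angle helper
using the convention arctan(d/L). This reproduces the published angles
(4.15°, 3.85°) to within 0.02°; the residual is an unstated rounding or
convention difference and is deliberately not "corrected".

## Paralyzable dead-time model

The count rate is modelled as C(A) = α·A·exp(−τ·α·A). The fit uses the
product τα (1/MBq) as the second parameter: the model depends on τ only
through τ·α, and (α, τα) are far less correlated than (α, τ); τ is
reported as the derived ratio τα/α. Initialization: α from the mean
low-activity slope (lowest third of retained points), τα = 1/max(A).
Least squares is unweighted on count rate; a Poisson-weighted variant
(σᵢ = √countsᵢ/durationᵢ) is available behind a flag.

Measurements past the observed global count-rate maximum lie on the
falling, paralyzed branch and are excluded from the fit (and recorded).
Single noise dips *before* the global maximum are retained — the published
rule ("decreasing points were not fitted") is stated loosely, and the
argmax convention makes it deterministic.

Closed-form inversions: A_peak = 1/τα; A at fractional loss f is
−ln(1−f)/τα, so A_f/A_peak = −ln(1−f) (0.10536 at 10%, 0.22314 at 20%)
independent of the fit. Applied to the published peak activities (102, 89,
193, 166 MBq) this reproduces the published 20%-loss activities (23, 20,
43, 37 MBq) exactly after integer rounding, and the 10%-loss values 11, 9
and 20 MBq; the published HE/79 keV 10% value (18 MBq) sits a rounding
edge away from the analytic 17.49 MBq. Thresholds are reported at full
precision and as integer MBq (the reported precision).

## TEW scatter correction

The trapezoidal triple-energy-window estimate
S = (C_low/w_low + C_up/w_up)·w_peak/2 is subtracted from the photopeak
counts and the result clamped at zero (counts are non-negative; clamping
happens before any statistics). Correction is applied at the finest
available granularity — per voxel/pixel when window images share a grid,
per VOI total otherwise. Whether the vendor chain applies TEW before or
after reconstruction is not public; image-space correction on the
provided grid is the default here.

## Digital phantoms and VOIs

The NEMA IQ phantom is modelled with six coplanar spheres (10–37 mm inner
diameter) on a 57.2 mm radius ring in the z = 0 plane, a 50 mm cold lung
cylinder on the axis, and a torso background. The torso interior is an
elliptical cylinder (semi-axes 147 × 107 mm, length 180 mm) — a
simplification of the true NEMA outline that preserves the features the
metrics touch (wall clearances, background volume scale). The calibration
phantom is a 5650 ml cylinder (radius 100 mm, length 179.8 mm). The
count-rate phantom is a body-shaped slab with a central vial, used only as
a label map.

Rasterization assigns each voxel the concentration of the compartment
containing its **center** — no partial-volume weighting. This makes masks
and maps bitwise deterministic and lets refinement control accuracy; at
2.4 mm voxels the cylinder's rasterized volume is ~1% low (flat-end
discretization), converging under refinement. Tests that compare against
analytic volumes use 1.2 mm grids.

VOIs mirror the published scheme: sphere VOIs concentric with the spheres;
**12 background spheres per diameter (72 total)**; three background
cylinders (45 mm × 150 mm, axial, at 80 mm radius between the hot
spheres); a 30 mm × 130 mm lung VOI. The original background-sphere
positions are not public, so placement is a deterministic candidate scan
(sphere plane first, then ±35 and ±50 mm slices; rings 50–95 mm; 10°
steps) accepting the first 12 centers that keep ≥ 15 mm clearance from
every hot-sphere surface, the lung insert and the phantom wall, without
mutual overlap. The layout is a pure function of the geometry;
faithfulness to the original placement is not claimed.

## Synthetic data generator

The generator works in image space: truth map → counts/voxel via
sensitivity × time × a **global** dead-time factor exp(−τα·A_total) →
Gaussian PSF blur → broad scatter background (wide-kernel blur, fraction
of primary) + uniform septal-penetration term inside the phantom → Poisson
sampling from one explicitly seeded generator. Scatter-window images are
background-only images scaled by window width, so TEW behaves as designed
on synthetic data. Planar views are line integrals along the detector
axis (posterior = mirrored), same degradation chain, no attenuation.

Defaults are the measured study conditions: sensitivities per protocol
from the planar line-source table (e.g. ²¹²Pb HE/239 keV: 622.7 cps/MBq);
τα = 1/A_peak for ²¹²Pb protocols and −ln(0.9)/A₁₀ for ²⁰³Pb (whose peaks
were not reported); PSF FWHM 9 mm (²⁰³Pb) / 12 mm (²¹²Pb) matching the
post-reconstruction filters; NEMA fills from the published schemes
(spheres ≈ 40 kBq/ml; 8:1 and 4:1 contrasts; unrounded contrast ratios
carried separately because printed concentrations are rounded — 38.4/4.8
≠ 7.73). Scatter fraction and penetration default to zero and are set
explicitly where a test exercises them.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: projection-space acquisition and OSEM
reconstruction (with its correlated noise, edge artefacts and
non-stationary resolution), attenuation and depth-dependent PSF,
energy-spectrum effects (pile-up peak shift/broadening, PMT artefacts),
and the true spatial distribution of ²¹²Pb-progeny down-scatter (the
wide-kernel/uniform stand-in is a declared approximation).

## Image-quality metrics

CRC uses the hot-sphere NEMA form 100·(N̄_S/N̄_BG − 1)/(R_true − 1); the
published description names the protocol without printing the formula,
and this form reproduces the printed example value (62.7 for the largest
sphere at measured ratio 5.22, R = 7.73). σ_BG in the CNR is the standard
deviation of the **12 background-VOI means** (the closest reading of "the
standard deviation of the counts in the 12 background VOIs"); the pooled
voxel-level alternative is available via a flag and is systematically
larger. CV_BG pools all voxels of the three large cylinders (SD/mean,
ddof = 1). ΔN_Lung is the lung-VOI mean over the large-background mean,
as a percentage. CRC and ΔN_Lung are reported as missing for
background-free fills (no defined ratio), mirroring the blank table cells
such setups produce.

Quantification: CF = N_VOI/(V_VOI·t·Ā) from a large VOI in the uniform
cylinder, eroded 20 mm from all surfaces to exclude edge blur; RC divides
the CF-converted VOI concentration by the truth. On the identity pipeline
(no blur/noise/scatter) CF equals the generator sensitivity and every RC
is 1 to machine precision — a structural round-trip, verified in the
acceptance suite.

Spatial resolution: the spherically averaged radial profile about a
sphere center (bins of half a voxel) is fit with
amplitude·B(r; R, σ) + baseline, where B is the closed-form radial
profile of a ball convolved with an isotropic Gaussian (an erf/Gaussian
expression; R is fixed at the known sphere radius). FWHM = 2√(2 ln 2)·σ.
Initialization σ₀ = 2 voxels; bounds keep σ in (0.001, 60) mm; a fit that
fails, diverges or pegs the bounds is reported as non-converged with a
missing FWHM — never a fabricated number.

## Problem sizes and numerical choices

Simulation-based checks run on the full phantom at 2.4 mm voxels
(≈ 1.1 M voxels) for identity, FWHM and TEW properties; at 1.2 mm where a
comparison against analytic geometry needs rasterization error under 2%
(partial-volume oracle, cylinder volume); and at 4.8 mm for the
100-phantom TEW ensemble, where per-phantom statistics, not geometry,
matter. The dead-time Monte Carlo uses 12 activities spanning 0.1–1.5 ×
A_peak, 120 s per point, 20 seeds. Fits use `scipy.optimize.curve_fit`
(trust-region reflective with non-negativity bounds); Gaussian blur uses
`scipy.ndimage.gaussian_filter` with reflect boundaries; all randomness
flows through `numpy.random.default_rng(seed)` passed explicitly.

## Known limitations

* Absolute sensitivities, CVs, lung errors and calibration factors of the
  physical scanner are not reproducible without the scanner; the package
  covers them with structural and ordering properties instead.
* The global dead-time factor ignores count-rate spatial structure; real
  paralysis is rate-dependent per detector region.
* The torso outline and the background-sphere layout are deterministic
  stand-ins, not replicas of the physical phantom or the original analyst's
  VOI placement.
* Planar simulation omits attenuation and scatter depth dependence;
  anterior/posterior views differ only by mirroring.
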