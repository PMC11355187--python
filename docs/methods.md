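# Methods

## Imaging model

The synthetic generator is a grey-level surrogate of a digital radiography
chain, not a photon-transport simulation. Region mean signals for the PMMA
carrier, Cu insert and Al insert are specified directly (defaults 2000, 120
and 1350 ADU in a 12-bit range) rather than derived from kVp and filtration,
because everything downstream consumes detector images, not spectra. The
chain is:

1. **Ideal scene.** Piecewise-constant indicator scene evaluated at 8× the
   detector pitch (sub-pixel edge placement error ≪ the ESF bin width of
   pitch/8), with the whole phantom rigidly rotated by `rotation_deg`
   (default 2.5°: slanted-edge estimation needs a small non-zero slant, and
   2–3° is standard practice).
2. **System blur.** Convolution with a Gaussian PSF, σ per axis
   (`psf_sigma_mm`, default 0.25 mm isotropic, which puts the raw-image
   MTF50 at 0.75 lp/mm — typical of an unprocessed DR system). An
   anisotropic σ emulates direction-dependent blur such as a poorly cut
   ("blunt") Cu edge.
3. **Pixel aperture.** Box-average onto the detector grid (default pitch
   0.15 mm). Column blur + column averaging are applied before the row
   pair; the two axes commute, which keeps the oversampled array
   short-lived.
4. **Noise.** Added after blur (quantum-dominated surrogate), Gaussian with
   the affine variance law var = gain·mean + read², defaults gain = 1.0,
   read = 5 ADU. The law — not the exact photon statistics — is what the
   oracle tests verify (χ² on empirical ROI variance). An optional
   per-exposure DC offset (`offset_jitter_sd`, default 0; 50 ADU in the
   variability study) emulates dark-level/auto-ranging drift: it moves
   absolute means, and hence SNR, without touching signal differences,
   which is exactly why SDNR is the more dependable of the two metrics.
5. **Quantization and photometrics.** Clip + round to `bit_depth`;
   MONOCHROME1 output is the exact bitwise complement of MONOCHROME2, and
   all analysis first normalizes to "higher value = more exposure".

Ground truth shipped with every render: the analytic MTF
exp(−2π²σ²f²), closed-form SDNR/SNR from the variance law, and exact insert
centers.

The "for presentation" surrogate is a sigmoid grey-level LUT (center at half
scale, width 1/6 of full scale) followed by unsharp masking (5×5 Gaussian
kernel, σ = 1 px, weight 0.6). Only the *direction* of its effects is
meaningful — higher measured MTF, non-increasing SDNR — since real vendor
pipelines are proprietary; the constants are fixed and documented rather
than configurable.

## Localization

Otsu thresholding on a lightly smoothed, photometrically normalized image
finds the Cu square (largest component of plausible physical size — gating
by size rather than template matching keeps detection independent of
SID/magnification); a second Otsu pass over the remaining field finds the
Al square (10 ± 3 mm side). Statistics ROIs are margin-eroded interiors
(25% per side for Cu, 20% for Al) so they stay clear of the blurred edge
transition. The SDNR background ROI sits on the carrier, displaced from the
Al square by two Al side lengths (center to center) toward the image
center along the dominant axis, falling back to other directions if that
position leaves the image or hits another ROI; no standard prescribes this
placement, so it is a documented package convention.

Each Cu edge is fitted by least squares through sub-pixel mid-level
crossings over the central 60% of the side. A rigid rotation by +θ appears
as +θ in near-horizontal edge fits but −θ in near-vertical ones; the
rotation estimate folds the four signed angles accordingly (mod 90°).

## Slanted-edge MTF

Edge profiles collect every pixel within a band around the fitted line
(default half-width max(10 px, 8 mm); the 8 mm guarantees the ESF spans
well beyond ±2 mm even at σ = 1 mm, and keeps the Hann window nearly flat
over the LSF support — a window narrow relative to the LSF biases the MTF
upward, measurably so at ±4 mm). Samples are sorted into a canonical order
before binning so the ESF is exactly permutation-invariant. Empty interior
bins are filled by linear interpolation; asymptotes (median of the outer
15% of bins per side) normalize the ESF to 0/1. The LSF is the centered
finite difference, Hann-windowed about its peak; the MTF is the modulus of
the zero-padded DFT, normalized at f = 0 and corrected for the
finite-difference transfer function sin(2πfΔ)/(2πfΔ). Threshold
frequencies use the first downward crossing with linear interpolation; a
level not crossed below Nyquist is reported as not-evaluable (a QC flag),
never an exception. A slant below 0.2° sets `zero_slant_warning` (aliased
ESF). The two edges of each orientation are averaged; a near-vertical edge
measures the horizontal MTF.

Residual bias of the estimator on noiseless Gaussian edges (pitch 0.15 mm,
σ = 0.5 mm) is below 0.005 absolute modulation — the pixel aperture, which
the analytic oracle deliberately omits, dominates it.

## Detectability index

d′ uses the non-prewhitening matched filter under a white-noise
approximation — no measured noise power spectrum — with the radially
averaged MTF (mean of H and V curves) and the disk task spectrum
T(ρ) = (πD²/4)·2J₁(πDρ)/(πDρ), integrated by trapezoid on the MTF grid up
to Nyquist. Two checks pin it down: with MTF ≡ 1 and an extended cutoff it
reduces to the Parseval limit SDNR·(D/a)·√π/2, and it is monotone in
contrast, noise, disk diameter and pointwise MTF improvement. Absolute d′
values depend on this task model and are not comparable across observer
models; orderings and trends are. ROI statistics use the sample SD (n−1)
throughout.

## Fleet statistics

One quantile convention everywhere (cross-checked by test): linear
interpolation of order statistics with the p-quantile at rank p·(n−1).

- **Outlier rule:** one-sided, v > Q3 + 1.5·(Q3−Q1), as appropriate for
  contrast anomalies that can only inflate SDNR (an over-thick Al insert).
  The rule degrades when a single anomalous data set contributes ≳25% of
  the pooled stratum — the fence then chases the contamination — so
  screening pools across the whole image-type stratum, and recommendations
  require the data set to dominate the outlier group (≥50% of its own
  exposures above the fence).
- **H/V asymmetry:** paired t on (HMTF50, VMTF50) per data set, two-sided,
  α = 0.01 by default. Degenerate inputs are defined exactly: all-zero
  differences give t = 0, p = 1; zero-variance non-zero differences give
  p = 0 with a flag.
- **Percentile thresholds:** the (1−0.75)-quantile of per-system medians,
  so 75% of systems lie at or above it. The shipped minimum-performance
  defaults are HMTF50 ≥ 1.2 lp/mm, SDNR ≥ 7.5, d′(0.3 mm) ≥ 3.4,
  boundary-inclusive.
- **Densities:** Gaussian KDE, Silverman bandwidth, grid spanning the data
  range ±3 bandwidths (trapezoid integral 1 within 1e-3).
- **Exclusion:** `flag_suspect_datasets` only recommends, with evidence
  attached; removing a data set from statistics is a manual, reasoned
  registry action.

## Synthetic fleets and what they do (not) show

Two fidelity tiers. The image-level tier renders and analyzes every
exposure and is used wherever the image-domain mechanism is the point
(thick-Al SDNR inflation, blunt-edge asymmetry, processing effects). The
metric-level tier draws the ten metrics directly from the noise-law-implied
distributions (per-exposure relative scatter 1.5% on MTF/SDNR, 7% on SNR,
3% per-data-set dose variation, isotropic per-data-set blur variation) and
is used for registry arithmetic and statistical calibration at scales —
hundreds of data sets, ~10³ exposures — where rendering images would add
runtime but no information about the statistic under test. Study sizes
used by the shipped tests: 200 rendered phantoms for SDNR/SNR recovery,
100 rendered raw/processed pairs for processing directionality, 500
metric-level data sets for asymmetry-test calibration, a 47-data-set /
968-exposure metric-level fleet for cohort arithmetic.

The generator reproduces the features the analysis depends on — edges with
known blur, affine noise, contrast set by insert thickness via a
Beer–Lambert surrogate (μ_Al = 0.0994 mm⁻¹), vendor DICOM pathologies —
and omits scatter, grid artifacts, detector lag/ghosting, spatially
correlated noise and real vendor processing. Passing tests therefore
demonstrate correctness of the estimators and statistics under the stated
model, not performance on any particular clinical system; in particular
the white-noise d′ will differ systematically from task-based indices
computed with a measured NPS.

## Numerical choices and degenerate inputs

- ESF bin width pitch/8; DFT zero-padded to ≥4096 for fine frequency
  interpolation; finite-difference correction clamped where the transfer
  function falls below 0.2.
- Noiseless images make SNR/SDNR denominators zero: explicit
  `degenerate ROI` errors, never masked division.
- Uniform images fail localization with `cu_not_found`; edges with fewer
  than 64 usable crossings fail with `edge_too_short`.
- mAs equal to an integer sets the heuristic `mas_rounded_suspect` flag
  (it cannot be distinguished from a genuinely integer exposure); exposure
  index and entrance dose are never imputed, only flagged missing.
- DICOM writing derives all UIDs from content, so identical inputs give
  byte-identical files; registry CSVs are read back with round-trip float
  parsing so save → load → save is byte-stable.

## Known limitations

Single-phantom scenes only; no NPS/NEQ/DQE estimation; the d′ observer
model is a documented stand-in for software-specific task models; cohort
clustering requires exact setup-key equality (a 1 cm SID difference makes a
new cohort by design); no multiple-testing correction across cohorts in
the asymmetry screen — at α = 0.01 a fleet of N clean data sets still
flags ~0.01·N of them, which is why recommendations carry their evidence.
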