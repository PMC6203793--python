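# Methods

`qdfish` quantifies single-molecule FISH images: every labeled transcript
appears as a diffraction-limited spot, and the package detects, localizes,
and counts those spots, calibrates spot intensity against single
fluorophores, and compares counts across imaging conditions.  Because the
method's statistical behavior can only be verified against known ground
truth, the package ships a first-class synthetic microscope-image
generator that emulates the two probe chemistries it was built to
contrast: organic dyes (dim, photobleaching) and compact quantum dots
(bright, photostable).

## Spot detection

### Model and statistic

Each fully interior 7×7 window (window half-width 3; configurable) is
tested with a generalized likelihood ratio test comparing

* H0: `y = b + ε` — local background only,
* H1: `y = a·g(x₀, y₀) + b + ε` — one spot of amplitude `a` on local
  background,

with `ε` i.i.d. Gaussian of unknown variance and `g` a symmetric 2D
Gaussian PSF of fixed width `σ` (default 1.2 px), sampled at pixel centers
and normalized to unit mass over the untruncated lattice.  Both models are
fitted by least squares in closed form and the statistic is

    T = N · ln(SS0 / SS1),   N = 49,

clamped to zero when the fitted amplitude is negative (dark dips are not
spots) or the window is constant.  `T` is invariant under affine
transformations of the pixel values, and because the background is
re-fitted in every window, detection responds to *local* contrast —
spatially slowly-varying autofluorescence is absorbed into `b` rather than
mistaken for signal.

Two conventions are worth stating explicitly because simulator and
detector must share them: coordinates are 0-based with the pixel center at
integer coordinates, and the PSF is *sampled* at pixel centers rather than
integrated over pixel area.  Sampling keeps rendering and fitting exactly
consistent, so fits of rendered spots are unbiased by construction; the
difference from pixel-integrated rendering is absorbed into the effective
σ a user would measure from beads.

### Threshold normalization

Detection stringency is a false-positive probability **per image** on a
decibel scale:

    threshold_db = −10 · log₁₀(P_false-positive per 512×512 image)

so 30 dB means one false spot per thousand images.  The per-image
probability is divided Bonferroni-style by the number of interior windows
(506² = 256,036 for 512×512; the Šidák correction differs negligibly at
these probabilities) to give a per-window error rate `p`, which is mapped
to a cutoff on `T` in one of three modes:

* `exact` (default): under the Gaussian null the amplitude t-statistic is
  Student-t with N−2 degrees of freedom and `T = N·ln(1 + t²/(N−2))` is a
  monotone function of it, so the one-sided cutoff
  `T_c = N·ln(1 + t₁₋ₚ²/(N−2))` is exact at any `p` — including the
  p ≈ 10⁻⁸–10⁻⁹ reached by a 25–35 dB threshold, far beyond what
  simulation can calibrate directly.
* `asymptotic`: the χ²(1) quantile at 1−p (one extra linear parameter).
  Conservative by up to 2× (it ignores the one-sided clamping) and
  inexact in the far tail at N = 49; retained as the textbook reference.
* `monte_carlo`: empirical (1−p) quantile of `T` over simulated pure-noise
  windows; requires at least 100/p samples and therefore only reaches
  moderate `p`.  It exists to validate the exact mapping (the two agree
  within Monte-Carlo error at p = 10⁻³ with 4·10⁵ windows) and for users
  who prefer a distribution-free calibration.

On simulated pure-noise images the measured false positives per image
match 10^(−threshold/10) within binomial error at 10 and 20 dB, the
largest rates measurable at practical frame counts.

### Candidates, depletion, and crowded fields

A single pass of "threshold the T map at its local maxima" fails in
crowded fields for a reason that is easy to miss: a bright neighbor inside
the window inflates the *local noise estimate* SS1, so every member of a
tight cluster can score below threshold simultaneously — three spots with
thousands of photons each, 3 px apart, can be jointly invisible to the
per-window GLRT.  Detection therefore proceeds in two stages:

1. **Provisional stage.**  Candidates are local maxima of the
   matched-filter amplitude map scored against a *locally robust* noise
   scale: the per-window residual variance map is reduced by tiled medians
   (32-px tiles, bilinearly interpolated), which is insensitive to the
   minority of windows containing spots while still adapting to the
   autofluorescence level across the cell.  The gate is deliberately lax
   (per-window p = 10⁻⁴); its role is completeness, not error control.
   Candidates are fitted brightest-first and each fitted model is
   subtracted from a working image ("serial depletion"); detection re-runs
   on the residual until no new candidate appears.  Two cyclic refinement
   passes then re-fit every spot on the image with its current neighbor
   models removed, which un-biases fits that were contaminated before
   their neighbors were known.

2. **Ghost pruning.**  An unresolved pair seeds its first candidate at the
   merged maximum *between* the true spots; depletion then finds the two
   outer lobes, leaving a spurious middle spot.  Any spot with ≥ 2
   provisional neighbors within 3.5 px is therefore tested for redundancy:
   remove it, refit the neighbors, and keep the removal if the local
   residual sum of squares grows by less than 25 local noise variances.
   A genuine middle spot leaves its flux unexplained on removal and
   survives.

3. **Final acceptance.**  Each surviving spot is re-scored with the true
   local GLRT on the depleted image with its own model added back (i.e.
   with neighbors removed) and accepted only if the re-scored `T` passes
   the threshold cutoff; rejected spots are re-added to the residual and
   scoring iterates to a fixed point.  For an isolated candidate the
   re-scored window equals the original image window, so the candidate
   gate and depletion machinery leave the false-positive calibration of
   the final threshold intact (the lax gate censors < 4% of the null tail
   at 10 dB, less at stricter thresholds).

Accepted spots closer than `min_separation_px` (default 2.0 px ≈ the
resolution limit at σ = 1.2) are deduplicated; below that distance a
second detection cannot be distinguished from the subtraction residual of
the first, because the least-squares fit assumes homoscedastic noise while
shot noise on a bright spot is not.

### Sub-pixel fitting

Each spot is fitted in its 7×7 window by nonlinear least squares over
(x, y, amplitude, background) with σ fixed.  The model is linear in
amplitude and background, so those are solved in closed form at every
position (variable projection) and a damped Gauss–Newton iteration runs
over the two position offsets only, constrained to ±1 px of the candidate
center.  On a noiseless rendered spot the fit recovers position and
amplitude to machine precision; at peak SNR 10 the mean localization error
is below 0.15 px.  Non-convergence falls back to the integer center with a
closed-form linear fit, flagged on the record.

Because the PSF kernel has unit mass, the fitted amplitude *is* the spot's
total photon count; spot intensities and single-fluorophore intensities
are therefore directly comparable without aperture corrections.

### Borders and 3D counting

Only fully interior windows are evaluated; spots within 3 px of the image
edge are undetectable by construction.  For z-stacks, 2D detection runs
per slice and spots in adjacent slices within `link_radius_px` (default
2σ) are merged by single linkage through consecutive slices; each cluster
is one 3D spot at its amplitude-weighted centroid.  The commercial
deconvolution + 3D-counting products used in comparable experiments are
replaced by this in-repo slice-linking counter.

## Single-fluorophore calibration and labeling density

Videos of sparse fluorophores under continuous excitation are reduced to
per-frame amplitude traces by the closed-form (amplitude, background) fit
at a fixed position.  Traces are segmented by binary changepoint
segmentation on the mean with a penalty of `10 · σ̂² · ln n` per split
(σ̂² the robust noise variance from median absolute first differences;
the penalty default was tuned once on simulated traces and is exposed as a
parameter).  A trace is classified single-molecule if it has exactly one
downward step, the post-step mean is within 2 noise SDs of background, and
the pre-step plateau CV is below 0.5 — excluding multi-emitter spots and
blinking-truncated traces.  The single-fluorophore intensity is the mean
pre-step plateau over kept traces; labeling density is spot amplitude
divided by that mean.  The whole chain is scale-equivariant: multiplying
all frames by c scales the calibration by c and leaves density estimates
unchanged.

The estimator is a truncated-sample mean: spots whose labeling happens to
fall below the detection limit are absent from the histogram, which biases
the mean upward by a few percent in the dye regime (where a 2–4
fluorophore spot is undetectable).  This bias is inherent to
intensity-histogram labeling-density estimates, simulated and real alike,
and is visible in the parameter-recovery tests as a small positive offset
within the 10% recovery band.

## Downstream analyses

* **Threshold sweep** — the full detection pipeline per cell per threshold
  (the candidate stage is threshold-independent and shared; results are
  identical to independent runs).  Slopes of mean count vs threshold are
  central finite differences, exact for quadratic curves.  The sweep's
  purpose is the robustness contrast: flat for bright QD-like probes,
  steep for dye-like probes convolved with autofluorescence.
* **Photostability series** — counts per time point of a
  continuous-excitation series, normalized to t = 0.
* **2D vs 3D** — per-cell counts at one focal plane vs the slice-linked
  3D count, with least-squares slope and Pearson correlation (flagged NaN
  for degenerate inputs).
* **Knockdown comparison** — percent change of mean counts,
  `100·(1 − mean_treated/mean_control)`, with a percentile bootstrap CI
  over cells (10⁴ resamples) and a Welch t-test.  Multiplexed experiments
  are analyzed as independent per-channel runs; the bandpass filters are
  spectrally disjoint, so no unmixing is performed.

## The synthetic-data generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions under which everything above is validated.

* **Geometry and optics** — 512×512 frames, 160 nm pixels, Gaussian PSF
  σ = 1.2 px, elliptical cell mask (semi-axes 210 × 175 px).  Z-stacks use
  0.22 µm steps with a Gaussian axial defocus envelope (σ_z = 0.30 µm), so
  a spot spans 2–4 slices.
* **Labeling** — per-transcript fluorophore counts are zero-truncated
  Poisson, parameterized by the mean; only means are empirically known, so
  the distribution family is a modeling choice.  Per-fluorophore
  brightness is gamma-distributed with CV 0.25.
* **Probe presets** — `dye`: 425 spots/cell, mean 8.0 fluorophores per
  transcript, 120 photons per fluorophore per frame, bleach rate
  0.01 s⁻¹; `qd13` (compact QDs): 487 spots/cell, mean 10, 1500
  photons, photostable; `qd17` (large, sterically hindered QDs): 75
  spots/cell, mean 2.3, 1500 photons, photostable.  The 12.5× QD/dye
  brightness ratio encodes the regime the method was designed around: a
  *single* QD (peak ≈ 11× the background fluctuation) is clearly
  detectable in a cell, while a single dye (peak ≈ 0.9×) is not, making
  dye counts threshold-sensitive and QD counts robust.  The dye bleach
  rate is anchored so that under continuous excitation counts fall ≈ 12%
  by 30 s and to near zero by 10 min, given the pipeline's measured
  detection limit of ≈ 5 remaining dyes per spot.
* **Autofluorescence** — a Gaussian random field (white noise low-pass
  filtered at correlation length 2 px, rescaled to SD 12 photons) plus a
  50-photon mean level, restricted to the cell mask; cellular background
  is nonuniform but has no published parametric model, so this is the
  simplest stationary choice with the right qualitative texture.
* **Camera** — Poisson shot noise × gain (1.0), Gaussian read noise
  (SD 3), offset 100, quantization to 8 or 16 bits.  EMCCD
  electron-multiplication excess noise is folded into the Gaussian term
  rather than modeled with the full EM-register gamma cascade — the
  detection statistic assumes Gaussian noise anyway, so the extra fidelity
  would not change what the tests can show.
* **Photophysics** — each fluorophore draws one exponential bleaching
  lifetime (survival is monotone per fluorophore across a time series);
  blinking is an optional per-frame Bernoulli thinning (on-fraction 1 by
  default; QD power-law blinking statistics are out of scope).
* **Spectra** — emission spectra are Gaussian approximations (QD608/12,
  QD693/15, QD800/18 nm peak/SD; dye 610/17) tabulated on a 1 nm grid;
  multichannel images split each probe's photons across the 600/37,
  698/70, 809/81 nm bandpass filters by the trapezoid-integrated band
  fraction.
* **Determinism** — one master seed; every cell/frame/channel derives its
  own stream via `SeedSequence.spawn`.  Identical configuration and seed
  give bit-identical images and truth tables.

What the generator does **not** emulate — optical aberrations and
depth-dependent PSFs, deconvolution artifacts, nonspecific probe binding,
transcript clustering (spots are uniform in the mask), dye spectral
crowding beyond Gaussian shapes, and EM-register noise statistics.
Passing tests therefore demonstrate the analysis is correct *under its own
stated model* and robust at realistic brightness, density, and background
levels; they do not certify counting accuracy on real micrographs, where
PSF mismatch and structured backgrounds add errors the simulator does not
produce.

## Problem sizes in the shipped tests

The acceptance-scale tests run the three probe regimes at full 512×512
frame size and preset spot counts, with 5–7 cells per sweep, 2–3 cells per
time series, 200 replicates for pair resolution, 500 noise frames per
false-positive threshold, 120 molecules per calibration video, and ~500
spots per labeling-density estimate; `scripts/acceptance.py` uses the same
sizes with the noise-frame count and sweep-cell count trimmed (300 frames,
5 cells) to keep a full run in the tens of minutes on one core.

## Known limitations

* Counting degrades when spot spacing approaches the 2 px separation
  floor; at the QD preset density (~0.4% of pixels occupied by spot
  centers) pair merging costs ~2% recall, and dense subcellular clusters
  would be undercounted.
* The exact threshold calibration assumes Gaussian pixel noise; under
  strongly Poisson-limited (low-background) or EM-dominated conditions the
  per-image false-positive rate is approximate, though threshold *sweeps*
  remain meaningful because the miscalibration is monotone.
* The changepoint classifier assumes steps are large relative to trace
  noise (single-frame SNR ≳ 5 per fluorophore); dimmer fluorophores
  require longer plateaus or temporal binning.
* 3D linking assumes spots in adjacent slices within 2σ belong to the same
  molecule; axially overlapping distinct molecules merge.
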