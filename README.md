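# qdfish

Single-molecule FISH (smFISH) quantification: every fluorescently labeled
mRNA appears as a diffraction-limited spot, and transcript abundance per
cell is the number of spots.  `qdfish` is for researchers who count those
spots and need the counting to be *statistically controlled* — detection
thresholds expressed as false-positive rates rather than arbitrary
intensity units — and who want to compare probe chemistries, most notably
organic dyes (dim, rapidly photobleaching) against compact quantum dots
(bright, photostable, spectrally multiplexable).

## What it implements

**Detection.**  Every 7×7 pixel window is tested with a generalized
likelihood ratio test (GLRT) of "spot + local background" against "local
background only", assuming Gaussian noise with unknown variance:

    H0: y = b + ε        H1: y = a·g(x₀,y₀) + b + ε
    T  = N · ln(SS0/SS1),  N = 49

with `g` a unit-mass Gaussian PSF (σ fixed, default 1.2 px) sampled at
pixel centers.  Because the background is fitted per window, spatially
nonuniform cellular autofluorescence is not mistaken for signal.  The
detection threshold is the probability of a false positive per 512×512
image on a decibel scale, `threshold_db = −10·log₁₀(P_img)`, shared
across the ~256,000 windows and mapped to a cutoff on `T` through the
exact finite-sample null distribution (a monotone function of a
Student-t(47) statistic).  Spots are fitted to sub-pixel precision,
subtracted, and the analysis repeats ("serial depletion"), which resolves
spots a few pixels apart; a ghost-pruning step removes the spurious
midpoint detections that unresolved pairs otherwise seed.

**Calibration.**  Videos of isolated fluorophores bleaching in single
steps are segmented by changepoint analysis; the pre-step plateau of
one-step traces gives the single-fluorophore intensity, and spot
amplitude divided by it gives fluorophores per transcript (labeling
density).

**Analyses.**  Count-vs-threshold sweeps with slopes (threshold-robustness
diagnostic), photostability count series, 2D vs 3D (slice-linked) counts,
and two-condition percent-knockdown comparison with bootstrap CI and
Welch t-test.

**Simulator.**  A seeded, ground-truthed image generator: zero-truncated
Poisson labeling, gamma fluorophore brightness, exponential bleaching
lifetimes, optional blinking, correlated autofluorescence inside an
elliptical cell mask, EMCCD camera noise, z-stacks with axial defocus,
and multichannel rendering through 600/37, 698/70, 809/81 nm bandpass
filters via spectral crosstalk coefficients.  Presets `dye`, `qd13`,
`qd17` encode the three probe regimes (425/487/75 spots per cell, mean
8.0/10/2.3 fluorophores per transcript).  See `docs/methods.md` for the
model and every default.

## Worked example

Simulate one compact-QD cell, detect spots at a 30 dB threshold (one
false positive per 10³ images), and estimate labeling density:

```python
import numpy as np
from qdfish import (PSFModel, DetectionConfig, preset, generate_cell_field,
                    detect_frame, simulate_calibration_video, extract_trace,
                    single_fluorophore_distribution, estimate_labeling_density)
from dataclasses import replace

psf = PSFModel(sigma_px=1.2)
cfg, fluor = preset("qd13")

frame, truth = generate_cell_field(cfg, fluor, seed=5)
spots = detect_frame(frame, psf, DetectionConfig(threshold_db=30.0))
print(f"{len(truth)} true spots, {len(spots)} detected")

video, mols = simulate_calibration_video(replace(fluor, bleach_rate=0.03),
                                         n_molecules=120, n_frames=150, seed=42)
calib = single_fluorophore_distribution(
    [extract_trace(video, (m.x, m.y), psf) for m in mols])
dens = estimate_labeling_density(np.array([s.amplitude for s in spots]), calib)
print(f"single-QD intensity {calib.mean_single_intensity:.0f} photons "
      f"(n={calib.n_molecules}), mean {dens.mean_n:.1f} QDs per transcript")
```

Output:

```
481 true spots, 483 detected
single-QD intensity 1489 photons (n=115), mean 10.0 QDs per transcript
```

481 transcripts were placed in the simulated cell and 483 spots pass the
30 dB test — at QD brightness the count is essentially exact (a couple of
sub-resolution pairs merge, a couple of autofluorescence bumps pass); the
calibration recovers the configured 1500-photon single-QD brightness from
115 one-step bleaching traces, and dividing spot intensities by it
recovers the configured labeling density of 10 QDs per transcript.

The same pipelines are scriptable from the shell:

```sh
qdfish simulate --preset qd13 --seed 7 --out run/
qdfish detect --image run/cell_000.tif --threshold-db 30 --sigma-px 1.2 --out run/
qdfish sweep --seed 7 --out run/        # count-vs-threshold curve + slopes
qdfish compare-conditions --control ctrl.csv --treated sirna.csv --out run/
```

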