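"""Synthetic smFISH microscopy: ground-truthed fields, stacks, and time-lapses.

Emulates the statistical structure of single-molecule FISH experiments that
compare organic-dye probes with compact quantum-dot (QD) probes:

* diffraction-limited spots, one per transcript, each carrying a random
  number of fluorophore-bearing probes (zero-truncated Poisson labeling);
* dye-like emitters (dimmer, exponentially photobleaching) versus QD-like
  emitters (brighter, photostable);
* spatially correlated cellular autofluorescence restricted to an
  elliptical cell mask;
* EMCCD camera noise (Poisson shot noise, gain, Gaussian read noise,
  offset, quantization);
* multichannel emission split across bandpass filters via spectral
  crosstalk coefficients.

Every generator is deterministic given its seed; sub-streams are derived
from a single master seed with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import ImageFrame, ImageStack
from .psf import PSFModel, gaussian_kernel, render_field

__all__ = [
    "FluorophoreModel",
    "SpotTruth",
    "CountDistribution",
    "EllipseMask",
    "AutofluorescenceModel",
    "CameraModel",
    "CellSimConfig",
    "BandpassFilter",
    "zero_truncated_poisson_rate",
    "sample_labeling_counts",
    "gaussian_spectrum",
    "crosstalk_coefficient",
    "autofluorescence_field",
    "apply_camera_noise",
    "sample_field_truth",
    "generate_cell_field",
    "simulate_timelapse",
    "simulate_zstack",
    "simulate_calibration_video",
    "simulate_multichannel_field",
    "amplitude_for_peak_snr",
    "background_noise_sd",
    "preset",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FluorophoreModel:
    """Photophysics of one fluorophore species.

    Parameters
    ----------
    mean_intensity
        Mean emitted photons per fluorophore per frame.
    intensity_cv
        Coefficient of variation of the per-fluorophore intensity
        (gamma-distributed brightness; 0 = identical fluorophores).
    bleach_rate
        Irreversible photobleaching rate in 1/s under excitation
        (0 = photostable, QD-like).
    blink_on_fraction
        Probability that an unbleached fluorophore emits in a given frame
        (1 = no blinking).
    emission_spectrum
        Optional ``(n, 2)`` table of (wavelength nm, relative intensity).
    """

    mean_intensity: float
    intensity_cv: float = 0.25
    bleach_rate: float = 0.0
    blink_on_fraction: float = 1.0
    emission_spectrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.mean_intensity > 0:
            raise ValueError("mean_intensity must be > 0")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if not 0 < self.blink_on_fraction <= 1:
            raise ValueError("blink_on_fraction must be in (0, 1]")
        if self.emission_spectrum is not None:
            spec = np.asarray(self.emission_spectrum, dtype=float)
            if spec.ndim != 2 or spec.shape[1] != 2:
                raise ValueError("emission_spectrum must be an (n, 2) table")
            if np.any(spec[:, 1] < 0):
                raise ValueError("spectrum intensities must be >= 0")
            object.__setattr__(self, "emission_spectrum", spec)


@dataclass
class SpotTruth:
    """Ground truth for one simulated transcript spot."""

    x: float
    y: float
    z_um: float = 0.0
    n_fluorophores: int = 1
    target_id: str = ""
    channel_id: str = ""
    # per-fluorophore photon emissions (length n_fluorophores); filled by the
    # generator so time-lapse rendering can bleach fluorophores individually
    fluorophore_intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_fluorophores < 1:
            raise ValueError("n_fluorophores must be >= 1")

    @property
    def amplitude(self) -> float:
        """Total spot photons per frame with all fluorophores emitting."""
        if self.fluorophore_intensities is None:
            raise ValueError("fluorophore intensities not populated")
        return float(self.fluorophore_intensities.sum())


@dataclass(frozen=True)
class CountDistribution:
    """Spec for a count distribution: Poisson(mean) or, with ``dispersion``
    > 1, negative binomial with that variance-to-mean ratio."""

    mean: float
    dispersion: float | None = None

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.dispersion is None or self.dispersion <= 1.0:
            return rng.poisson(self.mean, size=size)
        # NB with var = dispersion * mean
        p = 1.0 / self.dispersion
        r = self.mean * p / (1.0 - p)
        return rng.negative_binomial(r, p, size=size)


@dataclass(frozen=True)
class EllipseMask:
    """Elliptical cell-boundary geometry in pixel coordinates."""

    cx: float = 255.5
    cy: float = 255.5
    semi_x: float = 210.0
    semi_y: float = 175.0

    def contains(self, x, y):
        return ((np.asarray(x) - self.cx) / self.semi_x) ** 2 + (
            (np.asarray(y) - self.cy) / self.semi_y
        ) ** 2 <= 1.0

    def as_array(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(xx, yy)


@dataclass(frozen=True)
class AutofluorescenceModel:
    """Spatially correlated cellular background: a Gaussian random field
    (low-pass-filtered white noise) with the given standard deviation and
    correlation length, plus a mean level, restricted to the cell mask."""

    mean_photons: float = 50.0
    amplitude: float = 12.0
    corr_length_px: float = 2.0

    def __post_init__(self) -> None:
        if not self.corr_length_px > 0:
            raise ValueError("corr_length_px must be > 0")
        if self.mean_photons < 0 or self.amplitude < 0:
            raise ValueError("autofluorescence levels must be >= 0")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD readout: Poisson shot noise x gain + offset + Gaussian read
    noise, clipped and quantized to the bit depth.  EM-register excess
    noise is folded into the Gaussian read-noise term."""

    offset: float = 100.0
    read_noise_sd: float = 3.0
    gain: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.gain < 0 or self.read_noise_sd < 0:
            raise ValueError("gain and read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class CellSimConfig:
    """Full configuration for simulating one cell's image."""

    image_size: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 160.0
    n_spots: CountDistribution = field(default_factory=lambda: CountDistribution(425.0))
    labeling_density_mean: float = 8.0
    cell_mask: EllipseMask = field(default_factory=EllipseMask)
    autofluorescence: AutofluorescenceModel = field(default_factory=AutofluorescenceModel)
    base_photons: float = 5.0
    camera: CameraModel = field(default_factory=CameraModel)
    psf: PSFModel = field(default_factory=PSFModel)
    seed: int = 0
    target_id: str = ""
    channel_id: str = ""

    def __post_init__(self) -> None:
        k = 2 * self.psf.window_half + 1
        if self.image_size[0] < k or self.image_size[1] < k:
            raise ValueError("image_size must be at least the analysis window size")
        if (
            self.cell_mask.semi_x > self.image_size[1] / 2
            or self.cell_mask.semi_y > self.image_size[0] / 2
        ):
            raise ValueError("cell mask larger than image")


@dataclass(frozen=True)
class BandpassFilter:
    """Optical bandpass filter, center/full-width in nm (e.g. 600/37)."""

    center: float
    full_width: float

    def __post_init__(self) -> None:
        if not self.full_width > 0:
            raise ValueError("full_width must be > 0")

    @property
    def band(self) -> tuple[float, float]:
        return (self.center - self.full_width / 2.0, self.center + self.full_width / 2.0)


# ---------------------------------------------------------------------------
# labeling density


def zero_truncated_poisson_rate(mean: float) -> float:
    """Poisson rate lambda such that the zero-truncated Poisson has the
    requested mean, i.e. solve mean = lambda / (1 - exp(-lambda))."""
    if not mean > 1.0:
        raise ValueError("zero-truncated Poisson mean must be > 1")
    lam = mean  # good starting point; mean > lambda always
    for _ in range(100):
        e = math.exp(-lam)
        f = lam / (1.0 - e) - mean
        if abs(f) < 1e-12:
            break
        df = (1.0 - e - lam * e) / (1.0 - e) ** 2
        lam -= f / df
    return lam


def sample_labeling_counts(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n fluorophore counts from a zero-truncated Poisson with the
    given mean (per-transcript labeling density)."""
    if mean <= 1.0 + 1e-12:
        if mean < 1.0:
            raise ValueError("labeling-density mean must be >= 1")
        return np.ones(n, dtype=np.int64)
    lam = zero_truncated_poisson_rate(mean)
    out = rng.poisson(lam, size=n)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam, size=int(bad.sum()))
        bad = out == 0
    return out


# ---------------------------------------------------------------------------
# spectra


def gaussian_spectrum(
    peak_nm: float, sd_nm: float, grid: np.ndarray | None = None
) -> np.ndarray:
    """Tabulated Gaussian emission spectrum on a 1-nm grid (450-1000 nm)."""
    if grid is None:
        grid = np.arange(450.0, 1000.0 + 1e-9, 1.0)
    rel = np.exp(-((grid - peak_nm) ** 2) / (2.0 * sd_nm**2))
    return np.column_stack([grid, rel])


def crosstalk_coefficient(spectrum: np.ndarray, bp: BandpassFilter) -> float:
    """Fraction of a fluorophore's emission transmitted by a bandpass filter.

    Trapezoidal integral of the tabulated spectrum over the filter band,
    divided by the integral over all tabulated wavelengths.  In [0, 1].
    """
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 2 or spec.shape[1] != 2:
        raise ValueError("spectrum must be an (n, 2) table of (nm, intensity)")
    wl, inten = spec[:, 0], spec[:, 1]
    if np.any(inten < 0):
        raise ValueError("spectrum intensities must be >= 0")
    total = float(np.trapezoid(inten, wl))
    if total <= 0:
        raise ValueError("spectrum integrates to zero; crosstalk undefined")
    lo, hi = bp.band
    # integrate on the union of tabulated points inside the band plus the
    # interpolated band edges, so partial panels at the edges are exact
    inside = (wl > lo) & (wl < hi)
    pts = np.concatenate([[lo], wl[inside], [hi]])
    pts = pts[(pts >= wl[0]) & (pts <= wl[-1])]
    if pts.size < 2:
        return 0.0
    vals = np.interp(pts, wl, inten)
    return float(np.trapezoid(vals, pts) / total)


# ---------------------------------------------------------------------------
# noise and backgrounds


def autofluorescence_field(
    shape: tuple[int, int],
    model: AutofluorescenceModel,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expected autofluorescence photons per pixel (inside the mask).

    White noise is low-pass filtered with a Gaussian of sigma equal to the
    correlation length, rescaled to the requested standard deviation, added
    to the mean level, floored at zero, and restricted to the cell mask.
    """
    white = rng.normal(0.0, 1.0, size=shape)
    smooth = gaussian_filter(white, model.corr_length_px, mode="reflect")
    # variance of filtered unit white noise: 1 / (4 pi sigma^2)
    sd = 1.0 / (2.0 * model.corr_length_px * math.sqrt(math.pi))
    fieldv = model.mean_photons + model.amplitude * (smooth / sd)
    return np.where(mask, np.clip(fieldv, 0.0, None), 0.0)


def apply_camera_noise(
    clean_photons: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """EMCCD readout of an expected-photons image.

    Per pixel: ``Poisson(photons) * gain + offset + N(0, read_noise_sd)``,
    clipped to the detector range and quantized to integers of the
    configured bit depth.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    clean = np.asarray(clean_photons, dtype=float)
    if np.any(clean < 0):
        raise ValueError("expected photons must be >= 0")
    signal = rng.poisson(clean).astype(float) * camera.gain + camera.offset
    if camera.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, camera.read_noise_sd, size=clean.shape)
    maxval = 2**camera.bit_depth - 1
    quant = np.clip(np.rint(signal), 0, maxval)
    return quant.astype(np.uint8 if camera.bit_depth == 8 else np.uint16)


def background_noise_sd(config: CellSimConfig) -> float:
    """Detector-unit fluctuation sd of the in-cell background.

    Quadrature sum of shot noise on base + mean autofluorescence photons
    (times gain), read noise, and the autofluorescence spatial
    fluctuation: the full background variability a spot must stand out
    from.  Used to express spot brightness as a peak signal-to-noise
    ratio.
    """
    photons = config.base_photons + config.autofluorescence.mean_photons
    g = config.camera.gain
    return math.sqrt(
        photons * g**2
        + config.camera.read_noise_sd**2
        + (config.autofluorescence.amplitude * g) ** 2
    )


def amplitude_for_peak_snr(snr: float, noise_sd: float, psf: PSFModel) -> float:
    """Total spot photons whose brightest pixel is ``snr`` times ``noise_sd``
    (for a spot centered on a pixel)."""
    peak = float(gaussian_kernel(psf.sigma_px, psf.window_half)[psf.window_half, psf.window_half])
    return snr * noise_sd / peak


# ---------------------------------------------------------------------------
# field generation


def sample_field_truth(
    config: CellSimConfig,
    fluor: FluorophoreModel,
    rng: np.random.Generator,
    n_spots: int | None = None,
) -> list[SpotTruth]:
    """Draw spot positions (uniform inside the cell mask), per-spot
    fluorophore counts, and per-fluorophore intensities."""
    if n_spots is None:
        n_spots = int(config.n_spots.sample(rng))
    h, w = config.image_size
    truths: list[SpotTruth] = []
    if n_spots == 0:
        return truths
    counts = sample_labeling_counts(config.labeling_density_mean, n_spots, rng)
    cv = fluor.intensity_cv
    m = config.cell_mask
    for n_fl in counts:
        while True:
            x = rng.uniform(m.cx - m.semi_x, m.cx + m.semi_x)
            y = rng.uniform(m.cy - m.semi_y, m.cy + m.semi_y)
            if m.contains(x, y) and 0 <= x <= w - 1 and 0 <= y <= h - 1:
                break
        if cv > 0:
            shape_k = 1.0 / cv**2
            inten = rng.gamma(shape_k, fluor.mean_intensity / shape_k, size=int(n_fl))
        else:
            inten = np.full(int(n_fl), fluor.mean_intensity)
        truths.append(
            SpotTruth(
                x=float(x),
                y=float(y),
                n_fluorophores=int(n_fl),
                target_id=config.target_id,
                channel_id=config.channel_id,
                fluorophore_intensities=inten,
            )
        )
    return truths


def _expected_photons(
    config: CellSimConfig,
    truths: list[SpotTruth],
    amplitudes: np.ndarray | None,
    af: np.ndarray,
) -> np.ndarray:
    if amplitudes is None:
        amplitudes = np.array([t.amplitude for t in truths])
    xs = np.array([t.x for t in truths])
    ys = np.array([t.y for t in truths])
    spots = render_field(config.image_size, config.psf, xs, ys, amplitudes)
    return spots + af + config.base_photons


def generate_cell_field(
    config: CellSimConfig,
    fluor: FluorophoreModel,
    seed: int | None = None,
) -> tuple[ImageFrame, list[SpotTruth]]:
    """Simulate one cell: noisy frame plus exact ground-truth spot list.

    The seed (default ``config.seed``) fully determines the output; two
    calls with identical arguments return bit-identical frames and truths.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_truth, rng_af, rng_cam = (np.random.default_rng(s) for s in ss.spawn(3))
    truths = sample_field_truth(config, fluor, rng_truth)
    mask = config.cell_mask.as_array(config.image_size)
    af = autofluorescence_field(config.image_size, config.autofluorescence, mask, rng_af)
    photons = _expected_photons(config, truths, None, af)
    pixels = apply_camera_noise(photons, config.camera, rng_cam)
    frame = ImageFrame(
        pixels=pixels,
        pixel_size_nm=config.pixel_size_nm,
        channel_id=config.channel_id,
        bit_depth=config.camera.bit_depth,
    )
    return frame, truths


def simulate_timelapse(
    truths: list[SpotTruth],
    fluor: FluorophoreModel,
    times_s: list[float],
    config: CellSimConfig,
    seed: int = 0,
) -> ImageStack:
    """Render a continuous-excitation time-lapse of a fixed field.

    Each fluorophore draws one exponential photobleaching lifetime
    (rate ``fluor.bleach_rate``), so its survival is monotone across
    frames; surviving fluorophores are further thinned per frame by
    ``blink_on_fraction``.  The autofluorescence field is a fixed cell
    property; camera noise is drawn independently per frame.
    """
    times = np.asarray(times_s, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be increasing and start at >= 0")
    ss = np.random.SeedSequence(seed)
    rng_life, rng_af, rng_blink, rng_cam = (np.random.default_rng(s) for s in ss.spawn(4))
    mask = config.cell_mask.as_array(config.image_size)
    af = autofluorescence_field(config.image_size, config.autofluorescence, mask, rng_af)

    lifetimes = []
    for t in truths:
        if fluor.bleach_rate > 0:
            lifetimes.append(rng_life.exponential(1.0 / fluor.bleach_rate, size=t.n_fluorophores))
        else:
            lifetimes.append(np.full(t.n_fluorophores, np.inf))

    frames = []
    for tt in times:
        amps = np.empty(len(truths))
        for i, tr in enumerate(truths):
            alive = lifetimes[i] > tt
            if fluor.blink_on_fraction < 1.0:
                alive = alive & (rng_blink.random(tr.n_fluorophores) < fluor.blink_on_fraction)
            amps[i] = tr.fluorophore_intensities[alive].sum()
        photons = _expected_photons(config, truths, amps, af)
        pixels = apply_camera_noise(photons, config.camera, rng_cam)
        frames.append(
            ImageFrame(
                pixels=pixels,
                pixel_size_nm=config.pixel_size_nm,
                time_s=float(tt),
                channel_id=config.channel_id,
                bit_depth=config.camera.bit_depth,
            )
        )
    interval = float(times[1] - times[0]) if times.size > 1 else 1.0
    return ImageStack(frames=frames, axis="time", frame_interval_s=interval)


def simulate_zstack(
    config: CellSimConfig,
    fluor: FluorophoreModel,
    n_slices: int,
    z_step_um: float = 0.22,
    axial_sigma_um: float = 0.30,
    seed: int | None = None,
) -> tuple[ImageStack, list[SpotTruth]]:
    """Simulate a z-stack: spots at uniform depths, per-slice brightness
    attenuated by a Gaussian axial defocus envelope.

    The in-focus slice carries the spot's full amplitude; a spot typically
    appears in 2-4 consecutive slices at the default 0.22 um step.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_truth, rng_af, rng_cam = (np.random.default_rng(s) for s in ss.spawn(3))
    truths = sample_field_truth(config, fluor, rng_truth)
    z_total = (n_slices - 1) * z_step_um
    for t in truths:
        t.z_um = float(rng_truth.uniform(0.0, z_total))
    mask = config.cell_mask.as_array(config.image_size)
    af = autofluorescence_field(config.image_size, config.autofluorescence, mask, rng_af)
    base_amps = np.array([t.amplitude for t in truths])
    zs = np.array([t.z_um for t in truths])
    frames = []
    for k in range(n_slices):
        dz = k * z_step_um - zs
        amps = base_amps * np.exp(-(dz**2) / (2.0 * axial_sigma_um**2))
        photons = _expected_photons(config, truths, amps, af)
        pixels = apply_camera_noise(photons, config.camera, rng_cam)
        frames.append(
            ImageFrame(
                pixels=pixels,
                pixel_size_nm=config.pixel_size_nm,
                z_index=k,
                channel_id=config.channel_id,
                bit_depth=config.camera.bit_depth,
            )
        )
    return ImageStack(frames=frames, axis="z", z_step_um=z_step_um), truths


def simulate_calibration_video(
    fluor: FluorophoreModel,
    n_molecules: int = 100,
    n_frames: int = 200,
    frame_interval_s: float = 1.0,
    spacing_px: int = 12,
    base_photons: float = 5.0,
    camera: CameraModel | None = None,
    psf: PSFModel | None = None,
    seed: int = 0,
) -> tuple[ImageStack, list[SpotTruth]]:
    """Continuous-excitation video of isolated single fluorophores on glass.

    Emulates the single-molecule calibration experiment: probes adsorbed
    sparsely on a clean coverslip (no cell, no autofluorescence), imaged
    until they photobleach.  Molecules sit on a jittered grid with
    ``spacing_px`` pitch so traces do not overlap.  Use a fluorophore
    model with a nonzero bleach rate so one-step bleaching events occur
    within the video.
    """
    if camera is None:
        camera = CameraModel()
    if psf is None:
        psf = PSFModel()
    ss = np.random.SeedSequence(seed)
    rng_pos, rng_int, rng_life, rng_blink, rng_cam = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    per_row = int(np.ceil(np.sqrt(n_molecules)))
    size = per_row * spacing_px + 2 * spacing_px
    cv = fluor.intensity_cv
    truths = []
    for i in range(n_molecules):
        gx = spacing_px + (i % per_row) * spacing_px
        gy = spacing_px + (i // per_row) * spacing_px
        x = gx + rng_pos.uniform(-1.5, 1.5)
        y = gy + rng_pos.uniform(-1.5, 1.5)
        if cv > 0:
            k = 1.0 / cv**2
            inten = rng_int.gamma(k, fluor.mean_intensity / k, size=1)
        else:
            inten = np.full(1, fluor.mean_intensity)
        truths.append(
            SpotTruth(x=float(x), y=float(y), n_fluorophores=1,
                      fluorophore_intensities=inten)
        )
    if fluor.bleach_rate > 0:
        lifetimes = [rng_life.exponential(1.0 / fluor.bleach_rate, size=1) for _ in truths]
    else:
        lifetimes = [np.full(1, np.inf) for _ in truths]
    xs = np.array([t.x for t in truths])
    ys = np.array([t.y for t in truths])
    base_amp = np.array([t.amplitude for t in truths])
    frames = []
    for j in range(n_frames):
        tt = j * frame_interval_s
        alive = np.array([float(life[0] > tt) for life in lifetimes])
        if fluor.blink_on_fraction < 1.0:
            alive = alive * (rng_blink.random(len(truths)) < fluor.blink_on_fraction)
        amps = base_amp * alive
        photons = render_field((size, size), psf, xs, ys, amps) + base_photons
        pixels = apply_camera_noise(photons, camera, rng_cam)
        frames.append(
            ImageFrame(pixels=pixels, time_s=tt, bit_depth=camera.bit_depth)
        )
    stack = ImageStack(frames=frames, axis="time", frame_interval_s=frame_interval_s)
    return stack, truths


def simulate_multichannel_field(
    configs: dict[str, CellSimConfig],
    fluors: dict[str, FluorophoreModel],
    filters: dict[str, BandpassFilter],
    seed: int = 0,
) -> tuple[dict[str, ImageFrame], list[SpotTruth]]:
    """Simulate one cell imaged through several bandpass filters.

    ``configs``/``fluors`` are keyed by target; ``filters`` by channel.
    Each target's spot photons are split across channels by the crosstalk
    coefficient of its emission spectrum with each filter.  All targets
    share one cell (mask and autofluorescence from the first config).
    """
    ss = np.random.SeedSequence(seed)
    targets = sorted(configs)
    channels = sorted(filters)
    streams = ss.spawn(len(targets) + 1 + len(channels))
    ref = configs[targets[0]]
    mask = ref.cell_mask.as_array(ref.image_size)
    af = autofluorescence_field(
        ref.image_size, ref.autofluorescence, mask, np.random.default_rng(streams[len(targets)])
    )
    all_truths: list[SpotTruth] = []
    per_target: dict[str, list[SpotTruth]] = {}
    for i, tgt in enumerate(targets):
        cfg = replace(configs[tgt], target_id=tgt)
        truths = sample_field_truth(cfg, fluors[tgt], np.random.default_rng(streams[i]))
        per_target[tgt] = truths
        all_truths.extend(truths)
    out: dict[str, ImageFrame] = {}
    for j, ch in enumerate(channels):
        photons = af + ref.base_photons
        for tgt in targets:
            fl = fluors[tgt]
            if fl.emission_spectrum is None:
                raise ValueError(f"fluorophore for target {tgt!r} has no emission spectrum")
            c = crosstalk_coefficient(fl.emission_spectrum, filters[ch])
            truths = per_target[tgt]
            if truths and c > 0:
                xs = np.array([t.x for t in truths])
                ys = np.array([t.y for t in truths])
                amps = c * np.array([t.amplitude for t in truths])
                photons = photons + render_field(ref.image_size, ref.psf, xs, ys, amps)
        pixels = apply_camera_noise(
            photons, ref.camera, np.random.default_rng(streams[len(targets) + 1 + j])
        )
        out[ch] = ImageFrame(
            pixels=pixels,
            pixel_size_nm=ref.pixel_size_nm,
            channel_id=ch,
            bit_depth=ref.camera.bit_depth,
        )
    return out, all_truths


# ---------------------------------------------------------------------------
# presets: the dye vs compact-QD vs large-QD regimes

PRESET_NAMES = ("dye", "qd13", "qd17")

# Emission spectra (Gaussian approximations): dye ~ CAL Fluor Red 590-class
# red dye; QD608 / QD693 / QD800 are narrow tunable QD bands.
_SPECTRA = {
    "dye": (610.0, 17.0),
    "qd13": (608.0, 12.0),
    "qd17": (680.0, 14.0),
    "qd608": (608.0, 12.0),
    "qd693": (693.0, 15.0),
    "qd800": (800.0, 18.0),
}

# Default multiplexing filter set (center/full-width nm).
FILTERS = {
    "600/37": BandpassFilter(600.0, 37.0),
    "698/70": BandpassFilter(698.0, 70.0),
    "809/81": BandpassFilter(809.0, 81.0),
}


def preset(name: str) -> tuple[CellSimConfig, FluorophoreModel]:
    """Shipped study-condition presets.

    ``dye``  — 425 spots/cell, mean 8.0 fluorophores per transcript,
               120 photons/fluorophore, photobleaching at 0.01 /s.  At
               this rate a mean-labeled transcript falls below the
               detection limit (roughly five remaining dyes at the
               default imaging conditions) in about 12%% of spots after
               30 s of excitation, and counts approach zero by ~10 min —
               the qualitative time course of dye FISH under continuous
               excitation.
    ``qd13`` — compact QDs: 487 spots/cell, mean 10 per transcript,
               1500 photons/fluorophore (QDs under blue excitation are an
               order of magnitude brighter than dyes, far above the
               autofluorescence texture), photostable.
    ``qd17`` — large QDs: sterically hindered labeling, 75 spots/cell,
               mean 2.3 per transcript, 1500 photons/fluorophore,
               photostable.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    peak, sd = _SPECTRA[name]
    spectrum = gaussian_spectrum(peak, sd)
    if name == "dye":
        fluor = FluorophoreModel(
            mean_intensity=120.0, intensity_cv=0.25, bleach_rate=0.01,
            blink_on_fraction=1.0, emission_spectrum=spectrum,
        )
        cfg = CellSimConfig(
            n_spots=CountDistribution(425.0), labeling_density_mean=8.0,
            target_id="GAPDH", channel_id="600/37",
        )
    elif name == "qd13":
        fluor = FluorophoreModel(
            mean_intensity=1500.0, intensity_cv=0.25, bleach_rate=0.0,
            blink_on_fraction=1.0, emission_spectrum=spectrum,
        )
        cfg = CellSimConfig(
            n_spots=CountDistribution(487.0), labeling_density_mean=10.0,
            target_id="GAPDH", channel_id="600/37",
        )
    else:  # qd17
        fluor = FluorophoreModel(
            mean_intensity=1500.0, intensity_cv=0.25, bleach_rate=0.0,
            blink_on_fraction=1.0, emission_spectrum=spectrum,
        )
        cfg = CellSimConfig(
            n_spots=CountDistribution(75.0), labeling_density_mean=2.3,
            target_id="GAPDH", channel_id="585LP",
        )
    return cfg, fluor
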