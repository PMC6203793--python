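"""Single-fluorophore intensity calibration and labeling-density estimation.

Single fluorophores adsorbed on glass are imaged as videos under
continuous excitation.  A single molecule photobleaches in one discrete
step, so its background-subtracted intensity trace is a plateau followed
by noise around zero; aggregates and co-located pairs show multiple
steps.  Traces are segmented with a changepoint method, traces with
exactly one downward step terminating at background are kept, and the
mean pre-step plateau intensity estimates the photons emitted by one
fluorophore per frame.

Dividing FISH spot intensities by this single-fluorophore intensity
converts a spot intensity histogram into a fluorophores-per-transcript
("labeling density") distribution.  Because the fitted PSF kernel has
unit mass, a spot's fitted amplitude is its total photon count, so spot
amplitude / single-fluorophore intensity is the per-spot label count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import SpotRecord
from .frames import ImageStack
from .psf import PSFModel, gaussian_kernel

__all__ = [
    "IntensityTrace",
    "CalibrationResult",
    "LabelingDensityEstimate",
    "extract_trace",
    "detect_steps",
    "single_fluorophore_distribution",
    "estimate_labeling_density",
]


@dataclass
class IntensityTrace:
    """Background-subtracted spot intensity per frame at a fixed position."""

    values: np.ndarray
    frame_interval_s: float = 1.0
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 10:
            raise ValueError("trace must be 1D with at least 10 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CalibrationResult:
    """Single-fluorophore intensity distribution from kept traces."""

    single_intensity_samples: np.ndarray
    mean_single_intensity: float
    cv: float
    n_molecules: int
    method: str = "one-step photobleaching"

    def __post_init__(self) -> None:
        self.single_intensity_samples = np.asarray(
            self.single_intensity_samples, dtype=float
        )
        if self.n_molecules < 1:
            raise ValueError("calibration requires at least one kept molecule")
        if np.any(self.single_intensity_samples <= 0):
            raise ValueError("single-fluorophore intensities must be > 0")


@dataclass
class LabelingDensityEstimate:
    """Fluorophores per spot, spot-wise and averaged."""

    per_spot_n: np.ndarray
    mean_n: float
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    histogram: np.ndarray = field(default_factory=lambda: np.array([]))


def extract_trace(
    stack: ImageStack,
    spot: SpotRecord | tuple[float, float],
    psf: PSFModel,
) -> IntensityTrace:
    """Intensity time-trace of one spot from a time stack.

    Per frame, the amplitude and local background are fitted in closed
    form at the fixed spot position (PSF kernel sampled at the spot's
    sub-pixel offset); the returned values are the background-subtracted
    amplitudes, i.e. total spot photons per frame.
    """
    if stack.axis != "time":
        raise ValueError("extract_trace requires a time-axis stack")
    if isinstance(spot, SpotRecord):
        x, y = spot.x_sub, spot.y_sub
    else:
        x, y = spot
    h = psf.window_half
    shape = stack.frames[0].shape
    cx = min(max(round(x), h), shape[1] - h - 1)
    cy = min(max(round(y), h), shape[0] - h - 1)
    ker = gaussian_kernel(psf.sigma_px, h, x - cx, y - cy)
    kv = ker.ravel()
    n = kv.size
    k1 = kv.sum()
    kk = float(kv @ kv)
    den = n * kk - k1 * k1
    vals = np.empty(len(stack))
    for i, fr in enumerate(stack.frames):
        yv = fr.pixels[cy - h : cy + h + 1, cx - h : cx + h + 1].astype(float).ravel()
        sy = yv.sum()
        a = (n * float(kv @ yv) - k1 * sy) / den
        vals[i] = a
    return IntensityTrace(
        values=vals, frame_interval_s=stack.frame_interval_s, x=x, y=y
    )


# ---------------------------------------------------------------------------
# changepoint detection


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single split of ``x`` into two constant segments.

    Returns (index of first element of the right segment, SSE gain).
    Vectorized over all admissible splits.
    """
    m = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_sse = csq[-1] - csum[-1] ** 2 / m
    k = np.arange(1, m)
    left = csq[k - 1] - csum[k - 1] ** 2 / k
    rs = csum[-1] - csum[k - 1]
    rq = csq[-1] - csq[k - 1]
    right = rq - rs**2 / (m - k)
    gain = total_sse - (left + right)
    i = int(np.argmax(gain))
    return int(k[i]), float(gain[i])


def _noise_var(x: np.ndarray) -> float:
    """Robust noise variance from scaled median absolute first differences."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float((1.4826 * mad) ** 2 / 2.0) or float(np.var(d) / 2.0)


def detect_steps(
    trace: IntensityTrace | np.ndarray,
    penalty: float = 10.0,
    min_segment: int = 2,
) -> list[tuple[int, float]]:
    """Changepoints of a piecewise-constant trace by binary segmentation.

    A split is accepted while its residual-sum-of-squares gain exceeds
    ``penalty * sigma^2 * log(n)`` (an information-criterion style cost,
    with sigma^2 the robust noise variance of the whole trace).  Only
    downward steps (mean drop across the changepoint) are returned,
    ordered by frame; each entry is ``(first frame after the step,
    step size < 0)``.
    """
    x = trace.values if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    n = x.size
    sigma2 = _noise_var(x)
    if sigma2 <= 0:
        # noiseless trace: every level change is a changepoint
        idx = np.nonzero(np.diff(x) != 0)[0] + 1
        cps = [int(i) for i in idx]
    else:
        thresh = penalty * sigma2 * np.log(n)
        cps = []
        stack = [(0, n)]
        while stack:
            lo, hi = stack.pop()
            if hi - lo < 2 * min_segment:
                continue
            seg = x[lo:hi]
            k, gain = _best_split(seg)
            if k < min_segment or (hi - lo) - k < min_segment:
                # best split too close to the edge; try none
                continue
            if gain > thresh:
                cps.append(lo + k)
                stack.append((lo, lo + k))
                stack.append((lo + k, hi))
        cps.sort()
    steps = []
    bounds = [0] + cps + [n]
    for j in range(1, len(bounds) - 1):
        a = x[bounds[j - 1] : bounds[j]].mean()
        b = x[bounds[j] : bounds[j + 1]].mean()
        if b < a:
            steps.append((bounds[j], float(b - a)))
    return steps


def single_fluorophore_distribution(
    traces: list[IntensityTrace],
    penalty: float = 10.0,
    plateau_cv_max: float = 0.5,
    background_tol_sd: float = 2.0,
) -> CalibrationResult:
    """Single-fluorophore intensity from one-step photobleaching traces.

    A trace is classified single-molecule when it has exactly one downward
    step, the post-step mean is within ``background_tol_sd`` noise
    standard deviations of zero (the trace is background-subtracted), and
    the pre-step plateau coefficient of variation is below
    ``plateau_cv_max``.  The per-molecule sample is the pre-step plateau
    mean.
    """
    if not traces:
        raise ValueError("need at least one trace")
    samples = []
    for tr in traces:
        x = tr.values
        steps = detect_steps(tr, penalty=penalty)
        if len(steps) != 1:
            continue
        k, _size = steps[0]
        pre = x[:k]
        post = x[k:]
        sd = np.sqrt(_noise_var(x))
        # post-step level must be consistent with background (0) to within
        # background_tol_sd per-frame noise SDs, else the molecule did not
        # bleach to dark (multi-emitter or truncated blink)
        if sd > 0 and abs(post.mean()) > background_tol_sd * sd:
            continue
        mu = pre.mean()
        if mu <= 0:
            continue
        if sd > 0 and pre.std() / mu > plateau_cv_max:
            continue
        samples.append(mu)
    if not samples:
        raise ValueError(
            "no trace classified as single-molecule; review the step-detection "
            "penalty and plateau CV cutoff"
        )
    s = np.asarray(samples)
    return CalibrationResult(
        single_intensity_samples=s,
        mean_single_intensity=float(s.mean()),
        cv=float(s.std() / s.mean()) if s.mean() > 0 else 0.0,
        n_molecules=len(s),
    )


def estimate_labeling_density(
    spot_amplitudes: np.ndarray,
    calib: CalibrationResult,
    n_bins: int = 30,
) -> LabelingDensityEstimate:
    """Fluorophores per transcript: spot intensity over single-fluorophore
    intensity, with a histogram for plotting."""
    amps = np.asarray(spot_amplitudes, dtype=float)
    if amps.size == 0:
        raise ValueError("no spot amplitudes given")
    if not calib.mean_single_intensity > 0:
        raise ValueError("calibration mean single intensity must be > 0")
    per_n = amps / calib.mean_single_intensity
    hist, edges = np.histogram(per_n, bins=n_bins)
    return LabelingDensityEstimate(
        per_spot_n=per_n,
        mean_n=float(per_n.mean()),
        bin_edges=edges,
        histogram=hist,
    )
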