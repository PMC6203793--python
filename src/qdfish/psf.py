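"""Gaussian point-spread-function model and spot rendering.

The microscope's image of a point emitter is modeled as a symmetric 2D
Gaussian of standard deviation ``sigma_px`` pixels, evaluated at pixel
centers (not integrated over pixel area) and normalized so the kernel
summed over the full, untruncated pixel lattice has unit mass.  With this
convention a spot's fitted amplitude equals its total photon count, and
the simulator and the detector share one consistent sampling rule.

Coordinates are 0-based with the pixel center at integer coordinates;
all sub-pixel positions use this frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PSFModel", "gaussian_kernel", "kernel_norm_1d", "render_spot", "render_field"]


@dataclass(frozen=True)
class PSFModel:
    """Gaussian PSF width plus the square analysis-window geometry.

    Parameters
    ----------
    sigma_px
        Standard deviation of the Gaussian PSF in pixels. Must be > 0.
        Set from wavelength/NA or from bead measurements.
    window_half
        Half-width of the square analysis window; the window spans
        ``2 * window_half + 1`` pixels per side (default 3 -> 7x7).
    """

    sigma_px: float = 1.2
    window_half: int = 3

    def __post_init__(self) -> None:
        if not self.sigma_px > 0:
            raise ValueError(f"sigma_px must be > 0, got {self.sigma_px}")
        if self.window_half < 1:
            raise ValueError(f"window_half must be >= 1, got {self.window_half}")

    @property
    def window_size(self) -> int:
        return 2 * self.window_half + 1

    @property
    def n_pixels(self) -> int:
        return self.window_size ** 2


def kernel_norm_1d(sigma: float, frac: float = 0.0) -> float:
    """Sum of exp(-(i - frac)^2 / 2 sigma^2) over the full integer lattice.

    Truncated at 8 sigma + 2 pixels where the omitted tail is below 1e-14
    of the total, i.e. numerically untruncated.
    """
    reach = int(np.ceil(8.0 * sigma)) + 2
    i = np.arange(-reach, reach + 1, dtype=float)
    return float(np.exp(-((i - frac) ** 2) / (2.0 * sigma ** 2)).sum())


def gaussian_kernel(
    sigma: float,
    half: int,
    dx: float = 0.0,
    dy: float = 0.0,
) -> np.ndarray:
    """Unit-mass Gaussian kernel sampled at pixel centers.

    Returns a ``(2*half+1, 2*half+1)`` patch of the PSF for a spot at
    offset ``(dx, dy)`` pixels from the patch center (dx along columns/x,
    dy along rows/y).  Normalization is by the full-lattice sum, so the
    returned (truncated) patch sums to slightly less than 1.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    ax = np.arange(-half, half + 1, dtype=float)
    gx = np.exp(-((ax - dx) ** 2) / (2.0 * sigma ** 2))
    gy = np.exp(-((ax - dy) ** 2) / (2.0 * sigma ** 2))
    norm = kernel_norm_1d(sigma, dx) * kernel_norm_1d(sigma, dy)
    return np.outer(gy, gx) / norm


def render_spot(
    psf: PSFModel,
    x: float,
    y: float,
    amplitude: float,
    half: int | None = None,
) -> np.ndarray:
    """Additive contribution of one spot to a patch centered on round(x), round(y).

    ``amplitude`` is the spot's total photon count (unit-mass kernel).  The
    rendered patch sums to at most ``amplitude`` because of truncation to
    the finite patch.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if half is None:
        half = psf.window_half
    cx, cy = round(x), round(y)
    return amplitude * gaussian_kernel(psf.sigma_px, half, x - cx, y - cy)


def render_field(
    shape: tuple[int, int],
    psf: PSFModel,
    xs: np.ndarray,
    ys: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Render many spots into a full image (photons, no noise).

    Each spot is rendered over a support of ``ceil(7 sigma) + 1`` pixels so
    the mass omitted outside its patch is below 1e-10 of the amplitude;
    patches are clipped at image edges.
    """
    img = np.zeros(shape, dtype=float)
    h, w = shape
    half = int(np.ceil(7.0 * psf.sigma_px)) + 1
    for x, y, a in zip(np.asarray(xs, float), np.asarray(ys, float), np.asarray(amplitudes, float)):
        cx, cy = round(x), round(y)
        patch = render_spot(psf, x, y, a, half=half)
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        pr0 = max(0, -r0)
        pc0 = max(0, -c0)
        pr1 = patch.shape[0] - max(0, r1 - h)
        pc1 = patch.shape[1] - max(0, c1 - w)
        if pr1 <= pr0 or pc1 <= pc0:
            continue
        img[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] += patch[pr0:pr1, pc0:pc1]
    return img
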