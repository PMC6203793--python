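"""GLRT spot detection in sliding 7x7 windows with serial depletion.

Each fully interior window of the image is tested for a diffraction-limited
spot with a generalized likelihood ratio test (GLRT) comparing

* H0: pixels = b + eps              (local background only)
* H1: pixels = a * g + b + eps      (spot of amplitude a on local background)

with eps i.i.d. Gaussian of unknown variance and g the unit-mass Gaussian
PSF kernel sampled at pixel centers.  Both hypotheses are fitted by least
squares in closed form and the statistic is

    T = N * ln(SS0 / SS1),   N = window pixel count (49),

clamped to 0 when the fitted amplitude is negative (dark dips are not
spots) or when the window is constant.  Because the background is fitted
per window, detection responds to local contrast rather than global
intensity, which tolerates spatially nonuniform autofluorescence.

Detection stringency is expressed as a false-positive probability per
512x512 image on a decibel scale, threshold_db = -10*log10(P_img), divided
Bonferroni-style across the interior windows to a per-window error rate,
and mapped to a cutoff on T.  Under the Gaussian null the statistic is a
monotone function of an exact F(1, N-2) variable, so the default mapping
(``exact``) uses the one-sided Student-t(N-2) quantile; chi-square(1)
asymptotics and Monte-Carlo calibration are also available.

After each pass, fitted spots are subtracted from a working image and
detection repeats on the residual ("serial depletion"), which recovers
spots at high spatial density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import correlate, maximum_filter, uniform_filter

from .frames import ImageFrame, ImageStack
from .psf import PSFModel, gaussian_kernel, kernel_norm_1d

__all__ = [
    "DetectionConfig",
    "SpotRecord",
    "glrt_statistic",
    "glrt_map",
    "threshold_db_to_per_window_p",
    "calibrate_statistic_threshold",
    "detect_candidates",
    "fit_spot",
    "detect_frame",
    "detect_frame_thresholds",
    "count_per_cell",
    "detect_stack_3d",
    "Spot3D",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters.

    ``threshold_db`` is -10*log10 of the tolerated false-positive
    probability per image (e.g. 30 dB -> 1e-3 false spots per image).
    ``calibration_mode`` is ``exact`` (finite-sample Student-t, default),
    ``asymptotic`` (chi-square(1)), or ``monte_carlo``.
    """

    threshold_db: float = 30.0
    # per-window false-alarm probability of the provisional candidate gate
    # (matched-filter z against a locally robust noise scale); deliberately
    # lax so the gate censors a negligible fraction of the final GLRT tail
    candidate_gate_p: float = 1e-4
    max_depletion_rounds: int = 10
    # cyclic re-fit passes over all provisional spots (each re-fitted on the
    # image with its current neighbor models removed) before final scoring;
    # sharpens positions/amplitudes in crowded clusters
    refine_passes: int = 2
    # a spot with >= 2 provisional neighbors within ghost_radius_px is
    # tested for redundancy: remove it, refit the neighbors, and keep the
    # removal if the local residual sum of squares grows by less than
    # ghost_penalty * local noise variance.  Catches the spurious midpoint
    # detection seeded by the merged maximum of an unresolved pair.
    ghost_radius_px: float = 3.5
    ghost_penalty: float = 25.0
    max_spots: int = 10000
    calibration_mode: str = "exact"
    link_radius_px: float | None = None  # default 2 * sigma_px, see detect_stack_3d
    min_amplitude: float = 0.0
    # two accepted spots may not be closer than this; ~the resolution limit.
    # Below it, a second detection is indistinguishable from the subtraction
    # residual of the first (imperfect deflation under shot noise).
    min_separation_px: float = 2.0
    n_mc: int = 200_000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold_db > 0:
            raise ValueError("threshold_db must be > 0")
        if self.max_depletion_rounds < 1:
            raise ValueError("max_depletion_rounds must be >= 1")
        if self.calibration_mode not in ("exact", "asymptotic", "monte_carlo"):
            raise ValueError(f"unknown calibration_mode {self.calibration_mode!r}")
        if self.link_radius_px is not None and self.link_radius_px < 0:
            raise ValueError("link_radius_px must be >= 0")


@dataclass
class SpotRecord:
    """One accepted spot."""

    x_sub: float
    y_sub: float
    amplitude: float
    background: float
    glrt_score: float
    score_db: float
    depletion_round: int
    residual_var: float
    z_index: int | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# the statistic


def _window_stats(window: np.ndarray, g: np.ndarray):
    n = window.size
    y = window.astype(float).ravel()
    gr = g.ravel()
    gbar = gr.mean()
    sgg = float(((gr - gbar) ** 2).sum())
    ybar = y.mean()
    ss0 = float(((y - ybar) ** 2).sum())
    num = float((gr * y).sum() - gbar * y.sum())
    a = num / sgg
    b = ybar - a * gbar
    ss1 = ss0 - num * num / sgg
    return n, a, b, ss0, ss1


def glrt_statistic(window: np.ndarray, psf: PSFModel) -> float:
    """GLRT statistic T = N ln(SS0/SS1) for one analysis window.

    One-sided: a negative fitted amplitude returns 0.  A constant window
    (no variance, hence no spot evidence) returns 0 by convention.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (psf.window_size, psf.window_size):
        raise ValueError(
            f"window shape {window.shape} does not match PSF window "
            f"({psf.window_size}x{psf.window_size})"
        )
    g = gaussian_kernel(psf.sigma_px, psf.window_half)
    n, a, _, ss0, ss1 = _window_stats(window, g)
    if ss0 <= 0 or a <= 0 or ss1 <= 0:
        return 0.0
    return float(n * np.log(ss0 / ss1))


def _glrt_maps(frame: np.ndarray, psf: PSFModel):
    """Window-wise sums for the GLRT over all interior centers.

    Returns ``(t, num, ss1, sgg)`` where ``num`` is the centered kernel
    correlation (numerator of the amplitude estimate times ``sgg``) and
    ``ss1`` the H1 residual sum of squares.  Border rows/columns whose
    windows are not fully interior are zeroed.
    """
    y = np.asarray(frame, dtype=float)
    k = psf.window_size
    h = psf.window_half
    if y.shape[0] < k or y.shape[1] < k:
        raise ValueError("frame smaller than the analysis window")
    y = y - y.mean()  # conditioning only; T is shift-invariant
    g = gaussian_kernel(psf.sigma_px, h)
    n = g.size
    gbar = g.sum() / n
    sgg = float(((g - gbar) ** 2).sum())
    s1 = uniform_filter(y, k, mode="constant") * n
    s2 = uniform_filter(y * y, k, mode="constant") * n
    c = correlate(y, g, mode="constant")
    num = c - gbar * s1
    ss0 = s2 - s1 * s1 / n
    ss1 = ss0 - num * num / sgg
    eps = 1e-9 * max(float(s2.max()), 1.0)
    ok = (num > 0) & (ss1 > eps) & (ss0 > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = n * np.log(ss0 / ss1)
    t = np.where(ok, t, 0.0)
    for arr in (t, num, ss1):
        arr[:h, :] = 0.0
        arr[-h:, :] = 0.0
        arr[:, :h] = 0.0
        arr[:, -h:] = 0.0
    return t, num, ss1, sgg


def glrt_map(frame: np.ndarray, psf: PSFModel) -> np.ndarray:
    """T at every pixel whose window is fully interior; 0 elsewhere.

    Vectorized over the image with separable box sums and one correlation
    with the PSF kernel; identical to applying :func:`glrt_statistic` at
    each interior center.
    """
    return _glrt_maps(frame, psf)[0]


# ---------------------------------------------------------------------------
# threshold calibration


def threshold_db_to_per_window_p(
    threshold_db: float,
    image_size: tuple[int, int] = (512, 512),
    window_half: int = 3,
) -> float:
    """Per-window false-alarm probability from a per-image dB threshold.

    ``P_img = 10**(-threshold_db/10)`` is shared Bonferroni-style across
    the ``(H - 2*half) * (W - 2*half)`` fully interior windows (506^2 =
    256,036 for a 512x512 image and 7x7 window).
    """
    if not threshold_db > 0:
        raise ValueError("threshold_db must be > 0")
    h, w = image_size
    k = 2 * window_half + 1
    if h < k or w < k:
        raise ValueError("analysis window larger than image")
    n_windows = (h - 2 * window_half) * (w - 2 * window_half)
    p_img = 10.0 ** (-threshold_db / 10.0)
    return p_img / n_windows


def _simulate_null_t(psf: PSFModel, n_mc: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    g = gaussian_kernel(psf.sigma_px, psf.window_half)
    n = g.size
    gr = g.ravel()
    gbar = gr.mean()
    sgg = float(((gr - gbar) ** 2).sum())
    out = np.empty(n_mc)
    done = 0
    chunk = 200_000
    while done < n_mc:
        m = min(chunk, n_mc - done)
        y = rng.normal(size=(m, n))
        s1 = y.sum(axis=1)
        ss0 = (y * y).sum(axis=1) - s1 * s1 / n
        num = y @ gr - gbar * s1
        ss1 = ss0 - num * num / sgg
        t = np.where(num > 0, n * np.log(ss0 / ss1), 0.0)
        out[done : done + m] = t
        done += m
    return out


def calibrate_statistic_threshold(
    psf: PSFModel,
    per_window_p: float,
    mode: str = "exact",
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Cutoff on T with per-window false-alarm probability ``per_window_p``.

    ``exact``      one-sided finite-sample mapping: under the Gaussian null
                   the amplitude t-statistic is Student-t(N-2) and
                   T = N*ln(1 + t^2/(N-2)), so the cutoff is exact at any p.
    ``asymptotic`` chi-square(1) quantile at 1-p (one extra linear
                   parameter); conservative by up to 2x versus the
                   one-sided finite-sample law, and inexact in the far
                   tail for N = 49.
    ``monte_carlo`` empirical (1-p) quantile of T over ``n_mc`` simulated
                   pure-noise windows; requires n_mc >= 100/p.
    """
    if not 0 < per_window_p < 1:
        raise ValueError("per_window_p must be in (0, 1)")
    n = psf.n_pixels
    if mode == "exact":
        tq = stats.t.isf(per_window_p, n - 2)
        return float(n * np.log1p(tq * tq / (n - 2)))
    if mode == "asymptotic":
        return float(stats.chi2.isf(per_window_p, 1))
    if mode == "monte_carlo":
        if n_mc < 100.0 / per_window_p:
            raise ValueError(
                f"monte_carlo calibration at p={per_window_p:g} needs n_mc >= "
                f"{100.0 / per_window_p:.0f} noise windows, got {n_mc}"
            )
        t = _simulate_null_t(psf, n_mc, seed)
        return float(np.quantile(t, 1.0 - per_window_p))
    raise ValueError(f"unknown calibration mode {mode!r}")


# ---------------------------------------------------------------------------
# candidates and fitting


def detect_candidates(
    frame: np.ndarray, psf: PSFModel, cutoff: float
) -> list[tuple[int, int]]:
    """Integer centers that are strict local maxima of the T map with
    T >= cutoff, ordered by decreasing T."""
    t = glrt_map(frame, psf)
    mx = maximum_filter(t, size=3, mode="constant")
    cand = (t >= cutoff) & (t == mx) & (t > 0)
    ys, xs = np.nonzero(cand)
    order = np.argsort(-t[ys, xs], kind="stable")
    return [(int(ys[i]), int(xs[i])) for i in order]


def _robust_noise_var_map(
    ss1: np.ndarray, df: int, tile: int = 32
) -> np.ndarray:
    """Locally robust noise variance: median of the per-window residual
    variance over coarse tiles, bilinearly interpolated back to full
    resolution.  The median is insensitive to the minority of windows
    containing spots; tiling keeps it O(N)."""
    h, w = ss1.shape
    ny, nx = max(h // tile, 1), max(w // tile, 1)
    coarse = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            blk = ss1[
                i * tile : (i + 1) * tile if i < ny - 1 else h,
                j * tile : (j + 1) * tile if j < nx - 1 else w,
            ]
            vals = blk[blk > 0]
            coarse[i, j] = np.median(vals) if vals.size else 0.0
    # fill empty tiles with the global median so borders stay finite
    if np.any(coarse == 0):
        nz = coarse[coarse > 0]
        coarse[coarse == 0] = np.median(nz) if nz.size else 1.0
    yy = np.linspace(0, ny - 1, h)
    xx = np.linspace(0, nx - 1, w)
    rows = np.empty((ny, w))
    for i in range(ny):
        rows[i] = np.interp(xx, np.arange(nx), coarse[i])
    out = np.empty((h, w))
    for j in range(w):
        out[:, j] = np.interp(yy, np.arange(ny), rows[:, j])
    # median of chi2(df)/df under the null; removes small-sample bias
    return np.clip(out, 1e-12, None) / df / (stats.chi2.median(df) / df)


def _provisional_candidates(
    frame: np.ndarray,
    psf: PSFModel,
    config: DetectionConfig,
    var_map: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Candidate centers for the depletion stage.

    Local maxima of the matched-filter amplitude map scored against a
    locally robust noise scale (tiled median of the per-window residual
    variance), which is insensitive to the minority of windows containing
    spots — unlike the raw GLRT, whose local variance estimate is inflated
    by bright neighbors and can hide every member of a tight cluster.  The
    gate is deliberately lax (``candidate_gate_p``); final acceptance is
    by the true local GLRT after depletion.
    """
    t, num, ss1, sgg = _glrt_maps(frame, psf)
    df = psf.n_pixels - 2
    if var_map is None:
        var_map = _robust_noise_var_map(ss1, df)
    z = num / np.sqrt(sgg * var_map)
    z_gate = stats.norm.isf(config.candidate_gate_p)
    mx = maximum_filter(num, size=3, mode="constant")
    cand = (z >= z_gate) & (num == mx) & (num > 0)
    ys, xs = np.nonzero(cand)
    order = np.argsort(-z[ys, xs], kind="stable")
    return [(int(ys[i]), int(xs[i])) for i in order], var_map


def _linear_fit(window: np.ndarray, psf: PSFModel):
    """Closed-form (amplitude, background) fit at fixed center position."""
    g = gaussian_kernel(psf.sigma_px, psf.window_half)
    n, a, b, ss0, ss1 = _window_stats(window, g)
    return a, b, ss1 / max(n - 2, 1)


def fit_spot(
    frame: np.ndarray,
    center: tuple[int, int],
    psf: PSFModel,
    depletion_round: int = 0,
) -> SpotRecord:
    """Sub-pixel Gaussian fit of one spot in the window around ``center``.

    Nonlinear least squares over (x, y, amplitude, background) with the
    PSF width held fixed; the position is constrained within +-1 px of the
    candidate center.  Since the model is linear in (amplitude,
    background), those are solved in closed form at each position
    (variable projection) and a damped Gauss-Newton iteration runs over
    the two position offsets only.  On non-convergence, falls back to the
    integer center with a closed-form linear fit and flags the record.
    """
    frame = np.asarray(frame, dtype=float)
    cy, cx = center
    h = psf.window_half
    if not (h <= cy < frame.shape[0] - h and h <= cx < frame.shape[1] - h):
        raise ValueError(f"center {center} not fully interior for window half {h}")
    window = frame[cy - h : cy + h + 1, cx - h : cx + h + 1]
    n = window.size
    yv = window.ravel()
    sy = yv.sum()
    sigma = psf.sigma_px
    ax = np.arange(-h, h + 1, dtype=float)

    def solve_ab(dx, dy):
        """Kernel at offset (dx, dy) and the optimal (a, b, SS) there."""
        gx = np.exp(-((ax - dx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ax - dy) ** 2) / (2 * sigma**2))
        norm = kernel_norm_1d(sigma, dx) * kernel_norm_1d(sigma, dy)
        ker = np.outer(gy, gx) / norm
        kv = ker.ravel()
        k1 = kv.sum()
        kk = float(kv @ kv)
        sky = float(kv @ yv)
        den = n * kk - k1 * k1
        a = (n * sky - k1 * sy) / den
        b = (sy - a * k1) / n
        r = a * kv + b - yv
        return kv, gx, gy, norm, a, b, r, float(r @ r)

    dx = dy = 0.0
    kv, gx, gy, norm, amp, bkg, r, ss = solve_ab(dx, dy)
    lam = 1e-3
    converged = False
    for _ in range(50):
        # Kaufman variable-projection Jacobian: a * dk/d(dx,dy)
        jx = (amp * np.outer(gy, gx * (ax - dx) / sigma**2) / norm).ravel()
        jy = (amp * np.outer(gy * (ax - dy) / sigma**2, gx) / norm).ravel()
        g0 = np.array([jx @ r, jy @ r])
        jtj = np.array([[jx @ jx, jx @ jy], [jx @ jy, jy @ jy]])
        if not np.all(np.isfinite(jtj)):
            break
        step_ok = False
        for _damp in range(8):
            try:
                delta = np.linalg.solve(jtj + lam * np.eye(2) * max(jtj.max(), 1e-12), -g0)
            except np.linalg.LinAlgError:
                break
            ndx = min(max(dx + delta[0], -1.0), 1.0)
            ndy = min(max(dy + delta[1], -1.0), 1.0)
            trial = solve_ab(ndx, ndy)
            if trial[-1] <= ss:
                moved = max(abs(ndx - dx), abs(ndy - dy))
                dx, dy = ndx, ndy
                kv, gx, gy, norm, amp, bkg, r, ss = trial
                lam = max(lam * 0.3, 1e-10)
                step_ok = True
                if moved < 1e-9 or ss <= 1e-24 * max(sy * sy, 1.0):
                    converged = True
                break
            lam *= 10.0
        if converged or not step_ok:
            converged = converged or step_ok or ss < np.finfo(float).eps
            break
    else:
        converged = True  # iteration budget reached with monotone SS: accept
    if amp < 0 or not np.isfinite(amp):
        converged = False
    if not converged:
        amp, bkg, _rv = _linear_fit(window, psf)
        amp = max(amp, 0.0)
        dx = dy = 0.0
        r = None
    if r is not None:
        resid_var = float(ss / max(n - 4, 1))
    else:
        resid_var = _rv

    score = glrt_statistic(window, psf)
    p_win = stats.t.sf(np.sqrt(max(np.expm1(score / n) * (n - 2), 0.0)), n - 2)
    return SpotRecord(
        x_sub=float(cx + dx),
        y_sub=float(cy + dy),
        amplitude=float(amp),
        background=float(bkg),
        glrt_score=float(score),
        score_db=float(_score_to_db(p_win)),
        depletion_round=depletion_round,
        residual_var=resid_var,
        converged=converged,
    )


def _score_to_db(p_win: float, image_size=(512, 512), window_half: int = 3) -> float:
    """Express a per-window p-value as the per-image dB threshold at which
    the spot would be exactly at the acceptance boundary."""
    h, w = image_size
    n_windows = (h - 2 * window_half) * (w - 2 * window_half)
    p_img = min(p_win * n_windows, 1.0)
    if p_img <= 0:
        return float("inf")
    return -10.0 * np.log10(p_img)


# ---------------------------------------------------------------------------
# frame-level detection with serial depletion


def _subtract_spot(work: np.ndarray, rec: SpotRecord, psf: PSFModel) -> None:
    half = int(np.ceil(7.0 * psf.sigma_px)) + 1
    cx, cy = round(rec.x_sub), round(rec.y_sub)
    gk = rec.amplitude * gaussian_kernel(
        psf.sigma_px, half, rec.x_sub - cx, rec.y_sub - cy
    )
    hgt, wid = work.shape
    r0, r1 = cy - half, cy + half + 1
    c0, c1 = cx - half, cx + half + 1
    pr0, pc0 = max(0, -r0), max(0, -c0)
    pr1 = gk.shape[0] - max(0, r1 - hgt)
    pc1 = gk.shape[1] - max(0, c1 - wid)
    if pr1 <= pr0 or pc1 <= pc0:
        return
    work[max(r0, 0):min(r1, hgt), max(c0, 0):min(c1, wid)] -= gk[pr0:pr1, pc0:pc1]


def _add_spot(work: np.ndarray, rec: SpotRecord, psf: PSFModel) -> None:
    neg = SpotRecord(**{**rec.__dict__, "amplitude": -rec.amplitude})
    _subtract_spot(work, neg, psf)


def _rescore_window(work: np.ndarray, rec: SpotRecord, psf: PSFModel) -> float:
    """GLRT score of one spot on the depleted image with the spot's own
    model added back, i.e. with its neighbors removed."""
    h = psf.window_half
    cy, cx = round(rec.y_sub), round(rec.x_sub)
    cy = min(max(cy, h), work.shape[0] - h - 1)
    cx = min(max(cx, h), work.shape[1] - h - 1)
    window = work[cy - h : cy + h + 1, cx - h : cx + h + 1].copy()
    window += rec.amplitude * gaussian_kernel(
        psf.sigma_px, h, rec.x_sub - cx, rec.y_sub - cy
    )
    return glrt_statistic(window, psf)


def detect_frame(
    frame: ImageFrame | np.ndarray,
    psf: PSFModel,
    config: DetectionConfig,
    cutoff: float | None = None,
) -> list[SpotRecord]:
    """Detect all spots in one frame by GLRT + fit + serial depletion.

    Provisional candidates are gathered with the lax matched-filter gate
    (see ``candidate_gate_p``), fitted brightest-first (ties broken by
    row-major position), and subtracted from a working copy; detection
    re-runs on the residual until no new candidate appears or
    ``max_depletion_rounds`` is reached.  Depleting provisional neighbors
    first decontaminates the 7x7 windows of crowded spots, which a single
    pass at the final threshold would miss.

    Each provisional spot is then re-scored on the depleted image with its
    own model added back (its neighbors removed) and accepted only if the
    re-scored statistic passes the final ``threshold_db`` cutoff; rejected
    spots are re-added to the residual and the remaining spots re-scored
    until the accepted set is stable.  For an isolated candidate the
    re-scored window equals the original image window, so the
    false-positive calibration of the final threshold is unchanged.
    Accepted spots are deduplicated at ``config.min_separation_px``.
    """
    pixels = frame.pixels if isinstance(frame, ImageFrame) else frame
    pixels = np.asarray(pixels, dtype=float)
    if cutoff is None:
        p_final = threshold_db_to_per_window_p(
            config.threshold_db, pixels.shape, psf.window_half
        )
        cutoff = calibrate_statistic_threshold(
            psf, p_final, mode=config.calibration_mode, n_mc=config.n_mc,
            seed=config.mc_seed,
        )
    work, provisional, truncated = _provisional_stage(pixels, psf, config)
    active = _final_acceptance(work, provisional, psf, config, cutoff, pixels.shape)
    if truncated:
        import warnings

        warnings.warn(
            f"max_spots={config.max_spots} reached; detection truncated", stacklevel=2
        )
    return active


def _provisional_stage(
    pixels: np.ndarray, psf: PSFModel, config: DetectionConfig
) -> tuple[np.ndarray, list[SpotRecord], bool]:
    """Candidate gathering, depletion, and cyclic refinement (threshold-
    independent).  Returns the depleted working image, the provisional
    spot list, and a truncation flag."""
    work = pixels.copy()
    provisional: list[SpotRecord] = []
    truncated = False
    sep2 = config.min_separation_px**2
    var_map = None
    for rnd in range(config.max_depletion_rounds):
        cands, var_map = _provisional_candidates(work, psf, config, var_map)
        new_this_round = 0
        for cy, cx in cands:
            if any(
                (cx - r.x_sub) ** 2 + (cy - r.y_sub) ** 2 < sep2 for r in provisional
            ):
                continue
            rec = fit_spot(work, (cy, cx), psf, depletion_round=rnd)
            if rec.amplitude <= 0:
                continue
            if any(
                (rec.x_sub - r.x_sub) ** 2 + (rec.y_sub - r.y_sub) ** 2 < sep2
                for r in provisional
            ):
                continue
            _subtract_spot(work, rec, psf)
            provisional.append(rec)
            new_this_round += 1
            if len(provisional) >= config.max_spots:
                truncated = True
                break
        if truncated or new_this_round == 0:
            break

    # cyclic refinement: re-fit each spot on the neighbor-depleted image
    h = psf.window_half
    for _ in range(config.refine_passes):
        for rec in sorted(provisional, key=lambda r: -r.amplitude):
            _add_spot(work, rec, psf)
            cy = min(max(round(rec.y_sub), h), work.shape[0] - h - 1)
            cx = min(max(round(rec.x_sub), h), work.shape[1] - h - 1)
            new = fit_spot(work, (cy, cx), psf, depletion_round=rec.depletion_round)
            if new.amplitude > 0:
                rec.x_sub, rec.y_sub = new.x_sub, new.y_sub
                rec.amplitude, rec.background = new.amplitude, new.background
                rec.residual_var = new.residual_var
                rec.converged = new.converged
            _subtract_spot(work, rec, psf)

    _prune_ghosts(work, provisional, psf, config)
    return work, provisional, truncated


def _prune_ghosts(
    work: np.ndarray,
    provisional: list[SpotRecord],
    psf: PSFModel,
    config: DetectionConfig,
) -> None:
    """Remove redundant mid-cluster spots by local model comparison.

    An unresolved pair seeds its first candidate at the merged maximum
    between the true spots; depletion then finds the two outer lobes,
    leaving a three-spot representation of a two-spot cluster.  For each
    spot with at least two provisional neighbors within
    ``ghost_radius_px``, the spot's model is removed and the neighbors are
    refitted; if the local residual sum of squares increases by less than
    ``ghost_penalty`` times the local noise variance, the spot is dropped
    (its flux is absorbed by the neighbors), otherwise everything is
    restored.  A genuine middle spot leaves its flux unexplained on
    removal, so it survives the test.
    """
    if len(provisional) < 3:
        return
    r2 = config.ghost_radius_px**2
    h = psf.window_half
    render_half = int(np.ceil(7.0 * psf.sigma_px)) + 1
    reg_half = render_half + int(np.ceil(config.ghost_radius_px)) + 2
    hgt, wid = work.shape
    for s in sorted(provisional, key=lambda r: -r.amplitude):
        if s not in provisional:
            continue
        nbrs = [
            t
            for t in provisional
            if t is not s
            and (t.x_sub - s.x_sub) ** 2 + (t.y_sub - s.y_sub) ** 2 <= r2
        ]
        if len(nbrs) < 2:
            continue
        cy, cx = round(s.y_sub), round(s.x_sub)
        r0, r1 = max(cy - reg_half, 0), min(cy + reg_half + 1, hgt)
        c0, c1 = max(cx - reg_half, 0), min(cx + reg_half + 1, wid)
        region = work[r0:r1, c0:c1]
        patch_backup = region.copy()
        nbr_backup = [
            (t.x_sub, t.y_sub, t.amplitude, t.background) for t in nbrs
        ]
        centered = region - region.mean()
        ss_with = float((centered**2).sum())
        sigma2 = np.median(centered**2) / 0.4549  # robust: med(chi2_1) = 0.4549
        _add_spot(work, s, psf)
        for _ in range(2):
            for t in sorted(nbrs, key=lambda r: -r.amplitude):
                _add_spot(work, t, psf)
                ncy = min(max(round(t.y_sub), h), hgt - h - 1)
                ncx = min(max(round(t.x_sub), h), wid - h - 1)
                new = fit_spot(work, (ncy, ncx), psf, t.depletion_round)
                if new.amplitude > 0:
                    t.x_sub, t.y_sub = new.x_sub, new.y_sub
                    t.amplitude, t.background = new.amplitude, new.background
                _subtract_spot(work, t, psf)
        region = work[r0:r1, c0:c1]
        centered = region - region.mean()
        ss_without = float((centered**2).sum())
        if ss_without - ss_with <= config.ghost_penalty * sigma2:
            provisional.remove(s)
        else:
            work[r0:r1, c0:c1] = patch_backup
            for t, (x, y, a, b) in zip(nbrs, nbr_backup):
                t.x_sub, t.y_sub, t.amplitude, t.background = x, y, a, b


def _final_acceptance(
    work: np.ndarray,
    provisional: list[SpotRecord],
    psf: PSFModel,
    config: DetectionConfig,
    cutoff: float,
    image_shape: tuple[int, int],
) -> list[SpotRecord]:
    """Re-score each provisional spot on the depleted image with its own
    model added back; drop spots below the cutoff (re-adding their flux)
    and iterate until stable.  Operates on copies, so the same provisional
    stage can be re-evaluated at several thresholds."""
    import copy

    work = work.copy()
    active = [copy.copy(r) for r in provisional]
    for _ in range(5):
        dropped = False
        for rec in sorted(active, key=lambda r: r.amplitude):
            score = _rescore_window(work, rec, psf)
            rec.glrt_score = score
            if score < cutoff or rec.amplitude < config.min_amplitude:
                active.remove(rec)
                _add_spot(work, rec, psf)
                dropped = True
        if not dropped:
            break

    n = psf.n_pixels
    for rec in active:
        t2 = max(np.expm1(rec.glrt_score / n) * (n - 2), 0.0)
        p_win = stats.t.sf(np.sqrt(t2), n - 2)
        rec.score_db = float(_score_to_db(p_win, image_shape, psf.window_half))
    active.sort(key=lambda r: (-r.amplitude, r.y_sub, r.x_sub))
    return active


def detect_frame_thresholds(
    frame: ImageFrame | np.ndarray,
    psf: PSFModel,
    config: DetectionConfig,
    thresholds_db: list[float],
) -> dict[float, list[SpotRecord]]:
    """Detection at several per-image thresholds on one frame.

    The candidate/depletion/refinement stage does not depend on the final
    threshold, so it runs once; only final acceptance is repeated per
    threshold.  Results are identical to calling :func:`detect_frame` with
    each threshold."""
    pixels = frame.pixels if isinstance(frame, ImageFrame) else frame
    pixels = np.asarray(pixels, dtype=float)
    work, provisional, _trunc = _provisional_stage(pixels, psf, config)
    out: dict[float, list[SpotRecord]] = {}
    for thr in thresholds_db:
        p = threshold_db_to_per_window_p(thr, pixels.shape, psf.window_half)
        cutoff = calibrate_statistic_threshold(
            psf, p, mode=config.calibration_mode, n_mc=config.n_mc, seed=config.mc_seed
        )
        out[thr] = _final_acceptance(work, provisional, psf, config, cutoff, pixels.shape)
    return out


def count_per_cell(spots: list[SpotRecord], cell_mask: np.ndarray | None) -> int:
    """Number of accepted spots whose fitted center lies inside the mask."""
    if cell_mask is None:
        return len(spots)
    mask = np.asarray(cell_mask).astype(bool)
    n = 0
    for s in spots:
        iy, ix = round(s.y_sub), round(s.x_sub)
        if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
            n += 1
    return n


# ---------------------------------------------------------------------------
# 3D counting by slice linking


@dataclass
class Spot3D:
    """One 3D spot: intensity-weighted centroid of linked per-slice spots."""

    x: float
    y: float
    z_index: float
    amplitude: float
    n_slices: int
    members: list[SpotRecord] = field(default_factory=list)


def detect_stack_3d(
    stack: ImageStack,
    psf: PSFModel,
    config: DetectionConfig,
) -> list[Spot3D]:
    """Per-slice 2D detection followed by single-linkage merging of spots
    in adjacent slices within ``link_radius_px`` in xy.

    Each linked cluster is one 3D spot located at the amplitude-weighted
    centroid of its per-slice detections.  Default link radius is
    ``2 * sigma_px``.
    """
    if stack.axis != "z":
        raise ValueError("detect_stack_3d requires a z-axis stack")
    link_r = config.link_radius_px
    if link_r is None:
        link_r = 2.0 * psf.sigma_px
    if link_r < 0:
        raise ValueError("link_radius_px must be >= 0")

    shape = stack.frames[0].shape
    p = threshold_db_to_per_window_p(config.threshold_db, shape, psf.window_half)
    cutoff = calibrate_statistic_threshold(
        psf, p, mode=config.calibration_mode, n_mc=config.n_mc, seed=config.mc_seed
    )
    per_slice: list[list[SpotRecord]] = []
    for k, fr in enumerate(stack.frames):
        recs = detect_frame(fr, psf, config, cutoff=cutoff)
        for r in recs:
            r.z_index = k
        per_slice.append(recs)

    # union-find over all detections; link consecutive slices
    flat = [r for sl in per_slice for r in sl]
    parent = list(range(len(flat)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    offsets = np.cumsum([0] + [len(sl) for sl in per_slice])
    for k in range(len(per_slice) - 1):
        for i, a in enumerate(per_slice[k]):
            for j, b in enumerate(per_slice[k + 1]):
                if (a.x_sub - b.x_sub) ** 2 + (a.y_sub - b.y_sub) ** 2 <= link_r**2:
                    union(offsets[k] + i, offsets[k + 1] + j)

    clusters: dict[int, list[SpotRecord]] = {}
    for i, r in enumerate(flat):
        clusters.setdefault(find(i), []).append(r)

    out = []
    for members in clusters.values():
        w = np.array([max(m.amplitude, 1e-12) for m in members])
        x = float(np.average([m.x_sub for m in members], weights=w))
        y = float(np.average([m.y_sub for m in members], weights=w))
        z = float(np.average([m.z_index for m in members], weights=w))
        out.append(
            Spot3D(
                x=x, y=y, z_index=z,
                amplitude=float(w.max()),
                n_slices=len({m.z_index for m in members}),
                members=sorted(members, key=lambda m: m.z_index),
            )
        )
    out.sort(key=lambda s: (s.z_index, s.y, s.x))
    return out
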