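"""GLRT statistic, threshold calibration, fitting, depletion, 3D linking."""

import numpy as np
import pytest
from scipy import stats

from qdfish.detection import (
    DetectionConfig,
    calibrate_statistic_threshold,
    count_per_cell,
    detect_candidates,
    detect_frame,
    detect_frame_thresholds,
    detect_stack_3d,
    fit_spot,
    glrt_map,
    glrt_statistic,
    threshold_db_to_per_window_p,
)
from qdfish.frames import ImageFrame, ImageStack
from qdfish.psf import PSFModel, gaussian_kernel, render_field, render_spot
from qdfish.simulate import CameraModel, apply_camera_noise



def grid_search_glrt(window: np.ndarray, psf: PSFModel) -> float:
    """Independent brute-force evaluation of the GLRT by iteratively
    refined grid search over the model parameters (no closed-form
    least-squares projections).

    H0: y = b; H1: y = a g + b.  Residual sums of squares are minimized
    by scanning a b-grid (H0) and an (a, b)-grid (H1) and zooming around
    the argmin; the statistic is N ln(SS0/SS1) with negative-amplitude
    maxima clamped to zero (one-sided convention).
    """
    y = window.astype(float).ravel()
    g = gaussian_kernel(psf.sigma_px, psf.window_half).ravel()
    n = y.size
    span = float(y.max() - y.min()) + 1.0

    lo, hi = y.min() - span, y.max() + span
    for _ in range(40):
        bs = np.linspace(lo, hi, 31)
        sse = ((y[None, :] - bs[:, None]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        lo, hi = bs[max(i - 1, 0)], bs[min(i + 1, 30)]
    ss0 = float(sse[i])

    amax = 3.0 * span / float(g.max())
    alo, ahi = -amax, amax
    blo, bhi = y.min() - span, y.max() + span
    for _ in range(40):
        As = np.linspace(alo, ahi, 31)
        Bs = np.linspace(blo, bhi, 31)
        resid = y[None, None, :] - As[:, None, None] * g[None, None, :] - Bs[None, :, None]
        sse2 = (resid**2).sum(axis=2)
        ia, ib = np.unravel_index(np.argmin(sse2), sse2.shape)
        alo, ahi = As[max(ia - 1, 0)], As[min(ia + 1, 30)]
        blo, bhi = Bs[max(ib - 1, 0)], Bs[min(ib + 1, 30)]
    a_best = float(As[ia])
    ss1 = float(sse2[ia, ib])
    if a_best <= 0 or ss1 <= 0 or ss0 <= 0:
        return 0.0
    return float(n * np.log(ss0 / ss1))


# ---------------------------------------------------------------------------
# the statistic


def test_constant_window_scores_zero(psf):
    assert glrt_statistic(np.full((7, 7), 13.0), psf) == 0.0


def test_dark_dip_scores_zero(psf):
    window = 100.0 - render_spot(psf, 3.0, 3.0, 500.0)
    assert glrt_statistic(window, psf) == 0.0


def test_affine_invariance(psf, rng):
    for _ in range(20):
        w = rng.normal(50, 8, (7, 7))
        t = glrt_statistic(w, psf)
        t2 = glrt_statistic(2.5 * w + 17.0, psf)
        assert t2 == pytest.approx(t, rel=1e-9, abs=1e-9)


def test_statistic_matches_grid_search_oracle(psf, rng):
    """Closed-form T equals brute-force likelihood maximization on a grid
    for windows containing a noisy spot."""
    for i in range(5):
        w = render_spot(psf, 3.0, 3.0, 100.0) + 10.0 + rng.normal(0, 5, (7, 7))
        t = glrt_statistic(w, psf)
        t_oracle = grid_search_glrt(w, psf)
        assert t == pytest.approx(t_oracle, rel=1e-6)


def test_glrt_map_agrees_with_per_window_statistic(psf, rng):
    frame = rng.normal(100, 6, (24, 24))
    frame[10:17, 5:12] += render_spot(psf, 3.0, 3.0, 400.0)
    tmap = glrt_map(frame, psf)
    for cy, cx in [(13, 8), (7, 7), (12, 16)]:
        w = frame[cy - 3 : cy + 4, cx - 3 : cx + 4]
        assert tmap[cy, cx] == pytest.approx(glrt_statistic(w, psf), rel=1e-8, abs=1e-8)


# ---------------------------------------------------------------------------
# threshold calibration


def test_window_count_512():
    """A 512x512 image holds 506^2 = 256,036 interior 7x7 windows."""
    p = threshold_db_to_per_window_p(30.0, (512, 512), 3)
    assert p == pytest.approx(1e-3 / 256036)


def test_db_is_log10_per_image_probability():
    p30 = threshold_db_to_per_window_p(30.0)
    p40 = threshold_db_to_per_window_p(40.0)
    assert p30 / p40 == pytest.approx(10.0)


def test_huge_threshold_gives_vanishing_p():
    assert threshold_db_to_per_window_p(200.0) < 1e-25


def test_window_larger_than_image_rejected():
    with pytest.raises(ValueError):
        threshold_db_to_per_window_p(30.0, (5, 5), 3)


def test_asymptotic_median_is_chi2_median(psf):
    cut = calibrate_statistic_threshold(psf, 0.5, mode="asymptotic")
    assert cut == pytest.approx(0.4549, abs=1e-3)


def test_cutoff_monotone_in_p(psf):
    for mode in ("exact", "asymptotic"):
        c_strict = calibrate_statistic_threshold(psf, 1e-4, mode=mode)
        c_lax = calibrate_statistic_threshold(psf, 1e-2, mode=mode)
        assert c_strict > c_lax


def test_monte_carlo_guard(psf):
    with pytest.raises(ValueError):
        calibrate_statistic_threshold(psf, 1e-5, mode="monte_carlo", n_mc=1000)


def test_exact_cutoff_agrees_with_monte_carlo(psf):
    """The finite-sample Student-t calibration reproduces the Monte-Carlo
    quantile at a reachable p; the empirical exceedance of the exact
    cutoff on fresh noise windows is inside the binomial 95% CI."""
    p = 1e-3
    cut_exact = calibrate_statistic_threshold(psf, p, mode="exact")
    cut_mc = calibrate_statistic_threshold(psf, p, mode="monte_carlo", n_mc=400_000, seed=1)
    assert cut_mc == pytest.approx(cut_exact, rel=0.05)
    from qdfish.detection import _simulate_null_t

    t = _simulate_null_t(psf, 200_000, seed=2)
    k = int((t >= cut_exact).sum())
    lo, hi = stats.binom.interval(0.95, 200_000, p)
    assert lo <= k <= hi


# ---------------------------------------------------------------------------
# candidates


def test_all_zero_frame_no_candidates(psf):
    assert detect_candidates(np.zeros((32, 32)), psf, 1.0) == []


def test_single_spot_single_candidate(psf, rng):
    frame = np.full((32, 32), 10.0)
    frame += render_field(frame.shape, psf, [15.2], [17.6], [500.0])
    frame += rng.normal(0, 0.05, frame.shape)  # tiny jitter breaks ties
    cands = detect_candidates(frame, psf, 20.0)
    assert len(cands) == 1
    cy, cx = cands[0]
    assert (cy, cx) == (18, 15)


def test_intensity_gradient_produces_no_candidates(psf, rng):
    """Local background fitting makes detection insensitive to global
    intensity gradients: a plane plus noise yields no candidates at a
    calibrated cutoff."""
    yy, xx = np.mgrid[0:64, 0:64]
    frame = 50.0 + 3.0 * xx + 1.5 * yy + rng.normal(0, 2.0, (64, 64))
    p = threshold_db_to_per_window_p(20.0, frame.shape, 3)
    cutoff = calibrate_statistic_threshold(psf, p)
    assert detect_candidates(frame, psf, cutoff) == []


def test_candidate_count_monotone_in_cutoff(psf, rng):
    frame = rng.normal(100, 5, (96, 96))
    frame += render_field(frame.shape, psf, [20, 40, 60], [30, 50, 70], [300, 400, 500])
    counts = [len(detect_candidates(frame, psf, c)) for c in (5.0, 10.0, 20.0, 40.0)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# fitting


def test_noiseless_fit_recovers_exactly(psf):
    frame = np.full((41, 41), 5.0)
    frame += render_field(frame.shape, psf, [10.3], [20.7], [200.0])
    rec = fit_spot(frame, (21, 10), psf)
    assert rec.converged
    assert abs(rec.x_sub - 10.3) < 0.02 and abs(rec.y_sub - 20.7) < 0.02
    assert rec.amplitude == pytest.approx(200.0, rel=1e-6)
    assert rec.background == pytest.approx(5.0, rel=1e-6)


def test_symmetric_spot_fits_at_pixel_center(psf):
    frame = np.full((31, 31), 8.0)
    frame += render_field(frame.shape, psf, [15.0], [15.0], [300.0])
    rec = fit_spot(frame, (15, 15), psf)
    assert rec.x_sub == pytest.approx(15.0, abs=1e-9)
    assert rec.y_sub == pytest.approx(15.0, abs=1e-9)


def test_noisy_localization_accuracy(psf, rng):
    """Mean localization error at SNR ~10 stays below 0.15 px."""
    gmax = gaussian_kernel(1.2, 3)[3, 3]
    sigma_noise = 5.0
    amp = 10 * sigma_noise / gmax
    errs = []
    for _ in range(120):
        x, y = 15 + rng.uniform(-0.4, 0.4), 15 + rng.uniform(-0.4, 0.4)
        frame = np.full((31, 31), 50.0)
        frame += render_field(frame.shape, psf, [x], [y], [amp])
        frame += rng.normal(0, sigma_noise, frame.shape)
        rec = fit_spot(frame, (round(y), round(x)), psf)
        errs.append(np.hypot(rec.x_sub - x, rec.y_sub - y))
    assert np.mean(errs) < 0.15


def test_fit_requires_interior_center(psf):
    with pytest.raises(ValueError):
        fit_spot(np.zeros((20, 20)), (1, 1), psf)


# ---------------------------------------------------------------------------
# frame detection with depletion


def test_noiseless_single_spot_detected_once(psf):
    frame = np.full((64, 64), 20.0)
    frame += render_field(frame.shape, psf, [30.4], [25.8], [800.0])
    recs = detect_frame(frame, psf, DetectionConfig(threshold_db=30))
    assert len(recs) == 1
    assert abs(recs[0].x_sub - 30.4) < 0.02 and abs(recs[0].y_sub - 25.8) < 0.02
    assert recs[0].amplitude == pytest.approx(800.0, rel=1e-6)
    assert recs[0].score_db >= 30.0


def test_close_pair_resolved_by_depletion(psf, rng):
    """Two spots 3 px apart at SNR 15 are both recovered with sub-half-
    pixel positions (a few replicates; the acceptance suite runs 200)."""
    cam = CameraModel(offset=100.0, read_noise_sd=3.0, gain=1.0)
    gmax = gaussian_kernel(1.2, 3)[3, 3]
    amp = 15 * np.sqrt(59.0) / gmax
    hit = 0
    for _ in range(20):
        x1, y1 = 18 + rng.uniform(-0.5, 0.5), 20 + rng.uniform(-0.5, 0.5)
        photons = np.full((40, 40), 50.0)
        photons += render_field((40, 40), psf, [x1, x1 + 3.0], [y1, y1], [amp, amp])
        frame = apply_camera_noise(photons, cam, rng)
        recs = detect_frame(frame, psf, DetectionConfig(threshold_db=30))
        d1 = min((r.x_sub - x1) ** 2 + (r.y_sub - y1) ** 2 for r in recs) if recs else 9
        d2 = (
            min((r.x_sub - x1 - 3) ** 2 + (r.y_sub - y1) ** 2 for r in recs)
            if recs
            else 9
        )
        if d1 < 1.0 and d2 < 1.0:
            hit += 1
    assert hit >= 17


def test_depletion_is_idempotent(psf, rng):
    """Subtracting every accepted spot leaves a residual in which a second
    run finds nothing."""
    from qdfish.detection import _subtract_spot

    photons = np.full((96, 96), 50.0)
    xs = [20.0, 40.3, 60.7, 30.2]
    ys = [25.0, 45.6, 20.1, 70.4]
    photons += render_field((96, 96), psf, xs, ys, [900.0] * 4)
    frame = apply_camera_noise(photons, CameraModel(), rng).astype(float)
    cfgd = DetectionConfig(threshold_db=30)
    recs = detect_frame(frame, psf, cfgd)
    assert len(recs) == 4
    residual = frame.copy()
    for r in recs:
        _subtract_spot(residual, r, psf)
    assert detect_frame(residual, psf, cfgd) == []


def test_multi_threshold_equals_single_threshold(psf, rng):
    photons = np.full((96, 96), 50.0)
    photons += render_field((96, 96), psf, [20, 50, 75], [30, 60, 20], [600, 250, 900])
    frame = apply_camera_noise(photons, CameraModel(), rng)
    cfgd = DetectionConfig(threshold_db=30)
    multi = detect_frame_thresholds(frame, psf, cfgd, [20.0, 30.0])
    single = detect_frame(frame, psf, cfgd)
    assert [(r.x_sub, r.y_sub, r.amplitude) for r in multi[30.0]] == [
        (r.x_sub, r.y_sub, r.amplitude) for r in single
    ]
    assert len(multi[20.0]) >= len(multi[30.0])


# ---------------------------------------------------------------------------
# counting


def test_count_per_cell_mask_logic(psf):
    from qdfish.detection import SpotRecord

    def spot(x, y):
        return SpotRecord(x_sub=x, y_sub=y, amplitude=10, background=0,
                          glrt_score=50, score_db=40, depletion_round=0,
                          residual_var=1.0)

    mask = np.zeros((20, 20), bool)
    mask[:10, :10] = True
    spots = [spot(3, 4), spot(15, 15), spot(8, 2)]
    assert count_per_cell([], mask) == 0
    assert count_per_cell(spots, mask) == 2
    assert count_per_cell(spots, None) == 3


# ---------------------------------------------------------------------------
# 3D


def _stack_from_arrays(arrays, z_step=0.22):
    frames = [ImageFrame(pixels=a, z_index=i) for i, a in enumerate(arrays)]
    return ImageStack(frames=frames, axis="z", z_step_um=z_step)


def test_single_slice_stack_3d_equals_2d(psf, rng):
    photons = np.full((64, 64), 50.0)
    photons += render_field((64, 64), psf, [20, 44], [30, 50], [800, 700])
    arr = apply_camera_noise(photons, CameraModel(), rng)
    stack = _stack_from_arrays([arr])
    cfgd = DetectionConfig(threshold_db=30)
    spots3d = detect_stack_3d(stack, psf, cfgd)
    spots2d = detect_frame(arr, psf, cfgd)
    assert len(spots3d) == len(spots2d) == 2


def test_spot_spanning_slices_links_to_one(psf, rng):
    """One spot appearing in 3 consecutive slices at the same xy is a
    single 3D spot spanning 3 slices."""
    arrays = []
    for att in (0.5, 1.0, 0.5):
        photons = np.full((48, 48), 50.0)
        photons += render_field((48, 48), psf, [24.3], [22.6], [att * 1500.0])
        arrays.append(apply_camera_noise(photons, CameraModel(), rng))
    spots3d = detect_stack_3d(_stack_from_arrays(arrays), psf, DetectionConfig(threshold_db=30))
    assert len(spots3d) == 1
    assert spots3d[0].n_slices == 3
    assert abs(spots3d[0].x - 24.3) < 0.3 and abs(spots3d[0].y - 22.6) < 0.3


def test_negative_link_radius_rejected(psf):
    stack = _stack_from_arrays([np.zeros((32, 32), np.uint16)])
    with pytest.raises(ValueError):
        detect_stack_3d(stack, psf, DetectionConfig(threshold_db=30, link_radius_px=-1.0))
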