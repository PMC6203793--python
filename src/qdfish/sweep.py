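"""Downstream count analyses: threshold sweeps, photostability series,
2D-vs-3D comparison, and two-condition knockdown quantification.

The threshold sweep is the robustness diagnostic for automated spot
counting: per-cell transcript counts are recomputed across a range of
detection thresholds (dB of per-image false-positive probability) and the
slope of mean count versus threshold measures how sensitive the count is
to the choice — bright, uniform probes (QD-like) give flat curves, dim
probes embedded in autofluorescence (dye-like) give steep ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import (
    DetectionConfig,
    count_per_cell,
    detect_frame,
    detect_frame_thresholds,
    detect_stack_3d,
)
from .frames import ImageFrame, ImageStack
from .psf import PSFModel

__all__ = [
    "ThresholdSweep",
    "CountSeries",
    "ConditionComparison",
    "threshold_sweep",
    "sweep_slope",
    "photostability_series",
    "compare_2d_3d",
    "knockdown_fraction",
]


@dataclass
class ThresholdSweep:
    """Count-vs-threshold curves across cells."""

    thresholds_db: np.ndarray
    per_cell_counts: np.ndarray  # (n_cells, n_thresholds)
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    slopes: np.ndarray  # d(mean count)/d(threshold_db); NaN if < 3 thresholds


@dataclass
class CountSeries:
    """Counts along an excitation time series, normalized to t = 0."""

    times_s: np.ndarray
    per_cell_counts: np.ndarray  # (n_cells, n_times)
    normalized_mean: np.ndarray
    normalized_sd: np.ndarray


@dataclass
class ConditionComparison:
    """Two-condition (e.g. control vs siRNA-treated) count comparison."""

    counts_control: np.ndarray
    counts_treated: np.ndarray
    percent_change: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    n_boot: int


def threshold_sweep(
    frames: list[ImageFrame | np.ndarray],
    masks: list[np.ndarray | None],
    psf: PSFModel,
    thresholds_db: list[float],
    config: DetectionConfig,
) -> ThresholdSweep:
    """Full detection pipeline per cell per threshold.

    Returns per-cell count curves with across-cell mean and standard
    deviation per threshold, plus finite-difference slopes of the mean
    curve.  The candidate/refinement stage of detection is shared across
    thresholds of a given cell (results identical to independent runs).
    """
    thr = np.asarray(thresholds_db, dtype=float)
    if thr.size < 1 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds_db must be a non-empty increasing list")
    if len(frames) < 1 or len(frames) != len(masks):
        raise ValueError("need one mask (possibly None) per frame")
    counts = np.empty((len(frames), thr.size))
    for i, (fr, mask) in enumerate(zip(frames, masks)):
        per_thr = detect_frame_thresholds(fr, psf, config, list(thr))
        for j, t in enumerate(thr):
            counts[i, j] = count_per_cell(per_thr[t], mask)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if len(frames) > 1 else np.zeros(thr.size)
    return ThresholdSweep(
        thresholds_db=thr,
        per_cell_counts=counts,
        mean_counts=mean,
        sd_counts=sd,
        slopes=sweep_slope_values(thr, mean),
    )


def sweep_slope_values(thresholds: np.ndarray, mean_counts: np.ndarray) -> np.ndarray:
    """Central finite differences of mean counts vs threshold (one-sided at
    the ends); NaN when fewer than 3 thresholds."""
    t = np.asarray(thresholds, float)
    c = np.asarray(mean_counts, float)
    if t.size < 3:
        return np.full(t.size, np.nan)
    return np.gradient(c, t)


def sweep_slope(sweep: ThresholdSweep) -> np.ndarray:
    """Slopes d(mean count)/d(threshold) of a computed sweep."""
    return sweep_slope_values(sweep.thresholds_db, sweep.mean_counts)


def photostability_series(
    stacks: list[ImageStack],
    psf: PSFModel,
    config: DetectionConfig,
    masks: list[np.ndarray | None] | None = None,
) -> CountSeries:
    """Counts after increasing excitation time, normalized to t = 0.

    Each stack is one cell's time series (shared time grid); detection
    runs independently per time point.
    """
    if not stacks:
        raise ValueError("need at least one time stack")
    times = np.array([f.time_s for f in stacks[0].frames])
    for st in stacks:
        if st.axis != "time":
            raise ValueError("photostability_series requires time stacks")
        if len(st) != times.size:
            raise ValueError("all cells must share the same time grid")
    if masks is None:
        masks = [None] * len(stacks)
    counts = np.empty((len(stacks), times.size))
    for i, (st, mask) in enumerate(zip(stacks, masks)):
        for j, fr in enumerate(st.frames):
            counts[i, j] = count_per_cell(detect_frame(fr, psf, config), mask)
    mean0 = counts[:, 0].mean()
    if mean0 <= 0:
        raise ValueError("no spots detected at t = 0; cannot normalize")
    norm = counts.mean(axis=0) / mean0
    nsd = (
        counts.std(axis=0, ddof=1) / mean0
        if len(stacks) > 1
        else np.zeros(times.size)
    )
    return CountSeries(
        times_s=times, per_cell_counts=counts, normalized_mean=norm, normalized_sd=nsd
    )


def compare_2d_3d(
    stacks: list[ImageStack],
    focal_plane_index: int,
    psf: PSFModel,
    config: DetectionConfig,
    masks: list[np.ndarray | None] | None = None,
):
    """Per-cell 2D count at one focal plane versus 3D count from the stack.

    Returns ``(counts_2d, counts_3d, slope, pearson_r)`` where the slope
    is the least-squares regression of 3D on 2D counts.  With fewer than
    2 cells, or zero variance in the 2D counts, slope and correlation are
    returned as NaN.
    """
    if masks is None:
        masks = [None] * len(stacks)
    c2d = np.empty(len(stacks))
    c3d = np.empty(len(stacks))
    for i, (st, mask) in enumerate(zip(stacks, masks)):
        if not 0 <= focal_plane_index < len(st):
            raise ValueError("focal_plane_index outside the stack")
        spots2d = detect_frame(st.frames[focal_plane_index], psf, config)
        c2d[i] = count_per_cell(spots2d, mask)
        spots3d = detect_stack_3d(st, psf, config)
        if mask is None:
            c3d[i] = len(spots3d)
        else:
            m = np.asarray(mask).astype(bool)
            c3d[i] = sum(
                1
                for s in spots3d
                if 0 <= round(s.y) < m.shape[0]
                and 0 <= round(s.x) < m.shape[1]
                and m[round(s.y), round(s.x)]
            )
    if len(stacks) < 2 or np.allclose(c2d.var(), 0) or np.allclose(c3d.var(), 0):
        return c2d, c3d, float("nan"), float("nan")
    slope = float(np.polyfit(c2d, c3d, 1)[0])
    r = float(np.corrcoef(c2d, c3d)[0, 1])
    return c2d, c3d, slope, r


def knockdown_fraction(
    counts_control,
    counts_treated,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ConditionComparison:
    """Percent reduction of mean counts in the treated group.

    ``percent_change = 100 * (1 - mean_treated / mean_control)``, with a
    percentile bootstrap confidence interval over cells (independent
    resampling within each group) and a Welch two-sample t-test.
    """
    c = np.asarray(counts_control, dtype=float)
    t = np.asarray(counts_treated, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("both groups need at least 2 cells")
    if c.mean() <= 0:
        raise ValueError("control mean must be positive")
    pct = 100.0 * (1.0 - t.mean() / c.mean())
    rng = np.random.default_rng(seed)
    idx_c = rng.integers(0, c.size, size=(n_boot, c.size))
    idx_t = rng.integers(0, t.size, size=(n_boot, t.size))
    mc = c[idx_c].mean(axis=1)
    mt = t[idx_t].mean(axis=1)
    ok = mc > 0
    boot = 100.0 * (1.0 - mt[ok] / mc[ok])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    tt = stats.ttest_ind(c, t, equal_var=False)
    return ConditionComparison(
        counts_control=c,
        counts_treated=t,
        percent_change=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        t_statistic=float(tt.statistic),
        p_value=float(tt.pvalue),
        n_boot=int(n_boot),
    )
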