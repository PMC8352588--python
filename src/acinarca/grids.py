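"""Field-level grid analysis of %dF/F movies.

The imaged field is subdivided into square regions (by default 32 x 32 um,
giving an 8 x 8 grid over a 256 um field), each grid's spatial-mean trace
is extracted, and a grid is classified as responding when its trace exceeds
four times its own baseline standard deviation during the stimulus window.
Latency, peak amplitude and the SD of the stimulated fluctuations follow
from the same traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging import DffMovie


@dataclass
class GridTraceSet:
    """Per-grid spatial-mean %dF/F traces.

    ``traces`` has shape (rows, cols, n_frames); ``grid_um`` is the edge
    length of one grid square in micrometres.
    """

    traces: np.ndarray
    grid_um: float
    fps: float
    stim_window: tuple[float, float]
    baseline_window: tuple[int, int]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.traces.shape[:2]

    @property
    def n_grids(self) -> int:
        return self.traces.shape[0] * self.traces.shape[1]

    def stim_frames(self) -> slice:
        onset, offset = self.stim_window
        return slice(int(np.ceil(onset * self.fps)), int(np.ceil(offset * self.fps)))


@dataclass
class GridMetrics:
    """Responder classification and summary metrics, one entry per grid.

    All arrays have the grid shape (rows, cols).  ``latency_s`` is NaN for
    non-responding grids.
    """

    sigma0: np.ndarray
    responding: np.ndarray
    latency_s: np.ndarray
    peak_dff: np.ndarray
    fluct_sd: np.ndarray
    grid_um: float


def make_grids(dff: DffMovie, grid_um: float = 32.0) -> GridTraceSet:
    """Average a %dF/F movie over square grids.

    Trailing rows/columns that do not fill a complete grid are dropped
    (with a warning).
    """
    grid_px = int(round(grid_um / dff.pixel_um))
    n_t, n_r, n_c = dff.frames.shape
    if grid_px > min(n_r, n_c):
        raise ValueError(f"grid of {grid_px} px larger than {n_r}x{n_c} field")
    rows, cols = n_r // grid_px, n_c // grid_px
    if rows * grid_px != n_r or cols * grid_px != n_c:
        warnings.warn("field size not a multiple of grid size; trailing pixels dropped")
    cropped = dff.frames[:, : rows * grid_px, : cols * grid_px]
    blocks = cropped.reshape(n_t, rows, grid_px, cols, grid_px)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grids allowed
        traces = np.nanmean(blocks, axis=(2, 4))  # (t, rows, cols)
    return GridTraceSet(
        traces=np.moveaxis(traces, 0, 2),
        grid_um=grid_px * dff.pixel_um,
        fps=dff.fps,
        stim_window=dff.stim_window,
        baseline_window=dff.baseline_window,
    )


def classify_responders(
    grids: GridTraceSet, threshold_sigmas: float = 4.0, consecutive_frames: int = 1
) -> GridMetrics:
    """Classify responding grids by the 4-sigma criterion.

    A grid responds when its %dF/F trace exceeds ``threshold_sigmas`` times
    its baseline standard deviation (sample SD over the baseline window)
    during the stimulus window; the comparison is strictly greater-than.
    Latency is the time of the first supra-threshold frame minus stimulus
    onset.  ``consecutive_frames`` > 1 requires that many successive
    supra-threshold frames (exposed as an option; the default matches
    single-frame exceedance).
    """
    lo, hi = grids.baseline_window
    if hi - lo < 10:
        raise ValueError("baseline window must contain at least 10 frames")
    stim = grids.stim_frames()
    if stim.stop <= stim.start:
        raise ValueError("empty stimulus window")
    base = grids.traces[:, :, lo:hi]
    sigma0 = np.std(base, axis=2, ddof=1)
    stim_traces = grids.traces[:, :, stim]
    above = stim_traces > threshold_sigmas * sigma0[:, :, None]
    if consecutive_frames > 1:
        k = consecutive_frames
        kernel = np.ones(k, dtype=int)
        runs = np.apply_along_axis(lambda a: np.convolve(a, kernel, "valid"), 2, above.astype(int))
        hit = runs >= k
        responding = hit.any(axis=2)
        first = np.argmax(hit, axis=2)
    else:
        responding = above.any(axis=2)
        first = np.argmax(above, axis=2)
    onset = grids.stim_window[0]
    t_first = (stim.start + first) / grids.fps
    latency = np.where(responding, t_first - onset, np.nan)
    latency = np.maximum(latency, 0.0)
    peak = np.max(stim_traces, axis=2)
    fluct = np.std(stim_traces, axis=2, ddof=1)
    return GridMetrics(
        sigma0=sigma0,
        responding=responding,
        latency_s=latency,
        peak_dff=peak,
        fluct_sd=fluct,
        grid_um=grids.grid_um,
    )


def percent_responding(metrics: GridMetrics) -> float:
    """Percentage of grids classified as responding."""
    n = metrics.responding.size
    if n == 0:
        raise ValueError("no grids")
    return 100.0 * float(metrics.responding.sum()) / n


def mean_latency(metrics: GridMetrics) -> float:
    """Mean latency over responding grids (non-responders excluded)."""
    lat = metrics.latency_s[metrics.responding]
    return float(np.mean(lat)) if lat.size else float("nan")


def sort_by_reference(
    metrics_ref: GridMetrics, metrics_others: list[GridMetrics]
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Rank grids by the reference condition's peak dF/F.

    Grids are ordered by ascending reference ``peak_dff`` (ties broken by
    row-major grid index), and every other condition's peaks are emitted in
    that fixed order — the rank-sorting used to show that the same regions
    are the most responsive at every stimulation strength.

    Returns ``(order, ref_sorted, others_sorted)`` where ``order`` indexes
    the flattened row-major grid array.
    """
    ref = metrics_ref.peak_dff.ravel()
    for m in metrics_others:
        if m.peak_dff.shape != metrics_ref.peak_dff.shape:
            raise ValueError("mismatched grid shapes")
    order = np.argsort(ref, kind="stable")
    return order, ref[order], [m.peak_dff.ravel()[order] for m in metrics_others]


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
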