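"""Movie containers, I/O and temporal preprocessing.

Fluorescence movies are stored as ``time x rows x cols`` stacks together
with the acquisition metadata needed downstream: pixel size, frame rate and
the stimulus window.  Conversion to %dF/F0 follows the standard convention
for GCaMP recordings: the mean of the pre-stimulus frames is the per-pixel
baseline F0 and every frame is expressed as ``(F - F0) / F0 * 100``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

#: pixels with baseline below this are masked out of dF/F conversion
F0_EPSILON = 1e-6

#: default number of baseline frames used for F0 (100 frames at 10 fps)
DEFAULT_BASELINE_FRAMES = 100


@dataclass
class ImagingMovie:
    """A fluorescence time-lapse stack with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (t, rows, cols)
        Raw fluorescence counts (nonnegative).
    pixel_um : float
        Pixel size in micrometres.
    fps : float
        Frame rate in frames per second.
    stim_window : tuple of float
        Stimulus (onset_s, offset_s) in seconds from the start of the
        recording.
    """

    frames: np.ndarray
    pixel_um: float
    fps: float
    stim_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) stack")
        onset, offset = self.stim_window
        if not (0 <= onset <= offset <= self.duration_s + 1e-9):
            raise ValueError(
                f"stim_window {self.stim_window} outside recording [0, {self.duration_s}]"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def stim_frames(self) -> slice:
        """Frame-index slice covering the stimulus window."""
        onset, offset = self.stim_window
        return slice(int(np.ceil(onset * self.fps)), int(np.ceil(offset * self.fps)))


@dataclass
class DffMovie:
    """A movie converted to %dF/F0.

    ``frames`` holds percent dF/F0; pixels whose baseline F0 was at or
    below :data:`F0_EPSILON` are NaN and flagged in ``valid_mask``.
    """

    frames: np.ndarray
    pixel_um: float
    fps: float
    stim_window: tuple[float, float]
    baseline_window: tuple[int, int]
    f0_image: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.frames.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def stim_frames(self) -> slice:
        onset, offset = self.stim_window
        return slice(int(np.ceil(onset * self.fps)), int(np.ceil(offset * self.fps)))


_REQUIRED_META = ("pixel_um", "fps", "stim_onset_s", "stim_offset_s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_movie(movie: ImagingMovie, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    meta = {
        "pixel_um": movie.pixel_um,
        "fps": movie.fps,
        "stim_onset_s": movie.stim_window[0],
        "stim_offset_s": movie.stim_window[1],
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_movie(path: str | Path) -> ImagingMovie:
    """Read a multi-page TIFF written by :func:`write_movie`.

    Raises
    ------
    ValueError
        If the metadata sidecar is missing a required field; the message
        names the missing field.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"movie metadata is missing required field {key!r}")
    return ImagingMovie(
        frames=frames,
        pixel_um=float(meta["pixel_um"]),
        fps=float(meta["fps"]),
        stim_window=(float(meta["stim_onset_s"]), float(meta["stim_offset_s"])),
    )


def frame_average(movie: ImagingMovie, n: int) -> ImagingMovie:
    """Average every ``n`` consecutive frames (e.g. 30 fps -> 10 fps).

    Trailing frames that do not fill a complete group are dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > movie.n_frames:
        raise ValueError(f"n={n} exceeds the {movie.n_frames}-frame movie")
    if n == 1:
        return ImagingMovie(movie.frames.copy(), movie.pixel_um, movie.fps, movie.stim_window)
    n_out = movie.n_frames // n
    grouped = movie.frames[: n_out * n].reshape(n_out, n, *movie.frames.shape[1:])
    return ImagingMovie(
        frames=grouped.mean(axis=1),
        pixel_um=movie.pixel_um,
        fps=movie.fps / n,
        stim_window=movie.stim_window,
    )


def default_baseline_window(movie: ImagingMovie, max_frames: int = DEFAULT_BASELINE_FRAMES) -> tuple[int, int]:
    """All frames before stimulus onset, capped at ``max_frames``."""
    onset_frame = int(np.floor(movie.stim_window[0] * movie.fps))
    n = min(onset_frame, max_frames)
    return (onset_frame - n, onset_frame)


def delta_f_over_f(
    movie: ImagingMovie, baseline_window: tuple[int, int] | None = None
) -> DffMovie:
    """Convert raw fluorescence to percent dF/F0.

    F0 is the per-pixel mean over ``baseline_window`` (frame indices,
    half-open); by default all pre-stimulus frames capped at 100.  Pixels
    with F0 <= eps are masked (NaN) and reported through the module logger.
    """
    if baseline_window is None:
        baseline_window = default_baseline_window(movie)
    lo, hi = baseline_window
    if hi <= lo:
        raise ValueError("baseline_window must be nonempty")
    if hi > movie.stim_window[0] * movie.fps + 1e-9:
        raise ValueError("baseline_window must precede stimulus onset")
    f0 = movie.frames[lo:hi].astype(float).mean(axis=0)
    valid = f0 > F0_EPSILON
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("delta_f_over_f: masked %d pixels with F0 <= %g", n_bad, F0_EPSILON)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie.frames.astype(float) - f0) / f0 * 100.0
    dff[:, ~valid] = np.nan
    return DffMovie(
        frames=dff,
        pixel_um=movie.pixel_um,
        fps=movie.fps,
        stim_window=movie.stim_window,
        baseline_window=baseline_window,
        f0_image=f0,
        valid_mask=valid,
    )


def sd_image(
    movie: ImagingMovie | DffMovie, window: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-pixel standard deviation over a frame window.

    Uses the population (divide-by-N) convention, matching ImageJ's
    Z-project SD for the visualisation/ranking purpose it serves here.
    """
    frames = movie.frames
    if window is None:
        window = (0, frames.shape[0])
    lo, hi = window
    if lo < 0 or hi > frames.shape[0] or hi - lo < 2:
        raise ValueError(f"window {window} invalid for {frames.shape[0]}-frame movie")
    return np.nanstd(frames[lo:hi].astype(float), axis=0, ddof=0)


def register_translation(
    movie: ImagingMovie, upsample_factor: int = 10
) -> tuple[ImagingMovie, np.ndarray]:
    """Rigid-translation registration of every frame to the first.

    Subpixel shifts are estimated by phase cross-correlation and applied
    with spline interpolation.  Returns the registered movie and the
    (n_frames, 2) array of recovered (row, col) shifts.
    """
    ref = movie.frames[0].astype(float)
    out = np.empty_like(movie.frames, dtype=float)
    out[0] = ref
    shifts = np.zeros((movie.n_frames, 2))
    degenerate_ref = not np.any(ref)
    for i in range(1, movie.n_frames):
        frame = movie.frames[i].astype(float)
        if degenerate_ref or not np.any(frame):
            warnings.warn("register_translation: degenerate (all-zero) frame, zero shift")
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample_factor)
        shifts[i] = shift
        out[i] = ndimage.shift(frame, shift, order=1, mode="nearest")
    registered = ImagingMovie(out, movie.pixel_um, movie.fps, movie.stim_window)
    return registered, shifts
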