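"""Footprint time-course extraction and normalization.

The measurement chain mirrors the standard manual TIRF workflow: draw a
region of interest (ROI) around the adherent footprint of each cell and a
background ROI elsewhere in the field, take the per-frame mean pixel
intensity under each, subtract the background trace from the cell trace,
and normalize by the mean intensity over a baseline window immediately
before treatment application.  The normalized trace is dimensionless with
baseline 1, making it the fold-change input for
:mod:`tirfquant.translocation`, and is summarized per cell as its mean over
a treatment window (minutes after application) for cohort statistics.

Timestamps are seconds relative to treatment application (t = 0); summary
windows are minutes, half-open ``[start, end)`` on frame timestamps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "ImageStack",
    "RoiSet",
    "FootprintTrace",
    "TreatmentWindow",
    "WINDOW_PRESETS",
    "extract_trace",
    "background_subtract",
    "normalize_baseline",
    "window_summary",
    "process_stack",
    "polygon_to_mask",
]


@dataclass
class ImageStack:
    """A single-channel time-lapse stack.

    Attributes
    ----------
    frames : numpy.ndarray
        Intensities, shape (time, height, width), arbitrary camera units.
    channel_label : str
        e.g. ``"biosensor"`` or ``"channel"``.
    frame_interval : float
        Seconds between frames (default 10).
    start_time : float
        Timestamp of the first frame, seconds relative to treatment
        application (negative for pre-treatment frames).
    """

    frames: np.ndarray
    channel_label: str = ""
    frame_interval: float = 10.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if frames.shape[0] < 2:
            raise ValueError("stack must contain at least 2 frames")
        if np.any(frames < 0):
            raise ValueError("intensities must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps, s relative to treatment application."""
        return self.start_time + self.frame_interval * np.arange(self.n_frames)


@dataclass
class RoiSet:
    """Footprint and background masks for one field of view.

    Both are boolean images of the frame shape; they must be non-empty and
    disjoint.
    """

    cell_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_mask, dtype=bool)
        bg = np.asarray(self.background_mask, dtype=bool)
        if cell.shape != bg.shape:
            raise ValueError("cell and background masks must have the same shape")
        if not cell.any() or not bg.any():
            raise ValueError("ROI masks must be non-empty")
        if np.any(cell & bg):
            raise ValueError("cell and background ROIs must be disjoint")
        self.cell_mask = cell
        self.background_mask = bg


@dataclass(frozen=True)
class TreatmentWindow:
    """Half-open summary window ``[start, end)``, minutes after application."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end (minutes)")


#: Named summary windows (minutes after treatment application).  The early
#: presets bracket the biosensor peak; the late presets the slower channel
#: trafficking plateau.  Different figures of published workflows quote
#: slightly different windows, so all are first-class presets rather than a
#: single default.
WINDOW_PRESETS: dict[str, TreatmentWindow] = {
    "akt_ph_early": TreatmentWindow(4, 6),
    "akt_ph_late": TreatmentWindow(6, 8),
    "channel_early": TreatmentWindow(8, 10),
    "channel_late": TreatmentWindow(10, 12),
}


@dataclass
class FootprintTrace:
    """Background-corrected, baseline-normalized footprint time course.

    All vectors share one length.  ``time`` is seconds relative to
    treatment application.
    """

    time: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        vecs = [self.time, self.raw, self.background, self.corrected, self.normalized]
        lengths = {np.asarray(v).size for v in vecs}
        if len(lengths) != 1:
            raise ValueError("all trace vectors must have equal length")

    def summary(self, window: TreatmentWindow) -> float:
        return window_summary(self.normalized, self.time, window)


def extract_trace(stack: ImageStack, mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean of the pixels under ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape "
            f"{stack.frames.shape[1:]}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    return stack.frames[:, mask].mean(axis=1)


def background_subtract(cell: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise ``cell - background``.

    Non-positive corrected values are kept (clipping would bias the
    subsequent normalization) but trigger a warning, since a non-positive
    baseline would make normalization fail.
    """
    cell = np.asarray(cell, dtype=float)
    background = np.asarray(background, dtype=float)
    if cell.shape != background.shape:
        raise ValueError("cell and background traces must have equal length")
    corrected = cell - background
    if np.any(corrected <= 0):
        warnings.warn(
            "background-corrected trace contains values <= 0; normalization "
            "will fail if the baseline mean is non-positive",
            UserWarning,
            stacklevel=2,
        )
    return corrected


def normalize_baseline(
    trace: np.ndarray,
    time: np.ndarray,
    baseline_duration: float = 60.0,
) -> np.ndarray:
    """Divide by the mean over the pre-treatment baseline window.

    The baseline window is ``[-baseline_duration, 0)`` seconds; after
    normalization the mean of the in-window samples is exactly 1.

    Parameters
    ----------
    baseline_duration
        Length of the pre-application window, s.  60 s is the common
        choice; 120 s is also in use — it is a parameter, not a constant.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if trace.shape != time.shape:
        raise ValueError("trace and time must have equal length")
    if baseline_duration <= 0:
        raise ValueError("baseline_duration must be positive")
    in_window = (time >= -baseline_duration) & (time < 0)
    if not in_window.any():
        raise ValueError(
            f"no samples in baseline window [-{baseline_duration} s, 0 s)"
        )
    baseline = trace[in_window].mean()
    if baseline <= 0:
        raise ValueError(f"baseline mean is non-positive ({baseline:g})")
    return trace / baseline


def window_summary(
    normalized: np.ndarray,
    time: np.ndarray,
    window: TreatmentWindow,
) -> float:
    """Mean of the normalized trace over a treatment window.

    Samples with ``window.start <= t/60 < window.end`` (half-open on frame
    timestamps, so boundary frames are assigned deterministically).
    """
    normalized = np.asarray(normalized, dtype=float)
    time = np.asarray(time, dtype=float)
    in_window = (time >= window.start * 60.0) & (time < window.end * 60.0)
    if not in_window.any():
        raise ValueError(
            f"no samples in window [{window.start}, {window.end}) min"
        )
    return float(normalized[in_window].mean())


def process_stack(
    stack: ImageStack,
    rois: RoiSet,
    baseline_duration: float = 60.0,
) -> FootprintTrace:
    """Full chain: extract, background-subtract, baseline-normalize."""
    raw = extract_trace(stack, rois.cell_mask)
    background = extract_trace(stack, rois.background_mask)
    corrected = background_subtract(raw, background)
    time = stack.times
    normalized = normalize_baseline(corrected, time, baseline_duration)
    return FootprintTrace(
        time=time,
        raw=raw,
        background=background,
        corrected=corrected,
        normalized=normalized,
    )


def polygon_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon ROI to a boolean mask.

    ``vertices`` is an (n, 2) array of (x, y) pixel coordinates, 0-based,
    x = column and y = row (the convention of common ROI exports).
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise ValueError("polygon requires an (n>=3, 2) array of (x, y) vertices")
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, vertices[:, ::-1])
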