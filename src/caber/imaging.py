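"""Image-sequence analysis: from backlit silhouette frames to a diameter trace.

The measurement chain replicates the single-moving-platen workflow: the
pixel scale is calibrated from the known platen diameter before stretching;
each frame is optionally rotated/cropped, thresholded (fluid dark on a light
background), and reduced to a per-row width profile; the neck minimum is
located between the platens; platen-gap tracking yields the motion-stop
frame (time zero), and the trace ends at filament break-up.

Because only one platen moves, the neck position drifts along the filament
axis, so the minimum must be searched for in every frame rather than read at
a fixed mid-plane.

Conventions: the filament axis is image dimension ``axis`` (default 0,
rows); widths are integer pixel extents from the first to the last
foreground pixel in a row (robust to interior intensity dips); a frame's
time is ``frame_index * frame_interval`` (start-of-exposure).
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .constitutive import FilamentTrace
from .exceptions import (
    BinarizationError,
    CalibrationError,
    InvalidGeometryError,
    InvalidParameterError,
    MotionStopNotFoundError,
    PrematureBreakupError,
)

__all__ = [
    "FrameStack",
    "FilamentProfile",
    "EventIndices",
    "calibrate_scale",
    "preprocess",
    "binarize",
    "width_profile",
    "locate_midpoint",
    "track_gap",
    "detect_motion_stop",
    "detect_breakup",
    "extract_trace",
]

#: Break-up threshold: below this width (px) the measurement is
#: quantisation-dominated and the filament is considered ruptured.
BREAKUP_THRESHOLD_PX = 2.0

#: Fraction of the gap excluded at each platen to avoid the near-platen
#: fluid reservoirs when searching for the neck minimum.
PLATEN_MARGIN_FRACTION = 0.10


@dataclass
class FrameStack:
    """A calibrated grayscale image sequence.

    ``frames`` is a (n_frames, height, width) array; ``frame_interval`` the
    time between frames in seconds; ``pixel_scale`` metres per pixel (None
    until calibrated); ``axis`` the in-frame dimension along the filament.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_scale: Optional[float] = None
    axis: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InvalidParameterError(
                "frames must be a (n>=2, height, width) array"
            )
        if not self.frame_interval > 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("frame intensities must be finite")
        if self.axis not in (0, 1):
            raise InvalidParameterError("axis must be 0 (rows) or 1 (columns)")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @classmethod
    def from_tiff(cls, path, frame_interval: float, **kw) -> "FrameStack":
        """Load a multi-page TIFF (or a directory of single-frame TIFFs)."""
        import tifffile

        if os.path.isdir(path):
            files = sorted(glob.glob(os.path.join(path, "*.tif"))) + sorted(
                glob.glob(os.path.join(path, "*.tiff"))
            )
            if not files:
                raise FileNotFoundError(f"no TIFF frames in {path}")
            frames = np.stack([tifffile.imread(f) for f in files])
        else:
            frames = tifffile.imread(path)
            if frames.ndim == 2:
                frames = frames[None]
        return cls(frames=frames, frame_interval=frame_interval, **kw)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames)


@dataclass
class FilamentProfile:
    """Per-row filament widths for one frame, with the located neck.

    ``midpoint_index`` is ``None`` (break-up) when no foreground spans the
    searched region; otherwise ``min_width == widths[midpoint_index]``.
    """

    axial_positions: np.ndarray
    widths: np.ndarray
    midpoint_index: Optional[int] = None
    min_width: float = 0.0


@dataclass
class EventIndices:
    """Frame indices of the two timeline events: motion stop and break-up."""

    motion_stop_frame: int
    breakup_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.breakup_frame is not None and not (
            self.motion_stop_frame < self.breakup_frame
        ):
            raise InvalidParameterError(
                "motion_stop_frame must precede breakup_frame"
            )


# ---------------------------------------------------------------------------
# Per-frame primitives
# ---------------------------------------------------------------------------

def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
) -> np.ndarray:
    """Threshold one frame into a foreground (fluid/platen) mask.

    Backlit convention: the fluid is *darker* than the background, so
    foreground = intensity below threshold; ``invert=True`` flips this for
    bright-on-dark footage.  ``method`` is ``"otsu"`` (automatic, requires a
    non-constant frame) or ``"fixed"`` with an explicit ``threshold``
    (foreground strictly below it — deterministic).
    """
    frame = np.asarray(frame)
    if method == "otsu":
        if frame.min() == frame.max():
            raise BinarizationError("constant frame: Otsu threshold undefined")
        from skimage.filters import threshold_otsu

        # threshold_otsu returns the top of the lower intensity class, so
        # the dark class is `<= thr` and the bright class is `> thr`.
        thr = threshold_otsu(frame)
        return (frame > thr) if invert else (frame <= thr)
    if method == "fixed":
        if threshold is None:
            raise InvalidParameterError("fixed method requires a threshold")
        return (frame > threshold) if invert else (frame < threshold)
    raise InvalidParameterError(f"unknown binarization method {method!r}")


def width_profile(mask: np.ndarray, axis: int = 0) -> FilamentProfile:
    """Row-wise silhouette widths: outer-edge extent of foreground per row.

    The width at each axial position is the span from the first to the last
    foreground pixel (0 for empty rows), which is robust to interior
    intensity dips in the filament.  The neck is located afterwards by
    :func:`locate_midpoint`; the returned profile carries the margin-free
    minimum as a convenience.
    """
    mask = np.asarray(mask, dtype=bool)
    if axis == 1:
        mask = mask.T
    n = mask.shape[0]
    widths = np.zeros(n, dtype=float)
    any_fg = mask.any(axis=1)
    first = mask.argmax(axis=1)
    last = mask.shape[1] - 1 - mask[:, ::-1].argmax(axis=1)
    widths[any_fg] = (last - first + 1)[any_fg]
    profile = FilamentProfile(axial_positions=np.arange(n), widths=widths)
    idx, mw = locate_midpoint(profile, platen_margin=0)
    profile.midpoint_index = idx
    profile.min_width = mw
    return profile


def locate_midpoint(
    profile: FilamentProfile, platen_margin: int = 0
) -> Tuple[Optional[int], float]:
    """Locate the neck: index and value of the minimum width.

    Searches strictly inside ``platen_margin`` rows from each end.  Ties on
    the minimum are broken towards the centre of the filament span (the
    nonzero-width extent); an all-zero region signals break-up and returns
    ``(None, 0.0)`` rather than raising.
    """
    w = np.asarray(profile.widths, dtype=float)
    n = w.size
    m = int(platen_margin)
    if m < 0 or 2 * m >= n:
        raise InvalidParameterError("platen_margin leaves no interior rows")
    interior = w[m : n - m]
    if not (interior > 0).any():
        return None, 0.0
    mw = interior.min()
    if mw == 0.0:
        # a fully empty interior row while fluid remains elsewhere: ruptured
        return None, 0.0
    candidates = np.flatnonzero(interior == mw)
    nonzero = np.flatnonzero(interior > 0)
    centre = 0.5 * (nonzero[0] + nonzero[-1])
    best = candidates[np.argmin(np.abs(candidates - centre))]
    return int(best + m), float(mw)


def calibrate_scale(
    frame: np.ndarray,
    known_diameter: float = 1.2e-3,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
) -> float:
    """Pixel scale (m/px) from the known platen diameter.

    The widest foreground row in a pre-stretch frame is the platen
    silhouette; its pixel extent divided into ``known_diameter`` gives the
    scale.  Raises :class:`CalibrationError` when no foreground is found.
    """
    if not known_diameter > 0:
        raise InvalidGeometryError("known_diameter must be > 0")
    try:
        mask = binarize(frame, method=method, threshold=threshold, invert=invert)
    except BinarizationError as exc:
        raise CalibrationError(f"calibration failed: {exc}") from exc
    profile = width_profile(mask)
    platen_px = profile.widths.max()
    if platen_px <= 0:
        raise CalibrationError("no foreground object found in calibration frame")
    return known_diameter / platen_px


def preprocess(
    stack: FrameStack,
    rotate_deg: float = 0.0,
    crop_box: Optional[Tuple[int, int, int, int]] = None,
) -> FrameStack:
    """Rotate then crop every frame identically; metadata is preserved.

    ``crop_box`` is ``(row0, row1, col0, col1)`` (half-open) in the rotated
    frame.  Right-angle rotations are exact (``np.rot90``); other angles use
    bilinear resampling via scipy.ndimage.
    """
    frames = stack.frames
    if rotate_deg % 360 != 0:
        if rotate_deg % 90 == 0:
            k = int(rotate_deg // 90) % 4
            frames = np.rot90(frames, k=k, axes=(1, 2))
        else:
            from scipy.ndimage import rotate as nd_rotate

            frames = nd_rotate(
                frames, rotate_deg, axes=(1, 2), reshape=False, order=1,
                mode="nearest",
            )
    if crop_box is not None:
        r0, r1, c0, c1 = crop_box
        h, w = frames.shape[1], frames.shape[2]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise InvalidGeometryError(
                f"crop_box {crop_box} outside frame bounds {(h, w)}"
            )
        frames = frames[:, r0:r1, c0:c1]
    return replace(stack, frames=frames.copy())


# ---------------------------------------------------------------------------
# Frame-sequence measurements
# ---------------------------------------------------------------------------

def _measure_frame(
    mask: np.ndarray, axis: int = 0
) -> Tuple[Optional[int], Optional[int], float, Optional[int]]:
    """Platen faces, gap and neck in one binarized frame.

    Platen rows are identified as rows whose width is within 1 px of the
    frame's maximum (the platen silhouette); the gap is the run of
    non-platen rows between the lower edge of the top platen block and the
    upper edge of the bottom block.  Returns ``(gap_px, neck_index,
    neck_width_px, top_face_row)``; gap is None when no two platen blocks
    are visible.
    """
    profile = width_profile(mask, axis=axis)
    w = profile.widths
    if not (w > 0).any():
        return None, None, 0.0, None
    platen_px = w.max()
    is_platen = w >= platen_px - 1.0
    platen_rows = np.flatnonzero(is_platen)
    # top block: contiguous platen rows starting at the first platen row
    top_end = platen_rows[0]
    while top_end + 1 < w.size and is_platen[top_end + 1]:
        top_end += 1
    bottom_start = platen_rows[-1]
    while bottom_start - 1 >= 0 and is_platen[bottom_start - 1]:
        bottom_start -= 1
    if bottom_start <= top_end:  # single block: platens in contact / pre-stretch
        return 0, None, float(platen_px), int(top_end)
    gap_px = int(bottom_start - top_end - 1)
    margin = max(1, int(round(PLATEN_MARGIN_FRACTION * gap_px)))
    sub = FilamentProfile(
        axial_positions=np.arange(gap_px),
        widths=w[top_end + 1 : bottom_start],
    )
    if 2 * margin >= gap_px:
        margin = 0
    idx, mw = locate_midpoint(sub, platen_margin=margin)
    neck = None if idx is None else int(top_end + 1 + idx)
    return gap_px, neck, float(mw), int(top_end)


def track_gap(
    stack: FrameStack,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
) -> np.ndarray:
    """Platen gap per frame (metres; NaN where no gap is resolvable).

    Requires a calibrated stack.  The gap is measured between the inner
    faces of the two platen silhouettes (rows at full platen width).
    """
    if stack.pixel_scale is None:
        raise CalibrationError("stack must be calibrated before gap tracking")
    gaps = np.full(len(stack), np.nan)
    for i, frame in enumerate(stack.frames):
        mask = binarize(frame, method=method, threshold=threshold, invert=invert)
        gap_px, _, _, _ = _measure_frame(mask, axis=stack.axis)
        if gap_px is not None:
            gaps[i] = gap_px * stack.pixel_scale
    return gaps


def detect_motion_stop(
    gap_series: np.ndarray,
    g_f: float,
    tolerance: float = 0.02,
    min_frames: int = 5,
) -> int:
    """First frame from which the gap stays within ``±tolerance·g_f`` of g_f.

    The in-band condition must hold from the candidate frame to the end of
    the series, with at least ``min_frames`` frames of confirmation; this
    rejects transient in-band windows during the overshoot oscillation.
    Raises :class:`MotionStopNotFoundError` if the gap never settles
    (suggesting a longer recording).
    """
    gaps = np.asarray(gap_series, dtype=float)
    if not g_f > 0:
        raise InvalidGeometryError("g_f must be > 0")
    in_band = np.abs(gaps - g_f) <= tolerance * g_f
    in_band &= np.isfinite(gaps)
    # first index i with in_band[i:] all True
    if in_band.size and in_band[-1]:
        not_ok = np.flatnonzero(~in_band)
        i = 0 if not_ok.size == 0 else int(not_ok[-1] + 1)
        if gaps.size - i >= min_frames:
            return i
    raise MotionStopNotFoundError(
        f"gap never settled within {tolerance:.0%} of g_f for "
        f">= {min_frames} frames; record for longer"
    )


def detect_breakup(
    width_series: Sequence[float],
    threshold_px: float = BREAKUP_THRESHOLD_PX,
) -> Optional[int]:
    """First frame whose neck width falls below ``threshold_px`` (or None).

    Below ~2 px the width measurement is quantisation-dominated, so that is
    the default rupture criterion; a missing break-up (filament survives the
    recording) returns None rather than raising.
    """
    widths = np.asarray(width_series, dtype=float)
    below = np.flatnonzero(widths < threshold_px)
    return int(below[0]) if below.size else None


def measure_widths(
    stack: FrameStack,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
) -> np.ndarray:
    """Neck width in pixels for every frame (0 after rupture)."""
    widths = np.zeros(len(stack))
    for i, frame in enumerate(stack.frames):
        mask = binarize(frame, method=method, threshold=threshold, invert=invert)
        _, _, mw, _ = _measure_frame(mask, axis=stack.axis)
        widths[i] = mw
    return widths


def extract_trace(
    stack: FrameStack,
    events: EventIndices,
    method: str = "otsu",
    threshold: Optional[float] = None,
    invert: bool = False,
    breakup_threshold_px: float = BREAKUP_THRESHOLD_PX,
) -> FilamentTrace:
    """Build the diameter–time trace from a calibrated stack.

    Time is zeroed at ``events.motion_stop_frame``; the initial diameter D0
    is the neck width measured at that frame; frames at and after
    ``events.breakup_frame`` are excluded and the break-up time recorded.
    A filament already below the rupture threshold at motion stop raises
    :class:`PrematureBreakupError` (too inviscid for the stretch speed).
    """
    if stack.pixel_scale is None:
        raise CalibrationError("stack must be calibrated before extraction")
    widths = measure_widths(
        stack, method=method, threshold=threshold, invert=invert
    )
    stop = events.motion_stop_frame
    if not 0 <= stop < len(stack):
        raise InvalidParameterError("motion_stop_frame outside the recording")
    if widths[stop] < breakup_threshold_px:
        raise PrematureBreakupError(
            "filament already broken when the platens stopped: the fluid is "
            "too inviscid for this stretch (break-up within the separation "
            "period)"
        )
    end = events.breakup_frame if events.breakup_frame is not None else len(stack)
    idx = np.arange(stop, end)
    times = (idx - stop) * stack.frame_interval
    diameters = widths[idx] * stack.pixel_scale
    t_f = None
    if events.breakup_frame is not None:
        t_f = (events.breakup_frame - stop) * stack.frame_interval
    return FilamentTrace(times=times, diameters=diameters, t_f=t_f)
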