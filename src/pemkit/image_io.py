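"""Image-stack I/O and shared preprocessing primitives for SPR/PEM microscopy.

A plasmonic electrochemical microscopy (PEM) recording is a time-ordered
stack of reflected-intensity frames acquired at a fixed incident angle
slightly below the surface plasmon resonance angle.  This module holds the
in-memory container (:class:`ImageStack`), multi-page TIFF read/write, and
the preprocessing primitives every analysis stage shares: reference-frame
background subtraction, ``k x k`` spatial boxcar smoothing, centred temporal
moving averages, and single-pixel trace extraction.

Conventions
-----------
* Arrays are row-major, 0-based; row 0 is the image top.
* The surface plasmon propagation direction is the +column axis.
* Intensities are kept in raw camera units; a percent-reflectivity-change
  display transform relative to a baseline frame is provided separately.
* Timestamps are seconds from acquisition start (``t0_s`` offset).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "AcquisitionMeta",
    "PixelGeometry",
    "read_stack",
    "write_stack",
    "pixel_size_from_geometry",
    "background_subtract",
    "spatial_boxcar",
    "temporal_moving_average",
    "extract_trace",
    "percent_reflectivity_change",
    "save_trace_csv",
]


@dataclass
class ImageStack:
    """Time-ordered grid of reflected-intensity frames.

    Parameters
    ----------
    frames
        3-D array ``(time, rows, cols)`` of intensities in arbitrary camera
        units.
    frame_rate_hz
        Acquisition rate in frames per second (1 or 50 fps on the
        instrument this models).
    pixel_size_um
        Lateral size of one pixel in micrometres (~0.94 um on the
        450x600 um^2 / 480x640 px system).
    t0_s
        Acquisition start time in seconds.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, rows, cols); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not self.frame_rate_hz > 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times_s(self) -> np.ndarray:
        """Per-frame timestamps in seconds from acquisition start."""
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def frame_index_at(self, time_s: float) -> int:
        """Index of the frame acquired at (or latest before) ``time_s``."""
        idx = int(np.floor((time_s - self.t0_s) * self.frame_rate_hz + 1e-9))
        if not 0 <= idx < self.n_frames:
            raise IndexError(f"time {time_s} s falls outside the recorded stack")
        return idx

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """New stack sharing this stack's acquisition metadata."""
        return ImageStack(frames, self.frame_rate_hz, self.pixel_size_um, self.t0_s)


@dataclass
class AcquisitionMeta:
    """Acquisition geometry and experiment schedule.

    ``injection_schedule`` entries are dicts with keys ``time_s``, ``label``
    and optionally ``conc_nM`` (bulk) or an event tag.
    """

    fov_um: tuple[float, float]
    ccd_px: tuple[int, int]
    frame_rate_hz: float
    injection_schedule: list[dict] = field(default_factory=list)
    working_potential_V: float | None = None

    def __post_init__(self) -> None:
        geom = pixel_size_from_geometry(self.fov_um, self.ccd_px)
        if not geom.consistent:
            raise ValueError(
                "per-axis pixel sizes disagree by more than 1%: "
                f"{geom.row_um:.4f} vs {geom.col_um:.4f} um"
            )
        times = [e["time_s"] for e in self.injection_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("injection schedule times must be strictly increasing")

    @property
    def pixel_size_um(self) -> float:
        return pixel_size_from_geometry(self.fov_um, self.ccd_px).mean_um


class PixelGeometry(NamedTuple):
    """Per-axis pixel size derived from field of view and CCD dimensions."""

    row_um: float
    col_um: float
    mean_um: float
    consistent: bool


def pixel_size_from_geometry(
    fov_um: Sequence[float] | float,
    ccd_px: Sequence[int] | int,
    tolerance: float = 0.01,
) -> PixelGeometry:
    """Pixel size (um/px) from the optical field of view and CCD array.

    Accepts either per-axis ``(height, width)`` / ``(rows, cols)`` pairs or a
    single axis each.  For the instrument modelled here,
    450 um / 480 px = 600 um / 640 px = 0.9375 ~ 0.94 um per pixel.

    Axes whose derived sizes disagree by more than ``tolerance`` (relative)
    are flagged via ``consistent=False``.
    """
    fov = np.atleast_1d(np.asarray(fov_um, dtype=float))
    ccd = np.atleast_1d(np.asarray(ccd_px, dtype=float))
    if fov.size != ccd.size or fov.size not in (1, 2):
        raise ValueError("fov_um and ccd_px must both be scalars or both 2-vectors")
    if np.any(fov <= 0) or np.any(ccd <= 0):
        raise ValueError("field of view and CCD dimensions must be positive")
    sizes = fov / ccd
    row, col = (sizes[0], sizes[-1])
    mean = float(sizes.mean())
    consistent = bool(abs(row - col) <= tolerance * mean)
    return PixelGeometry(float(row), float(col), mean, consistent)


def read_stack(path: str | os.PathLike, meta: AcquisitionMeta | dict) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    ``meta`` supplies acquisition parameters: either an
    :class:`AcquisitionMeta` or a dict with ``frame_rate_hz`` and either
    ``pixel_size_um`` or ``fov_um``/``ccd_px``.  Integer pixel data are
    preserved bit-exactly.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"stack file not found: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:  # single-page TIFF -> 1-frame stack
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError(f"expected a grayscale multi-page TIFF, got shape {frames.shape}")
    if isinstance(meta, AcquisitionMeta):
        frame_rate = meta.frame_rate_hz
        pixel_size = meta.pixel_size_um
        t0 = 0.0
    else:
        frame_rate = meta["frame_rate_hz"]
        if "pixel_size_um" in meta:
            pixel_size = meta["pixel_size_um"]
        else:
            pixel_size = pixel_size_from_geometry(meta["fov_um"], meta["ccd_px"]).mean_um
        t0 = meta.get("t0_s", 0.0)
    return ImageStack(frames, frame_rate_hz=frame_rate, pixel_size_um=pixel_size, t0_s=t0)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


def background_subtract(stack: ImageStack, ref_frame_index: int) -> ImageStack:
    """Subtract a reference frame from every frame of the stack.

    The reference is typically the frame immediately preceding an injection
    event; its own frame becomes all zeros.  Static structure shared by all
    frames (illumination baseline, interference fringes, fixed scattering
    patterns) cancels exactly.
    """
    if not 0 <= ref_frame_index < stack.n_frames:
        raise IndexError(
            f"reference frame {ref_frame_index} outside stack of {stack.n_frames} frames"
        )
    frames = stack.frames.astype(np.float64, copy=False)
    out = frames - frames[ref_frame_index]
    return stack.with_frames(out)


def spatial_boxcar(frame: np.ndarray, k: int = 5) -> np.ndarray:
    """``k x k`` spatial averaging filter with edge-replication padding.

    Each pixel is replaced by the mean of its ``k x k`` neighbourhood; the
    output has the input's dimensions so per-pixel maps stay aligned.  The
    default ``k=5`` matches the high-frequency spatial-noise filter used for
    endpoint images.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("spatial_boxcar expects a single 2-D frame")
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {k}")
    if min(frame.shape) < k:
        raise ValueError(f"frame {frame.shape} smaller than {k}x{k} kernel")
    if k == 1:
        return frame.copy()
    return ndimage.uniform_filter(frame, size=k, mode="nearest")


def temporal_moving_average(trace: np.ndarray, window: int) -> np.ndarray:
    """Length-preserving centred moving average of a 1-D trace.

    Near the trace ends the window shrinks to the available samples, so no
    phantom values are introduced and a constant trace is left unchanged.
    For even ``window`` the centred span carries one extra trailing sample.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("temporal_moving_average expects a 1-D trace")
    window = int(window)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = trace.size
    if window > n:
        raise ValueError(f"window {window} longer than trace of {n} samples")
    if window == 1:
        return trace.copy()
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, None)
    hi = np.clip(idx + half_hi + 1, None, n)
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def extract_trace(stack: ImageStack, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
    """Temporal intensity profile of one pixel.

    Returns ``(times_s, values)`` with timestamps
    ``frame_index / frame_rate_hz + t0_s``.
    """
    n_rows, n_cols = stack.frame_shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise IndexError(f"pixel ({row}, {col}) outside {n_rows}x{n_cols} frame")
    return stack.times_s, np.asarray(stack.frames[:, row, col], dtype=np.float64)


def percent_reflectivity_change(stack: ImageStack, ref_frame_index: int) -> np.ndarray:
    """Display transform: 100*(I - I_ref)/I_ref relative to a baseline frame.

    Raw camera units remain canonical for analysis; this matches the
    percent-change grayscale used for displayed endpoint images.  Zero-valued
    reference pixels yield NaN (with a warning suppressed for the exact-zero
    case rather than propagating a divide warning).
    """
    if not 0 <= ref_frame_index < stack.n_frames:
        raise IndexError("reference frame index out of range")
    ref = np.asarray(stack.frames[ref_frame_index], dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (stack.frames.astype(np.float64) - ref) / ref
    if np.any(ref == 0):
        warnings.warn("zero-valued reference pixels produce NaN percent change")
    return out


def save_trace_csv(
    path: str | os.PathLike,
    axis_values: np.ndarray,
    values: np.ndarray,
    axis_label: str = "time_s",
    value_label: str = "value",
) -> None:
    """Export a trace or profile as a two-column CSV with header."""
    pd.DataFrame({axis_label: np.asarray(axis_values), value_label: np.asarray(values)}).to_csv(
        path, index=False
    )
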