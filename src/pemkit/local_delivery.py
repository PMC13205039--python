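"""Localized-delivery analysis: dip/deposit decoupling, profiles, ROI mass response.

A localized micropipette delivery superimposes two interfacial phenomena on
the sensor: a transient, circular negative dip from the hydrodynamic
pressure of the pumped flow, and a persistent, spatially asymmetric bright
deposit from the electropolymerized film (plus a slowly growing diffusion
halo).  After event-referenced background subtraction (which cancels the
static fringes and scattering patterns exactly), this module

* builds stacked, color-mapped line-profile series for visualisation,
* classifies each pixel as transient-physical / persistent-chemical /
  inactive from two window statistics (pump-window mean and late-window
  mean against a +/- k*sigma noise band),
* quantifies the dip (magnitude, half-minimum equivalent radius, recovery
  time),
* integrates the deposit signal inside a fixed circular ROI (166 um
  diameter by default), and
* aggregates replicate injections into the nominal-amount mass-response
  table (integrated signal vs concentration x pumped volume, log-log).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack, background_subtract, spatial_boxcar, temporal_moving_average

__all__ = [
    "DeliveryEvent",
    "LineSpec",
    "LineProfileStack",
    "ROIMask",
    "DipMetrics",
    "DeliverySummary",
    "reference_event",
    "estimate_noise_sigma",
    "profile_stack",
    "decouple_phases",
    "quantify_dip",
    "circular_roi",
    "integrate_roi",
    "nominal_amount",
    "summarize_event",
    "mass_response",
    "loglog_fit",
]


@dataclass
class DeliveryEvent:
    """One localized delivery: pump interval plus injection parameters."""

    stack: ImageStack
    pump_on_frame: int
    pump_off_frame: int
    conc_uM: float
    pump_volume_mL: float
    pipette_rc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pump_on_frame < self.pump_off_frame < self.stack.n_frames:
            raise ValueError("need 0 <= pump_on_frame < pump_off_frame < stack end")
        if self.conc_uM < 0 or self.pump_volume_mL < 0:
            raise ValueError("concentration and pumped volume must be nonnegative")


def reference_event(stack: ImageStack, event: DeliveryEvent) -> ImageStack:
    """Background-subtract using the frame immediately preceding pump-on.

    Static structure (fringes, fixed scatterer wakes, illumination baseline)
    cancels exactly; the frame before pump-on becomes all zeros.
    """
    if event.pump_on_frame < 1:
        raise ValueError("pump-on at frame 0 leaves no pre-injection reference frame")
    return background_subtract(stack, event.pump_on_frame - 1)


def estimate_noise_sigma(referenced: ImageStack, end_frame: int) -> float:
    """Scalar per-frame noise sigma from the pre-pump segment.

    Median over pixels of the temporal SD of the referenced pre-pump
    frames; falls back to a frame-difference estimate when fewer than three
    pre-pump frames exist.
    """
    pre = referenced.frames[:end_frame].astype(np.float64)
    if pre.shape[0] >= 3:
        return float(np.median(pre.std(axis=0, ddof=1)))
    diff = np.diff(referenced.frames[: max(end_frame + 2, 2)].astype(np.float64), axis=0)
    if diff.shape[0] == 0:
        raise ValueError("cannot estimate noise from fewer than two frames")
    return float(np.median(np.abs(diff)) / (np.sqrt(2.0) * 0.6745))


# --------------------------------------------------------------------------
# Line profiles
# --------------------------------------------------------------------------


@dataclass
class LineSpec:
    """Placement of a profile line: a row or column, optionally band-averaged."""

    orientation: str  # "row" (profile along columns) or "col" (along rows)
    index: int
    band_halfwidth: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("row", "col"):
            raise ValueError("orientation must be 'row' or 'col'")
        if self.index < 0 or self.band_halfwidth < 0:
            raise ValueError("line index and band halfwidth must be nonnegative")


@dataclass
class LineProfileStack:
    """Stacked temporal line profiles with display offsets.

    ``profiles`` holds the smoothed, *offset* traces used for the stacked
    top-down rendering; ``color_values`` holds the original un-offset
    intensities so color mapping conveys true signal magnitude.
    """

    positions_um: np.ndarray
    times_s: np.ndarray
    profiles: np.ndarray  # (n_times, n_positions), offsets applied
    offsets: np.ndarray
    color_values: np.ndarray  # (n_times, n_positions), un-offset

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for i, t in enumerate(self.times_s):
            records.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "position_um": self.positions_um,
                        "offset_value": self.profiles[i],
                        "value": self.color_values[i],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def profile_stack(
    referenced: ImageStack,
    line_spec: LineSpec | dict,
    times_s: Sequence[float],
    window: int = 10,
    offset_step: float | None = None,
) -> LineProfileStack:
    """Extract smoothed, stacked spatial line profiles at chosen timepoints.

    Each profile is the (band-averaged) pixel line at the requested time,
    smoothed with a ``window``-point moving average (10 by default).
    Monotone vertical offsets separate successive profiles for top-down
    display; ``offset_step=None`` picks the maximum peak-to-peak amplitude
    so profiles never overlap, and 0 disables offsetting.
    """
    if isinstance(line_spec, dict):
        line_spec = LineSpec(**line_spec)
    rows, cols = referenced.frame_shape
    limit = rows if line_spec.orientation == "row" else cols
    if line_spec.index >= limit:
        raise IndexError(f"line index {line_spec.index} outside frame of {limit} lines")

    raw_profiles = []
    for t in times_s:
        frame = referenced.frames[referenced.frame_index_at(t)].astype(np.float64)
        lo = max(0, line_spec.index - line_spec.band_halfwidth)
        hi = min(limit, line_spec.index + line_spec.band_halfwidth + 1)
        if line_spec.orientation == "row":
            prof = frame[lo:hi, :].mean(axis=0)
        else:
            prof = frame[:, lo:hi].mean(axis=1)
        raw_profiles.append(temporal_moving_average(prof, window) if window > 1 else prof)
    color = np.stack(raw_profiles)
    if offset_step is None:
        p2p = float(color.max() - color.min())
        offset_step = 1.1 * p2p if p2p > 0 else 1.0
    offsets = offset_step * np.arange(len(raw_profiles))
    profiles = color + offsets[:, None]
    n_pos = color.shape[1]
    return LineProfileStack(
        positions_um=np.arange(n_pos) * referenced.pixel_size_um,
        times_s=np.asarray(list(times_s), dtype=float),
        profiles=profiles,
        offsets=offsets,
        color_values=color,
    )


# --------------------------------------------------------------------------
# Phase decoupling
# --------------------------------------------------------------------------


def decouple_phases(
    referenced: ImageStack,
    event: DeliveryEvent,
    k: float = 3.0,
    late_fraction: float = 0.2,
    sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify pixels as transient-physical vs persistent-chemical.

    Two window statistics per pixel: W1, the mean over the pump interval,
    and W2, the mean over the last ``late_fraction`` of the record, both
    baseline-corrected by the pre-pump mean (which cancels the noise the
    single reference frame injects into every referenced frame).  A pixel
    is *transient physical* when W1 < -k*sigma while |W2| < k*sigma (the dip
    came and went) and *persistent chemical* when W2 > +k*sigma (the deposit
    remains).  ``sigma`` is the per-frame baseline noise, estimated from the
    pre-pump segment when not supplied.  The masks are disjoint by
    construction; all-zero stacks yield two empty masks.
    """
    n = referenced.n_frames
    n_late = max(1, int(round(late_fraction * n)))
    if event.pump_off_frame >= n or n_late > n:
        raise ValueError("classification windows fall outside the stack")
    if sigma is None:
        sigma = estimate_noise_sigma(referenced, event.pump_on_frame)
    if event.pump_on_frame >= 1:
        baseline = referenced.frames[: event.pump_on_frame].mean(axis=0, dtype=np.float64)
    else:
        baseline = 0.0
    w1 = (
        referenced.frames[event.pump_on_frame : event.pump_off_frame].mean(
            axis=0, dtype=np.float64
        )
        - baseline
    )
    w2 = referenced.frames[n - n_late :].mean(axis=0, dtype=np.float64) - baseline
    band = k * sigma
    persistent = w2 > band
    transient = (w1 < -band) & ~persistent & (np.abs(w2) < band)
    return transient, persistent


# --------------------------------------------------------------------------
# Dip quantification
# --------------------------------------------------------------------------


@dataclass
class DipMetrics:
    """Magnitude, spread and relaxation of the transient pressure dip."""

    dip_min: float
    dip_frame: int
    dip_radius_um: float  # equivalent radius of the below-half-minimum region
    dip_centroid_rc: tuple[float, float] | None
    recovery_s: float | None  # None if the dip never recovers within the record
    no_dip: bool


def quantify_dip(
    referenced: ImageStack,
    event: DeliveryEvent,
    boxcar_k: int = 5,
    k: float = 3.0,
    sigma: float | None = None,
) -> DipMetrics:
    """Measure the hydrodynamic dip of one delivery event.

    The dip minimum is the global minimum over the pump window after
    ``boxcar_k`` spatial smoothing; its spatial spread is the equivalent
    radius (same-area circle) of the region at or below half the minimum in
    the worst frame; recovery is the first post-pump time at which that
    region's mean rises above ``-k*sigma``.  When no excursion below
    ``-k*sigma`` occurs the metrics are zero-magnitude and flagged
    ``no_dip``.
    """
    if sigma is None:
        sigma = estimate_noise_sigma(referenced, event.pump_on_frame)
    smoothed = np.stack(
        [
            spatial_boxcar(referenced.frames[i].astype(np.float64), boxcar_k)
            for i in range(event.pump_on_frame, event.pump_off_frame)
        ]
    )
    flat_idx = int(np.argmin(smoothed))
    f_rel, r_idx, c_idx = np.unravel_index(flat_idx, smoothed.shape)
    dip_min = float(smoothed[f_rel, r_idx, c_idx])
    dip_frame = event.pump_on_frame + int(f_rel)

    if dip_min >= -k * sigma:
        return DipMetrics(dip_min, dip_frame, 0.0, None, None, no_dip=True)

    worst = smoothed[f_rel]
    region = worst <= dip_min / 2.0
    n_px = int(region.sum())
    radius_um = referenced.pixel_size_um * np.sqrt(n_px / np.pi)
    centroid = ndimage.center_of_mass(region)

    recovery_s = None
    post = referenced.frames[event.pump_off_frame :]
    region_means = post[:, region].mean(axis=1)
    above = np.nonzero(region_means > -k * sigma)[0]
    if above.size:
        recovery_s = float(
            (event.pump_off_frame + above[0]) / referenced.frame_rate_hz
            + referenced.t0_s
        )
    return DipMetrics(
        dip_min=dip_min,
        dip_frame=dip_frame,
        dip_radius_um=float(radius_um),
        dip_centroid_rc=(float(centroid[0]), float(centroid[1])),
        recovery_s=recovery_s,
        no_dip=False,
    )


# --------------------------------------------------------------------------
# ROI integration and mass response
# --------------------------------------------------------------------------


@dataclass
class ROIMask:
    """Fixed circular region of interest for signal integration."""

    center_rc: tuple[float, float]
    diameter_um: float
    pixel_size_um: float
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def circular_roi(
    center_rc: tuple[float, float],
    shape: tuple[int, int],
    pixel_size_um: float,
    diameter_um: float = 166.0,
) -> ROIMask:
    """Build the fixed circular ROI (166 um diameter by default).

    A pixel belongs to the ROI when its centre lies within the radius.  The
    ROI must fit fully inside the frame.
    """
    rows, cols = shape
    radius_um = diameter_um / 2.0
    radius_px = radius_um / pixel_size_um
    cr, cc = center_rc
    if (
        cr - radius_px < -0.5
        or cc - radius_px < -0.5
        or cr + radius_px > rows - 0.5
        or cc + radius_px > cols - 0.5
    ):
        raise ValueError("ROI extends outside the frame bounds")
    rr = np.arange(rows)[:, None]
    cc_ = np.arange(cols)[None, :]
    mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius_px**2
    if not mask.any():
        raise ValueError("degenerate ROI: no pixel centre falls inside the radius")
    return ROIMask(center_rc=center_rc, diameter_um=diameter_um, pixel_size_um=pixel_size_um, mask=mask)


def integrate_roi(frame: np.ndarray, roi: ROIMask) -> float:
    """Sum of pixel values inside the circular ROI (raw, no normalization).

    Negative pixels are included as-is; the result is a plain additive
    integral so integrate(a*F + b*G) = a*integrate(F) + b*integrate(G).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != roi.mask.shape:
        raise ValueError("frame and ROI mask shapes differ")
    return float(frame[roi.mask].sum())


def nominal_amount(conc_uM: float, pump_volume_mL: float) -> float:
    """Nominal delivered amount: concentration (uM) x pumped volume (mL), a.u.

    The true volume reaching the interface is unknown (fluidic resistance,
    dead volume), but is assumed proportional to the pump displacement, so
    the product serves as the delivered-mass proxy in arbitrary units.
    """
    if conc_uM < 0 or pump_volume_mL < 0:
        raise ValueError("concentration and volume must be nonnegative")
    return conc_uM * pump_volume_mL


@dataclass
class DeliverySummary:
    """Per-event metrics feeding the mass-response aggregation."""

    conc_uM: float
    pump_volume_mL: float
    nominal_amount_au: float
    integrated_signal_au: float
    roi_center_rc: tuple[float, float]
    roi_pixel_count: int
    dip_min: float
    dip_radius_um: float
    dip_recovery_s: float | None
    no_dip: bool
    n_transient_px: int
    n_persistent_px: int

    def to_json(self, path) -> None:
        record = {
            k: (v if not isinstance(v, tuple) else list(v))
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)


def summarize_event(
    stack: ImageStack,
    event: DeliveryEvent,
    roi_diameter_um: float = 166.0,
    roi_center_rc: tuple[float, float] | None = None,
    integration_frames: int = 1,
    k: float = 3.0,
) -> tuple[DeliverySummary, np.ndarray, np.ndarray]:
    """Full single-event analysis: reference, decouple, quantify, integrate.

    The ROI is centred on the centroid of the persistent-chemical mask
    unless an explicit centre is given (manual override); integration uses
    the final frame of the record, or the mean of the last
    ``integration_frames`` frames.  Returns the summary plus the transient
    and persistent masks.
    """
    referenced = reference_event(stack, event)
    sigma = estimate_noise_sigma(referenced, event.pump_on_frame)
    transient, persistent = decouple_phases(referenced, event, k=k, sigma=sigma)
    dip = quantify_dip(referenced, event, k=k, sigma=sigma)

    if roi_center_rc is None:
        if persistent.any():
            com = ndimage.center_of_mass(persistent)
            roi_center_rc = (float(com[0]), float(com[1]))
        else:
            rows, cols = stack.frame_shape
            roi_center_rc = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    roi = circular_roi(roi_center_rc, stack.frame_shape, stack.pixel_size_um, roi_diameter_um)

    n_int = max(1, int(integration_frames))
    final = referenced.frames[-n_int:].astype(np.float64).mean(axis=0)
    integrated = integrate_roi(final, roi)

    summary = DeliverySummary(
        conc_uM=event.conc_uM,
        pump_volume_mL=event.pump_volume_mL,
        nominal_amount_au=nominal_amount(event.conc_uM, event.pump_volume_mL),
        integrated_signal_au=integrated,
        roi_center_rc=roi_center_rc,
        roi_pixel_count=roi.pixel_count,
        dip_min=dip.dip_min,
        dip_radius_um=dip.dip_radius_um,
        dip_recovery_s=dip.recovery_s,
        no_dip=dip.no_dip,
        n_transient_px=int(transient.sum()),
        n_persistent_px=int(persistent.sum()),
    )
    return summary, transient, persistent


def mass_response(summaries: Sequence[DeliverySummary]) -> pd.DataFrame:
    """Group replicate injections into the nominal-amount response table.

    Rows are (concentration, volume) conditions with the nominal amount,
    mean and sample SD of the integrated ROI signal, and replicate count;
    single-replicate conditions report SD 0 with ``n = 1`` flagging the
    degenerate estimate.  Sorted by nominal amount for log-log plotting.
    """
    if not summaries:
        raise ValueError("mass_response needs at least one delivery summary")
    df = pd.DataFrame(
        {
            "conc_uM": [s.conc_uM for s in summaries],
            "pump_volume_mL": [s.pump_volume_mL for s in summaries],
            "nominal_au": [s.nominal_amount_au for s in summaries],
            "integrated_au": [s.integrated_signal_au for s in summaries],
        }
    )
    grouped = (
        df.groupby(["conc_uM", "pump_volume_mL"], sort=False)
        .agg(
            nominal_au=("nominal_au", "first"),
            mean_au=("integrated_au", "mean"),
            sd_au=("integrated_au", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n=("integrated_au", "size"),
        )
        .reset_index()
        .sort_values("nominal_au", ignore_index=True)
    )
    return grouped


def loglog_fit(table: pd.DataFrame) -> tuple[float, float, float]:
    """OLS fit of log10(mean signal) vs log10(nominal amount).

    Returns ``(slope, intercept, r_squared)``; a mass-integrating sensor
    yields slope ~ 1.  Conditions with nonpositive means are excluded.
    """
    sel = (table["nominal_au"] > 0) & (table["mean_au"] > 0)
    if sel.sum() < 2:
        raise ValueError("need at least two positive conditions for a log-log fit")
    x = np.log10(table.loc[sel, "nominal_au"].to_numpy(dtype=float))
    y = np.log10(table.loc[sel, "mean_au"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    fit = slope * x + intercept
    sst = ((y - y.mean()) ** 2).sum()
    sse = ((y - fit) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return float(slope), float(intercept), float(r2)
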