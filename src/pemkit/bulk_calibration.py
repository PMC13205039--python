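"""Ethanol-referenced calibration, pixel-wise regression maps, and LOD.

The bulk analysis converts raw reflected-intensity changes into standard
resonance-angle shift units (mDeg) with a calibration matrix derived from a
1% ethanol control injection, whose bulk refractive-index step corresponds
to a known uniform shift (60 mDeg).  Because the same static illumination
profile multiplies both the ethanol response and the dopamine response,
the per-pixel division inherently corrects for uneven illumination.

Calibrated 10-min endpoint frames for each bulk concentration then feed an
ordinary-least-squares regression of shift versus log10(concentration, nM)
executed independently at every pixel, yielding sensitivity (slope),
intercept and R^2 heatmaps, a global calibration (mean +/- SD over pixels),
and a single-pixel limit of detection

    LOD = 10 ** ((3.3*sigma - intercept) / slope)   [nM]

with sigma the sample SD of the calibrated pre-injection baseline.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image_io import ImageStack, spatial_boxcar

__all__ = [
    "CalibrationMatrix",
    "PixelFitMaps",
    "GlobalCalibration",
    "LODEstimate",
    "nominal_concentration",
    "build_calibration_matrix",
    "calibrate_stack",
    "endpoint_shifts",
    "pixelwise_regression",
    "global_calibration",
    "estimate_lod",
    "export_heatmaps",
    "run_bulk_analysis",
]


def nominal_concentration(stock_nM: float, inject_uL: float, buffer_uL: float = 400.0) -> float:
    """Nominal bulk concentration after injecting a stock aliquot.

    Uses the nominal convention ``c_stock * V_inj / V_buffer`` (the volume
    increment from the aliquot itself is ignored), matching the stated
    series: 4 uL of 10 nM stock into 400 uL -> 0.1 nM.
    """
    if stock_nM < 0 or inject_uL < 0 or buffer_uL <= 0:
        raise ValueError("volumes must be positive and concentration nonnegative")
    return stock_nM * inject_uL / buffer_uL


# --------------------------------------------------------------------------
# Calibration matrix
# --------------------------------------------------------------------------


@dataclass
class CalibrationMatrix:
    """Per-pixel (or global scalar) factor converting intensity to mDeg."""

    factor: np.ndarray  # (rows, cols); in global mode a constant grid
    mode: str
    reference_shift_mdeg: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.factor.shape != self.valid_mask.shape:
            raise ValueError("factor and valid_mask must share a shape")


def _window_mean(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        return frames
    if frames.ndim == 3:
        if frames.shape[0] == 0:
            raise ValueError("empty frame window")
        return frames.mean(axis=0)
    raise ValueError("frame windows must be 2-D frames or 3-D (n, rows, cols)")


def build_calibration_matrix(
    pre_frames: np.ndarray,
    post_frames: np.ndarray,
    reference_shift_mdeg: float = 60.0,
    mode: str = "per_pixel",
    min_delta: float | None = None,
) -> CalibrationMatrix:
    """Derive the intensity-to-mDeg conversion from the ethanol control.

    ``pre_frames``/``post_frames`` are frame windows straddling the ethanol
    step.  The per-pixel factor is ``reference_shift / (mean(post) -
    mean(pre))``; pixels whose |delta| falls below ``min_delta`` (default:
    3x the baseline noise of the window means, estimated from the pre
    window's temporal scatter) are masked invalid and, in ``per_pixel``
    mode, filled with the globally averaged factor — mirroring the global
    fallback used when ethanol-window noise precludes per-pixel
    normalization.  ``global`` mode applies one factor everywhere.
    """
    if mode not in ("per_pixel", "global"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    pre = np.asarray(pre_frames, dtype=np.float64)
    post = np.asarray(post_frames, dtype=np.float64)
    pre_mean = _window_mean(pre)
    post_mean = _window_mean(post)
    if pre_mean.shape != post_mean.shape:
        raise ValueError("pre and post windows must share frame dimensions")
    delta = post_mean - pre_mean
    mean_delta = delta.mean()
    if mean_delta == 0:
        raise ValueError("zero mean intensity change across the ethanol step")

    if min_delta is None:
        if pre.ndim == 3 and pre.shape[0] >= 2:
            sigma_frame = float(np.median(pre.std(axis=0, ddof=1)))
            n_pre = pre.shape[0]
            n_post = post.shape[0] if post.ndim == 3 else 1
            sigma_mean = sigma_frame * np.sqrt(1.0 / n_pre + 1.0 / n_post)
            min_delta = 3.0 * sigma_mean
        else:
            min_delta = 0.0

    valid = np.abs(delta) > min_delta
    if not valid.any():
        raise ValueError("no pixel shows a usable ethanol response above the noise floor")

    if reference_shift_mdeg == 0:
        factor = np.zeros_like(delta)
        return CalibrationMatrix(factor, mode, 0.0, valid)

    global_factor = reference_shift_mdeg / delta[valid].mean()
    if mode == "global":
        factor = np.full_like(delta, reference_shift_mdeg / mean_delta)
        return CalibrationMatrix(factor, mode, reference_shift_mdeg, valid)

    factor = np.full_like(delta, global_factor)
    factor[valid] = reference_shift_mdeg / delta[valid]
    return CalibrationMatrix(factor, mode, reference_shift_mdeg, valid)


def calibrate_stack(stack: ImageStack | np.ndarray, matrix: CalibrationMatrix):
    """Convert background-referenced intensities to mDeg pixel-wise.

    Accepts a full :class:`ImageStack` (returns a stack in mDeg units) or a
    single 2-D difference frame (returns a frame).
    """
    if isinstance(stack, ImageStack):
        if stack.frame_shape != matrix.factor.shape:
            raise ValueError("calibration matrix shape does not match the stack frames")
        return stack.with_frames(stack.frames * matrix.factor[None, :, :])
    frame = np.asarray(stack, dtype=np.float64)
    if frame.shape != matrix.factor.shape:
        raise ValueError("calibration matrix shape does not match the frame")
    return frame * matrix.factor


# --------------------------------------------------------------------------
# Endpoint extraction and pixel-wise regression
# --------------------------------------------------------------------------


def endpoint_shifts(
    stack: ImageStack,
    schedule: list[dict],
    window_s: float = 600.0,
    boxcar_k: int = 5,
    endpoint_avg_frames: int = 1,
) -> tuple[np.ndarray, list[float]]:
    """Per-concentration endpoint difference frames.

    For each dopamine injection in ``schedule`` (entries with a positive
    ``conc_nM``), computes (frame at injection + ``window_s``) minus (frame
    just before that injection), then applies the ``boxcar_k`` spatial
    averaging filter.  ``endpoint_avg_frames`` > 1 replaces the single
    endpoint frame by the mean of the last that many frames of the window.

    Returns ``(frames, conc_nM)`` with ``frames`` of shape
    ``(n_conc, rows, cols)``.
    """
    fps = stack.frame_rate_hz
    frames_out = []
    concs: list[float] = []
    for entry in schedule:
        conc = entry.get("conc_nM")
        if conc is None:
            continue
        idx_inj = stack.frame_index_at(entry["time_s"])
        idx_base = idx_inj - 1
        if idx_base < 0:
            raise ValueError(f"injection at t={entry['time_s']} s has no preceding baseline frame")
        idx_end = int(round((entry["time_s"] + window_s - stack.t0_s) * fps))
        if idx_end >= stack.n_frames:
            raise ValueError(
                f"endpoint window for t={entry['time_s']} s extends past the recorded stack"
            )
        k = max(1, int(endpoint_avg_frames))
        end = stack.frames[idx_end - k + 1 : idx_end + 1].astype(np.float64).mean(axis=0)
        diff = end - stack.frames[idx_base].astype(np.float64)
        frames_out.append(spatial_boxcar(diff, boxcar_k) if boxcar_k > 1 else diff)
        concs.append(float(conc))
    if not frames_out:
        raise ValueError("schedule contains no dopamine injections")
    return np.stack(frames_out), concs


@dataclass
class PixelFitMaps:
    """Per-pixel OLS results of calibrated shift vs log10(concentration)."""

    slope: np.ndarray  # mDeg per log10(nM)
    intercept: np.ndarray  # mDeg
    r_squared: np.ndarray  # in [0, 1]
    n_points: int
    flat_mask: np.ndarray | None = None  # pixels with zero response variance

    def __post_init__(self) -> None:
        if not (self.slope.shape == self.intercept.shape == self.r_squared.shape):
            raise ValueError("fit maps must share a shape")
        self.r_squared = np.clip(self.r_squared, 0.0, 1.0)


def pixelwise_regression(
    endpoint_mdeg_frames: np.ndarray, conc_nM: list[float] | np.ndarray
) -> PixelFitMaps:
    """Independent OLS of calibrated shift vs log10(c, nM) at every pixel.

    Requires at least 3 concentrations.  R^2 is ``1 - SSE/SST``; pixels with
    a flat response (SST = 0) get R^2 = 0 and are flagged in ``flat_mask``.
    """
    y = np.asarray(endpoint_mdeg_frames, dtype=np.float64)
    conc = np.asarray(conc_nM, dtype=np.float64)
    if y.ndim != 3 or y.shape[0] != conc.size:
        raise ValueError("need endpoint frames shaped (n_conc, rows, cols) matching conc list")
    if conc.size < 3:
        raise ValueError("pixel-wise regression requires at least 3 concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive for the log10 axis")
    x = np.log10(conc)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero variance in log-concentration axis")
    xc = (x - x.mean())[:, None, None]
    y_mean = y.mean(axis=0)
    slope = (xc * (y - y_mean)).sum(axis=0) / sxx
    intercept = y_mean - slope * x.mean()
    fit = slope[None] * x[:, None, None] + intercept[None]
    sse = ((y - fit) ** 2).sum(axis=0)
    sst = ((y - y_mean) ** 2).sum(axis=0)
    flat = sst == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
    r2[flat] = 0.0
    return PixelFitMaps(slope, intercept, r2, n_points=conc.size, flat_mask=flat)


@dataclass
class GlobalCalibration:
    """Mean +/- SD of the per-pixel calibration over the valid region."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    n_pixels: int


def global_calibration(
    fit_maps: PixelFitMaps, valid_mask: np.ndarray | None = None
) -> GlobalCalibration:
    """Aggregate pixel fits into a global calibration equation.

    SDs use the sample (n-1) estimator; a single-pixel region reports SD 0.
    """
    if valid_mask is None:
        valid_mask = np.ones(fit_maps.slope.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not valid_mask.any():
        raise ValueError("empty valid-pixel mask")
    slopes = fit_maps.slope[valid_mask]
    intercepts = fit_maps.intercept[valid_mask]
    n = slopes.size
    ddof = 1 if n > 1 else 0
    return GlobalCalibration(
        slope=float(slopes.mean()),
        intercept=float(intercepts.mean()),
        slope_sd=float(slopes.std(ddof=ddof)) if n > 1 else 0.0,
        intercept_sd=float(intercepts.std(ddof=ddof)) if n > 1 else 0.0,
        n_pixels=int(n),
    )


# --------------------------------------------------------------------------
# Limit of detection
# --------------------------------------------------------------------------


@dataclass
class LODEstimate:
    """Single-pixel limit of detection from baseline noise (3.3 sigma)."""

    baseline_sigma_mdeg: float
    slope: float
    intercept: float
    lod_log10_nM: float
    lod_nM: float
    lod_pM: float
    n_baseline: int


def estimate_lod(
    baseline_trace_mdeg: np.ndarray,
    slope: float,
    intercept: float,
    min_baseline_n: int = 200,
    strict: bool = False,
) -> LODEstimate:
    """LOD from the calibrated pre-injection baseline of one pixel.

    sigma is the sample SD (n-1) of the baseline trace; the LOD exponent is
    ``(3.3*sigma - intercept) / slope`` in log10(nM).  A baseline shorter
    than ``min_baseline_n`` samples (the protocol's 200 s at 1 fps) warns,
    or raises under ``strict``.
    """
    if not slope > 0:
        raise ValueError("LOD requires a positive calibration slope")
    trace = np.asarray(baseline_trace_mdeg, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("baseline trace must be 1-D with at least 2 samples")
    if trace.size < min_baseline_n:
        msg = f"baseline of {trace.size} samples is shorter than the {min_baseline_n}-sample floor"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    sigma = float(trace.std(ddof=1))
    lod_log10 = (3.3 * sigma - intercept) / slope
    lod_nM = float(10.0**lod_log10)
    return LODEstimate(
        baseline_sigma_mdeg=sigma,
        slope=float(slope),
        intercept=float(intercept),
        lod_log10_nM=float(lod_log10),
        lod_nM=lod_nM,
        lod_pM=1000.0 * lod_nM,
        n_baseline=int(trace.size),
    )


# --------------------------------------------------------------------------
# Export / pipeline
# --------------------------------------------------------------------------


def export_heatmaps(
    fit_maps: PixelFitMaps, out_dir: str | os.PathLike, prefix: str = "bulk"
) -> dict[str, str]:
    """Write sensitivity/linearity maps as float TIFFs, figures, and a CSV.

    Produces ``<prefix>_slope.tif``, ``<prefix>_intercept.tif`` and
    ``<prefix>_r_squared.tif`` (float32 pixel values equal to the map
    values), rendered PNG heatmaps for slope and R^2, and a CSV of
    distribution statistics per map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    maps = {
        "slope": fit_maps.slope,
        "intercept": fit_maps.intercept,
        "r_squared": fit_maps.r_squared,
    }
    stats = []
    for name, grid in maps.items():
        tif_path = out / f"{prefix}_{name}.tif"
        tifffile.imwrite(tif_path, grid.astype(np.float32))
        paths[f"{name}_tif"] = str(tif_path)
        stats.append(
            {
                "map": name,
                "mean": float(np.mean(grid)),
                "sd": float(np.std(grid, ddof=1)) if grid.size > 1 else 0.0,
                "min": float(np.min(grid)),
                "max": float(np.max(grid)),
            }
        )
    for name, label in (("slope", "sensitivity (mDeg/log(nM))"), ("r_squared", "R$^2$")):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(maps[name], cmap="viridis")
        fig.colorbar(im, ax=ax, label=label)
        ax.set_title(f"{name} heatmap")
        png_path = out / f"{prefix}_{name}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths[f"{name}_png"] = str(png_path)
    csv_path = out / f"{prefix}_map_stats.csv"
    pd.DataFrame(stats).to_csv(csv_path, index=False)
    paths["stats_csv"] = str(csv_path)
    return paths


def run_bulk_analysis(
    stack: ImageStack,
    schedule: list[dict],
    ethanol_time_s: float | None = None,
    reference_shift_mdeg: float = 60.0,
    mode: str = "per_pixel",
    window_s: float = 600.0,
    ethanol_pre_s: float = 30.0,
    ethanol_settle_s: float = 10.0,
    ethanol_post_s: float = 30.0,
    baseline_end_s: float | None = None,
    n_lod_pixels: int = 3,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Full bulk pipeline: calibrate, regress, aggregate, estimate LOD.

    ``schedule`` lists injections as dicts (``time_s``, ``label``,
    ``conc_nM`` with ``None``/missing for the ethanol control).  The
    ethanol step time defaults to the entry labelled ``ethanol``.  The LOD
    is computed at ``n_lod_pixels`` randomly chosen pixels on the
    calibrated pre-injection baseline; the reported exponent is their mean
    +/- SD, following the random-pixel protocol.
    """
    rng = np.random.default_rng(seed)
    if ethanol_time_s is None:
        eth = [e for e in schedule if e.get("label") == "ethanol" or e.get("conc_nM") is None]
        if not eth:
            raise ValueError("schedule has no ethanol control entry and none was specified")
        ethanol_time_s = eth[0]["time_s"]

    fps = stack.frame_rate_hz
    i_eth = stack.frame_index_at(ethanol_time_s)
    n_pre = max(1, int(round(ethanol_pre_s * fps)))
    n_settle = int(round(ethanol_settle_s * fps))
    n_post = max(1, int(round(ethanol_post_s * fps)))
    pre = stack.frames[max(0, i_eth - n_pre) : i_eth].astype(np.float64)
    post_start = i_eth + n_settle
    post = stack.frames[post_start : post_start + n_post].astype(np.float64)
    if post.shape[0] == 0:
        raise ValueError("ethanol post-step window extends past the recorded stack")
    matrix = build_calibration_matrix(pre, post, reference_shift_mdeg, mode=mode)

    raw_endpoints, concs = endpoint_shifts(stack, schedule, window_s=window_s)
    calibrated = np.stack([calibrate_stack(frame, matrix) for frame in raw_endpoints])
    fits = pixelwise_regression(calibrated, concs)
    glob = global_calibration(fits, valid_mask=None if mode == "global" else matrix.valid_mask)

    first_inj = min(e["time_s"] for e in schedule if e.get("conc_nM") is not None)
    if baseline_end_s is None:
        baseline_end_s = first_inj
    i_base_end = stack.frame_index_at(baseline_end_s)
    if i_base_end < 2:
        raise ValueError("no pre-injection baseline available for LOD estimation")
    rows, cols = stack.frame_shape
    lods = []
    for _ in range(n_lod_pixels):
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        trace = stack.frames[:i_base_end, r, c].astype(np.float64) * matrix.factor[r, c]
        lods.append(estimate_lod(trace, glob.slope, glob.intercept, strict=False))
    exponents = np.array([l.lod_log10_nM for l in lods])

    result = {
        "matrix": matrix,
        "fit_maps": fits,
        "global_calibration": glob,
        "lod_estimates": lods,
        "lod_log10_nM_mean": float(exponents.mean()),
        "lod_log10_nM_sd": float(exponents.std(ddof=1)) if len(lods) > 1 else 0.0,
        "lod_pM_mean": float(1000.0 * 10.0 ** exponents.mean()),
        "concentrations_nM": concs,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result["heatmap_paths"] = export_heatmaps(fits, out)
        report = {
            "global_slope_mdeg_per_log_nM": glob.slope,
            "global_slope_sd": glob.slope_sd,
            "global_intercept_mdeg": glob.intercept,
            "global_intercept_sd": glob.intercept_sd,
            "n_valid_pixels": glob.n_pixels,
            "lod_log10_nM_mean": result["lod_log10_nM_mean"],
            "lod_log10_nM_sd": result["lod_log10_nM_sd"],
            "lod_pM_mean": result["lod_pM_mean"],
            "calibration_mode": mode,
            "n_lod_pixels": n_lod_pixels,
        }
        with open(out / "lod_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        result["report_path"] = str(out / "lod_report.json")
    return result
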