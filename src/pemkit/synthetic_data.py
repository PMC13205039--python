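"""Physically grounded synthetic PEM image stacks with a ground-truth ledger.

The simulator emulates the two experiment classes the analysis pipeline is
built for:

* **Bulk sequential injection** — a 1 fps recording of an equilibration
  baseline followed by stepwise dopamine injections.  Each injection adds a
  transient optical spike plus a saturating film-growth signal whose endpoint
  obeys the log-concentration calibration law ``S*log10(c_nM) + B``; a
  terminal 1% ethanol control produces an ideal uniform 60 mDeg bulk
  refractive-index step used for intensity-to-mDeg calibration.
* **Localized delivery** — a 50 fps recording of a micropipette injection:
  a transient circular negative dip (hydrodynamic deformation of the sensor
  film), a persistent asymmetric polydopamine deposit, a slowly growing
  diffusion halo, and static point-scatterer wakes with parabolic tails.

Resonance-angle shift fields (mDeg) are converted to camera intensities
either through a linear working-point slope or through a Kretschmann
transfer-matrix reflectivity model of the prism/Ti/Au/water multilayer, then
multiplied by a static illumination field; static sinusoidal interference
fringes and i.i.d. Gaussian pixel noise are added on top.  Every run emits a
:class:`GroundTruth` ledger recording the true parameters, rendered truth
components, and per-pixel class masks, so each analysis stage can be tested
against known truth.  Identical ``(config, seed)`` pairs produce identical
stacks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .image_io import ImageStack

__all__ = [
    "Layer",
    "LayerStack",
    "TransductionModel",
    "GrowthKinetics",
    "FringeConfig",
    "IlluminationConfig",
    "BulkConfig",
    "DipTruth",
    "DepositTruth",
    "HaloTruth",
    "LocalConfig",
    "LocalEventTruth",
    "GroundTruth",
    "fresnel_reflectivity",
    "working_point",
    "film_growth_mdeg",
    "psf_kernel",
    "fringe_pattern",
    "add_fringes",
    "illumination_field",
    "simulate_bulk",
    "simulate_local",
    "default_gold_stack",
]


# --------------------------------------------------------------------------
# Kretschmann multilayer optics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Layer:
    """One stratum of the optical multilayer.

    ``thickness_nm=None`` marks a semi-infinite bounding medium (the prism
    on the incidence side, the aqueous buffer on the exit side).
    """

    refractive_index: complex
    thickness_nm: float | None = None


@dataclass(frozen=True)
class LayerStack:
    """Ordered multilayer, incidence side first, at one working wavelength."""

    layers: tuple[Layer, ...]
    wavelength_nm: float

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a layer stack needs at least two bounding media")
        if self.layers[0].thickness_nm is not None or self.layers[-1].thickness_nm is not None:
            raise ValueError("first and last layers must be semi-infinite (thickness None)")
        for lay in self.layers[1:-1]:
            if lay.thickness_nm is None or lay.thickness_nm < 0:
                raise ValueError("interior layers need nonnegative finite thickness")
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength must be positive")


def default_gold_stack() -> LayerStack:
    """Prism / 2 nm Ti / 50 nm Au / water fixture at 690 nm.

    The metal optical constants are fixture values for the simulator, not
    measured material claims.
    """
    return LayerStack(
        layers=(
            Layer(1.515),
            Layer(2.48 + 3.43j, 2.0),
            Layer(0.14 + 4.05j, 50.0),
            Layer(1.33),
        ),
        wavelength_nm=690.0,
    )


def fresnel_reflectivity(angle_deg, layer_stack: LayerStack):
    """p-polarised reflectance of a stratified multilayer.

    Uses the characteristic (transfer) matrix of each interior layer for
    p-polarisation.  ``angle_deg`` is the angle of incidence inside the
    first (prism) medium and may be a scalar or array; the return value is
    the reflectance fraction in [0, 1] (exactly 1 for lossless total
    internal reflection).
    """
    angles = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    if np.any((angles <= 0.0) | (angles >= 90.0)):
        raise ValueError("incidence angle must lie strictly between 0 and 90 degrees")
    layers = layer_stack.layers
    n = np.array([lay.refractive_index for lay in layers], dtype=complex)
    k0 = 2.0 * np.pi / layer_stack.wavelength_nm  # rad/nm
    kx = n[0].real * k0 * np.sin(np.deg2rad(angles))  # conserved transverse wavevector
    kz = np.sqrt((n[:, None] * k0) ** 2 - kx[None, :] ** 2 + 0j)
    kz = np.where(kz.imag < 0, -kz, kz)  # decaying/outgoing branch
    q = kz / n[:, None] ** 2  # p-pol admittance (up to a constant factor)

    m11 = np.ones_like(kx, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for j in range(1, len(layers) - 1):
        beta = kz[j] * layers[j].thickness_nm
        c, s = np.cos(beta), np.sin(beta)
        a11, a12 = c, -1j * s / q[j]
        a21, a22 = -1j * q[j] * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )
    q0, qs = q[0], q[-1]
    num = q0 * (m11 + m12 * qs) - (m21 + m22 * qs)
    den = q0 * (m11 + m12 * qs) + (m21 + m22 * qs)
    r = num / den
    refl = np.abs(r) ** 2
    return float(refl[0]) if np.isscalar(angle_deg) else refl


# --------------------------------------------------------------------------
# Working point / transduction
# --------------------------------------------------------------------------


@dataclass
class TransductionModel:
    """Conversion between resonance-angle shift (mDeg) and camera intensity.

    In ``linear`` mode the intensity is ``reference + local_slope * mdeg``
    with a configured working-point slope, so analysis tests need not depend
    on optics fixtures.  In ``fresnel`` mode the intensity is
    ``reference * R(working_angle - mdeg/1000)``: a positive resonance shift
    moves the effective angle further below the reflectivity minimum and
    brightens the image, matching the bright-spot signature of deposition.
    """

    mode: str = "linear"
    working_angle_deg: float | None = None
    local_slope: float = 1.0  # intensity units per mDeg at the working angle
    reference_intensity: float = 100.0
    layer_stack: LayerStack | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "fresnel"):
            raise ValueError(f"unknown transduction mode {self.mode!r}")
        if self.mode == "linear" and self.local_slope == 0:
            raise ValueError("linear transduction requires a nonzero local slope")
        if self.mode == "fresnel" and (self.layer_stack is None or self.working_angle_deg is None):
            raise ValueError("fresnel transduction requires a layer stack and working angle")

    def intensity(self, mdeg) -> np.ndarray:
        """Camera intensity for a resonance-shift field in mDeg."""
        mdeg = np.asarray(mdeg, dtype=np.float64)
        if self.mode == "linear":
            return self.reference_intensity + self.local_slope * mdeg
        eff = self.working_angle_deg - mdeg / 1000.0
        refl = fresnel_reflectivity(eff.ravel(), self.layer_stack).reshape(mdeg.shape)
        return self.reference_intensity * refl


def working_point(
    layer_stack: LayerStack | TransductionModel,
    offset_deg: float = 1.0,
    angle_range_deg: tuple[float, float] = (60.0, 80.0),
    n_scan: int = 4001,
    reference_intensity: float = 100.0,
) -> TransductionModel:
    """Fix the imaging angle slightly below the reflectivity minimum.

    Scans the p-polarised reflectivity curve, refines the minimum with a
    parabolic fit, and places the working angle ``offset_deg`` below it.
    The local slope is the finite-difference derivative of intensity with
    respect to a resonance-angle shift at that angle (positive below
    resonance: film growth brightens the image).

    A linear-mode :class:`TransductionModel` passed in is returned
    unchanged (its configured slope already is the working point).
    """
    if isinstance(layer_stack, TransductionModel):
        if layer_stack.mode == "linear":
            return layer_stack
        layer_stack = layer_stack.layer_stack
    lo, hi = angle_range_deg
    angles = np.linspace(lo, hi, n_scan)
    refl = fresnel_reflectivity(angles, layer_stack)
    i_min = int(np.argmin(refl))
    if i_min in (0, n_scan - 1):
        raise ValueError("no interior reflectivity minimum in the scanned angle range")
    # parabolic refinement of the minimum position
    y0, y1, y2 = refl[i_min - 1 : i_min + 2]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = angles[1] - angles[0]
    angle_min = angles[i_min] + shift * step
    working = angle_min - offset_deg
    h = 1e-3  # deg
    dref = (
        fresnel_reflectivity(working + h, layer_stack)
        - fresnel_reflectivity(working - h, layer_stack)
    ) / (2 * h)
    # a +delta mDeg resonance shift lowers the effective angle: dI/ddelta = -I0 R'/1000
    local_slope = -reference_intensity * dref / 1000.0
    return TransductionModel(
        mode="fresnel",
        working_angle_deg=working,
        local_slope=float(local_slope),
        reference_intensity=reference_intensity,
        layer_stack=layer_stack,
    )


# --------------------------------------------------------------------------
# Film-growth kinetics
# --------------------------------------------------------------------------


@dataclass
class GrowthKinetics:
    """Saturating polydopamine film-growth law with injection artifact.

    The endpoint resonance shift for a bulk concentration ``c`` (nM) follows
    the calibration law ``S*log10(c) + B`` (defaults 40 and 79 mDeg); growth
    approaches it with time constant ``tau_s`` (150 s reaches >98% of the
    endpoint within the 10-min observation window).  Each injection also
    adds a short-lived optical spike from the injection perturbation.
    """

    sensitivity_S: float = 40.0  # mDeg per log10(nM)
    offset_B: float = 79.0  # mDeg
    tau_s: float = 150.0
    spike_amplitude_mdeg: float = 20.0
    spike_decay_s: float = 3.0

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError("tau_s must be positive")
        if not self.sensitivity_S > 0:
            raise ValueError("sensitivity_S must be positive")

    def endpoint_mdeg(self, conc_nM: float) -> float:
        if not conc_nM > 0:
            raise ValueError("concentration must be positive")
        return self.sensitivity_S * np.log10(conc_nM) + self.offset_B


def film_growth_mdeg(t_s, conc_nM: float, kinetics: GrowthKinetics) -> np.ndarray:
    """Resonance shift of the growing film at time ``t_s`` after injection.

    Zero at t=0, monotone nondecreasing, approaching
    ``S*log10(c_nM) + B`` as t -> infinity.
    """
    endpoint = kinetics.endpoint_mdeg(conc_nM)
    t = np.asarray(t_s, dtype=np.float64)
    growth = endpoint * (1.0 - np.exp(-np.clip(t, 0.0, None) / kinetics.tau_s))
    return growth if growth.shape else float(growth)


# --------------------------------------------------------------------------
# Point-spread function
# --------------------------------------------------------------------------


def psf_kernel(
    pixel_size_um: float,
    sigma_perp_um: float = 0.85,
    decay_par_um: float = 20.0,
    mode: str = "exp",
    wake_wavelength_um: float = 6.0,
    wake_strength: float = 0.5,
    n_sigma: float = 4.0,
    n_decay: float = 5.0,
) -> np.ndarray:
    """Anisotropic SPR imaging point-spread function, unit sum.

    Perpendicular to plasmon propagation (rows) the response is Gaussian
    with ``FWHM = 2.355*sigma_perp`` (~2 um for the default 0.85 um sigma);
    along propagation (+columns) it decays one-sidedly with length
    ``decay_par_um`` (tens of micrometres, set by the plasmon propagation
    length).  Modes:

    ``exp``
        Gaussian(perp) x one-sided exponential(par); the default.
    ``sym``
        Gaussian(perp) x symmetric exponential(par); used to smear broad
        fields without displacing them.
    ``wake``
        ``exp`` plus an interference term oscillating on the constant
        path-difference surfaces ``r - x = const``, producing the parabolic
        wavefront tails observed behind point scatterers.
    """
    if pixel_size_um <= 0 or sigma_perp_um <= 0 or decay_par_um <= 0:
        raise ValueError("pixel size and PSF scales must be positive")
    if mode not in ("exp", "sym", "wake"):
        raise ValueError(f"unknown PSF mode {mode!r}")
    half_rows = max(1, int(np.ceil(n_sigma * sigma_perp_um / pixel_size_um)))
    half_cols = max(1, int(np.ceil(n_decay * decay_par_um / pixel_size_um)))
    y = (np.arange(-half_rows, half_rows + 1) * pixel_size_um)[:, None]
    x = (np.arange(-half_cols, half_cols + 1) * pixel_size_um)[None, :]
    gauss = np.exp(-0.5 * (y / sigma_perp_um) ** 2)
    if mode == "sym":
        kern = gauss * np.exp(-np.abs(x) / decay_par_um)
    else:
        kern = gauss * np.exp(-x / decay_par_um) * (x >= 0)
        if mode == "wake":
            r = np.hypot(x, y)
            phase = 2.0 * np.pi * (r - x) / wake_wavelength_um
            wake = (
                wake_strength
                * np.exp(-r / decay_par_um)
                * np.cos(phase)
                / (1.0 + r / wake_wavelength_um)
            )
            kern = kern + np.where(x >= 0, wake, 0.0)
    total = kern.sum()
    if not total > 0:
        raise ValueError("degenerate PSF: kernel sum is not positive")
    return kern / total


# --------------------------------------------------------------------------
# Static artifacts: fringes and illumination
# --------------------------------------------------------------------------


@dataclass
class FringeConfig:
    """Static low-spatial-frequency interference fringes (ribbon patterns)."""

    amplitude_au: float = 1.0
    wavelength_um: float = 40.0
    angle_deg: float = 20.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_au < 0:
            raise ValueError("fringe amplitude must be nonnegative")
        if not self.wavelength_um > 0:
            raise ValueError("fringe wavelength must be positive")


def fringe_pattern(shape: tuple[int, int], pixel_size_um: float, cfg: FringeConfig) -> np.ndarray:
    """Render the static sinusoidal fringe field (peak-to-peak 2*amplitude)."""
    rows, cols = shape
    y = np.arange(rows)[:, None] * pixel_size_um
    x = np.arange(cols)[None, :] * pixel_size_um
    ang = np.deg2rad(cfg.angle_deg)
    proj = x * np.cos(ang) + y * np.sin(ang)
    return cfg.amplitude_au * np.sin(2.0 * np.pi * proj / cfg.wavelength_um + cfg.phase_rad)


def add_fringes(frame_field: np.ndarray, cfg: FringeConfig, pixel_size_um: float = 1.0) -> np.ndarray:
    """Add the static fringe pattern to a frame field (identity at amplitude 0)."""
    frame_field = np.asarray(frame_field, dtype=np.float64)
    if cfg.amplitude_au == 0:
        return frame_field.copy()
    return frame_field + fringe_pattern(frame_field.shape, pixel_size_um, cfg)


@dataclass
class IlluminationConfig:
    """Smooth static illumination field: 1 + linear gradients across the frame."""

    gradient_row: float = 0.2
    gradient_col: float = 0.3


def illumination_field(shape: tuple[int, int], cfg: IlluminationConfig) -> np.ndarray:
    rows, cols = shape
    rr = np.linspace(-0.5, 0.5, rows)[:, None]
    cc = np.linspace(-0.5, 0.5, cols)[None, :]
    g = 1.0 + cfg.gradient_row * rr + cfg.gradient_col * cc
    if np.any(g <= 0):
        raise ValueError("illumination gradients must keep the field positive")
    return g


# --------------------------------------------------------------------------
# Ground truth ledger
# --------------------------------------------------------------------------


@dataclass
class LocalEventTruth:
    """True parameters and rendered truth components of one delivery event."""

    center_rc: tuple[float, float]
    dip: dict
    deposit: dict
    halo: dict
    scatterers: list[dict]
    mask_threshold_mdeg: float
    class_masks: dict[str, np.ndarray]
    dip_field_peak: np.ndarray  # rendered (post-PSF) dip field at its worst frame
    deposit_field_final: np.ndarray
    halo_field_final: np.ndarray
    w1_true: np.ndarray  # pump-window mean of the noise-free mDeg field
    w2_true: np.ndarray  # late-window mean of the noise-free mDeg field
    dip_half_min_radius_um: float
    integrated_chemical_mdeg: float  # sum over final deposit+halo truth field
    pump_on_frame: int
    pump_off_frame: int
    mass_scale: float


@dataclass
class GroundTruth:
    """Simulator ledger: everything needed to score an analysis against truth."""

    seed: int
    pixel_size_um: float
    frame_rate_hz: float
    noise_sigma_au: float
    illumination: np.ndarray
    fringes: np.ndarray
    transduction: dict
    kinetics: GrowthKinetics | None = None
    schedule: list[dict] | None = None
    ethanol: dict | None = None
    mdeg_trace: np.ndarray | None = None  # bulk: spatially uniform true mDeg vs time
    endpoint_increment_mdeg: dict | None = None  # conc label -> true endpoint increment
    events: list[LocalEventTruth] | None = None
    scatter_field: np.ndarray | None = None

    def to_json_dict(self) -> dict[str, Any]:
        """JSON-safe summary: scalars verbatim, arrays as shape + SHA-256 digest.

        Hashing the arrays keeps the serialized ledger compact while still
        letting byte-identity of reruns be checked.
        """

        def enc(value):
            if isinstance(value, np.ndarray):
                return {
                    "shape": list(value.shape),
                    "dtype": str(value.dtype),
                    "sha256": hashlib.sha256(np.ascontiguousarray(value).tobytes()).hexdigest(),
                }
            if isinstance(value, (np.floating, np.integer)):
                return value.item()
            if isinstance(value, GrowthKinetics):
                return dataclasses.asdict(value)
            if isinstance(value, LocalEventTruth):
                return {k: enc(v) for k, v in dataclasses.asdict(value).items()}
            if isinstance(value, dict):
                return {str(k): enc(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [enc(v) for v in value]
            return value

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Bulk sequential-injection simulation
# --------------------------------------------------------------------------


@dataclass
class BulkConfig:
    """Study conditions for the bulk sequential-injection experiment.

    Defaults reproduce the protocol the analysis targets: 1 fps, 2-min
    equilibration, five ten-minute injection windows reaching 0.1, 1, 10,
    100 and 1000 nM, then a 1% ethanol control worth a uniform 60 mDeg.
    """

    shape: tuple[int, int] = (480, 640)
    pixel_size_um: float = 0.94
    frame_rate_hz: float = 1.0
    equilibration_s: float = 120.0
    window_s: float = 600.0
    concentrations_nM: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    ethanol_window_s: float = 120.0
    ethanol_shift_mdeg: float = 60.0
    kinetics: GrowthKinetics = field(default_factory=GrowthKinetics)
    transduction_mode: str = "linear"
    reference_intensity: float = 100.0
    linear_slope_au_per_mdeg: float = 1.0
    working_offset_deg: float = 1.0
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)
    fringes: FringeConfig = field(default_factory=FringeConfig)
    noise_sigma_au: float = 1.5

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations_nM):
            raise ValueError("all scheduled concentrations must be positive")
        if self.noise_sigma_au < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.equilibration_s < 0 or self.window_s <= 0:
            raise ValueError("equilibration and window durations must be valid")

    def schedule(self) -> list[dict]:
        """Injection schedule entries (time_s, label, conc_nM), ethanol last."""
        entries = []
        for i, conc in enumerate(self.concentrations_nM):
            entries.append(
                {
                    "time_s": self.equilibration_s + i * self.window_s,
                    "label": f"DA_{conc:g}nM",
                    "conc_nM": float(conc),
                }
            )
        entries.append(
            {
                "time_s": self.equilibration_s + len(self.concentrations_nM) * self.window_s,
                "label": "ethanol",
                "conc_nM": None,
            }
        )
        return entries

    def n_frames(self) -> int:
        total_s = (
            self.equilibration_s
            + len(self.concentrations_nM) * self.window_s
            + self.ethanol_window_s
        )
        return int(round(total_s * self.frame_rate_hz))


def _build_transduction(cfg) -> TransductionModel:
    if cfg.transduction_mode == "linear":
        return TransductionModel(
            mode="linear",
            local_slope=cfg.linear_slope_au_per_mdeg,
            reference_intensity=cfg.reference_intensity,
        )
    stack = default_gold_stack()
    return working_point(
        stack, offset_deg=cfg.working_offset_deg, reference_intensity=cfg.reference_intensity
    )


def simulate_bulk(config: BulkConfig, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Simulate a bulk sequential-injection PEM stack with ground truth.

    The true resonance-shift trace is spatially uniform (the film grows
    everywhere); spatial structure in the recorded intensities comes from
    the illumination field, static fringes, and pixel noise — exactly the
    nuisances the per-pixel ethanol calibration is designed to remove.
    """
    rng = np.random.default_rng(seed)
    kin = config.kinetics
    n_frames = config.n_frames()
    t = np.arange(n_frames) / config.frame_rate_hz

    mdeg_t = np.zeros(n_frames)
    schedule = config.schedule()
    endpoint_increment: dict[str, float] = {}
    for entry in schedule:
        t_inj = entry["time_s"]
        dt = t - t_inj
        # effects begin strictly after the injection timestamp, so the frame
        # at t_inj (the previous window's 10-min endpoint) is uncontaminated
        active = dt > 0
        if entry["label"] == "ethanol":
            mdeg_t[active] += config.ethanol_shift_mdeg
            continue
        endpoint = kin.endpoint_mdeg(entry["conc_nM"])
        mdeg_t[active] += endpoint * (1.0 - np.exp(-dt[active] / kin.tau_s))
        mdeg_t[active] += kin.spike_amplitude_mdeg * np.exp(-dt[active] / kin.spike_decay_s)
        endpoint_increment[entry["label"]] = endpoint * (
            1.0 - np.exp(-config.window_s / kin.tau_s)
        )

    model = _build_transduction(config)
    illum = illumination_field(config.shape, config.illumination)
    fringes = fringe_pattern(config.shape, config.pixel_size_um, config.fringes)

    frames = np.empty((n_frames,) + tuple(config.shape), dtype=np.float32)
    base = model.intensity(mdeg_t)  # (T,) in linear mode; elementwise otherwise
    frames[:] = illum[None, :, :] * np.asarray(base)[:, None, None]
    frames += fringes[None, :, :].astype(np.float32)
    if config.noise_sigma_au > 0:
        frames += config.noise_sigma_au * rng.standard_normal(frames.shape, dtype=np.float32)

    stack = ImageStack(
        frames,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
    )
    truth = GroundTruth(
        seed=seed,
        pixel_size_um=config.pixel_size_um,
        frame_rate_hz=config.frame_rate_hz,
        noise_sigma_au=config.noise_sigma_au,
        illumination=illum,
        fringes=fringes,
        transduction={
            "mode": model.mode,
            "local_slope": model.local_slope,
            "reference_intensity": model.reference_intensity,
            "working_angle_deg": model.working_angle_deg,
        },
        kinetics=kin,
        schedule=schedule,
        ethanol={
            "time_s": schedule[-1]["time_s"],
            "shift_mdeg": config.ethanol_shift_mdeg,
        },
        mdeg_trace=mdeg_t,
        endpoint_increment_mdeg=endpoint_increment,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Localized-delivery simulation
# --------------------------------------------------------------------------


@dataclass
class DipTruth:
    """Transient hydrodynamic dip: a radially symmetric raised-cosine dome.

    The footprint expands rapidly at the start of delivery: radius and
    (negative) amplitude grow linearly over ``rise_s`` seconds to
    ``max_radius_um`` and ``amplitude_mdeg``, then hold while the pump is
    on; after pump-off the amplitude decays exponentially with ``decay_s``
    and the footprint dissipates in place.
    """

    max_radius_um: float = 50.0
    amplitude_mdeg: float = -60.0
    rise_s: float = 1.0
    decay_s: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude_mdeg > 0:
            raise ValueError("dip amplitude must be negative (dark region)")
        if self.max_radius_um <= 0 or self.decay_s <= 0 or self.rise_s <= 0:
            raise ValueError("dip radius, rise and decay must be positive")


@dataclass
class DepositTruth:
    """Persistent polydopamine deposit: skewed anisotropic Gaussian spot."""

    amplitude_mdeg: float = 40.0
    sigma_row_um: float = 12.0
    sigma_col_um: float = 20.0
    skew: float = 0.5  # relative widening/narrowing downstream/upstream
    offset_um: tuple[float, float] = (0.0, 8.0)  # (row, col) offset from dip centre
    saturation_tau_s: float = 5.0

    def __post_init__(self) -> None:
        if self.amplitude_mdeg < 0:
            raise ValueError("deposit amplitude must be nonnegative (bright spot)")
        if not (0 <= self.skew < 1):
            raise ValueError("skew must lie in [0, 1)")


@dataclass
class HaloTruth:
    """Slowly growing annular halo from radial diffusion of unconfined dopamine."""

    amplitude_mdeg: float = 5.0
    inner_radius_um: float = 25.0
    outer_radius_um: float = 60.0
    growth_tau_s: float = 30.0

    def __post_init__(self) -> None:
        if self.amplitude_mdeg < 0:
            raise ValueError("halo amplitude must be nonnegative")
        if not self.outer_radius_um > self.inner_radius_um > 0:
            raise ValueError("halo radii must satisfy 0 < inner < outer")


@dataclass
class LocalConfig:
    """Study conditions for a localized micropipette-delivery recording.

    Defaults: 50 fps, 20 s record, pump on from 1 to 4 s, 1 uM dopamine
    driven by a 10 mL syringe.  ``mass_scale`` rescales the delivered mass:
    deposit/halo amplitudes scale with sqrt(mass) and their spatial axes
    with mass^(1/4), so the integrated chemical signal is proportional to
    the delivered mass.
    """

    shape: tuple[int, int] = (480, 640)
    pixel_size_um: float = 0.94
    frame_rate_hz: float = 50.0
    duration_s: float = 20.0
    pump_on_s: float = 1.0
    pump_off_s: float = 4.0
    conc_uM: float = 1.0
    pump_volume_mL: float = 10.0
    mass_scale: float = 1.0
    center_frac: tuple[float, float] = (0.5, 0.5)
    dip: DipTruth = field(default_factory=DipTruth)
    deposit: DepositTruth = field(default_factory=DepositTruth)
    halo: HaloTruth = field(default_factory=HaloTruth)
    n_scatterers: int = 5
    scatterer_strength_au: float = 3.0
    psf_sigma_perp_um: float = 0.85
    psf_decay_par_um: float = 20.0
    wake_wavelength_um: float = 6.0
    transduction_mode: str = "linear"
    reference_intensity: float = 100.0
    linear_slope_au_per_mdeg: float = 1.0
    working_offset_deg: float = 1.0
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)
    fringes: FringeConfig = field(default_factory=FringeConfig)
    noise_sigma_au: float = 1.5
    mask_threshold_mdeg: float | None = None  # default: 3 x noise sigma (mDeg equivalent)

    def __post_init__(self) -> None:
        if not 0 <= self.pump_on_s < self.pump_off_s < self.duration_s:
            raise ValueError("need 0 <= pump_on < pump_off < duration")
        if self.mass_scale <= 0:
            raise ValueError("mass_scale must be positive")
        if self.noise_sigma_au < 0:
            raise ValueError("noise sigma must be nonnegative")

    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def _dome(r_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Raised-cosine dome of unit peak, support r < radius."""
    if radius_um <= 0:
        return np.zeros_like(r_um)
    inside = r_um < radius_um
    out = np.zeros_like(r_um)
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * r_um[inside] / radius_um))
    return out


def _convolve_field(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(field, kernel, mode="same")


def simulate_local(config: LocalConfig, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Simulate a localized-delivery PEM stack with ground truth.

    The time-dependent resonance-shift field is the sum of the transient
    dip, the persistent deposit and the growing halo, smeared with the
    symmetric-variant anisotropic PSF (broad fields are blurred by the
    finite plasmon propagation length without being displaced, keeping the
    configured event geometry the literal truth).  Point-scatterer wakes
    (one-sided, parabolic tails) and fringes are static background and
    cancel under event-referenced background subtraction.
    """
    rng = np.random.default_rng(seed)
    rows, cols = config.shape
    px = config.pixel_size_um
    n_frames = config.n_frames()
    t = np.arange(n_frames) / config.frame_rate_hz
    i_on = int(round(config.pump_on_s * config.frame_rate_hz))
    i_off = int(round(config.pump_off_s * config.frame_rate_hz))
    if not 0 <= i_on < i_off < n_frames:
        raise ValueError("pump interval does not fit within the stack duration")

    c_row = config.center_frac[0] * (rows - 1)
    c_col = config.center_frac[1] * (cols - 1)
    yy = (np.arange(rows)[:, None] - c_row) * px
    xx = (np.arange(cols)[None, :] - c_col) * px
    r = np.hypot(yy, xx)

    m = config.mass_scale
    amp_scale = np.sqrt(m)
    axis_scale = m**0.25

    # --- static chemical patterns (unit time profile applied later) ---
    dep = config.deposit
    d_row = yy - dep.offset_um[0]
    d_col = xx - dep.offset_um[1]
    sig_row = dep.sigma_row_um * axis_scale
    sig_col = np.where(
        d_col >= 0,
        dep.sigma_col_um * (1.0 + dep.skew) * axis_scale,
        dep.sigma_col_um * (1.0 - dep.skew) * axis_scale,
    )
    deposit_pattern = dep.amplitude_mdeg * amp_scale * np.exp(
        -0.5 * ((d_row / sig_row) ** 2 + (d_col / sig_col) ** 2)
    )

    halo = config.halo
    r_in = halo.inner_radius_um * axis_scale
    r_out = halo.outer_radius_um * axis_scale
    band = (r >= r_in) & (r <= r_out)
    halo_pattern = np.zeros_like(r)
    halo_pattern[band] = (
        halo.amplitude_mdeg * amp_scale * np.sin(np.pi * (r[band] - r_in) / (r_out - r_in)) ** 2
    )

    field_kernel = psf_kernel(
        px,
        sigma_perp_um=config.psf_sigma_perp_um,
        decay_par_um=config.psf_decay_par_um,
        mode="sym",
    )
    deposit_c = _convolve_field(deposit_pattern, field_kernel)
    halo_c = _convolve_field(halo_pattern, field_kernel)
    dome_full_c = _convolve_field(
        config.dip.amplitude_mdeg * _dome(r, config.dip.max_radius_um), field_kernel
    )

    # --- time profiles ---
    rise_frac = np.clip((t - config.pump_on_s) / config.dip.rise_s, 0.0, 1.0)
    dip_amp = np.where(
        t < config.pump_on_s,
        0.0,
        np.where(
            t < config.pump_off_s,
            rise_frac,
            np.exp(-(t - config.pump_off_s) / config.dip.decay_s),
        ),
    )
    s_dep = np.where(
        t >= config.pump_on_s,
        1.0 - np.exp(-np.clip(t - config.pump_on_s, 0, None) / dep.saturation_tau_s),
        0.0,
    )
    s_halo = np.where(
        t >= config.pump_off_s,
        1.0 - np.exp(-np.clip(t - config.pump_off_s, 0, None) / halo.growth_tau_s),
        0.0,
    )

    # --- assemble the mDeg field frame by frame ---
    mdeg = np.empty((n_frames, rows, cols), dtype=np.float32)
    for i in range(n_frames):
        if i < i_on:
            dip_i = 0.0
        elif i < i_off and rise_frac[i] < 1.0:
            # expanding footprint: render the partial dome honestly
            partial = config.dip.amplitude_mdeg * rise_frac[i] * _dome(
                r, config.dip.max_radius_um * rise_frac[i]
            )
            dip_i = _convolve_field(partial, field_kernel)
        else:
            dip_i = dome_full_c * dip_amp[i]
        mdeg[i] = dip_i + deposit_c * s_dep[i] + halo_c * s_halo[i]

    # --- truth statistics on the noise-free field ---
    late_start = n_frames - max(1, int(round(0.2 * n_frames)))
    w1_true = mdeg[i_on:i_off].mean(axis=0, dtype=np.float64)
    w2_true = mdeg[late_start:].mean(axis=0, dtype=np.float64)
    slope_au = (
        config.linear_slope_au_per_mdeg
        if config.transduction_mode == "linear"
        else _build_transduction(config).local_slope
    )
    thr = (
        config.mask_threshold_mdeg
        if config.mask_threshold_mdeg is not None
        else 3.0 * config.noise_sigma_au / abs(slope_au)
    )
    # labels describe the recorded image: the illumination field scales the
    # optical signal a classifier sees, so it scales the truth statistics too
    illum = illumination_field(config.shape, config.illumination)
    persistent = illum * w2_true > thr
    transient = (illum * w1_true < -thr) & ~persistent
    inactive = ~(persistent | transient)
    class_masks = {
        "persistent_chemical": persistent,
        "transient_physical": transient,
        "inactive": inactive,
    }

    dip_peak_field = np.asarray(mdeg[max(i_off - 1, i_on)], dtype=np.float64) - (
        deposit_c * s_dep[max(i_off - 1, i_on)] + halo_c * s_halo[max(i_off - 1, i_on)]
    )
    dip_min = dip_peak_field.min()
    if dip_min < 0:
        below_half = dip_peak_field <= dip_min / 2.0
        dip_half_min_radius = px * np.sqrt(below_half.sum() / np.pi)
    else:
        dip_half_min_radius = 0.0

    chemical_final = deposit_c * s_dep[-1] + halo_c * s_halo[-1]

    # --- camera intensities ---
    model = _build_transduction(config)
    fringes = fringe_pattern(config.shape, px, config.fringes)

    scatter = np.zeros(config.shape)
    scatterers: list[dict] = []
    if config.n_scatterers > 0:
        wake = psf_kernel(
            px,
            sigma_perp_um=config.psf_sigma_perp_um,
            decay_par_um=config.psf_decay_par_um,
            mode="wake",
            wake_wavelength_um=config.wake_wavelength_um,
        )
        pts = np.zeros(config.shape)
        for _ in range(config.n_scatterers):
            rr_ = int(rng.integers(0, rows))
            cc_ = int(rng.integers(0, cols))
            strength = config.scatterer_strength_au * float(rng.uniform(0.5, 1.5))
            pts[rr_, cc_] += strength
            scatterers.append({"row": rr_, "col": cc_, "strength_au": strength})
        scatter = _convolve_field(pts, wake)

    frames = np.empty_like(mdeg)
    if model.mode == "linear":
        frames[:] = illum[None] * (model.reference_intensity + model.local_slope * mdeg)
    else:
        for i in range(n_frames):
            frames[i] = illum * model.intensity(mdeg[i])
    frames += (fringes + scatter)[None].astype(np.float32)
    if config.noise_sigma_au > 0:
        frames += config.noise_sigma_au * rng.standard_normal(frames.shape, dtype=np.float32)

    stack = ImageStack(frames, frame_rate_hz=config.frame_rate_hz, pixel_size_um=px)
    event = LocalEventTruth(
        center_rc=(c_row, c_col),
        dip=dataclasses.asdict(config.dip),
        deposit=dataclasses.asdict(config.deposit),
        halo=dataclasses.asdict(config.halo),
        scatterers=scatterers,
        mask_threshold_mdeg=float(thr),
        class_masks=class_masks,
        dip_field_peak=dip_peak_field,
        deposit_field_final=deposit_c * s_dep[-1],
        halo_field_final=halo_c * s_halo[-1],
        w1_true=w1_true,
        w2_true=w2_true,
        dip_half_min_radius_um=float(dip_half_min_radius),
        integrated_chemical_mdeg=float(chemical_final.sum()),
        pump_on_frame=i_on,
        pump_off_frame=i_off,
        mass_scale=m,
    )
    truth = GroundTruth(
        seed=seed,
        pixel_size_um=px,
        frame_rate_hz=config.frame_rate_hz,
        noise_sigma_au=config.noise_sigma_au,
        illumination=illum,
        fringes=fringes,
        transduction={
            "mode": model.mode,
            "local_slope": model.local_slope,
            "reference_intensity": model.reference_intensity,
            "working_angle_deg": model.working_angle_deg,
        },
        events=[event],
        scatter_field=scatter,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Config (de)serialization helpers
# --------------------------------------------------------------------------


_NESTED_FIELDS = {
    "kinetics": GrowthKinetics,
    "illumination": IlluminationConfig,
    "fringes": FringeConfig,
    "dip": DipTruth,
    "deposit": DepositTruth,
    "halo": HaloTruth,
}


def config_from_mapping(cls, mapping: dict) -> Any:
    """Build a config dataclass from a plain (YAML-derived) mapping.

    Nested blocks (kinetics, fringes, dip, ...) are promoted to their
    dataclasses; unknown keys raise with the offending field path so CLI
    schema violations are reported usefully.
    """
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in names:
            raise ValueError(f"unknown configuration field '{key}' for {cls.__name__}")
        if key in _NESTED_FIELDS and isinstance(value, dict):
            sub = _NESTED_FIELDS[key]
            sub_names = {f.name for f in dataclasses.fields(sub)}
            bad = set(value) - sub_names
            if bad:
                raise ValueError(f"unknown configuration field '{key}.{sorted(bad)[0]}'")
            value = sub(**value)
        elif isinstance(value, list) and key in ("shape", "concentrations_nM", "center_frac", "offset_um"):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
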