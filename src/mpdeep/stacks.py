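"""Histogram-based z-stack analysis: background, signal, SBR and model fits.

These are the measurement-side procedures applied to multiphoton z-stacks:

* per-slice background = the most abundant pixel value (the histogram mode),
  valid when fluorescent structures are sparse enough that most pixels see
  only background;
* per-slice signal = a histogram threshold location minus the background,
  using either an absolute occurrence count or a brighter-pixel fraction;
* SBR profiles with the top-slice zero convention (the zero value is one
  count below the top slice's background, so the top-slice background is
  exactly 1 and no division by zero can occur);
* log–log power-series slope (the excitation nonlinearity order);
* attenuation-length estimation from the surface power required for constant
  focal brightness versus depth;
* 1/e² PSF radii fitted from bead stacks;
* Fourier low-pass filtering for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "ImageStack",
    "ThresholdConfig",
    "SBRProfile",
    "PowerSeries",
    "SignalEstimate",
    "PowerLawFit",
    "AttenuationLengthFit",
    "PSFRadiiFit",
    "NoSpotFoundError",
    "background_level",
    "signal_level",
    "sbr_profile",
    "fit_power_exponent",
    "estimate_attenuation_length",
    "fit_psf_radii",
    "fourier_lowpass",
]

CHANNELS = ("blue", "green", "red")
CHANNEL_BANDS_NM = {"blue": (400, 480), "green": (490, 560), "red": (570, 640)}
MAX_COUNT = 65535


class NoSpotFoundError(ValueError):
    """No bright spot rises above the noise floor of a bead stack."""


@dataclass
class ImageStack:
    """Single-channel image stack in detector counts.

    ``voxels`` is (slice, row, col), slices ordered shallow → deep; the
    depth of slice ``i`` is ``i * z_step_um`` (surface at slice 0).
    ``surface_powers`` optionally records the applied excitation power per
    slice (relative scale allowed).
    """

    voxels: np.ndarray
    z_step_um: float
    pixel_size_um: float
    channel: str = "blue"
    surface_powers: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("voxels must be a 3-D (slice, row, col) array")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("voxels must be integer detector counts")
        if v.min() < 0 or v.max() > MAX_COUNT:
            raise ValueError("counts must fit the 16-bit detector range")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.surface_powers is not None:
            p = np.asarray(self.surface_powers, dtype=float)
            if p.shape != (v.shape[0],):
                raise ValueError("surface_powers must have one entry per slice")
            self.surface_powers = p
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.z_step_um


@dataclass(frozen=True)
class ThresholdConfig:
    """Signal-threshold strategy applied identically to every channel of a stack.

    ``count_threshold``: the signal location is the highest pixel value whose
    histogram count exceeds ``count_threshold`` pixels.
    ``brighter_fraction``: the signal location is the highest value with more
    than that fraction of pixels brighter than it.
    """

    strategy: Literal["count_threshold", "brighter_fraction"] = "brighter_fraction"
    count_threshold: int = 50
    brighter_fraction: float = 0.002

    def __post_init__(self) -> None:
        if self.strategy not in ("count_threshold", "brighter_fraction"):
            raise ValueError("unknown threshold strategy")
        if self.strategy == "count_threshold" and self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1 pixel")
        if self.strategy == "brighter_fraction" and not 0 < self.brighter_fraction < 1:
            raise ValueError("brighter_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SignalEstimate:
    """Signal level above background for one slice; ``flagged`` marks slices
    where no pixel value satisfied the threshold predicate (signal forced 0)."""

    signal: int
    threshold_location: int | None
    background: int
    flagged: bool


def _as_int_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image must be non-empty")
    if not np.issubdtype(img.dtype, np.integer):
        if not np.all(np.equal(np.mod(img, 1), 0)):
            raise ValueError("image must contain integer detector counts")
        img = img.astype(np.int64)
    if img.min() < 0:
        raise ValueError("counts must be non-negative")
    return img


def background_level(image) -> int:
    """Most abundant pixel value (integer histogram mode; ties -> lowest value).

    Valid as a background estimate when fluorescent structures are sparse, so
    the most common value is seen where nothing fluoresces in the focal volume.
    Histogram bins are unit-width integers (detector counts).
    """
    img = _as_int_image(image)
    counts = np.bincount(img.ravel())
    return int(counts.argmax())  # argmax takes the first (lowest) maximum


def signal_level(image, cfg: ThresholdConfig = ThresholdConfig()) -> SignalEstimate:
    """Signal level of one slice: threshold location minus histogram mode.

    With the ``count_threshold`` strategy the location is
    ``max{v : hist(v) > count_threshold}``; with ``brighter_fraction`` it is
    ``max{v : fraction(pixels > v) > brighter_fraction}``.  When no value
    satisfies the predicate (e.g. a structureless image) the signal is 0 and
    the estimate is flagged.
    """
    img = _as_int_image(image)
    bg = background_level(img)
    counts = np.bincount(img.ravel())
    loc: int | None = None
    if cfg.strategy == "count_threshold":
        sel = np.nonzero(counts > cfg.count_threshold)[0]
        if sel.size:
            loc = int(sel[-1])
    else:
        # tail[v] = number of pixels with value > v, over the full count range
        tail = img.size - np.cumsum(counts)
        sel = np.nonzero(tail > cfg.brighter_fraction * img.size)[0]
        if sel.size:
            loc = int(sel[-1])
    if loc is None:
        return SignalEstimate(signal=0, threshold_location=None, background=bg, flagged=True)
    signal = max(loc - bg, 0)
    return SignalEstimate(signal=signal, threshold_location=loc, background=bg, flagged=signal == 0)


@dataclass
class SBRProfile:
    """Per-slice background, signal and ratio with the top-slice zero convention."""

    depths_um: np.ndarray
    background: np.ndarray
    signal: np.ndarray
    ratio: np.ndarray
    zero_value: int
    flagged: np.ndarray
    channel: str = "blue"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths_um,
                "background_counts": self.background,
                "signal_counts": self.signal,
                "sbr": self.ratio,
                "flagged": self.flagged,
            }
        )


def sbr_profile(stack: ImageStack, cfg: ThresholdConfig = ThresholdConfig()) -> SBRProfile:
    """SBR versus depth for a stack.

    The zero value is one count below the detected background of the
    uppermost slice, so the top-slice background is exactly 1 count and the
    ratio stays finite everywhere; deeper backgrounds are clamped to >= 1
    count above zero for the same reason.
    """
    if stack.n_slices < 1:
        raise ValueError("stack must contain at least one slice")
    zero = background_level(stack.voxels[0]) - 1
    bg = np.empty(stack.n_slices, dtype=float)
    sig = np.empty(stack.n_slices, dtype=float)
    flagged = np.zeros(stack.n_slices, dtype=bool)
    for i in range(stack.n_slices):
        est = signal_level(stack.voxels[i], cfg)
        bg[i] = max(est.background - zero, 1)
        sig[i] = est.signal
        flagged[i] = est.flagged
    return SBRProfile(
        depths_um=stack.depths_um,
        background=bg,
        signal=sig,
        ratio=sig / bg,
        zero_value=zero,
        flagged=flagged,
        channel=stack.channel,
    )


@dataclass(frozen=True)
class PowerSeries:
    """Mean fluorescence signal versus applied excitation power for one channel."""

    powers: np.ndarray
    signals: np.ndarray
    channel: str = "blue"

    def __post_init__(self) -> None:
        p = np.asarray(self.powers, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if p.ndim != 1 or p.shape != s.shape:
            raise ValueError("powers and signals must be matching 1-D arrays")
        if np.any(p <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("powers must be positive and strictly increasing")
        if np.any(s <= 0):
            raise ValueError("signals must be positive")
        object.__setattr__(self, "powers", p)
        object.__setattr__(self, "signals", s)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log(signal) = exponent * log(power) + intercept."""

    exponent: float
    intercept: float
    stderr: float
    residual_rms: float
    n: int

    def summary(self) -> str:
        return (
            f"power-law fit: S ∝ P^{self.exponent:.3f} "
            f"(SE {self.stderr:.3f}, residual RMS {self.residual_rms:.3f}, n={self.n})"
        )


def fit_power_exponent(series: PowerSeries) -> PowerLawFit:
    """Excitation nonlinearity order: the log–log slope of signal vs power.

    A slope near 2 indicates two-photon, near 3 three-photon excitation;
    intermediate values indicate mixed excitation pathways.
    """
    if series.powers.size < 3:
        raise ValueError("need at least 3 (power, signal) points")
    lp, ls = np.log(series.powers), np.log(series.signals)
    res = linregress(lp, ls)
    resid = ls - (res.slope * lp + res.intercept)
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n=series.powers.size,
    )


@dataclass(frozen=True)
class AttenuationLengthFit:
    """Attenuation length from ln(power) vs depth; ``inf`` when power is flat."""

    length_um: float
    stderr_um: float
    slope_per_um: float
    n: int
    warnings: tuple[str, ...] = ()

    def summary(self) -> str:
        return (
            f"attenuation length {self.length_um:.1f} µm "
            f"(SE {self.stderr_um:.1f} µm, n={self.n})"
        )


def estimate_attenuation_length(
    depths_um: Sequence[float], surface_powers: Sequence[float]
) -> AttenuationLengthFit:
    """Attenuation length from the power needed for constant focal brightness.

    Maintaining a constant focal intensity against ballistic loss requires
    the surface power to grow as ``exp(depth / le)``, so ``le`` is the
    inverse slope of the least-squares line through ln(power) vs depth.
    Scale-invariant in the power units.  A non-increasing power schedule
    (real schedules jitter) is reported as a warning, not an error; a flat
    or decreasing trend yields an infinite-length sentinel.
    """
    d = np.asarray(depths_um, dtype=float)
    p = np.asarray(surface_powers, dtype=float)
    if d.ndim != 1 or d.shape != p.shape or d.size < 3:
        raise ValueError("need at least 3 matching (depth, power) pairs")
    if np.any(np.diff(d) <= 0):
        raise ValueError("depths must be strictly increasing")
    if np.any(p <= 0):
        raise ValueError("powers must be positive")
    warnings: list[str] = []
    if np.any(np.diff(p) < 0):
        warnings.append("power schedule is not monotonically increasing")
    res = linregress(d, np.log(p))
    if res.slope <= 0 or not np.isfinite(res.slope):
        return AttenuationLengthFit(
            length_um=math.inf,
            stderr_um=math.nan,
            slope_per_um=float(res.slope),
            n=d.size,
            warnings=tuple(warnings + ["non-positive slope: no measurable attenuation"]),
        )
    le = 1.0 / res.slope
    stderr = res.stderr / res.slope**2  # delta method on 1/slope
    return AttenuationLengthFit(
        length_um=float(le),
        stderr_um=float(stderr),
        slope_per_um=float(res.slope),
        n=d.size,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class PSFRadiiFit:
    """1/e² radii of a fitted bead image, per axis (µm)."""

    lateral_x_um: float
    lateral_y_um: float
    axial_um: float
    center_voxel: tuple[int, int, int]
    amplitude: float
    offset: float

    @property
    def lateral_um(self) -> float:
        """Mean of the two lateral radii."""
        return 0.5 * (self.lateral_x_um + self.lateral_y_um)

    def summary(self) -> str:
        return (
            f"PSF 1/e² radii: x {self.lateral_x_um:.3f} µm, "
            f"y {self.lateral_y_um:.3f} µm, z {self.axial_um:.3f} µm"
        )


def _gauss1d(t, amp, t0, radius, offset):
    return amp * np.exp(-2.0 * (t - t0) ** 2 / radius**2) + offset


def _fit_profile_radius(coords: np.ndarray, values: np.ndarray, bg: float) -> float:
    amp0 = float(values.max() - bg)
    t00 = float(coords[np.argmax(values)])
    r0 = max((coords[-1] - coords[0]) / 6.0, 1e-3)
    popt, _ = curve_fit(
        _gauss1d,
        coords,
        values.astype(float),
        p0=[amp0, t00, r0, bg],
        maxfev=20000,
    )
    return abs(float(popt[2]))


def fit_psf_radii(bead_stack: ImageStack, min_snr: float = 5.0) -> PSFRadiiFit:
    """Fit 1/e² PSF radii from an isolated bright spot in a bead stack.

    Locates the brightest connected spot (after light smoothing), extracts
    the x-, y- and z-profiles through its peak voxel, and least-squares fits
    a Gaussian with a constant-background nuisance term to each profile.
    Raises :class:`NoSpotFoundError` when the maximum does not exceed the
    background by ``min_snr`` noise standard deviations.
    """
    v = bead_stack.voxels.astype(float)
    bg = float(background_level(bead_stack.voxels))
    smooth = ndimage.gaussian_filter(v, sigma=(0.5, 1.0, 1.0))
    resid = v - bg
    noise_sd = float(1.4826 * np.median(np.abs(resid))) or 1.0
    if smooth.max() - bg <= min_snr * noise_sd:
        raise NoSpotFoundError("no spot rises above the background noise floor")
    kz, ky, kx = np.unravel_index(int(np.argmax(smooth)), smooth.shape)

    xs = np.arange(v.shape[2]) * bead_stack.pixel_size_um
    ys = np.arange(v.shape[1]) * bead_stack.pixel_size_um
    zs = np.arange(v.shape[0]) * bead_stack.z_step_um
    rx = _fit_profile_radius(xs, v[kz, ky, :], bg)
    ry = _fit_profile_radius(ys, v[kz, :, kx], bg)
    rz = _fit_profile_radius(zs, v[:, ky, kx], bg)
    return PSFRadiiFit(
        lateral_x_um=rx,
        lateral_y_um=ry,
        axial_um=rz,
        center_voxel=(int(kz), int(ky), int(kx)),
        amplitude=float(v[kz, ky, kx] - bg),
        offset=bg,
    )


def fourier_lowpass(image, cutoff_cycles_per_um: float, pixel_size_um: float = 1.0) -> np.ndarray:
    """Remove spatial frequencies above ``cutoff`` (radial, cycles/µm).

    Zeroes all Fourier components with radial frequency above the cutoff and
    returns a real-valued image of the same shape.  A cutoff at or above the
    sampling Nyquist frequency leaves the image untouched (the filter acts
    only on pixel noise above the optical band limit, never on resolution).
    Idempotent at a fixed cutoff.
    """
    if not cutoff_cycles_per_um > 0:
        raise ValueError("cutoff must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    nyquist = 1.0 / (2.0 * pixel_size_um)
    if cutoff_cycles_per_um >= nyquist:
        return img.copy()
    fy = np.fft.fftfreq(img.shape[0], d=pixel_size_um)
    fx = np.fft.fftfreq(img.shape[1], d=pixel_size_um)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    spectrum = np.fft.fft2(img)
    spectrum[fr > cutoff_cycles_per_um] = 0.0
    return np.real(np.fft.ifft2(spectrum))
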