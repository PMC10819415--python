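"""Synthetic phantoms and forward rendering through the excitation model.

Raw deep-imaging stacks of mycelial communities are not publicly available,
so every analysis stage in this package is exercised on synthetic data with
known ground truth:

* filamentous scenes — smooth correlated random-walk tubes grown until they
  occupy a target fill fraction (~10% of the volume, mimicking intertwined
  bacterial filaments);
* rendered z-stacks — per-slice in-focus structure blurred by the m-photon
  PSF plus a slowly varying out-of-focus background whose depth dependence
  follows the signal/background model, with detector offset, Poisson photon
  noise and Gaussian read noise;
* power series per detection channel (pure cubic/quadratic responses for the
  blue/red channels, a calibrated 2P+3P mixture for the green channel);
* bead stacks for PSF fitting;
* surface-power schedules for attenuation-length estimation.

All generators are deterministic for a fixed seed; independent random
streams are derived as ``default_rng([seed, tag])`` with fixed per-purpose
tags, so generating one output never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import BeamParameters, _check_order, _sphere_offsets, intensity, psf_lateral_radius
from .sbr import MediumProperties, background_signal, focal_signal
from .stacks import CHANNELS, ImageStack, PowerSeries

__all__ = [
    "MixedOrder",
    "FilamentScene",
    "RenderConfig",
    "PowerSchedule",
    "DEFAULT_POWERS",
    "DEFAULT_CHANNEL_RESPONSES",
    "GREEN_ORDER_WEIGHTS",
    "generate_filament_scene",
    "render_stack",
    "generate_power_series",
    "generate_power_schedule",
    "generate_bead_stack",
]

# random-stream tags (fixed so each generator draws independently of the rest)
_STREAM_CHANNEL = {"blue": 0, "green": 1, "red": 2}
_STREAM_SCHEDULE = 101
_STREAM_SCENE = 211
_STREAM_RENDER = 307
_STREAM_BEADS = 401

#: Default relative power grid: one decade, normalised to the highest power.
DEFAULT_POWERS = np.geomspace(0.1, 1.0, 10)

#: Green-channel 2P/3P mixing weights, calibrated once so the noiseless
#: least-squares log–log slope over DEFAULT_POWERS equals 2.81 exactly.
GREEN_ORDER_WEIGHTS = ((2, 0.0631117835), (3, 0.9368882165))


@dataclass(frozen=True)
class MixedOrder:
    """Weighted sum of excitation orders: signal(P) = sum_w w * P**m."""

    weights: tuple[tuple[int, float], ...] = GREEN_ORDER_WEIGHTS

    def signal(self, powers) -> np.ndarray:
        p = np.asarray(powers, dtype=float)
        return sum(w * p**m for m, w in self.weights)


#: Per-channel power responses emulated by the generator: measured apparent
#: exponents for the pure channels, the calibrated 2P+3P mixture for green.
DEFAULT_CHANNEL_RESPONSES: dict[str, float | MixedOrder] = {
    "blue": 3.09,
    "green": MixedOrder(),
    "red": 1.96,
}

#: Physical excitation pathways per detection channel used by the renderer.
RENDER_ORDERS: dict[str, tuple[tuple[int, float], ...]] = {
    "blue": ((3, 1.0),),
    "green": GREEN_ORDER_WEIGHTS,
    "red": ((2, 1.0),),
}


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and coefficient of variation cv."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2.0, sigma, n))


# ---------------------------------------------------------------------------
# filament scenes


@dataclass
class FilamentScene:
    """Ground-truth fluorophore density map built from filament tubes.

    ``density`` is (z, y, x) with anisotropic voxels; values are per-filament
    brightness in [0, ~1.5] (lognormal jitter around 1), 0 outside filaments.
    """

    density: np.ndarray
    voxel_xy_um: float
    voxel_z_um: float
    filaments: list[np.ndarray]
    filament_radius_um: float
    fill_fraction_target: float
    seed: int
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CHANNELS}
    )

    @property
    def volume_um(self) -> tuple[float, float, float]:
        nz, ny, nx = self.density.shape
        return (nx * self.voxel_xy_um, ny * self.voxel_xy_um, nz * self.voxel_z_um)

    @property
    def fill_fraction(self) -> float:
        """Realised fill fraction (occupied voxel fraction)."""
        return float(np.mean(self.density > 0))


def generate_filament_scene(
    volume_um: tuple[float, float, float] = (25.6, 25.6, 100.0),
    fill_fraction_target: float = 0.10,
    filament_radius_um: float = 0.5,
    filament_length_um: float = 40.0,
    voxel_xy_um: float = 0.4,
    voxel_z_um: float = 0.5,
    step_um: float = 0.5,
    persistence: float = 0.9,
    brightness_cv: float = 0.2,
    seed: int = 0,
) -> FilamentScene:
    """Grow correlated random-walk filaments until the target fill is reached.

    Filaments are polylines with persistent (slowly turning) directions,
    reflected at the volume boundaries, rasterised as tubes of the given
    radius.  Deterministic for a fixed seed.  The realised fill fraction
    lands within a few voxel-quantisation percent of the target (the loop
    stops at the first filament that reaches it).
    """
    sx, sy, sz = (float(v) for v in volume_um)
    if min(sx, sy, sz) < 4 * filament_radius_um:
        raise ValueError("volume must be at least 4 filament radii per side")
    if not 0 < fill_fraction_target <= 1:
        raise ValueError("fill_fraction_target must lie in (0, 1]")
    rng = np.random.default_rng([seed, _STREAM_SCENE])

    nx = max(int(round(sx / voxel_xy_um)), 2)
    ny = max(int(round(sy / voxel_xy_um)), 2)
    nz = max(int(round(sz / voxel_z_um)), 2)
    density = np.zeros((nz, ny, nx), dtype=np.float32)

    # tube cross-section stencil in (anisotropic) voxel offsets
    rz = int(math.ceil(filament_radius_um / voxel_z_um))
    rxy = int(math.ceil(filament_radius_um / voxel_xy_um))
    oz, oy, ox = np.mgrid[-rz : rz + 1, -rxy : rxy + 1, -rxy : rxy + 1]
    mask = (
        (oz * voxel_z_um) ** 2 + (oy * voxel_xy_um) ** 2 + (ox * voxel_xy_um) ** 2
        <= filament_radius_um**2
    )
    offs = np.stack([oz[mask], oy[mask], ox[mask]], axis=1)  # (K, 3) z,y,x

    n_steps = max(int(filament_length_um / step_um), 2)
    lims = np.array([sx, sy, sz])
    filaments: list[np.ndarray] = []
    max_filaments = 100_000
    occupied = 0  # occupied-voxel count, maintained incrementally
    n_voxels = density.size
    while occupied / n_voxels < fill_fraction_target and len(filaments) < max_filaments:
        pos = rng.uniform(filament_radius_um, lims - filament_radius_um)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pts = np.empty((n_steps, 3))
        for k in range(n_steps):
            pts[k] = pos
            turn = rng.standard_normal(3)
            direction = persistence * direction + (1 - persistence) * turn
            direction /= np.linalg.norm(direction)
            pos = pos + step_um * direction
            # reflect at the boundaries
            for ax in range(3):
                if pos[ax] < 0:
                    pos[ax] = -pos[ax]
                    direction[ax] = -direction[ax]
                elif pos[ax] > lims[ax]:
                    pos[ax] = 2 * lims[ax] - pos[ax]
                    direction[ax] = -direction[ax]
        filaments.append(pts)
        amp = float(_lognormal_factors(rng, brightness_cv, 1)[0])
        iz = np.clip(np.round(pts[:, 2] / voxel_z_um).astype(int), 0, nz - 1)
        iy = np.clip(np.round(pts[:, 1] / voxel_xy_um).astype(int), 0, ny - 1)
        ix = np.clip(np.round(pts[:, 0] / voxel_xy_um).astype(int), 0, nx - 1)
        zz = np.clip(iz[:, None] + offs[None, :, 0], 0, nz - 1).ravel()
        yy = np.clip(iy[:, None] + offs[None, :, 1], 0, ny - 1).ravel()
        xx = np.clip(ix[:, None] + offs[None, :, 2], 0, nx - 1).ravel()
        flat = np.unique((zz * ny + yy) * nx + xx)
        occupied += int(np.count_nonzero(density.flat[flat] == 0))
        density.flat[flat] = np.maximum(density.flat[flat], amp)

    return FilamentScene(
        density=density,
        voxel_xy_um=voxel_xy_um,
        voxel_z_um=voxel_z_um,
        filaments=filaments,
        filament_radius_um=filament_radius_um,
        fill_fraction_target=fill_fraction_target,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stack rendering


@dataclass
class RenderConfig:
    """Detector and illumination configuration for stack rendering.

    ``photon_scale`` is the expected count of an in-focus filament at the
    reference (top-slice) power; the default puts the top-slice SBR in the
    tens-to-hundred range typical of sparse autofluorescent samples.
    ``surface_powers`` is the per-slice applied power on a relative scale
    (defaults to constant); rendering scales signal and background with
    ``P**m`` for each excitation pathway.
    """

    beam: BeamParameters = field(default_factory=BeamParameters)
    medium: MediumProperties = field(default_factory=MediumProperties)
    z_step_um: float = 4.0
    detector_offset: int = 100
    photon_scale: float = 80.0
    read_noise_sd: float = 2.0
    surface_powers: np.ndarray | None = None
    texture_amplitude: float = 0.2
    texture_correlation_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detector_offset < 0:
            raise ValueError("detector_offset must be >= 0")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


def _axial_kernel(beam: BeamParameters, order: int, voxel_z_um: float, radius_um: float):
    """On-axis excitation weights over fine planes, normalised so that one
    filament of the given radius crossing the focal plane responds with 1."""
    a = beam.axial_scale_um
    half = int(math.ceil(4.0 * a / voxel_z_um))
    dz = np.arange(-half, half + 1) * voxel_z_um
    w = (1.0 + (dz / a) ** 2) ** (-order)
    coupling = w[np.abs(dz) <= radius_um].sum()
    return w / coupling


def render_stack(
    scene: FilamentScene,
    cfg: RenderConfig,
    channels: tuple[str, ...] = CHANNELS,
) -> dict[str, ImageStack]:
    """Render a scene into per-channel detector stacks.

    Per slice at depth ``d``: the in-focus term is the scene density around
    the focal plane, weighted by the on-axis m-photon profile and blurred by
    the lateral m-photon PSF, scaled by the model focal signal at ``d``; the
    background term is a slowly varying multiplicative texture around the
    model background signal at ``d``.  Both carry the applied-power factor
    ``(P(d)/P(0))**m``, and counts are offset + Poisson + read noise, clipped
    to the 16-bit range (clipping is flagged in ``meta``).
    """
    nz_fine = scene.density.shape[0]
    depth_max = (nz_fine - 1) * scene.voxel_z_um
    n_slices = int(math.floor(depth_max / cfg.z_step_um)) + 1
    if cfg.surface_powers is not None:
        powers = np.asarray(cfg.surface_powers, dtype=float)
        if powers.shape != (n_slices,):
            raise ValueError(
                f"surface_powers must have {n_slices} entries (one per rendered slice)"
            )
    else:
        powers = np.ones(n_slices)
    rng = np.random.default_rng([cfg.seed, _STREAM_RENDER])
    depths = np.arange(n_slices) * cfg.z_step_um
    ny, nx = scene.density.shape[1:]

    # slowly varying background texture (multiplicative, mean ~1)
    g = rng.standard_normal((n_slices, ny, nx))
    sig_xy = cfg.texture_correlation_um / scene.voxel_xy_um
    sig_z = max(cfg.texture_correlation_um / cfg.z_step_um, 0.5)
    g = ndimage.gaussian_filter(g, sigma=(sig_z, sig_xy, sig_xy))
    sd = g.std()
    texture = 1.0 + cfg.texture_amplitude * (g / sd if sd > 0 else g)
    np.clip(texture, 0.05, None, out=texture)

    orders = sorted({m for c in channels for m, _ in RENDER_ORDERS[c]})
    kernels = {
        m: _axial_kernel(cfg.beam, m, scene.voxel_z_um, scene.filament_radius_um)
        for m in orders
    }
    sigma_px = {
        m: psf_lateral_radius(cfg.beam, m) / 2.0 / scene.voxel_xy_um for m in orders
    }
    f_curve = {
        m: np.array([focal_signal(d, cfg.beam, cfg.medium, m) for d in depths])
        for m in orders
    }
    b_curve = {
        m: np.array(
            [background_signal(d, cfg.beam, cfg.medium, m) if d > 0 else 0.0 for d in depths]
        )
        for m in orders
    }
    p_rel = powers / powers[0]

    # in-focus maps per order and slice
    infocus = {m: np.empty((n_slices, ny, nx)) for m in orders}
    for m in orders:
        kern = kernels[m]
        half = kern.size // 2
        for i, d in enumerate(depths):
            j = int(round(d / scene.voxel_z_um))
            lo, hi = max(j - half, 0), min(j + half + 1, nz_fine)
            w = kern[(lo - (j - half)) : (hi - (j - half))]
            plane = np.tensordot(w, scene.density[lo:hi], axes=(0, 0))
            infocus[m][i] = ndimage.gaussian_filter(plane, sigma=sigma_px[m])

    stacks: dict[str, ImageStack] = {}
    for c in channels:
        pathways = RENDER_ORDERS[c]
        norm = sum(wt * f_curve[m][0] for m, wt in pathways)
        lam = np.zeros((n_slices, ny, nx))
        amp = scene.channel_amplitudes.get(c, 1.0)
        for m, wt in pathways:
            scale = amp * wt * cfg.photon_scale / norm * p_rel**m
            lam += scale[:, None, None] * (
                f_curve[m][:, None, None] * infocus[m]
                + b_curve[m][:, None, None] * texture
            )
        counts = cfg.detector_offset + rng.poisson(lam).astype(float)
        if cfg.read_noise_sd > 0:
            counts += rng.normal(0.0, cfg.read_noise_sd, counts.shape)
        counts = np.rint(counts)
        clipped = bool(np.any(counts > 65535) or np.any(counts < 0))
        counts = np.clip(counts, 0, 65535).astype(np.uint16)
        stacks[c] = ImageStack(
            voxels=counts,
            z_step_um=cfg.z_step_um,
            pixel_size_um=scene.voxel_xy_um,
            channel=c,
            surface_powers=powers,
            meta={"clipped": clipped, "seed": cfg.seed, "scene_seed": scene.seed},
        )
    return stacks


# ---------------------------------------------------------------------------
# power series and power schedules


def generate_power_series(
    powers=None,
    responses: dict[str, float | MixedOrder] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, PowerSeries]:
    """Per-channel fluorescence-vs-power series with multiplicative noise.

    Signals follow ``c * P**gamma`` (or the weighted 2P+3P mixture for the
    green channel) times lognormal noise of the given coefficient of
    variation.  Each channel draws from its own ``[seed, channel]`` stream,
    so the series are identical whether channels are generated singly or
    together.
    """
    p = np.asarray(DEFAULT_POWERS if powers is None else powers, dtype=float)
    responses = dict(DEFAULT_CHANNEL_RESPONSES) if responses is None else responses
    out: dict[str, PowerSeries] = {}
    for channel, resp in responses.items():
        rng = np.random.default_rng([seed, _STREAM_CHANNEL[channel]])
        base = resp.signal(p) if isinstance(resp, MixedOrder) else p ** float(resp)
        noise = _lognormal_factors(rng, noise_cv, p.size)
        out[channel] = PowerSeries(powers=p, signals=base * noise, channel=channel)
    return out


@dataclass(frozen=True)
class PowerSchedule:
    """Surface power required for constant focal brightness versus depth."""

    depths_um: np.ndarray
    powers: np.ndarray
    le_um: float
    truncated: bool


def generate_power_schedule(
    le_um: float = 170.0,
    depths_um=None,
    base_power: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    max_power: float | None = None,
) -> PowerSchedule:
    """Exponential surface-power schedule ``P = P0 exp(d / le)`` with noise.

    The default attenuation length (170 µm) corresponds to a low-density
    sample.  ``max_power`` emulates running out of available laser power;
    the cap is flagged via ``truncated``.
    """
    if not le_um > 0:
        raise ValueError("le_um must be > 0")
    d = np.asarray(
        np.linspace(0.0, 500.0, 6) if depths_um is None else depths_um, dtype=float
    )
    rng = np.random.default_rng([seed, _STREAM_SCHEDULE])
    p = base_power * np.exp(d / le_um) * _lognormal_factors(rng, noise_cv, d.size)
    truncated = False
    if max_power is not None:
        truncated = bool(np.any(p > max_power))
        p = np.minimum(p, max_power)
    return PowerSchedule(depths_um=d, powers=p, le_um=float(le_um), truncated=truncated)


# ---------------------------------------------------------------------------
# bead stacks


def generate_bead_stack(
    beam: BeamParameters | None = None,
    order: int = 3,
    bead_diameter_um: float = 0.5,
    z_step_um: float = 0.25,
    pixel_size_um: float = 0.1,
    fov_um: float = 6.4,
    z_span_um: float = 8.0,
    detector_offset: int = 100,
    photon_scale: float = 4000.0,
    read_noise_sd: float = 2.0,
    noise: bool = True,
    seed: int = 0,
    channel: str = "blue",
) -> ImageStack:
    """Render one centred fluorescent bead through the m-photon PSF.

    The bead is a uniform solid sphere; its image is the m-photon excitation
    density convolved with the sphere (evaluated in radial coordinates and
    interpolated onto the pixel grid), with the peak scaled to
    ``photon_scale`` counts above the detector offset.  ``noise=False``
    renders the noiseless expectation (rounded to integer counts).
    """
    beam = BeamParameters() if beam is None else beam
    m = _check_order(order)
    if bead_diameter_um < 0:
        raise ValueError("bead_diameter_um must be >= 0")
    if bead_diameter_um >= min(fov_um, z_span_um):
        raise ValueError("bead must fit inside the rendered volume")
    n_slices = int(round(z_span_um / z_step_um)) + 1
    npx = int(round(fov_um / pixel_size_um))
    zs = (np.arange(n_slices) - (n_slices - 1) / 2.0) * z_step_um
    rmax = fov_um / math.sqrt(2.0) + bead_diameter_um
    rs = np.arange(0.0, rmax + pixel_size_um, pixel_size_um / 2.0)

    if bead_diameter_um > 0:
        offs = _sphere_offsets(bead_diameter_um, bead_diameter_um / 15.0)  # (K, 3)
        r_eval = rs[None, :, None] - offs[None, None, :, 0]
        y_eval = -offs[None, None, :, 1]
        z_eval = zs[:, None, None] - offs[None, None, :, 2]
        prof = np.asarray(intensity(r_eval, y_eval, z_eval, beam)) ** m
        prof = prof.mean(axis=2)  # (n_slices, n_r)
    else:
        prof = np.asarray(intensity(rs[None, :], 0.0, zs[:, None], beam)) ** m
    prof /= prof.max()

    ax = (np.arange(npx) - (npx - 1) / 2.0) * pixel_size_um
    rpix = np.hypot(ax[:, None], ax[None, :])
    lam = np.empty((n_slices, npx, npx))
    for i in range(n_slices):
        lam[i] = np.interp(rpix, rs, prof[i]) * photon_scale

    if noise:
        rng = np.random.default_rng([seed, _STREAM_BEADS])
        counts = detector_offset + rng.poisson(lam).astype(float)
        if read_noise_sd > 0:
            counts += rng.normal(0.0, read_noise_sd, counts.shape)
    else:
        counts = detector_offset + lam
    counts = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return ImageStack(
        voxels=counts,
        z_step_um=z_step_um,
        pixel_size_um=pixel_size_um,
        channel=channel,
        meta={"bead_diameter_um": bead_diameter_um, "order": m, "seed": seed},
    )
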