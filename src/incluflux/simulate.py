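"""Seeded synthetic-microscopy generator.

Produces trajectories, rendered movies and z-stacks, FRAP time series and
photoconversion pulse-chase time courses with the statistical structure the
downstream analyses assume, together with ground-truth records, so the whole
pipeline is testable without any acquired data.

The generator emulates the experimental regime it is calibrated against:

* small cytoplasmic aggregates diffusing freely in 2D with
  D ≈ 5.9 × 10⁻² μm²/s, imaged at ~30 or ~10 frames/s;
* inclusion bodies moving super-diffusively (diffusion plus persistent
  drift whose direction resamples at random times);
* ovoid inclusions of 0.2–1 μm scale over a uniform cytoplasmic
  background, with a darker vacuolar region;
* per-exposure photobleaching with a constant retention fraction;
* green→red photoconversion kinetics with continued green synthesis,
  inclusion/cytoplasm exchange, degradation, and cell-division dilution
  (daughter ≈ 70% of the mother).

All stochastic functions take an explicit integer ``seed``; identical seeds
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import FluxSeries, ImageStack, Track

__all__ = [
    "MotionKind",
    "MotionModel",
    "AcquisitionConfig",
    "PulseChaseModel",
    "InclusionSpec",
    "GroundTruth",
    "FrapMode",
    "simulate_trajectory",
    "simulate_ensemble",
    "render_timelapse",
    "render_cell_zstack",
    "simulate_frap",
    "simulate_pulse_chase",
]

# Default optics/geometry: 100×/1.45 NA scale — 0.1 μm pixels, 64×64 px
# field, Gaussian PSF sigma 0.12 μm.  All configurable.
DEFAULT_PIXEL_SIZE_UM = 0.1
DEFAULT_FIELD_PX = 64
DEFAULT_PSF_SIGMA_UM = 0.12


class MotionKind(str, Enum):
    BROWNIAN = "brownian"
    DIRECTED = "directed"
    BALLISTIC = "ballistic"
    STATIONARY = "stationary"


@dataclass
class MotionModel:
    """Particle motion model: pure diffusion, diffusion plus persistent
    drift, constant-velocity, or immobile.

    ``drift_persistence_s`` is the mean waiting time between random
    re-orientations of the drift direction; a directed walker with finite
    persistence interpolates between diffusive (α → 1) and ballistic
    (α → 2) scaling on the lag times probed.
    """

    kind: MotionKind = MotionKind.BROWNIAN
    diffusion_um2_s: float = 5.9e-2
    drift_speed_um_s: float = 0.0
    drift_persistence_s: float = 1.0

    def __post_init__(self) -> None:
        self.kind = MotionKind(self.kind)
        if self.diffusion_um2_s < 0 or self.drift_speed_um_s < 0:
            raise ValueError("rates must be non-negative")
        if self.kind is MotionKind.BROWNIAN and self.drift_speed_um_s != 0:
            raise ValueError("brownian motion has drift_speed = 0")
        if self.kind is MotionKind.STATIONARY and (
            self.diffusion_um2_s != 0 or self.drift_speed_um_s != 0
        ):
            raise ValueError("stationary motion has D = 0 and drift_speed = 0")


@dataclass
class AcquisitionConfig:
    """Imaging parameters used when rendering synthetic data."""

    frame_interval_s: float = 1 / 32
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_spacing_um: float = 0.2
    exposure_s: float = 0.01
    field_px: tuple[int, int] = (DEFAULT_FIELD_PX, DEFAULT_FIELD_PX)
    psf_sigma_um: float = DEFAULT_PSF_SIGMA_UM
    background_level: float = 10.0
    shot_noise: bool = True
    read_noise_sd: float = 1.0
    # per-channel fluorescence retained after one exposure (1.0 = no bleach)
    bleach_retention_per_exposure: dict = field(default_factory=lambda: {"ch0": 1.0})
    channels: Sequence[str] = ("ch0",)

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_interval_s and pixel_size_um must be positive")
        for ch, r in self.bleach_retention_per_exposure.items():
            if not (0 < r <= 1):
                raise ValueError(f"bleach retention for {ch} must be in (0, 1]")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um


@dataclass
class PulseChaseModel:
    """Two-pool (cytoplasm ↔ inclusion), two-colour kinetic model.

    At t = 0 a fraction ``conversion_fraction`` of all green protein is
    irreversibly converted to red.  Green protein continues to be
    synthesised into the cytoplasm at ``synthesis_rate``; no new red is ever
    made.  Exchange between cytoplasm and inclusion follows first-order
    rates ``k_in`` and ``k_out``; released cytoplasmic protein is degraded
    at ``k_deg``.  At each division the cytoplasmic pool is split with the
    daughter (size ``daughter_fraction`` of the mother); the inclusion stays
    with the mother.
    """

    k_in_per_min: float = 0.02
    k_out_per_min: float = 0.012
    k_deg_per_min: float = 0.008
    synthesis_rate_au_min: float = 0.6
    conversion_fraction: float = 0.5
    division_times_min: Sequence[float] = ()
    daughter_fraction: float = 0.7
    cyto0_au: float = 100.0
    ib0_au: float = 60.0

    def __post_init__(self) -> None:
        for r in (self.k_in_per_min, self.k_out_per_min, self.k_deg_per_min,
                  self.synthesis_rate_au_min):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not (0 <= self.conversion_fraction <= 1):
            raise ValueError("conversion_fraction must be in [0, 1]")
        if not (0 < self.daughter_fraction < 1):
            raise ValueError("daughter_fraction must be in (0, 1)")


@dataclass
class InclusionSpec:
    """Specification of one ovoid inclusion for z-stack rendering.

    ``center_um`` is (x, y, z); ``radii_um`` the ellipsoid semi-axes
    (rx, ry, rz); ``intensity_rel`` the interior intensity as a multiple of
    the cytoplasmic mean.
    """

    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    intensity_rel: float = 1.6


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    true_tracks: list = field(default_factory=list)
    true_masks: Optional[np.ndarray] = None  # per-frame / per-slice labels
    true_parameters: dict = field(default_factory=dict)
    seed: int = 0


class FrapMode(str, Enum):
    INTERIOR_MIXING = "interior_mixing"
    SURFACE_ACCRETION = "surface_accretion"
    NO_EXCHANGE = "no_exchange"


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_trajectory(
    model: MotionModel,
    n_frames: int,
    frame_interval_s: float,
    seed: int,
    start_um: tuple[float, float] = (0.0, 0.0),
    bounds_um: Optional[tuple[float, float]] = None,
    intensity: float = 1.0,
) -> Track:
    """Simulate one 2D particle trajectory.

    Per-axis Brownian increments have variance 2·D·Δt.  The directed kind
    adds a drift step of length ``drift_speed·Δt`` whose direction resamples
    at exponentially distributed waiting times with mean
    ``drift_persistence``.  If ``bounds_um`` = (width, height) is given the
    walk reflects at the field edges; by default it is unbounded.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    step_sd = np.sqrt(2.0 * model.diffusion_um2_s * dt)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) if step_sd > 0 else np.zeros(
        (n_frames - 1, 2)
    )

    if model.kind in (MotionKind.DIRECTED, MotionKind.BALLISTIC) and model.drift_speed_um_s > 0:
        theta = rng.uniform(0, 2 * np.pi)
        drift_len = model.drift_speed_um_s * dt
        for i in range(n_frames - 1):
            steps[i, 0] += drift_len * np.cos(theta)
            steps[i, 1] += drift_len * np.sin(theta)
            if model.kind is MotionKind.DIRECTED:
                # memoryless re-orientation with mean waiting drift_persistence
                if rng.random() < 1.0 - np.exp(-dt / model.drift_persistence_s):
                    theta = rng.uniform(0, 2 * np.pi)

    pos = np.empty((n_frames, 2))
    pos[0] = start_um
    pos[1:] = start_um + np.cumsum(steps, axis=0)

    if bounds_um is not None:
        w, h = bounds_um
        # reflective boundaries via triangle-wave folding
        pos[:, 0] = _reflect(pos[:, 0], 0.0, w)
        pos[:, 1] = _reflect(pos[:, 1], 0.0, h)

    frames = np.arange(n_frames)
    return Track(
        frames=frames,
        t_s=frames * dt,
        x_um=pos[:, 0],
        y_um=pos[:, 1],
        intensity=np.full(n_frames, float(intensity)),
        pixel_size_um=1.0,
        frame_interval_s=dt,
    )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def simulate_ensemble(
    model: MotionModel,
    n_tracks: int,
    n_frames: int,
    frame_interval_s: float,
    seed: int,
    **kwargs,
) -> list[Track]:
    """Simulate ``n_tracks`` independent trajectories with per-track seeds
    derived from ``seed`` via numpy's seed-spawning machinery."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_tracks)
    tracks = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        tr = simulate_trajectory(model, n_frames, frame_interval_s, sub_seed, **kwargs)
        tr.track_id = i
        tracks.append(tr)
    return tracks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_gaussian_spot(frame: np.ndarray, x_px: float, y_px: float,
                       amplitude: float, sigma_px: float) -> None:
    """Add a sampled 2D Gaussian in place (evaluated at pixel centres)."""
    h, w = frame.shape
    half = int(np.ceil(5 * sigma_px))
    x0, x1 = int(np.floor(x_px)) - half, int(np.floor(x_px)) + half + 1
    y0, y1 = int(np.floor(y_px)) - half, int(np.floor(y_px)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    r2 = (xx - x_px) ** 2 + (yy - y_px) ** 2
    frame[y0c:y1c, x0c:x1c] += amplitude * np.exp(-r2 / (2 * sigma_px**2))


def render_timelapse(
    tracks: Sequence[Track],
    config: AcquisitionConfig,
    seed: int,
    amplitude: float = 100.0,
    out_of_field: str = "clip",
) -> tuple[ImageStack, GroundTruth]:
    """Render trajectories as a single-channel 2D movie.

    Each particle is a sampled 2D Gaussian of ``psf_sigma`` on a uniform
    background; intensity is attenuated by ``bleach_retention^frame``;
    Poisson shot noise then Gaussian read noise are applied if enabled.
    ``out_of_field`` is ``"clip"`` (render what is visible) or ``"error"``.
    """
    rng = np.random.default_rng(seed)
    h, w = config.field_px
    n_frames = max(int(t.frames.max()) for t in tracks) + 1 if tracks else 1
    retention = config.bleach_retention_per_exposure.get(config.channels[0], 1.0)
    sigma_px = config.psf_sigma_px

    movie = np.full((n_frames, h, w), float(config.background_level))
    for tr in tracks:
        xs_px = tr.x_um / config.pixel_size_um
        ys_px = tr.y_um / config.pixel_size_um
        if out_of_field == "error" and (
            (xs_px < 0).any() or (xs_px > w - 1).any()
            or (ys_px < 0).any() or (ys_px > h - 1).any()
        ):
            raise ValueError(f"track {tr.track_id} leaves the field")
        for fi, frame_idx in enumerate(tr.frames):
            amp = amplitude * tr.intensity[fi] * retention ** int(frame_idx)
            _add_gaussian_spot(movie[int(frame_idx)], xs_px[fi], ys_px[fi], amp, sigma_px)

    if config.shot_noise:
        movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        movie = movie + rng.normal(0.0, config.read_noise_sd, size=movie.shape)

    stack = ImageStack(
        data=movie[:, np.newaxis, np.newaxis],  # T -> TZCYX
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        channel_names=tuple(config.channels[:1]),
    )
    gt = GroundTruth(
        true_tracks=list(tracks),
        true_parameters={"amplitude": amplitude, "config": config},
        seed=seed,
    )
    return stack, gt


def render_cell_zstack(
    inclusions: Sequence[InclusionSpec],
    config: AcquisitionConfig,
    seed: int,
    n_slices: int = 18,
    cytoplasm_mean: float = 100.0,
    vacuole_center_um: Optional[tuple[float, float, float]] = None,
    vacuole_radius_um: float = 0.0,
    vacuole_rel: float = 0.3,
    particles: Sequence[tuple[float, float, float]] = (),
    particle_amplitude_rel: float = 1.6,
    allow_merge: bool = False,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-timepoint z-stack of a cell with ovoid inclusions.

    Inclusions are filled ellipsoids at ``intensity_rel × cytoplasm_mean``
    blurred in-plane by the PSF; the cytoplasm is uniform; an optional
    spherical vacuole is rendered darker; point particles are rendered as
    PSF-sized Gaussians.  Returns the stack and a per-slice label image
    (one label per inclusion; particles are not labelled).
    """
    rng = np.random.default_rng(seed)
    h, w = config.field_px
    px = config.pixel_size_um
    dz = config.z_spacing_um
    zs = (np.arange(n_slices) - (n_slices - 1) / 2) * dz  # centred μm z coords
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = xx * px
    y_um = yy * px

    labels = np.zeros((n_slices, h, w), dtype=np.int32)
    vol = np.full((n_slices, h, w), float(cytoplasm_mean))

    if vacuole_center_um is not None and vacuole_radius_um > 0:
        vx, vy, vz = vacuole_center_um
        for zi, z in enumerate(zs):
            m = ((x_um - vx) ** 2 + (y_um - vy) ** 2
                 + (z - vz) ** 2) <= vacuole_radius_um**2
            vol[zi][m] = vacuole_rel * cytoplasm_mean

    for li, spec in enumerate(inclusions, start=1):
        cx, cy, cz = spec.center_um
        rx, ry, rz = spec.radii_um
        for zi, z in enumerate(zs):
            m = (((x_um - cx) / rx) ** 2 + ((y_um - cy) / ry) ** 2
                 + ((z - cz) / rz) ** 2) <= 1.0
            if not m.any():
                continue
            overlap = labels[zi][m] != 0
            if overlap.any() and not allow_merge:
                raise ValueError(
                    f"inclusion specs {li} and {labels[zi][m][overlap][0]} overlap; "
                    "pass allow_merge=True to merge"
                )
            vol[zi][m] = spec.intensity_rel * cytoplasm_mean
            labels[zi][m] = li

    sigma_px = config.psf_sigma_px
    if sigma_px > 0:
        for zi in range(n_slices):
            vol[zi] = ndimage.gaussian_filter(vol[zi], sigma_px, mode="nearest")

    for (px_x, px_y, px_z) in particles:
        zi = int(np.argmin(np.abs(zs - px_z)))
        _add_gaussian_spot(vol[zi], px_x / px, px_y / px,
                           particle_amplitude_rel * cytoplasm_mean, max(sigma_px, 0.5))

    if config.shot_noise:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        vol = vol + rng.normal(0.0, config.read_noise_sd, size=vol.shape)

    stack = ImageStack(
        data=vol[np.newaxis, :, np.newaxis],  # Z -> TZCYX
        pixel_size_um=px,
        z_spacing_um=dz,
        channel_names=tuple(config.channels[:1]),
    )
    # ground-truth class per spec: supra-threshold bodies under 0.01 μm²
    # (equatorial section π·rx·ry) are small particles, larger ones IBs
    classes = [
        "small_particle" if np.pi * s.radii_um[0] * s.radii_um[1] < 0.01 else "IB"
        for s in inclusions
    ]
    gt = GroundTruth(
        true_masks=labels,
        true_parameters={
            "inclusions": list(inclusions),
            "classes": classes,
            "cytoplasm_mean": cytoplasm_mean,
            "z_coords_um": zs,
        },
        seed=seed,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap(
    radius_um: float,
    mode: FrapMode | str,
    exchange_rate_per_min: float,
    bleach_depth: float,
    config: AcquisitionConfig,
    duration_min: float,
    seed: int,
    sampling_interval_min: float = 0.5,
    shell_fraction: float = 0.15,
    pre_bleach_frames: int = 1,
    imaging_retention: float = 1.0,
    photons_per_unit: float = 200.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate FRAP of a spherical compartment under three exchange regimes.

    The compartment (equatorial disk of ``radius_um``) starts uniform at
    relative concentration 1; the bleach removes ``bleach_depth`` of it.
    Recovered material R(t) = bleach_depth·(1 − exp(−k·t)) enters the
    compartment and is placed

    * uniformly throughout it (``interior_mixing``),
    * only in a boundary shell of the outer ``shell_fraction`` of the radius
      (``surface_accretion``), or
    * not at all (``no_exchange``).

    Frames are compartment-scale concentration maps on the cytoplasmic
    background: optical blur is deliberately omitted so that the spatial
    pattern of recovery (interior vs. boundary) is directly measurable.
    ``imaging_retention`` < 1 additionally bleaches the whole field per
    acquired frame.
    """
    mode = FrapMode(mode)
    if not (0 <= bleach_depth <= 1):
        raise ValueError("bleach_depth must be in [0, 1]")
    if exchange_rate_per_min < 0:
        raise ValueError("exchange_rate_per_min must be non-negative")
    if not (0 < imaging_retention <= 1):
        raise ValueError("imaging_retention must be in (0, 1]")

    rng = np.random.default_rng(seed)
    h, w = config.field_px
    px = config.pixel_size_um
    cx, cy = (w - 1) / 2 * px, (h - 1) / 2 * px
    yy, xx = np.mgrid[0:h, 0:w]
    r_um = np.hypot(xx * px - cx, yy * px - cy)
    disk = r_um <= radius_um
    shell = disk & (r_um >= (1.0 - shell_fraction) * radius_um)
    core = disk & ~shell
    shell_frac_area = shell.sum() / disk.sum()

    times = np.concatenate([
        -sampling_interval_min * np.arange(pre_bleach_frames, 0, -1),
        np.arange(0.0, duration_min + 1e-9, sampling_interval_min),
    ])
    n_frames = len(times)
    u0 = 1.0
    ub = (1.0 - bleach_depth) * u0
    k = exchange_rate_per_min

    frames = np.empty((n_frames, h, w))
    for i, t in enumerate(times):
        img = np.full((h, w), float(config.background_level))
        if t < 0:
            img[disk] += u0
        else:
            recovered = (u0 - ub) * (1.0 - np.exp(-k * t)) if k > 0 else 0.0
            if mode is FrapMode.INTERIOR_MIXING:
                img[disk] += ub + recovered
            elif mode is FrapMode.SURFACE_ACCRETION:
                img[disk] += ub
                if shell_frac_area > 0:
                    img[shell] += recovered / shell_frac_area
            else:  # NO_EXCHANGE
                img[disk] += ub
        img = (img - config.background_level) * imaging_retention**i + config.background_level
        if config.shot_noise:
            img = (rng.poisson(np.clip(img * photons_per_unit, 0, None))
                   / photons_per_unit)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        frames[i] = img

    stack = ImageStack(
        data=frames[:, np.newaxis, np.newaxis],
        pixel_size_um=px,
        frame_interval_s=sampling_interval_min * 60.0,
        channel_names=tuple(config.channels[:1]),
    )
    gt = GroundTruth(
        true_masks=disk[np.newaxis].repeat(n_frames, axis=0),
        true_parameters={
            "mode": mode.value,
            "radius_um": radius_um,
            "center_px": ((w - 1) / 2, (h - 1) / 2),
            "times_min": times,
            "bleach_frame": pre_bleach_frames,
            "shell_fraction": shell_fraction,
            "exchange_rate_per_min": exchange_rate_per_min,
            "bleach_depth": bleach_depth,
        },
        seed=seed,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# photoconversion pulse-chase
# ---------------------------------------------------------------------------

def simulate_pulse_chase(
    model: PulseChaseModel,
    config: AcquisitionConfig,
    duration_min: float,
    sampling_interval_min: float,
    seed: int,
    noise_sd_frac: float = 0.0,
    ib_area_um2: float = 0.6,
    cyto_volume_au: float = 10.0,
) -> FluxSeries:
    """Integrate the two-pool, two-colour pulse-chase model and sample it.

    The deterministic pools (cytoplasm C, inclusion I, per colour) follow

        C' = −k_in·C + k_out·I − k_deg·C  (+ synthesis, green only)
        I' =  k_in·C − k_out·I

    integrated by a fixed-step explicit update at step ≤ 0.1 / max-rate.
    At each ``division_times`` entry the cytoplasmic pool is divided by
    (1 + daughter_fraction); the amount handed to daughters is retained in
    a ledger (``meta["daughter_au"]``) so that mass balance is checkable.
    Photobleaching physically depletes both pools of a colour by that
    channel's retention factor after every observation.  Measurement noise
    (``noise_sd_frac`` × value, Gaussian) is applied to the reported values
    only.  The returned values are raw (uncorrected) observations.
    """
    if duration_min < 0:
        raise ValueError("duration_min must be non-negative")
    if sampling_interval_min <= 0 or duration_min < sampling_interval_min:
        raise ValueError("need duration >= sampling_interval > 0")

    rng = np.random.default_rng(seed)
    rates = [model.k_in_per_min, model.k_out_per_min, model.k_deg_per_min]
    max_rate = max(rates + [1e-9])
    dt = min(0.1 / max_rate, sampling_interval_min / 10.0)

    # pools: green / red, cytoplasm / inclusion (amounts, A.U.)
    green_c = model.cyto0_au * (1 - model.conversion_fraction)
    green_i = model.ib0_au * (1 - model.conversion_fraction)
    red_c = model.cyto0_au * model.conversion_fraction
    red_i = model.ib0_au * model.conversion_fraction
    degraded = {"green": 0.0, "red": 0.0}
    daughters = {"green": 0.0, "red": 0.0}

    ret = config.bleach_retention_per_exposure
    ret_g = ret.get("green", 1.0)
    ret_r = ret.get("red", 1.0)

    obs_times = np.arange(0.0, duration_min + 1e-9, sampling_interval_min)
    divisions = sorted(float(d) for d in model.division_times_min)
    div_idx = 0

    rows = []
    t = 0.0
    next_obs = 0
    k_in, k_out, k_deg, synth = (model.k_in_per_min, model.k_out_per_min,
                                 model.k_deg_per_min, model.synthesis_rate_au_min)

    def observe(time_min: float) -> None:
        nonlocal green_c, green_i, red_c, red_i
        for ch, (c, i) in (("green", (green_c, green_i)), ("red", (red_c, red_i))):
            mean_i = i / ib_area_um2
            cyto = c / cyto_volume_au
            if noise_sd_frac > 0:
                mean_i *= 1.0 + rng.normal(0.0, noise_sd_frac)
                cyto *= 1.0 + rng.normal(0.0, noise_sd_frac)
            rows.append({
                "time_min": time_min,
                "channel": ch,
                "ib_area_um2": ib_area_um2,
                "ib_mean": mean_i,
                "ib_integrated": mean_i * ib_area_um2,
                "cyto_mean": cyto,
                "corrected": False,
            })
        # imaging photobleaching depletes the pools
        green_c *= ret_g
        green_i *= ret_g
        red_c *= ret_r
        red_i *= ret_r

    observe(0.0)
    next_obs = 1
    t_end = obs_times[-1]
    while next_obs < len(obs_times):
        t_target = obs_times[next_obs]
        while t < t_target - 1e-12:
            step = min(dt, t_target - t)
            # events (divisions) inside this step
            while div_idx < len(divisions) and divisions[div_idx] <= t + 1e-12:
                f = model.daughter_fraction
                lost_g = green_c * (1 - 1 / (1 + f))
                lost_r = red_c * (1 - 1 / (1 + f))
                green_c /= (1 + f)
                red_c /= (1 + f)
                daughters["green"] += lost_g
                daughters["red"] += lost_r
                div_idx += 1
            if div_idx < len(divisions) and divisions[div_idx] < t + step:
                step = divisions[div_idx] - t
            dg_c = (-k_in * green_c + k_out * green_i - k_deg * green_c + synth) * step
            dg_i = (k_in * green_c - k_out * green_i) * step
            dr_c = (-k_in * red_c + k_out * red_i - k_deg * red_c) * step
            dr_i = (k_in * red_c - k_out * red_i) * step
            degraded["green"] += k_deg * green_c * step
            degraded["red"] += k_deg * red_c * step
            green_c += dg_c
            green_i += dg_i
            red_c += dr_c
            red_i += dr_i
            t += step
        # division exactly at the observation time fires before observing
        while div_idx < len(divisions) and divisions[div_idx] <= t + 1e-12:
            f = model.daughter_fraction
            daughters["green"] += green_c * (1 - 1 / (1 + f))
            daughters["red"] += red_c * (1 - 1 / (1 + f))
            green_c /= (1 + f)
            red_c /= (1 + f)
            div_idx += 1
        observe(t_target)
        next_obs += 1

    df = pd.DataFrame(rows)
    meta = {
        "model": model,
        "config": config,
        "daughter_au": dict(daughters),
        "degraded_au": dict(degraded),
        "final_pools": {
            "green_cyto": green_c, "green_ib": green_i,
            "red_cyto": red_c, "red_ib": red_i,
        },
        "ib_area_um2": ib_area_um2,
        "cyto_volume_au": cyto_volume_au,
        "retention": {"green": ret_g, "red": ret_r},
        "seed": seed,
    }
    return FluxSeries(data=df, meta=meta)
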