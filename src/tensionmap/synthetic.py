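"""Synthetic ground-truth scenes and raw acquisition rendering.

Scenes hold per-pixel ground truth (phi, theta, i_max); the renderer turns
a scene into raw striped montages — per-frame expected intensity from the
forward dipole model at the frame's excitation angle, multiplied by a
sinusoidal stripe pattern oriented with the polarization, with Poisson shot
noise, optional Gaussian read noise, and a camera baseline.

Coordinate convention: the in-plane angle phi is measured from the +x
(column) axis toward the +y (row) axis, in degrees, axial (modulo 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import alignment_parameter
from .orientation import AlphaTriplet, DEFAULT_ALPHAS, DEFAULT_B, forward_intensity
from .preprocess import ORIENTATION_MAJOR, SimMontage
from .timelapse import alignment_model, spreading_model

__all__ = [
    "NoiseModel",
    "SyntheticScene",
    "SpreadSchedule",
    "make_uniform_scene",
    "make_platelet_scene",
    "make_bead_phantom",
    "render_montage",
    "render_timelapse",
]


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise description; reproducible given ``seed``."""

    shot_noise: bool = True
    read_noise_sd: float = 0.0
    baseline: float = 200.0
    seed: int = 0


@dataclass
class SyntheticScene:
    """Ground-truth orientation scene: per-pixel phi, theta, i_max."""

    phi: np.ndarray
    theta: np.ndarray
    i_max: np.ndarray
    pixel_size_nm: float = 60.0
    kind: str = "custom"

    def __post_init__(self):
        self.phi = np.mod(np.asarray(self.phi, dtype=float), 180.0)
        self.theta = np.asarray(self.theta, dtype=float)
        self.i_max = np.asarray(self.i_max, dtype=float)
        if not (self.phi.shape == self.theta.shape == self.i_max.shape):
            raise ValueError("scene channels must share one shape")
        if np.any(self.theta < 0) or np.any(self.theta > 90):
            raise ValueError("theta must lie in [0, 90]")
        if np.any(self.i_max < 0):
            raise ValueError("i_max must be nonnegative")

    @property
    def mask(self) -> np.ndarray:
        return self.i_max > 0


def make_uniform_scene(
    shape=(64, 64),
    phi: float = 45.0,
    theta: float = 90.0,
    i_max: float = 1000.0,
    pixel_size_nm: float = 60.0,
) -> SyntheticScene:
    """Scene with one orientation and intensity everywhere."""
    h, w = shape
    return SyntheticScene(
        phi=np.full((h, w), phi),
        theta=np.full((h, w), theta),
        i_max=np.full((h, w), i_max),
        pixel_size_nm=pixel_size_nm,
        kind="uniform",
    )


def _position_angles(shape, center):
    rows, cols = np.indices(shape)
    dy = rows - center[0]
    dx = cols - center[1]
    r = np.hypot(dy, dx)
    psi = np.degrees(np.arctan2(dy, dx))  # (-180, 180]
    return r, psi


def make_platelet_scene(
    shape=(128, 128),
    radius_um: float = 2.4,
    n_lobes: int = 2,
    ring_width_nm: float = 480.0,
    i_max_levels=(1000.0, 800.0),
    pixel_size_nm: float = 60.0,
    seed: int = 0,
    theta_mean: float = 47.0,
    theta_sd: float = 5.0,
) -> SyntheticScene:
    """Platelet-like tension scene: radial outer ring plus aligned inner lobes.

    Ring pixels point radially (phi along the line to the centroid); each
    inner lobe is a sector of the inner disk sharing one common axis (its
    bisector).  Tilt angles are drawn Normal(theta_mean, theta_sd) truncated
    to [0, 90].

    ``i_max_levels`` gives the (ring, lobe) intensity levels.
    """
    if radius_um <= 0:
        raise ValueError("platelet radius must be positive")
    if n_lobes not in (0, 2, 3, 4):
        raise ValueError(f"lobe count must be one of 0, 2, 3, 4; got {n_lobes}")
    h, w = shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius_px = radius_um * 1000.0 / pixel_size_nm
    ring_w_px = max(ring_width_nm / pixel_size_nm, 1.0)
    r, psi = _position_angles(shape, center)

    ring = (r <= radius_px) & (r > radius_px - ring_w_px)
    inner = r <= radius_px - ring_w_px
    if not ring.any():
        raise ValueError("scene radius too small for the image: empty ring")

    rng = np.random.default_rng(seed)
    phi = np.zeros(shape)
    theta = np.zeros(shape)
    i_max = np.zeros(shape)

    ring_level, lobe_level = i_max_levels
    phi[ring] = np.mod(psi[ring], 180.0)  # radial axis, toward the centroid
    i_max[ring] = ring_level

    if n_lobes == 0:
        # ring-only scene: keep the (isotropic, radial) ring and leave the
        # interior dark
        inner = np.zeros(shape, dtype=bool)
    else:
        sector = np.mod(psi[inner], 360.0) // (360.0 / n_lobes)
        bisector = (sector + 0.5) * (360.0 / n_lobes)
        phi[inner] = np.mod(bisector, 180.0)
        i_max[inner] = lobe_level

    cell = ring | inner
    theta[cell] = np.clip(rng.normal(theta_mean, theta_sd, int(cell.sum())), 0.0, 90.0)
    return SyntheticScene(
        phi=phi, theta=theta, i_max=i_max, pixel_size_nm=pixel_size_nm, kind="platelet"
    )


def make_bead_phantom(
    radius_px: float = 12.0,
    i_max: float = 1000.0,
    shape=None,
    pixel_size_nm: float = 60.0,
) -> SyntheticScene:
    """Circle of in-plane dipoles tangent to a bead perimeter.

    Perimeter pixels carry theta = 90 and phi tangent to the circle, so the
    recovered intensity around the perimeter at fixed excitation angle is
    sinusoidal with period 180 degrees.
    """
    if radius_px < 5:
        raise ValueError("bead radius must be at least 5 px")
    if shape is None:
        n = int(2 * radius_px + 9)
        shape = (n, n)
    h, w = shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r, psi = _position_angles(shape, center)
    perimeter = np.abs(r - radius_px) <= 1.0
    phi = np.zeros(shape)
    theta = np.zeros(shape)
    i_max_map = np.zeros(shape)
    phi[perimeter] = np.mod(psi[perimeter] + 90.0, 180.0)  # tangent axis
    theta[perimeter] = 90.0
    i_max_map[perimeter] = i_max
    return SyntheticScene(
        phi=phi, theta=theta, i_max=i_max_map, pixel_size_nm=pixel_size_nm, kind="bead-phantom"
    )


def _stripe_pattern(shape, alpha_deg, period_px, phase_rad, modulation):
    if modulation == 0.0:
        return np.ones(shape)
    rows, cols = np.indices(shape)
    # stripes run along the polarization direction; intensity varies along
    # the perpendicular axis
    perp = np.radians(alpha_deg + 90.0)
    u = cols * np.cos(perp) + rows * np.sin(perp)
    return 1.0 + modulation * np.cos(2.0 * np.pi * u / period_px + phase_rad)


def _expected_scene_intensity(scene, alpha_deg, b):
    base = forward_intensity(scene.phi, scene.theta, scene.i_max, alpha_deg, b=b)
    return np.where(scene.mask, base, 0.0)


def render_montage(
    scene: SyntheticScene,
    alphas: AlphaTriplet | None = None,
    phases: int = 5,
    stripe_period_px: float = 8.0,
    modulation: float = 0.8,
    noise: NoiseModel | None = None,
    b: float = DEFAULT_B,
    rng: np.random.Generator | None = None,
    timestamp_min: float | None = None,
    intensity_scale: float = 1.0,
) -> SimMontage:
    """Render a raw striped acquisition of a scene.

    Each frame is ``baseline + noise(scene intensity at the frame's alpha
    times the stripe pattern)``; the P phase steps are 2*pi/P apart so that
    phase averaging cancels the stripes exactly.
    """
    if phases not in (1, 3, 5):
        raise ValueError(f"phases must be 1, 3 or 5; got {phases}")
    if stripe_period_px < 4:
        raise ValueError("stripe period must be at least 4 px")
    if alphas is None:
        alphas = AlphaTriplet(*DEFAULT_ALPHAS)
    if noise is None:
        noise = NoiseModel(shot_noise=False, baseline=0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    frames = []
    for alpha in alphas.as_array():
        expected = _expected_scene_intensity(scene, alpha, b) * intensity_scale
        for j in range(phases):
            phase = 2.0 * np.pi * j / phases
            pattern = _stripe_pattern(scene.phi.shape, alpha, stripe_period_px, phase, modulation)
            frame = expected * pattern
            if noise.shot_noise:
                frame = rng.poisson(frame).astype(float)
            if noise.read_noise_sd > 0:
                frame = frame + rng.normal(0.0, noise.read_noise_sd, frame.shape)
            frames.append(frame + noise.baseline)
    return SimMontage(
        frames=np.stack(frames),
        alphas=alphas,
        camera_baseline=noise.baseline,
        pixel_size_nm=scene.pixel_size_nm,
        layout=ORIENTATION_MAJOR,
        timestamp_min=timestamp_min,
    )


@dataclass(frozen=True)
class SpreadSchedule:
    """Ground-truth kinetic parameters driving a synthetic timelapse."""

    t_max_um2: float = 20.0
    t_attach_min: float = 10.0
    t_detach_min: float = 24.0
    tau_spread_min: float = 1.7
    tau_retract_min: float = 2.0
    t0_um2: float = 0.0
    r0: float = 0.2
    r_max: float = 0.7
    tau_align_min: float = 5.0
    phi_axis_deg: float = 30.0
    theta_deg: float = 90.0
    i_max: float = 1000.0
    background_i_max: float = 50.0

    def tension_area(self, t):
        return spreading_model(
            t,
            self.t_max_um2,
            self.t_attach_min,
            self.t_detach_min,
            self.tau_spread_min,
            self.tau_retract_min,
            self.t0_um2,
        )

    def alignment(self, t):
        t = np.asarray(t, dtype=float)
        r = alignment_model(t, self.r0, self.r_max, self.tau_align_min, self.t_attach_min)
        return np.where(t >= self.t_attach_min, r, self.r0)


def _schedule_scene(
    schedule: SpreadSchedule,
    t: float,
    shape,
    pixel_size_nm: float,
    center,
    rng: np.random.Generator,
    bleach_factor: float,
    texture=None,
):
    h, w = shape
    px_um2 = (pixel_size_nm * 1e-3) ** 2
    area_px = float(schedule.tension_area(t)) / px_um2
    phi = rng.uniform(0.0, 180.0, size=shape)
    theta = np.full(shape, schedule.theta_deg)
    i_max = np.full(shape, schedule.background_i_max * bleach_factor)
    disk = np.zeros(shape, dtype=bool)
    if area_px >= 1.0:
        radius = np.sqrt(area_px / np.pi)
        r, _ = _position_angles(shape, center)
        disk = r <= radius
        r_align = float(np.clip(schedule.alignment(t), 0.0, 1.0))
        aligned = rng.random(size=shape) < r_align
        phi = np.where(disk & aligned, schedule.phi_axis_deg, phi)
        cell_i_max = schedule.i_max * bleach_factor
        if texture is not None:
            cell_i_max = cell_i_max * texture
        i_max = np.where(disk, cell_i_max, i_max)
    scene = SyntheticScene(
        phi=phi, theta=theta, i_max=i_max, pixel_size_nm=pixel_size_nm, kind="schedule"
    )
    return scene, disk


def render_timelapse(
    schedule: SpreadSchedule,
    shape=(96, 96),
    interval_min: float = 2.0,
    duration_min: float = 82.0,
    bleach_tau_min: float = np.inf,
    drift_per_frame_px=(0.0, 0.0),
    noise: NoiseModel | None = None,
    alphas: AlphaTriplet | None = None,
    phases: int = 5,
    stripe_period_px: float = 8.0,
    modulation: float = 0.8,
    pixel_size_nm: float = 60.0,
):
    """Render a timelapse of raw montages driven by a kinetic schedule.

    Global intensity decays as exp(-t / bleach_tau); the cell centroid
    drifts by ``drift_per_frame_px`` (row, col) each frame.

    Returns
    -------
    montages : list of SimMontage
    truth : dict
        Per-frame ground truth: times, tension area, alignment, bleach
        factor, cumulative drift.
    """
    if noise is None:
        noise = NoiseModel(shot_noise=False, baseline=0.0)
    times = np.arange(0.0, duration_min + 1e-9, interval_min)
    rng = np.random.default_rng(noise.seed)
    h, w = shape
    base_center = ((h - 1) / 2.0, (w - 1) / 2.0)

    # static intensity texture pinned to the cell (moves with the drift):
    # real tension maps are textured, which is what makes frame-to-frame
    # registration well-posed
    from scipy import ndimage as _ndi

    n_frames = times.size
    total_drift = np.abs(np.asarray(drift_per_frame_px, dtype=float)) * (n_frames - 1)
    margin = int(np.ceil(total_drift.max())) + 4
    tex_rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(1)[0])
    tex_big = _ndi.gaussian_filter(tex_rng.random((h + 2 * margin, w + 2 * margin)), 2.0)
    tex_big = 0.7 + 0.6 * (tex_big - tex_big.min()) / max(np.ptp(tex_big), 1e-12)
    montages = []
    drifts = np.zeros((times.size, 2))
    bleach = np.ones(times.size)
    realized_r = np.full(times.size, np.nan)
    for k, t in enumerate(times):
        drifts[k] = np.asarray(drift_per_frame_px, dtype=float) * k
        bleach[k] = np.exp(-t / bleach_tau_min) if np.isfinite(bleach_tau_min) else 1.0
        center = (base_center[0] + drifts[k][0], base_center[1] + drifts[k][1])
        rows = np.arange(h)[:, None] + margin - drifts[k][0]
        cols = np.arange(w)[None, :] + margin - drifts[k][1]
        texture = _ndi.map_coordinates(
            tex_big,
            np.broadcast_arrays(rows + np.zeros((h, w)), cols + np.zeros((h, w))),
            order=1,
            mode="nearest",
        )
        scene, disk = _schedule_scene(
            schedule, t, shape, pixel_size_nm, center, rng, bleach[k], texture=texture
        )
        if disk.any():
            realized_r[k] = alignment_parameter(scene.phi[disk])
        montages.append(
            render_montage(
                scene,
                alphas=alphas,
                phases=phases,
                stripe_period_px=stripe_period_px,
                modulation=modulation,
                noise=noise,
                rng=rng,
                timestamp_min=float(t),
            )
        )
    truth = {
        "times_min": times,
        "tension_area_um2": schedule.tension_area(times),
        "alignment": schedule.alignment(times),
        "alignment_realized": realized_r,
        "bleach_factor": bleach,
        "drift_px": drifts,
    }
    return montages, truth
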