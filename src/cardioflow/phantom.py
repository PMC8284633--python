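"""Synthetic beating-heart and tracer-flow phantoms with exhaustive ground truth.

The phantom emulates the two acquisitions the analysis pipeline consumes:

* a periodically contracting ellipsoidal myocardial shell, imaged slice by
  slice so that each z-slice time sequence carries an unknown cardiac phase
  offset (the retrospective-gating input), and
* sparse blood-cell tracers advected along a curved planar path with a
  pulsatile, sign-changing speed profile (the particle-tracking input).

Every generated dataset is paired with a :class:`PhantomTruth` that exposes
the analytic displacement field, the true particle trajectories, the true
path geometry, and the per-slice phase offsets, so each downstream stage can
be scored against exact ground truth.

Motion model
------------
Material points are labelled by their normalized offset ``mu`` from the shell
center (offset divided by the ellipsoid semi-axes). A point moves as::

    x(t) = c + mu * radii * g(t, z_ref)
    g(t, z_ref) = 1 + a * sin(2*pi*t/P + k * (z_ref - z_apex))

with contraction amplitude ``a``, period ``P`` frames, and phase-propagation
rate ``k`` (rad/um) along the apex->base axis, so contraction starts at the
apex and travels toward the base. The map is exactly periodic in ``t`` and
closed-form invertible (a scalar fixed point), which gives an analytic
displacement sampler between any two frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datatypes import SliceScan, Volume4D

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_beating_heart",
    "simulate_slice_scan",
    "make_particle_flow",
    "make_oscillating_slab",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic acquisition.

    Defaults describe a 3 dpf-scale ventricle: ~80 um ellipsoidal shell with
    an 8 um wall contracting by 12% of its radius, beating with a 40-frame
    period at 200 Hz, and ~20 circulating tracers whose pulsatile speed
    profile (mean 1200 um/s, amplitude 2400 um/s) reverses below
    -1000 um/s for a third of the cycle.
    """

    shape: tuple[int, int, int] = (32, 64, 64)      # (z, y, x) voxels
    voxel_size_um: float = 2.0                      # isotropic
    period_frames: int = 40
    n_cycles: int = 4
    frame_rate_hz: float = 200.0
    center_um: Optional[tuple[float, float, float]] = None  # default: grid center
    radii_um: tuple[float, float, float] = (24.0, 40.0, 34.0)  # (z, y, x) semi-axes
    wall_thickness_um: float = 8.0
    contraction_amplitude: float = 0.12             # fraction of radius
    phase_rate_rad_per_um: float = 0.02             # apex -> base propagation
    edge_sigma_um: float = 2.0                      # Gaussian shell edge (1 voxel)
    n_particles: int = 20
    speed_mean_um_s: float = 1200.0
    speed_amplitude_um_s: Optional[float] = 2400.0
    reversal_fraction: Optional[float] = None       # derives amplitude if set
    path_radius_um: float = 40.0
    path_span_rad: float = 8.0 * np.pi / 9.0        # 160 degree arc
    tube_radius_um: float = 6.0                     # lateral tracer spread
    spot_sigma_um: float = 2.0
    noise_sigma: float = 0.0                        # additive Gaussian, intensity units
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_frames < 8:
            raise ValueError("cardiac period must be at least 8 frames")
        if not (0.0 <= self.contraction_amplitude < 0.5):
            raise ValueError("contraction amplitude must lie in [0, 0.5)")
        if self.n_particles < 0:
            raise ValueError("particle count must be nonnegative")
        for name in ("voxel_size_um", "wall_thickness_um", "edge_sigma_um",
                     "path_radius_um", "tube_radius_um", "spot_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(r <= 0 for r in self.radii_um):
            raise ValueError("shell radii must be positive")
        if self.n_cycles < 1 or self.frame_rate_hz <= 0:
            raise ValueError("need at least one cycle and a positive frame rate")
        if self.reversal_fraction is not None:
            if not (0.0 <= self.reversal_fraction < 0.5):
                raise ValueError("reversal fraction must lie in [0, 0.5)")
            # v(t) = m + A sin(2 pi t / P) is negative for a fraction
            # f = 1/2 - asin(m/A)/pi of the cycle; inverting gives A:
            self.speed_amplitude_um_s = self.speed_mean_um_s / np.cos(
                np.pi * self.reversal_fraction
            )
        elif self.speed_amplitude_um_s is None:
            raise ValueError("give either speed_amplitude_um_s or reversal_fraction")

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def grid_center_um(self) -> np.ndarray:
        if self.center_um is not None:
            return np.asarray(self.center_um, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0 * self.voxel_size_um

    def speed_profile(self, t_frames: np.ndarray) -> np.ndarray:
        """Pulsatile tracer speed v(t) in um/s at (possibly fractional) frames."""
        t = np.asarray(t_frames, dtype=float)
        return self.speed_mean_um_s + self.speed_amplitude_um_s * np.sin(
            2.0 * np.pi * t / self.period_frames
        )

    def reversal_window_frames(self) -> Optional[tuple[float, float]]:
        """Closed-form frame interval where the speed profile is negative."""
        m, a = self.speed_mean_um_s, self.speed_amplitude_um_s
        if a <= m:
            return None
        p = self.period_frames
        x = np.arcsin(m / a)
        return ((np.pi + x) * p / (2 * np.pi), (2 * np.pi - x) * p / (2 * np.pi))


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom dataset."""

    config: PhantomConfig
    displacement: Optional[Callable] = None     # (points_um, t0, t1) -> (n, 3) um
    slice_offsets: Optional[np.ndarray] = None  # (Z,) int frames in [0, P)
    trajectories: Optional[dict] = None         # id -> dict(frames, positions_um, wrapped)
    path_points_um: Optional[np.ndarray] = None # dense true centerline samples
    path_center_um: Optional[np.ndarray] = None
    wall_positions_um: Optional[Callable] = None  # slab phantom: t -> (y_lo, y_hi)

    def shell_points(self, n: int, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Random material points on the shell mid-surface, reference positions (um)."""
        rng = rng or np.random.default_rng(self.config.seed + 101)
        v = rng.normal(size=(n, 3))
        mu = v / np.linalg.norm(v, axis=1, keepdims=True)
        return self.config.grid_center_um + mu * np.asarray(self.config.radii_um)

    def true_velocity(self, track_id: int) -> np.ndarray:
        """Finite-difference velocities (um/s) of a true trajectory; NaN on wrap steps."""
        tr = self.trajectories[track_id]
        pos, frames = tr["positions_um"], tr["frames"]
        v = np.full_like(pos, np.nan)
        dt = np.diff(frames)[:, None] * self.config.frame_interval_s
        v[:-1] = np.diff(pos, axis=0) / dt
        v[:-1][tr["wrapped"][1:]] = np.nan
        return v


# ---------------------------------------------------------------------------
# beating-heart shell
# ---------------------------------------------------------------------------

def _scale_factor(cfg: PhantomConfig, q_norm: np.ndarray, t: float,
                  n_iter: int = 40, tol: float = 1e-13) -> np.ndarray:
    """Solve g = 1 + a sin(w t + k (z_ref - z_apex)) with z_ref = c_z + q_z r_z / g.

    ``q_norm`` are Eulerian normalized offsets (x - c) / radii at frame t.
    The fixed point contracts because a * k * r_z < 1 for sane configs.
    """
    a = cfg.contraction_amplitude
    w = 2.0 * np.pi / cfg.period_frames
    k = cfg.phase_rate_rad_per_um
    rz = cfg.radii_um[0]
    qz = q_norm[..., 0]
    # z_apex is the low-z pole of the reference shell
    g = np.ones_like(qz)
    for _ in range(n_iter):
        z_ref_rel = qz * rz / g          # z_ref - c_z
        g_new = 1.0 + a * np.sin(w * t + k * (z_ref_rel + rz))
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new
    return g


def _phase_at(cfg: PhantomConfig, z_ref_um: np.ndarray) -> np.ndarray:
    """Local contraction phase offset k (z_ref - z_apex) for reference z (um)."""
    c = cfg.grid_center_um
    z_apex = c[0] - cfg.radii_um[0]
    return cfg.phase_rate_rad_per_um * (np.asarray(z_ref_um) - z_apex)


def _render_shell_frame(cfg: PhantomConfig, t: float,
                        coords_norm: np.ndarray, radial_um: np.ndarray) -> np.ndarray:
    """Intensity image of the shell at frame t on the precomputed grid."""
    g = _scale_factor(cfg, coords_norm, t)
    m_ref = np.linalg.norm(coords_norm, axis=-1) / g   # material normalized radius
    # physical signed distance from the (current) shell mid-surface, measured
    # along the ray through the voxel: current radius to the surface is
    # r_dir * g where r_dir = |x - c| / |q_norm|
    with np.errstate(invalid="ignore", divide="ignore"):
        r_dir = np.where(m_ref > 0, radial_um / np.maximum(m_ref * g, 1e-12), np.inf)
    delta = (m_ref - 1.0) * r_dir * g
    delta = np.where(np.isfinite(delta), delta, -1e6)
    excess = np.maximum(np.abs(delta) - cfg.wall_thickness_um / 2.0, 0.0)
    return np.exp(-(excess ** 2) / (2.0 * cfg.edge_sigma_um ** 2)).astype(np.float32)


def make_beating_heart(config: PhantomConfig) -> tuple[Volume4D, PhantomTruth]:
    """Render the contracting-shell series and its analytic displacement sampler.

    Returns a clean (noise-free) ``(n_cycles * period)``-frame series; the
    noise model applies to the simulated acquisitions built from it
    (:func:`simulate_slice_scan`). Exactly periodic with the cardiac period
    by construction and deterministic given the config.
    """
    cfg = config
    c = cfg.grid_center_um
    radii = np.asarray(cfg.radii_um, dtype=float)
    half_extent = (np.asarray(cfg.shape) - 1) * cfg.voxel_size_um / 2.0
    max_r = radii * (1.0 + cfg.contraction_amplitude) + cfg.wall_thickness_um / 2.0
    if cfg.center_um is None and np.any(max_r > half_extent + cfg.voxel_size_um):
        raise ValueError(
            f"shell radii {tuple(radii)} um (plus wall and contraction) exceed the "
            f"grid half-extent {tuple(half_extent)} um"
        )

    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * cfg.voxel_size_um for n in cfg.shape), indexing="ij"
    )
    coords = np.stack([zz, yy, xx], axis=-1) - c
    coords_norm = coords / radii
    radial_um = np.linalg.norm(coords, axis=-1)

    one_period = np.stack(
        [_render_shell_frame(cfg, t, coords_norm, radial_um)
         for t in range(cfg.period_frames)]
    )
    data = np.tile(one_period, (cfg.n_cycles, 1, 1, 1))
    vol = Volume4D(
        data=data,
        spacing_um=(cfg.voxel_size_um,) * 3,
        frame_interval_s=cfg.frame_interval_s,
    )

    w = 2.0 * np.pi / cfg.period_frames
    a = cfg.contraction_amplitude

    def displacement(points_um: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """Analytic material displacement (um) from frame t0 to t1 at points given at t0."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        q = (pts - c) / radii
        g0 = _scale_factor(cfg, q, t0)
        mu = q / g0[..., None]                     # material coordinates
        z_ref = c[0] + mu[..., 0] * radii[0]
        phi = _phase_at(cfg, z_ref)
        g1 = 1.0 + a * np.sin(w * t1 + phi)
        x1 = c + mu * radii * g1[..., None]
        return x1 - pts

    truth = PhantomTruth(config=cfg, displacement=displacement)
    return vol, truth


# ---------------------------------------------------------------------------
# slice-scanned acquisition
# ---------------------------------------------------------------------------

def simulate_slice_scan(
    truth_volume: Volume4D,
    config: PhantomConfig,
    truth: Optional[PhantomTruth] = None,
) -> tuple[SliceScan, PhantomTruth]:
    """Re-image the periodic truth volume slice by slice with random phase offsets.

    Each z slice becomes an independent time sequence of ``n_cycles * period``
    frames (>= 4 cardiac cycles with the defaults, tiling the periodic
    truth), circularly offset by an integer phase drawn uniformly on
    [0, period) per slice, then corrupted with the configured background and
    Gaussian noise. The drawn offsets are recorded in the returned truth.
    """
    cfg = config
    P = cfg.period_frames
    if truth_volume.n_frames < P:
        raise ValueError("truth volume must cover at least one full period")
    rng = np.random.default_rng([cfg.seed, 1])
    n_z = truth_volume.shape_zyx[0]
    offsets = rng.integers(0, P, size=n_z)
    one_period = np.asarray(truth_volume.data[:P], dtype=np.float32)
    n_frames = cfg.n_cycles * P

    sequences = []
    for k in range(n_z):
        sl = one_period[:, k]                             # (P, Y, X)
        idx = (np.arange(n_frames) + offsets[k]) % P
        seq = sl[idx] + cfg.background
        if cfg.noise_sigma > 0:
            seq = seq + rng.normal(0.0, cfg.noise_sigma, size=seq.shape)
        sequences.append(seq.astype(np.float32))

    scan = SliceScan(
        z_positions_um=np.arange(n_z) * truth_volume.spacing_um[0],
        sequences=sequences,
        frame_rate_hz=cfg.frame_rate_hz,
        pixel_size_um=truth_volume.spacing_um[1],
    )
    if truth is None:
        truth = PhantomTruth(config=cfg)
    truth.slice_offsets = offsets
    return scan, truth


# ---------------------------------------------------------------------------
# particle flow
# ---------------------------------------------------------------------------

def _arc_path(cfg: PhantomConfig):
    """Default tracer path: a planar circular arc (AV canal -> outflow tract).

    Returns (position(theta), tangent(theta), normal(theta), theta span,
    total arc length). The arc lies in the central z plane.
    """
    c = cfg.grid_center_um
    R = cfg.path_radius_um

    def position(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(theta)
        return np.stack(
            [np.full_like(theta, c[0]),
             c[1] + R * np.sin(theta),
             c[2] + R * np.cos(theta)], axis=-1
        )

    def tangent(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(theta)
        t = np.stack(
            [np.zeros_like(theta), np.cos(theta), -np.sin(theta)], axis=-1
        )
        return t

    def normal(theta: np.ndarray) -> np.ndarray:       # outward radial
        theta = np.atleast_1d(theta)
        return np.stack(
            [np.zeros_like(theta), np.sin(theta), np.cos(theta)], axis=-1
        )

    return position, tangent, normal, cfg.path_span_rad, R * cfg.path_span_rad


def _integrated_arclength(cfg: PhantomConfig, t_frames: np.ndarray) -> np.ndarray:
    """Closed-form integral of the speed profile from 0 to each frame time (um)."""
    t = np.asarray(t_frames, dtype=float) * cfg.frame_interval_s
    period_s = cfg.period_frames * cfg.frame_interval_s
    w = 2.0 * np.pi / period_s
    m, a = cfg.speed_mean_um_s, cfg.speed_amplitude_um_s
    return m * t - (a / w) * (np.cos(w * t) - 1.0)


def _render_spots(cfg: PhantomConfig, shape, positions_um: np.ndarray) -> np.ndarray:
    """Additively render Gaussian spots (amplitude 1) at the given positions."""
    frame = np.zeros(shape, dtype=np.float32)
    vs = cfg.voxel_size_um
    sig = cfg.spot_sigma_um / vs
    half = int(np.ceil(4 * sig))
    for p in positions_um:
        v = p / vs
        lo = np.maximum(np.floor(v - half).astype(int), 0)
        hi = np.minimum(np.ceil(v + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        d2 = sum((g - vv) ** 2 for g, vv in zip(grids, v))
        frame[tuple(slice(l, h) for l, h in zip(lo, hi))] += np.exp(
            -d2 / (2.0 * sig ** 2)
        ).astype(np.float32)
    return frame


def make_particle_flow(config: PhantomConfig) -> tuple[Volume4D, PhantomTruth]:
    """Advect tracers along the arc path with the pulsatile speed profile.

    Tracers carry fixed lateral offsets (within ``tube_radius_um``) in the
    parallel-transported frame of the path, so the pooled cloud fills a tube
    around the true centerline. Arc length wraps at the path ends (a cell
    exiting the outflow tract is replaced by one entering at the AV canal,
    recorded as a ``wrapped`` step in the truth). Spots leaving the grid are
    dropped from the images but kept in the truth.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    position, tangent, normal, span, total_len = _arc_path(cfg)
    n_frames = cfg.n_cycles * cfg.period_frames
    n = cfg.n_particles

    # Tracers transit the path once each, like blood cells traversing the
    # ventricle: entries are staggered in arc length so only a few cells are
    # on the path at any time and concurrent spots stay well separated.
    # Lateral offsets follow a golden-angle layout in the tube cross-section
    # with a small seeded jitter.
    i = np.arange(n)
    ds = _integrated_arclength(cfg, np.arange(n_frames))
    net_advance = ds[-1] if n_frames > 1 else total_len
    entry_gap = (net_advance + total_len) / max(n, 1)
    s0 = -i * entry_gap + rng.uniform(-0.05, 0.05, size=n) * entry_gap
    golden = 2.0 * np.pi * (1.0 - 1.0 / 1.618033988749895)
    off_r = cfg.tube_radius_um * np.cos(golden * i)
    off_z = cfg.tube_radius_um * np.sin(golden * i)

    s = s0[:, None] + ds[None, :]                       # (n, T) own arc length
    shape = tuple(cfg.shape)
    extent = (np.asarray(shape) - 1) * cfg.voxel_size_um
    trajectories: dict[int, dict] = {}
    frames_data = np.zeros((n_frames,) + shape, dtype=np.float32)

    # plug flow: every tracer advances along its own laterally offset curve
    # at exactly the profile speed v(t), so per-frame displacement magnitude
    # is the integrated speed for every cell
    radius_k = cfg.path_radius_um + off_r
    theta_all = s / radius_k[:, None]
    present = (theta_all >= 0.0) & (theta_all <= span)

    positions_all = np.empty((n, n_frames, 3))
    zhat = np.array([1.0, 0.0, 0.0])
    for k in range(n):
        th = np.clip(theta_all[k], 0.0, span)
        base = position(th)
        nrm = normal(th)
        positions_all[k] = base + off_r[k] * nrm + off_z[k] * zhat

    for t in range(n_frames):
        pts = positions_all[present[:, t], t]
        if len(pts):
            inside = np.all((pts >= 0) & (pts <= extent), axis=1)
            frame = _render_spots(cfg, shape, pts[inside])
        else:
            frame = np.zeros(shape, dtype=np.float32)
        frame = frame + cfg.background
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape).astype(
                np.float32
            )
        frames_data[t] = frame

    for k in range(n):
        on = np.flatnonzero(present[k])
        if on.size == 0:
            continue
        # contiguous presence only: a tracer that backs out across the AV end
        # during reversal re-enters as the same id; mark the discontinuity
        gaps = np.diff(on) != 1
        wrapped = np.zeros(on.size, dtype=bool)
        wrapped[1:] = gaps
        trajectories[k] = {
            "frames": on,
            "positions_um": positions_all[k, on],
            "wrapped": wrapped,
            "arc_length_um": s[k, on],
        }

    theta_dense = np.linspace(0.0, span, 200)
    truth = PhantomTruth(
        config=cfg,
        trajectories=trajectories,
        path_points_um=position(theta_dense),
        path_center_um=cfg.grid_center_um.copy(),
    )
    vol = Volume4D(
        data=frames_data,
        spacing_um=(cfg.voxel_size_um,) * 3,
        frame_interval_s=cfg.frame_interval_s,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# oscillating-slab phantom (kymograph angle-dependence fixture)
# ---------------------------------------------------------------------------

def make_oscillating_slab(
    config: PhantomConfig,
    half_gap_um: float = 24.0,
    oscillation_um: float = 6.0,
) -> tuple[Volume4D, PhantomTruth]:
    """Synthetic fixture: two parallel walls (normal to y) breathing apart.

    The walls sit at ``y = c_y -/+ h(t)`` with ``h(t) = half_gap +
    oscillation * sin(2 pi t / P)`` and move purely along y, so a sampling
    line tilted by ``alpha`` from y sees the boundary gap inflated by exactly
    ``1 / cos(alpha)`` — the geometric oracle for the kymograph
    angle-dependence check. Truth provides the wall positions and velocities.
    """
    cfg = config
    shape = tuple(cfg.shape)
    c = cfg.grid_center_um
    n_frames = cfg.n_cycles * cfg.period_frames
    y = np.arange(shape[1]) * cfg.voxel_size_um
    w = cfg.wall_thickness_um
    sig = cfg.edge_sigma_um
    omega = 2.0 * np.pi / cfg.period_frames

    def h(t):
        return half_gap_um + oscillation_um * np.sin(omega * t)

    data = np.zeros((n_frames,) + shape, dtype=np.float32)
    for t in range(n_frames):
        ht = h(t)
        prof = np.zeros_like(y)
        for wall_y in (c[1] - ht, c[1] + ht):
            excess = np.maximum(np.abs(y - wall_y) - w / 2.0, 0.0)
            prof += np.exp(-(excess ** 2) / (2.0 * sig ** 2))
        data[t] = prof[None, :, None]

    def wall_positions(t):
        return (c[1] - h(t), c[1] + h(t))

    truth = PhantomTruth(config=cfg, wall_positions_um=wall_positions)
    vol = Volume4D(
        data=data,
        spacing_um=(cfg.voxel_size_um,) * 3,
        frame_interval_s=cfg.frame_interval_s,
    )
    return vol, truth
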