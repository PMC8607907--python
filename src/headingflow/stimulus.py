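"""Dot-cloud optic-flow stimulus generation.

A virtual observer translates at constant speed through a 3D cloud of dots.
The scene is observer-centered: +z is the optical axis, x/y follow
right-handed conventions, and dots are projected onto a 128x128 pixel image
through a pinhole camera.  Horizontal heading ``theta`` (azimuth, degrees)
gives the translation vector ``T = (o*sin(theta), 0, o*cos(theta))``.

Rigid "signal" dots stream past the observer and their image motion follows
the instantaneous optic-flow equations.  "Noise" dots instead hold a constant
mean position relative to the observer (their *anchor*) and jitter around it
uniformly each frame, producing locally incoherent directions and speeds that
share the background statistics of the scene.  Dots that leave the field of
view or come closer than the near clip are replaced so that every frame
carries exactly ``n_dots`` motion vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SceneConfig",
    "DotCloud",
    "FlowFrame",
    "FlowSequence",
    "px_to_deg",
    "deg_to_px",
    "project",
    "analytic_flow",
    "init_cloud",
    "step_cloud",
    "generate_sequence",
    "IMAGE_SIZE",
    "FOCAL_PX",
    "IMAGE_CENTER",
]

#: image resolution (square, pixels)
IMAGE_SIZE = 128
#: focal length in pixel units; a 90 deg field of view puts the image
#: half-width exactly one focal length from the optical axis.
FOCAL_PX = 64.0
#: image center in grid coordinates (pixels)
IMAGE_CENTER = (64.0, 64.0)


def px_to_deg(d_px, f: float = FOCAL_PX):
    """Convert a pixel offset from the image center to visual degrees.

    Uses the tangent mapping ``deg = atan(d/f)`` of the pinhole camera,
    e.g. 8 px -> 7.1 deg and 128 px -> 63.4 deg with f = 64.
    """
    return np.degrees(np.arctan2(d_px, f))


def deg_to_px(d_deg, f: float = FOCAL_PX):
    """Inverse of :func:`px_to_deg`: visual degrees to pixel offset."""
    return f * np.tan(np.radians(d_deg))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one optic-flow stimulus.

    Defaults reproduce the standard scene: 300 dots in a 300 x 300 x 100 m
    volume starting 1 m in front of the observer, 1.5 m/s self-motion,
    a 90 deg field of view and a 2 s / 60 frame video.
    """

    heading_deg: float = 0.0
    speed: float = 1.5                      # m/s
    extent: tuple[float, float, float] = (300.0, 300.0, 100.0)  # m
    n_dots: int = 300
    fov_deg: float = 90.0
    focal_px: float = FOCAL_PX
    n_frames: int = 60
    frame_rate: float = 30.0                # frames/s
    noise_prop: float = 0.0                 # fraction of noise dots in [0, 1]
    noise_jitter: float = 1.0               # max per-axis displacement width (m)
    grid_px: int = IMAGE_SIZE
    min_depth: float = 1.0                  # near clip (m)
    observer_height: float = 1.61           # m; carried for provenance, unused

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_prop <= 1.0:
            raise ValueError(f"noise_prop must be in [0, 1], got {self.noise_prop}")
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.n_frames <= 0 or self.frame_rate <= 0:
            raise ValueError("n_frames and frame_rate must be positive")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")
        if self.noise_jitter < 0:
            raise ValueError("noise_jitter must be nonnegative")

    @property
    def n_noise(self) -> int:
        return int(round(self.noise_prop * self.n_dots))

    @property
    def translation(self) -> np.ndarray:
        """Observer translation (Tx, Ty, Tz) in m/s."""
        th = np.radians(self.heading_deg)
        return np.array([self.speed * np.sin(th), 0.0, self.speed * np.cos(th)])

    @property
    def tan_half_fov(self) -> float:
        return float(np.tan(np.radians(self.fov_deg) / 2.0))

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DotCloud:
    """Observer-centered dot positions for one frame.

    ``positions`` are (n_dots, 3) in meters.  Noise dots carry a constant
    ``anchor`` (their mean observer-relative position); rigid dots have no
    anchor entry.
    """

    positions: np.ndarray           # (T, 3) m
    is_noise: np.ndarray            # (T,) bool
    anchors: np.ndarray             # (n_noise, 3) m, rows align with is_noise order

    def copy(self) -> "DotCloud":
        return DotCloud(self.positions.copy(), self.is_noise.copy(), self.anchors.copy())


@dataclass(frozen=True)
class FlowFrame:
    """One frame of optic flow: image positions (px) and velocities (px/s)."""

    index: int
    positions: np.ndarray           # (T, 2) grid coordinates, origin top-left-ish corner
    velocities: np.ndarray          # (T, 2) px/s
    is_noise: np.ndarray            # (T,) bool

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])

    @property
    def directions_rad(self) -> np.ndarray:
        return np.arctan2(self.velocities[:, 1], self.velocities[:, 0])


@dataclass
class FlowSequence:
    """An ordered stack of flow frames plus the generating config and seed."""

    config: SceneConfig
    seed: int | None
    positions: np.ndarray           # (F, T, 2) px, grid coordinates
    velocities: np.ndarray          # (F, T, 2) px/s
    is_noise: np.ndarray            # (T,) bool

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __iter__(self) -> Iterator[FlowFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def frame(self, i: int) -> FlowFrame:
        return FlowFrame(i, self.positions[i], self.velocities[i], self.is_noise)

    @property
    def speeds(self) -> np.ndarray:
        """(F, T) optical speeds in px/s."""
        return np.hypot(self.velocities[..., 0], self.velocities[..., 1])

    @property
    def directions_rad(self) -> np.ndarray:
        """(F, T) motion directions in radians."""
        return np.arctan2(self.velocities[..., 1], self.velocities[..., 0])

    def speed_range(self) -> tuple[float, float]:
        s = self.speeds
        return float(s.min()), float(s.max())

    def to_frame_table(self) -> pd.DataFrame:
        """Long-format table: frame, dot_id, is_noise, x_px, y_px, vx_px_s, vy_px_s."""
        n_f, n_t, _ = self.positions.shape
        frame_idx = np.repeat(np.arange(n_f), n_t)
        dot_id = np.tile(np.arange(n_t), n_f)
        return pd.DataFrame(
            {
                "frame": frame_idx,
                "dot_id": dot_id,
                "is_noise": np.tile(self.is_noise, n_f),
                "x_px": self.positions[..., 0].ravel(),
                "y_px": self.positions[..., 1].ravel(),
                "vx_px_s": self.velocities[..., 0].ravel(),
                "vy_px_s": self.velocities[..., 1].ravel(),
            }
        )

    def save(self, path: str | Path) -> None:
        """Write the sequence as CSV with a JSON sidecar holding config+seed."""
        path = Path(path)
        self.to_frame_table().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"config": self.config.to_dict(), "seed": self.seed}, indent=2)
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def project(points: np.ndarray, f: float = FOCAL_PX) -> np.ndarray:
    """Pinhole projection ``(x, y) = f/Z (X, Y)`` in center-origin pixels.

    ``points`` is (..., 3); all depths must be strictly positive (dots behind
    or at the camera plane must be respawned before projection).
    """
    points = np.asarray(points, dtype=float)
    z = points[..., 2]
    if np.any(z <= 0):
        raise ValueError("cannot project points with non-positive depth")
    return f * points[..., :2] / z[..., None]


def analytic_flow(
    positions_px: np.ndarray,
    depths: np.ndarray,
    heading_deg: float,
    speed: float,
    f: float = FOCAL_PX,
) -> np.ndarray:
    """Instantaneous optic flow of rigid scene points, in px/s.

    Evaluates the translational flow equations at center-origin image
    positions ``(x, y)`` with metric depths ``Z``:

        xdot = (-f*Tx + x*Tz) / Z
        ydot = (-f*Ty + y*Tz) / Z

    with ``T = (o*sin(theta), 0, o*cos(theta))``.  The flow vanishes at the
    focus of expansion ``x = f*tan(theta), y = 0``.
    """
    positions_px = np.asarray(positions_px, dtype=float)
    depths = np.asarray(depths, dtype=float)
    th = np.radians(heading_deg)
    tx = speed * np.sin(th)
    tz = speed * np.cos(th)
    vx = (-f * tx + positions_px[..., 0] * tz) / depths
    vy = (positions_px[..., 1] * tz) / depths       # Ty = 0 for horizontal headings
    return np.stack([vx, vy], axis=-1)


# ---------------------------------------------------------------------------
# cloud construction and evolution
# ---------------------------------------------------------------------------

def _uniform_in_volume(config: SceneConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    ex, ey, ez = config.extent
    out = np.empty((n, 3))
    out[:, 0] = rng.uniform(-ex / 2.0, ex / 2.0, n)
    out[:, 1] = rng.uniform(-ey / 2.0, ey / 2.0, n)
    out[:, 2] = rng.uniform(config.min_depth, config.min_depth + ez, n)
    return out


def _visible(positions: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Mask of dots inside the field of view and beyond the near clip."""
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    t = config.tan_half_fov
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (z >= config.min_depth) & (np.abs(x) <= t * z) & (np.abs(y) <= t * z)
    return ok


def _respawn_positions(config: SceneConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n positions uniform in the volume, rejecting any outside the FOV."""
    out = np.empty((n, 3))
    need = np.arange(n)
    while need.size:
        cand = _uniform_in_volume(config, rng, need.size)
        ok = _visible(cand, config)
        out[need[ok]] = cand[ok]
        need = need[~ok]
    return out


def init_cloud(config: SceneConfig, rng: np.random.Generator) -> DotCloud:
    """Draw the initial dot cloud, uniform over the scene volume.

    The first ``round(noise_prop * n_dots)`` dots are flagged as noise dots
    and their anchors are set to the initial positions.  Dots initially
    outside the field of view are respawned on first use by
    :func:`generate_sequence` so that every emitted frame is fully visible.
    """
    positions = _uniform_in_volume(config, rng, config.n_dots)
    is_noise = np.zeros(config.n_dots, dtype=bool)
    is_noise[: config.n_noise] = True
    anchors = positions[is_noise].copy()
    return DotCloud(positions, is_noise, anchors)


def _advance(cloud: DotCloud, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Tentative next-frame positions before clipping/respawn.

    Rigid dots move opposite the observer's translation; noise dots are
    re-placed at their anchor plus an independent per-axis uniform jitter on
    [-noise_jitter/2, +noise_jitter/2], so the anchor is the mean position.
    """
    nxt = cloud.positions.copy()
    rigid = ~cloud.is_noise
    nxt[rigid] -= config.translation / config.frame_rate
    if cloud.anchors.shape[0]:
        half = config.noise_jitter / 2.0
        jitter = rng.uniform(-half, half, cloud.anchors.shape)
        nxt[cloud.is_noise] = cloud.anchors + jitter
    return nxt


def step_cloud(cloud: DotCloud, config: SceneConfig, rng: np.random.Generator) -> DotCloud:
    """Advance the cloud one frame, respawning clipped dots.

    Dots that exit the field of view or come within the near clip are replaced
    by fresh dots drawn uniformly over the (visible part of the) volume; a
    replaced noise dot receives a new anchor at its respawn position.  Dot
    count is conserved.
    """
    nxt = _advance(cloud, config, rng)
    return _respawn(DotCloud(nxt, cloud.is_noise.copy(), cloud.anchors.copy()), config, rng)


def _respawn(cloud: DotCloud, config: SceneConfig, rng: np.random.Generator) -> DotCloud:
    bad = ~_visible(cloud.positions, config)
    if np.any(bad):
        cloud.positions[bad] = _respawn_positions(config, rng, int(bad.sum()))
        bad_noise = bad[cloud.is_noise]
        if np.any(bad_noise):
            cloud.anchors[bad_noise] = cloud.positions[cloud.is_noise][bad_noise]
    return cloud


def generate_sequence(
    config: SceneConfig, rng: np.random.Generator | int | None = None
) -> FlowSequence:
    """Generate a full optic-flow video for one heading/noise condition.

    Rigid-dot motion vectors are evaluated analytically from the flow
    equations at the dot's current image position.  Noise dots have no rigid
    flow, so their vectors are the frame difference of projected positions
    times the frame rate (px/s); the differencing uses the dot's physical
    displacement before any clipping, matching how exiting dots are clipped
    and replaced only on the following frame.
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(seed)

    f = config.focal_px
    center = np.array([config.grid_px / 2.0, config.grid_px / 2.0])
    cloud = _respawn(init_cloud(config, rng), config, rng)

    n_f, n_t = config.n_frames, config.n_dots
    positions = np.empty((n_f, n_t, 2))
    velocities = np.empty((n_f, n_t, 2))
    noise = cloud.is_noise

    for t in range(n_f):
        pos_c = project(cloud.positions, f)             # center-origin px
        positions[t] = pos_c + center
        velocities[t] = analytic_flow(
            pos_c, cloud.positions[:, 2], config.heading_deg, config.speed, f
        )
        tentative = _advance(cloud, config, rng)
        if np.any(noise):
            # non-rigid motion: finite difference of projected positions
            z_next = np.maximum(tentative[noise, 2], 1e-6)
            nxt_px = f * tentative[noise, :2] / z_next[:, None]
            velocities[t, noise] = (nxt_px - pos_c[noise]) * config.frame_rate
        cloud = _respawn(DotCloud(tentative, noise.copy(), cloud.anchors), config, rng)

    return FlowSequence(config, seed, positions, velocities, noise.copy())
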