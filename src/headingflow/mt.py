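"""Model area MT: direction- and speed-tuned motion units.

Each MT unit has a Gaussian receptive field (RF) centered at ``r`` on the
image, a preferred direction ``d*`` drawn around the radial direction from
the image center, and a preferred speed ``s*``.  Its input is the average
over all flow vectors of the product of three Gaussian factors — distance
from the RF center, direction mismatch, and speed mismatch — and its
activation follows a saturating leaky-integrator.

Four speed-tuning variants are supported:

``direction_only``
    the speed factor is dropped entirely;
``uniform``
    s* uniform over the dynamic range of speeds in the stimulus;
``ecc_speed``
    s* drawn from a beta distribution whose mean equals the unit's
    normalized RF eccentricity, so peripheral units prefer faster speeds;
``ecc_speed_rf``
    as ``ecc_speed``, with RF width additionally growing linearly with
    eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .stimulus import FlowSequence, IMAGE_CENTER, IMAGE_SIZE, deg_to_px, px_to_deg

__all__ = [
    "SpeedModel",
    "MTParams",
    "MTPopulation",
    "place_grid",
    "place_random",
    "sample_directions",
    "sample_speeds_uniform",
    "eccentricity_norm",
    "beta_shapes",
    "sample_speeds_eccentric",
    "rf_size_from_ecc",
    "mt_input",
    "mt_input_sequence",
    "integrate_leaky",
    "sample_population",
]

SpeedModel = Literal["direction_only", "uniform", "ecc_speed", "ecc_speed_rf"]

#: clamp for normalized eccentricity so both beta-shape branches stay valid
_ECC_EPS = 1e-3


@dataclass(frozen=True)
class MTParams:
    """MT population parameters (defaults are the standard model values)."""

    n_units: int = 225
    sigma_d: float = 180.0          # max direction deviation about radial (deg)
    sigma_r: float = 7.0            # RF width (px)
    sigma_v: float = 10.0           # direction sensitivity (deg)
    sigma_s: float = 0.45           # speed sensitivity (px/s)
    alpha: float = 0.1              # passive decay rate (1/frame)
    beta: float = 2.5               # activation upper bound
    dt: float = 0.1                 # integration step (frames)
    placement: Literal["grid", "random"] = "grid"
    speed_model: SpeedModel = "uniform"
    k_s: float = 4.0                # baseline beta shape
    beta_ecc0: float = 0.19         # RF-size regression intercept (deg)
    beta_ecc1: float = 0.27         # RF-size regression slope (deg per deg)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma_d <= 360.0:
            raise ValueError(f"sigma_d must be in [0, 360], got {self.sigma_d}")
        if min(self.alpha, self.beta, self.dt, self.sigma_r) <= 0:
            raise ValueError("alpha, beta, dt and sigma_r must be positive")
        if self.k_s <= 0:
            raise ValueError("k_s must be positive")

    @property
    def substeps(self) -> int:
        """Euler sub-steps per video frame."""
        return int(round(1.0 / self.dt))


@dataclass
class MTPopulation:
    """A sampled MT population (one model run)."""

    rf_centers: np.ndarray          # (N, 2) px, grid coordinates
    pref_dir: np.ndarray            # (N,) deg in [0, 360)
    pref_speed: np.ndarray | None   # (N,) px/s, or None for direction_only
    rf_width: np.ndarray            # (N,) px
    activation: np.ndarray          # (N,)
    params: MTParams

    @property
    def n_units(self) -> int:
        return self.rf_centers.shape[0]

    def snapshot(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": np.arange(self.n_units),
                "rx": self.rf_centers[:, 0],
                "ry": self.rf_centers[:, 1],
                "pref_dir_deg": self.pref_dir,
                "pref_speed": (
                    np.full(self.n_units, np.nan)
                    if self.pref_speed is None
                    else self.pref_speed
                ),
                "rf_width": self.rf_width,
            }
        )

    def save_snapshot(self, path: str | Path) -> None:
        self.snapshot().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# placement and preference sampling
# ---------------------------------------------------------------------------

def place_grid(params: MTParams, spacing_px: float = 8.0) -> np.ndarray:
    """RF centers on a square grid centered on the image (15 x 15 by default).

    The default 8 px spacing corresponds to 7.1 deg between neighbors.
    """
    side = int(round(np.sqrt(params.n_units)))
    if side * side != params.n_units:
        raise ValueError(f"grid placement needs a square unit count, got {params.n_units}")
    offsets = (np.arange(side) - (side - 1) / 2.0) * spacing_px
    gx, gy = np.meshgrid(IMAGE_CENTER[0] + offsets, IMAGE_CENTER[1] + offsets)
    return np.column_stack([gx.ravel(), gy.ravel()])


def place_random(params: MTParams, rng: np.random.Generator) -> np.ndarray:
    """RF centers uniform over the image."""
    return rng.uniform(0.0, IMAGE_SIZE, (params.n_units, 2))


def sample_directions(
    rf_centers: np.ndarray, sigma_d: float, rng: np.random.Generator
) -> np.ndarray:
    """Preferred directions: radial angle from image center + uniform deviate.

    The radial angle is the four-quadrant angle of the RF center relative to
    the image center; the deviate is uniform on [-sigma_d/2, +sigma_d/2].
    An RF exactly at the image center has no radial direction, so its
    preference is drawn uniformly over the circle.  Output in [0, 360) deg.
    """
    dx = rf_centers[:, 0] - IMAGE_CENTER[0]
    dy = rf_centers[:, 1] - IMAGE_CENTER[1]
    radial = np.degrees(np.arctan2(dy, dx))
    at_center = (dx == 0) & (dy == 0)
    deviate = rng.uniform(-sigma_d / 2.0, sigma_d / 2.0, rf_centers.shape[0])
    if np.any(at_center):
        radial = radial.copy()
        radial[at_center] = rng.uniform(0.0, 360.0, int(at_center.sum()))
    return np.mod(radial + deviate, 360.0)


def sample_speeds_uniform(flow: FlowSequence, n_units: int, rng: np.random.Generator) -> np.ndarray:
    """Preferred speeds uniform over the dynamic range of the input flow."""
    lo, hi = flow.speed_range()
    return rng.uniform(lo, hi, n_units)


def eccentricity_norm(rf_centers: np.ndarray) -> np.ndarray:
    """RF eccentricity normalized by the center-to-corner distance, in [0, 1]."""
    d = np.hypot(
        rf_centers[:, 0] - IMAGE_CENTER[0], rf_centers[:, 1] - IMAGE_CENTER[1]
    )
    return d / np.hypot(*IMAGE_CENTER)


def beta_shapes(ecc_norm: np.ndarray, k_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Beta shape parameters (a, b) whose mean a/(a+b) equals ``ecc_norm``.

    Units closer than halfway to the corner keep b = k_s and shrink a;
    units at or beyond halfway keep a = k_s and shrink b.  Eccentricities
    are clamped away from {0, 1} so both shapes stay positive.
    """
    e = np.clip(np.asarray(ecc_norm, dtype=float), _ECC_EPS, 1.0 - _ECC_EPS)
    a = np.where(e < 0.5, k_s * e / (1.0 - e), k_s)
    b = np.where(e < 0.5, k_s, k_s * (1.0 / e - 1.0))
    return a, b


def sample_speeds_eccentric(
    rf_centers: np.ndarray,
    flow: FlowSequence,
    k_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Eccentricity-scaled speed preferences.

    Each unit draws a normalized speed from Beta(a, b) with mean equal to its
    normalized eccentricity, then maps it affinely onto the dynamic range of
    the input flow: foveal units prefer the slowest stimulus speeds,
    far-peripheral units the fastest.
    """
    lo, hi = flow.speed_range()
    a, b = beta_shapes(eccentricity_norm(rf_centers), k_s)
    x = rng.beta(a, b)
    return x * (hi - lo) + lo


def rf_size_from_ecc(ecc_deg, beta_ecc0: float = 0.19, beta_ecc1: float = 0.27):
    """Linear MT RF-size scaling with eccentricity: size_deg = b0 + b1 * ecc_deg."""
    ecc_deg = np.asarray(ecc_deg, dtype=float)
    if np.any(ecc_deg < 0):
        raise ValueError("eccentricity must be nonnegative")
    return beta_ecc0 + beta_ecc1 * ecc_deg


def sample_population(
    params: MTParams,
    flow: FlowSequence,
    rng: np.random.Generator,
) -> MTPopulation:
    """Sample a full MT population for one model run."""
    if params.placement == "grid":
        centers = place_grid(params)
    else:
        centers = place_random(params, rng)
    pref_dir = sample_directions(centers, params.sigma_d, rng)

    if params.speed_model == "direction_only":
        pref_speed = None
    elif params.speed_model == "uniform":
        pref_speed = sample_speeds_uniform(flow, params.n_units, rng)
    else:
        pref_speed = sample_speeds_eccentric(centers, flow, params.k_s, rng)

    if params.speed_model == "ecc_speed_rf":
        ecc_deg = px_to_deg(
            np.hypot(centers[:, 0] - IMAGE_CENTER[0], centers[:, 1] - IMAGE_CENTER[1])
        )
        rf_width = deg_to_px(rf_size_from_ecc(ecc_deg, params.beta_ecc0, params.beta_ecc1))
        rf_width = np.maximum(rf_width, 1e-3)
    else:
        rf_width = np.full(params.n_units, params.sigma_r)

    return MTPopulation(
        rf_centers=centers,
        pref_dir=pref_dir,
        pref_speed=pref_speed,
        rf_width=rf_width,
        activation=np.zeros(params.n_units),
        params=params,
    )


# ---------------------------------------------------------------------------
# input and dynamics
# ---------------------------------------------------------------------------

def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180] degrees."""
    return delta - 360.0 * np.round(delta / 360.0)


def mt_input(pop: MTPopulation, frame, params: MTParams | None = None) -> np.ndarray:
    """Net input to every MT unit for one frame of flow.

    I_MT = mean over dots of I_c * I_v * I_s, where each factor is a
    Gaussian in, respectively, the distance between dot and RF center,
    the (circularly wrapped) direction difference, and the speed
    difference.  Always lies in [0, 1].  ``frame`` is a
    :class:`~headingflow.stimulus.FlowFrame`.
    """
    return mt_input_sequence(
        pop, frame.positions[None], frame.velocities[None], params
    )[0]


def mt_input_sequence(
    pop: MTPopulation,
    positions: np.ndarray,
    velocities: np.ndarray,
    params: MTParams | None = None,
    dist_sq: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized MT input over a whole stimulus: returns (F, N) array.

    ``positions``/``velocities`` are (F, T, 2).  ``dist_sq`` may carry the
    precomputed (F, N, T) squared dot-to-RF distances (they depend only on
    the stimulus and the RF layout, so callers that reuse one stimulus
    across model resamplings can share them).
    """
    params = params or pop.params
    if dist_sq is None:
        dist_sq = rf_distance_sq(pop.rf_centers, positions)
    sig_r = pop.rf_width[None, :, None]
    expo = dist_sq / (-2.0 * sig_r**2)

    dirs = np.degrees(np.arctan2(velocities[..., 1], velocities[..., 0]))    # (F, T)
    dv = _wrap_deg(dirs[:, None, :] - pop.pref_dir[None, :, None])
    expo = expo - dv**2 / (2.0 * params.sigma_v**2)

    if pop.pref_speed is not None:
        speeds = np.hypot(velocities[..., 0], velocities[..., 1])
        ds = speeds[:, None, :] - pop.pref_speed[None, :, None]
        expo -= ds**2 / (2.0 * params.sigma_s**2)

    return np.exp(expo).mean(axis=2)


def rf_distance_sq(rf_centers: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """(F, N, T) squared distances between dots and RF centers."""
    dx = positions[:, None, :, 0] - rf_centers[None, :, None, 0]
    dy = positions[:, None, :, 1] - rf_centers[None, :, None, 1]
    return dx**2 + dy**2


def integrate_leaky(
    activation: np.ndarray,
    drive: np.ndarray | float,
    alpha: float,
    beta: float,
    dt: float,
    steps: int,
) -> np.ndarray:
    """Forward-Euler leaky integration dm/dt = -alpha*m + (beta - m)*I.

    The drive I is held fixed for all ``steps`` sub-steps.  With
    dt*(alpha + I) < 1 (required; asserted) the update is a contraction
    toward the equilibrium beta*I/(alpha+I), and trajectories started in
    [0, beta] remain there.
    """
    m = np.asarray(activation, dtype=float)
    drive = np.asarray(drive, dtype=float)
    if np.any(dt * (alpha + drive) >= 1.0):
        raise ValueError("unstable Euler step: require dt*(alpha + I) < 1")
    for _ in range(steps):
        m = m + dt * (-alpha * m + (beta - m) * drive)
    return m
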