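"""Model area MSTd: heading-tuned template units.

Each MSTd unit prefers a heading, represented as the 2D image position of
the corresponding focus of expansion.  Its feedforward weight onto each MT
unit is the product of a direction-match term — how well the MT unit's
preferred direction agrees with the radial outflow direction implied by the
preferred heading at that retinotopic location — and a Gaussian in the
distance between the heading position and the MT receptive field.  These
weights are static within a run; only MT activity changes frame to frame.

Preferred-heading radii are sampled as ``R = R_max * x^gamma`` with
``x ~ U[0, 1]``, so ``gamma < 1`` overrepresents peripheral headings and
``gamma > 1`` central ones, while preferred-heading polar angles cover the
circle equiangularly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import IMAGE_CENTER, px_to_deg
from .mt import MTPopulation, integrate_leaky

__all__ = [
    "MSTdParams",
    "MSTdPopulation",
    "sample_headings",
    "radial_templates",
    "direction_match",
    "build_weights",
    "mstd_input",
    "sample_population",
    "R_MAX",
]

#: maximum preferred-heading radius: center-to-corner distance (px)
R_MAX = float(np.hypot(*IMAGE_CENTER))

#: weight-matrix pairs closer than this are treated as coincident (template
#: direction undefined) and zeroed
_COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class MSTdParams:
    """MSTd population parameters (defaults are the standard model values)."""

    n_units: int = 169
    gamma: float = 0.5              # center-peripheral exponent
    sigma_mst: float = 77.0         # RF extent (px)
    q: int = 2                      # direction-selectivity exponent
    alpha: float = 0.1              # passive decay rate (1/frame)
    beta: float = 2.5               # activation upper bound
    dt: float = 0.1                 # integration step (frames)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.q < 1 or int(self.q) != self.q:
            raise ValueError(f"q must be an integer >= 1, got {self.q}")
        if min(self.sigma_mst, self.alpha, self.beta, self.dt) <= 0:
            raise ValueError("sigma_mst, alpha, beta, dt must be positive")

    @property
    def substeps(self) -> int:
        return int(round(1.0 / self.dt))


@dataclass
class MSTdPopulation:
    """A sampled MSTd population with its static MT -> MSTd weights."""

    pref_heading: np.ndarray        # (N_MST, 2) px, grid coordinates
    weights: np.ndarray             # (N_MST, N_MT) static template weights
    activation: np.ndarray          # (N_MST,)
    params: MSTdParams

    @property
    def n_units(self) -> int:
        return self.pref_heading.shape[0]

    def snapshot(self) -> pd.DataFrame:
        hx = self.pref_heading[:, 0] - IMAGE_CENTER[0]
        return pd.DataFrame(
            {
                "unit_id": np.arange(self.n_units),
                "hx_px": self.pref_heading[:, 0],
                "hy_px": self.pref_heading[:, 1],
                "pref_heading_deg": px_to_deg(hx),
            }
        )

    def save_snapshot(self, path: str | Path) -> None:
        self.snapshot().to_csv(path, index=False)


def sample_headings(params: MSTdParams, rng: np.random.Generator) -> np.ndarray:
    """Sample preferred-heading positions in polar coordinates about center.

    Angles are equiangular over [0, 360); radii are R_max * x^gamma with
    x ~ U[0, 1], whose CDF is P(R <= t*R_max) = t**(1/gamma).
    """
    n = params.n_units
    theta = np.arange(n) * (2.0 * np.pi / n)
    radius = R_MAX * rng.uniform(0.0, 1.0, n) ** params.gamma
    return np.column_stack(
        [
            IMAGE_CENTER[0] + radius * np.cos(theta),
            IMAGE_CENTER[1] + radius * np.sin(theta),
        ]
    )


def radial_templates(mt_centers: np.ndarray, heading_pos: np.ndarray) -> np.ndarray:
    """Unit vectors from each heading position toward each MT RF center.

    Returns (N_MST, N_MT, 2).  A coincident pair (distance ~ 0) has no
    defined radial direction; its vector is left as zero and the
    corresponding weight is zeroed in :func:`build_weights`.
    """
    diff = mt_centers[None, :, :] - heading_pos[:, None, :]
    norm = np.linalg.norm(diff, axis=-1, keepdims=True)
    safe = np.where(norm > _COINCIDENT_TOL, norm, 1.0)
    u = diff / safe
    u[np.broadcast_to(norm <= _COINCIDENT_TOL, u.shape)] = 0.0
    return u


def direction_match(u: np.ndarray, pref_dir_deg: np.ndarray, q: int) -> np.ndarray:
    """Rectified power-cosine match between template and preferred directions.

    U = max(2*max(cos(angle(u) - d*), 0)**q - 1, 0).  The power q >= 1
    narrows the tuning; the affine 2x-1 restores the [0, 1] cosine-power
    range to [-1, 1] before the outer half-wave rectification.  U = 1 at an
    exact match and, for q = 2, falls to 0 at a 45 deg mismatch.  The inner
    rectification keeps anti-preferred directions (mismatch > 90 deg) at
    zero for every q — a template never recruits motion opposite to its
    radial pattern, as the cosine down-weighting intends; without it, even
    exponents would spuriously assign full weight at a 180 deg mismatch.
    """
    ang = np.arctan2(u[..., 1], u[..., 0])
    c = np.maximum(np.cos(ang - np.radians(pref_dir_deg)), 0.0)
    return np.maximum(2.0 * c**q - 1.0, 0.0)


def build_weights(
    heading_pos: np.ndarray,
    mt: MTPopulation,
    params: MSTdParams,
) -> np.ndarray:
    """Static template weight matrix W[(mstd unit), (mt unit)].

    W = U * exp(-||h - r||^2 / (2 sigma^2)) / (2 pi sigma^2), where U is the
    direction match of the MT unit's preference with the radial direction of
    the template.  Pairs with coincident heading and RF positions get
    weight 0.  Recompute whenever MT preferences are resampled.
    """
    u = radial_templates(mt.rf_centers, heading_pos)
    match = direction_match(u, mt.pref_dir[None, :], params.q)
    d2 = np.sum(
        (heading_pos[:, None, :] - mt.rf_centers[None, :, :]) ** 2, axis=-1
    )
    gauss = np.exp(-d2 / (2.0 * params.sigma_mst**2)) / (2.0 * np.pi * params.sigma_mst**2)
    w = match * gauss
    w[d2 <= _COINCIDENT_TOL**2] = 0.0
    return w


def mstd_input(weights: np.ndarray, mt_activation: np.ndarray) -> np.ndarray:
    """Net MSTd input: template-weighted MT activity averaged over MT units."""
    return weights @ mt_activation / weights.shape[1]


def sample_population(
    params: MSTdParams, mt: MTPopulation, rng: np.random.Generator
) -> MSTdPopulation:
    """Sample preferred headings and build static weights against ``mt``."""
    heading_pos = sample_headings(params, rng)
    weights = build_weights(heading_pos, mt, params)
    return MSTdPopulation(
        pref_heading=heading_pos,
        weights=weights,
        activation=np.zeros(params.n_units),
        params=params,
    )
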