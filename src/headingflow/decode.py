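"""Population-vector decoding of heading from MSTd activity.

The horizontal heading is decoded each frame as the activation-weighted mean
of the MSTd units' preferred-heading x-positions (the y-coordinate is
constant across stimuli).  Per-frame decodes are smoothed by an exponential
moving average, and the smoothed value at the final frame, converted through
the tangent pixel-to-degree mapping, is the single heading estimate for the
video.

Bias convention: positive bias is an error toward the straight-ahead
direction (center bias), negative is an error away from it (peripheral
bias).  For a straight-ahead stimulus any deviation counts as peripheral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import IMAGE_CENTER, px_to_deg

__all__ = [
    "InvalidDecodeError",
    "HeadingTrace",
    "population_vector",
    "ema",
    "bias",
    "DECODE_DENOM_TOL",
    "DEFAULT_LAMBDA",
]

#: total-activation threshold below which a decode is declared invalid
DECODE_DENOM_TOL = 1e-12

#: EMA smoothing weight on the newest decoded value
DEFAULT_LAMBDA = 0.25


class InvalidDecodeError(RuntimeError):
    """Raised when total MSTd activation is too small to decode heading."""


@dataclass
class HeadingTrace:
    """Per-frame decoded heading and the resulting single estimate."""

    decoded_px: np.ndarray      # per-frame population-vector readout (px)
    smoothed_px: np.ndarray     # EMA of decoded_px (px)
    true_heading_deg: float
    valid: bool

    @property
    def estimate_deg(self) -> float:
        if not self.valid:
            raise InvalidDecodeError("trace is invalid; no heading estimate")
        return float(px_to_deg(self.smoothed_px[-1] - IMAGE_CENTER[0]))

    @property
    def bias_deg(self) -> float:
        return bias(self.true_heading_deg, self.estimate_deg)


def population_vector(activation: np.ndarray, pref_x: np.ndarray) -> float:
    """Activation-weighted mean of preferred x-positions (px).

    Invariant under rescaling of the activations.  Raises
    :class:`InvalidDecodeError` when the total activation is at or below
    ``DECODE_DENOM_TOL`` — the signal that this model sampling cannot decode
    the stimulus and must be redrawn.
    """
    total = float(np.sum(activation))
    if total <= DECODE_DENOM_TOL:
        raise InvalidDecodeError(f"total MSTd activation {total:g} too small to decode")
    return float(np.dot(pref_x, activation) / total)


def ema(decoded: np.ndarray, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Exponential moving average h[t] = lam*x[t] + (1-lam)*h[t-1].

    Initialized at the first decoded value, so a constant input is a fixed
    point from the start.  lam must lie in (0, 1]; lam = 1 disables
    smoothing.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    decoded = np.asarray(decoded, dtype=float)
    if decoded.size == 0:
        raise ValueError("cannot smooth an empty trace")
    out = np.empty_like(decoded)
    out[0] = decoded[0]
    for t in range(1, decoded.size):
        out[t] = lam * decoded[t] + (1.0 - lam) * out[t - 1]
    return out


def bias(true_deg: float, estimate_deg: float) -> float:
    """Signed heading bias in degrees: + toward center, - toward periphery.

    For nonzero true headings, bias = sign(theta) * (theta - estimate): an
    estimate short of the true eccentricity is a center bias (positive).
    For theta = 0 any deviation is peripheral, so bias = -|estimate|.
    """
    if true_deg == 0.0:
        return -abs(estimate_deg)
    return float(np.sign(true_deg) * (true_deg - estimate_deg))
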