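"""Parameter-sweep experiments over the MT -> MSTd template model.

Five standard experiments probe how physiological tuning shapes heading
estimates, each sweeping one factor away from the default model:

======================  =====================================  =======================
name                    swept factor                           values
======================  =====================================  =======================
``mstd_heading``        MSTd center-peripheral exponent gamma  0.1, 0.2, 0.5, 1, 2, 5, 10
``mstd_rf``             MSTd RF extent sigma (px)              12.8 ... 128
``mstd_direction``      MSTd direction exponent q              1, 2, 4, 6, 8
``mt_direction``        MT direction deviation sigma_d (deg)   0, 60, ..., 360
``mt_speed``            MT speed-tuning model                  direction_only, uniform,
                                                               ecc_speed, ecc_speed_rf
======================  =====================================  =======================

Protocol: the optic-flow stimulus for a given heading is fixed across runs,
so across-run variability reflects only the random sampling of model tuning.
Each condition is repeated ``runs`` times (default 50).  Noise conditions
additionally regenerate the stimulus ``stim_reps`` times (default 10) with
the model runs divided evenly across stimuli.  A run whose final decode has
(near-)zero total MSTd activation is invalid and is retried with a fresh
model seed until a valid estimate is obtained.

All randomness derives from a single base seed; reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import mstd as mstd_mod
from . import mt as mt_mod
from .decode import (
    DECODE_DENOM_TOL,
    DEFAULT_LAMBDA,
    HeadingTrace,
    InvalidDecodeError,
    bias,
    ema,
)
from .mstd import MSTdParams, mstd_input
from .mt import MTParams, integrate_leaky, mt_input_sequence, rf_distance_sq
from .stimulus import IMAGE_CENTER, FlowSequence, SceneConfig, generate_sequence, px_to_deg

__all__ = [
    "DEFAULT_HEADINGS",
    "NOISE_LEVELS",
    "EXPERIMENT_VALUES",
    "ExperimentSpec",
    "simulate_trace",
    "run_single",
    "run_experiment",
    "summarize",
    "compute_mae",
    "mean_sd",
    "summarize_noise_effect",
    "noise_effect_stats",
]

#: the 21 standard headings: -50 to +50 deg in 5 deg steps
DEFAULT_HEADINGS: tuple[float, ...] = tuple(float(h) for h in range(-50, 55, 5))

#: standard noise-dot proportions
NOISE_LEVELS: tuple[float, ...] = (0.7, 0.8, 0.9)

#: swept values of each standard experiment
EXPERIMENT_VALUES: dict[str, tuple] = {
    "mstd_heading": (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0),
    "mstd_rf": (12.8, 25.6, 51.2, 76.8, 102.4, 128.0),
    "mstd_direction": (1, 2, 4, 6, 8),
    "mt_direction": (0.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0),
    "mt_speed": ("direction_only", "uniform", "ecc_speed", "ecc_speed_rf"),
}

#: RF-size regression slopes (deg/deg) available for the ecc_speed_rf model
RF_SLOPES: tuple[float, ...] = (0.27, 0.54, 0.81, 1.07)

_MAX_RETRIES = 50


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a swept factor crossed with headings and noise levels."""

    name: str
    values: tuple = ()
    headings: tuple[float, ...] = DEFAULT_HEADINGS
    noise_levels: tuple[float, ...] = ()
    runs: int = 50
    stim_reps: int = 10
    base_seed: int = 0
    gamma: float = 0.5          # MSTd heading exponent for non-gamma sweeps
    scene: SceneConfig = field(default_factory=SceneConfig)
    mt_params: MTParams = field(default_factory=MTParams)
    mstd_params: MSTdParams = field(default_factory=MSTdParams)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_VALUES:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {sorted(EXPERIMENT_VALUES)}"
            )
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.stim_reps < 1:
            raise ValueError("stim_reps must be >= 1")
        if not self.values:
            object.__setattr__(self, "values", EXPERIMENT_VALUES[self.name])

    def condition_params(self, value) -> tuple[MTParams, MSTdParams]:
        """Default-model parameters with the swept value applied."""
        mt_p = self.mt_params
        mstd_p = replace(self.mstd_params, gamma=self.gamma)
        if self.name == "mstd_heading":
            mstd_p = replace(mstd_p, gamma=float(value))
        elif self.name == "mstd_rf":
            mstd_p = replace(mstd_p, sigma_mst=float(value))
        elif self.name == "mstd_direction":
            mstd_p = replace(mstd_p, q=int(value))
        elif self.name == "mt_direction":
            # MT-focused experiments place MT RFs randomly
            mt_p = replace(mt_p, sigma_d=float(value), placement="random")
        elif self.name == "mt_speed":
            model, _, slope = str(value).partition(":")
            mt_p = replace(mt_p, speed_model=model, placement="random")
            if slope:
                mt_p = replace(mt_p, beta_ecc1=float(slope))
        return mt_p, mstd_p


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def _derive_seed(*entropy: int) -> int:
    """Deterministically fold an entropy tuple into a 31-bit seed."""
    ss = np.random.SeedSequence([int(e) for e in entropy])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def stimulus_seed(base_seed: int, heading_idx: int, noise_idx: int, rep: int) -> int:
    """Stimulus seeds depend only on the condition, never on the model."""
    return _derive_seed(base_seed, 101, heading_idx, noise_idx, rep)


def model_seed(
    base_seed: int, value_idx: int, heading_idx: int, noise_idx: int, rep: int, run: int
) -> int:
    return _derive_seed(base_seed, 202, value_idx, heading_idx, noise_idx, rep, run)


# ---------------------------------------------------------------------------
# single-run simulation
# ---------------------------------------------------------------------------

def simulate_trace(
    flow: FlowSequence,
    mt_params: MTParams,
    mstd_params: MSTdParams,
    rng: np.random.Generator,
    dist_sq: np.ndarray | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> HeadingTrace:
    """Run one model sampling over one stimulus and decode heading.

    Per frame: the MT drive is computed from the flow, MT activations take
    ``substeps`` Euler sub-steps with the drive fixed, the MSTd drive is
    computed from the updated MT activity, MSTd takes its sub-steps, and the
    population vector is read out.  Frames whose total MSTd activation is at
    or below the decode tolerance inherit the previous decoded value
    (leading such frames are back-filled from the first decodable frame); a
    run is invalid if the final frame cannot be decoded.
    """
    mt_pop = mt_mod.sample_population(mt_params, flow, rng)
    mstd_pop = mstd_mod.sample_population(mstd_params, mt_pop, rng)

    if dist_sq is not None and mt_params.placement != "grid":
        raise ValueError("precomputed distances require grid placement")
    drive = mt_input_sequence(mt_pop, flow.positions, flow.velocities, mt_params, dist_sq)

    n_frames = len(flow)
    m = np.zeros(mt_params.n_units)
    big_m = np.zeros(mstd_params.n_units)
    pref_x = mstd_pop.pref_heading[:, 0]
    decoded = np.full(n_frames, np.nan)
    for t in range(n_frames):
        m = integrate_leaky(
            m, drive[t], mt_params.alpha, mt_params.beta, mt_params.dt, mt_params.substeps
        )
        i_mst = mstd_input(mstd_pop.weights, m)
        big_m = integrate_leaky(
            big_m, i_mst, mstd_params.alpha, mstd_params.beta,
            mstd_params.dt, mstd_params.substeps,
        )
        total = big_m.sum()
        if total > DECODE_DENOM_TOL:
            decoded[t] = np.dot(pref_x, big_m) / total
        elif t > 0:
            decoded[t] = decoded[t - 1]

    finite = np.isfinite(decoded)
    valid = bool(finite[-1])
    if valid and not finite.all():
        decoded[~finite] = decoded[finite][0]    # back-fill leading undecodable frames
    smoothed = ema(decoded, lam) if valid else np.full(n_frames, np.nan)
    return HeadingTrace(
        decoded_px=decoded,
        smoothed_px=smoothed,
        true_heading_deg=flow.config.heading_deg,
        valid=valid,
    )


def run_single(
    scene: SceneConfig,
    mt_params: MTParams,
    mstd_params: MSTdParams,
    stim_seed: int,
    model_seed: int,
    *,
    flow: FlowSequence | None = None,
    dist_sq: np.ndarray | None = None,
    max_retries: int = _MAX_RETRIES,
) -> tuple[HeadingTrace, int]:
    """One complete run: stimulus -> model sampling -> heading estimate.

    The stimulus may be passed in (``flow``) to share it across runs;
    otherwise it is generated from ``stim_seed``.  Invalid decodes trigger a
    model resampling with a fresh seed, up to ``max_retries`` times.
    Returns the trace and the number of retries used.
    """
    if flow is None:
        flow = generate_sequence(scene, stim_seed)
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(model_seed), attempt]))
        trace = simulate_trace(flow, mt_params, mstd_params, rng, dist_sq)
        if trace.valid:
            return trace, attempt
    raise InvalidDecodeError(
        f"no valid heading estimate after {max_retries} model resamplings"
    )


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def run_experiment(spec: ExperimentSpec, progress: bool = False) -> pd.DataFrame:
    """Run a full sweep and return long-format per-run results.

    Columns: experiment, value, heading_deg, noise, stim_rep, run,
    stim_seed, model_seed, retries, estimate_deg, bias_deg, valid.
    """
    conditions = list(_iter_conditions(spec))
    iterator: Iterable = conditions
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(conditions, desc=spec.name)
        except ImportError:                      # pragma: no cover
            pass

    rows: list[dict] = []
    for h_idx, heading, noise_idx, noise, rep in iterator:
        sseed = stimulus_seed(spec.base_seed, h_idx, noise_idx, rep)
        cfg = replace(spec.scene, heading_deg=heading, noise_prop=noise)
        flow = generate_sequence(cfg, sseed)
        grid_dist_sq: np.ndarray | None = None
        runs_here = spec.runs if noise == 0.0 else max(1, spec.runs // spec.stim_reps)
        for v_idx, value in enumerate(spec.values):
            mt_p, mstd_p = spec.condition_params(value)
            dist_sq = None
            if mt_p.placement == "grid":
                if grid_dist_sq is None:
                    grid_dist_sq = rf_distance_sq(mt_mod.place_grid(mt_p), flow.positions)
                dist_sq = grid_dist_sq
            for run in range(runs_here):
                mseed = model_seed(spec.base_seed, v_idx, h_idx, noise_idx, rep, run)
                trace, retries = run_single(
                    cfg, mt_p, mstd_p, sseed, mseed, flow=flow, dist_sq=dist_sq
                )
                rows.append(
                    {
                        "experiment": spec.name,
                        "value": value,
                        "heading_deg": heading,
                        "noise": noise,
                        "stim_rep": rep,
                        "run": run,
                        "stim_seed": sseed,
                        "model_seed": mseed,
                        "retries": retries,
                        "estimate_deg": trace.estimate_deg,
                        "bias_deg": trace.bias_deg,
                        "valid": trace.valid,
                    }
                )
    return pd.DataFrame(rows)


def _iter_conditions(spec: ExperimentSpec):
    for h_idx, heading in enumerate(spec.headings):
        yield h_idx, heading, 0, 0.0, 0
        for noise_idx, noise in enumerate(spec.noise_levels, start=1):
            for rep in range(spec.stim_reps):
                yield h_idx, heading, noise_idx, noise, rep


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary: mean bias, SD of estimates, run count.

    One row per (value, heading, noise).  The SD is taken across all runs of
    the condition (pooled over stimulus repetitions for noise conditions)
    and is reported as missing when fewer than two runs exist.
    """
    grouped = results.groupby(["value", "heading_deg", "noise"], sort=True)
    out = grouped.agg(
        mean_bias=("bias_deg", "mean"),
        mean_estimate=("estimate_deg", "mean"),
        sd_estimate=("estimate_deg", lambda s: s.std(ddof=1) if len(s) > 1 else np.nan),
        n_runs=("run", "size"),
    ).reset_index()
    return out


def compute_mae(summary: pd.DataFrame, value=None, noise: float = 0.0) -> float | pd.Series:
    """Mean absolute heading error: mean over headings of |mean bias|.

    With ``value=None`` returns a Series indexed by swept value; otherwise a
    single float for that value.  Uses the requested noise level (default:
    the no-noise condition).
    """
    sel = summary[summary["noise"] == noise]
    mae = sel.groupby("value")["mean_bias"].apply(lambda s: float(np.abs(s).mean()))
    if value is None:
        return mae
    return float(mae.loc[value])


def mae_per_run(results: pd.DataFrame, value, noise: float = 0.0) -> float:
    """Alternative error metric: mean over individual runs of |bias|."""
    sel = results[(results["value"] == value) & (results["noise"] == noise)]
    return float(np.abs(sel["bias_deg"]).mean())


def mean_sd(summary: pd.DataFrame, value=None, noise: float = 0.0) -> float | pd.Series:
    """Mean across headings of the across-run SD of heading estimates (deg)."""
    sel = summary[summary["noise"] == noise]
    out = sel.groupby("value")["sd_estimate"].mean()
    if value is None:
        return out
    return float(out.loc[value])


def summarize_noise_effect(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-condition change in mean bias relative to the no-noise baseline.

    Returns one row per (value, heading, noise level > 0) with column
    ``delta_bias`` = mean bias with noise minus mean bias without.  With 21
    headings and three noise levels this yields the standard 63 differences
    per model.
    """
    clean = summary[summary["noise"] == 0.0].set_index(["value", "heading_deg"])
    noisy = summary[summary["noise"] > 0.0]
    if noisy.empty:
        raise ValueError("summary contains no noise conditions")
    missing = set(zip(noisy["value"], noisy["heading_deg"])) - set(clean.index)
    if missing:
        raise ValueError(f"no-noise baseline missing for conditions: {sorted(missing)[:5]}")
    base = clean["mean_bias"].reindex(
        pd.MultiIndex.from_frame(noisy[["value", "heading_deg"]])
    ).to_numpy()
    out = noisy[["value", "heading_deg", "noise", "mean_bias"]].copy()
    out["delta_bias"] = out["mean_bias"].to_numpy() - base
    return out.reset_index(drop=True)


def noise_effect_stats(deltas: pd.DataFrame) -> pd.DataFrame:
    """Aggregate noise effects per swept value.

    ``mean_abs_delta``/``median_abs_delta`` summarize |delta_bias| over all
    (heading, noise) cells; ``per_heading`` averages the signed delta over
    noise levels (one curve per value).
    """
    agg = deltas.groupby("value")["delta_bias"].agg(
        mean_abs_delta=lambda s: float(np.abs(s).mean()),
        median_abs_delta=lambda s: float(np.abs(s).median()),
        mean_delta="mean",
    )
    return agg.reset_index()
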