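# Methods

`headingflow` simulates how the primate dorsal visual stream could estimate
heading (the direction of self-motion) from optic flow, using a feedforward
template model of areas MT and MSTd, and quantifies the heading bias and
variability that different physiological tuning assumptions produce.

## Stimulus model

A virtual observer translates at speed *o* = 1.5 m/s along a horizontal
heading θ through a cloud of *T* = 300 dots placed uniformly in a
300 × 300 × 100 m volume starting 1 m in front of the eye.  Dots are
projected through a pinhole camera onto a 128 × 128 px image; a 90°
field of view makes the focal length exactly 64 pixel-units, so pixel
offsets *d* from the image center correspond to visual angles
atan(*d*/64).  All angular parameters in the model tables follow this
tangent convention (8 px ↔ 7.1°, 77 px ↔ 50°, 128 px ↔ 63.4°).

Rigid dots stream past the observer; their image velocities are evaluated
analytically from the instantaneous translational flow equations, which
vanish at the focus of expansion *x* = 64·tan θ.  Videos last 2 s
(60 frames at 30 fps).  Dots that leave the field of view or come within
1 m of the eye are replaced by fresh dots drawn uniformly over the visible
part of the volume, keeping exactly 300 flow vectors per frame.

**Noise dots.**  A fraction *n* ∈ {0.7, 0.8, 0.9} of dots is decoupled from
the self-motion: each holds a constant mean position relative to the
observer (its anchor) and is redrawn every frame at the anchor plus an
independent per-axis uniform displacement.  The stated maximum per-axis
displacement (1 m) is implemented as a symmetric interval of that width,
[−0.5, +0.5] m, so the anchor is the mean position; a one-sided interval
would drift the dots.  Because these dots are not rigid, their image
velocities are computed by frame-differencing their projected positions
(using the physical displacement before any clipping) rather than from the
flow equations.  Positions and velocities are kept in continuous pixel
coordinates; rasterization would only add quantization noise.

## Model area MT

225 direction- and speed-tuned units.  For experiments that manipulate
MSTd, their receptive fields (RFs) sit on a 15 × 15 grid with 8 px
(7.1°) spacing to keep the MT substrate constant across runs; for MT
experiments they are placed uniformly at random.  Each unit's preferred
direction is the radial direction of its RF center (relative to the image
center) plus a uniform deviate on ±σ_d/2, with σ_d = 180° by default —
the physiological bias of MT direction preferences toward a radially
expanding pattern.  σ_d = 0° makes the population strictly radial and
σ_d = 360° makes it uniform.

Preferred speeds are, by default, uniform over the dynamic range of
optical speeds in the current stimulus (computed over all frames; using
only the first frame changes the range by < 20% and the results not at
all).  Two eccentricity-scaled variants draw the normalized preferred
speed from a beta distribution whose mean equals the unit's normalized
eccentricity (shape baseline *k_s* = 4), optionally also scaling RF width
linearly with eccentricity (intercept 0.19°, slope 0.27°/° by default; the
tabulated pixel equivalent of the intercept is inconsistent with the
tangent convention, so the degree values are treated as canonical).  A
fourth variant drops the speed factor entirely.

The drive to a unit is the average over the 300 flow vectors of the
product of three Gaussian factors: distance of the dot from the RF center
(σ_r = 7 px, used literally as the Gaussian σ), direction difference
(σ_v = 10°, wrapped to ±180° before squaring — unwrapped differences
would double-penalize near-opposite directions), and speed difference
(σ_s = 0.45 px/s).  The distance factor is computed on dot *positions*;
a published variant of the formula that subtracts RF centers from
velocity components is treated as a typographical slip.  Activations
follow a saturating leaky integrator dm/dt = −αm + (β − m)I with
α = 0.1/frame, β = 2.5, integrated by forward Euler with dt = 0.1 frame
(10 sub-steps per video frame, drive held constant within a frame,
m(0) = 0).  The scheme requires dt(α + I) < 1 and is a contraction toward
the equilibrium βI/(α + I).

## Model area MSTd

169 heading-tuned template units.  Preferred headings are 2D image
positions drawn in polar coordinates about the image center: angles are
equiangular over the circle, radii are R_max·x^γ with x ~ U[0, 1] and
R_max = √(64² + 64²) ≈ 90.5 px (the center-to-corner distance), giving
P(R ≤ t·R_max) = t^{1/γ}.  γ < 1 overrepresents peripheral headings,
γ > 1 central ones; γ = 0.5 ("peripheral model") and γ = 2 ("central
model") are the reference configurations.  This normalization is chosen
because the raw power transform of a radius-squared uniform variate is
degenerate for γ ≠ 0.5 (radii far outside the image); for γ = 0.5 the two
forms coincide exactly.  For strongly central populations (γ ≥ 5) radii
below ~10⁻¹³ px are absorbed into the center coordinate by double
precision; this is harmless and acknowledged in the tests.

Each MSTd unit weights each MT unit by the product of

1. a direction match U = max(2·max(cos Δ, 0)^q − 1, 0) between the MT
   unit's preferred direction and the radial direction from the template's
   heading position to the MT RF, with q = 2 by default (U falls to zero
   at a 45° mismatch).  The inner rectification keeps anti-preferred
   directions at zero for every exponent: a heading template never
   recruits motion opposite to its radial pattern.  Without it, even
   exponents would assign full weight at a 180° mismatch, letting
   far-peripheral templates match every active MT unit; empirically that
   doubles the mean absolute heading error of the peripheral model.
2. a Gaussian in the distance between heading position and RF center
   (σ_MST = 77 px ≈ 50°, again used literally as the Gaussian σ), with
   the 1/(2πσ²) normalization.

Weights are time-invariant within a run and cached; a pair whose heading
position coincides with the RF center has no defined radial direction and
gets weight zero.  The MSTd drive is the weight matrix applied to MT
activity, averaged over MT units, and MSTd activations follow the same
leaky-integrator dynamics (α = 0.1, β = 2.5).

## Decoding and bias

Heading is decoded each frame as the activation-weighted mean of the
units' preferred-heading x-positions (population vector); only the
horizontal coordinate is decoded because stimuli vary heading along the
horizon.  Per-frame decodes are smoothed by an exponential moving average
with λ = 0.25, initialized at the first decoded value so a constant input
is a fixed point (initializing at zero would only inject a transient that
decays by (0.75)^t).  The smoothed value at the final frame, converted to
degrees by the tangent map, is the single estimate for the video.

Bias is positive toward straight-ahead (center bias) and negative away
from it: α = sign(θ)(θ − θ̂) for θ ≠ 0, and −|θ̂| at θ = 0, where any
error is peripheral.  A run whose final total MSTd activation is at or
below 10⁻¹² cannot be decoded; the model is resampled with a fresh seed
(bounded at 50 attempts), matching the protocol of re-running until valid
estimates are obtained.  Frames before the first decodable frame inherit
the first decodable value so the smoother starts at the first informative
readout.

## Simulation protocol and experiments

For each condition the stimulus is generated once and held fixed while the
model (MT preferences and MSTd headings) is resampled on each of 50 runs;
across-run variability therefore reflects tuning-parameter sampling only.
Noise conditions regenerate the stimulus 10 times, with runs divided
evenly across stimuli.  Five standard sweeps are provided: the MSTd γ
family (0.1–10), MSTd RF size (12.8–128 px), MSTd direction exponent
q (1–8), MT direction deviation σ_d (0–360°), and the four MT
speed-tuning models.  Summaries report per-condition mean bias, the SD of
estimates across runs, the mean absolute error (mean over headings of
|mean bias|; a per-run variant is also exposed), the mean across-heading
SD, and noise-minus-baseline bias deltas (63 per model: 21 headings × 3
noise levels).

All randomness flows from one base seed through deterministic seed
derivations: stimulus seeds depend only on (heading, noise, repetition),
never on the swept value or run, so every model variant sees identical
stimuli; model seeds additionally encode value and run; decode-failure
retries increment an attempt counter.  Full experiments are bit-identical
across reruns.

## Problem sizes

The default test suite runs the 21-heading peripheral-model sweep at 10
model samplings per heading, the γ=10 check at 10 samplings, and the
noise protocol for the full γ family at 2 samplings with one stimulus per
noise condition; `scripts/acceptance.py` uses the full 50-sampling
protocol (about 3–4 minutes on one core).  These sizes keep the sampling
error of summary statistics well below the effects being measured.

## What the generator does and does not emulate

The dot-cloud stimulus reproduces the geometry of translational optic
flow exactly (it is computed from the flow equations), so conclusions
about the mapping from flow structure to decoded heading transfer
directly.  It does not model luminance, contrast, occlusion, eye
movements, rotational flow components, or structured environments
(ground planes), and MT units are driven by idealized vectors rather
than spatiotemporal filtering of images — matching the scope of the
modeled pathway, which abstracts away V1 and earlier stages.  Passing
tests therefore validate the population-readout account of heading bias,
not a full image-computable pipeline.

## Known limitations

Reproduction of the published summary statistics is qualitative-to-
semiquantitative.  Every directional effect is reproduced: near-zero
central bias uniquely at γ = 0.5; peripheral bias for γ < 0.5 at central
headings turning into center bias in the far periphery; center bias
growing with eccentricity for γ ≥ 1; the RF-size improvement plateauing
near 77 px; V-shaped bias under strictly radial MT tuning; the
center-to-peripheral bias flip when MT speed preference scales with
eccentricity; S-shaped raw-estimate curves.  Magnitudes, however, run
larger than the published ones for periphery-heavy statistics (e.g. the
peripheral model's mean absolute error computes to ~7.8° rather than
5.7°, its mean across-run SD to ~4.8° rather than 1.7°, and the γ = 10
model's bias at ±50° to ~47° rather than 30°), because the MSTd
activation profile implied by the published weight equations is broad: a
linear population vector over a strongly center-weighted γ = 10
population cannot reach a 20° readout unless peripheral templates
out-activate central ones by an order of magnitude, a ratio the
rectified-cosine/Gaussian weight structure with q = 2 and σ_MST = 77 px
does not produce (and that the concave leaky-integrator map cannot
amplify).  The discrepancy most likely reflects an implementation detail
of the original code not recoverable from its published description.
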