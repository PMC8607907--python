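# headingflow

Simulation of heading perception from optic flow with a feedforward
MT → MSTd template model.

Humans judge their direction of self-motion (heading) from the expanding
pattern of retinal motion — optic flow — accurately near straight-ahead,
with systematic errors toward the periphery.  The prevailing neural account
is that heading sensitivity arises in area MSTd by feedforward integration
of local motion signals from area MT arranged in radial "templates": an
MSTd unit tuned to heading **h** pools MT units whose preferred directions
match the radial outflow that self-motion toward **h** would produce.
`headingflow` implements this model end to end and quantifies how
physiological tuning assumptions shape the accuracy (bias) and precision
(across-run variability) of decoded heading:

- **Stimuli** — 2 s, 60-frame videos of translation at 1.5 m/s through a
  3D dot cloud, projected on a 128 × 128 px image (90° field of view,
  pinhole camera), with an optional proportion of "noise dots" that jitter
  around observer-fixed anchors instead of moving rigidly.
- **MT** — 225 units with Gaussian RFs (σ_r = 7 px), direction tuning
  biased toward the radial pattern (deviation up to ±σ_d/2, σ_d = 180°),
  Gaussian direction (σ_v = 10°) and speed (σ_s = 0.45 px/s) tuning, and
  saturating leaky-integrator dynamics dm/dt = −αm + (β − m)I.
- **MSTd** — 169 heading templates whose preferred headings are sampled
  with a center–peripheral exponent γ (radius ∝ x^γ, x ~ U[0,1]; γ < 1
  overrepresents the periphery), rectified-cosine direction matching
  raised to a power q, a Gaussian spatial kernel (σ_MST = 77 px), and the
  same leaky-integrator dynamics.
- **Decoding** — per-frame population vector over preferred-heading
  x-positions, exponentially smoothed (λ = 0.25); the final smoothed value
  is the heading estimate.  Bias is reported as positive toward
  straight-ahead (center bias) and negative away from it.
- **Experiments** — five standard sweeps (MSTd γ, MSTd RF size, MSTd
  direction exponent q, MT direction deviation σ_d, MT speed-tuning
  models), each with 50 model samplings per condition over the 21 headings
  −50°…50°, with optional 70/80/90% noise conditions.

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices, and known limitations.

## Worked example

```python
from headingflow import SceneConfig, MTParams, MSTdParams, ExperimentSpec, run_experiment, summarize
from headingflow.experiments import run_single, compute_mae

# one run: stimulus at -20 deg heading, default peripheral model (gamma = 0.5)
trace, retries = run_single(
    SceneConfig(heading_deg=-20.0), MTParams(), MSTdParams(gamma=0.5),
    stim_seed=7, model_seed=42,
)
print(f"estimate: {trace.estimate_deg:+.1f} deg   bias: {trace.bias_deg:+.1f} deg")
```

```
estimate: -13.8 deg   bias: +6.2 deg
```

The model undershoots the −20° heading by 6.2°, an error toward
straight-ahead (center bias).  A small sweep contrasts the peripheral
(γ = 0.5) and central (γ = 2) models:

```python
spec = ExperimentSpec(name="mstd_heading", values=(0.5, 2.0),
                      headings=(-40.0, -20.0, 0.0, 20.0, 40.0), runs=10, base_seed=1)
summary = summarize(run_experiment(spec))
print(summary[["value", "heading_deg", "mean_bias", "sd_estimate"]].round(1).to_string(index=False))
print("MAE by gamma:", compute_mae(summary).round(1).to_dict())
```

```
 value  heading_deg  mean_bias  sd_estimate
   0.5        -40.0       12.7          4.5
   0.5        -20.0        3.1          4.0
   0.5          0.0       -3.1          3.8
   0.5         20.0        5.1          4.9
   0.5         40.0       13.3          4.3
   2.0        -40.0       29.7          2.7
   2.0        -20.0       14.4          1.7
   2.0          0.0       -0.9          1.1
   2.0         20.0       14.4          2.6
   2.0         40.0       30.4          4.1
MAE by gamma: {0.5: 7.4, 2.0: 18.0}
```

The model that overrepresents peripheral headings (γ = 0.5) stays nearly
unbiased for central headings and limits center bias to ~13° at ±40°,
while the central model's (γ = 2) center bias grows steeply with
eccentricity — more than doubling the overall mean absolute error (MAE,
the mean over headings of |mean bias|).  `sd_estimate` is the SD of
estimates across the 10 model samplings; only the model, never the
stimulus, is resampled between runs.

## Command line

```bash
headingflow stimgen --heading -20 --noise 0.7 --seed 3 --out stim.csv
headingflow run --experiment mstd_heading --runs 5 --seed 7 --out results/
headingflow run --gamma 0.5 --headings -50:5:50 --noise --out results_noise/
headingflow summarize results/results.csv --out summary.json
headingflow plot results/results.csv --out bias.png
```

`run` writes a long-format `results.csv` (one row per run, with seeds),
`summary.csv`, and a `summary.json` with per-condition means/SDs, MAE, and
noise-effect statistics.  Experiments are bit-identical for a fixed
`--seed`.

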