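# popnoise

Trial-to-trial variability analysis for whole-brain calcium imaging of
larval zebrafish during visually evoked behavior — and a planted-structure
synthetic generator that makes every stage of the analysis testable
against known ground truth.

Larval zebrafish respond to a moving dot with approach (small, prey-like
objects) or avoidance (large, predator-like objects), but individual
trials of the same stimulus produce wildly different responses. This
package implements the population-level analysis of that variability:

- **Stimulus decoding.** A size-weighted, side-signed stimulus regressor
  convolved with the GCaMP kernel; partial least squares (PLS) regression
  extracts the visually-evoked subspace and the optimal decoding
  direction **w**_opt; lasso-logistic classifiers decode stimulus
  identity trial by trial.
- **Noise-mode geometry.** Within the PLS subspace, the mean within-class
  covariance of trial responses, C = Σ_α λ_α **e**_α **e**_αᵀ, yields the
  noise modes; cos θ_α = **w**_opt·**e**_α / (|**w**_opt||**e**_α|)
  measures whether trial-to-trial variability can limit stimulus
  information (θ = 90° — harmless; θ = 0° — information-limiting).
- **Behavior.** Tail-curvature bout extraction at the σ_active threshold
  (one SD of |curvature|), ±σ_active turn labeling, vigor/direction
  regressors, freely-swimming approach/avoidance distances.
- **Pre-motor decoding.** Trials time-warped to align stimulus onset and
  movement initiation; classifiers swept over integration windows predict
  single-trial turn direction and responsiveness; macro-F profiles against
  label-shuffled baselines reveal a slow pre-stimulus bias and a ramp
  rising ~1 s before movement; shuffle-calibrated significant-neuron maps
  and their distribution across brain regions.
- **Spontaneous transfer.** The frozen evoked turn model applied to the
  second before each spontaneous turn tests whether one circuit drives
  both evoked and spontaneous turning.
- **Optics.** The Fourier light-field microscope's theoretical resolution,
  R_xy = λ·f_FL/(d_MLA·M).

The synthetic generator (`popnoise.synthetic`) plants all of this —
per-size encoding directions, a vigor noise factor at a configurable angle
to **w**_opt, slow Ornstein–Uhlenbeck turn/responsiveness biases,
pre-movement ramps, an ARTR-like alternating spontaneous-turn chain,
GCaMP convolution, photobleaching — and records the ground truth, so each
estimator is validated by recovery.

## Worked example

```python
import numpy as np
from popnoise.experiments import noise_mode_angle

res = noise_mode_angle(seed=9010, angle_deg=90.0, n_neurons=500, n_trials=180)
print("PLS dimensionality:", res["d"])
print("variance fraction of mode 1:", round(res["var_fraction1"], 2))
print("angle(e1, w_opt):", round(res["theta1_deg"], 1), "deg")
print("w_opt recovery error:", round(res["wopt_error_deg"], 1), "deg")
```

prints

```
PLS dimensionality: 2
variance fraction of mode 1: 0.8
angle(e1, w_opt): 89.8 deg
w_opt recovery error: 4.7 deg
```

that is: on a session whose dominant shared-noise loading was planted
orthogonal to the stimulus-encoding direction, the pipeline recovers the
decoding direction to within ~5° and finds the largest trial-to-trial
noise mode (~80% of the within-class variance) at ~90° to it — the
geometry under which strong trial-to-trial variability leaves stimulus
decoding intact.

The full pipeline (simulate → preprocess → behavior → encoding → noise
geometry → pre-motor decoding → transfer) runs from one config:

```
popnoise run-all --out results/demo
popnoise optics --lambda-um 0.515 --ffl-mm 180 --dmla-mm 1.5 --mag 20
```

The second command prints `R_xy = 3.090 um` (and the axial estimate for
the selected formula variant). Every run writes a manifest with the
config hash and seeds next to its outputs.

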