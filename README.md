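# myokin

**Surface-EMG-driven estimation of 3D lip movement.**

Predicting how the lips will move from the electrical activity of the
facial muscles is a building block for patient-specific functional
modelling in oral-cancer surgery planning: if a model can be driven by a
person's own muscle activations, the functional consequences of removing
tissue can be simulated before operating. `myokin` implements such a
model for healthy-speaker data: 16 channels of bipolar facial sEMG
(8 muscles × 2 sides, 2048 Hz) on the input side, and 10 lip markers
tracked in 3D at 100 Hz (a 30-dimensional position vector **X**, in mm)
on the output side.

## Method

1. Band-pass each channel (Butterworth order 4, 15–500 Hz, zero phase)
   and reduce it to one of four window statistics per 100 Hz frame —
   RMS, MAV, waveform length (WL) or Willison amplitude (WAMP) — over a
   trailing window (50–300 ms), compensating the ~30 ms
   electromechanical activation delay.
2. Augment the 16 features **g** with all 136 quadratic terms
   g_i·g_j (i ≤ j) → **ḡ** ∈ ℝ¹⁵². A PCA of the standardised joint
   vectors **z** = [**X**; **ḡ**] ∈ ℝ¹⁸² gives orthonormal loadings
   **Y** (182 × D) and latent coefficients **b** = **Y**ᵀ**z**. The rows
   of **Y** split into **Y**_x (markers) and **Y**_g (features), yielding
   the pseudo-linear measurement model **ḡ** = **Y**_g **b** + **v**,
   cov(**v**) = **C**_v.
3. Track **b**(t) with a discrete Kalman filter in information form,
   under first-order dynamics **b**(t+1) = **F b**(t) + **w**(t) or D
   decoupled AR(2) models (second order), and decode marker positions
   through **Y**_x. A *static* variant (process-noise std × 10⁶) uses
   measurements only.
4. Evaluate by rotating repetitions (train on 4, test on 1), scoring the
   RMS error over all 30 coordinates; tune the design parameters
   (D, c_v, c_w and, for order 2, c_f, c_d) by cross-validated successive
   parabolic coordinate descent; compare model variants with the exact
   one-sided paired Wilcoxon signed-rank test.

The original five-volunteer recordings were never deposited, so the
package ships a two-tier synthetic-data generator (latent-dynamics tier
and raw-signal tier, both with stored ground truth) that emulates the
statistical structure the method assumes. See `docs/methods.md` for the
model details, the generator's scope and its limits.

## Worked example

Simulate a small subject, extract WAMP features, cross-validate a
first-order model and compare with the static variant:

```sh
myokin simulate --out demo --seed 42 --instructions 6 --repetitions 3 --frames 100
myokin features --manifest demo/manifest.yaml --out demo/features --feature WAMP --wamp-threshold 10
myokin evaluate --manifest demo/manifest.yaml --order 1 --dim 12 --feature WAMP
myokin evaluate --manifest demo/manifest.yaml --order static --dim 12 --feature WAMP
```

which prints

```
cross-validated RMS error: 0.688 (0.008) mm
cross-validated RMS error: 0.683 (0.008) mm
```

i.e. the pipeline tracks the held-out lip trajectories of this synthetic
subject with ~0.7 mm RMS error against an injected tracking-noise floor
of 0.5 mm. With clean, information-rich measurements like these, static
(measurement-only) and dynamic estimation are essentially tied; the
dynamic model pulls ahead when the feature measurements are substantially
noisier (the acceptance script quantifies exactly that on five noisy
synthetic subjects). A model can be fitted and stored with `myokin fit`,
applied to a single trial with `myokin predict`, and tuned with `myokin
optimize`.

The same pipeline is available as a library:

```python
import myokin as mk

cfg = mk.SynthConfig(seed=1, D_true=8, frames_per_trial=105)
fts, truth = mk.generate_latent_mode(cfg)
result = mk.cross_validate(fts, order=1, design=mk.DesignParams(D=8, c_v=0.1, c_w=0.2))
print(result.mean_rms, result.sd_rms)
```

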