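# Methods

## Model overview

`myokin` estimates 3D lip-marker trajectories (10 markers at 100 Hz, in mm,
flattened to a 30-vector X) from 16 channels of facial surface EMG sampled
at 2048 Hz. The estimation chain is:

1. **Signal conditioning.** Each sEMG channel is band-pass filtered with a
   4th-order Butterworth filter, 15–500 Hz, applied forward–backward
   (zero phase). Zero-phase filtering avoids adding group delay on top of
   the explicitly modelled electromechanical delay.
2. **Windowed features.** For each 100 Hz marker frame at time τ, one of
   four window statistics — RMS, MAV (mean absolute value), WL (waveform
   length) or WAMP (Willison amplitude, count of successive differences
   ≥ a threshold x_lim) — is computed per channel from the raw samples in
   the trailing window [τ − delay − w, τ − delay]. The activation delay
   (default 30 ms, i.e. 3 frames) accounts for muscle electrical activity
   preceding the motion it produces. Features are evaluated directly at
   the 100 Hz output times, which is numerically identical to
   maximum-overlap sliding at 2048 Hz followed by decimation, at ~1/20 of
   the cost.
3. **Quadratic augmentation.** The 16-vector g is extended with all 136
   monomials g_i·g_j (i ≤ j), in a fixed lexicographic order, to a
   152-vector ḡ. This is a second-order truncated Taylor expansion of
   the (nonlinear) feature-to-position map; it is what lets a linear
   latent model capture, e.g., bilateral co-contraction effects.
4. **Joint PCA measurement model.** Training vectors z = [X; ḡ] ∈ R^182
   are standardised elementwise (training mean/std only; test data reuse
   the training statistics, so no leakage) and the first D principal
   directions Y (182 × D, orthonormal, SVD-based with a deterministic
   sign convention) define latent coefficients b = Yᵀ z_norm. Splitting
   Y into its marker rows Y_x (30) and feature rows Y_g (152) yields the
   pseudo-linear measurement model ḡ_norm = Y_g b + v. The residual
   covariance C_v (152 × 152) is estimated from the training residuals at
   the chosen D and regularised by shrinkage towards the scaled identity,
   C_v ← (1 − c_v)·C_v + c_v·mean(diag C_v)·I, which preserves the trace.
5. **Latent dynamics.** Either a first-order model b(t+1) = F b(t) + w(t)
   with the moment estimator F̂ = mean[b(t+1)b(t)ᵀ]·mean[b(t)b(t)ᵀ]⁻¹, or
   D decoupled AR(2) models b_n(t+1) = α_n b_n(t) + β_n b_n(t−1) + w_n(t)
   fitted per coefficient by least squares (state [b(t−1); b(t)], block
   transition [[0, I], [diag β, diag α]], process noise only in the lower
   block, C_22 diagonal). F and C_w are diagonalised by default — the PCA
   decorrelates the coefficients, so the off-diagonal entries are
   estimation noise — with a flag to keep the full matrices. Transition
   pairs (and AR(2) triples) spanning trial-concatenation seams are
   excluded from every fit. Each AR(2) pair maps to a natural frequency
   and relative damping via f = √(1 − α − β)/(2πT) and
   ζ = (−α − 2)/(2√(1 − α − β)); the inverse is algebraically exact. Note
   the sign convention of ζ: it comes out negative for typical stable
   poles. The formula is kept as-is, with the exact inverse guaranteeing
   consistency, and the c_d correction scales whatever sign results.
6. **Tuning corrections.** Five design parameters: D (latent dimension),
   c_v, c_w ∈ [0, 1] (covariance shrinkage), and for the second-order
   model c_f, c_d > 0, which scale the natural frequencies and dampings
   before converting back to AR coefficients. The process-noise
   correction replaces C_22 by (1 − c_w)·C_22 + c_w·diag(smoothed
   diagonal), where the smoother is a centred moving average of width 3
   over the component index (edges use available neighbours); the width
   is configurable. Defaults (D = 20, c_v = 0.1, c_w = 0.2, c_f = 3.4,
   c_d = 0.7) are the published average optima of the five-volunteer
   study the method was developed on.
7. **Estimation.** A discrete Kalman filter in information form:
   C(t|t) = (C⁻¹(t|t−1) + Hᵀ C_v⁻¹ H)⁻¹ and
   x̂(t|t) = C(t|t)(C⁻¹(t|t−1) x̂(t|t−1) + Hᵀ C_v⁻¹ ḡ(t)), with H = Y_g
   (first order) or [0 Y_g] (second order). Because D ≪ 152, only
   state-sized matrices are inverted per frame once Hᵀ C_v⁻¹ H and
   C_v⁻¹ H are cached; the tests verify equivalence with the textbook
   gain form to 1e-8. A *static* (measurement-only) estimator is obtained
   by multiplying the process-noise standard deviation by 1e6 (literal
   infinity would break invertibility) together with a correspondingly
   diffuse initial prior; it coincides with the frame-wise GLS solution
   b̂ = (Y_gᵀ C_v⁻¹ Y_g)⁻¹ Y_gᵀ C_v⁻¹ ḡ_norm to 1e-6.
8. **Evaluation.** Trials (19 instructions × 5 repetitions in the
   reference protocol) are pooled by concatenation, instructions
   ascending within each repetition. Cross-validation rotates the
   repetitions: train on R − 1, filter the held-out repetition (filter
   state re-initialised at each concatenation seam), and score the RMS of
   the error over all 30 coordinates and all test frames; folds are
   averaged. A per-marker Euclidean *distance* RMS is available behind a
   flag. Design parameters are tuned by cyclic coordinate descent —
   order D, c_v, c_w(, c_f, c_d) — with successive parabolic
   interpolation per parameter (memoised; safeguarded by gap bisection;
   integer-snapped for D), at most 3 cycles, stopping when a cycle
   improves the criterion by < 0.1%. The tuning operates on the same
   cross-validation criterion it reports (a nested mode is deliberately
   out of scope here; the flat protocol is the one being reproduced).
   Static and dynamic variants are compared with the exact one-sided
   paired Wilcoxon signed-rank test (ties dropped); one-sided is
   justified because the static model is a special case of the dynamic
   one.

## Numerical choices

- All symmetric solves add a relative jitter of 1e-10·mean(diag) and
  covariances are re-symmetrised each step; this keeps thousands of
  filter steps PSD in float64.
- Standardisation floors zero-variance elements at 1e-12 (logged) so a
  constant channel cannot produce NaNs.
- The filter is initialised at the latent mean (zero) with the training
  latent covariance C_b (duplicated block-diagonally for order 2) — a
  stationary prior.
- PCA component signs are fixed (largest-magnitude loading positive) for
  cross-platform determinism.
- Initial parameters and all optimiser evaluations are deterministic
  given the data; a seed argument exists for interface uniformity.

## Synthetic data: what it emulates and what it does not

No public recordings exist for this task, so the generator provides two
tiers with stored ground truth.

**Latent mode** draws D_true stable AR(2) latent processes
(parameterised by natural frequency in Hz and a standard damping ratio
ζ ∈ (0,1), mapped to AR coefficients by exact pole mapping) and emits
features ḡ = s_g·Y_g b + v and markers X = X₀ + s_x·Y_x b + e. Scales are
set so clean feature elements have unit variance (making the measurement
noise parameter a relative noise level) and clean marker coordinates have
a configurable excursion std (3 mm default — lip-scale motion). Trials
share an instruction-specific latent component across repetitions
(correlation 0.7 by default), which leaves the second-order statistics of
each series exactly AR(2).

The emission is, by default, built from cosine/sine Fourier column pairs
over the 182 element indices rather than a generic random orthonormal
matrix. The pairs give every element exactly equal signal variance, so
the elementwise standardisation inside the model fit reduces to a uniform
scaling and the PCA recovers the latent components themselves (up to
rotation within a pair, which is harmless because paired components share
their variance and dynamics). With a generic random orthonormal emission
the standardisation re-weights rows unevenly and the recovered components
are mixtures of the true ones — per-component parameter recovery is then
ill-posed no matter how much data is available. A `random` emission mode
is kept for subspace-level (not per-component) checks.

**Raw mode** synthesises the acquisition itself: per channel, an
instruction-specific activation envelope (sparse raised-cosine bursts,
bilaterally symmetric except for the two asymmetric instructions, with
repetition-to-repetition amplitude jitter) multiplies a 15–500 Hz
band-limited unit-variance noise carrier at 2048 Hz; markers respond to
the envelope delayed by 30 ms through a linear mixing plus a quadratic
term (so the augmentation's cross products are genuinely informative),
plus tracking noise. The sEMG stream starts 0.5 s before the first marker
frame so trailing windows always have data.

Not emulated: volume conduction/crosstalk beyond linear mixing,
non-stationary carrier spectra, electrode artefacts, biomechanical tissue
dynamics, head-movement residuals. Passing tests therefore demonstrate
the correctness and internal consistency of the estimation machinery
under the model's own assumptions, not performance on real recordings —
the published per-volunteer RMS errors cannot be reproduced without the
original data, and no attempt is made to match their absolute values.

## Study configurations used by the tests and the acceptance script

- *Parameter recovery*: D_true = 8 (four Fourier pairs), 19 × 5 trials of
  105 frames (~10⁴ frames), natural frequencies geometrically spaced over
  2–5 Hz (speech-articulation range — and, at T = 10 ms, low enough
  frequencies make 1 − α − β so small that its estimate is dominated by
  sampling noise, which is an identifiability limit of the estimator, not
  a bug), dampings 0.15–0.3 (lightly damped, sharply peaked spectra keep
  the frequencies well identified at this sample size), independent
  repetitions, feature noise 0.1, marker noise 0.25 mm. Note the AR fit
  on encoded coefficients is a least-squares fit on a noisy series; large
  feature noise attenuates the estimated AR coefficients
  (errors-in-variables), so the recovery study keeps the noise light.
- *Static-vs-dynamic comparison*: five subjects, D_true = 6, 19 × 5
  trials of 50 frames, feature noise 2.0 (substantial — per-frame
  measurement-only estimation is then genuinely noisy and temporal
  smoothing can pay off), marker noise 0.5 mm. Both models are tuned by
  the same coordinate-descent optimiser (D and c_v for the static model;
  D, c_v, c_w for the first-order model) before comparison.

Problem sizes were chosen so the full suite and the acceptance script
run comfortably on a single CPU.

## Known limitations

- WAMP thresholds are interpreted in the units of the recording and are
  fully configurable; published values of 10 and 20 mV are far above
  typical facial sEMG amplitudes, suggesting a units inconsistency in the
  original report, so no unit conversion is hard-coded.
- The ζ sign convention (negative for stable poles) is preserved from the
  source formulation; only round trips and the multiplicative c_d
  correction rely on it.
- Whether features should be computed before or after downsampling is
  unspecified in the source protocol; this implementation computes them
  on the raw 2048 Hz samples.
- The "Average" column of the published benchmark is reproduced as given;
  it is not the arithmetic mean of the per-volunteer bests (it reflects a
  single shared configuration), and both interpretations are exposed in
  `myokin.reference`.
- Smoothing (forward–backward), adaptive noise estimation and streaming
  operation are out of scope.
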