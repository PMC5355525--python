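"""Synthetic trial sets with the statistical structure the method assumes.

Two generation tiers:

* **Latent mode** emulates the estimator's own data model directly: per
  latent coefficient, a stable AR(2) process (parameterised by natural
  frequency and damping ratio); augmented features arise by a linear
  emission ``gbar = Y_g b + v`` and markers by ``X = X0 + s (Y_x b) + e``
  with a random orthonormal 182 x D_true emission matrix.  This isolates
  the measurement-model, state-space and estimation modules from signal
  processing.

* **Raw mode** emulates the acquisition itself: 16 channels of
  amplitude-modulated band-limited (15-500 Hz) noise at 2048 Hz, driven by
  smooth instruction-specific activation envelopes (bilaterally symmetric
  except for the two asymmetric instructions), and 100 Hz marker
  trajectories responding to the envelopes through a linear-plus-quadratic
  mixing with the activation leading the motion by a configurable delay
  (30 ms by default).  The quadratic mixing makes the cross products of
  the feature augmentation genuinely informative.

Every draw is governed by a single root seed; repetition-to-repetition
variability comes from shared-vs-individual latent components (latent
mode) or envelope amplitude jitter (raw mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .datatypes import (
    DEFAULT_CHANNEL_LABELS,
    EmgRecording,
    FeatureTrialSet,
    MarkerTrajectory,
    N_CHANNELS,
    N_COORDS,
    TrialSet,
)
from .measurement import N_AUG, N_FEAT, augment


def _per_pair(values: np.ndarray, D: int, paired: bool) -> np.ndarray:
    return np.repeat(values, 2)[:D] if paired else values


def _default_freqs(D: int, paired: bool) -> np.ndarray:
    """Natural frequencies (Hz) over the speech-articulation band 2-5 Hz."""
    n = (D + 1) // 2 if paired else D
    return _per_pair(np.geomspace(2.0, 5.0, n), D, paired)


def _default_dampings(D: int, paired: bool) -> np.ndarray:
    """Damping ratios (standard convention, 0 < zeta < 1): well damped."""
    n = (D + 1) // 2 if paired else D
    return _per_pair(np.linspace(0.5, 0.8, n), D, paired)


def _default_latent_stds(D: int, paired: bool) -> np.ndarray:
    """Descending stationary stds (geometric), giving a clear PCA ordering."""
    n = (D + 1) // 2 if paired else D
    return _per_pair(1.0 * 0.66 ** np.arange(n), D, paired)


@dataclass
class SynthConfig:
    """Configuration of the synthetic-data generator.

    Defaults emulate the reference acquisition: 19 instructions x 5
    repetitions, 100 Hz marker frames, 2048 Hz sEMG, a 30 ms activation
    delay, lip-scale marker excursions of a few mm and sub-mm tracking
    noise.
    """

    seed: int = 0
    D_true: int = 8
    n_instructions: int = 19
    n_repetitions: int = 5
    frames_per_trial: int = 100
    frame_rate: float = 100.0
    fs: float = 2048.0
    latent_freqs: np.ndarray | None = None  # Hz, per component
    latent_dampings: np.ndarray | None = None  # standard zeta in (0, 1)
    latent_stds: np.ndarray | None = None  # stationary stds, descending
    cross_rep_corr: float = 0.7  # latent correlation between repetitions
    marker_signal_std_mm: float = 3.0  # per-coordinate excursion scale
    marker_noise_mm: float = 0.5  # additive tracking noise
    measurement_noise: float = 0.5  # feature noise, relative to unit signal
    delay_ms: float = 30.0  # activation-to-motion delay (raw mode)
    emg_amplitude: float = 30.0  # carrier scale at full activation
    emg_floor: float = 0.05  # baseline activation level
    quadratic_strength: float = 0.35  # raw mode: quadratic mixing weight
    emission: str = "fourier"  # latent mode: "fourier" (identifiable) or "random"
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        D = self.D_true
        if not 1 <= D <= N_COORDS:
            raise ValueError(f"D_true must lie in [1, {N_COORDS}]")
        if self.emission not in ("fourier", "random"):
            raise ValueError("emission must be 'fourier' or 'random'")
        if self.emission == "fourier" and D % 2:
            raise ValueError("fourier emission requires an even D_true")
        paired = self.emission == "fourier"
        if self.latent_freqs is None:
            self.latent_freqs = _default_freqs(D, paired)
        if self.latent_dampings is None:
            self.latent_dampings = _default_dampings(D, paired)
        if self.latent_stds is None:
            self.latent_stds = _default_latent_stds(D, paired)
        self.latent_freqs = np.asarray(self.latent_freqs, dtype=float)
        self.latent_dampings = np.asarray(self.latent_dampings, dtype=float)
        self.latent_stds = np.asarray(self.latent_stds, dtype=float)
        for name in ("latent_freqs", "latent_dampings", "latent_stds"):
            if getattr(self, name).shape != (D,):
                raise ValueError(f"{name} must have length D_true={D}")
        if not 0.0 <= self.cross_rep_corr < 1.0:
            raise ValueError("cross_rep_corr must lie in [0, 1)")
        for name in ("marker_noise_mm", "measurement_noise", "quadratic_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    config: SynthConfig
    latents: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    clean_markers: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    alpha: np.ndarray | None = None  # AR(2) lag-1 coefficients actually used
    beta: np.ndarray | None = None  # AR(2) lag-2 coefficients actually used
    Y: np.ndarray | None = None  # latent-mode emission matrix (182 x D_true)
    marker_scale: float | None = None
    X0: np.ndarray | None = None
    envelopes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    mixing: np.ndarray | None = None  # raw mode: linear 30 x 16 mixing


def _pole_ar2(f: np.ndarray, zeta: np.ndarray, T: float):
    """Stable AR(2) coefficients by exact pole mapping of a damped oscillator.

    alpha = 2 exp(-zeta w T) cos(w T sqrt(1 - zeta^2)), beta = -exp(-2 zeta w T),
    with w = 2 pi f; valid for 0 < zeta < 1 (underdamped poles inside the
    unit circle).
    """
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any((zeta <= 0) | (zeta >= 1)):
        raise ValueError("damping ratios must lie in (0, 1)")
    damp = np.exp(-zeta * w * T)
    alpha = 2.0 * damp * np.cos(w * T * np.sqrt(1.0 - zeta**2))
    beta = -(damp**2)
    # pole radius < 1 guaranteed by construction; guard anyway
    if np.any(np.abs(beta) >= 1.0) or np.any(1.0 - alpha - beta <= 0.0):
        raise ValueError("requested AR(2) poles are not stable")
    return alpha, beta


def _ar2_stationary_noise_std(alpha, beta, target_std):
    """Innovation std giving the requested stationary std of an AR(2)."""
    gamma0_unit = (1.0 - beta) / ((1.0 + beta) * ((1.0 - beta) ** 2 - alpha**2))
    return np.asarray(target_std) / np.sqrt(gamma0_unit)


def _simulate_ar2(alpha, beta, sigma_w, n, rng, burn_in=300):
    """Simulate D decoupled AR(2) series, discarding a burn-in."""
    D = alpha.shape[0]
    total = n + burn_in
    w = rng.standard_normal((total, D)) * sigma_w
    b = np.zeros((total, D))
    for t in range(2, total):
        b[t] = alpha * b[t - 1] + beta * b[t - 2] + w[t]
    return b[burn_in:]


def _random_orthonormal(rows, cols, rng):
    q, r = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q * np.sign(np.diag(r))


def _fourier_pair_basis(rows, cols, rng):
    """Orthonormal emission with exactly flat row energy.

    Columns come in cosine/sine pairs at distinct Fourier frequencies of
    the row index, so each pair contributes ``1/(rows/2)`` to every row:
    the element variances of the emitted vectors are identical, and the
    elementwise normalisation applied during model fitting reduces to a
    uniform scaling that does not mix latent components.  A random
    orthonormal emission lacks this property (its rows have uneven
    energy), which makes per-component parameter recovery ill-posed.
    Pairs are expected to share their variance and dynamics, making the
    within-pair rotational ambiguity of the PCA irrelevant.
    """
    if cols % 2:
        raise ValueError("fourier basis requires an even number of columns")
    half = rows // 2
    ks = rng.choice(np.arange(1, half), size=cols // 2, replace=False)
    j = np.arange(rows)
    columns = []
    for k in ks:
        phase = 2.0 * np.pi * k * j / rows
        columns.append(np.cos(phase))
        columns.append(np.sin(phase))
    Y = np.column_stack(columns)
    return Y / np.linalg.norm(Y, axis=0)


def generate_latent_mode(config: SynthConfig):
    """Generate a trial set with precomputed augmented features.

    Returns ``(FeatureTrialSet, GroundTruth)``.  The features are the 152-d
    measurements ``gbar = Y_g b + v`` (no raw sEMG exists in this tier);
    markers are ``X0 + s (Y_x b) + e`` in mm, with a global scale ``s``
    chosen so the clean per-coordinate excursion std equals
    ``marker_signal_std_mm``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = 1.0 / cfg.frame_rate
    alpha, beta = _pole_ar2(cfg.latent_freqs, cfg.latent_dampings, T)
    sigma_w = _ar2_stationary_noise_std(alpha, beta, cfg.latent_stds)

    if cfg.emission == "fourier":
        Y = _fourier_pair_basis(N_COORDS + N_AUG, cfg.D_true, rng)
    else:
        Y = _random_orthonormal(N_COORDS + N_AUG, cfg.D_true, rng)
    Y_x, Y_g = Y[:N_COORDS], Y[N_COORDS:]
    X0 = rng.uniform(-30.0, 30.0, size=N_COORDS)

    rho = cfg.cross_rep_corr
    n = cfg.frames_per_trial
    shared = {
        i: _simulate_ar2(alpha, beta, sigma_w, n, rng)
        for i in range(1, cfg.n_instructions + 1)
    }
    gt = GroundTruth(
        config=cfg, alpha=alpha, beta=beta, Y=Y, X0=X0
    )
    latents = {}
    for r in range(1, cfg.n_repetitions + 1):
        for i in range(1, cfg.n_instructions + 1):
            indiv = _simulate_ar2(alpha, beta, sigma_w, n, rng)
            latents[(i, r)] = np.sqrt(rho) * shared[i] + np.sqrt(1 - rho) * indiv

    # global scales so the clean marker coordinates have the configured std
    # and the clean feature elements unit std (measurement_noise is relative)
    all_b = np.concatenate(list(latents.values()))
    clean_x_unit = all_b @ Y_x.T
    scale = cfg.marker_signal_std_mm / float(
        np.sqrt(np.mean(clean_x_unit.var(axis=0)))
    )
    gt.marker_scale = scale
    clean_g_unit = all_b @ Y_g.T
    g_scale = 1.0 / float(np.sqrt(np.mean(clean_g_unit.var(axis=0))))

    features, markers = {}, {}
    for key, b in latents.items():
        g_clean = g_scale * (b @ Y_g.T)
        g = g_clean + cfg.measurement_noise * rng.standard_normal(g_clean.shape)
        x_clean = X0 + scale * (b @ Y_x.T)
        x = x_clean + cfg.marker_noise_mm * rng.standard_normal(x_clean.shape)
        gt.latents[key] = b
        gt.clean_markers[key] = x_clean
        features[key] = g
        markers[key] = x
    fts = FeatureTrialSet(
        features=features, markers=markers, subject_id=cfg.subject_id
    )
    return fts, gt


def recovery_study_config(seed: int) -> SynthConfig:
    """Conditions of the parameter-recovery study.

    D_true = 8 (four cosine/sine pairs), ~10^4 frames in total, lightly
    damped articulatory resonances (zeta 0.15-0.3, sharply peaked spectra
    that keep the AR natural frequencies well identified at this sample
    size), statistically independent repetitions, and light noise
    (feature noise 0.1 relative, marker noise 0.25 mm).
    """
    return SynthConfig(
        seed=seed,
        D_true=8,
        frames_per_trial=105,
        measurement_noise=0.1,
        marker_noise_mm=0.25,
        cross_rep_corr=0.0,
        latent_dampings=np.repeat(np.linspace(0.15, 0.3, 4), 2),
    )


def noisy_subject_config(seed: int) -> SynthConfig:
    """Conditions of the static-vs-dynamic comparison study.

    Substantial feature measurement noise (2.0 relative to unit signal) so
    that per-frame measurement-only estimation is genuinely noisy and the
    temporal smoothing of a dynamic model can pay off; moderate trial
    length keeps repeated cross-validation affordable.
    """
    return SynthConfig(
        seed=seed,
        D_true=6,
        frames_per_trial=50,
        measurement_noise=2.0,
        marker_noise_mm=0.5,
    )


# -- raw mode --------------------------------------------------------------

_N_MUSCLES = 8
_ASYMMETRIC_INSTRUCTIONS = (18, 19)


def _raised_cosine(t, center, width):
    u = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m]))
    return out


def _instruction_envelopes(cfg: SynthConfig, rng, duration: float):
    """Per-instruction muscle activation patterns as callables on time.

    Each instruction activates a sparse subset of the eight muscles with
    one or two raised-cosine bursts.  Bilateral channels share the pattern
    except for the asymmetric instructions, whose left side is time-shifted
    and re-weighted.
    """
    patterns = {}
    for i in range(1, cfg.n_instructions + 1):
        active = rng.choice(_N_MUSCLES, size=rng.integers(2, 5), replace=False)
        bursts = []
        for m in active:
            n_b = int(rng.integers(1, 3))
            amp = rng.uniform(0.5, 1.0)
            centers = rng.uniform(0.2 * duration, 0.8 * duration, size=n_b)
            widths = rng.uniform(0.25 * duration, 0.6 * duration, size=n_b)
            bursts.append((int(m), amp, centers, widths))
        asym_shift = rng.uniform(0.08, 0.2) * duration if i in _ASYMMETRIC_INSTRUCTIONS else 0.0
        asym_gain = rng.uniform(0.4, 0.8) if i in _ASYMMETRIC_INSTRUCTIONS else 1.0
        patterns[i] = (bursts, asym_shift, asym_gain)
    return patterns


def _envelope_matrix(pattern, t, jitter_amp, rng):
    """Evaluate a 16-channel envelope (channels in muscle-major R/L order)."""
    bursts, asym_shift, asym_gain = pattern
    env = np.zeros((t.size, N_CHANNELS))
    for m, amp, centers, widths in bursts:
        right = np.zeros(t.size)
        left = np.zeros(t.size)
        for c, w in zip(centers, widths):
            right += _raised_cosine(t, c, w)
            left += _raised_cosine(t, c + asym_shift, w)
        jr = amp * (1.0 + jitter_amp * rng.standard_normal())
        jl = amp * asym_gain * (1.0 + jitter_amp * rng.standard_normal())
        env[:, 2 * m] += max(jr, 0.0) * right
        env[:, 2 * m + 1] += max(jl, 0.0) * left
    return np.clip(env, 0.0, None)


def _bandlimited_noise(n, fs, band, rng):
    sos = _signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(n), axis=0)
    return x / x.std()


def generate_raw_mode(config: SynthConfig):
    """Generate raw sEMG + marker trials.  Returns ``(TrialSet, GroundTruth)``.

    Channel ``n`` carries ``(floor + env_n(t)) * carrier_n(t)`` at 2048 Hz,
    where the carrier is 15-500 Hz band-limited unit-variance noise and the
    envelope is the instruction's activation pattern.  Markers at 100 Hz
    respond to the *delayed* envelope: ``X(tau) = X0 + M a(tau - delay) +
    q M2 quad(a(tau - delay)) + e``.  The sEMG stream starts 0.5 s before
    the first marker frame so trailing feature windows always have data.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.frames_per_trial / cfg.frame_rate
    delay = cfg.delay_ms / 1000.0
    pre_roll = 0.5

    patterns = _instruction_envelopes(cfg, rng, duration)
    M = rng.standard_normal((N_COORDS, N_CHANNELS)) * (3.0 / np.sqrt(N_CHANNELS))
    M2 = rng.standard_normal((N_COORDS, N_AUG - N_FEAT)) * (
        3.0 / np.sqrt(N_AUG - N_FEAT)
    )
    X0 = rng.uniform(-30.0, 30.0, size=N_COORDS)

    n_emg = int(round((duration + pre_roll + 0.1) * cfg.fs))
    emg_t = -pre_roll + np.arange(n_emg) / cfg.fs
    frame_t = np.arange(cfg.frames_per_trial) / cfg.frame_rate

    gt = GroundTruth(config=cfg, X0=X0, mixing=M)
    trials = {}
    for i in range(1, cfg.n_instructions + 1):
        for r in range(1, cfg.n_repetitions + 1):
            env_emg = _envelope_matrix(patterns[i], emg_t, 0.1, rng)
            carriers = np.column_stack(
                [
                    _bandlimited_noise(n_emg, cfg.fs, (15.0, 500.0), rng)
                    for _ in range(N_CHANNELS)
                ]
            )
            samples = cfg.emg_amplitude * (cfg.emg_floor + env_emg) * carriers
            emg = EmgRecording(samples=samples, fs=cfg.fs, t0=-pre_roll)

            # markers respond to the envelope `delay` seconds earlier
            a = np.column_stack(
                [
                    np.interp(frame_t - delay, emg_t, env_emg[:, c])
                    for c in range(N_CHANNELS)
                ]
            )
            quad = augment(a)[:, N_FEAT:]
            x_clean = (
                X0
                + a @ M.T
                + cfg.quadratic_strength * (quad @ M2.T)
            )
            x = x_clean + cfg.marker_noise_mm * rng.standard_normal(x_clean.shape)
            markers = MarkerTrajectory(positions=x, frame_rate=cfg.frame_rate)
            trials[(i, r)] = (emg, markers)
            gt.envelopes[(i, r)] = a
            gt.clean_markers[(i, r)] = x_clean
    return TrialSet(trials=trials, subject_id=cfg.subject_id), gt


def make_fixture_suite(seed: int, outdir) -> dict:
    """Write a tiny deterministic raw-mode trial set for tests and docs.

    Creates per-trial sEMG and marker CSVs, a YAML manifest and a
    ground-truth ``.npz``; returns a dict with the manifest path and the
    in-memory objects.
    """
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(
        seed=seed,
        n_instructions=4,
        n_repetitions=2,
        frames_per_trial=120,
        D_true=4,
    )
    trialset, gt = generate_raw_mode(cfg)
    paths = {}
    for (i, r), (emg, markers) in sorted(trialset.trials.items()):
        emg_path = outdir / f"emg_i{i:02d}_r{r}.csv"
        mrk_path = outdir / f"markers_i{i:02d}_r{r}.csv"
        mio.write_emg(emg, emg_path)
        mio.write_markers(markers, mrk_path)
        paths[(i, r)] = (emg_path, mrk_path)
    manifest = outdir / "manifest.yaml"
    mio.write_manifest(
        manifest, cfg.subject_id, paths, fs=cfg.fs, frame_rate=cfg.frame_rate
    )
    np.savez(
        outdir / "ground_truth.npz",
        X0=gt.X0,
        mixing=gt.mixing,
        **{f"env_i{i:02d}_r{r}": env for (i, r), env in gt.envelopes.items()},
    )
    return {"manifest": manifest, "trialset": trialset, "ground_truth": gt}
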