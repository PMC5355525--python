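"""Core container types for sEMG recordings, marker trajectories and trial sets.

The pipeline works with two acquisition streams: multichannel facial surface
EMG (16 bipolar channels, nominally 2048 Hz) and head-movement-corrected 3D
lip-marker trajectories (10 markers, 100 Hz, mm, flattened to 30 columns in
fixed ``m01_x, m01_y, m01_z, ..., m10_z`` order).  Trials are indexed by an
instruction number ``i`` (1..19 in the reference protocol) and a repetition
number ``r`` (1..5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default muscle channel labels: eight facial muscles, right then left side.
DEFAULT_CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{m}_{s}"
    for m in ("ZYG", "RIS", "OOS", "OOI", "MEN", "DAO", "LLS", "DIG")
    for s in ("R", "L")
)

N_CHANNELS = 16
N_MARKERS = 10
N_COORDS = 3 * N_MARKERS

#: Marker column names in the canonical flattening order.
MARKER_COLUMNS: tuple[str, ...] = tuple(
    f"m{m:02d}_{ax}" for m in range(1, N_MARKERS + 1) for ax in "xyz"
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


class ArchiveError(ValueError):
    """Raised when a model archive is corrupt or internally inconsistent."""


@dataclass
class EmgRecording:
    """Raw multichannel sEMG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, 16)
        Bipolar channel amplitudes in the units of the recording (assumed mV).
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique channel labels (muscle abbreviation + side, e.g. ``"ZYG_R"``).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float = 2048.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNEL_LABELS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise FormatError(
                f"expected {N_CHANNELS} signal channels, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 2:
            raise FormatError("recording must contain at least 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channel labels")
        if len(set(self.channel_labels)) != N_CHANNELS:
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Time span covered by the samples, in seconds."""
        return (self.n_samples - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class MarkerTrajectory:
    """Head-movement-corrected 3D lip-marker positions, flattened to 30 columns."""

    positions: np.ndarray
    frame_rate: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != N_COORDS:
            raise FormatError(
                f"expected {N_COORDS} coordinate columns, got shape {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise FormatError("trajectory must contain at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            bad = np.argwhere(~np.isfinite(self.positions))[0]
            raise FormatError(
                f"non-finite marker coordinate at frame {bad[0]}, column {bad[1]}"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class TrialSet:
    """Collection of (instruction, repetition) trials for one subject."""

    trials: dict[tuple[int, int], tuple[EmgRecording, MarkerTrajectory]]
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("trial set is empty")

    @property
    def instructions(self) -> list[int]:
        return sorted({i for i, _ in self.trials})

    @property
    def repetitions(self) -> list[int]:
        return sorted({r for _, r in self.trials})

    def __getitem__(self, key: tuple[int, int]):
        try:
            return self.trials[key]
        except KeyError:
            raise KeyError(f"trial (instruction={key[0]}, repetition={key[1]}) missing")


@dataclass
class FeatureTrialSet:
    """Trials whose sEMG has been reduced to frame-rate feature vectors.

    ``features[(i, r)]`` holds an ``(n_frames, 16)`` matrix of windowed sEMG
    features (or an ``(n_frames, 152)`` matrix if the quadratic augmentation
    has already been applied, as produced by the latent-mode synthetic
    generator); ``markers[(i, r)]`` the matching marker positions.
    """

    features: dict[tuple[int, int], np.ndarray]
    markers: dict[tuple[int, int], np.ndarray]
    subject_id: str = "anonymous"
    feature_config: "object | None" = None

    def __post_init__(self) -> None:
        if set(self.features) != set(self.markers):
            raise ValueError("feature and marker trial keys differ")
        for key in self.features:
            g = np.asarray(self.features[key], dtype=float)
            x = np.asarray(self.markers[key], dtype=float)
            if g.shape[0] != x.shape[0]:
                raise ValueError(f"trial {key}: feature/marker frame counts differ")
            self.features[key] = g
            self.markers[key] = x

    @property
    def instructions(self) -> list[int]:
        return sorted({i for i, _ in self.features})

    @property
    def repetitions(self) -> list[int]:
        return sorted({r for _, r in self.features})
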