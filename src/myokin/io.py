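"""File formats: delimited-text signals, trial manifests, model archives.

All tabular files are comma-separated UTF-8 text with a mandatory header
row, '.' decimal separator and time in seconds as the first column.  sEMG
files carry 16 signal columns; marker files 30 coordinate columns in the
fixed ``m01_x ... m10_z`` order.  A trial manifest is a YAML file mapping
(instruction, repetition) to the two file paths.  A fitted model is stored
as a single ``.npz`` archive of named numeric arrays plus a JSON metadata
block.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ArchiveError,
    EmgRecording,
    FormatError,
    MARKER_COLUMNS,
    MarkerTrajectory,
    N_CHANNELS,
    N_COORDS,
    TrialSet,
)
from .features import FeatureConfig, FeatureSeries
from .measurement import MeasurementModel
from .statespace import StateSpaceModel

_REL_TOL = 1e-6


def _check_uniform_time(time: np.ndarray, path) -> float:
    """Validate a strictly increasing, uniform time column; return the step."""
    dt = np.diff(time)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2  # +1 for header, +1 for 0-base
        raise FormatError(f"{path}: time not strictly increasing at row {row}")
    step = float(np.median(dt))
    bad = np.abs(dt - step) > _REL_TOL * step
    if np.any(bad):
        row = int(np.argmax(bad)) + 2
        raise FormatError(f"{path}: non-uniform sampling at row {row}")
    return step


def read_emg(path, fs: float | None = None) -> EmgRecording:
    """Read a 17-column sEMG CSV (time + 16 channels).

    If ``fs`` is given it must agree with the file's time column within the
    uniformity tolerance; otherwise the rate is inferred from the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 1 + N_CHANNELS:
        raise FormatError(
            f"{path}: expected {1 + N_CHANNELS} columns (time + {N_CHANNELS} channels), "
            f"got {df.shape[1]}"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2
        raise FormatError(f"{path}: missing value at row {row}")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    step = _check_uniform_time(time, path)
    fs_file = 1.0 / step
    if fs is not None and abs(fs_file - fs) > _REL_TOL * fs:
        raise FormatError(
            f"{path}: file sampling rate {fs_file:.6g} Hz does not match requested {fs} Hz"
        )
    return EmgRecording(
        samples=df.iloc[:, 1:].to_numpy(dtype=float),
        fs=fs_file,
        channel_labels=tuple(df.columns[1:]),
        t0=float(time[0]),
    )


def write_emg(recording: EmgRecording, path) -> None:
    df = pd.DataFrame(recording.samples, columns=list(recording.channel_labels))
    df.insert(0, "time_s", recording.times())
    df.to_csv(path, index=False)


def read_markers(path) -> MarkerTrajectory:
    """Read a 31-column marker CSV (time + 30 coordinates, mm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 1 + N_COORDS:
        raise FormatError(
            f"{path}: expected {1 + N_COORDS} columns (time + {N_COORDS} coordinates), "
            f"got {df.shape[1]}"
        )
    if df.isna().any().any():
        mask = df.isna()
        row = int(mask.any(axis=1).idxmax())
        col = mask.columns[int(np.argmax(mask.iloc[row].to_numpy()))]
        raise FormatError(f"{path}: missing value at row {row + 2}, column {col!r}")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    step = _check_uniform_time(time, path)
    return MarkerTrajectory(
        positions=df.iloc[:, 1:].to_numpy(dtype=float),
        frame_rate=1.0 / step,
        t0=float(time[0]),
    )


def write_markers(traj: MarkerTrajectory, path) -> None:
    df = pd.DataFrame(traj.positions, columns=list(MARKER_COLUMNS))
    df.insert(0, "time_s", traj.times())
    df.to_csv(path, index=False)


def write_features(series: FeatureSeries, path, labels=None) -> None:
    """Write a feature series (time + 16 feature columns) with a JSON sidecar."""
    labels = list(labels) if labels else [f"ch{i + 1:02d}" for i in range(series.values.shape[1])]
    df = pd.DataFrame(series.values, columns=labels)
    df.insert(0, "time_s", series.t0 + np.arange(series.n_frames) / series.frame_rate)
    df.to_csv(path, index=False)
    if series.config is not None:
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        cfg = series.config
        sidecar.write_text(
            json.dumps(
                {
                    "feature_type": cfg.feature_type,
                    "wamp_threshold": cfg.wamp_threshold,
                    "window_ms": cfg.window_ms,
                    "delay_ms": cfg.delay_ms,
                    "band": list(cfg.band),
                    "filter_order": cfg.filter_order,
                },
                indent=2,
            )
        )


# -- trial manifest --------------------------------------------------------


def write_manifest(path, subject_id, trials, fs=2048.0, frame_rate=100.0) -> None:
    """Write a YAML manifest mapping (instruction, repetition) to files.

    ``trials`` maps ``(i, r)`` to ``(emg_path, marker_path)``; paths are
    stored relative to the manifest's directory when possible.
    """
    root = Path(path).parent
    entries = []
    for (i, r), (emg_path, marker_path) in sorted(trials.items()):
        def rel(p):
            try:
                return str(Path(p).relative_to(root))
            except ValueError:
                return str(p)

        entries.append(
            {
                "instruction": int(i),
                "repetition": int(r),
                "emg": rel(emg_path),
                "markers": rel(marker_path),
            }
        )
    doc = {
        "subject": str(subject_id),
        "emg_fs_hz": float(fs),
        "marker_rate_hz": float(frame_rate),
        "trials": entries,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_trialset(manifest_path) -> TrialSet:
    """Load every trial referenced by a manifest into a :class:`TrialSet`."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    root = manifest_path.parent
    trials = {}
    for entry in doc["trials"]:
        i, r = int(entry["instruction"]), int(entry["repetition"])
        emg = read_emg(root / entry["emg"], fs=doc.get("emg_fs_hz"))
        markers = read_markers(root / entry["markers"])
        trials[(i, r)] = (emg, markers)
    return TrialSet(trials=trials, subject_id=str(doc.get("subject", "anonymous")))


# -- model archive ---------------------------------------------------------


@dataclass
class ModelArchive:
    """Fitted measurement + state-space model with provenance metadata."""

    measurement_model: MeasurementModel
    state_space: StateSpaceModel
    feature_config: FeatureConfig | None = None
    metadata: dict = None

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = {}
        self.validate()

    def validate(self) -> None:
        if self.measurement_model.D != self.state_space.D:
            raise ArchiveError(
                f"inconsistent latent dimension: measurement D={self.measurement_model.D}, "
                f"state space D={self.state_space.D}"
            )


def save_model(archive: ModelArchive, path) -> None:
    """Serialise a model archive to a single ``.npz`` file."""
    archive.validate()
    arrays = {}
    for k, v in archive.measurement_model.to_arrays().items():
        arrays[f"mm_{k}"] = v
    for k, v in archive.state_space.to_arrays().items():
        arrays[f"ss_{k}"] = v
    meta = dict(archive.metadata)
    if archive.feature_config is not None:
        cfg = archive.feature_config
        meta["feature_config"] = {
            "feature_type": cfg.feature_type,
            "wamp_threshold": cfg.wamp_threshold,
            "window_ms": cfg.window_ms,
            "delay_ms": cfg.delay_ms,
            "band": list(cfg.band),
            "filter_order": cfg.filter_order,
        }
    arrays["metadata_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> ModelArchive:
    """Load a model archive, verifying completeness and consistency."""
    try:
        with open(path, "rb") as fh:
            with np.load(fh) as data:
                arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, OSError, ValueError, EOFError) as exc:
        raise ArchiveError(f"{path}: corrupt or truncated model archive: {exc}")
    try:
        mm_arrays = {
            k[3:]: arrays[k] for k in arrays if k.startswith("mm_")
        }
        ss_arrays = {
            k[3:]: arrays[k] for k in arrays if k.startswith("ss_")
        }
        mm = MeasurementModel.from_arrays(mm_arrays)
        ssm = StateSpaceModel.from_arrays(ss_arrays)
        meta = json.loads(bytes(arrays["metadata_json"]).decode("utf-8"))
    except (KeyError, IndexError) as exc:
        raise ArchiveError(f"{path}: missing array in model archive: {exc}")
    fc = None
    if "feature_config" in meta:
        d = meta.pop("feature_config")
        fc = FeatureConfig(
            feature_type=d["feature_type"],
            wamp_threshold=d["wamp_threshold"],
            window_ms=d["window_ms"],
            delay_ms=d["delay_ms"],
            band=tuple(d["band"]),
            filter_order=d["filter_order"],
        )
    return ModelArchive(
        measurement_model=mm, state_space=ssm, feature_config=fc, metadata=meta
    )
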