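"""Domain types, validation and file I/O for multi-device IMU sessions.

A session is a set of 2-5 body-worn monitoring devices, each recording a
3-axis accelerometer (units: g) and a 3-axis gyroscope (units: deg/s) at a
nominal 59.5 Hz.  Channels are expressed in the device frame in which the
x-axis carries the gravity component when the limb is vertical and the
z-axis points away from the body (dorsal mounting).

Two on-disk dialects are supported:

* CSV — one file per device, header ``t,ax,ay,az,gx,gy,gz``, one sample per
  row, with optional ``# device_id:`` / ``# sample_rate_hz:`` comment lines
  before the header.  Extra magnetometer columns (``mx,my,mz``) are
  tolerated and discarded.
* HDF5 — one group per device under ``/devices/<device_id>`` holding an
  ``acc`` (N x 3) and a ``gyro`` (N x 3) dataset, with a ``sample_rate_hz``
  group attribute.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "AlgorithmParams",
    "DeviceRecording",
    "SessionBundle",
    "ValidationError",
    "ParameterError",
    "read_recording",
    "write_recording",
    "read_session_dir",
    "validate_session",
]

#: Nominal sampling frequency of the monitoring devices, in Hz.
DEFAULT_SAMPLE_RATE = 59.5

_CSV_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
_MAG_COLUMNS = ("mx", "my", "mz")


class ValidationError(ValueError):
    """A recording or session violates a structural invariant."""


class ParameterError(ValueError):
    """An algorithm parameter is outside its admissible range."""


@dataclass(frozen=True)
class AlgorithmParams:
    """Handcrafted thresholds of the placement identification algorithm.

    Attributes
    ----------
    gravity_region_threshold
        Half-width of the central region of the low-pass-filtered x-axis
        acceleration, in g.  Values in ``(-thr, thr)`` are region 0.
    walking_energy_threshold
        Gyroscope magnitude, in deg/s, above which a sample counts toward
        the walking-energy average GEn.
    vertical_acc_threshold
        |ax| threshold, in g, above which the limb is taken as vertical
        for the z-gyroscope extension/flexion feature.
    extension_energy_threshold
        z-gyroscope magnitude, in deg/s, above which samples enter the
        GyroPos / GyroNeg averages.
    correlation_gate_threshold
        |gy| gate, in deg/s, for the x-y gyroscope product feature Cxy.
    gravity_lowpass_cutoff
        Cutoff, in Hz, of the low-pass filter isolating gravity in ax.
    min_duration
        Minimum session duration in seconds for the validation gate.
    enforce_min_duration
        When False the duration gate is skipped (short test signals).
    """

    gravity_region_threshold: float = 0.25
    walking_energy_threshold: float = 70.0
    vertical_acc_threshold: float = 0.7
    extension_energy_threshold: float = 100.0
    correlation_gate_threshold: float = 20.0
    gravity_lowpass_cutoff: float = 0.5
    min_duration: float = 7200.0
    enforce_min_duration: bool = True

    def __post_init__(self) -> None:
        for name in (
            "gravity_region_threshold",
            "walking_energy_threshold",
            "vertical_acc_threshold",
            "extension_energy_threshold",
            "correlation_gate_threshold",
            "gravity_lowpass_cutoff",
            "min_duration",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")

    def with_overrides(self, **kwargs) -> "AlgorithmParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DeviceRecording:
    """One device's time-synchronised accelerometer + gyroscope channels.

    ``acc`` is an (N, 3) array in g, ``gyro`` an (N, 3) array in deg/s,
    both in the dorsal device frame.  Uniform sampling at ``sample_rate``
    Hz is assumed; all algorithm quantities are index-based.
    """

    device_id: str
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        acc = np.asarray(self.acc, dtype=np.float64)
        gyro = np.asarray(self.gyro, dtype=np.float64)
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyro", gyro)
        if acc.ndim != 2 or acc.shape[1] != 3:
            raise ValidationError(f"acc must be (N, 3); got {acc.shape}")
        if gyro.ndim != 2 or gyro.shape[1] != 3:
            raise ValidationError(f"gyro must be (N, 3); got {gyro.shape}")
        if acc.shape[0] != gyro.shape[0]:
            raise ValidationError(
                f"acc and gyro lengths differ: {acc.shape[0]} != {gyro.shape[0]}"
            )
        if acc.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        if not np.isfinite(acc).all():
            raise ValidationError("non-finite accelerometer sample")
        if not np.isfinite(gyro).all():
            raise ValidationError("non-finite gyroscope sample")

    @property
    def n_samples(self) -> int:
        return int(self.acc.shape[0])

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeviceRecording):
            return NotImplemented
        return (
            self.device_id == other.device_id
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.acc, other.acc)
            and np.array_equal(self.gyro, other.gyro)
        )


@dataclass(frozen=True)
class SessionBundle:
    """An ordered collection of 2-5 device recordings from one session."""

    recordings: tuple[DeviceRecording, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "recordings", tuple(self.recordings))
        ids = [r.device_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate device ids in session: {ids}")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_dialect(path: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "hdf5"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    ext = os.path.splitext(str(path))[1].lower()
    return "hdf5" if ext in (".h5", ".hdf5", ".hdf") else "csv"


def read_recording(
    path: str,
    dialect: str | None = None,
    device_id: str | None = None,
    sample_rate: float | None = None,
) -> DeviceRecording:
    """Read a single-device recording from a CSV or HDF5 file.

    ``device_id`` defaults to the value stored in the file, or the file
    name stem for CSV files without one.  ``sample_rate`` likewise
    defaults to the stored value, falling back to 59.5 Hz.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        return _read_csv(path, device_id, sample_rate)
    return _read_hdf5(path, device_id, sample_rate)


def _read_csv(
    path: str, device_id: str | None, sample_rate: float | None
) -> DeviceRecording:
    file_device = None
    file_rate = None
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            key = key.strip().lower()
            if key == "device_id":
                file_device = value.strip()
            elif key == "sample_rate_hz":
                file_rate = float(value)
    try:
        df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface parse location
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in _CSV_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"{path}: non-numeric values in column {col!r}")
        bad = ~np.isfinite(df[col].to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path}: non-finite value in column {col!r} at data row {row}"
            )
    t = df["t"].to_numpy()
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValidationError(f"{path}: time column is not strictly increasing")
    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return DeviceRecording(
        device_id=device_id or file_device or stem,
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        sample_rate=sample_rate or file_rate or DEFAULT_SAMPLE_RATE,
    )


def _read_hdf5(
    path: str, device_id: str | None, sample_rate: float | None
) -> DeviceRecording:
    with h5py.File(path, "r") as fh:
        if "devices" not in fh:
            raise ValidationError(f"{path}: missing /devices group")
        names = sorted(fh["devices"].keys())
        if device_id is None:
            if len(names) != 1:
                raise ValidationError(
                    f"{path}: holds {len(names)} devices; pass device_id"
                )
            device_id = names[0]
        elif device_id not in names:
            raise ValidationError(f"{path}: no device {device_id!r}")
        grp = fh["devices"][device_id]
        acc = np.asarray(grp["acc"], dtype=np.float64)
        gyro = np.asarray(grp["gyro"], dtype=np.float64)
        rate = sample_rate or float(grp.attrs.get("sample_rate_hz", DEFAULT_SAMPLE_RATE))
    return DeviceRecording(device_id=device_id, acc=acc, gyro=gyro, sample_rate=rate)


def write_recording(rec: DeviceRecording, path: str, dialect: str | None = None) -> str:
    """Write a recording to ``path``; returns the path.

    The HDF5 dialect round-trips bit-exactly; the CSV dialect writes the
    shortest decimal representation that parses back to the same float64,
    so a read-after-write reproduces every sample exactly as well.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        t = np.arange(rec.n_samples) / rec.sample_rate
        df = pd.DataFrame(
            np.column_stack([t, rec.acc, rec.gyro]), columns=list(_CSV_COLUMNS)
        )
        buf = io.StringIO()
        buf.write(f"# device_id: {rec.device_id}\n")
        buf.write(f"# sample_rate_hz: {rec.sample_rate!r}\n")
        df.to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    else:
        mode = "a" if os.path.exists(str(path)) else "w"
        with h5py.File(path, mode) as fh:
            dev = fh.require_group("devices")
            if rec.device_id in dev:
                del dev[rec.device_id]
            grp = dev.create_group(rec.device_id)
            grp.create_dataset("acc", data=rec.acc)
            grp.create_dataset("gyro", data=rec.gyro)
            grp.attrs["sample_rate_hz"] = rec.sample_rate
    return str(path)


def read_session_dir(directory: str, pattern_exts=(".csv", ".h5", ".hdf5")) -> SessionBundle:
    """Read every recording file in a directory into a session bundle."""
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if os.path.splitext(f)[1].lower() in pattern_exts
        and not f.startswith(".")
    )
    recs = [read_recording(p) for p in paths]
    return SessionBundle(recordings=tuple(recs), metadata={"source": str(directory)})


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_session(
    bundle: SessionBundle, params: AlgorithmParams | None = None
) -> list[str]:
    """Return a list of named violations; empty when the session is usable.

    Checks the supported device count (2-5), channel integrity of each
    recording, and — when ``params.enforce_min_duration`` — that every
    recording lasts at least ``params.min_duration`` seconds.  Pure
    function: diagnostics only, never raises, never mutates.
    """
    params = params or AlgorithmParams()
    issues: list[str] = []
    n = len(bundle.recordings)
    if n < 2:
        issues.append("too_few_devices")
    elif n > 5:
        issues.append("too_many_devices")
    for rec in bundle.recordings:
        # DeviceRecording construction already guarantees finiteness and
        # equal channel lengths; only the duration gate can fail here.
        if params.enforce_min_duration and rec.duration < params.min_duration:
            issues.append(f"below_min_duration:{rec.device_id}")
    return issues
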