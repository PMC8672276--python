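"""Synthetic multi-device IMU sessions with known ground-truth placements.

The generator is signature-faithful rather than biomechanically faithful:
each channel is synthesised directly from parametrised waveforms (slow
forearm-rotation cosines, asymmetric gait half-waves, noise) chosen so
that a clean session reproduces exactly the motion signatures the
placement rules exploit:

* wrists flip the gravity-carrying x-acceleration during walking bouts
  (orientation changes) and swing with correlated x/y angular velocity,
  the product positive on the left and negative on the right;
* shanks rotate fast about z during walking with extension peaks above
  +100 deg/s stronger than flexion on the left (mirrored on the right),
  and carry the highest walking gyroscope energy;
* the waist moves little, with brief turning bursts that keep its walking
  energy defined but well below the shanks'.

Right-side devices are exact mirrors of left-side ones: same seed, with
the x-gyroscope (wrist) or z-gyroscope (shank) negated — so the
classifier's left/right symmetry is directly testable.

Impairment knobs emulate the documented failure modes: ``arm_swing_scale``
shrinks wrist excursions (rigidity/bradykinesia — at 0 the wrist produces
no orientation changes at all), ``tremor_amplitude`` adds a 5 Hz
rest-tremor-band oscillation to limb gyroscopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classifier import BD, LH, LL, RH, RL, SHANK, WRIST, identify_placements
from .signal_model import (
    DEFAULT_SAMPLE_RATE,
    AlgorithmParams,
    DeviceRecording,
    SessionBundle,
)

__all__ = [
    "Impairment",
    "ActivitySchedule",
    "SimulatedSession",
    "RecoveryResult",
    "default_schedule",
    "simulate_device",
    "simulate_session",
    "recovery_study",
    "write_session",
    "CONFIG_POSITIONS",
    "CONFIG_LABELS",
]

_ACTIVITIES = ("walk", "sit", "lie", "still")

#: Anatomical positions realised for each supported configuration.
CONFIG_POSITIONS = {
    "two": (LH, LL),
    "three": (LH, LL, BD),
    "four": (LH, RH, LL, RL),
    "five": (LH, RH, LL, RL, BD),
}

#: Ground-truth labels in the classifier's output space (two- and
#: three-device layouts are side-agnostic).
CONFIG_LABELS = {
    "two": {LH: WRIST, LL: SHANK},
    "three": {LH: WRIST, LL: SHANK, BD: BD},
    "four": {LH: LH, RH: RH, LL: LL, RL: RL},
    "five": {LH: LH, RH: RH, LL: LL, RL: RL, BD: BD},
}

# Waveform constants (deg/s, g, Hz).  Chosen for robust separability of
# the feature signatures, not population realism.
_GAIT_HZ = 1.0            # stride cycle
_FLIP_HZ = 0.05           # forearm full-rotation rate during walking
_WRIST_GX = 60.0          # arm-swing x-gyro amplitude
_WRIST_GY = 50.0          # arm-swing y-gyro amplitude
_WRIST_GZ = 20.0
_SHANK_EXT = 240.0        # knee-extension z-gyro peak
_SHANK_FLEX = 160.0       # knee-flexion z-gyro peak (magnitude)
_SHANK_GXY = 28.0
_WAIST_SWAY = 18.0
_WAIST_BURST = 85.0       # brief turning burst peak
_WAIST_BURST_S = 1.5      # burst length at the start of each walk bout
_TREMOR_HZ = 5.0          # parkinsonian rest-tremor band centre


@dataclass(frozen=True)
class Impairment:
    """Degradation parameters applied uniformly to a session.

    ``arm_swing_scale`` in [0, 1] scales all wrist excursions (1 = healthy
    swing, 0 = rigid arm); ``tremor_amplitude`` (deg/s) drives a 5 Hz
    oscillation on limb gyroscopes; the noise terms are additive Gaussian
    per channel.
    """

    arm_swing_scale: float = 1.0
    tremor_amplitude: float = 0.0
    noise_sd_acc: float = 0.01
    noise_sd_gyro: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.arm_swing_scale <= 1.0:
            raise ValueError("arm_swing_scale must be within [0, 1]")
        if self.tremor_amplitude < 0 or self.noise_sd_acc < 0 or self.noise_sd_gyro < 0:
            raise ValueError("tremor and noise amplitudes must be non-negative")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered activity segments plus session-wide impairment parameters."""

    segments: tuple[tuple[str, float], ...]
    impairment: Impairment = field(default_factory=Impairment)

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for activity, duration in self.segments:
            if activity not in _ACTIVITIES:
                raise ValueError(f"unknown activity {activity!r}")
            if not duration > 0:
                raise ValueError("segment durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def with_impairment(self, **kwargs) -> "ActivitySchedule":
        return ActivitySchedule(
            segments=self.segments, impairment=replace(self.impairment, **kwargs)
        )


def default_schedule(
    total_duration: float = 600.0, impairment: Impairment | None = None
) -> ActivitySchedule:
    """A mixed free-living schedule with ~30% walking.

    The base pattern interleaves three walking bouts with sitting, lying
    and quiet standing; durations scale linearly with ``total_duration``
    (default 10 min, a desk-scale stand-in for the 2 h wear sessions).
    """
    base = (
        ("sit", 60.0),
        ("walk", 60.0),
        ("still", 30.0),
        ("walk", 60.0),
        ("sit", 90.0),
        ("walk", 60.0),
        ("lie", 120.0),
        ("still", 60.0),
        ("sit", 60.0),
    )
    scale = total_duration / 600.0
    return ActivitySchedule(
        segments=tuple((a, d * scale) for a, d in base),
        impairment=impairment or Impairment(),
    )


@dataclass(frozen=True)
class SimulatedSession:
    """A session bundle together with its generating seed and ground truth."""

    bundle: SessionBundle
    ground_truth: dict[str, str]   # device_id -> label in classifier space
    positions: dict[str, str]      # device_id -> anatomical position
    configuration: str
    seed: int
    schedule: ActivitySchedule


# ---------------------------------------------------------------------------
# per-device synthesis
# ---------------------------------------------------------------------------


def _segment_waveforms(
    kind: str, activity: str, tau: np.ndarray, imp: Impairment
) -> np.ndarray:
    """Noise-free 6-channel block (ax, ay, az, gx, gy, gz) for one segment.

    ``kind`` is the canonical left-side device family; mirroring to the
    right side happens by axis negation afterwards.
    """
    n = tau.shape[0]
    out = np.zeros((n, 6))
    s = imp.arm_swing_scale
    gait = 2 * np.pi * _GAIT_HZ * tau
    if kind == "wrist":
        if activity == "walk":
            # slow full forearm rotations flip the gravity component
            out[:, 0] = (1.0 - s) + s * np.cos(2 * np.pi * _FLIP_HZ * tau)
            out[:, 2] = 0.1
            swing = np.sin(gait)
            out[:, 3] = _WRIST_GX * s * swing
            out[:, 4] = _WRIST_GY * s * swing
            out[:, 5] = _WRIST_GZ * s * np.sin(gait + 1.0)
        else:
            out[:, 0] = {"sit": 0.2, "lie": 0.0, "still": 1.0}[activity]
            out[:, 2] = 0.1
    elif kind == "shank":
        if activity == "walk":
            out[:, 0] = 0.95 + 0.08 * np.sin(gait + 0.7)
            swing = np.sin(gait)
            out[:, 3] = _SHANK_GXY * np.sin(gait + 0.3)
            out[:, 4] = _SHANK_GXY * np.sin(gait + 1.1)
            # extension (positive z) rotates faster than flexion
            out[:, 5] = _SHANK_EXT * np.maximum(swing, 0.0) - _SHANK_FLEX * np.maximum(
                -swing, 0.0
            )
        else:
            out[:, 0] = {"sit": 0.95, "lie": 0.15, "still": 0.95}[activity]
    elif kind == "waist":
        if activity == "walk":
            out[:, 0] = 0.98 + 0.03 * np.sin(gait)
            out[:, 3] = _WAIST_SWAY * np.sin(gait + 0.2)
            out[:, 4] = _WAIST_SWAY * np.sin(gait + 1.4)
            out[:, 5] = _WAIST_SWAY * np.sin(gait + 2.6)
            # a short turning burst keeps the waist walking-energy defined
            burst = tau < _WAIST_BURST_S
            out[burst, 4] += _WAIST_BURST * np.sin(
                np.pi * tau[burst] / _WAIST_BURST_S
            )
        else:
            out[:, 0] = {"sit": 0.98, "lie": 0.1, "still": 0.98}[activity]
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown device family {kind!r}")
    return out


_POSITION_FAMILY = {
    LH: ("wrist", None),
    RH: ("wrist", 3),   # negate gx
    LL: ("shank", None),
    RL: ("shank", 5),   # negate gz
    BD: ("waist", None),
}


def simulate_device(
    position: str,
    schedule: ActivitySchedule,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    device_id: str | None = None,
) -> DeviceRecording:
    """Synthesise one device recording for a given anatomical position.

    Right-side devices are exact mirrors of left-side ones under the same
    seed: the x-gyroscope (wrists) or z-gyroscope (shanks) of the left
    template is negated after noise injection.
    """
    if position not in _POSITION_FAMILY:
        raise ValueError(f"unknown position {position!r}; expected one of "
                         f"{sorted(_POSITION_FAMILY)}")
    kind, mirror_col = _POSITION_FAMILY[position]
    imp = schedule.impairment
    rng = np.random.default_rng(seed)
    blocks = []
    for activity, duration in schedule.segments:
        n = max(1, int(round(duration * sample_rate)))
        tau = np.arange(n) / sample_rate
        blocks.append(_segment_waveforms(kind, activity, tau, imp))
    sig = np.concatenate(blocks, axis=0)
    n_total = sig.shape[0]
    t = np.arange(n_total) / sample_rate
    if imp.tremor_amplitude > 0 and kind in ("wrist", "shank"):
        amp = imp.tremor_amplitude * (1.0 if kind == "wrist" else 0.5)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for c in range(3):
            sig[:, 3 + c] += amp * np.sin(2 * np.pi * _TREMOR_HZ * t + phases[c])
    sig[:, :3] += rng.normal(0.0, imp.noise_sd_acc, size=(n_total, 3))
    sig[:, 3:] += rng.normal(0.0, imp.noise_sd_gyro, size=(n_total, 3))
    if mirror_col is not None:
        sig[:, mirror_col] = -sig[:, mirror_col]
    return DeviceRecording(
        device_id=device_id or f"{position.lower()}-sim",
        acc=sig[:, :3],
        gyro=sig[:, 3:],
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# sessions and recovery studies
# ---------------------------------------------------------------------------


def simulate_session(
    configuration: str,
    schedule: ActivitySchedule | None = None,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> SimulatedSession:
    """Generate a full multi-device session with ground-truth labels.

    Device ids are random hex strings; the presentation order of the
    recordings is shuffled so position cannot be inferred from order.
    Bit-identical output for identical (configuration, schedule, seed).
    """
    if configuration not in CONFIG_POSITIONS:
        raise ValueError(
            f"unknown configuration {configuration!r}; "
            f"expected one of {sorted(CONFIG_POSITIONS)}"
        )
    schedule = schedule or default_schedule()
    positions = CONFIG_POSITIONS[configuration]
    ss = np.random.SeedSequence(seed)
    dev_seeds = [int(s) % (2**31) for s in ss.generate_state(len(positions))]
    rng = np.random.default_rng(ss.spawn(1)[0])
    ids = []
    while len(ids) < len(positions):
        cand = f"md-{rng.integers(0, 16**6):06x}"
        if cand not in ids:
            ids.append(cand)
    recs = [
        simulate_device(pos, schedule, sample_rate, dev_seed, device_id=dev_id)
        for pos, dev_seed, dev_id in zip(positions, dev_seeds, ids)
    ]
    order = rng.permutation(len(recs))
    recs = [recs[i] for i in order]
    label_of = CONFIG_LABELS[configuration]
    return SimulatedSession(
        bundle=SessionBundle(recordings=tuple(recs), metadata={"seed": str(seed)}),
        ground_truth={r.device_id: label_of[p] for r, p in
                      zip(recs, [positions[i] for i in order])},
        positions={r.device_id: positions[i] for r, i in zip(recs, order)},
        configuration=configuration,
        seed=seed,
        schedule=schedule,
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Per-label recovery counts over repeated simulated sessions."""

    configuration: str
    n_sessions: int
    correct: dict[str, int]
    total: dict[str, int]
    diagnostic_counts: dict[str, int]

    @property
    def per_label_accuracy(self) -> dict[str, float]:
        return {k: self.correct[k] / self.total[k] for k in self.total}

    @property
    def overall_accuracy(self) -> float:
        return sum(self.correct.values()) / sum(self.total.values())

    def table(self):
        """Accuracy table as a DataFrame (one row per label plus overall)."""
        import pandas as pd

        rows = [
            {
                "label": k,
                "correct": self.correct[k],
                "total": self.total[k],
                "accuracy": self.correct[k] / self.total[k],
            }
            for k in sorted(self.total)
        ]
        rows.append(
            {
                "label": "overall",
                "correct": sum(self.correct.values()),
                "total": sum(self.total.values()),
                "accuracy": self.overall_accuracy,
            }
        )
        return pd.DataFrame(rows)


def recovery_study(
    n_sessions: int,
    configuration: str,
    schedule: ActivitySchedule | None = None,
    seed: int = 0,
    params: AlgorithmParams | None = None,
) -> RecoveryResult:
    """Run the classifier on independent simulated sessions and score it."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be at least 1")
    schedule = schedule or default_schedule()
    params = params or AlgorithmParams(enforce_min_duration=False)
    session_seeds = [
        int(s) % (2**31)
        for s in np.random.SeedSequence(seed).generate_state(n_sessions)
    ]
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    diag_counts: dict[str, int] = {}
    for s in session_seeds:
        sess = simulate_session(configuration, schedule, seed=s)
        assignment = identify_placements(sess.bundle, params)
        for dev, truth in sess.ground_truth.items():
            total[truth] = total.get(truth, 0) + 1
            if assignment.mapping[dev] == truth:
                correct[truth] = correct.get(truth, 0) + 1
            else:
                correct.setdefault(truth, 0)
        for d in assignment.diagnostics:
            diag_counts[d.code] = diag_counts.get(d.code, 0) + 1
    return RecoveryResult(
        configuration=configuration,
        n_sessions=n_sessions,
        correct=correct,
        total=total,
        diagnostic_counts=diag_counts,
    )


def write_session(session: SimulatedSession, directory: str) -> list[str]:
    """Write a session's recordings (CSV) plus a ground-truth manifest."""
    import json
    import os

    from .signal_model import write_recording

    os.makedirs(directory, exist_ok=True)
    paths = []
    for rec in session.bundle.recordings:
        path = os.path.join(directory, f"{rec.device_id}.csv")
        write_recording(rec, path, dialect="csv")
        paths.append(path)
    manifest = {
        "configuration": session.configuration,
        "seed": session.seed,
        "ground_truth": session.ground_truth,
        "positions": session.positions,
        "segments": [list(s) for s in session.schedule.segments],
    }
    mpath = os.path.join(directory, "manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    paths.append(mpath)
    return paths
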