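"""The four per-device inertial signal features driving placement rules.

Each wearing position leaves a distinct signature in the 6-channel signal:

* ``count_orientation_changes`` — how often the gravity component of the
  x-axis acceleration flips sign (forearm rotations); large on wrists.
* ``walking_gyro_energy`` (GEn) — mean gyroscope magnitude over samples
  exceeding the walking threshold; highest on shanks, lowest on the waist.
* ``xy_gyro_correlation`` (Cxy) — gated mean product of the x- and y-axis
  angular velocities; positive on the left wrist, negative on the right
  under dorsal mounting.  This is a gated mean product, *not* a Pearson
  correlation coefficient.
* ``extension_flexion_diff`` (GyroPos, GyroNeg, GDiff) — knee extension
  rotates the shank faster than flexion, so the mean high-magnitude
  positive z-gyroscope energy exceeds the negative one on the left shank
  and vice versa on the right.

Gated means are undefined when no sample passes the gate; that state is
carried explicitly (``None`` plus a defined-ness flag) so the classifier
can branch on it instead of propagating NaNs.  All threshold comparisons
are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .signal_model import AlgorithmParams, DeviceRecording, ParameterError

__all__ = [
    "FeatureVector",
    "gravity_component",
    "region_sequence",
    "count_orientation_changes",
    "walking_gyro_energy",
    "xy_gyro_correlation",
    "vertical_gyro_z",
    "extension_flexion_diff",
    "extract_features",
    "features_table",
]

#: Butterworth order of the gravity-isolation low-pass filter.
_FILTER_ORDER = 4


@dataclass(frozen=True)
class FeatureVector:
    """Per-device feature values with explicit defined-ness.

    Undefined gated means are ``None``; ``gdiff`` is defined only when
    both ``gyro_pos`` and ``gyro_neg`` are.
    """

    device_id: str
    orientation_changes: int
    gen: float | None
    cxy: float | None
    gyro_pos: float | None
    gyro_neg: float | None
    gdiff: float | None

    @property
    def gen_defined(self) -> bool:
        return self.gen is not None

    @property
    def cxy_defined(self) -> bool:
        return self.cxy is not None

    @property
    def gdiff_defined(self) -> bool:
        return self.gdiff is not None

    def as_dict(self) -> dict:
        return {
            "device_id": self.device_id,
            "orientation_changes": self.orientation_changes,
            "gen": self.gen,
            "cxy": self.cxy,
            "gyro_pos": self.gyro_pos,
            "gyro_neg": self.gyro_neg,
            "gdiff": self.gdiff,
            "gen_defined": self.gen_defined,
            "cxy_defined": self.cxy_defined,
            "gdiff_defined": self.gdiff_defined,
        }


def gravity_component(
    acc_x: np.ndarray,
    sample_rate: float,
    cutoff: float = 0.5,
) -> np.ndarray:
    """Isolate the gravity component of the x-axis acceleration.

    A 4th-order Butterworth low-pass applied forward-backward (zero phase,
    so sign-flip positions are not shifted), with mirror padding for
    warm-up.  Signals shorter than the padding length are returned
    unfiltered: too short for the filter to settle, and in practice far
    below any plausible session length.
    """
    acc_x = np.asarray(acc_x, dtype=np.float64)
    if not cutoff < sample_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below Nyquist ({sample_rate / 2} Hz)"
        )
    b, a = butter(_FILTER_ORDER, cutoff, btype="low", fs=sample_rate)
    padlen = 3 * max(len(a), len(b))
    if acc_x.shape[0] <= padlen:
        return acc_x.copy()
    return filtfilt(b, a, acc_x, padtype="even")


def region_sequence(filtered_x: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Collapse the filtered x-acceleration into its run of gravity regions.

    Per sample: region 1 when the value is above ``threshold``, -1 when
    below ``-threshold``, 0 in between (boundary values leave region 0);
    consecutive repeats are then collapsed so the result lists only the
    distinct regions traversed, in order.
    """
    if not threshold > 0:
        raise ParameterError("threshold must be strictly positive")
    filtered_x = np.asarray(filtered_x, dtype=np.float64)
    labels = np.zeros(filtered_x.shape[0], dtype=np.int8)
    labels[filtered_x >= threshold] = 1
    labels[filtered_x <= -threshold] = -1
    if labels.size == 0:
        return labels.astype(np.int64)
    keep = np.ones(labels.size, dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return labels[keep].astype(np.int64)


def count_orientation_changes(
    acc_x: np.ndarray,
    sample_rate: float,
    params: AlgorithmParams | None = None,
) -> int:
    """Count gravity zero-crossings of the x-axis acceleration.

    The gravity component is extracted, partitioned into regions, and
    every consecutive triple of distinct regions matching [-1, 0, 1] or
    [1, 0, -1] counts as one orientation change (the limb flipped from
    gravity-aligned to anti-aligned or back).  Triples are evaluated at
    every region change, so overlapping matches all count.
    """
    params = params or AlgorithmParams()
    g = gravity_component(acc_x, sample_rate, params.gravity_lowpass_cutoff)
    regions = region_sequence(g, params.gravity_region_threshold)
    return count_region_crossings(regions)


def count_region_crossings(regions: np.ndarray) -> int:
    """Count [-1, 0, 1] and [1, 0, -1] triples in a collapsed region run."""
    regions = np.asarray(regions)
    if regions.size < 3:
        return 0
    a, b, c = regions[:-2], regions[1:-1], regions[2:]
    hits = (b == 0) & (a == -c) & (a != 0)
    return int(hits.sum())


def walking_gyro_energy(
    gyro: np.ndarray, params: AlgorithmParams | None = None
) -> float | None:
    """Mean gyroscope magnitude over samples above the walking threshold.

    The per-sample energy is the Euclidean magnitude of the angular
    velocity vector, in deg/s, so it is directly comparable with the
    70 deg/s gate; samples at or below the gate are discarded (they
    correspond to sitting or low-amplitude dyskinetic motion).  Returns
    ``None`` when no sample qualifies.
    """
    params = params or AlgorithmParams()
    gyro = np.asarray(gyro, dtype=np.float64)
    g_en = np.sqrt((gyro * gyro).sum(axis=1))
    mask = g_en > params.walking_energy_threshold
    if not mask.any():
        return None
    return float(g_en[mask].mean())


def xy_gyro_correlation(
    gyro: np.ndarray, params: AlgorithmParams | None = None
) -> float | None:
    """Gated mean product of the x- and y-axis angular velocities (Cxy).

    Averages ``gx * gy`` over the samples where ``|gy|`` exceeds the
    gate (20 deg/s by default); ``None`` when no sample qualifies.  The
    gate applies to the y axis only.
    """
    params = params or AlgorithmParams()
    gyro = np.asarray(gyro, dtype=np.float64)
    mask = np.abs(gyro[:, 1]) > params.correlation_gate_threshold
    if not mask.any():
        return None
    return float((gyro[mask, 0] * gyro[mask, 1]).mean())


def vertical_gyro_z(
    acc_x: np.ndarray,
    gyro_z: np.ndarray,
    params: AlgorithmParams | None = None,
) -> np.ndarray:
    """z-gyroscope samples taken while the limb is near-vertical (gVert).

    Keeps ``gz`` at samples where ``|ax|`` exceeds the vertical-limb
    threshold (0.7 g by default), preserving order.  Operates on the raw
    acceleration: with the limb vertical the gravity component dominates
    ``ax`` directly.
    """
    params = params or AlgorithmParams()
    acc_x = np.asarray(acc_x, dtype=np.float64)
    gyro_z = np.asarray(gyro_z, dtype=np.float64)
    if acc_x.shape[0] != gyro_z.shape[0]:
        raise ValueError("acc_x and gyro_z must have equal length")
    return gyro_z[np.abs(acc_x) > params.vertical_acc_threshold]


def extension_flexion_diff(
    acc_x: np.ndarray,
    gyro_z: np.ndarray,
    params: AlgorithmParams | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Extension/flexion asymmetry of the vertical-limb z-gyroscope.

    Over gVert: GyroPos is the mean magnitude of samples above the
    extension threshold (+100 deg/s), GyroNeg the mean magnitude of
    samples below its negative, and GDiff their difference.  GDiff is
    ``None`` unless both sides have qualifying samples.
    """
    params = params or AlgorithmParams()
    g_vert = vertical_gyro_z(acc_x, gyro_z, params)
    thr = params.extension_energy_threshold
    pos = g_vert[g_vert > thr]
    neg = g_vert[g_vert < -thr]
    gyro_pos = float(np.abs(pos).mean()) if pos.size else None
    gyro_neg = float(np.abs(neg).mean()) if neg.size else None
    gdiff = None
    if gyro_pos is not None and gyro_neg is not None:
        gdiff = gyro_pos - gyro_neg
    return gyro_pos, gyro_neg, gdiff


def extract_features(
    rec: DeviceRecording, params: AlgorithmParams | None = None
) -> FeatureVector:
    """Compute the full feature vector for one device recording."""
    params = params or AlgorithmParams()
    acc_x = rec.acc[:, 0]
    changes = count_orientation_changes(acc_x, rec.sample_rate, params)
    gen = walking_gyro_energy(rec.gyro, params)
    cxy = xy_gyro_correlation(rec.gyro, params)
    gyro_pos, gyro_neg, gdiff = extension_flexion_diff(acc_x, rec.gyro[:, 2], params)
    return FeatureVector(
        device_id=rec.device_id,
        orientation_changes=changes,
        gen=gen,
        cxy=cxy,
        gyro_pos=gyro_pos,
        gyro_neg=gyro_neg,
        gdiff=gdiff,
    )


def features_table(feature_vectors) -> "pd.DataFrame":
    """Flatten feature vectors into an audit table (one row per device)."""
    import pandas as pd

    return pd.DataFrame([fv.as_dict() for fv in feature_vectors])
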