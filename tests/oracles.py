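"""Naive per-sample loop reference implementations of every feature.

Deliberately written as plain Python loops mirroring the feature
definitions one sample at a time, with no vectorisation, so they stay
independent of the array implementations they are used to check.
"""

from __future__ import annotations

import math


def naive_region_labels(values, threshold):
    labels = []
    for v in values:
        if v >= threshold:
            labels.append(1)
        elif v <= -threshold:
            labels.append(-1)
        else:
            labels.append(0)
    return labels


def naive_collapse(labels):
    out = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def naive_region_sequence(values, threshold):
    return naive_collapse(naive_region_labels(values, threshold))


def naive_count_crossings(regions):
    count = 0
    for i in range(len(regions) - 2):
        triple = (regions[i], regions[i + 1], regions[i + 2])
        if triple == (-1, 0, 1) or triple == (1, 0, -1):
            count += 1
    return count


def naive_walking_energy(gyro_rows, threshold=70.0):
    total = 0.0
    n = 0
    for gx, gy, gz in gyro_rows:
        mag = math.sqrt(gx * gx + gy * gy + gz * gz)
        if mag > threshold:
            total += mag
            n += 1
    return total / n if n else None


def naive_cxy(gyro_rows, gate=20.0):
    total = 0.0
    n = 0
    for gx, gy, _gz in gyro_rows:
        if abs(gy) > gate:
            total += gx * gy
            n += 1
    return total / n if n else None


def naive_gvert(acc_x, gyro_z, vert_threshold=0.7):
    out = []
    for ax, gz in zip(acc_x, gyro_z):
        if ax > vert_threshold or ax < -vert_threshold:
            out.append(gz)
    return out


def naive_extension_flexion(acc_x, gyro_z, vert_threshold=0.7, ext_threshold=100.0):
    g_vert = naive_gvert(acc_x, gyro_z, vert_threshold)
    pos = [abs(v) for v in g_vert if v > ext_threshold]
    neg = [abs(v) for v in g_vert if v < -ext_threshold]
    gyro_pos = sum(pos) / len(pos) if pos else None
    gyro_neg = sum(neg) / len(neg) if neg else None
    gdiff = None
    if gyro_pos is not None and gyro_neg is not None:
        gdiff = gyro_pos - gyro_neg
    return gyro_pos, gyro_neg, gdiff
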