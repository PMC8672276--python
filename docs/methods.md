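# Methods

## Problem and scope

`wearloc` solves offline, fixed-class on-body placement identification: given
2–5 simultaneous 6-channel inertial recordings from one wear session, assign
each device to one of five predefined positions — waist (`BD`), left/right
shank (`LL`/`RL`), left/right wrist (`LH`/`RH`). Inputs are assumed to be
already expressed in the dorsal device frame (x-axis along the limb carrying
gravity when the limb is vertical, z-axis pointing away from the body);
aligning raw sensor axes to that frame is out of scope, as are activity
recognition, symptom quantification, and any position outside the five
classes. Magnetometer channels, if present in input files, are read and
discarded.

## Signal model and features

Uniform sampling at a nominal 59.5 Hz is assumed and all computations are
index-based; an explicit time column in CSV input is checked for
monotonicity only. All thresholds compare strictly (`>` / `<`).

**Gravity isolation.** The x-acceleration is low-pass filtered at 0.5 Hz.
The filter is a 4th-order Butterworth applied forward–backward
(`scipy.signal.filtfilt`, mirror padding). Processing is offline, so zero
phase costs nothing and matters: a causal filter would delay the signal and
shift the positions of sign flips. Signals shorter than the padding length
(~27 samples) are returned unfiltered — they are degenerate inputs far below
any plausible session, and refusing to filter keeps the pipeline total.

**Region partition and orientation changes.** Filtered values split into
region 0 on (−0.25, 0.25) g, region 1 above, region −1 below. Boundary
values (exactly ±0.25 g) leave region 0; the choice is measure-zero but
fixed for bit-exact reproducibility. The per-sample labels are run-length
collapsed and every consecutive triple equal to `[−1, 0, 1]` or `[1, 0, −1]`
counts once; triples are evaluated at every region change, so overlapping
matches count. A direct −1→1 jump with no intervening 0 sample matches
neither pattern and counts zero — with a 0.5 Hz low-pass at 59.5 Hz such a
jump is practically impossible, and the literal pattern rule is kept.

**Walking gyroscope energy (GEn).** The per-sample energy is the Euclidean
magnitude of the angular-velocity vector, in deg/s, so it is directly
comparable with the 70 deg/s gate; GEn is the mean over the gated samples.
(The alternative reading — a squared magnitude — would make the stated
threshold dimensionally inconsistent; only the magnitude reading keeps the
70 deg/s gate meaningful.)

**Cxy.** A gated mean product, not a Pearson correlation: mean of `ωx·ωy`
over samples with `|ωy| > 20` deg/s, with the gate on the y-axis only.

**GDiff.** Over z-gyroscope samples where `|ax| > 0.7` g (limb vertical):
GyroPos = mean magnitude of samples > +100 deg/s, GyroNeg = mean magnitude
of samples < −100 deg/s, GDiff = GyroPos − GyroNeg.

**Undefined states.** Each gated mean divides by the gated-set size, so an
empty gate makes the feature *undefined*. This is carried as an explicit
flag (`None`) rather than 0 or NaN, because "no sample exceeded the walking
threshold" is itself informative — it is the signature of the waist or of a
low-activity session — and the classifier branches on it explicitly.

## Classifier

Decisions are applied stepwise in order of feature reliability:
orientation changes select wrists; among non-wrists the lowest GEn is the
waist; wrist side comes from the Cxy sign (positive → left) and shank side
from the GDiff ordering (higher → left). The shank rule is implemented as a
pairwise comparison, not a sign test: it coincides with the sign test when
the two GDiff values straddle zero but stays decidable when they do not.
When the two wrist Cxy values do not strictly disagree in sign (both
positive, both negative, or undefined), the sign rule is undecidable; the
higher value is called left and the case is flagged (`cxy_signs_agree`,
plus `both_cxy_negative` when applicable) — both-negative Cxy is exactly
what ventral (inward-facing) mounting of a wrist device produces.

Undefined features rank below any defined value in every comparison. All
ties break deterministically in favour of the earlier device in input
order, and every fallback emits a diagnostic
(`tie_broken_by_input_order`, `zero_orientation_changes`, `gen_undefined`,
`gdiff_undefined`, `cxy_undefined`). Deterministic-plus-flagged was chosen
over randomisation deliberately: the one documented field failure of this
method class is precisely an arbitrary pick among zero-orientation-change
devices, and a reproducible pick with a visible flag makes that failure
auditable. No confidence scores beyond these boolean diagnostics are
produced; the method is purely rule-based and calibrated confidences would
exceed what the rules support.

Two- and three-device sessions cannot determine side (no second wrist for
the Cxy comparison, no second shank for GDiff), so they emit side-agnostic
labels `H?` / `L?` rather than guessing. Configuration is keyed purely on
device count; a nonconforming layout (e.g. four devices that are not
wrists+shanks) is undetectable by design.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `gravity_region_threshold` | 0.25 | g | region-0 half-width for orientation changes |
| `walking_energy_threshold` | 70 | deg/s | gate for GEn (walking vs sitting/dyskinesia) |
| `vertical_acc_threshold` | 0.7 | g | limb-vertical gate for GDiff |
| `extension_energy_threshold` | 100 | deg/s | extension/flexion gate for GyroPos/GyroNeg |
| `correlation_gate_threshold` | 20 | deg/s | \|ωy\| gate for Cxy |
| `gravity_lowpass_cutoff` | 0.5 | Hz | gravity isolation |
| `min_duration` | 7200 | s | validation gate |

The thresholds are handcrafted operating points of the shipped algorithm,
exposed for override (YAML / keyword) but not fitted here. The two-hour
minimum duration is a validation gate, not an algorithmic constant: the
mathematics runs on any length, so `enforce_min_duration=False` lets tests
and demos use short sessions. File formats (CSV with a
`t,ax,ay,az,gx,gy,gz` header; HDF5 with one group per device) are this
package's own convention — units are fixed by contract as g and deg/s,
never auto-detected.

## Simulator

The generator is *signature-faithful*, not biomechanically faithful: it
synthesises channels directly from parametrised waveforms rather than a
skeletal model, because the classifier consumes only the four features and
signature-level fidelity is the testable contract. During walking bouts:

* wrists flip the gravity component with a slow (0.05 Hz) forearm-rotation
  cosine and swing with in-phase x/y gyroscope sinusoids (60 / 50 deg/s at
  1 Hz), giving a positive gated product on the left;
* shanks rotate about z with asymmetric half-waves (+240 deg/s extension,
  −160 deg/s flexion at the 1 Hz stride rate) while `ax ≈ 0.95` g;
* the waist sways at 18 deg/s with a single 1.5 s, 85 deg/s turning burst
  per walking bout — enough to keep its GEn *defined* (≈80–90 deg/s) yet
  far below the shanks' (≈150–160 deg/s).

Sitting/lying/still segments carry only noise, with activity-appropriate
static x-acceleration levels chosen so non-wrist devices never cross the
−0.25 g region boundary (zero orientation changes off the wrists). The
default schedule is 10 minutes with 30% walking — a desk-scale stand-in for
the 2 h wear sessions the full system expects; durations scale linearly.
Additive Gaussian noise defaults to 0.01 g / 0.5 deg/s per channel.

Right-side devices are exact mirrors of left-side ones under the same seed
(x-gyroscope negated for wrists, z-gyroscope for shanks), which makes the
classifier's left/right symmetry directly and exactly testable.

Impairment knobs emulate the documented degradation modes:
`arm_swing_scale` ∈ [0, 1] scales all wrist excursions (0 reproduces the
rigidity/bradykinesia degeneracy: zero orientation changes, undefined Cxy);
`tremor_amplitude` adds a 5 Hz rest-tremor-band sinusoid (independent phase
per channel) to wrist gyroscopes and, at half amplitude, to shanks.

What passing tests on simulated sessions show — and do not show: they
verify that the implementation applies the rules correctly and that the
rules recover placements whenever the motion signatures hold with clean
margins. They do not establish clinical accuracy: real gait has variable
cadence, multi-axis cross-talk, posture transitions that graze the region
boundaries, and inter-subject variation that no waveform synthesis covers.
Simulator amplitudes were chosen for robust separability of the
signatures, not population realism — no published motion statistics exist
for these features beyond a handful of printed case values.

## Numerical choices and degenerate inputs

* CSV round-trips are exact: floats are written in shortest-repr form and
  parsed with `float_precision="round_trip"`; HDF5 stores float64 natively.
* Empty sessions, single devices, or more than five devices are rejected
  with named errors; all-zero or identical recordings classify without
  crashing and carry tie diagnostics.
* All randomness is generator-based (`numpy.random.default_rng`); identical
  (configuration, schedule, seed) triples give bit-identical sessions, and
  classification itself is deterministic.

## Known limitations

* Ventral (inward-facing) mounting flips axis signs and inverts the
  left/right rules; the method detects the both-negative-Cxy symptom but
  cannot correct the mounting.
* Side is undeterminable in two- and three-device layouts.
* The count-keyed configuration dispatch cannot notice a nonconforming
  layout.
* Thresholds are fixed operating points; no per-subject adaptation.
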