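# wearloc

Offline, rule-based identification of **where on the body** each device of a
small wearable IMU network was worn — left/right wrist, left/right shank, or
waist — from its accelerometer and gyroscope channels alone.

Body sensor networks for movement-disorder monitoring (e.g. long-term
Parkinson's disease monitoring at home) ship several physically identical
sensing units. Users, who may be cognitively or motorically impaired, attach
them without labels; the recording is only interpretable if post-processing
can recover which unit sat on which body part. `wearloc` implements a
fixed-class placement classifier for that setting, driven by four handcrafted
signal features, plus a synthetic session simulator with ground-truth
placements so the whole method is testable without clinical recordings.

## The method

Each device records 3-axis acceleration (g) and angular velocity (deg/s) at a
nominal 59.5 Hz, in a frame where the x-axis carries gravity when the limb is
vertical and the z-axis points away from the body (dorsal mounting). Four
features are extracted per device:

* **Orientation changes** — the x-acceleration is low-pass filtered at
  0.5 Hz to isolate gravity, partitioned into regions −1 / 0 / 1 at ±0.25 g,
  and every traversal matching the collapsed region pattern `[−1, 0, 1]` or
  `[1, 0, −1]` counts as one orientation change. Arms rotate far more than
  any other mounting point, so wrists dominate this count.
* **GEn** — mean gyroscope magnitude `√(ωx² + ωy² + ωz²)` over the samples
  exceeding 70 deg/s (the walking regions). Highest on shanks, lowest at the
  waist; undefined when no sample qualifies.
* **Cxy** — mean of `ωx·ωy` over samples with `|ωy| > 20` deg/s. Positive on
  the left wrist, negative on the right under dorsal mounting.
* **GDiff = GyroPos − GyroNeg** — over z-gyroscope samples taken while the
  limb is vertical (`|ax| > 0.7 g`), GyroPos is the mean magnitude of samples
  above +100 deg/s and GyroNeg the mean magnitude below −100 deg/s. Knee
  extension rotates the shank faster than flexion, so GDiff is higher on the
  left shank than the right.

The classifier is stepwise: wrists by orientation-change count, waist as the
lowest-GEn non-wrist device, wrist side by the sign of Cxy, shank side by the
GDiff ordering. Two- and three-device sessions cannot determine side and emit
the side-agnostic labels `H?` / `L?`. Every degenerate situation (ties,
undefined gated means, zero orientation changes on a wrist, agreeing Cxy
signs) is resolved deterministically by input order and reported as a named
diagnostic.

## Worked example

```python
import wearloc as w

params = w.AlgorithmParams(enforce_min_duration=False)   # short demo session
session = w.simulate_session("five", w.default_schedule(600.0), seed=3)
assignment = w.identify_placements(session.bundle, params)
print(assignment.mapping)
print(assignment.mapping == session.ground_truth, list(assignment.diagnostics))
```

prints

```
{'md-427eb1': 'BD', 'md-60f110': 'RL', 'md-a21df0': 'LH', 'md-8a9733': 'RH', 'md-21dc2e': 'LL'}
True []
```

— a simulated 10-minute five-device session whose waist (`BD`), shank
(`LL`/`RL`) and wrist (`LH`/`RH`) devices are all recovered from the signals
alone, with no degeneracy diagnostics. The same pipeline runs from the shell:

```bash
wearloc simulate --config five --seed 3 --out session/   # CSVs + manifest
wearloc identify --input session/ --no-min-duration
wearloc recovery-study --config five --n 100 --preset rigidity
```

The `rigidity` preset suppresses arm swing entirely; wrist identification
then degrades and every affected session carries the
`zero_orientation_changes` diagnostic — the algorithm's documented clinical
failure mode.

## Layout

* `src/wearloc/signal_model.py` — recording/session types, validation, CSV + HDF5 I/O
* `src/wearloc/features.py` — the four features, with explicit undefined states
* `src/wearloc/classifier.py` — the four configuration-specific procedures
* `src/wearloc/simulator.py` — signature-faithful synthetic sessions
* `src/wearloc/cli.py` — `wearloc identify | simulate | recovery-study | features`
* `docs/methods.md` — model assumptions, parameter rationale, limitations
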