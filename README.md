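# posturekit

A toolkit for IMU-based posture monitoring and joint-angle measurement.
Body-worn 9-axis sensors stream fused orientation quaternions; posturekit
turns those streams into joint angles, watches a 13-segment body model
against scenario-specific range-of-motion limits, and raises alerts when
a segment stays outside its safe range.

No hardware is required: a built-in simulator emits the same packet
dialect with configurable output rate (1–60 Hz), rotational noise, and
slow drift, so the full pipeline — including a goniometer-style sweep
validation protocol — runs end-to-end on synthetic motion.

## Features

- **Quaternion core** — exact unit-quaternion algebra, axis-angle
  construction, vector rotation, and Euler conversion under one fixed
  convention (intrinsic Z–X′–Y″, degrees, components wrapped to
  [−180, 180)) with a deterministic gimbal-lock tie-break.
- **Three joint-angle methods** over parent/child segment pairs:
  1. unsigned angle between a reference axis seen from both segments
     (dot product + arc cosine, always in [0, 180]);
  2. signed Euler angles of `inverse(parent) * child` — the default;
  3. Euler angles of the child's local rotation including its rig
     rest-pose offset.
- **Calibration** — capture a reference pose on a trigger token and
  subtract it per axis, re-zeroing slow drift.
- **Posture monitor** — 13 named segments, scenario presets 0 (none)
  through 4 (lifting) with ±30° default limits on head/chest/pelvis,
  strict-inequality flags, and sustained-violation events (default 5 s).
- **Streaming** — newline-delimited JSON packets (`wq/xq/yq/zq`
  components, `wq` the real part) and lossless CSV orientation logs.
- **Synthetic motion** — seeded, reproducible ramp-and-hold motions and
  goniometer sweeps for the wrist (ulnar/radial, flexion/extension,
  pronation/supination), knee, and elbow.
- **Validation tables** — regenerate sweep grids (0–50° in 10° steps),
  compare method outputs per axis, and report MAE, max error, within-±1°
  proportion, and range-normalized percent accuracy.

## CLI

```sh
# stream a synthetic 30-degree head pivot as JSON lines
posturekit simulate --joint head --motion pivot --target 30 --rate 60 --out stream.jsonl

# replay a CSV orientation log as a packet stream
posturekit replay log.csv

# monitor a stream against the lifting scenario; a bare "C" line in the
# stream triggers calibration (re-zeroing)
posturekit monitor stream.jsonl --scenario 4 --events-out events.csv

# run a simulated goniometer sweep and report accuracy metrics
posturekit validate --joint elbow --motion flexion --sigma 1.0 --seed 1 \
    --table-out table.csv --metrics-out metrics.json
```

## Library example

```python
from posturekit import (
    MotionProfile, method2_angles, simulate_goniometer_sweep,
)

samples = simulate_goniometer_sweep(
    "elbow", "flexion", (0, 10, 20, 30, 40, 50),
    MotionProfile(joint="elbow", motion="flexion", noise_sigma_deg=1.0, seed=1),
)
for s in samples:
    angles = method2_angles(s.parent.quaternion(), s.child.quaternion())
    print(s.target_deg, angles.y)
```

## Conventions

- Quaternions are scalar-first `(w, x, y, z)`, unit norm, canonicalized
  to `w >= 0`.
- All public angles are degrees.
- Euler order is intrinsic Z–X′–Y″ everywhere; at gimbal lock the Y
  component is set to 0 and the residual goes to Z.
- Violation flags use strict inequality (`|angle| > limit`); the wrap
  interval is half-open `[-180, 180)`.
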