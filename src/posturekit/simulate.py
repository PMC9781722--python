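"""Synthetic sensor motion: scripted segment rotations as packet streams.

Stands in for the physical 9-axis sensors, emitting already-fused
orientation packets at a configurable output rate (1-60 Hz) with optional
rotational noise and slow drift, so the whole pipeline is testable with
no hardware.

Noise model: each emitted orientation is the true orientation composed
with a small random rotation of angle ~ N(0, sigma) degrees about a
uniformly random axis.  This keeps the noise convention-independent
(it is a rotation, not per-Euler-component jitter).

Drift model: a linear bias ramp about the motion axis, in degrees per
minute, mimicking slow heading drift between re-calibrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .joints import SegmentRig
from .quaternion import AxisAngle, Quaternion, from_axis_angle, multiply
from .streaming import MotionPacket

__all__ = [
    "MotionProfile",
    "SweepSample",
    "MOTION_TYPES",
    "resolve_motion_axis",
    "script_motion",
    "simulate_goniometer_sweep",
]

MOTION_TYPES = (
    "pivot",
    "flexion",
    "extension",
    "rotation",
    "ulnar",
    "radial",
    "pronation",
    "supination",
)

_BASIS = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
)

# (axis index, sign) of the signed Euler component each exercise drives,
# keyed by (joint, motion).  Wrist deviations live on Y, wrist
# flexion/extension on X, forearm pronation/supination on Z; knee flexion
# reads negative on Z and elbow flexion positive on Y.  Head and chest
# follow pivot/flexion/rotation -> X/Y/Z; the hips swap flexion and
# rotation onto Z and Y.
_MOTION_AXIS: Dict[Tuple[str, str], Tuple[int, float]] = {
    ("wrist", "ulnar"): (1, 1.0),
    ("wrist", "radial"): (1, -1.0),
    ("wrist", "flexion"): (0, 1.0),
    ("wrist", "extension"): (0, -1.0),
    ("wrist", "pronation"): (2, 1.0),
    ("wrist", "supination"): (2, -1.0),
    ("knee", "flexion"): (2, -1.0),
    ("knee", "extension"): (2, 1.0),
    ("elbow", "flexion"): (1, 1.0),
    ("elbow", "extension"): (1, -1.0),
    ("head", "pivot"): (0, 1.0),
    ("head", "flexion"): (1, 1.0),
    ("head", "rotation"): (2, 1.0),
    ("chest", "pivot"): (0, 1.0),
    ("chest", "flexion"): (1, 1.0),
    ("chest", "rotation"): (2, 1.0),
    ("hips", "pivot"): (0, 1.0),
    ("hips", "flexion"): (2, 1.0),
    ("hips", "rotation"): (1, 1.0),
    ("pelvis", "pivot"): (0, 1.0),
    ("pelvis", "flexion"): (2, 1.0),
    ("pelvis", "rotation"): (1, 1.0),
}

_DEFAULT_AXIS: Dict[str, Tuple[int, float]] = {
    "pivot": (0, 1.0),
    "flexion": (1, 1.0),
    "extension": (1, -1.0),
    "rotation": (2, 1.0),
    "ulnar": (1, 1.0),
    "radial": (1, -1.0),
    "pronation": (2, 1.0),
    "supination": (2, -1.0),
}


def resolve_motion_axis(joint: str, motion: str) -> Tuple[int, float]:
    """Map (joint, motion type) to the driven Euler axis index and sign."""
    if motion not in MOTION_TYPES:
        raise ValueError(f"unknown motion type {motion!r}")
    return _MOTION_AXIS.get((joint, motion), _DEFAULT_AXIS[motion])


@dataclass(frozen=True)
class MotionProfile:
    """Parameters for one scripted motion of one segment or joint."""

    joint: str = "wrist"
    motion: str = "flexion"
    target_deg: float = 30.0
    ramp_s: float = 1.0
    hold_s: float = 2.0
    rate_hz: float = 60.0
    noise_sigma_deg: float = 0.0
    drift_deg_per_min: float = 0.0
    seed: int = 0
    sensor_id: str = "s1"

    def __post_init__(self) -> None:
        if not 1.0 <= self.rate_hz <= 60.0:
            raise ValueError(
                f"rate must lie in the 1-60 Hz streaming range, got {self.rate_hz}"
            )
        if self.noise_sigma_deg < 0 or self.drift_deg_per_min < 0:
            raise ValueError("noise sigma and drift rate must be non-negative")
        if self.motion not in MOTION_TYPES:
            raise ValueError(f"unknown motion type {self.motion!r}")


@dataclass(frozen=True)
class SweepSample:
    """One grid point of a goniometer-style sweep."""

    target_deg: float
    parent: MotionPacket
    child: MotionPacket


def _noise_rotation(rng: np.random.Generator, sigma_deg: float) -> Quaternion:
    """Random rotation: angle ~ N(0, sigma) degrees, uniform random axis."""
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    while norm < 1e-12:  # pragma: no cover - probability ~0
        axis = rng.normal(size=3)
        norm = np.linalg.norm(axis)
    axis = axis / norm
    angle = rng.normal(0.0, sigma_deg)
    return from_axis_angle(AxisAngle(tuple(axis), angle))


def _pose(
    axis_index: int,
    angle_deg: float,
    rng: Optional[np.random.Generator],
    sigma_deg: float,
) -> Quaternion:
    q = from_axis_angle(AxisAngle(_BASIS[axis_index], angle_deg))
    if rng is not None and sigma_deg > 0.0:
        q = multiply(q, _noise_rotation(rng, sigma_deg))
    return q


def script_motion(profile: MotionProfile) -> List[MotionPacket]:
    """Emit packets for a ramp-then-hold motion toward the target angle.

    Deterministic given the profile's seed.  During the hold phase the
    noiseless orientation is exactly the target rotation about the
    motion's axis; drift adds ``drift_deg_per_min * t / 60`` on that axis.
    """
    axis_index, sign = resolve_motion_axis(profile.joint, profile.motion)
    rng = np.random.default_rng(profile.seed)
    period = 1.0 / profile.rate_hz
    n_samples = int(round((profile.ramp_s + profile.hold_s) * profile.rate_hz)) + 1
    packets = []
    for i in range(n_samples):
        t = i * period
        if profile.ramp_s > 0.0:
            progress = min(t / profile.ramp_s, 1.0)
        else:
            progress = 1.0
        angle = sign * profile.target_deg * progress
        angle += sign * profile.drift_deg_per_min * (t / 60.0)
        q = _pose(axis_index, angle, rng, profile.noise_sigma_deg)
        packets.append(MotionPacket.from_quaternion(profile.sensor_id, t, q))
    return packets


def simulate_goniometer_sweep(
    joint: str,
    motion: str,
    grid: Sequence[float],
    profile: Optional[MotionProfile] = None,
    rig: Optional[SegmentRig] = None,
) -> List[SweepSample]:
    """One steady parent/child packet pair per grid target angle.

    The parent is held at its rig rest orientation (the goniometer arm on
    the table); the child rotates away from it by the target angle about
    the motion's axis.  Noise, if configured, lands on the child sensor.
    """
    if profile is None:
        profile = MotionProfile(joint=joint, motion=motion)
    for target in grid:
        if not -180.0 <= target < 180.0:
            raise ValueError(f"grid target {target} outside [-180, 180)")
    axis_index, sign = resolve_motion_axis(joint, motion)
    rig = rig if rig is not None else SegmentRig()
    rng = np.random.default_rng(profile.seed)
    hold = max(profile.hold_s, 1.0 / profile.rate_hz)
    samples = []
    for row, target in enumerate(grid):
        t = row * hold
        parent_q = rig.parent_rest
        child_q = multiply(
            parent_q, from_axis_angle(AxisAngle(_BASIS[axis_index], sign * target))
        )
        if profile.noise_sigma_deg > 0.0:
            child_q = multiply(child_q, _noise_rotation(rng, profile.noise_sigma_deg))
        samples.append(
            SweepSample(
                target_deg=float(target),
                parent=MotionPacket.from_quaternion("parent", t, parent_q),
                child=MotionPacket.from_quaternion("child", t, child_q),
            )
        )
    return samples
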