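"""Three joint-angle measurement methods over parent/child orientation pairs.

Method 1: rotate a shared reference axis by each segment's orientation and
take the arc cosine of the dot product of the two rotated vectors — an
unsigned angle in [0, 180].  It is computed per basis axis to fill the
X/Y/Z columns of a validation table.

Method 2: the Euler decomposition of ``inverse(parent) * child`` — a signed
triple, and the framework's default method.

Method 3: the Euler decomposition of the child's *local* rotation including
its rig rest-pose offset, so joints whose segments are rigged away from the
world frame report non-zero baselines even at anatomical zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .quaternion import (
    EulerTriple,
    Quaternion,
    from_euler,
    multiply,
    relative,
    rotate_vector,
    to_euler,
)
from .streaming import MotionPacket

__all__ = [
    "SegmentRig",
    "JointMeasurement",
    "method1_angle",
    "method1_triple",
    "method2_angles",
    "method3_angles",
    "measure_joint",
    "BASIS_AXES",
]

#: Reference axes for Method 1, one per output column.
BASIS_AXES: Tuple[Tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
)

#: Maximum timestamp skew accepted when pairing packets, as a fraction of
#: the sample period.
PAIRING_TOLERANCE_FRACTION = 0.5


@dataclass(frozen=True)
class SegmentRig:
    """Rest-pose configuration of a parent/child segment pair."""

    parent_rest: Quaternion = field(default_factory=Quaternion.identity)
    child_rest: Quaternion = field(default_factory=Quaternion.identity)
    rest_offset: EulerTriple = EulerTriple(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class JointMeasurement:
    """One joint-angle reading: which joint, which method, and the angles."""

    joint: str
    method: int
    angles: EulerTriple
    timestamp: float

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3):
            raise ValueError(f"method must be 1, 2 or 3, got {self.method}")


def method1_angle(
    parent: Quaternion, child: Quaternion, ref_axis: Sequence[float]
) -> float:
    """Unsigned angle between a reference axis seen from both segments.

    The dot product is clamped to [-1, 1] before the arc cosine, so the
    result is always a finite angle in [0, 180] degrees.
    """
    axis = np.asarray(ref_axis, dtype=float)
    norm = float(np.linalg.norm(axis))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"reference axis must be unit length (|axis| = {norm:.12g})")
    vp = rotate_vector(parent, axis)
    vc = rotate_vector(child, axis)
    dot = max(-1.0, min(1.0, float(np.dot(vp, vc))))
    return math.degrees(math.acos(dot))


def method1_triple(parent: Quaternion, child: Quaternion) -> Tuple[float, float, float]:
    """Method 1 evaluated on each of the three basis axes (X/Y/Z columns)."""
    return tuple(method1_angle(parent, child, axis) for axis in BASIS_AXES)


def method2_angles(parent: Quaternion, child: Quaternion) -> EulerTriple:
    """Signed Euler angles of the child relative to the parent."""
    return to_euler(relative(parent, child))


def method3_angles(rig: SegmentRig, joint_motion: Quaternion) -> EulerTriple:
    """Euler angles of the child's stored local rotation.

    The rig rest-pose offset composes with the joint motion, which is why
    a joint rigged at, say, (-80, 0, 0) reports that triple at zero motion.
    """
    local = multiply(from_euler(rig.rest_offset), joint_motion)
    return to_euler(local)


def measure_joint(
    joint: str,
    parent_packet: MotionPacket,
    child_packet: MotionPacket,
    method: int,
    rig: SegmentRig | None = None,
    *,
    rate_hz: float = 60.0,
) -> JointMeasurement:
    """Pair two packets and dispatch to the selected measurement method.

    Packets must share a timestamp to within half a sample period at the
    configured output rate; larger skew is rejected.
    """
    if method not in (1, 2, 3):
        raise ValueError(f"method must be 1, 2 or 3, got {method}")
    tolerance = PAIRING_TOLERANCE_FRACTION / rate_hz
    skew = abs(parent_packet.timestamp - child_packet.timestamp)
    if skew > tolerance:
        raise ValueError(
            f"packet timestamps differ by {skew:.6g} s, "
            f"beyond the pairing tolerance of {tolerance:.6g} s"
        )
    parent = parent_packet.quaternion()
    child = child_packet.quaternion()
    if method == 1:
        angles = EulerTriple(*method1_triple(parent, child))
    elif method == 2:
        angles = method2_angles(parent, child)
    else:
        rig = rig if rig is not None else SegmentRig()
        angles = method3_angles(rig, relative(parent, child))
    return JointMeasurement(
        joint=joint, method=method, angles=angles, timestamp=child_packet.timestamp
    )
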