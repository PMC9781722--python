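"""Unit-quaternion algebra with degree-based Euler conversion.

Conventions used throughout the package:

* Quaternions are scalar-first ``(w, x, y, z)`` and kept at unit norm.
  ``q`` and ``-q`` encode the same rotation; public constructors and
  operations canonicalize to ``w >= 0`` so results are deterministic.
* Euler triples are intrinsic Z-X'-Y'' decompositions in degrees, each
  component wrapped to ``[-180, 180)``.  This one fixed order is the
  convention for every angle the package reports.
* All public angles are degrees; radians appear only inside functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "Quaternion",
    "AxisAngle",
    "EulerTriple",
    "wrap_degrees",
    "from_axis_angle",
    "multiply",
    "inverse",
    "rotate_vector",
    "to_euler",
    "from_euler",
    "relative",
    "to_matrix",
]

_UNIT_TOL = 1e-6
_AXIS_TOL = 1e-9
_GIMBAL_TOL = 1e-9


def wrap_degrees(angle: float) -> float:
    """Wrap a finite angle in degrees into the half-open interval [-180, 180)."""
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle!r}")
    wrapped = math.fmod(angle + 180.0, 360.0)
    if wrapped < 0.0:
        wrapped += 360.0
    return wrapped - 180.0


@dataclass(frozen=True)
class EulerTriple:
    """Intrinsic Z-X'-Y'' Euler angles in degrees, wrapped to [-180, 180)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", wrap_degrees(float(self.x)))
        object.__setattr__(self, "y", wrap_degrees(float(self.y)))
        object.__setattr__(self, "z", wrap_degrees(float(self.z)))

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass(frozen=True)
class AxisAngle:
    """A rotation of ``theta`` degrees about a unit ``axis``."""

    axis: Tuple[float, float, float]
    theta: float

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        norm = float(np.linalg.norm(ax))
        if abs(norm - 1.0) > _AXIS_TOL:
            raise ValueError(f"axis must be unit length (|axis| = {norm:.12g})")
        if not math.isfinite(float(self.theta)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "axis", (float(ax[0]), float(ax[1]), float(ax[2])))
        object.__setattr__(self, "theta", float(self.theta))


@dataclass(frozen=True)
class Quaternion:
    """A unit rotation quaternion, scalar component first.

    The component names mirror the streaming packet fields ``wq/xq/yq/zq``:
    ``w`` is the real part, ``x/y/z`` the imaginary parts.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        comps = np.array([self.w, self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(comps)):
            raise ValueError("quaternion components must be finite")
        norm = float(np.linalg.norm(comps))
        if norm < _UNIT_TOL:
            raise ValueError("zero quaternion does not represent a rotation")
        if abs(norm - 1.0) > _UNIT_TOL:
            comps = comps / norm
        if comps[0] < 0.0:
            comps = -comps
        object.__setattr__(self, "w", float(comps[0]))
        object.__setattr__(self, "x", float(comps[1]))
        object.__setattr__(self, "y", float(comps[2]))
        object.__setattr__(self, "z", float(comps[3]))

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))


IDENTITY = Quaternion.identity()


def from_axis_angle(aa: AxisAngle) -> Quaternion:
    """Build the quaternion cos(theta/2) + sin(theta/2)*(ux i + uy j + uz k)."""
    half = math.radians(aa.theta) / 2.0
    s = math.sin(half)
    return Quaternion(
        math.cos(half), aa.axis[0] * s, aa.axis[1] * s, aa.axis[2] * s
    )


def multiply(a: Quaternion, b: Quaternion) -> Quaternion:
    """Hamilton product ``a * b``: the rotation "apply b, then a"."""
    w = a.w * b.w - a.x * b.x - a.y * b.y - a.z * b.z
    x = a.w * b.x + a.x * b.w + a.y * b.z - a.z * b.y
    y = a.w * b.y - a.x * b.z + a.y * b.w + a.z * b.x
    z = a.w * b.z + a.x * b.y - a.y * b.x + a.z * b.w
    return Quaternion(w, x, y, z)


def inverse(q: Quaternion) -> Quaternion:
    """Inverse of a unit quaternion (its conjugate)."""
    return Quaternion(q.w, -q.x, -q.y, -q.z)


def relative(parent: Quaternion, child: Quaternion) -> Quaternion:
    """Relative rotation taking the parent frame to the child frame.

    ``inverse(parent) * child``: the joint rotation expressed in the
    parent's frame, invariant under any common world-frame rotation.
    """
    return multiply(inverse(parent), child)


def to_matrix(q: Quaternion) -> np.ndarray:
    """The 3x3 rotation matrix acting on column vectors."""
    w, x, y, z = q.w, q.x, q.y, q.z
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate_vector(q: Quaternion, v: Iterable[float]) -> np.ndarray:
    """Rotate a 3-vector by the quaternion (norm-preserving)."""
    vec = np.asarray(v, dtype=float)
    if vec.shape != (3,):
        raise ValueError("v must be a 3-vector")
    # q v q* expanded via the cross-product form; cheaper than the matrix.
    u = np.array([q.x, q.y, q.z])
    t = 2.0 * np.cross(u, vec)
    return vec + q.w * t + np.cross(u, t)


def _clamp(value: float) -> float:
    return max(-1.0, min(1.0, value))


def to_euler(q: Quaternion) -> EulerTriple:
    """Decompose a rotation into intrinsic Z-X'-Y'' angles in degrees.

    At gimbal lock (|x| -> 90 deg) the y component is set to 0 and the
    residual rotation is carried entirely by the z component, which makes
    the decomposition deterministic even though one degree of freedom
    is lost.
    """
    m = to_matrix(q)
    sx = _clamp(m[2, 1])
    x = math.asin(sx)
    if abs(sx) < 1.0 - _GIMBAL_TOL:
        y = math.atan2(-m[2, 0], m[2, 2])
        z = math.atan2(-m[0, 1], m[1, 1])
    else:
        y = 0.0
        z = math.atan2(m[1, 0], m[0, 0])
    return EulerTriple(math.degrees(x), math.degrees(y), math.degrees(z))


def from_euler(e: EulerTriple) -> Quaternion:
    """Compose intrinsic Z-X'-Y'' angles back into a quaternion."""
    qz = from_axis_angle(AxisAngle((0.0, 0.0, 1.0), e.z))
    qx = from_axis_angle(AxisAngle((1.0, 0.0, 0.0), e.x))
    qy = from_axis_angle(AxisAngle((0.0, 1.0, 0.0), e.y))
    return multiply(multiply(qz, qx), qy)
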