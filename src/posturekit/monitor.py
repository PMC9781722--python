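"""13-segment body model, scenario range-of-motion limits, violation events.

The body model mirrors the original array-of-structs layout: each of the
13 segments holds a quaternion plus Euler triples for rotation,
correction, and positional control, a sensor id, and a name.  Scenario
presets (0 = none through 4 = lifting) monitor the head, chest, and
pelvis with a default +/-30 degree safe range per axis; a flag is raised
only when the calibrated angle *strictly* exceeds the limit, and flags
must persist for a configurable minimum duration (default 5 s) before
they become a violation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .calibration import CalibrationState, apply_calibration
from .quaternion import EulerTriple, Quaternion, to_euler
from .streaming import MotionPacket

__all__ = [
    "SEGMENT_NAMES",
    "AXES",
    "SegmentState",
    "BodyModel",
    "PostureLimits",
    "ViolationEvent",
    "default_sensor_map",
    "update_body",
    "check_limits",
    "sustained_violation",
    "scenario_config",
    "SCENARIO_NAMES",
]

#: The 13 monitored body segments.
SEGMENT_NAMES: Tuple[str, ...] = (
    "head",
    "chest",
    "pelvis",
    "left_upper_arm",
    "right_upper_arm",
    "left_lower_arm",
    "right_lower_arm",
    "left_hand",
    "right_hand",
    "left_upper_leg",
    "right_upper_leg",
    "left_lower_leg",
    "right_lower_leg",
)

AXES: Tuple[str, str, str] = ("x", "y", "z")

SCENARIO_NAMES: Dict[int, str] = {
    0: "none",
    1: "standing",
    2: "sitting",
    3: "joint",
    4: "lifting",
}

DEFAULT_LIMIT_DEGREES = 30.0
DEFAULT_MIN_DURATION_S = 5.0


@dataclass
class SegmentState:
    """One body segment: orientation plus its three Euler triples."""

    name: str
    sensor_id: str
    orientation: Quaternion = field(default_factory=Quaternion.identity)
    rotation: EulerTriple = EulerTriple(0.0, 0.0, 0.0)
    correction: EulerTriple = EulerTriple(0.0, 0.0, 0.0)
    position: EulerTriple = EulerTriple(0.0, 0.0, 0.0)
    last_update: float = float("-inf")


def default_sensor_map() -> Dict[str, str]:
    """Sensor ids s01..s13 assigned to the segments in canonical order."""
    return {f"s{i + 1:02d}": name for i, name in enumerate(SEGMENT_NAMES)}


@dataclass
class BodyModel:
    """Exactly 13 uniquely named segments addressed by sensor id."""

    segments: Dict[str, SegmentState]
    sensor_map: Dict[str, str]

    @classmethod
    def create(cls, sensor_map: Optional[Mapping[str, str]] = None) -> "BodyModel":
        mapping = dict(sensor_map) if sensor_map is not None else default_sensor_map()
        if sorted(mapping.values()) != sorted(SEGMENT_NAMES):
            raise ValueError(
                "sensor map must cover each of the 13 segments exactly once"
            )
        segment_of = {name: sid for sid, name in mapping.items()}
        segments = {
            name: SegmentState(name=name, sensor_id=segment_of[name])
            for name in SEGMENT_NAMES
        }
        return cls(segments=segments, sensor_map=mapping)


@dataclass(frozen=True)
class PostureLimits:
    """Safe angular range per axis for one segment, plus event timing."""

    segment: str
    limits: Dict[str, float]  # axis -> max |angle| in degrees
    min_duration_s: float = DEFAULT_MIN_DURATION_S
    scenario: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"scenario id must be 0-4, got {self.scenario}")
        for axis, limit in self.limits.items():
            if axis not in AXES:
                raise ValueError(f"unknown axis {axis!r}")
            if limit <= 0:
                raise ValueError(f"limit for axis {axis} must be positive")


@dataclass(frozen=True)
class ViolationEvent:
    """One sustained excursion beyond a segment's safe range."""

    segment: str
    axis: str
    start: float
    end: float
    peak: float


def update_body(
    model: BodyModel,
    packets: Iterable[MotionPacket],
    calibration: Optional[CalibrationState] = None,
) -> BodyModel:
    """Apply a batch of packets to the model, newest timestamp winning.

    Unknown sensor ids are skipped.  The calibrated Euler triple lands in
    the segment's ``rotation`` field; the raw reading minus the rotation
    is recorded as the ``correction``.
    """
    import logging

    logger = logging.getLogger(__name__)
    for packet in packets:
        segment_name = model.sensor_map.get(packet.sensor_id)
        if segment_name is None:
            logger.warning("unknown sensor id %r; packet skipped", packet.sensor_id)
            continue
        segment = model.segments[segment_name]
        if packet.timestamp < segment.last_update:
            continue
        orientation = packet.quaternion()
        raw = to_euler(orientation)
        if calibration is not None:
            calibrated = apply_calibration(calibration, segment_name, raw)
        else:
            calibrated = raw
        segment.orientation = orientation
        segment.rotation = calibrated
        segment.correction = EulerTriple(
            raw.x - calibrated.x, raw.y - calibrated.y, raw.z - calibrated.z
        )
        segment.last_update = packet.timestamp
    return model


def check_limits(segment: SegmentState, limits: PostureLimits) -> Dict[str, bool]:
    """Per-axis flags; an axis flags iff |angle| strictly exceeds its limit."""
    angles = dict(zip(AXES, segment.rotation.as_tuple()))
    return {
        axis: abs(angles[axis]) > limit for axis, limit in limits.limits.items()
    }


def sustained_violation(
    samples: Sequence[Tuple[float, bool, float]],
    limits: PostureLimits,
    *,
    axis: str = "x",
    segment: Optional[str] = None,
    sample_period_s: float = 1.0 / 60.0,
) -> List[ViolationEvent]:
    """Collapse a flag time series into sustained violation events.

    ``samples`` is a sequence of ``(timestamp, flagged, angle)`` with
    monotone timestamps.  Contiguous flagged runs lasting at least the
    configured minimum duration become one event each; unflagged gaps
    shorter than one sample period are bridged into the surrounding run.
    """
    name = segment if segment is not None else limits.segment
    times = [t for t, _, _ in samples]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("sample timestamps must be monotone non-decreasing")

    events: List[ViolationEvent] = []
    run_start: Optional[float] = None
    run_end: Optional[float] = None
    run_peak = 0.0

    def close_run() -> None:
        nonlocal run_start, run_end, run_peak
        if run_start is not None and run_end is not None:
            if run_end - run_start >= limits.min_duration_s:
                events.append(
                    ViolationEvent(
                        segment=name,
                        axis=axis,
                        start=run_start,
                        end=run_end,
                        peak=run_peak,
                    )
                )
        run_start = run_end = None
        run_peak = 0.0

    for t, flagged, angle in samples:
        if flagged:
            if run_start is None:
                run_start, run_end, run_peak = t, t, angle
            else:
                # bridge: gap between this flag and the end of the run,
                # beyond the expected one sample period, must stay < 1 period
                gap = (t - run_end) - sample_period_s
                if gap < sample_period_s:
                    run_end = t
                    if abs(angle) > abs(run_peak):
                        run_peak = angle
                else:
                    close_run()
                    run_start, run_end, run_peak = t, t, angle
        else:
            if run_end is not None and (t - run_end) >= 2.0 * sample_period_s:
                close_run()
    close_run()
    return events


def scenario_config(scenario_id: int) -> Dict[str, PostureLimits]:
    """Per-segment limit presets for a monitoring scenario.

    Scenario 0 imposes no limits; scenarios 1-4 (standing, sitting,
    joint, lifting) monitor the head, chest, and pelvis with a 30 degree
    safe range on every axis.
    """
    if scenario_id not in SCENARIO_NAMES:
        raise ValueError(f"scenario id must be an integer 0-4, got {scenario_id!r}")
    if scenario_id == 0:
        return {}
    monitored = ("head", "chest", "pelvis")
    return {
        segment: PostureLimits(
            segment=segment,
            limits={axis: DEFAULT_LIMIT_DEGREES for axis in AXES},
            min_duration_s=DEFAULT_MIN_DURATION_S,
            scenario=scenario_id,
        )
        for segment in monitored
    }
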