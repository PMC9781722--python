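"""Re-zeroing calibration: capture a reference pose, subtract it per axis.

The reference is captured for every active segment at once, stored as
wrapped Euler triples, and subtracted component-wise from subsequent
readings.  Subtraction happens in Euler space — deliberately, matching
the original trigger-button implementation — which is an exact rotation
correction for single-axis motion and an approximation otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Union

from .quaternion import EulerTriple, wrap_degrees

__all__ = ["CalibrationState", "wrap_angle", "capture_reference", "apply_calibration"]

logger = logging.getLogger(__name__)


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into [-180, 180); rejects non-finite input."""
    return wrap_degrees(a)


@dataclass(frozen=True)
class CalibrationState:
    """Per-segment reference triples captured at one instant."""

    references: Dict[str, EulerTriple] = field(default_factory=dict)
    captured_at: float = 0.0

    def to_json(self) -> str:
        payload = {
            "captured_at": self.captured_at,
            "references": {
                name: list(ref.as_tuple()) for name, ref in self.references.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationState":
        payload = json.loads(text)
        refs = {
            name: EulerTriple(*vals)
            for name, vals in payload.get("references", {}).items()
        }
        return cls(references=refs, captured_at=float(payload.get("captured_at", 0.0)))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CalibrationState":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def capture_reference(
    readings: Mapping[str, EulerTriple],
    *,
    timestamp: float = 0.0,
    expected_segments=None,
) -> CalibrationState:
    """Store the current per-segment readings as the new zero reference.

    If ``expected_segments`` is given, every one of them must be present.
    """
    if expected_segments is not None:
        missing = [s for s in expected_segments if s not in readings]
        if missing:
            raise ValueError(f"missing reading for segment(s): {', '.join(missing)}")
    references = {name: EulerTriple(*triple) for name, triple in readings.items()}
    return CalibrationState(references=references, captured_at=timestamp)


def apply_calibration(
    state: CalibrationState, segment: str, reading: EulerTriple
) -> EulerTriple:
    """Per-axis difference between the reading and the stored reference.

    A segment without a stored reference passes through unchanged with a
    logged warning rather than failing the stream.
    """
    ref = state.references.get(segment)
    if ref is None:
        logger.warning("segment %r has no calibration reference; passing through", segment)
        return reading
    return EulerTriple(
        wrap_degrees(reading.x - ref.x),
        wrap_degrees(reading.y - ref.y),
        wrap_degrees(reading.z - ref.z),
    )
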