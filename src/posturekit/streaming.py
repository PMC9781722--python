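"""Newline-delimited JSON packet dialect and CSV orientation logs.

One packet is one JSON object per line carrying a sensor id, a timestamp
in seconds from stream start, and the four quaternion components named
``wq`` (real part) and ``xq``/``yq``/``zq`` (imaginary parts).  CSV logs
carry the same fields under named columns and round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Union

from .quaternion import Quaternion

__all__ = [
    "MotionPacket",
    "parse_packet",
    "serialize_packet",
    "read_jsonl",
    "write_jsonl",
    "read_csv_log",
    "write_csv_log",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("timestamp", "sensor_id", "wq", "xq", "yq", "zq")

_COMPONENT_KEYS = ("wq", "xq", "yq", "zq")
_INGEST_NORM_TOL = 1e-3


@dataclass(frozen=True)
class MotionPacket:
    """One timestamped orientation reading from one sensor."""

    sensor_id: str
    timestamp: float
    wq: float
    xq: float
    yq: float
    zq: float

    def __post_init__(self) -> None:
        comps = (self.wq, self.xq, self.yq, self.zq)
        if not all(math.isfinite(c) for c in comps):
            raise ValueError("quaternion components must be finite")
        if not math.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        norm = math.sqrt(sum(c * c for c in comps))
        if abs(norm - 1.0) > _INGEST_NORM_TOL:
            raise ValueError(
                f"quaternion norm {norm:.6g} outside the ingest tolerance "
                f"of {_INGEST_NORM_TOL} from 1"
            )

    def quaternion(self) -> Quaternion:
        """The packet orientation, renormalized to an exact unit quaternion."""
        return Quaternion(self.wq, self.xq, self.yq, self.zq)

    @classmethod
    def from_quaternion(
        cls, sensor_id: str, timestamp: float, q: Quaternion
    ) -> "MotionPacket":
        return cls(sensor_id, timestamp, q.w, q.x, q.y, q.z)


def parse_packet(line: str) -> MotionPacket:
    """Parse one JSON line into a packet; unknown keys are ignored."""
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed packet JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ValueError("packet line must be a JSON object")
    sensor_id = obj.get("id", obj.get("sensor_id"))
    if sensor_id is None:
        raise ValueError("packet missing field 'id'")
    timestamp = obj.get("t", obj.get("timestamp"))
    if timestamp is None:
        raise ValueError("packet missing field 't'")
    components = []
    for key in _COMPONENT_KEYS:
        if key not in obj:
            raise ValueError(f"packet missing field {key!r}")
        components.append(float(obj[key]))
    return MotionPacket(str(sensor_id), float(timestamp), *components)


def serialize_packet(p: MotionPacket) -> str:
    """Serialize a packet to a single JSON line (no trailing newline).

    ``repr``-precision floats make serialize/parse round trips lossless.
    """
    obj = {
        "id": p.sensor_id,
        "t": p.timestamp,
        "wq": p.wq,
        "xq": p.xq,
        "yq": p.yq,
        "zq": p.zq,
    }
    return json.dumps(obj, separators=(", ", ": "))


def read_jsonl(source: Union[str, Path, Iterable[str]]) -> Iterator[MotionPacket]:
    """Stream packets from a JSON-lines file path or an iterable of lines.

    Blank lines are skipped; bare ``C`` lines (the calibration trigger
    token) are skipped here and handled by the monitor loop.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from read_jsonl(handle)
        return
    for line in source:
        stripped = line.strip()
        if not stripped or stripped == "C":
            continue
        yield parse_packet(stripped)


def write_jsonl(packets: Iterable[MotionPacket], path: Union[str, Path]) -> int:
    """Write packets one JSON line each; returns the number written."""
    count = 0
    with open(path, "w", encoding="utf-8") as handle:
        for packet in packets:
            handle.write(serialize_packet(packet) + "\n")
            count += 1
    return count


def read_csv_log(path: Union[str, Path]) -> List[MotionPacket]:
    """Read an orientation log; columns are matched by header name."""
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            return []
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"CSV log missing column(s): {', '.join(missing)}")
        packets = []
        for row in reader:
            packets.append(
                MotionPacket(
                    sensor_id=row["sensor_id"],
                    timestamp=float(row["timestamp"]),
                    wq=float(row["wq"]),
                    xq=float(row["xq"]),
                    yq=float(row["yq"]),
                    zq=float(row["zq"]),
                )
            )
    return packets


def write_csv_log(packets: Sequence[MotionPacket], path: Union[str, Path]) -> None:
    """Write packets to CSV with repr-precision floats (lossless round trip)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for p in packets:
            writer.writerow(
                [repr(p.timestamp), p.sensor_id, repr(p.wq), repr(p.xq), repr(p.yq), repr(p.zq)]
            )
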