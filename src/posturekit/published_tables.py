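"""Embedded copies of the published goniometer-comparison grids.

Each grid pairs goniometer target angles (0-50 degrees in 10-degree
steps) with the X/Y/Z angles reported per measurement method (or per
body part, for the full-body grid).  ``None`` marks cells the source
printed as NAN or N/A; summaries exclude them.

These are fixture data for validation summaries and integrity tests —
nothing in the measurement pipeline reads them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

__all__ = ["PublishedTable", "PUBLISHED_TABLES", "FULL_BODY", "JOINT_SWEEPS"]

Cell = Optional[float]
Column = Tuple[Cell, ...]


@dataclass(frozen=True)
class PublishedTable:
    """A published sweep grid: targets by (column group, axis) cells."""

    name: str
    joint: str
    motion: str
    targets: Tuple[float, ...]
    columns: Dict[Tuple[str, str], Column]

    def cell(self, group: str, axis: str, row: int) -> Cell:
        return self.columns[(group, axis)][row]


_TARGETS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


def _methods(
    m1: Tuple[Tuple[Cell, Cell, Cell], ...],
    m2: Tuple[Tuple[Cell, Cell, Cell], ...],
    m3: Tuple[Tuple[Cell, Cell, Cell], ...],
) -> Dict[Tuple[str, str], Column]:
    cols: Dict[Tuple[str, str], Column] = {}
    for label, rows in (("method1", m1), ("method2", m2), ("method3", m3)):
        for axis_index, axis in enumerate(("x", "y", "z")):
            cols[(label, axis)] = tuple(row[axis_index] for row in rows)
    return cols


FULL_BODY = PublishedTable(
    name="full_body",
    joint="body",
    motion="mixed",
    targets=_TARGETS,
    columns={
        ("head", "x"): (0, 10, 20, 29, 40, 49),
        ("head", "y"): (0, 10, 20, 30, 38, 50),
        ("head", "z"): (0, 8, 19, 30, 40, 50),
        ("chest", "x"): (0, 11, 20, 29, 40, 49),
        ("chest", "y"): (0, 10, 20, 30, 40, 50),
        ("chest", "z"): (0, 9, 20, 30, 39, 47),
        ("hips", "x"): (0, 10, 20, 30, 40, 50),
        ("hips", "y"): (0, 10, 20, 30, 40, 49),
        ("hips", "z"): (0, 11, 18, 30, None, None),
    },
)

WRIST_ULNAR = PublishedTable(
    name="wrist_ulnar",
    joint="wrist",
    motion="ulnar",
    targets=_TARGETS,
    columns=_methods(
        ((0, 0, 1), (11, None, 11), (19, None, 19), (30, None, 30), (38, None, 38), (50, None, 50)),
        ((-1, 0, 0), (-1, 12, 0), (-1, 19, 0), (-1, 31, 0), (-1, 39, 0), (-1, 52, 0)),
        ((-7, -83, -35), (-1, -74, -36), (4, -67, -35), (11, -58, -34), (16, -49, -32), (21, -40, -29)),
    ),
)

WRIST_RADIAL = PublishedTable(
    name="wrist_radial",
    joint="wrist",
    motion="radial",
    targets=_TARGETS,
    columns=_methods(
        ((1, None, 1), (11, 3, 11), (20, 4, 20), (29, 4, 29), (42, 5, 42), (50, 6, 50)),
        ((-1, 1, 0), (-1, -9, 0), (-1, -20, 0), (-1, -29, 0), (-1, -38, 0), (-1, -51, 0)),
        ((-6, -82, -36), (-12, -91, -34), (-18, -100, -32), (-23, -108, -29), (-28, -120, -24), (-31, -129, -19)),
    ),
)

WRIST_FLEXION = PublishedTable(
    name="wrist_flexion",
    joint="wrist",
    motion="flexion",
    targets=_TARGETS,
    columns=_methods(
        ((0, 1, 1), (3, 11, 11), (2, 22, 22), (1, 29, 29), (1, 39, 39), (2, 50, 49)),
        ((-1, 0, 0), (10, 3, 0), (21, 2, 0), (29, 1, 0), (39, 1, 1), (48, 3, 1)),
        ((-7, -83, -35), (3, -87, -35), (11, -93, -36), (19, -100, -37), (26, -106, -39), (34, -113, -43)),
    ),
)

WRIST_EXTENSION = PublishedTable(
    name="wrist_extension",
    joint="wrist",
    motion="extension",
    targets=_TARGETS,
    columns=_methods(
        ((16, None, 17), (19, 10, 22), (21, 18, 29), (23, 31, 37), (24, 39, 45), (25, 49, 54)),
        ((-1, 16, 1), (-11, 19, 1), (-20, 21, 1), (-29, 22, 1), (-41, 23, 1), (-50, 24, 2)),
        ((2, -69, -35), (-4, -61, -35), (-10, -54, -35), (-18, -47, -36), (-25, -40, -38), (-32, -32, -41)),
    ),
)

WRIST_PRONATION = PublishedTable(
    name="wrist_pronation",
    joint="wrist",
    motion="pronation",
    targets=_TARGETS,
    columns=_methods(
        ((18, None, 18), (22, 12, 19), (27, 23, 17), (34, 28, 16), (42, 41, 15), (52, 51, 14)),
        ((-1, 18, -1), (-1, 19, 11), (-1, 17, 21), (-1, 16, 30), (-1, 15, 38), (-1, 14, 52)),
        ((4, -68, -37), (4, -67, -24), (3, -69, -15), (3, -69, -5), (2, -70, 4), (1, -71, 14)),
    ),
)

WRIST_SUPINATION = PublishedTable(
    name="wrist_supination",
    joint="wrist",
    motion="supination",
    targets=_TARGETS,
    columns=_methods(
        ((17, None, 17), (18, 9, 16), (24, 22, 14), (32, 31, 11), (41, 43, 9), (50, 51, 8)),
        ((-2, 17, 0), (-1, 16, -12), (-1, 14, -21), (-1, 11, -30), (0, 9, -43), (2, 8, -51)),
        ((3, -68, -35), (2, -70, -46), (1, -71, -56), (-1, -74, -66), (-1, -76, -75), (-1, -78, -85)),
    ),
)

KNEE_FLEXION = PublishedTable(
    name="knee_flexion",
    joint="knee",
    motion="flexion",
    targets=_TARGETS,
    columns=_methods(
        ((0, None, 1), (11, 10, 4), (21, 20, 6), (30, 30, 7), (40, 40, 8), (51, 51, 10)),
        ((-1, 0, 0), (-1, -4, -10), (-2, -5, -20), (-2, -6, -30), (-3, -8, -39), (-4, -9, -50)),
        ((0, 5, 0), (0, 1, -10), (0, -1, -20), (1, -2, -29), (1, -4, -39), (0, -6, -50)),
    ),
)

ELBOW_FLEXION = PublishedTable(
    name="elbow_flexion",
    joint="elbow",
    motion="flexion",
    targets=_TARGETS,
    columns=_methods(
        ((0, None, 1), (10, None, 10), (21, None, 21), (31, None, 31), (40, None, 40), (51, None, 51)),
        ((-1, 0, 0), (-1, 10, 0), (-1, 21, 0), (-1, 30, 0), (-1, 42, 0), (-1, 50, 0)),
        ((-2, 1, -80), (7, 3, -80), (18, 5, -79), (27, 7, -78), (36, 10, -77), (46, 13, -74)),
    ),
)

JOINT_SWEEPS = (
    WRIST_ULNAR,
    WRIST_RADIAL,
    WRIST_FLEXION,
    WRIST_EXTENSION,
    WRIST_PRONATION,
    WRIST_SUPINATION,
    KNEE_FLEXION,
    ELBOW_FLEXION,
)

PUBLISHED_TABLES: Dict[str, PublishedTable] = {
    table.name: table for table in (FULL_BODY,) + JOINT_SWEEPS
}
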