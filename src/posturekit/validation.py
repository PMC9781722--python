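"""Build goniometer-style validation tables from sweeps; accuracy summaries.

A :class:`ValidationTable` has one row per goniometer target angle and
one cell per (method, axis).  Because no single accuracy metric is
standard for these comparisons, :func:`accuracy_metrics` reports several
clearly labeled figures instead of one headline number: mean absolute
error, maximum absolute error, the proportion of cells within one
degree, and a range-normalized percent accuracy
``100 * (1 - MAE / full_scale)``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .joints import SegmentRig, method1_triple, method2_angles, method3_angles
from .quaternion import relative
from .simulate import SweepSample, resolve_motion_axis

__all__ = [
    "ValidationTable",
    "build_validation_table",
    "accuracy_metrics",
    "grid_mae",
]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ValidationTable:
    """Measured angles over a sweep grid, per method and axis."""

    joint: str
    motion: str
    targets: Tuple[float, ...]
    cells: Dict[Tuple[int, str], Tuple[Optional[float], ...]]
    noise_sigma_deg: float = 0.0
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.targets, self.targets[1:]):
            if b <= a:
                raise ValueError("row targets must be strictly increasing")
        for key, column in self.cells.items():
            if len(column) != len(self.targets):
                raise ValueError(f"column {key} length does not match targets")

    def column(self, method: int, axis: str) -> Tuple[Optional[float], ...]:
        return self.cells[(method, axis)]

    def methods(self) -> Tuple[int, ...]:
        return tuple(sorted({m for m, _ in self.cells}))

    def write_csv(self, path: Union[str, Path]) -> None:
        methods = self.methods()
        header = ["target"] + [f"method{m}_{ax}" for m in methods for ax in AXES]
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(header)
            for row, target in enumerate(self.targets):
                out = [target]
                for m in methods:
                    for ax in AXES:
                        cell = self.cells[(m, ax)][row]
                        out.append("" if cell is None else f"{cell:.6f}")
                writer.writerow(out)


def build_validation_table(
    dataset: Sequence[SweepSample],
    methods: Sequence[int] = (1, 2, 3),
    rig: Optional[SegmentRig] = None,
    *,
    joint: str = "",
    motion: str = "",
    noise_sigma_deg: float = 0.0,
) -> ValidationTable:
    """Evaluate each requested method at every steady pose of a sweep."""
    if not dataset:
        raise ValueError("dataset is empty")
    for m in methods:
        if m not in (1, 2, 3):
            raise ValueError(f"method must be 1, 2 or 3, got {m}")
    rig = rig if rig is not None else SegmentRig()
    columns: Dict[Tuple[int, str], List[Optional[float]]] = {
        (m, ax): [] for m in methods for ax in AXES
    }
    targets = []
    for sample in dataset:
        targets.append(sample.target_deg)
        parent = sample.parent.quaternion()
        child = sample.child.quaternion()
        if 1 in methods:
            for ax, value in zip(AXES, method1_triple(parent, child)):
                columns[(1, ax)].append(value)
        if 2 in methods:
            triple = method2_angles(parent, child)
            for ax, value in zip(AXES, triple.as_tuple()):
                columns[(2, ax)].append(value)
        if 3 in methods:
            triple = method3_angles(rig, relative(parent, child))
            for ax, value in zip(AXES, triple.as_tuple()):
                columns[(3, ax)].append(value)
    return ValidationTable(
        joint=joint,
        motion=motion,
        targets=tuple(targets),
        cells={key: tuple(col) for key, col in columns.items()},
        noise_sigma_deg=noise_sigma_deg,
    )


def grid_mae(
    cells: Sequence[Optional[float]], targets: Sequence[float]
) -> Tuple[float, float, int]:
    """(sum of |cell - target|, max |cell - target|, count) skipping None."""
    total = 0.0
    worst = 0.0
    count = 0
    for cell, target in zip(cells, targets):
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            continue
        err = abs(cell - target)
        total += err
        worst = max(worst, err)
        count += 1
    return total, worst, count


def accuracy_metrics(
    table: ValidationTable,
    method: int,
    axis: str,
    *,
    sign: Optional[float] = None,
    full_scale: float = 50.0,
) -> Dict[str, float]:
    """Accuracy summary of one method's active-axis column against the grid.

    ``sign`` is the sign convention of the driven axis (resolved from the
    table's joint/motion when omitted), so, e.g., a knee column that reads
    -30 at a 30-degree target scores zero error.
    """
    if not any(t != 0 for t in table.targets):
        raise ValueError("table needs at least one nonzero-target row")
    if sign is None:
        if table.joint and table.motion:
            _, sign = resolve_motion_axis(table.joint, table.motion)
        else:
            sign = 1.0
    column = table.column(method, axis)
    oriented = [None if c is None else sign * c for c in column]
    total, worst, count = grid_mae(oriented, table.targets)
    if count == 0:
        raise ValueError(f"column (method {method}, axis {axis}) has no usable cells")
    mae = total / count
    within_1 = sum(
        1
        for c, t in zip(oriented, table.targets)
        if c is not None and abs(c - t) <= 1.0
    )
    return {
        "mae_deg": mae,
        "max_abs_error_deg": worst,
        "within_1deg_proportion": within_1 / count,
        "percent_accuracy": 100.0 * (1.0 - mae / full_scale),
        "n_cells": count,
    }
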