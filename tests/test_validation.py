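"""Validation-table construction, accuracy metrics, and fixture integrity.

The integrity tests keep an independent verbatim transcription of the
published sweep grids as raw text and compare it cell-for-cell against
the package's embedded fixtures, so a typo in either copy is caught.
"""

import numpy as np
import pytest

from posturekit.joints import SegmentRig
from posturekit.published_tables import FULL_BODY, JOINT_SWEEPS, PUBLISHED_TABLES
from posturekit.quaternion import EulerTriple
from posturekit.simulate import MotionProfile, resolve_motion_axis, simulate_goniometer_sweep
from posturekit.validation import (
    ValidationTable,
    accuracy_metrics,
    build_validation_table,
    grid_mae,
)

GRID = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
AXES = ("x", "y", "z")

# Verbatim transcriptions: one row per target, cells ordered
# method1 X Y Z, method2 X Y Z, method3 X Y Z.  NAN marks unprintable
# cells.  The full-body grid is head X Y Z, chest X Y Z, hips X Y Z
# with N/A for the two missing hip cells.
RAW_FULL_BODY = """
0   0 0 0    0 0 0    0 0 0
10  10 10 8  11 10 9  10 10 11
20  20 20 19 20 20 20 20 20 18
30  29 30 30 29 30 30 30 30 30
40  40 38 40 40 40 39 40 40 N/A
50  49 50 50 49 50 47 50 49 N/A
"""

RAW_JOINT_SWEEPS = {
    "wrist_ulnar": """
0   0 0 1      -1 0 0    -7 -83 -35
10  11 NAN 11  -1 12 0   -1 -74 -36
20  19 NAN 19  -1 19 0   4 -67 -35
30  30 NAN 30  -1 31 0   11 -58 -34
40  38 NAN 38  -1 39 0   16 -49 -32
50  50 NAN 50  -1 52 0   21 -40 -29
""",
    "wrist_radial": """
0   1 NAN 1    -1 1 0    -6 -82 -36
10  11 3 11    -1 -9 0   -12 -91 -34
20  20 4 20    -1 -20 0  -18 -100 -32
30  29 4 29    -1 -29 0  -23 -108 -29
40  42 5 42    -1 -38 0  -28 -120 -24
50  50 6 50    -1 -51 0  -31 -129 -19
""",
    "wrist_flexion": """
0   0 1 1      -1 0 0    -7 -83 -35
10  3 11 11    10 3 0    3 -87 -35
20  2 22 22    21 2 0    11 -93 -36
30  1 29 29    29 1 0    19 -100 -37
40  1 39 39    39 1 1    26 -106 -39
50  2 50 49    48 3 1    34 -113 -43
""",
    "wrist_extension": """
0   16 NAN 17  -1 16 1   2 -69 -35
10  19 10 22   -11 19 1  -4 -61 -35
20  21 18 29   -20 21 1  -10 -54 -35
30  23 31 37   -29 22 1  -18 -47 -36
40  24 39 45   -41 23 1  -25 -40 -38
50  25 49 54   -50 24 2  -32 -32 -41
""",
    "wrist_pronation": """
0   18 NAN 18  -1 18 -1  4 -68 -37
10  22 12 19   -1 19 11  4 -67 -24
20  27 23 17   -1 17 21  3 -69 -15
30  34 28 16   -1 16 30  3 -69 -5
40  42 41 15   -1 15 38  2 -70 4
50  52 51 14   -1 14 52  1 -71 14
""",
    "wrist_supination": """
0   17 NAN 17  -2 17 0   3 -68 -35
10  18 9 16    -1 16 -12 2 -70 -46
20  24 22 14   -1 14 -21 1 -71 -56
30  32 31 11   -1 11 -30 -1 -74 -66
40  41 43 9    0 9 -43   -1 -76 -75
50  50 51 8    2 8 -51   -1 -78 -85
""",
    "knee_flexion": """
0   0 NAN 1    -1 0 0    0 5 0
10  11 10 4    -1 -4 -10 0 1 -10
20  21 20 6    -2 -5 -20 0 -1 -20
30  30 30 7    -2 -6 -30 1 -2 -29
40  40 40 8    -3 -8 -39 1 -4 -39
50  51 51 10   -4 -9 -50 0 -6 -50
""",
    "elbow_flexion": """
0   0 NAN 1    -1 0 0    -2 1 -80
10  10 NAN 10  -1 10 0   7 3 -80
20  21 NAN 21  -1 21 0   18 5 -79
30  31 NAN 31  -1 30 0   27 7 -78
40  40 NAN 40  -1 42 0   36 10 -77
50  51 NAN 51  -1 50 0   46 13 -74
""",
}


def parse_raw(text):
    """(targets, rows) where each row is a list of float-or-None cells."""
    targets, rows = [], []
    for line in text.strip().splitlines():
        cells = line.split()
        targets.append(float(cells[0]))
        rows.append(
            [None if c in ("NAN", "N/A") else float(c) for c in cells[1:]]
        )
    return targets, rows


class TestFixtureIntegrity:
    def test_full_body_cell_for_cell(self):
        targets, rows = parse_raw(RAW_FULL_BODY)
        assert tuple(targets) == FULL_BODY.targets
        groups = ("head", "chest", "hips")
        for row_index, row in enumerate(rows):
            for col_index, cell in enumerate(row):
                group = groups[col_index // 3]
                axis = AXES[col_index % 3]
                assert FULL_BODY.cell(group, axis, row_index) == cell, (
                    group, axis, row_index,
                )

    @pytest.mark.parametrize("name", sorted(RAW_JOINT_SWEEPS))
    def test_joint_sweeps_cell_for_cell(self, name):
        table = PUBLISHED_TABLES[name]
        targets, rows = parse_raw(RAW_JOINT_SWEEPS[name])
        assert tuple(targets) == table.targets
        for row_index, row in enumerate(rows):
            for col_index, cell in enumerate(row):
                method = f"method{col_index // 3 + 1}"
                axis = AXES[col_index % 3]
                assert table.cell(method, axis, row_index) == cell, (
                    method, axis, row_index,
                )

    def test_published_registry_complete(self):
        assert len(PUBLISHED_TABLES) == 9
        assert len(JOINT_SWEEPS) == 8

    def test_full_body_mae_arithmetic_oracle(self):
        # brute-force sum over the raw transcription, no package code
        _, rows = parse_raw(RAW_FULL_BODY)
        targets, _ = parse_raw(RAW_FULL_BODY)
        total, count = 0.0, 0
        for target, row in zip(targets, rows):
            for cell in row:
                if cell is None:
                    continue
                total += abs(cell - target)
                count += 1
        assert count == 52 and total == 19.0
        # same figure through the package helper on the embedded fixture
        pkg_total, pkg_count = 0.0, 0
        for column in FULL_BODY.columns.values():
            t, _, c = grid_mae(column, FULL_BODY.targets)
            pkg_total += t
            pkg_count += c
        assert pkg_count == count
        assert pkg_total == pytest.approx(total)
        assert pkg_total / pkg_count == pytest.approx(19.0 / 52.0)


class TestBuildValidationTable:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            build_validation_table([])

    def test_invalid_method_rejected(self):
        samples = simulate_goniometer_sweep("elbow", "flexion", GRID)
        with pytest.raises(ValueError):
            build_validation_table(samples, methods=(4,))

    def test_noiseless_elbow_method2_column(self):
        samples = simulate_goniometer_sweep("elbow", "flexion", GRID)
        table = build_validation_table(samples, (2,), joint="elbow", motion="flexion")
        np.testing.assert_allclose(table.column(2, "y"), GRID, atol=1e-9)
        np.testing.assert_allclose(table.column(2, "x"), 0.0, atol=1e-9)
        np.testing.assert_allclose(table.column(2, "z"), 0.0, atol=1e-9)

    def test_noiseless_method1_orthogonal_columns_track_grid(self):
        # elbow flexion rotates about Y: the X and Z reference axes both
        # move through the target angle while the Y column stays pinned
        samples = simulate_goniometer_sweep("elbow", "flexion", GRID)
        table = build_validation_table(samples, (1,), joint="elbow", motion="flexion")
        np.testing.assert_allclose(table.column(1, "x"), GRID, atol=1e-6)
        np.testing.assert_allclose(table.column(1, "z"), GRID, atol=1e-6)
        np.testing.assert_allclose(table.column(1, "y"), 0.0, atol=1e-4)

    def test_method3_baseline_offset(self):
        rig = SegmentRig(rest_offset=EulerTriple(-80.0, 0.0, 0.0))
        samples = simulate_goniometer_sweep("elbow", "flexion", (0.0, 10.0))
        table = build_validation_table(samples, (3,), rig, joint="elbow", motion="flexion")
        assert table.column(3, "x")[0] == pytest.approx(-80.0, abs=1e-9)

    def test_deterministic_given_dataset(self):
        profile = MotionProfile(joint="knee", motion="flexion", noise_sigma_deg=1.0, seed=11)
        samples = simulate_goniometer_sweep("knee", "flexion", GRID, profile)
        t1 = build_validation_table(samples, (1, 2), joint="knee", motion="flexion")
        t2 = build_validation_table(samples, (1, 2), joint="knee", motion="flexion")
        assert t1.cells == t2.cells

    def test_noisy_cells_near_targets(self):
        profile = MotionProfile(joint="knee", motion="flexion", noise_sigma_deg=1.0, seed=11)
        samples = simulate_goniometer_sweep("knee", "flexion", GRID, profile)
        table = build_validation_table(samples, (2,), joint="knee", motion="flexion")
        _, sign = resolve_motion_axis("knee", "flexion")
        for cell, target in zip(table.column(2, "z"), GRID):
            assert abs(sign * cell - target) <= 3.0

    def test_targets_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            ValidationTable(
                joint="elbow", motion="flexion", targets=(0.0, 0.0),
                cells={(2, ax): (0.0, 0.0) for ax in AXES},
            )

    def test_csv_output(self, tmp_path):
        samples = simulate_goniometer_sweep("elbow", "flexion", GRID)
        table = build_validation_table(samples, (1, 2), joint="elbow", motion="flexion")
        path = tmp_path / "table.csv"
        table.write_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "target,method1_x,method1_y,method1_z,method2_x,method2_y,method2_z"
        assert len(lines) == 1 + len(GRID)


class TestAccuracyMetrics:
    def make_table(self, column, sign_axis="y"):
        cells = {(2, ax): tuple(column) if ax == sign_axis else (0.0,) * len(column) for ax in AXES}
        return ValidationTable(
            joint="elbow", motion="flexion", targets=GRID, cells=cells
        )

    def test_zero_error_table(self):
        metrics = accuracy_metrics(self.make_table(GRID), 2, "y")
        assert metrics["mae_deg"] == 0.0
        assert metrics["max_abs_error_deg"] == 0.0
        assert metrics["within_1deg_proportion"] == 1.0
        assert metrics["percent_accuracy"] == 100.0

    def test_constant_one_degree_shift(self):
        shifted = tuple(t + 1.0 for t in GRID)
        metrics = accuracy_metrics(self.make_table(shifted), 2, "y")
        assert metrics["mae_deg"] == pytest.approx(1.0)
        assert metrics["percent_accuracy"] == pytest.approx(98.0)
        assert metrics["within_1deg_proportion"] == 1.0

    def test_monotone_in_single_error(self):
        base = list(GRID)
        worse = list(GRID)
        worse[3] += 5.0
        m_base = accuracy_metrics(self.make_table(tuple(base)), 2, "y")
        m_worse = accuracy_metrics(self.make_table(tuple(worse)), 2, "y")
        assert m_worse["mae_deg"] > m_base["mae_deg"]
        assert m_worse["percent_accuracy"] < m_base["percent_accuracy"]

    def test_row_permutation_invariant(self):
        # permuting (target, cell) pairs together leaves every metric fixed
        values = (1.0, 9.0, 21.0, 31.0, 38.0, 52.0)
        m1 = accuracy_metrics(self.make_table(values), 2, "y")
        order = [3, 0, 5, 1, 4, 2]
        # rebuild with permuted rows re-sorted by target (table requires
        # increasing targets, so permutation must land back in order)
        pairs = sorted(
            ((GRID[i], values[i]) for i in order), key=lambda pair: pair[0]
        )
        permuted = tuple(v for _, v in pairs)
        m2 = accuracy_metrics(self.make_table(permuted), 2, "y")
        assert m1 == m2

    def test_sign_resolved_from_motion(self):
        # knee flexion drives Z negative; a perfect column scores MAE 0
        cells = {(2, ax): tuple(-t for t in GRID) if ax == "z" else (0.0,) * 6 for ax in AXES}
        table = ValidationTable(joint="knee", motion="flexion", targets=GRID, cells=cells)
        metrics = accuracy_metrics(table, 2, "z")
        assert metrics["mae_deg"] == 0.0

    def test_all_zero_targets_rejected(self):
        cells = {(2, ax): (0.0,) for ax in AXES}
        table = ValidationTable(joint="e", motion="f", targets=(0.0,), cells=cells)
        with pytest.raises(ValueError):
            accuracy_metrics(table, 2, "y")

    def test_all_missing_column_rejected(self):
        cells = {(2, ax): (None,) * 6 for ax in AXES}
        table = ValidationTable(joint="elbow", motion="flexion", targets=GRID, cells=cells)
        with pytest.raises(ValueError):
            accuracy_metrics(table, 2, "y")

    def test_missing_cells_excluded(self):
        column = (0.0, 10.0, None, 30.0, None, 50.0)
        metrics = accuracy_metrics(self.make_table(column), 2, "y")
        assert metrics["n_cells"] == 4
        assert metrics["mae_deg"] == 0.0
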