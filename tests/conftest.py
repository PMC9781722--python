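import numpy as np
import pytest

from posturekit.quaternion import Quaternion


def random_quaternion(rng: np.random.Generator) -> Quaternion:
    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    return Quaternion(*v)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def quat_to_matrix_oracle(q: Quaternion) -> np.ndarray:
    """Independent rotation-matrix construction (textbook formula, no reuse
    of the package's to_matrix)."""
    w, x, y, z = q.w, q.x, q.y, q.z
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def rotation_angle_between(m_a: np.ndarray, m_b: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotation matrices.

    Uses the skew-part (sine) formula for small angles, where the
    arccos-of-trace formula loses ~8 digits of resolution."""
    r = m_a.T @ m_b
    c = (np.trace(r) - 1.0) / 2.0
    if c > 0.5:
        s = (r - r.T) / 2.0
        v = np.array([s[2, 1], s[0, 2], s[1, 0]])
        return float(np.degrees(np.arcsin(np.clip(np.linalg.norm(v), -1.0, 1.0))))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
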