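"""Helix axis extraction and the quaternion description of helix reorientation.

A helix reorientation is carried by a unit quaternion

    Q = (cos(θ/2), sin(θ/2)·u1, sin(θ/2)·u2, sin(θ/2)·u3)

where (u1, u2, u3) is the rotation axis, obtained from the cross product of
the helix axis before and after the motion, and θ the rotation angle about
it.  The scalar part is kept non-negative so θ ∈ [0°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_UNIT_TOL = 1e-6
_PARALLEL_TOL = 1e-9


@dataclass(frozen=True)
class UnitQuaternion:
    """Rotation carrier (q0, q1, q2, q3) with q0 = cos(θ/2) ≥ 0."""

    q0: float
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if abs(self.norm() - 1.0) > _UNIT_TOL:
            raise ValueError(f"quaternion norm {self.norm():.8f} deviates from 1")

    def norm(self) -> float:
        return float(np.sqrt(self.q0**2 + self.q1**2 + self.q2**2 + self.q3**2))

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3])

    @property
    def angle_deg(self) -> float:
        return quaternion_angle(self)

    @property
    def axis(self) -> np.ndarray:
        """Rotation axis (u1, u2, u3); the z unit vector for the identity."""
        v = self.vector
        s = np.linalg.norm(v)
        if s < _PARALLEL_TOL:
            return np.array([0.0, 0.0, 1.0])
        return v / s

    def conjugate(self) -> "UnitQuaternion":
        return UnitQuaternion(self.q0, -self.q1, -self.q2, -self.q3)

    def compose(self, other: "UnitQuaternion") -> "UnitQuaternion":
        """Hamilton product self∘other (apply ``other`` first), renormalized."""
        a0, a = self.q0, self.vector
        b0, b = other.q0, other.vector
        s = a0 * b0 - a @ b
        v = a0 * b + b0 * a + np.cross(a, b)
        return _make(s, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.q0, self.q1, self.q2, self.q3])


IDENTITY = UnitQuaternion(1.0, 0.0, 0.0, 0.0)


def _make(s: float, v: np.ndarray) -> UnitQuaternion:
    """Build a normalized quaternion with non-negative scalar part."""
    q = np.concatenate(([s], v))
    q = q / np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return UnitQuaternion(*q)


def helix_axis(calpha_coords: np.ndarray) -> np.ndarray:
    """Helix axis of an ordered Cα point cloud, from bond-bisector geometry.

    For consecutive Cα positions, the second differences (bisectors)
    h_i = (P_{i+2} − P_{i+1}) − (P_{i+1} − P_i) point radially toward the
    helix axis, so each cross product h_i × h_{i+1} lies along the axis;
    their sum is exact for an ideal helix and averages out thermal noise
    for a real one.  The sign is fixed so the axis points N-terminus →
    C-terminus (positive projection of the end-to-end displacement).

    Requires at least 5 Cα positions; raises on a degenerate (collinear
    or coincident) point set.
    """
    pts = np.asarray(calpha_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    n = len(pts)
    if n < 5:
        raise ValueError(f"need at least 5 Calpha positions to fit an axis, got {n}")
    bonds = np.diff(pts, axis=0)
    bisectors = np.diff(bonds, axis=0)
    crosses = np.cross(bisectors[:-1], bisectors[1:])
    axis = crosses.sum(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate point set: no helical curvature to fit an axis")
    axis = axis / norm
    half = n // 2
    direction = pts[n - half :].mean(axis=0) - pts[:half].mean(axis=0)
    if direction @ axis < 0:
        axis = -axis
    return axis


def rotation_quaternion(axis_before: np.ndarray, axis_after: np.ndarray) -> UnitQuaternion:
    """Quaternion rotating ``axis_before`` onto ``axis_after``.

    Rotation axis = normalized cross product of the two helix axes;
    θ = atan2(‖a×b‖, a·b).  Parallel inputs give the identity;
    antiparallel inputs give a 180° turn about a deterministic
    perpendicular direction.
    """
    a = np.asarray(axis_before, dtype=float)
    b = np.asarray(axis_after, dtype=float)
    for v in (a, b):
        if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
            raise ValueError("axis vectors must be unit length")
    cross = np.cross(a, b)
    s = np.linalg.norm(cross)
    d = float(a @ b)
    if s < _PARALLEL_TOL:
        if d > 0:
            return IDENTITY
        # antiparallel: 180° about the canonical basis vector (smallest
        # index) least parallel to a, orthogonalized against a
        k = int(np.argmin(np.abs(a)))
        perp = np.zeros(3)
        perp[k] = 1.0
        perp -= (perp @ a) * a
        perp /= np.linalg.norm(perp)
        return UnitQuaternion(0.0, *perp)
    theta = np.arctan2(s, d)  # radians, in (0, π)
    u = cross / s
    half = theta / 2.0
    return _make(np.cos(half), np.sin(half) * u)


def quaternion_angle(q: UnitQuaternion) -> float:
    """Rotation angle 2·arccos(q0) in degrees, in [0°, 180°]."""
    if abs(q.norm() - 1.0) > _UNIT_TOL:
        raise ValueError("non-unit quaternion")
    return float(np.degrees(2.0 * np.arccos(np.clip(q.q0, -1.0, 1.0))))


def apply_rotation(q: UnitQuaternion, v: np.ndarray) -> np.ndarray:
    """Rotate a 3-vector by quaternion conjugation q v q*."""
    v = np.asarray(v, dtype=float)
    u = q.vector
    # Rodrigues form of q v q*
    return v + 2.0 * q.q0 * np.cross(u, v) + 2.0 * np.cross(u, np.cross(u, v))


def interpolate_orientation(q_target: UnitQuaternion, fraction: float) -> UnitQuaternion:
    """Spherical interpolation from the identity toward ``q_target``.

    The rotation angle scales linearly: the result is a rotation by
    fraction·θ about the target's axis.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    theta = np.radians(quaternion_angle(q_target))
    if theta < 1e-12:
        return IDENTITY
    half = fraction * theta / 2.0
    return _make(np.cos(half), np.sin(half) * q_target.axis)
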