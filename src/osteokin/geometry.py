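"""Small 3D geometry primitives: planes, axes, rigid transforms.

All coordinates are millimetres in a right-handed frame
(+X lateral for a right limb, +Y anterior, +Z proximal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.point) @ self.normal

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class Axis:
    """Line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))

    def distance_to(self, p: np.ndarray) -> float:
        """Perpendicular distance from a point to the axis line."""
        r = np.asarray(p, dtype=float) - self.point
        perp = r - (r @ self.direction) * self.direction
        return float(np.linalg.norm(perp))


class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    __slots__ = ("R", "t")

    def __init__(self, R: np.ndarray, t: np.ndarray):
        self.R = np.asarray(R, dtype=float)
        self.t = np.asarray(t, dtype=float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def rotation_about_axis(cls, axis: Axis, angle_rad: float) -> "RigidTransform":
        """Rotation by `angle_rad` about the (infinite) line `axis`."""
        R = rotation_matrix(axis.direction, angle_rad)
        t = axis.point - R @ axis.point
        return cls(R, t)

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply `other` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        Rt = self.R.T
        return RigidTransform(Rt, -Rt @ self.t)

    def is_proper(self, tol: float = 1e-9) -> bool:
        RtR = self.R.T @ self.R
        return (
            np.abs(RtR - np.eye(3)).max() < tol
            and abs(np.linalg.det(self.R) - 1.0) < tol
        )

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M


def rotation_matrix(direction: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit direction."""
    d = unit(direction)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    K = np.array(
        [[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]], dtype=float
    )
    return np.eye(3) * c + s * K + (1 - c) * np.outer(d, d)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle undefined for zero-length vector")
    c = float(np.dot(u, v) / (nu * nv))
    c = max(-1.0, min(1.0, c))
    return math.degrees(math.acos(c))


def orthonormalize(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Component of `secondary` orthogonal to `primary`, normalized."""
    p = unit(primary)
    s = np.asarray(secondary, dtype=float)
    return unit(s - (s @ p) * p)
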