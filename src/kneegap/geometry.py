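"""Low-level 3D/2D geometric primitives.

Conventions used throughout the package:

* all lengths are millimetres;
* all angles are degrees at API boundaries (radians internally);
* a :class:`Plane`'s positive halfspace is the *resected* side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Plane",
    "Circle2D",
    "signed_distance",
    "extreme_point",
    "rotate_about_axis",
    "fit_circle_2d",
    "project_to_plane",
]

_UNIT_TOL = 1e-9


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class Plane:
    """Oriented plane; points with positive signed distance lie on the resected side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point, "point"))
        n = _as_vec3(self.normal, "normal")
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-6:
            if norm == 0:
                raise ValueError("plane normal must be non-zero")
            n = n / norm
        object.__setattr__(self, "normal", n)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}


@dataclass(frozen=True)
class Circle2D:
    """Circle in a named 2D projection plane."""

    center: np.ndarray
    radius: float
    plane_name: str = field(default="", compare=False)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (2,):
            raise ValueError("Circle2D center must be a 2-vector")
        object.__setattr__(self, "center", c)
        if not self.radius > 0:
            raise ValueError(f"Circle2D radius must be positive, got {self.radius}")


def signed_distance(plane: Plane, p) -> float | np.ndarray:
    """Signed distance(s) from ``p`` to ``plane``; positive on the resected side.

    Accepts a single 3-vector or an ``(n, 3)`` array.
    """
    a = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    if a.ndim == 1:
        return float(np.dot(plane.normal, a - plane.point))
    return (a - plane.point) @ plane.normal


def extreme_point(points, direction) -> np.ndarray:
    """Point of ``points`` maximizing the dot product with ``direction``.

    Ties are broken by first occurrence in input order (``np.argmax`` semantics).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("extreme_point requires a non-empty point set")
    d = _as_vec3(direction, "direction")
    return pts[int(np.argmax(pts @ d))].copy()


def rotate_about_axis(v, axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle_deg`` degrees."""
    v = _as_vec3(v, "v")
    a = _as_vec3(axis, "axis")
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    if abs(n - 1.0) > 1e-9:
        raise ValueError("rotation axis must be unit length")
    th = np.deg2rad(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(a, v) * np.sin(th)
        + a * np.dot(a, v) * (1.0 - np.cos(th))
    )


def fit_circle_2d(points, plane_name: str = "") -> Circle2D:
    """Algebraic (Kåsa) least-squares circle through 2D ``points``.

    Solves ``min sum((x-a)^2 + (y-b)^2 - r^2)^2`` via the linear system in
    ``(2a, 2b, r^2 - a^2 - b^2)``; exact when the points lie on a circle.

    Raises ``ValueError`` for fewer than 3 points or (near-)collinear input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("fit_circle_2d expects an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("fit_circle_2d requires at least 3 points")
    # centre the data for conditioning
    mean = pts.mean(axis=0)
    q = pts - mean
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    b = (q**2).sum(axis=1)
    sol, residuals, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    # collinearity check: the smallest singular value of the centred coordinate
    # block vanishes when all points lie on a line
    if np.linalg.svd(q, compute_uv=False)[-1] < 1e-8 * max(1.0, sv[0]):
        raise ValueError("fit_circle_2d: points are collinear within tolerance")
    center = sol[:2] + mean
    r2 = sol[2] + np.dot(sol[:2], sol[:2])
    if r2 <= 0:
        raise ValueError("fit_circle_2d: degenerate fit (non-positive radius)")
    return Circle2D(center=center, radius=float(np.sqrt(r2)), plane_name=plane_name)


def project_to_plane(p, origin, basis) -> np.ndarray:
    """Coordinates of ``p - origin`` in an orthonormal 2-vector ``basis``.

    ``basis`` is a pair of orthonormal 3-vectors; ``p`` may be ``(3,)`` or ``(n, 3)``.
    """
    e1 = _as_vec3(basis[0], "basis[0]")
    e2 = _as_vec3(basis[1], "basis[1]")
    if (
        abs(np.linalg.norm(e1) - 1) > _UNIT_TOL
        or abs(np.linalg.norm(e2) - 1) > _UNIT_TOL
        or abs(np.dot(e1, e2)) > _UNIT_TOL
    ):
        raise ValueError("basis must be orthonormal within 1e-9")
    origin = _as_vec3(origin, "origin")
    a = np.asarray(p, dtype=float)
    rel = a - origin
    if a.ndim == 1:
        return np.array([np.dot(rel, e1), np.dot(rel, e2)])
    return np.column_stack([rel @ e1, rel @ e2])
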