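"""Virtual bone cuts: plane construction and resected-thickness measurement.

Cut planes are oriented with the resected material on the positive halfspace.
Default resection depth is 9 mm, measured from the extreme point of the
surface along the plane normal, so the deepest compartment is resected by
exactly the nominal depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .anatomy import AnatomicalFrame, ReferenceAxisResult
from .geometry import Plane, extreme_point, signed_distance

__all__ = [
    "CutPlane",
    "ThicknessPair",
    "DEFAULT_DEPTH_MM",
    "build_distal_femoral_plane",
    "build_proximal_tibial_plane",
    "build_posterior_femoral_plane",
    "resected_thickness",
]

DEFAULT_DEPTH_MM = 9.0


@dataclass(frozen=True)
class CutPlane:
    plane: Plane
    cut_kind: str  # distal_femoral | proximal_tibial | posterior_femoral
    method: Optional[str] = None  # posterior reference tag, None for distal/tibial
    depth: float = DEFAULT_DEPTH_MM

    def __post_init__(self):
        if not self.depth > 0:
            raise ValueError("cut depth must be positive")

    def to_dict(self) -> dict:
        return {
            "cut_kind": self.cut_kind,
            "method": self.method,
            "depth": self.depth,
            **self.plane.to_dict(),
        }


@dataclass(frozen=True)
class ThicknessPair:
    medial: float
    lateral: float

    def __post_init__(self):
        if self.medial < 0 or self.lateral < 0:
            raise ValueError("thicknesses must be non-negative")


def _nonempty(points, what):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError(f"{what}: empty surface")
    return pts


def _depth_plane(points, normal, depth, cut_kind, method=None) -> CutPlane:
    """Plane with ``normal`` placed ``depth`` behind the extreme surface point."""
    p_star = extreme_point(points, normal)
    return CutPlane(
        plane=Plane(point=p_star - depth * np.asarray(normal, float), normal=normal),
        cut_kind=cut_kind,
        method=method,
        depth=depth,
    )


def build_distal_femoral_plane(
    femur_points, frame: AnatomicalFrame, depth: float = DEFAULT_DEPTH_MM
) -> CutPlane:
    """Distal cut perpendicular to the femoral mechanical axis, ``depth`` mm
    from the most distal condylar point; resected side is distal."""
    pts = _nonempty(femur_points, "distal femoral cut")
    return _depth_plane(pts, -frame.z, depth, "distal_femoral")


def build_proximal_tibial_plane(
    tibia_points, tibial_axis, depth: float = DEFAULT_DEPTH_MM
) -> CutPlane:
    """Tibial cut perpendicular to the tibial mechanical axis, ``depth`` mm
    from the most proximal plateau point; resected side is proximal."""
    pts = _nonempty(tibia_points, "proximal tibial cut")
    axis = np.asarray(tibial_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return _depth_plane(pts, axis, depth, "proximal_tibial")


def build_posterior_femoral_plane(
    femur_points,
    frame: AnatomicalFrame,
    ref: ReferenceAxisResult,
    depth: float = DEFAULT_DEPTH_MM,
) -> CutPlane:
    """Posterior cut parallel to a reference axis and perpendicular to the
    distal plane, ``depth`` mm from the globally most posterior condylar point."""
    pts = _nonempty(femur_points, "posterior femoral cut")
    d = np.asarray(ref.direction, dtype=float)
    if abs(np.dot(d, frame.z)) > 1e-6:
        raise ValueError("reference axis must be orthogonal to the mechanical axis")
    n = np.cross(frame.z, d)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("reference axis parallel to the mechanical axis")
    n = n / nn
    if np.dot(n, frame.y) > 0:
        n = -n  # resected side is posterior
    return _depth_plane(pts, n, depth, "posterior_femoral", method=ref.method)


def resected_thickness(medial_points, lateral_points, cut: CutPlane) -> ThicknessPair:
    """Maximal resected thickness per compartment under ``cut``.

    Thickness is the largest positive signed distance of the compartment's
    surface points to the cut plane, clamped at 0 when the plane misses the
    compartment entirely (a warning is emitted, not an error).
    """
    out = {}
    for name, points in (("medial", medial_points), ("lateral", lateral_points)):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            raise ValueError(f"resected_thickness: empty {name} compartment")
        d = float(np.max(signed_distance(cut.plane, pts)))
        if d < 0:
            warnings.warn(
                f"{cut.cut_kind} cut misses the {name} compartment entirely; thickness set to 0",
                stacklevel=2,
            )
            d = 0.0
        out[name] = d
    return ThicknessPair(medial=out["medial"], lateral=out["lateral"])
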