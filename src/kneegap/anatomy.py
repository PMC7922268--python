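"""Anatomical axes and frames.

Builds the femoral/tibial mechanical axes, the per-knee anatomical coordinate
frame, the signed hip-knee-ankle (HKA) angle and the four posterior femoral
reference axes (TEA, WSL perpendicular, PCA + external rotation, FEA).

Frame convention (the single convention used everywhere downstream):

* ``z`` — femoral mechanical axis, pointing proximal;
* ``x`` — medio-lateral, pointing **lateral** (side-aware);
* ``y`` — pointing **anterior** (side-aware sign of ``z × x``).

With ``x`` forced lateral and ``y`` forced anterior the triad is right-handed
for left knees and left-handed for right knees; the frame records its
handedness so that rotation senses (e.g. external rotation) stay anatomical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import extreme_point, fit_circle_2d, project_to_plane, Circle2D

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "ReferenceAxisResult",
    "femoral_mechanical_axis",
    "tibial_mechanical_axis",
    "build_frame",
    "compute_hka",
    "axis_tea",
    "axis_wsl",
    "axis_pca",
    "axis_fea",
    "METHODS",
]

METHODS = ("TEA", "WSL", "PCA", "FEA")

LANDMARK_NAMES = (
    "hip_center",
    "ankle_center",
    "intercondylar_notch",
    "proximal_tibia_center",
    "medial_epicondylar_sulcus",
    "lateral_epicondyle",
    "trochlear_groove_point",
)


def _vec(v, name):
    a = np.asarray(v, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValueError(f"landmark {name!r} must be a finite 3-vector")
    return a


@dataclass(frozen=True, eq=False)
class LandmarkSet:
    """Named anatomical landmarks of one knee, in world millimetres."""

    hip_center: np.ndarray
    ankle_center: np.ndarray
    intercondylar_notch: np.ndarray
    proximal_tibia_center: np.ndarray
    medial_epicondylar_sulcus: np.ndarray
    lateral_epicondyle: np.ndarray
    trochlear_groove_point: np.ndarray
    side: str = "right"

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, _vec(getattr(self, name), name))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.allclose(self.hip_center, self.intercondylar_notch):
            raise ValueError("hip_center coincides with intercondylar_notch")
        if np.allclose(self.proximal_tibia_center, self.ankle_center):
            raise ValueError("proximal_tibia_center coincides with ankle_center")

    def __eq__(self, other):
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return self.side == other.side and all(
            np.array_equal(getattr(self, n), getattr(other, n)) for n in LANDMARK_NAMES
        )

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "landmarks": {n: getattr(self, n).tolist() for n in LANDMARK_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        lm = d["landmarks"]
        return cls(side=d["side"], **{n: lm[n] for n in LANDMARK_NAMES})


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal femoral frame: origin at the intercondylar notch,
    ``z`` proximal, ``x`` lateral, ``y`` anterior."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    side: str = "right"

    @property
    def handedness(self) -> float:
        """+1 for a right-handed (x, y, z) triad, -1 for left-handed."""
        return float(np.sign(np.dot(np.cross(self.x, self.y), self.z)))

    def to_frame(self, pts):
        """World points -> frame coordinates (x lateral, y anterior, z proximal)."""
        a = np.asarray(pts, dtype=float)
        M = np.column_stack([self.x, self.y, self.z])
        return (a - self.origin) @ M

    def dir_to_frame(self, v):
        return np.asarray(v, dtype=float) @ np.column_stack([self.x, self.y, self.z])

    def dir_from_frame(self, u):
        return np.column_stack([self.x, self.y, self.z]) @ np.asarray(u, dtype=float)


@dataclass(frozen=True)
class ReferenceAxisResult:
    """A posterior femoral reference axis: unit world direction orthogonal to
    the frame's mechanical axis, oriented medial -> lateral."""

    method: str
    direction: np.ndarray
    diagnostics: dict = field(default_factory=dict, compare=False)


def femoral_mechanical_axis(landmarks: LandmarkSet) -> np.ndarray:
    """Unit vector from the intercondylar notch to the hip center (distal -> proximal)."""
    v = landmarks.hip_center - landmarks.intercondylar_notch
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("femoral mechanical axis endpoints coincide")
    return v / n


def tibial_mechanical_axis(landmarks: LandmarkSet) -> np.ndarray:
    """Unit vector from the ankle center to the proximal tibia center (distal -> proximal)."""
    v = landmarks.proximal_tibia_center - landmarks.ankle_center
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("tibial mechanical axis endpoints coincide")
    return v / n


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame from the mechanical axis and the epicondylar landmarks.

    ``x`` is the epicondylar vector (medial sulcus -> lateral epicondyle)
    orthogonalized against ``z``; ``y`` is ``z x x`` with its sign fixed per
    side so that it points anterior.
    """
    z = femoral_mechanical_axis(landmarks)
    epi = landmarks.lateral_epicondyle - landmarks.medial_epicondylar_sulcus
    x = epi - np.dot(epi, z) * z
    nx = np.linalg.norm(x)
    # reject epicondylar axes within 0.5 deg of the mechanical axis
    if nx < np.linalg.norm(epi) * np.sin(np.deg2rad(0.5)) or nx < 1e-9:
        raise ValueError("degenerate anatomy: epicondylar axis parallel to mechanical axis")
    x = x / nx
    y = np.cross(z, x)
    if landmarks.side == "right":
        y = -y  # z x x points posterior on a right knee
    return AnatomicalFrame(
        origin=landmarks.intercondylar_notch.copy(), x=x, y=y, z=z, side=landmarks.side
    )


def compute_hka(fem_axis, tib_axis, frame: AnatomicalFrame) -> float:
    """Signed HKA in degrees from coronal-plane projections of the two axes.

    Positive values are varus; the boundary 0 is classified downstream.
    """
    f = np.asarray(fem_axis, dtype=float)
    t = np.asarray(tib_axis, dtype=float)
    fx, fz = np.dot(f, frame.x), np.dot(f, frame.z)
    tx, tz = np.dot(t, frame.x), np.dot(t, frame.z)
    return float(np.degrees(np.arctan2(fx * tz - fz * tx, fx * tx + fz * tz)))


def _in_plane_lateral(v, frame: AnatomicalFrame, what: str) -> np.ndarray:
    """Project a world vector orthogonal to frame.z, normalize, orient lateral-positive."""
    u = np.asarray(v, dtype=float)
    u = u - np.dot(u, frame.z) * frame.z
    n = np.linalg.norm(u)
    if n < 1e-9:
        raise ValueError(f"{what}: direction parallel to the mechanical axis")
    u = u / n
    if np.dot(u, frame.x) < 0:
        u = -u
    return u


def axis_tea(landmarks: LandmarkSet, frame: AnatomicalFrame) -> ReferenceAxisResult:
    """Surgical transepicondylar axis: lateral epicondylar prominence to medial
    sulcus, projected into the axial plane."""
    d = _in_plane_lateral(
        landmarks.lateral_epicondyle - landmarks.medial_epicondylar_sulcus, frame, "TEA"
    )
    return ReferenceAxisResult(method="TEA", direction=d)


def axis_wsl(landmarks: LandmarkSet, frame: AnatomicalFrame) -> ReferenceAxisResult:
    """Whiteside-line cut reference: the in-plane perpendicular of the line
    from the deepest trochlear-groove point to the intercondylar notch."""
    w = landmarks.intercondylar_notch - landmarks.trochlear_groove_point
    w_ip = w - np.dot(w, frame.z) * frame.z
    n = np.linalg.norm(w_ip)
    if n < 1e-9:
        raise ValueError("WSL: trochlear line has no component orthogonal to the mechanical axis")
    w_ip = w_ip / n
    perp = np.cross(frame.z, w_ip)
    d = _in_plane_lateral(perp, frame, "WSL")
    return ReferenceAxisResult(method="WSL", direction=d, diagnostics={"ap_line": w_ip})


def _rotate_external(direction, frame: AnatomicalFrame, angle_deg: float) -> np.ndarray:
    """Rotate an in-plane direction externally (lateral end moves posterior)."""
    dx = np.dot(direction, frame.x)
    dy = np.dot(direction, frame.y)
    th = np.deg2rad(angle_deg)
    # in frame coordinates external rotation is clockwise in the (x, y) plane
    rx = dx * np.cos(th) + dy * np.sin(th)
    ry = -dx * np.sin(th) + dy * np.cos(th)
    return rx * frame.x + ry * frame.y


def axis_pca(
    medial_posterior,
    lateral_posterior,
    frame: AnatomicalFrame,
    external_rotation_deg: float = 3.0,
) -> ReferenceAxisResult:
    """Posterior condylar axis with external rotation.

    The raw PCA is tangent to the most posterior point of each condyle; the
    returned cut reference is the raw PCA rotated externally about the
    mechanical axis (lateral end moved posterior) by ``external_rotation_deg``.
    """
    med = np.atleast_2d(np.asarray(medial_posterior, dtype=float))
    lat = np.atleast_2d(np.asarray(lateral_posterior, dtype=float))
    if med.size == 0 or lat.size == 0:
        raise ValueError("PCA: posterior condylar regions must be non-empty")
    p_med = extreme_point(med, -frame.y)
    p_lat = extreme_point(lat, -frame.y)
    raw = _in_plane_lateral(p_lat - p_med, frame, "PCA")
    d = _rotate_external(raw, frame, external_rotation_deg)
    return ReferenceAxisResult(
        method="PCA",
        direction=d,
        diagnostics={
            "raw_pca": raw,
            "external_rotation_deg": external_rotation_deg,
            "posterior_point_medial": p_med,
            "posterior_point_lateral": p_lat,
        },
    )


def _fit_condyle_circle(points, frame, sagittal_normal, label) -> tuple[np.ndarray, Circle2D]:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 10:
        raise ValueError(f"FEA: condyle {label!r} needs >= 10 posterior articular points")
    # sagittal basis: anterior-ish and proximal, both orthogonal to the normal
    e1 = np.cross(frame.z, sagittal_normal)
    e1 = e1 / np.linalg.norm(e1)
    e2 = frame.z
    origin = frame.origin
    try:
        circ = fit_circle_2d(project_to_plane(pts, origin, (e1, e2)), plane_name=f"sagittal_{label}")
    except ValueError as exc:
        raise ValueError(f"FEA: degenerate circle fit for condyle {label!r}: {exc}") from exc
    ml = float(np.mean((pts - origin) @ sagittal_normal))
    center3 = origin + circ.center[0] * e1 + circ.center[1] * e2 + ml * sagittal_normal
    return center3, circ


def axis_fea(
    medial_posterior,
    lateral_posterior,
    frame: AnatomicalFrame,
    sagittal_normal=None,
) -> ReferenceAxisResult:
    """Flexion-extension axis: joins the centers of circles fitted to each
    posterior condyle's sagittal profile.

    ``sagittal_normal`` defaults to the TEA-projected medio-lateral axis
    (``frame.x`` when no TEA is supplied).
    """
    n = frame.x if sagittal_normal is None else np.asarray(sagittal_normal, dtype=float)
    n = n / np.linalg.norm(n)
    c_med, circ_med = _fit_condyle_circle(medial_posterior, frame, n, "medial")
    c_lat, circ_lat = _fit_condyle_circle(lateral_posterior, frame, n, "lateral")
    d = _in_plane_lateral(c_lat - c_med, frame, "FEA")
    return ReferenceAxisResult(
        method="FEA",
        direction=d,
        diagnostics={
            "circle_medial": circ_med,
            "circle_lateral": circ_lat,
            "center_medial": c_med,
            "center_lateral": c_lat,
        },
    )
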