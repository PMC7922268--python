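"""Parametric synthetic knee generator and cohort sampler.

Knees are assembled from analytic primitives in a canonical coordinate system
(x lateral, y anterior, z proximal, intercondylar notch at the origin):

* two distal condyles = spherical caps;
* two posterior condyles = sagittal circular-arc strips swept medio-laterally;
* a V-groove trochlea (cosmetic, never load-bearing for any cut);
* a tibia with two flat plateau facets and a skirt.

Cartilage is an outward offset of each articular primitive; compartment wear
thins it (distal/plateau wear in full, posterior femoral wear scaled by
``posterior_wear_fraction`` — weight-bearing erosion is extension-zone
dominant). Because every primitive is analytic, the generator emits exact
ground truth (axes, HKA, cut extremes, resected thicknesses, gaps) alongside
the meshes; the sampled grids contain the analytically extreme vertices, so
noise-free mesh measurements reproduce the closed forms exactly.

Right knees are mirrored in x so that a knee's world coordinates are
side-consistent; region labels stay anatomical (medial/lateral).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .anatomy import LandmarkSet

__all__ = ["KneeParams", "KneeModel", "CohortSpec", "generate_knee", "generate_cohort"]

FEMUR_REGIONS = (
    "femur_medial",
    "femur_lateral",
    "femur_posterior_medial_articular",
    "femur_posterior_lateral_articular",
    "femur_trochlea",
)
TIBIA_REGIONS = ("tibia_medial", "tibia_lateral")

# arc parameterisation: theta = 0 at the most distal point, 90 deg at the most
# posterior point; strips span ARC_MIN..ARC_MAX with the articular (circle-fit)
# region ARC_ARTICULAR_MIN..ARC_ARTICULAR_MAX. ARC_MIN = 40 guarantees the
# posterior arc never reaches below the distal sphere (distal extremes stay
# sphere-defined for all admissible parameters).
ARC_MIN, ARC_MAX = 40.0, 120.0
ARC_ARTICULAR_MIN, ARC_ARTICULAR_MAX = 40.0, 100.0


@dataclass(frozen=True)
class KneeParams:
    """Ground-truth parameters of one synthetic knee. Lengths in mm, angles in degrees."""

    side: str = "right"
    hka_deg: float = 0.0  # > 0 varus
    # bone geometry
    r_distal: float = 21.0  # distal condyle sphere radius (bone)
    r_posterior: float = 19.0  # posterior condyle arc radius (bone)
    distal_asym: float = 0.0  # > 0: medial condyle reaches further distal
    posterior_asym: float = 0.0  # > 0: medial condyle reaches further posterior
    condyle_sep: float = 44.0  # medio-lateral distance between condyle centres
    condyle_halfwidth: float = 8.0
    epicondylar_width: float = 80.0
    tea_rotation_deg: float = 0.0  # TEA external rotation w.r.t. the condylar centre line
    trochlea_rotation_deg: float = 0.0  # WSL-perpendicular external rotation
    # cartilage
    cartilage: float = 2.0  # per-surface cartilage thickness
    wear_fem_med: float = 0.0  # distal femoral cartilage wear per compartment
    wear_fem_lat: float = 0.0
    wear_tib_med: float = 0.0
    wear_tib_lat: float = 0.0
    posterior_wear_fraction: float = 0.25
    # tibia
    tibial_slope_deg: float = 0.0
    tibial_asym: float = 0.0  # > 0: medial plateau lower (bone loss)
    # discretisation / noise
    noise_sigma: float = 0.0
    n_arc: int = 41  # theta samples; the step must divide 90 - ARC_MIN so the
    # posterior extreme (theta = 90) is an exact grid vertex
    n_strip: int = 9  # medio-lateral samples per condylar strip
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if min(self.r_distal, self.r_posterior) <= 5:
            raise ValueError("condylar radii must exceed 5 mm")
        if self.cartilage < 0 or self.noise_sigma < 0:
            raise ValueError("cartilage and noise_sigma must be non-negative")
        budget = self.cartilage + 2.0  # cartilage plus allowed bone loss
        for name in ("wear_fem_med", "wear_fem_lat", "wear_tib_med", "wear_tib_lat"):
            w = getattr(self, name)
            if not 0 <= w <= budget:
                raise ValueError(f"{name}={w} outside [0, {budget}] wear budget")
        if not 0 <= self.posterior_wear_fraction <= 1:
            raise ValueError("posterior_wear_fraction must be in [0, 1]")
        # the posterior arc must not undercut the distal sphere, otherwise the
        # distal extreme would no longer be sphere-defined
        cos_min = np.cos(np.deg2rad(ARC_MIN))
        if (
            self.R_post_med * cos_min >= self.R_distal_med
            or self.R_post_lat * cos_min >= self.R_distal_lat
        ):
            raise ValueError(
                "geometrically impossible parameters: posterior condyle would "
                "reach below the distal condyle"
            )

    # effective (bone + remaining cartilage) radii -------------------------------
    @property
    def R_distal_med(self) -> float:
        return self.r_distal + self.distal_asym / 2 + self.cartilage - self.wear_fem_med

    @property
    def R_distal_lat(self) -> float:
        return self.r_distal - self.distal_asym / 2 + self.cartilage - self.wear_fem_lat

    @property
    def R_post_med(self) -> float:
        return (
            self.r_posterior
            + self.posterior_asym / 2
            + self.cartilage
            - self.posterior_wear_fraction * self.wear_fem_med
        )

    @property
    def R_post_lat(self) -> float:
        return (
            self.r_posterior
            - self.posterior_asym / 2
            + self.cartilage
            - self.posterior_wear_fraction * self.wear_fem_lat
        )


@dataclass
class KneeModel:
    """Synthetic knee: meshes, landmarks, region labels and ground truth."""

    femur_vertices: np.ndarray
    femur_faces: np.ndarray
    tibia_vertices: np.ndarray
    tibia_faces: np.ndarray
    landmarks: LandmarkSet
    regions: dict
    truth: dict
    params: Optional[KneeParams] = None
    knee_id: str = "knee"

    def femur_region(self, name: str) -> np.ndarray:
        return self.femur_vertices[self.regions[name]]

    def tibia_region(self, name: str) -> np.ndarray:
        return self.tibia_vertices[self.regions[name]]


# fixed layout constants (canonical coordinates)
_Z_CONDYLE = -30.0  # z of distal sphere / posterior arc centres
_Y_POST = -8.0  # y of posterior arc centres
_Z_EPI = -30.0
_Z_PLATEAU = -57.0  # tibial plateau bone level
_Z_TIBIA_CENTER = -60.0
_FEMUR_LEN = 400.0
_TIBIA_LEN = 340.0
_GROOVE_DIST = 18.0  # distance of the trochlear groove point anterior of the notch
_Z_GROOVE = -28.0


def _grid_faces(nu: int, nv: int, offset: int) -> np.ndarray:
    """Two triangles per quad of an (nu x nv) vertex grid stored row-major."""
    i, j = np.meshgrid(np.arange(nu - 1), np.arange(nv - 1), indexing="ij")
    a = (i * nv + j).ravel() + offset
    b = a + nv
    return np.concatenate([np.stack([a, b, a + 1], 1), np.stack([a + 1, b, b + 1], 1)])


class _MeshBuilder:
    def __init__(self):
        self.vertices = []
        self.faces = []
        self.regions = {}
        self._n = 0

    def add_grid(self, verts: np.ndarray, nu: int, nv: int, labels=()):
        idx = np.arange(self._n, self._n + len(verts))
        self.faces.append(_grid_faces(nu, nv, self._n))
        self.vertices.append(verts)
        self._n += len(verts)
        for lab in labels:
            self.regions.setdefault(lab, []).append(idx)
        return idx

    def build(self):
        v = np.concatenate(self.vertices)
        f = np.concatenate(self.faces)
        regions = {k: np.concatenate(ix) for k, ix in self.regions.items()}
        return v, f, regions


def _sphere_cap(center, radius, n_phi=12, n_psi=24):
    """Lower spherical cap (polar angle <= 55 deg from the distal pole); the
    pole vertex is on the grid so the distal extreme is exact."""
    phi = np.deg2rad(np.linspace(0.0, 55.0, n_phi))
    psi = np.deg2rad(np.linspace(0.0, 360.0, n_psi))
    P, S = np.meshgrid(phi, psi, indexing="ij")
    pts = np.stack(
        [np.sin(P) * np.cos(S), np.sin(P) * np.sin(S), -np.cos(P)], axis=-1
    ).reshape(-1, 3)
    return center + radius * pts, n_phi, n_psi


def _arc_strip(x_lo, x_hi, center_yz, radius, n_arc, n_strip):
    """Posterior condylar strip: sagittal circle arc swept along x.

    theta grid contains 90 deg exactly and the strip edges are on the x grid,
    so posterior extremes under any axial-plane cut normal are exact.
    """
    theta = np.deg2rad(np.linspace(ARC_MIN, ARC_MAX, n_arc))
    xs = np.linspace(x_lo, x_hi, n_strip)
    X, T = np.meshgrid(xs, theta, indexing="ij")
    y = center_yz[0] - radius * np.sin(T)
    z = center_yz[1] - radius * np.cos(T)
    verts = np.stack([X, y, z], axis=-1).reshape(-1, 3)
    theta_deg = np.rad2deg(T).ravel()
    articular = (theta_deg >= ARC_ARTICULAR_MIN - 1e-9) & (theta_deg <= ARC_ARTICULAR_MAX + 1e-9)
    return verts, articular, len(xs), n_arc


def _trochlea(groove_point, rotation_deg, n=8):
    """Two planar walls meeting at the groove line (anterior, never extreme
    for any distal/posterior/proximal query)."""
    tau = np.deg2rad(rotation_deg)
    ap = np.array([np.sin(tau), np.cos(tau), 0.0])  # groove deepest line direction (anterior)
    lat = np.array([np.cos(tau), -np.sin(tau), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    t = np.linspace(-6.0, 6.0, n)[:, None]  # along the groove (proximal-distal-ish)
    s = np.linspace(0.0, 10.0, 4)[None, :, None]
    line = groove_point + t * (0.55 * ap + up * 1.6)  # groove climbs anterior-proximal
    walls = []
    for sgn in (-1.0, 1.0):
        wall = line[:, None, :] + s * (sgn * 0.8 * lat + 0.6 * ap)
        walls.append(wall.reshape(-1, 3))
    return walls, n, 4


def _facet(center_xy, half_x, y_lo, y_hi, z_level, slope_deg, n=7, m=9):
    """Flat (optionally sloped) tibial plateau facet; corners on the grid."""
    xs = np.linspace(center_xy[0] - half_x, center_xy[0] + half_x, n)
    ys = np.linspace(y_lo, y_hi, m)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    # posterior slope: plateau drops towards posterior, peak at the anterior edge
    z = z_level + np.tan(np.deg2rad(slope_deg)) * (Y - y_hi)
    return np.stack([X, Y, z], axis=-1).reshape(-1, 3), n, m


def _rotate_y(points, angle_deg, pivot):
    """Rotate about the canonical y axis through ``pivot``."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return (np.asarray(points) - pivot) @ R.T + pivot


def _external_rot_dir(angle_deg):
    """Unit in-plane direction at ``angle_deg`` of external rotation (lateral
    end posterior) from the medio-lateral axis, canonical coordinates."""
    th = np.deg2rad(angle_deg)
    return np.array([np.cos(th), -np.sin(th), 0.0])


def _posterior_truth(params: KneeParams, ref_dir, depth):
    """Closed-form posterior resected thicknesses for a cut parallel to the
    in-plane reference direction ``ref_dir`` (canonical coords, lateral-positive)."""
    n = np.array([ref_dir[1], -ref_dir[0], 0.0])
    if n[1] > 0:
        n = -n
    xc = params.condyle_sep / 2
    hw = params.condyle_halfwidth
    d = {}
    for comp, sign, R in (
        ("medial", -1.0, params.R_post_med),
        ("lateral", 1.0, params.R_post_lat),
    ):
        edges = [sign * xc - hw, sign * xc + hw]
        d[comp] = max(x * n[0] for x in edges) + (_Y_POST - R) * n[1]
    d_ref = max(d.values())
    return {c: depth - (d_ref - v) for c, v in d.items()}


def _canon_to_frame(v, tea_rotation_deg):
    """Canonical coordinates -> anatomical-frame coordinates.

    The anatomical frame's x axis is the TEA projection, i.e. the canonical
    axes rotated externally by ``tea_rotation_deg`` about z.
    """
    te = np.deg2rad(tea_rotation_deg)
    v = np.asarray(v, dtype=float)
    return np.array(
        [
            v[0] * np.cos(te) - v[1] * np.sin(te),
            v[0] * np.sin(te) + v[1] * np.cos(te),
            v[2],
        ]
    )


def compute_truth(params: KneeParams, depth: float = 9.0, pca_rotation: float = 3.0) -> dict:
    """Analytic ground truth for a noise-free knee.

    Directions and positions are given in anatomical-frame coordinates
    (x lateral = TEA projection, y anterior, z proximal, origin at the notch),
    matching what the measurement pipeline reports. ``hka`` is the HKA as
    measured in the frame's coronal plane; ``hka_true`` is the imposed tibial
    tilt (they differ by O(te^2) when the TEA is rotated against the condyles).
    """
    xc = params.condyle_sep / 2
    te = params.tea_rotation_deg
    hka_measured = np.degrees(
        np.arctan2(
            np.sin(np.deg2rad(params.hka_deg)) * np.cos(np.deg2rad(te)),
            np.cos(np.deg2rad(params.hka_deg)),
        )
    )
    truth: dict = {
        "hka": hka_measured,
        "hka_true": params.hka_deg,
        "group": "varus" if params.hka_deg > 0 else "valgus",
        "side": params.side,
        "noise_free": params.noise_sigma == 0,
        "depth": depth,
        "pca_rotation": pca_rotation,
    }
    # reference axis directions, canonical coordinates (x lateral, y anterior)
    tea_c = _external_rot_dir(te)
    wsl_c = _external_rot_dir(params.trochlea_rotation_deg)
    pca_raw_c = np.array([params.condyle_sep, params.R_post_med - params.R_post_lat, 0.0])
    pca_raw_c /= np.linalg.norm(pca_raw_c)
    th = np.deg2rad(pca_rotation)
    pca_c = np.array(
        [
            pca_raw_c[0] * np.cos(th) + pca_raw_c[1] * np.sin(th),
            -pca_raw_c[0] * np.sin(th) + pca_raw_c[1] * np.cos(th),
            0.0,
        ]
    )
    fea_c = np.array([1.0, 0.0, 0.0])
    truth["tea_dir"] = _canon_to_frame(tea_c, te)
    truth["wsl_dir"] = _canon_to_frame(wsl_c, te)
    truth["pca_raw_dir"] = _canon_to_frame(pca_raw_c, te)
    truth["pca_dir"] = _canon_to_frame(pca_c, te)
    truth["fea_dir"] = _canon_to_frame(fea_c, te)
    truth["fea_center_medial"] = _canon_to_frame(np.array([-xc, _Y_POST, _Z_CONDYLE]), te)
    truth["fea_center_lateral"] = _canon_to_frame(np.array([xc, _Y_POST, _Z_CONDYLE]), te)
    truth["fea_radius_medial"] = params.R_post_med
    truth["fea_radius_lateral"] = params.R_post_lat

    # distal femoral cut
    z_med = _Z_CONDYLE - params.R_distal_med
    z_lat = _Z_CONDYLE - params.R_distal_lat
    z_min = min(z_med, z_lat)
    fem_ext = {"medial": depth - (z_med - z_min), "lateral": depth - (z_lat - z_min)}
    truth["femoral_extension_thickness"] = fem_ext

    # tibial cut (plateau heights along the tibial axis are tilt-invariant;
    # with a posterior slope the peak sits at the anterior facet edge, at the
    # nominal level)
    h_med = _Z_PLATEAU + params.cartilage - params.wear_tib_med - params.tibial_asym
    h_lat = _Z_PLATEAU + params.cartilage - params.wear_tib_lat
    h_max = max(h_med, h_lat)
    tib = {"medial": depth - (h_max - h_med), "lateral": depth - (h_max - h_lat)}
    truth["tibial_thickness"] = tib

    # posterior cuts per method (canonical directions: the cut geometry is
    # coordinate-independent, the resulting thicknesses are scalars)
    refs = {"TEA": tea_c, "WSL": wsl_c, "PCA": pca_c, "FEA": fea_c}
    truth["femoral_flexion_thickness"] = {
        m: _posterior_truth(params, r, depth) for m, r in refs.items()
    }
    truth["gaps"] = {
        m: {
            "ext_med": fem_ext["medial"] + tib["medial"],
            "ext_lat": fem_ext["lateral"] + tib["lateral"],
            "flex_med": flex["medial"] + tib["medial"],
            "flex_lat": flex["lateral"] + tib["lateral"],
        }
        for m, flex in truth["femoral_flexion_thickness"].items()
    }
    return truth


def generate_knee(params: KneeParams, knee_id: str = "knee") -> KneeModel:
    """Build the triangle meshes, landmarks, region labels and ground truth for
    one knee. Deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    xc = params.condyle_sep / 2
    hw = params.condyle_halfwidth

    fb = _MeshBuilder()
    for comp, sign, R_d, R_p in (
        ("medial", -1.0, params.R_distal_med, params.R_post_med),
        ("lateral", 1.0, params.R_distal_lat, params.R_post_lat),
    ):
        cap, nu, nv = _sphere_cap(np.array([sign * xc, 0.0, _Z_CONDYLE]), R_d)
        fb.add_grid(cap, nu, nv, labels=(f"femur_{comp}",))
        strip, articular, nu, nv = _arc_strip(
            sign * xc - hw, sign * xc + hw, (_Y_POST, _Z_CONDYLE), R_p,
            params.n_arc, params.n_strip,
        )
        idx = fb.add_grid(strip, nu, nv, labels=(f"femur_{comp}",))
        fb.regions.setdefault(f"femur_posterior_{comp}_articular", []).append(idx[articular])

    tau = np.deg2rad(params.trochlea_rotation_deg)
    groove_point = np.array(
        [_GROOVE_DIST * np.sin(tau), _GROOVE_DIST * np.cos(tau), _Z_GROOVE]
    )
    walls, nu, nv = _trochlea(groove_point, params.trochlea_rotation_deg)
    for wall in walls:
        fb.add_grid(wall, nu, nv, labels=("femur_trochlea",))
    femur_v, femur_f, femur_regions = fb.build()

    tb = _MeshBuilder()
    for comp, sign, wear, extra in (
        ("medial", -1.0, params.wear_tib_med, params.tibial_asym),
        ("lateral", 1.0, params.wear_tib_lat, 0.0),
    ):
        z_level = _Z_PLATEAU + params.cartilage - wear - extra
        facet, nu, nv = _facet(
            (sign * xc, -8.0), 7.0, -18.0, 2.0, z_level, params.tibial_slope_deg
        )
        tb.add_grid(facet, nu, nv, labels=(f"tibia_{comp}",))
        # skirt: vertical wall dropping from the anterior facet edge
        xs = np.linspace(sign * xc - 7.0, sign * xc + 7.0, 5)
        zs = np.linspace(z_level, -90.0, 4)
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        wall = np.stack([X, np.full_like(X, 2.0), Z], axis=-1).reshape(-1, 3)
        tb.add_grid(wall, 5, 4)
    tibia_v, tibia_f, tibia_regions = tb.build()

    # impose the coronal deformity: rotate the tibia (mesh + landmarks) about
    # the knee centre so the tibial mechanical axis tilts by hka
    pivot = np.array([0.0, 0.0, _Z_TIBIA_CENTER])
    tibia_v = _rotate_y(tibia_v, -params.hka_deg, pivot)
    ankle = _rotate_y(np.array([0.0, 0.0, _Z_TIBIA_CENTER - _TIBIA_LEN]), -params.hka_deg, pivot)

    te = np.deg2rad(params.tea_rotation_deg)
    epi_dir = np.array([np.cos(te), -np.sin(te), 0.0])
    we = params.epicondylar_width / 2
    landmarks_c = {
        "hip_center": np.array([0.0, 0.0, _FEMUR_LEN]),
        "ankle_center": ankle,
        "intercondylar_notch": np.zeros(3),
        "proximal_tibia_center": pivot,
        "medial_epicondylar_sulcus": -we * epi_dir + np.array([0.0, 0.0, _Z_EPI]),
        "lateral_epicondyle": we * epi_dir + np.array([0.0, 0.0, _Z_EPI]),
        "trochlear_groove_point": groove_point,
    }

    if params.noise_sigma > 0:
        femur_v = femur_v + rng.normal(0.0, params.noise_sigma, femur_v.shape)
        tibia_v = tibia_v + rng.normal(0.0, params.noise_sigma, tibia_v.shape)

    # canonical coordinates have x lateral; right knees are mirrored in world x
    if params.side == "right":
        femur_v = femur_v * np.array([-1.0, 1.0, 1.0])
        tibia_v = tibia_v * np.array([-1.0, 1.0, 1.0])
        landmarks_c = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in landmarks_c.items()}
        femur_f = femur_f[:, ::-1]
        tibia_f = tibia_f[:, ::-1]

    landmarks = LandmarkSet(side=params.side, **landmarks_c)
    regions = {**femur_regions, **tibia_regions}
    truth = compute_truth(params)
    return KneeModel(
        femur_vertices=femur_v,
        femur_faces=femur_f,
        tibia_vertices=tibia_v,
        tibia_faces=tibia_f,
        landmarks=landmarks,
        regions=regions,
        truth=truth,
        params=params,
        knee_id=knee_id,
    )


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a synthetic OA cohort.

    Defaults emulate the target population: HKA 8.2 +/- 3.6 deg in the varus
    group (range-truncated at 0.1..22.7) and -3.9 +/- 3.4 deg in the valgus
    group (-15.7..-0.1), with wear biased to the overloaded compartment
    (medial for varus, lateral for valgus).
    """

    n_varus: int = 631
    n_valgus: int = 107
    seed: int = 0
    hka_varus: tuple = (8.2, 3.6, 0.1, 22.7)  # (mean, sd, lo, hi)
    hka_valgus: tuple = (-3.9, 3.4, -15.7, -0.1)
    wear_fem_worn: tuple = (1.8, 0.8, 0.0, 3.5)
    wear_tib_worn: tuple = (1.5, 0.8, 0.0, 3.5)
    wear_intact: tuple = (0.2, 0.2, 0.0, 1.0)
    distal_asym: tuple = (0.5, 0.7, -2.0, 2.0)
    posterior_asym: tuple = (1.0, 0.8, -1.5, 3.0)
    tea_rotation_deg: tuple = (1.5, 1.2, -2.0, 5.0)
    trochlea_rotation_deg: tuple = (0.0, 2.0, -5.0, 5.0)
    tibial_slope_deg: tuple = (2.0, 1.5, 0.0, 7.0)
    noise_sigma: float = 0.0
    mesh_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_varus < 0 or self.n_valgus < 0:
            raise ValueError("cohort counts must be non-negative")
        for name in (
            "hka_varus", "hka_valgus", "wear_fem_worn", "wear_tib_worn",
            "wear_intact", "distal_asym", "posterior_asym", "tea_rotation_deg",
            "trochlea_rotation_deg", "tibial_slope_deg",
        ):
            mean, sd, lo, hi = getattr(self, name)
            if sd < 0 or lo > hi:
                raise ValueError(f"invalid distribution tuple for {name}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown cohort spec key(s): {sorted(bad)}")
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)


def _draw(rng, dist):
    mean, sd, lo, hi = dist
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_params(spec: CohortSpec, group: str, rng: np.random.Generator) -> KneeParams:
    """Draw one knee's parameters for the given alignment group."""
    varus = group == "varus"
    hka = _draw(rng, spec.hka_varus if varus else spec.hka_valgus)
    wf = _draw(rng, spec.wear_fem_worn)
    wt = _draw(rng, spec.wear_tib_worn)
    wo_f = _draw(rng, spec.wear_intact)
    wo_t = _draw(rng, spec.wear_intact)
    return KneeParams(
        side=("right" if rng.random() < 0.5 else "left"),
        hka_deg=hka,
        distal_asym=_draw(rng, spec.distal_asym),
        posterior_asym=_draw(rng, spec.posterior_asym),
        tea_rotation_deg=_draw(rng, spec.tea_rotation_deg),
        trochlea_rotation_deg=_draw(rng, spec.trochlea_rotation_deg),
        tibial_slope_deg=_draw(rng, spec.tibial_slope_deg),
        wear_fem_med=wf if varus else wo_f,
        wear_fem_lat=wo_f if varus else wf,
        wear_tib_med=wt if varus else wo_t,
        wear_tib_lat=wo_t if varus else wt,
        noise_sigma=spec.noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
        **spec.mesh_overrides,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[KneeModel], pd.DataFrame]:
    """Sample and build a full cohort; returns the knees and a truth table of
    every drawn parameter. Reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    knees = []
    rows = []
    groups = ["varus"] * spec.n_varus + ["valgus"] * spec.n_valgus
    for i, group in enumerate(groups):
        params = sample_params(spec, group, rng)
        knee_id = f"{group}_{i:04d}"
        knees.append(generate_knee(params, knee_id=knee_id))
        rows.append({"knee_id": knee_id, "group": group, **asdict(params)})
    return knees, pd.DataFrame(rows)
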