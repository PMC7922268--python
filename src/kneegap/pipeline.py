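"""Per-knee simulation pipeline: landmarks -> frame -> axes -> cuts -> gaps.

Produces one :class:`~kneegap.gaps.ImbalanceRecord` per knee and posterior
reference method. The extension (distal + tibial) cuts are method-independent
and computed once per knee.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import anatomy
from .anatomy import METHODS, build_frame, compute_hka, femoral_mechanical_axis, tibial_mechanical_axis
from .cohort import KneeModel
from .gaps import ImbalanceRecord, classify_alignment, gap_distances
from .resection import (
    DEFAULT_DEPTH_MM,
    build_distal_femoral_plane,
    build_posterior_femoral_plane,
    build_proximal_tibial_plane,
    resected_thickness,
)

__all__ = ["simulate_knee", "simulate_cohort", "records_to_frame", "RESULT_COLUMNS"]

RESULT_COLUMNS = [
    "knee_id",
    "side",
    "group",
    "hka",
    "method",
    "ext_med",
    "ext_lat",
    "flex_med",
    "flex_lat",
    "mli_ext",
    "mli_flex",
    "fei_med",
    "fei_lat",
]


def _compartments(model: KneeModel):
    """Medial/lateral femoral and tibial compartment point sets.

    Uses generator region labels when present, otherwise falls back to the
    sign of the frame-x coordinate relative to the notch.
    """
    if "femur_medial" in model.regions:
        return (
            model.femur_region("femur_medial"),
            model.femur_region("femur_lateral"),
            model.tibia_region("tibia_medial"),
            model.tibia_region("tibia_lateral"),
        )
    frame = build_frame(model.landmarks)
    fx = (model.femur_vertices - frame.origin) @ frame.x
    tx = (model.tibia_vertices - frame.origin) @ frame.x
    return (
        model.femur_vertices[fx < 0],
        model.femur_vertices[fx >= 0],
        model.tibia_vertices[tx < 0],
        model.tibia_vertices[tx >= 0],
    )


def _posterior_articular_fallback(model: KneeModel, frame):
    """Heuristic posterior articular candidates for unlabeled meshes: the most
    posterior band of each compartment (frame-y below 70% of the posterior
    extreme), which isolates the posterior condylar facets from the distal
    weight-bearing surface."""
    rel = model.femur_vertices - frame.origin
    x = rel @ frame.x
    y = rel @ frame.y
    z = rel @ frame.z
    candidates = (y < 0) & (z < 0)
    y_min = y[candidates].min()
    band = candidates & (y <= 0.7 * y_min)
    med = model.femur_vertices[band & (x < 0)]
    lat = model.femur_vertices[band & (x >= 0)]
    return med, lat


def reference_axes(model: KneeModel, frame, pca_rotation: float = 3.0) -> dict:
    """The four posterior reference axes of a knee."""
    if "femur_posterior_medial_articular" in model.regions:
        post_med = model.femur_region("femur_posterior_medial_articular")
        post_lat = model.femur_region("femur_posterior_lateral_articular")
    else:
        post_med, post_lat = _posterior_articular_fallback(model, frame)
    tea = anatomy.axis_tea(model.landmarks, frame)
    return {
        "TEA": tea,
        "WSL": anatomy.axis_wsl(model.landmarks, frame),
        "PCA": anatomy.axis_pca(post_med, post_lat, frame, external_rotation_deg=pca_rotation),
        "FEA": anatomy.axis_fea(post_med, post_lat, frame, sagittal_normal=tea.direction),
    }


def simulate_knee(
    model: KneeModel,
    depth: float = DEFAULT_DEPTH_MM,
    pca_rotation: float = 3.0,
    methods: Iterable[str] = METHODS,
) -> list[ImbalanceRecord]:
    """Run the full measured-resection simulation for one knee."""
    frame = build_frame(model.landmarks)
    fem_axis = femoral_mechanical_axis(model.landmarks)
    tib_axis = tibial_mechanical_axis(model.landmarks)
    hka = compute_hka(fem_axis, tib_axis, frame)
    group = classify_alignment(hka)

    fem_med, fem_lat, tib_med, tib_lat = _compartments(model)
    fem_all = np.vstack([fem_med, fem_lat])
    tib_all = np.vstack([tib_med, tib_lat])

    distal = build_distal_femoral_plane(fem_all, frame, depth=depth)
    tibial = build_proximal_tibial_plane(tib_all, tib_axis, depth=depth)
    fem_ext = resected_thickness(fem_med, fem_lat, distal)
    tib_th = resected_thickness(tib_med, tib_lat, tibial)

    axes = reference_axes(model, frame, pca_rotation=pca_rotation)
    records = []
    for method in methods:
        post = build_posterior_femoral_plane(fem_all, frame, axes[method], depth=depth)
        fem_flex = resected_thickness(fem_med, fem_lat, post)
        gaps = gap_distances(fem_ext, fem_flex, tib_th, method=method)
        records.append(
            ImbalanceRecord(
                knee_id=model.knee_id, group=group, hka=hka, method=method, gaps=gaps
            )
        )
    return records


def records_to_frame(records: Iterable[ImbalanceRecord], sides: Optional[dict] = None) -> pd.DataFrame:
    """Flatten imbalance records into the stable per-knee x method results table."""
    rows = []
    for r in records:
        rows.append(
            {
                "knee_id": r.knee_id,
                "side": (sides or {}).get(r.knee_id, ""),
                "group": r.group,
                "hka": r.hka,
                "method": r.method,
                "ext_med": r.gaps.ext_med,
                "ext_lat": r.gaps.ext_lat,
                "flex_med": r.gaps.flex_med,
                "flex_lat": r.gaps.flex_lat,
                "mli_ext": r.mli_ext,
                "mli_flex": r.mli_flex,
                "fei_med": r.fei_med,
                "fei_lat": r.fei_lat,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def simulate_cohort(
    models: Iterable[KneeModel],
    depth: float = DEFAULT_DEPTH_MM,
    pca_rotation: float = 3.0,
) -> pd.DataFrame:
    """Simulate every knee of a cohort; one row per knee x method."""
    records = []
    sides = {}
    for model in models:
        sides[model.knee_id] = model.landmarks.side
        records.extend(simulate_knee(model, depth=depth, pca_rotation=pca_rotation))
    return records_to_frame(records, sides=sides)
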