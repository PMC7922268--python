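"""Readers and writers for every on-disk artifact.

Meshes are ASCII PLY (preferred: preserves vertex order, so region labels can
reference vertex indices) or ASCII STL; landmarks and cut planes are JSON;
cohort specs are YAML; results and truth tables are CSV.

Landmark JSON schema (version 1)::

    {"schema_version": 1,
     "side": "right" | "left",
     "landmarks": {name: [x, y, z]},          # mm
     "regions": {region_name: [vertex indices]}}

Region names starting with ``femur_``/``tibia_`` index into the femur/tibia
vertex arrays respectively.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import LandmarkSet
from .cohort import CohortSpec, KneeModel
from .pipeline import RESULT_COLUMNS

__all__ = [
    "write_ply",
    "read_ply",
    "write_stl",
    "read_stl",
    "write_landmarks",
    "read_landmarks",
    "save_knee",
    "load_knee",
    "load_cohort_spec",
    "save_cohort_spec",
    "write_results",
    "read_results",
]

LANDMARK_SCHEMA_VERSION = 1


# ----------------------------------------------------------------- meshes ---

def write_ply(path, vertices, faces) -> None:
    """ASCII PLY; vertex order is preserved exactly."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path):
    """Minimal ASCII PLY reader for files produced by :func:`write_ply`."""
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        for line in fh:
            tok = line.split()
            if tok[:2] == ["element", "vertex"]:
                n_vert = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                n_face = int(tok[2])
            elif tok[0] == "format" and tok[1] != "ascii":
                raise ValueError(f"{path}: only ASCII PLY is supported")
            elif tok[0] == "end_header":
                break
        vertices = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        faces = np.array(
            [[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)],
            dtype=int,
        )
    if len(vertices) != n_vert or len(faces) != n_face:
        raise ValueError(f"{path}: truncated PLY file")
    return vertices, faces


def write_stl(path, vertices, faces, name: str = "surface") -> None:
    """ASCII STL (vertex indexing is lost; use PLY when regions matter)."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for facet, nv in zip(tri, n):
            fh.write(f"facet normal {nv[0]:.9g} {nv[1]:.9g} {nv[2]:.9g}\n outer loop\n")
            for v in facet:
                fh.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write(f"endsolid {name}\n")


def read_stl(path):
    """ASCII STL reader; returns (vertices, faces) with duplicated vertices merged."""
    verts = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if tok and tok[0] == "vertex":
                verts.append([float(x) for x in tok[1:4]])
    if not verts or len(verts) % 3:
        raise ValueError(f"{path}: malformed ASCII STL")
    flat = np.asarray(verts, dtype=float)
    uniq, inverse = np.unique(flat.round(6), axis=0, return_inverse=True)
    return uniq, inverse.reshape(-1, 3)


# -------------------------------------------------------------- landmarks ---

def write_landmarks(path, landmarks: LandmarkSet, regions: dict | None = None) -> None:
    doc = {
        "schema_version": LANDMARK_SCHEMA_VERSION,
        **landmarks.to_dict(),
        "regions": {k: np.asarray(v).tolist() for k, v in (regions or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_landmarks(path) -> tuple[LandmarkSet, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != LANDMARK_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported landmark schema version {version!r}")
    landmarks = LandmarkSet.from_dict(doc)
    regions = {k: np.asarray(v, dtype=int) for k, v in doc.get("regions", {}).items()}
    return landmarks, regions


# ------------------------------------------------------------------ knees ---

def save_knee(model: KneeModel, out_dir, mesh_format: str = "ply") -> dict:
    """Write one knee's meshes + landmark JSON; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for bone in ("femur", "tibia"):
        v = getattr(model, f"{bone}_vertices")
        f = getattr(model, f"{bone}_faces")
        path = out / f"{model.knee_id}_{bone}.{mesh_format}"
        if mesh_format == "ply":
            write_ply(path, v, f)
        elif mesh_format == "stl":
            write_stl(path, v, f, name=f"{model.knee_id}_{bone}")
        else:
            raise ValueError(f"unsupported mesh format {mesh_format!r}")
        files[bone] = path.name
    lm_path = out / f"{model.knee_id}_landmarks.json"
    write_landmarks(lm_path, model.landmarks, model.regions)
    files["landmarks"] = lm_path.name
    return files


def load_knee(in_dir, knee_id: str, mesh_format: str = "ply") -> KneeModel:
    """Reload a knee written by :func:`save_knee` (ground truth is not on disk)."""
    reader = read_ply if mesh_format == "ply" else read_stl
    in_dir = Path(in_dir)
    femur_v, femur_f = reader(in_dir / f"{knee_id}_femur.{mesh_format}")
    tibia_v, tibia_f = reader(in_dir / f"{knee_id}_tibia.{mesh_format}")
    landmarks, regions = read_landmarks(in_dir / f"{knee_id}_landmarks.json")
    if mesh_format == "stl":
        # STL does not preserve vertex order; index-based regions are
        # meaningless and the pipeline falls back to geometric heuristics
        regions = {}
    return KneeModel(
        femur_vertices=femur_v,
        femur_faces=femur_f,
        tibia_vertices=tibia_v,
        tibia_faces=tibia_f,
        landmarks=landmarks,
        regions=regions,
        truth={},
        knee_id=knee_id,
    )


# ----------------------------------------------------------------- config ---

def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: cohort spec must be a YAML mapping")
    try:
        return CohortSpec.from_dict(doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid cohort spec: {exc}") from exc


def save_cohort_spec(path, spec: CohortSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------- results ---

def write_results(path, results: pd.DataFrame) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing column(s): {missing}")
    results[RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: results table missing column(s): {missing}")
    if df.empty:
        raise ValueError(f"{path}: results table is empty")
    return df
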