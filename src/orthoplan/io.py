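"""File formats touched by the workflow: STL meshes, landmark JSON, plan JSON.

Meshes are held as :class:`trimesh.Trimesh` objects (vertices in mm).
Landmark files are JSON objects mapping a landmark name to ``[x, y, z]`` in
mm; a controlled vocabulary covers the tooth, facial and occlusal landmarks
used by the pipeline, and unknown names are kept with a warning so ad-hoc
points survive a round trip.
"""

from __future__ import annotations

import json
import struct
import warnings
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "FACIAL_LANDMARKS",
    "LANDMARK_VOCABULARY",
    "OCCLUSAL_LANDMARKS",
    "TOOTH_LANDMARKS",
    "LandmarkSet",
    "StlParseError",
    "read_landmarks",
    "read_stl",
    "write_landmarks",
    "write_stl",
]

# Maxillary dentition landmarks used for the linear discrepancy evaluation.
TOOTH_LANDMARKS = (
    "right incisor",
    "left incisor",
    "right canine",
    "left canine",
    "right 1st molar",
    "left 1st molar",
    "right 2nd molar",
    "left 2nd molar",
)

# Facial landmarks used for head-pose (natural head position) estimation.
FACIAL_LANDMARKS = (
    "pronasale",
    "right exocanthion",
    "left exocanthion",
    "right endocanthion",
    "left endocanthion",
    "right cheilion",
    "left cheilion",
)

# Landmarks defining the maxillary occlusal plane.
OCCLUSAL_LANDMARKS = (
    "mesiobuccal cusp right 1st molar",
    "mesiobuccal cusp left 1st molar",
    "central-incisor midpoint",
)

LANDMARK_VOCABULARY = frozenset(TOOTH_LANDMARKS + FACIAL_LANDMARKS + OCCLUSAL_LANDMARKS)


class StlParseError(ValueError):
    """Raised for malformed STL files; the message names the byte offset."""


class LandmarkSet(dict):
    """Named 3D landmarks: an ordered mapping ``name -> (3,) float array``."""

    def __setitem__(self, name: str, point) -> None:
        p = np.asarray(point, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"landmark {name!r} has non-finite coordinates")
        super().__setitem__(str(name), p)

    @classmethod
    def from_mapping(cls, mapping) -> "LandmarkSet":
        ls = cls()
        for k, v in mapping.items():
            ls[k] = v
        return ls

    def as_array(self, names=None) -> np.ndarray:
        """Stack landmarks into an (N, 3) array in the order of ``names``."""
        names = list(self) if names is None else list(names)
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")
        return np.array([self[n] for n in names])

    def transformed(self, transform) -> "LandmarkSet":
        """Apply a :class:`~orthoplan.geometry.RigidTransform` to every point."""
        out = LandmarkSet()
        for k, v in self.items():
            out[k] = transform.apply(v)
        return out


def _read_ascii_stl(path: Path) -> trimesh.Trimesh:
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a mixture of error types
        raise StlParseError(f"{path}: malformed ASCII STL near byte offset 0: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise StlParseError(f"{path}: ASCII STL contains no facets (byte offset 0)")
    return mesh


def read_stl(path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file into a Trimesh.

    Duplicate vertices are merged (1e-6 mm grid) so facet soups regain shared
    connectivity.  Malformed binary files raise :class:`StlParseError` naming
    the byte offset where the record structure breaks down.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    # Binary files declare a facet count at byte 80; validate record length
    # before handing off, so truncation is reported with its offset.
    is_ascii = raw[:6].strip().lower().startswith(b"solid") and b"facet" in raw[:2048]
    if is_ascii:
        mesh = _read_ascii_stl(path)
    else:
        if len(raw) < 84:
            raise StlParseError(
                f"{path}: binary STL truncated at byte offset {len(raw)} (header needs 84 bytes)"
            )
        (count,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * count
        if len(raw) != expected:
            raise StlParseError(
                f"{path}: binary STL declares {count} facets (expects {expected} bytes) "
                f"but ends at byte offset {len(raw)}"
            )
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    mesh.merge_vertices(digits_vertex=6)
    if len(mesh.vertices) and not np.all(np.isfinite(mesh.vertices)):
        raise StlParseError(f"{path}: non-finite vertex coordinates")
    return mesh


def write_stl(mesh: trimesh.Trimesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL; facet normals are recomputed from vertex winding."""
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    data = trimesh.exchange.stl.export_stl_ascii(mesh) if dialect == "ascii" else \
        trimesh.exchange.stl.export_stl(mesh)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def _reject_duplicates(pairs):
    seen = {}
    for k, v in pairs:
        if k in seen:
            raise ValueError(f"duplicate landmark name {k!r} in file")
        seen[k] = v
    return seen


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file ``{name: [x, y, z]}`` (mm).

    Unknown names outside the controlled vocabulary are retained with a
    warning; a duplicated name is an error.
    """
    with open(path) as fh:
        data = json.load(fh, object_pairs_hook=_reject_duplicates)
    ls = LandmarkSet()
    for name, xyz in data.items():
        if name not in LANDMARK_VOCABULARY:
            warnings.warn(f"landmark {name!r} is outside the controlled vocabulary; keeping it")
        ls[name] = xyz
    return ls


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in landmarks.items()}, fh, indent=1)
        fh.write("\n")
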