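"""Core geometric containers: triangle meshes, landmark sets, homologous models.

All coordinates are in millimetres. A :class:`HomologousModel` is a mesh that
shares a fixed template topology with every other model produced from the same
template, so vertex ``i`` carries the same anatomical meaning across specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Scheme",
    "TM20_NAMES",
    "HM12_NAMES",
    "TriangleMesh",
    "LandmarkSet",
    "HomologousModel",
    "MeshInvariantError",
    "LandmarkSchemeError",
]


class MeshInvariantError(ValueError):
    """A mesh violates a structural invariant (bad indices, non-finite coords)."""


class LandmarkSchemeError(ValueError):
    """A landmark set does not match its declared anatomical scheme."""


class Scheme(str, Enum):
    """Landmark schemes: 20-point total mandible, 12-point (right) half mandible."""

    TM20 = "TM20"
    HM12 = "HM12"


# Canonical landmark orders for the two schemes. Names follow the standard
# anatomical scheme for the adult mandible: condylar heads, mandibular
# notches, coronoid processes, gonial angles, dental-arch interproximal
# points, and midline chin points.
TM20_NAMES: tuple[str, ...] = (
    "Right condylar head",
    "Left condylar head",
    "Right mandibular notch",
    "Left mandibular notch",
    "Right coronoid process",
    "Left coronoid process",
    "Between right lower first and second premolar",
    "Between left lower first and second premolar",
    "Between right lower incisor and canine",
    "Between left lower incisor and canine",
    "Right mandibular angle",
    "Left mandibular angle",
    "Mandibular plane between right lower incisor and canine",
    "Mandibular plane between left lower incisor and canine",
    "Between right lower central and lateral incisor",
    "Between left lower central and lateral incisor",
    "Centre of mentaris",
    "Mental spines",
    "Between No 18 and No 20",
    "Between right and left lower central",
)

HM12_NAMES: tuple[str, ...] = (
    "Right condylar head",
    "Right mandibular notch",
    "Right coronoid process",
    "Between right lower first and second premolar",
    "Between right lower incisor and canine",
    "Right mandibular angle",
    "Mandibular plane between right lower incisor and canine",
    "Between right lower central and lateral incisor",
    "Centre of mentaris",
    "Mental spines",
    "Between No 10 and No 12",
    "Left lower central",
)

SCHEME_NAMES: dict[Scheme, tuple[str, ...]] = {
    Scheme.TM20: TM20_NAMES,
    Scheme.HM12: HM12_NAMES,
}


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (V, 3) float mm, ``faces`` (F, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- invariants ---------------------------------------------------------
    def validate(self, check_winding: bool = False) -> "TriangleMesh":
        """Check structural invariants; raise :class:`MeshInvariantError` on failure.

        Winding consistency is a warn-level check (non-manifold regions make it
        ill-defined), enabled with ``check_winding=True``.
        """
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshInvariantError("mesh is empty (no vertices or no faces)")
        if not np.isfinite(self.vertices).all():
            raise MeshInvariantError("mesh has non-finite vertex coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise MeshInvariantError(
                f"face indices out of range [0, {len(self.vertices)})"
            )
        f = self.faces
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise MeshInvariantError("degenerate face with repeated vertex index")
        if check_winding and not self.to_trimesh().is_winding_consistent:
            warnings.warn("mesh winding is not consistent", stacklevel=2)
        return self

    # -- conversions --------------------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    # -- derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds
        return float(np.linalg.norm(hi - lo))

    def triangles(self) -> np.ndarray:
        """Corner coordinates per face, shape (F, 3, 3)."""
        return self.vertices[self.faces]

    def merge_duplicate_vertices(self) -> "TriangleMesh":
        """Merge exactly coincident vertices (bitwise coordinate equality).

        STL stores vertices per facet; duplicates there are bit-identical, so
        exact matching restores shared topology deterministically without a
        welding tolerance.
        """
        uniq, first, inverse = np.unique(
            self.vertices, axis=0, return_index=True, return_inverse=True
        )
        # keep first-occurrence order so duplicate-free meshes pass through unchanged
        order = np.argsort(first, kind="stable")
        rank = np.empty(len(uniq), dtype=np.int64)
        rank[order] = np.arange(len(uniq))
        uniq = uniq[order]
        faces = rank[inverse.reshape(-1)][self.faces]
        keep = ~(
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        return TriangleMesh(uniq, faces[keep])


@dataclass
class LandmarkSet:
    """Ordered, named anatomical points for one scheme (canonical order enforced)."""

    names: list[str]
    points: np.ndarray
    scheme: Scheme

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        canonical = SCHEME_NAMES[self.scheme]
        given = list(self.names)
        if len(set(given)) != len(given):
            dupes = sorted({n for n in given if given.count(n) > 1})
            raise LandmarkSchemeError(f"duplicate landmark names: {dupes}")
        missing = [n for n in canonical if n not in given]
        extra = [n for n in given if n not in canonical]
        if missing or extra:
            raise LandmarkSchemeError(
                f"landmark set does not match scheme {self.scheme.value} "
                f"({len(canonical)} landmarks): missing={missing}, unexpected={extra}"
            )
        if len(self.points) != len(given):
            raise LandmarkSchemeError(
                f"{len(given)} names but {len(self.points)} points"
            )
        # canonicalize order
        order = [given.index(n) for n in canonical]
        self.names = list(canonical)
        self.points = self.points[order]
        if not np.isfinite(self.points).all():
            raise LandmarkSchemeError("non-finite landmark coordinates")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet(list(self.names), transform.apply(self.points), self.scheme)

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(zip(self.names, self.points))


@dataclass
class HomologousModel:
    """A mesh guaranteed to share a template's topology, plus landmark vertex ids."""

    mesh: TriangleMesh
    template_id: str
    landmark_vertex_ids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.mesh.n_vertices
        for name, idx in self.landmark_vertex_ids.items():
            if not 0 <= int(idx) < v:
                raise MeshInvariantError(
                    f"landmark '{name}' vertex id {idx} out of range [0, {v})"
                )

    @property
    def scheme(self) -> Scheme:
        names = set(self.landmark_vertex_ids)
        for scheme, canonical in SCHEME_NAMES.items():
            if names == set(canonical):
                return scheme
        raise LandmarkSchemeError(
            "landmark vertex ids do not cover a known scheme's full landmark list"
        )

    def landmark_points(self) -> LandmarkSet:
        scheme = self.scheme
        names = list(SCHEME_NAMES[scheme])
        pts = np.array([self.mesh.vertices[self.landmark_vertex_ids[n]] for n in names])
        return LandmarkSet(names, pts, scheme)

    def flatten(self) -> np.ndarray:
        """Vertices flattened row-major to a length-3V vector (x1, y1, z1, ...)."""
        return self.mesh.vertices.reshape(-1).copy()

    def with_vertices(self, vertices: np.ndarray) -> "HomologousModel":
        mesh = TriangleMesh(np.asarray(vertices, dtype=float).reshape(-1, 3),
                            self.mesh.faces.copy())
        return HomologousModel(mesh, self.template_id, dict(self.landmark_vertex_ids))
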