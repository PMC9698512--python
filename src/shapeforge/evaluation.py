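"""Face-to-face surface distance between predicted and actual meshes.

"Face-to-face distance" is implemented as the distance from each source
vertex to the nearest point of the target surface (interior, edge and vertex
regions of each triangle handled exactly) — the standard mesh-comparison
metric in morphometry tooling. Reported as mean absolute error ± SD over
per-vertex distances; with non-negative skewed distances the SD can exceed
the mean. The SD divisor is n (population SD over the vertices measured).

The implementation is exact: a KD-tree upper bound plus triangle AABB culling
only prune triangles that provably cannot contain the minimum, so results are
identical to exhaustive search over all triangles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import TriangleMesh

__all__ = [
    "DistanceReport",
    "point_to_mesh_distance",
    "point_mesh_distances",
    "face_to_face",
    "cohort_evaluation",
]


def _point_triangle_distance_block(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from points (N, 3) to triangles (M, 3, 3) -> (N, M).

    Vectorized closest-point-on-triangle classification (vertex, edge and
    face Voronoi regions of each triangle).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]  # (M, 3)
    ab = b - a
    ac = c - a
    p = points[:, None, :]  # (N, 1, 3)

    ap = p - a
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    bp = p - b
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    cp = p - c
    d5 = np.einsum("mk,nmk->nm", ab, cp)
    d6 = np.einsum("mk,nmk->nm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_abc = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom_abc != 0, vb / denom_abc, 0.0)
        w_face = np.where(denom_abc != 0, vc / denom_abc, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, num_bc / den_bc, 0.0)

    # region masks, in the classical order
    r_a = (d1 <= 0) & (d2 <= 0)
    r_b = (d3 >= 0) & (d4 <= d3)
    r_c = (d6 >= 0) & (d5 <= d6)
    r_ab = (~r_a) & (~r_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    r_ac = (~r_a) & (~r_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    r_bc = (~r_b) & (~r_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    v_par = np.clip(v_face, 0.0, 1.0)
    w_par = np.clip(w_face, 0.0, 1.0)
    v_par = np.where(r_ab, np.clip(v_ab, 0.0, 1.0), v_par)
    w_par = np.where(r_ab, 0.0, w_par)
    v_par = np.where(r_ac, 0.0, v_par)
    w_par = np.where(r_ac, np.clip(w_ac, 0.0, 1.0), w_par)
    v_par = np.where(r_bc, 1.0 - np.clip(w_bc, 0.0, 1.0), v_par)
    w_par = np.where(r_bc, np.clip(w_bc, 0.0, 1.0), w_par)
    v_par = np.where(r_a, 0.0, v_par)
    w_par = np.where(r_a, 0.0, w_par)
    v_par = np.where(r_b, 1.0, v_par)
    w_par = np.where(r_b, 0.0, w_par)
    v_par = np.where(r_c, 0.0, v_par)
    w_par = np.where(r_c, 1.0, w_par)

    closest = a + v_par[..., None] * ab + w_par[..., None] * ac
    return np.linalg.norm(p - closest, axis=2)


def point_mesh_distances(
    points: np.ndarray, mesh: TriangleMesh, chunk: int = 256
) -> np.ndarray:
    """Minimum distance from each point to the mesh surface (exact)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if mesh.n_faces == 0:
        raise ValueError("empty target mesh")
    tri = mesh.triangles()
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    # upper bound: nearest target vertex (a point of the surface)
    ub, _ = cKDTree(mesh.vertices).query(points)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        pts = points[s : s + chunk]
        bound = ub[s : s + chunk].max() + 1e-12
        # a triangle can beat the bound only if its centroid is within bound+radius
        lo = np.linalg.norm(centroids - pts.mean(axis=0), axis=1) - radii
        lo -= np.linalg.norm(pts - pts.mean(axis=0), axis=1).max()
        cand = lo <= bound
        d = _point_triangle_distance_block(pts, tri[cand])
        out[s : s + chunk] = d.min(axis=1)
    return out


def point_to_mesh_distance(point: np.ndarray, mesh: TriangleMesh) -> float:
    """Minimum Euclidean distance from one point to any triangle of ``mesh``."""
    return float(point_mesh_distances(np.asarray(point, dtype=float).reshape(1, 3), mesh)[0])


@dataclass
class DistanceReport:
    """Per-vertex source-to-target surface distances with summary statistics."""

    per_vertex: np.ndarray
    mae: float
    sd: float
    max: float
    n_vertices: int
    reverse: "DistanceReport | None" = None
    symmetric_mae: float | None = None

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceReport":
        return cls(
            per_vertex=d,
            mae=float(d.mean()),
            sd=float(d.std()),  # population SD, divisor n
            max=float(d.max()),
            n_vertices=len(d),
        )


def face_to_face(
    source: TriangleMesh, target: TriangleMesh, symmetric: bool = False
) -> DistanceReport:
    """Distance report from source vertices to the target surface.

    With ``symmetric=True`` the reverse direction is also computed and the
    report carries the average of the two directions' MAEs.
    """
    report = DistanceReport.from_distances(point_mesh_distances(source.vertices, target))
    if symmetric:
        rev = DistanceReport.from_distances(point_mesh_distances(target.vertices, source))
        report.reverse = rev
        report.symmetric_mae = (report.mae + rev.mae) / 2.0
    return report


def cohort_evaluation(
    predicted: list[TriangleMesh],
    actual: list[TriangleMesh],
    symmetric: bool = False,
    specimen_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[DistanceReport]]:
    """Per-specimen reports plus a pooled row over all per-vertex distances.

    The pooled mean ± SD aggregates every vertex of every specimen, so
    specimens with more vertices weigh proportionally more.
    """
    if len(predicted) != len(actual):
        raise ValueError(
            f"{len(predicted)} predicted vs {len(actual)} actual meshes"
        )
    ids = specimen_ids or [f"specimen_{i}" for i in range(len(predicted))]
    reports = [face_to_face(p, a, symmetric=symmetric) for p, a in zip(predicted, actual)]
    rows = [
        {
            "specimen": sid,
            "n_vertices": r.n_vertices,
            "mae_mm": r.mae,
            "sd_mm": r.sd,
            "max_mm": r.max,
        }
        for sid, r in zip(ids, reports)
    ]
    pooled = np.concatenate([r.per_vertex for r in reports])
    rows.append(
        {
            "specimen": "pooled",
            "n_vertices": len(pooled),
            "mae_mm": float(pooled.mean()),
            "sd_mm": float(pooled.std()),
            "max_mm": float(pooled.max()),
        }
    )
    return pd.DataFrame(rows), reports
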