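"""Non-rigid landmark-constrained template fitting ("homologous" modeling).

A specimen is first posed rigidly into a canonical landmark-defined frame,
then the template mesh is deformed onto the specimen's point cloud by
alternating minimization of

    w_ext * sum_i ||v_i - c_i||^2            (external: distance to matched data points)
  + w_int * sum_i ||L(v - v0)_i||^2          (internal: local deformation from template)
  + w_lm  * sum_j ||v_lm(j) - p_j||^2        (landmark fidelity)

where ``c_i`` is vertex i's nearest target point, ``L`` the uniform graph
Laplacian (umbrella operator), and ``v0`` the stage's initial template. The
solve step is a sparse symmetric positive-definite linear system, factorized
once per stage; total energy is non-increasing across iterations of a stage.
Coarse-to-fine refinement subdivides the template between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RBFInterpolator
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .geometry import (
    HomologousModel,
    LandmarkSet,
    Scheme,
    TriangleMesh,
)

__all__ = [
    "RigidTransform",
    "DegenerateFrameError",
    "FitParams",
    "FitResult",
    "canonical_frame",
    "subdivide",
    "make_template",
    "TemplateFitter",
    "fit_template",
    "build_cohort",
]


class DegenerateFrameError(ValueError):
    """Frame landmarks are coincident or collinear; no canonical pose exists."""


class FitError(RuntimeError):
    """Template fitting failed (empty target, non-finite energy, ...)."""


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion p -> R @ p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateFrameError(f"{what} is degenerate (zero-length direction)")
    return v / n


def canonical_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Landmark-defined canonical pose for a specimen.

    TM20: origin at the midpoint of the condylar heads, x-axis along the
    inter-condylar direction (right condyle at +x), y-axis toward the chin
    (component of mentaris orthogonal to x). HM12: origin at the right
    condylar head, y-axis toward the mentaris, x/z fixed by the gonion.
    In both frames the mentaris maps into the plane spanned by the condylar
    axis and +y; for bilaterally symmetric landmarks it lies exactly in the
    y-z plane.
    """
    if landmarks.scheme == Scheme.TM20:
        c_r = landmarks["Right condylar head"]
        c_l = landmarks["Left condylar head"]
        m = landmarks["Centre of mentaris"]
        origin = (c_r + c_l) / 2.0
        ex = _unit(c_r - c_l, "inter-condylar axis (condylar heads coincide?)")
        w = (m - origin) - np.dot(m - origin, ex) * ex
        ey = _unit(w, "condylar axis and mentaris are collinear")
        ez = np.cross(ex, ey)
        rot = np.stack([ex, ey, ez])
    else:
        c = landmarks["Right condylar head"]
        g = landmarks["Right mandibular angle"]
        m = landmarks["Centre of mentaris"]
        origin = c
        ey = _unit(m - c, "condylar head and mentaris coincide")
        w = (g - c) - np.dot(g - c, ey) * ey
        ez = -_unit(w, "condylar head, gonion and mentaris are collinear")
        ex = np.cross(ey, ez)
        rot = np.stack([ex, ey, ez])
    return RigidTransform(rot, -rot @ origin)


# ---------------------------------------------------------------------------
# Subdivision
# ---------------------------------------------------------------------------

def subdivide(mesh: TriangleMesh, levels: int) -> TriangleMesh:
    """Midpoint (1-to-4) subdivision; original vertices keep their indices."""
    if levels < 0:
        raise ValueError("levels must be >= 0")
    out = mesh
    for _ in range(levels):
        v, f = out.vertices, out.faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
        midpoints = (v[uniq[:, 0]] + v[uniq[:, 1]]) / 2.0
        mid_idx = len(v) + inverse.reshape(3, -1)  # rows: ab, bc, ca per face
        mab, mbc, mca = mid_idx
        a, b, c = f[:, 0], f[:, 1], f[:, 2]
        new_faces = np.concatenate(
            [
                np.stack([a, mab, mca], axis=1),
                np.stack([mab, b, mbc], axis=1),
                np.stack([mca, mbc, c], axis=1),
                np.stack([mab, mbc, mca], axis=1),
            ]
        )
        out = TriangleMesh(np.vstack([v, midpoints]), new_faces)
    return out


def make_template(
    mesh: TriangleMesh, landmarks: LandmarkSet, template_id: str
) -> HomologousModel:
    """Bind world-coordinate landmarks to their nearest template vertices."""
    tree = cKDTree(mesh.vertices)
    _, idx = tree.query(landmarks.points)
    ids = {name: int(i) for name, i in zip(landmarks.names, idx)}
    return HomologousModel(mesh.copy(), template_id, ids)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitParams:
    """Weights and schedule for template fitting.

    ``w_ext``/``w_int``/``w_lm`` weight the external (data), internal
    (deformation) and landmark energies; the landmark default is 10x the
    external weight, a soft constraint strong enough to pin anatomy while
    keeping the solve well-posed. ``subdivision_schedule`` lists template
    subdivision levels for coarse-to-fine stages.

    ``tps_init`` warps the template by the thin-plate spline interpolating
    template landmarks onto target landmarks before the first stage. Nearest-
    point correspondence only registers shape differences it can "see"
    normally to the surface; starting from the landmark-interpolating warp
    keeps anatomical correspondence from sliding tangentially during the
    alternating minimization. It is an initialization only — the energies
    minimized are unchanged (the internal energy anchors to the stage's
    initial template as always).
    """

    w_ext: float = 1.0
    w_int: float = 0.1
    w_lm: float = 10.0
    max_iters: int = 50
    tol: float = 1e-6
    subdivision_schedule: tuple[int, ...] = (0,)
    tps_init: bool = True

    def __post_init__(self) -> None:
        if min(self.w_ext, self.w_int, self.w_lm) < 0 or max(
            self.w_ext, self.w_int, self.w_lm
        ) <= 0:
            raise ValueError("weights must be >= 0 with at least one > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        levels = tuple(self.subdivision_schedule)
        if any(l < 0 for l in levels) or list(levels) != sorted(levels):
            raise ValueError("subdivision_schedule must be non-decreasing levels >= 0")


@dataclass
class FitResult:
    """Fitted homologous model plus the final energy decomposition."""

    model: HomologousModel
    final_energy: tuple[float, float, float]  # (E_ext, E_int, E_lm), unweighted
    iterations: int
    converged: bool
    energy_trace: list[float] = field(default_factory=list)


def _umbrella_laplacian(mesh: TriangleMesh) -> sp.csr_matrix:
    """Uniform graph Laplacian L = I - D^-1 A over the mesh edge graph."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    n = mesh.n_vertices
    adj = sp.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    dinv = sp.diags(1.0 / deg)
    return (sp.identity(n) - dinv @ adj).tocsr()


class TemplateFitter:
    """Scikit-learn-style estimator deforming a template onto a point cloud.

    Parameters are the template (a :class:`HomologousModel` whose landmark
    scheme matches the target's) and a :class:`FitParams`. After ``fit`` the
    registered model is in ``model_`` (in the canonical landmark frame), with
    ``energy_trace_``, ``n_iter_`` and ``converged_`` describing the run.
    """

    def __init__(self, template: HomologousModel, params: FitParams | None = None,
                 canonicalize: bool = True):
        self.template = template
        self.params = params or FitParams()
        self.canonicalize = canonicalize

    def get_params(self, deep: bool = True) -> dict:
        return {
            "template": self.template,
            "params": self.params,
            "canonicalize": self.canonicalize,
        }

    def set_params(self, **kwargs) -> "TemplateFitter":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None, *, landmarks: LandmarkSet) -> "TemplateFitter":
        """Register the template to target points ``X`` (N, 3) with landmarks."""
        X = np.asarray(X, dtype=float).reshape(-1, 3)
        if len(X) == 0:
            raise FitError("empty target point cloud")
        if len(X) < 100:
            raise FitError(f"need >= 100 target points, got {len(X)}")
        template = self.template
        if template.scheme != landmarks.scheme:
            raise ValueError(
                f"template scheme {template.scheme.value} != target scheme "
                f"{landmarks.scheme.value}"
            )
        params = self.params

        if self.canonicalize:
            t_target = canonical_frame(landmarks)
            X = t_target.apply(X)
            lm_pts = t_target.apply(landmarks.points)
            t_temp = canonical_frame(template.landmark_points())
            verts = t_temp.apply(template.mesh.vertices)
        else:
            lm_pts = landmarks.points.copy()
            verts = template.mesh.vertices.copy()
        lm_lookup = dict(zip(landmarks.names, lm_pts))

        if params.tps_init:
            src = verts[[template.landmark_vertex_ids[n] for n in landmarks.names]]
            verts = RBFInterpolator(src, lm_pts, kernel="thin_plate_spline")(verts)

        mesh = TriangleMesh(verts, template.mesh.faces.copy())
        lm_ids = dict(template.landmark_vertex_ids)
        tree = cKDTree(X)

        current_level = 0
        trace: list[float] = []
        n_iter_total = 0
        converged = False
        for level in params.subdivision_schedule:
            if level > current_level:
                mesh = subdivide(mesh, level - current_level)
                current_level = level
            v0 = mesh.vertices.copy()
            n = len(v0)
            lap = _umbrella_laplacian(mesh)
            ltl = (lap.T @ lap).tocsr()
            names = list(lm_ids)
            sel_rows = np.array([lm_ids[k] for k in names])
            p_lm = np.array([lm_lookup[k] for k in names])
            s_diag = np.zeros(n)
            sts_rhs = np.zeros((n, 3))
            # accumulate S^T S and S^T p allowing repeated vertex ids
            for row, pt in zip(sel_rows, p_lm):
                s_diag[row] += 1.0
                sts_rhs[row] += pt
            system = (
                params.w_ext * sp.identity(n)
                + params.w_int * ltl
                + params.w_lm * sp.diags(s_diag)
            ).tocsc()
            lu = splu(system)
            const_rhs = params.w_int * (ltl @ v0) + params.w_lm * sts_rhs

            v = mesh.vertices
            e_prev = np.inf
            for _ in range(params.max_iters):
                _, nn = tree.query(v)
                c = X[nn]
                rhs = params.w_ext * c + const_rhs
                v = np.column_stack([lu.solve(rhs[:, k]) for k in range(3)])
                n_iter_total += 1
                # energy at (v, NN(v))
                d, nn = tree.query(v)
                c = X[nn]
                e_ext = float(np.sum(d**2))
                e_int = float(np.sum((lap @ (v - v0)) ** 2))
                e_lm = float(np.sum((v[sel_rows] - p_lm) ** 2))
                e_tot = params.w_ext * e_ext + params.w_int * e_int + params.w_lm * e_lm
                if not np.isfinite(e_tot):
                    raise FitError(f"non-finite energy at iteration {n_iter_total}")
                trace.append(e_tot)
                if e_prev - e_tot < params.tol * max(e_prev, 1e-300):
                    converged = True
                    e_prev = e_tot
                    break
                e_prev = e_tot
            mesh = TriangleMesh(v, mesh.faces)

        self.model_ = HomologousModel(
            mesh,
            f"{template.template_id}+sub{current_level}" if current_level else template.template_id,
            lm_ids,
        )
        self.final_energy_ = (e_ext, e_int, e_lm)
        self.energy_trace_ = trace
        self.n_iter_ = n_iter_total
        self.converged_ = converged
        return self

    def result(self) -> FitResult:
        return FitResult(
            model=self.model_,
            final_energy=self.final_energy_,
            iterations=self.n_iter_,
            converged=self.converged_,
            energy_trace=list(self.energy_trace_),
        )


def fit_template(
    template: HomologousModel,
    target_points: np.ndarray,
    target_landmarks: LandmarkSet,
    params: FitParams | None = None,
) -> FitResult:
    """Functional wrapper over :class:`TemplateFitter`."""
    fitter = TemplateFitter(template, params)
    fitter.fit(target_points, landmarks=target_landmarks)
    return fitter.result()


def half_point_mask(points: np.ndarray, tm_landmarks: LandmarkSet,
                    margin: float = 1.0) -> np.ndarray:
    """Mask of points on the preserved (right) half: x >= -margin in the
    canonical total-mandible frame."""
    frame = canonical_frame(tm_landmarks)
    return frame.apply(points)[:, 0] >= -margin


def build_cohort(
    tm_template: HomologousModel,
    hm_template: HomologousModel,
    specimens,
    params: FitParams | None = None,
) -> tuple[list[HomologousModel], list[HomologousModel]]:
    """Fit both templates to every specimen; outputs are index-aligned.

    Each specimen needs ``surface`` plus ``tm_landmarks`` and ``hm_landmarks``.
    The TM template fits the whole surface; the HM template fits the right-half
    point set (x >= -1 mm in the canonical TM frame).
    """
    tm_models, hm_models = [], []
    for i, spec in enumerate(specimens):
        label = getattr(spec, "specimen_id", f"specimen {i}")
        for attr in ("tm_landmarks", "hm_landmarks"):
            if getattr(spec, attr, None) is None:
                raise ValueError(f"{label}: missing {attr}")
        points = spec.surface.vertices
        try:
            tm_models.append(
                fit_template(tm_template, points, spec.tm_landmarks, params).model
            )
            half = points[half_point_mask(points, spec.tm_landmarks)]
            hm_models.append(
                fit_template(hm_template, half, spec.hm_landmarks, params).model
            )
        except Exception as exc:
            raise FitError(f"{label}: {exc}") from exc
    return tm_models, hm_models
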