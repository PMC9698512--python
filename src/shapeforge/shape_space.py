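"""PCA shape spaces over corresponded vertex coordinates.

Each homologous model contributes one row of flattened vertex coordinates
(x1, y1, z1, ..., in mm). PCA is run on the sample covariance of the
mean-centered rows (divisor n-1), with no per-variable scaling and no
Procrustes/size normalization: size is a mode of interest (typically PC1) and
raw mm geometry is what back-calculation must return. Specimens are assumed
already posed in the canonical landmark frame, so rigid motion is controlled
by alignment, not removed by the model.

Contribution rates divide each eigenvalue by the total variance over *all*
nontrivial components, so the kept components' cumulative rate can stay below
100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .geometry import HomologousModel, TriangleMesh

__all__ = [
    "ShapeMatrix",
    "ShapeSpacePCA",
    "PCScores",
    "build_shape_matrix",
    "fit_pca",
    "project",
    "reconstruct",
    "variance_report",
]

DEFAULT_N_COMPONENTS = 16


@dataclass
class ShapeMatrix:
    """n specimens x 3V flattened coordinates from one template topology."""

    data: np.ndarray
    template_id: str
    faces: np.ndarray | None = None
    landmark_vertex_ids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or len(self.data) < 2:
            raise ValueError("shape matrix needs >= 2 rows of flattened coordinates")


@dataclass
class PCScores:
    """Principal-component scores of one specimen in a referenced space."""

    values: np.ndarray
    space_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)


def build_shape_matrix(models: list[HomologousModel]) -> ShapeMatrix:
    """Stack flattened model vertices; all models must share one template."""
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    tids = {m.template_id for m in models}
    if len(tids) != 1:
        raise ValueError(f"mixed template_ids in cohort: {sorted(tids)}")
    first = models[0]
    for m in models[1:]:
        if not np.array_equal(m.mesh.faces, first.mesh.faces):
            raise ValueError("models share template_id but have different face arrays")
    data = np.stack([m.flatten() for m in models])
    return ShapeMatrix(
        data,
        first.template_id,
        faces=first.mesh.faces.copy(),
        landmark_vertex_ids=dict(first.landmark_vertex_ids),
    )


class ShapeSpacePCA(BaseEstimator, TransformerMixin):
    """PCA shape space: mean + orthonormal components + eigenvalue bookkeeping.

    Fitted attributes: ``mean_`` (3V,), ``components_`` (K, 3V) orthonormal,
    ``eigenvalues_`` (K,) variances in mm^2, ``contribution_`` and
    ``cumulative_`` rates in percent (denominator: total variance over all
    nontrivial components), ``total_variance_``. Sign convention: each
    component's largest-magnitude entry is positive.
    """

    def __init__(self, n_components: int = DEFAULT_N_COMPONENTS, template_id: str = ""):
        self.n_components = n_components
        self.template_id = template_id

    def fit(self, X, y=None) -> "ShapeSpacePCA":
        if isinstance(X, ShapeMatrix):
            if not self.template_id:
                self.template_id = X.template_id
            self.faces_ = X.faces
            self.landmark_vertex_ids_ = dict(X.landmark_vertex_ids)
            X = X.data
        else:
            self.faces_ = getattr(self, "faces_", None)
            self.landmark_vertex_ids_ = getattr(self, "landmark_vertex_ids_", {})
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        rank_bound = min(n - 1, p)
        if self.n_components > rank_bound:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank bound "
                f"min(n-1, 3V) = {rank_bound} for n={n} specimens"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        with np.errstate(invalid="ignore", divide="ignore"):  # zero-variance cohorts
            pca.fit(X)
        comps = pca.components_.copy()
        # sign convention: largest-|entry| positive
        flip = comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)] < 0
        comps[flip] *= -1.0
        self.mean_ = pca.mean_
        self.components_ = comps
        self.eigenvalues_ = pca.explained_variance_.copy()
        centered = X - self.mean_
        self.total_variance_ = float(np.sum(centered**2) / (n - 1))
        if self.total_variance_ > 0:
            self.contribution_ = 100.0 * self.eigenvalues_ / self.total_variance_
        else:
            self.contribution_ = np.zeros_like(self.eigenvalues_)
        self.cumulative_ = np.cumsum(self.contribution_)
        self.n_samples_ = n
        return self

    # -- projection / back-calculation --------------------------------------
    def transform(self, X) -> np.ndarray:
        X = self._as_rows(X)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return self.mean_ + scores @ self.components_

    def project(self, model) -> PCScores:
        vec = self._as_rows(model)[0]
        return PCScores((vec - self.mean_) @ self.components_.T, self.template_id)

    def reconstruct(self, scores) -> HomologousModel:
        """Back-calculate a mesh from PC scores (mean + sum score_k * comp_k)."""
        if isinstance(scores, PCScores):
            scores = scores.values
        scores = np.asarray(scores, dtype=float).reshape(-1)
        if len(scores) != len(self.components_):
            raise ValueError(
                f"scores length {len(scores)} != n_components {len(self.components_)}"
            )
        if self.faces_ is None:
            raise ValueError("space was fitted without template topology")
        flat = self.mean_ + scores @ self.components_
        mesh = TriangleMesh(flat.reshape(-1, 3), self.faces_.copy())
        return HomologousModel(mesh, self.template_id, dict(self.landmark_vertex_ids_))

    def _as_rows(self, X) -> np.ndarray:
        if isinstance(X, HomologousModel):
            if self.template_id and X.template_id != self.template_id:
                raise ValueError(
                    f"model template_id {X.template_id!r} != space {self.template_id!r}"
                )
            X = X.flatten()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.mean_):
            raise ValueError(f"expected {len(self.mean_)} coordinates, got {X.shape[1]}")
        return X


# -- functional wrappers -----------------------------------------------------

def fit_pca(matrix: ShapeMatrix, n_components: int = DEFAULT_N_COMPONENTS) -> ShapeSpacePCA:
    return ShapeSpacePCA(n_components=n_components).fit(matrix)


def project(space: ShapeSpacePCA, model) -> PCScores:
    return space.project(model)


def reconstruct(space: ShapeSpacePCA, scores) -> HomologousModel:
    return space.reconstruct(scores)


def variance_report(space: ShapeSpacePCA) -> pd.DataFrame:
    """Eigenvalue / contribution% / cumulative% table, one row per component."""
    return pd.DataFrame(
        {
            "principal_component": np.arange(1, len(space.eigenvalues_) + 1),
            "eigenvalue": space.eigenvalues_,
            "contribution_pct": space.contribution_,
            "cumulative_pct": space.cumulative_,
        }
    )
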