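"""Per-component OLS regression predicting whole-mandible PC scores from
half-mandible PC scores, and its composition with back-calculation.

Each total-mandible (TM) component score is fit by an independent ordinary
least-squares equation on *all* half-mandible (HM) component scores plus an
intercept:

    Estimated PCj(TM) = z_j + sum_k c_jk * PCk(HM)

(one equation per TM component; no variable selection, no regularization).
Composed with projection and back-calculation this yields a full predicted
mandible mesh from a preserved half.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression

from .geometry import HomologousModel
from .shape_space import PCScores, ShapeSpacePCA

__all__ = [
    "RegressionModel",
    "PCScoreRegressor",
    "fit_regression",
    "predict_scores",
    "predict_mandible",
    "equation_report",
    "parse_equation",
    "save_regression_model",
    "load_regression_model",
]


@dataclass
class RegressionModel:
    """Intercepts (K_TM,) and coefficient matrix (K_TM, K_HM) plus space refs."""

    intercepts: np.ndarray
    coefficients: np.ndarray
    tm_space_ref: str = ""
    hm_space_ref: str = ""

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float).reshape(-1)
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if len(self.intercepts) != len(self.coefficients):
            raise ValueError("intercepts / coefficient rows mismatch")
        if not (np.isfinite(self.intercepts).all() and np.isfinite(self.coefficients).all()):
            raise ValueError("non-finite regression parameters")


class PCScoreRegressor(BaseEstimator, RegressorMixin):
    """Multi-output OLS: TM scores (targets) on HM scores (predictors).

    Equivalent to one independent OLS fit per TM component on all HM
    predictors plus intercept. Fitted attributes: ``coef_`` (K_TM, K_HM),
    ``intercept_`` (K_TM,).
    """

    def fit(self, X, y) -> "PCScoreRegressor":
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] != X.shape[0]:
            raise ValueError("predictor/target row counts differ")
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(
                f"OLS with {k} predictors plus intercept needs n > {k + 1} "
                f"specimens, got n = {n}"
            )
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < k + 1:
            raise ValueError(
                "predictor score matrix is rank deficient; use fewer HM components"
            )
        if n < 2 * (k + 1):
            warnings.warn(
                f"only n = {n} specimens for {k + 1} parameters per equation; "
                "coefficient estimates will be noisy",
                stacklevel=2,
            )
        lr = LinearRegression().fit(X, y)
        self.coef_ = np.atleast_2d(lr.coef_)
        self.intercept_ = np.atleast_1d(lr.intercept_)
        self.n_samples_ = n
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        out = np.atleast_2d(X) @ self.coef_.T + self.intercept_
        return out[0] if one else out

    def to_model(self, tm_space_ref: str = "", hm_space_ref: str = "") -> RegressionModel:
        return RegressionModel(self.intercept_, self.coef_, tm_space_ref, hm_space_ref)


# -- functional interface ----------------------------------------------------

def fit_regression(tm_scores: np.ndarray, hm_scores: np.ndarray) -> RegressionModel:
    """OLS fit of TM scores (n, K_TM) on HM scores (n, K_HM), rows aligned."""
    reg = PCScoreRegressor().fit(np.asarray(hm_scores), np.asarray(tm_scores))
    return reg.to_model()


def predict_scores(model: RegressionModel, hm_scores) -> np.ndarray:
    """Estimated TM scores: intercept_j + sum_k coeff_jk * hm_k."""
    if isinstance(hm_scores, PCScores):
        hm_scores = hm_scores.values
    hm = np.asarray(hm_scores, dtype=float)
    if hm.shape[-1] != model.coefficients.shape[1]:
        raise ValueError(
            f"expected {model.coefficients.shape[1]} HM scores, got {hm.shape[-1]}"
        )
    return hm @ model.coefficients.T + model.intercepts


def predict_mandible(
    model: RegressionModel,
    tm_space: ShapeSpacePCA,
    hm_space: ShapeSpacePCA,
    hm_input,
) -> HomologousModel:
    """Project (if a mesh), regress, back-calculate: half in, whole mesh out."""
    if isinstance(hm_input, (HomologousModel,)):
        hm_scores = hm_space.project(hm_input).values
    elif isinstance(hm_input, PCScores):
        hm_scores = hm_input.values
    else:
        hm_scores = np.asarray(hm_input, dtype=float).reshape(-1)
    tm_scores = predict_scores(model, hm_scores)
    return tm_space.reconstruct(tm_scores)


# -- reporting ---------------------------------------------------------------

def _fmt_coef(c: float, precision: int) -> str:
    s = f"{c:.{precision}f}"
    return f"({s})" if c < 0 else s


def equation_report(model: RegressionModel, precision: int = 2) -> str:
    """One printed equation per TM component, e.g.

    ``Estimated PC1(TM) = 0.11 + (-1.38) x PC1(HM) + ...``
    """
    lines = []
    for j, (z, row) in enumerate(zip(model.intercepts, model.coefficients), start=1):
        terms = " + ".join(
            f"{_fmt_coef(c, precision)} × PC{k}(HM)" for k, c in enumerate(row, start=1)
        )
        lines.append(f"Estimated PC{j}(TM) = {_fmt_coef(z, precision)} + {terms}")
    return "\n".join(lines)


_TERM_RE = re.compile(r"\(?(-?\d+\.?\d*)\)?\s*×\s*PC(\d+)\(HM\)")


def parse_equation(line: str) -> tuple[float, np.ndarray]:
    """Inverse of one :func:`equation_report` line -> (intercept, coefficients)."""
    head, _, rest = line.partition("=")
    if not head.strip().startswith("Estimated PC"):
        raise ValueError(f"not an equation line: {line!r}")
    first = rest.strip().split(" + ")[0]
    intercept = float(first.strip("()"))
    terms = sorted((int(k), float(c)) for c, k in _TERM_RE.findall(rest))
    coefs = np.array([c for _, c in terms])
    return intercept, coefs


# -- serialization -----------------------------------------------------------

def save_regression_model(model: RegressionModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "intercepts": model.intercepts.tolist(),
                "coefficients": model.coefficients.tolist(),
                "tm_space_ref": model.tm_space_ref,
                "hm_space_ref": model.hm_space_ref,
            },
            indent=1,
        )
    )


def load_regression_model(path: str | Path) -> RegressionModel:
    d = json.loads(Path(path).read_text())
    return RegressionModel(
        d["intercepts"], d["coefficients"], d["tm_space_ref"], d["hm_space_ref"]
    )
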