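"""End-to-end orchestration: simulate -> fit templates -> PCA -> regression ->
predict -> evaluate, with a single seed, a YAML-able config, and a manifest.

:class:`MandiblePredictor` is the composite estimator: given index-aligned
half- and whole-mandible homologous models it fits both shape spaces and the
score regression, and predicts a whole mesh from a half model. Honest error
reporting uses leave-one-out cross-validation (each specimen predicted by a
model trained without it); an in-sample mode is available for comparison.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import cohort_evaluation
from .geometry import HomologousModel
from .mesh_io import write_landmarks, write_mesh
from .pc_regression import PCScoreRegressor, equation_report, save_regression_model
from .shape_space import ShapeSpacePCA, build_shape_matrix, variance_report
from .synthetic_mandible import (
    DEFAULT_FACTOR_SDS,
    DEFAULT_NOISE_SD,
    make_reference_half_mandible,
    make_reference_mandible,
    sample_population,
)
from .template_fit import FitParams, build_cohort, make_template

__all__ = [
    "MandiblePredictor",
    "PipelineError",
    "RunConfig",
    "run_pipeline",
    "loo_predictions",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


class MandiblePredictor:
    """Half-to-whole shape predictor: two PCA spaces + per-component OLS."""

    def __init__(self, n_components: int = 16):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **kw) -> "MandiblePredictor":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, hm_models: list[HomologousModel], tm_models: list[HomologousModel]
            ) -> "MandiblePredictor":
        if len(hm_models) != len(tm_models):
            raise ValueError("hm/tm model lists must be index-aligned")
        self.tm_space_ = ShapeSpacePCA(self.n_components).fit(build_shape_matrix(tm_models))
        self.hm_space_ = ShapeSpacePCA(self.n_components).fit(build_shape_matrix(hm_models))
        self.tm_scores_ = self.tm_space_.transform(np.stack([m.flatten() for m in tm_models]))
        self.hm_scores_ = self.hm_space_.transform(np.stack([m.flatten() for m in hm_models]))
        self.regressor_ = PCScoreRegressor().fit(self.hm_scores_, self.tm_scores_)
        return self

    def predict(self, hm_input) -> HomologousModel:
        """Predict the whole-mandible mesh from a half model (or HM scores)."""
        if isinstance(hm_input, HomologousModel):
            hm_scores = self.hm_space_.project(hm_input).values
        else:
            hm_scores = np.asarray(hm_input, dtype=float).reshape(-1)
        tm_scores = self.regressor_.predict(hm_scores)
        return self.tm_space_.reconstruct(tm_scores)

    def regression_model(self):
        return self.regressor_.to_model(
            tm_space_ref=self.tm_space_.template_id,
            hm_space_ref=self.hm_space_.template_id,
        )


def loo_predictions(
    tm_models: list[HomologousModel],
    hm_models: list[HomologousModel],
    n_components: int = 16,
) -> list[HomologousModel]:
    """Leave-one-out predicted meshes: specimen i predicted by a pipeline
    (both PCA spaces + regression) trained on all other specimens."""
    n = len(tm_models)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n OLS warning repeats per fold
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            predictor = MandiblePredictor(n_components).fit(
                [hm_models[j] for j in keep], [tm_models[j] for j in keep]
            )
            out.append(predictor.predict(hm_models[i]))
    return out


# ---------------------------------------------------------------------------
# Config-driven run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full reproducible run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "shapeforge_run"
    n_components: int = 16
    population_n: int = 44
    factor_sds: dict = field(default_factory=lambda: dict(DEFAULT_FACTOR_SDS))
    noise_sd: float = DEFAULT_NOISE_SD
    surface_resolution: int = 3
    template_resolution: int = 0
    fit: dict = field(default_factory=lambda: {"subdivision_schedule": [0, 1]})
    prediction: str = "loo"  # or "in_sample"
    symmetric_distance: bool = False
    write_meshes: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.prediction not in ("loo", "in_sample"):
            raise ValueError("prediction must be 'loo' or 'in_sample'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fit_params(self) -> FitParams:
        fit = dict(self.fit)
        if "subdivision_schedule" in fit:
            fit["subdivision_schedule"] = tuple(fit["subdivision_schedule"])
        return FitParams(**fit)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    All randomness flows from ``config.seed``. Rerunning with the same config
    reproduces all numbers (the manifest carries no timestamps).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def record(path: Path) -> Path:
        files.append(str(path.relative_to(out_dir)))
        return path

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("simulate"):
        population = sample_population(
            n=config.population_n,
            factor_sds=config.factor_sds,
            noise_sd=config.noise_sd,
            seed=config.seed,
            resolution=config.surface_resolution,
        )
        truth = pd.DataFrame([asdict(s.truth) for s in population])
        truth.insert(0, "specimen", [f"specimen_{i}" for i in range(len(population))])
        truth.to_csv(record(out_dir / "population_truth.csv"), index=False)
        if config.write_meshes:
            for i, spec in enumerate(population):
                write_mesh(spec.surface, record(out_dir / f"specimen_{i:03d}.stl"))
                write_landmarks(
                    spec.tm_landmarks, record(out_dir / f"specimen_{i:03d}_tm.csv")
                )
                write_landmarks(
                    spec.hm_landmarks, record(out_dir / f"specimen_{i:03d}_hm.csv")
                )

    with stage("fit-template"):
        ref_mesh, ref_tm, _ = make_reference_mandible(config.template_resolution)
        half_mesh, ref_hm = make_reference_half_mandible(config.template_resolution)
        tm_template = make_template(ref_mesh, ref_tm, "tm-reference")
        hm_template = make_template(half_mesh, ref_hm, "hm-reference")
        tm_models, hm_models = build_cohort(
            tm_template, hm_template, population, config.fit_params()
        )

    with stage("build-pca"):
        predictor = MandiblePredictor(config.n_components).fit(hm_models, tm_models)
        for label, space in (("tm", predictor.tm_space_), ("hm", predictor.hm_space_)):
            variance_report(space).to_csv(
                record(out_dir / f"variance_report_{label}.csv"), index=False
            )

    with stage("train"):
        model = predictor.regression_model()
        save_regression_model(model, record(out_dir / "regression_model.json"))
        record(out_dir / "equations.txt").write_text(equation_report(model) + "\n")

    with stage("predict"):
        if config.prediction == "loo":
            predicted = loo_predictions(tm_models, hm_models, config.n_components)
        else:
            predicted = [predictor.predict(h) for h in hm_models]
        if config.write_meshes:
            for i, pred in enumerate(predicted):
                write_mesh(pred.mesh, record(out_dir / f"predicted_{i:03d}.stl"))

    with stage("evaluate"):
        table, _ = cohort_evaluation(
            [p.mesh for p in predicted],
            [m.mesh for m in tm_models],
            symmetric=config.symmetric_distance,
        )
        table.to_csv(record(out_dir / "evaluation.csv"), index=False)
        pooled = table.iloc[-1]

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_components": config.n_components,
        "n_specimens": config.population_n,
        "prediction": config.prediction,
        "files": sorted(files),
        "cohort_mae_mm": float(pooled["mae_mm"]),
        "cohort_sd_mm": float(pooled["sd_mm"]),
        "cohort_max_mm": float(pooled["max_mm"]),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
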