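# shapeforge

Predicting the intact shape of a mandible from a preserved half.

When trauma or tumour resection destroys part of the lower jaw, surgeons
conventionally mirror the opposite side to plan the reconstruction — but
mandibles are not symmetric, and the mirrored guess can be millimetres off.
`shapeforge` implements a statistical alternative for researchers in
craniofacial image analysis and geometric morphometrics:

1. **Homologous modeling.** Every specimen's surface (from segmented CT,
   here emulated synthetically) is converted to a mesh with *identical*
   topology by deforming a common template onto its point cloud under
   anatomical-landmark constraints, minimizing an external (data) plus
   internal (deformation) energy. Vertex *i* then means the same anatomy on
   every specimen.
2. **PCA shape spaces.** Flattened vertex coordinates of the whole-mandible
   (TM) and half-mandible (HM) cohorts each get a principal-component space
   (16 components by default): mean shape **m**, orthonormal modes
   **u**₁…**u**₁₆, eigenvalues λₖ with contribution rates λₖ / Σλ.
3. **Score regression.** One ordinary-least-squares equation per whole-shape
   component,

   PCⱼ(TM) = zⱼ + Σₖ cⱼₖ · PCₖ(HM),  k = 1…16,

   links the preserved half's scores to the whole shape's scores.
4. **Back-calculation.** Predicted scores are expanded to a full mesh:
   **x̂** = **m** + Σⱼ PĈⱼ · **u**ⱼ.
5. **Evaluation.** Face-to-face distance (each predicted vertex to the
   nearest point of the actual surface), summarized as MAE ± SD in mm,
   with honest leave-one-out cross-validation.

A seeded synthetic-mandible generator (parametric arch + rami with latent
size, ramus length/angle, arch V/U shape, asymmetry and noise factors)
provides fully controlled cohorts, so the entire pipeline is testable
without patient data.

## Worked example

The score regression in action — a published reference equation for the
first whole-mandible component (coefficients rounded to two decimals)
applied to an example specimen's sixteen half-mandible PC scores:

```python
import numpy as np
from shapeforge import RegressionModel, predict_scores, equation_report

model = RegressionModel(
    intercepts=[0.11],
    coefficients=[[-1.38, -0.07, -0.02, 0.06, 0.11, -0.04, -0.15, -0.12,
                   -0.22, -0.03, 0.16, -0.02, -0.17, 0.30, 0.20, 0.50]],
)
print(equation_report(model))
hm = np.array([-9.7, -48.7, 42.5, -9.9, 1.7, -3.0, 9.7, 15.3,
               -4.6, 8.4, -5.8, -2.7, 3.5, 4.1, -4.5, -0.9])
print("estimated PC1(TM) =", predict_scores(model, hm)[0])
```

prints

```
Estimated PC1(TM) = 0.11 + (-1.38) × PC1(HM) + (-0.07) × PC2(HM) + ... + 0.50 × PC16(HM)
estimated PC1(TM) = 11.647999999999996
```

i.e. this specimen sits ≈11.6 score units (mm-scale projections onto the
first whole-mandible mode, dominated by overall size) — recovered from
half-jaw geometry alone.

End-to-end on synthetic data, from a YAML config:

```yaml
# cfg.yaml
seed: 7
out_dir: demo_run
population_n: 12
n_components: 8
```

```text
$ shapeforge run --config cfg.yaml
cohort MAE 0.2095 ± 0.1762 mm (loo, n=12); manifest: demo_run/manifest.json
```

The pooled leave-one-out error of 0.21 mm means each specimen's whole
mandible, predicted from its right half by a model trained on the other
eleven, lies on average within a fifth of a millimetre of its actual
surface. `demo_run/` contains the variance reports (eigenvalue /
contribution% / cumulative% tables), the fitted regression equations, the
per-specimen evaluation CSV and a manifest that makes the run bitwise
reproducible.

Other subcommands (`simulate`, `fit-template`, `build-pca`, `train`,
`predict`, `evaluate`) expose the individual stages; the library surface
(`TemplateFitter`, `ShapeSpacePCA`, `PCScoreRegressor`, `MandiblePredictor`)
follows scikit-learn conventions and composes with its tooling.

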