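# Methods

This note documents the models, numerical choices and limitations behind
`shapeforge`. All coordinates are millimetres.

## Homologous models by template fitting

A *homologous model* is a mesh produced by deforming a fixed template onto a
specimen so that every vertex keeps the same anatomical meaning across
specimens (identical vertex count and face array). Construction has three
parts.

**Canonical frame.** Each specimen is first posed rigidly by its landmarks.
Whole mandible (TM20 scheme): origin at the midpoint of the two condylar
heads, x-axis along the inter-condylar direction (right condyle at +x),
y-axis toward the chin — the component of the mentaris landmark orthogonal
to the condylar axis. Half mandible (HM12): origin at the right condylar
head, y-axis toward the mentaris, the gonion fixing the remaining rotation.
A cranial reference plane (as used with full-skull CT) is not available
from mandible meshes alone, so the frame is defined entirely from
mandibular landmarks; it is deterministic and self-contained. Note a rigid
transform cannot force the mentaris *exactly* into the y–z plane of the TM
frame when the landmark set is asymmetric (its coordinate along the
condylar axis is rigid-invariant); for bilaterally symmetric landmark sets
the condition holds exactly, and otherwise the mentaris retains its
(small) lateral offset. Degenerate configurations — coincident condylar
heads, collinear frame landmarks — raise an error rather than produce an
arbitrary frame.

**Energy.** With template vertices v, stage-initial template v⁰, matched
target points c, landmark vertex set lm(j) and landmark targets p:

    E(v) = w_ext Σᵢ ‖vᵢ − cᵢ‖²  +  w_int Σᵢ ‖L(v − v⁰)ᵢ‖²  +  w_lm Σⱼ ‖v_lm(j) − pⱼ‖²

L is the uniform ("umbrella") graph Laplacian, L = I − D⁻¹A over the mesh
edge graph — a standard discrete measure of local deformation; no specific
differential operator is canonical here, and the uniform weighting keeps
the solve independent of triangle quality. Minimization alternates (a) a
correspondence step pairing every template vertex with its nearest target
point (ties broken toward the lowest target index) and (b) a solve step,
a sparse symmetric positive-definite linear system factorized once per
stage (`splu`) and reused each iteration. Both steps are exact
minimizations over their block, so the total energy is non-increasing
within a stage; iteration stops when the relative decrease falls below
`tol` (default 1e-6) or after `max_iters` (default 50). Coarse-to-fine
refinement subdivides the template (midpoint 1→4; original vertices keep
their indices, so landmark vertex ids survive) between the stages listed in
`subdivision_schedule`.

**Initialization.** Nearest-point correspondence only "sees" shape
differences normal to the surface; starting the minimization from the
canonical-frame template lets anatomical correspondence slide tangentially,
and the slide is specimen-dependent — on controlled cohorts it appeared as
a ~2–3 mm high-rank registration noise that dominated downstream
prediction error. The fitter therefore first warps the template by the
thin-plate spline interpolating template landmarks onto target landmarks
(`tps_init=True`, default) — the standard landmark-interpolation warp of
geometric morphometrics. This changes only the starting point (and the
stage anchor v⁰, as for any stage); the energies and the alternating
minimization are unchanged. With it, fitted models are smooth functions of
the generator's latent factors and leave-one-out prediction error on clean
cohorts drops by an order of magnitude.

**Defaults.** w_ext = 1, w_int = 0.1, w_lm = 10. The landmark weight is a
soft constraint: large enough to pin anatomy against tangential drift,
finite so the linear system stays well-conditioned and landmark noise is
not enforced exactly. w_int trades data fidelity against smoothness; 0.1
recovers a smooth 4 mm bend to within 5% of its amplitude in the test
suite. The full pipeline fits templates at subdivision level 0 then 1
(`(0, 1)`), giving whole-mandible models of 1 984 faces and half-mandible
models of 1 024 faces.

## Synthetic cohorts

The generator is parametric-analytic, not data-derived: a tube of varying
radius swept along an elliptic dental arch with two posterior rami,
Gaussian-bump coronoid processes, a condylar-head swell, and closed caps.
The surface is exactly mirror-symmetric about x = 0 at the identity
factors, closed and consistently wound, and carries the 20-point
whole-mandible and 12-point right-half landmark schemes at anatomical
analog positions. Midpoint subdivision supplies resolution levels (level r
has 4^r × 496 faces).

Latent factors, applied in order with landmarks carried through every warp:

| factor | unit | population SD (default) | action |
|---|---|---|---|
| size | — (1 = reference) | 0.05 | global scaling about the centroid |
| ramus_length | mm | 2.0 | smooth elongation of each ramus along its axis |
| ramus_angle | degrees | 3.0 | rotation about the lateral axis through each gonion |
| arch_shape | — | 0.5 | anterior arch-width warp (negative V-like, positive U-like) |
| asymmetry | — (≈mm) | 0.3 | smooth right-side-only displacement field |
| noise_sd | mm | 0.2 | per-vertex Gaussian noise along vertex normals |

Symmetric warps act on the right half and are mirror-conjugated onto the
left, so bilateral symmetry is preserved to machine precision when
asymmetry and noise are zero. Noise along normals (rather than isotropic)
avoids tangential shuffling and self-intersection at small amplitudes.
Population draws are independent Gaussians around the identity factors;
`asymmetry` takes the absolute value of its draw to respect non-negativity.
All randomness descends from a single integer seed and populations are
bitwise reproducible. Cohort surfaces default to subdivision level 3
(~31.7 k faces, ~15.9 k vertices), standing in for a dense measured CT
point cloud.

What the generator does **not** emulate: tooth crowns and dentition-driven
shape effects, cortical/trabecular interior structure, segmentation
artifacts, landmark placement error (landmarks are exact up to the warps),
and realistic residual asymmetry structure. Passing the synthetic
acceptance bounds therefore demonstrates the pipeline's correctness and
stability — not clinical-grade accuracy on patient CT.

## Shape spaces

PCA runs on flattened canonical-frame vertex coordinates: sample
covariance of mean-centered rows (divisor n − 1), no per-variable scaling,
no Procrustes superimposition and no size normalization — overall size is
itself the leading anatomical mode and must survive into back-calculation,
and rigid pose is already controlled by the landmark frame (a property
test verifies that a common translation shifts only the mean).
Contribution rates divide each eigenvalue by the total variance over *all*
n − 1 nontrivial directions, so the 16 kept components legitimately
cumulate below 100%. Component signs follow a fixed convention (the
largest-magnitude entry of each component is positive); projection and
reconstruction identities are sign-invariant. The decomposition is
delegated to scikit-learn's full-SVD PCA and cross-checked in the tests
against an independent covariance eigendecomposition at 1e-8.

Requesting more components than min(n − 1, 3V) is an error naming the rank
bound. A cohort of identical shapes yields all-zero eigenvalues and, by
convention, zero contribution rates.

## Score regression and prediction

One OLS equation per whole-mandible component on all 16 half-mandible
scores plus intercept — equivalently a multi-output linear regression; no
variable selection, no regularization. Identifiability requires
n > K_HM + 1; a rank-deficient predictor matrix is an error suggesting
fewer components; n < 2(K_HM + 1) triggers a warning that 17 parameters
per equation from a 44-specimen cohort is noisy — a deliberate property of
the reproduced protocol, not of this implementation. Prediction composes
projection, regression and back-calculation, and is therefore affine in
the half-shape scores (property-tested). The default evaluation protocol
is leave-one-out cross-validation (each specimen predicted by spaces *and*
regression refit without it); an in-sample mode exists for comparison with
protocols that do not hold data out.

## Distance evaluation

"Face-to-face" distance is the distance from each source vertex to the
nearest point of the target surface, with the vertex/edge/interior regions
of every triangle handled exactly. The implementation vectorizes the
classical closest-point-on-triangle classification over point×triangle
blocks; a KD-tree nearest-vertex upper bound plus triangle-bound culling
prunes only triangles that provably cannot win, so results equal
exhaustive search (tested at 1e-12 against an independent
plane-projection + 2-D polygon-distance oracle). Reported statistics: MAE,
population SD (divisor n) over per-vertex distances, and max. The default
direction is predicted → actual; a symmetric mode averages both
directions. Cohort evaluation pools every vertex of every specimen, so
specimens weigh by vertex count. Because distances are non-negative and
right-skewed, SD can exceed MAE.

## Problem sizes and determinism

The acceptance-level pipeline uses 44 specimens, level-3 target surfaces,
level-0→1 templates (~2 000-face models), 16 components and full
leave-one-out refitting; one such run completes in well under a minute on
a single CPU. Every stochastic stage draws from a generator seeded from
the single run seed, and the run manifest records the config hash and all
written files; rerunning a config reproduces all numbers exactly.

## Known limitations

- Correspondence quality is only as good as the landmark scheme plus the
  smoothness prior; between landmarks, "homology" is geometric, not
  biological.
- The linear shape space cannot represent large articulated variation
  (e.g. extreme gonial-angle change) without curvature error; scores are
  global, so localized defects influence all components.
- The half-mandible point selection (x ≥ −1 mm in the canonical frame)
  assumes the preserved half is the right side, matching the half-landmark
  scheme.
- Binary STL output quantizes coordinates to float32 (~6e-6 mm at 100 mm);
  ASCII STL/OBJ/PLY round-trip at full precision.
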