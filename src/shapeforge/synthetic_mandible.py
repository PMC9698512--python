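"""Seeded generator of mandible-like bilateral surfaces with known latent structure.

The generator is parametric-analytic: a tube swept along a parabolic-elliptic
dental arch with two posterior rami, Gaussian-bump condylar and coronoid
processes, and a closed cap at each condyle. It emulates a CT-derived cohort
whose dominant modes of variation are overall size, ramus length/angle, and
arch V/U shape, with controllable left-right asymmetry and vertex-level noise
— exactly the latent factors the downstream shape space is meant to recover.

The right side is the "preserved" half: the half-mandible landmark scheme is
right-sided and the asymmetry warp acts on the right side only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    HM12_NAMES,
    LandmarkSet,
    Scheme,
    TM20_NAMES,
    TriangleMesh,
)
from .template_fit import subdivide

__all__ = [
    "LatentFactors",
    "SyntheticSpecimen",
    "DEFAULT_FACTOR_SDS",
    "make_reference_mandible",
    "make_reference_half_mandible",
    "deform_reference",
    "sample_population",
]

# -- reference geometry constants (mm) --------------------------------------
_ARCH_HALF_WIDTH = 48.0     # lateral half-width of the dental arch ellipse
_ARCH_DEPTH = 52.0          # anterior depth of the arch ellipse
_THETA_MAX = 1.95           # arch sweep angle (rad) from chin to gonion
_CONDYLE = np.array([49.0, -28.0, 42.0])   # right condylar endpoint
_N_BODY_RINGS = 10
_N_RAMUS_RINGS = 6
_N_SEGMENTS = 8

# Cohort sampling defaults: per-factor standard deviations of the population.
DEFAULT_FACTOR_SDS: dict[str, float] = {
    "size": 0.05,          # ~5% overall size variation
    "ramus_length": 2.0,   # mm
    "ramus_angle": 3.0,    # degrees
    "arch_shape": 0.5,     # dimensionless V(-)/U(+) factor
    "asymmetry": 0.3,      # ~0.3 mm smooth right-side-only warp
}
DEFAULT_NOISE_SD = 0.2     # mm, along vertex normals


@dataclass(frozen=True)
class LatentFactors:
    """Ground-truth generative factors for one specimen.

    ``size`` is a dimensionless scale (1 = reference); ``ramus_length`` (mm)
    and ``ramus_angle`` (degrees) deform the rami about each gonion;
    ``arch_shape`` warps arch width (negative = V-like, positive = U-like);
    ``asymmetry`` (>= 0) drives a smooth right-side-only warp; ``noise_sd``
    (mm) is per-vertex Gaussian noise along vertex normals.
    """

    size: float = 1.0
    ramus_length: float = 0.0
    ramus_angle: float = 0.0
    arch_shape: float = 0.0
    asymmetry: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"size must be > 0, got {self.size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.asymmetry < 0:
            raise ValueError(f"asymmetry must be >= 0, got {self.asymmetry}")


@dataclass
class SyntheticSpecimen:
    """A generated surface plus both landmark sets and the generative truth."""

    surface: TriangleMesh
    tm_landmarks: LandmarkSet
    hm_landmarks: LandmarkSet
    truth: LatentFactors


# ---------------------------------------------------------------------------
# Reference surface construction
# ---------------------------------------------------------------------------

def _body_center(t: np.ndarray) -> np.ndarray:
    """Arch centerline for t in [0, 1] (0 = chin midline, 1 = gonion)."""
    theta = np.asarray(t) * _THETA_MAX
    return np.stack(
        [
            _ARCH_HALF_WIDTH * np.sin(theta),
            _ARCH_DEPTH * np.cos(theta),
            3.0 * np.asarray(t) ** 2,
        ],
        axis=-1,
    )


def _body_radius(t: np.ndarray) -> np.ndarray:
    return 7.5 - 1.5 * np.asarray(t)


def _gonion() -> np.ndarray:
    return _body_center(np.array(1.0))


def _ramus_center(u: np.ndarray) -> np.ndarray:
    """Ramus centerline for u in (0, 1] from gonion to condyle, slightly bowed."""
    u = np.asarray(u)[..., None]
    pg = _gonion()
    bow = np.sin(np.pi * u) * np.array([1.5, -3.0, 0.0])
    return pg + u * (_CONDYLE - pg) + bow


def _ramus_radius(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u)
    return 6.0 - 2.2 * u + 2.0 * np.exp(-(((u - 1.0) / 0.15) ** 2))


def _coronoid_bump(points: np.ndarray) -> np.ndarray:
    """Mirror-paired Gaussian bump displacement realizing the coronoid processes."""
    center_r = np.array([48.9, -20.0, 34.0])
    direction = np.array([0.0, 0.3, 1.0])
    direction = direction / np.linalg.norm(direction)
    amp, sigma = 7.0, 4.5
    out = np.zeros_like(points)
    for center, mirror in ((center_r, 1.0), (center_r * [-1, 1, 1], -1.0)):
        w = np.exp(-np.sum((points - center) ** 2, axis=1) / (2 * sigma**2))
        d = direction * np.array([mirror, 1.0, 1.0])
        out += amp * w[:, None] * d
    return out


def _right_tube() -> tuple[np.ndarray, np.ndarray, int, int]:
    """Right-half ring vertices (rings stacked, condyle tip last, coronoid bump
    applied) plus the ring centers; returns (vertices, centers, n_rings, k)."""
    k = _N_SEGMENTS
    t_body = np.linspace(0.0, 1.0, _N_BODY_RINGS)
    u_ramus = np.arange(1, _N_RAMUS_RINGS + 1) / _N_RAMUS_RINGS
    centers = np.vstack([_body_center(t_body), _ramus_center(u_ramus)])
    radii = np.concatenate([_body_radius(t_body), _ramus_radius(u_ramus)])
    n_rings = len(centers)

    # parallel-transported cross-section frames along the centerline
    tangents = np.gradient(centers, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    e1 = np.zeros_like(centers)
    e2 = np.zeros_like(centers)
    e1[0] = (0.0, 1.0, 0.0)
    e2[0] = (0.0, 0.0, 1.0)
    for i in range(1, n_rings):
        v = e1[i - 1] - np.dot(e1[i - 1], tangents[i]) * tangents[i]
        e1[i] = v / np.linalg.norm(v)
        e2[i] = np.cross(tangents[i], e1[i])

    phi = 2 * np.pi * np.arange(k) / k
    rings = (
        centers[:, None, :]
        + radii[:, None, None]
        * (np.cos(phi)[None, :, None] * e1[:, None, :]
           + np.sin(phi)[None, :, None] * e2[:, None, :])
    )
    right = rings.reshape(-1, 3)
    tip_r = centers[-1] + tangents[-1] * 0.8 * radii[-1]
    right = np.vstack([right, tip_r])
    right += _coronoid_bump(right)
    return right, centers, n_rings, k


def _build_base_mandible() -> tuple[TriangleMesh, dict[str, np.ndarray]]:
    """Construct the level-0 closed tube surface plus right/midline anchor points."""
    right, centers, n_rings, k = _right_tube()
    radii = np.concatenate(
        [
            _body_radius(np.linspace(0.0, 1.0, _N_BODY_RINGS)),
            _ramus_radius(np.arange(1, _N_RAMUS_RINGS + 1) / _N_RAMUS_RINGS),
        ]
    )

    # ring 0 lies exactly in the x = 0 plane; left half mirrors rings 1..n-1
    assert np.allclose(right[:k, 0], 0.0, atol=1e-12)
    left = right[k:] * np.array([-1.0, 1.0, 1.0])
    vertices = np.vstack([right, left])
    n_right = len(right)

    def rid(ring: int, seg: int) -> int:
        return ring * k + seg % k

    def lid(ring: int, seg: int) -> int:
        if ring == 0:
            return rid(0, seg)
        return n_right + (ring - 1) * k + seg % k

    faces: list[tuple[int, int, int]] = []
    for vid, flip in ((rid, False), (lid, True)):
        for i in range(n_rings - 1):
            for s in range(k):
                a, b = vid(i, s), vid(i, s + 1)
                c, d = vid(i + 1, s), vid(i + 1, s + 1)
                quad = [(a, b, d), (a, d, c)]
                if flip:
                    quad = [tuple(reversed(f)) for f in quad]
                faces.extend(quad)
        tip = (n_right - 1) if not flip else (len(vertices) - 1)
        for s in range(k):
            f = (vid(n_rings - 1, s), vid(n_rings - 1, s + 1), tip)
            faces.append(tuple(reversed(f)) if flip else f)

    mesh = TriangleMesh(vertices, np.array(faces))

    # -- landmark anchors (right side + midline), from the same analytics ----
    chin_c, chin_r = centers[0], radii[0]
    bump_w = np.exp(
        -np.sum((right - np.array([48.9, -20.0, 34.0])) ** 2, axis=1) / (2 * 4.5**2)
    )
    coronoid = right[int(np.argmax(bump_w))]
    condyle = right[n_right - 1]
    notch = (coronoid + condyle) / 2.0 - np.array([0.0, 0.0, 3.0])
    pg = _gonion()
    out_dir = pg * np.array([1.0, 1.0, 0.0])
    out_dir = out_dir / np.linalg.norm(out_dir)
    gonion_pt = pg + _body_radius(np.array(1.0)) * (0.6 * out_dir + np.array([0, 0, -0.8]))

    def arch_top(t: float) -> np.ndarray:
        return _body_center(np.array(t)) + _body_radius(np.array(t)) * np.array([0, 0, 1.0])

    def arch_bottom(t: float) -> np.ndarray:
        return _body_center(np.array(t)) - _body_radius(np.array(t)) * np.array([0, 0, 1.0])

    anchors = {
        "condylar head": condyle,
        "mandibular notch": notch,
        "coronoid process": coronoid,
        "premolar": arch_top(0.33),
        "incisor-canine": arch_top(0.18),
        "mandibular angle": gonion_pt,
        "plane incisor-canine": arch_bottom(0.18),
        "central-lateral": arch_top(0.08),
        "mentaris": chin_c + chin_r * np.array([0.0, 1.0, 0.0]),
        "mental spines": chin_c + chin_r * np.array([0.0, -1.0, 0.0]),
        "spines-central": chin_c + chin_r * np.array([0.0, -0.7071067811865476, 0.7071067811865476]),
        "central midline": chin_c + chin_r * np.array([0.0, 0.0, 1.0]),
        "lower central near": arch_top(0.04),
    }
    return mesh, anchors


def _mirror(p: np.ndarray) -> np.ndarray:
    return p * np.array([-1.0, 1.0, 1.0])


def _landmarks_from_anchors(anchors: dict[str, np.ndarray]) -> tuple[LandmarkSet, LandmarkSet]:
    a = anchors
    tm = {
        "Right condylar head": a["condylar head"],
        "Left condylar head": _mirror(a["condylar head"]),
        "Right mandibular notch": a["mandibular notch"],
        "Left mandibular notch": _mirror(a["mandibular notch"]),
        "Right coronoid process": a["coronoid process"],
        "Left coronoid process": _mirror(a["coronoid process"]),
        "Between right lower first and second premolar": a["premolar"],
        "Between left lower first and second premolar": _mirror(a["premolar"]),
        "Between right lower incisor and canine": a["incisor-canine"],
        "Between left lower incisor and canine": _mirror(a["incisor-canine"]),
        "Right mandibular angle": a["mandibular angle"],
        "Left mandibular angle": _mirror(a["mandibular angle"]),
        "Mandibular plane between right lower incisor and canine": a["plane incisor-canine"],
        "Mandibular plane between left lower incisor and canine": _mirror(a["plane incisor-canine"]),
        "Between right lower central and lateral incisor": a["central-lateral"],
        "Between left lower central and lateral incisor": _mirror(a["central-lateral"]),
        "Centre of mentaris": a["mentaris"],
        "Mental spines": a["mental spines"],
        "Between No 18 and No 20": a["spines-central"],
        "Between right and left lower central": a["central midline"],
    }
    hm = {
        "Right condylar head": a["condylar head"],
        "Right mandibular notch": a["mandibular notch"],
        "Right coronoid process": a["coronoid process"],
        "Between right lower first and second premolar": a["premolar"],
        "Between right lower incisor and canine": a["incisor-canine"],
        "Right mandibular angle": a["mandibular angle"],
        "Mandibular plane between right lower incisor and canine": a["plane incisor-canine"],
        "Between right lower central and lateral incisor": a["central-lateral"],
        "Centre of mentaris": a["mentaris"],
        "Mental spines": a["mental spines"],
        "Between No 10 and No 12": a["spines-central"],
        "Left lower central": _mirror(a["lower central near"]),
    }
    tm_set = LandmarkSet(list(TM20_NAMES), np.array([tm[n] for n in TM20_NAMES]), Scheme.TM20)
    hm_set = LandmarkSet(list(HM12_NAMES), np.array([hm[n] for n in HM12_NAMES]), Scheme.HM12)
    return tm_set, hm_set


def make_reference_mandible(
    resolution: int = 0,
) -> tuple[TriangleMesh, LandmarkSet, LandmarkSet]:
    """Build the closed, mirror-symmetric reference mandible surface.

    ``resolution`` applies midpoint subdivision: level r+1 has 4x the faces of
    level r. Returns (mesh, TM20 landmarks, HM12 landmarks); the mesh is
    exactly symmetric about the midsagittal plane x = 0.
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    mesh, anchors = _build_base_mandible()
    if resolution > 0:
        mesh = subdivide(mesh, resolution)
    tm, hm = _landmarks_from_anchors(anchors)
    return mesh, tm, hm


def make_reference_half_mandible(resolution: int = 0) -> tuple[TriangleMesh, LandmarkSet]:
    """Build the right half-mandible reference: the right tube, closed by a cap
    at the condyle and a fan cap on the midsagittal ring. Returns the mesh and
    its HM12 landmarks (identical points to the full reference's right side)."""
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    right, centers, n_rings, k = _right_tube()
    chin_center = centers[0] + _coronoid_bump(centers[:1])[0]
    vertices = np.vstack([right, chin_center])
    tip = len(right) - 1
    chin = len(vertices) - 1

    def rid(ring: int, seg: int) -> int:
        return ring * k + seg % k

    faces: list[tuple[int, int, int]] = []
    for i in range(n_rings - 1):
        for s in range(k):
            a, b = rid(i, s), rid(i, s + 1)
            c, d = rid(i + 1, s), rid(i + 1, s + 1)
            faces.extend([(a, b, d), (a, d, c)])
    for s in range(k):
        faces.append((rid(n_rings - 1, s), rid(n_rings - 1, s + 1), tip))
        faces.append((rid(0, s + 1), rid(0, s), chin))
    mesh = TriangleMesh(vertices, np.array(faces))
    if resolution > 0:
        mesh = subdivide(mesh, resolution)
    _, anchors = _build_base_mandible()
    _, hm = _landmarks_from_anchors(anchors)
    return mesh, hm


# ---------------------------------------------------------------------------
# Deformation
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _ramus_weight(points: np.ndarray) -> np.ndarray:
    """Smooth weight selecting the ramus (vanishes on the body and midline)."""
    wz = _smoothstep((points[:, 2] - 6.0) / 18.0)
    wy = _smoothstep((-points[:, 1] - 5.0) / 10.0)
    return wz * wy


def _warp_ramus_right(points: np.ndarray, length: float, angle_deg: float,
                      gonion: np.ndarray, condyle: np.ndarray) -> np.ndarray:
    """Right-side ramus warp: elongation along the ramus axis + rotation about
    the lateral axis through the gonion, both weighted smoothly."""
    w = _ramus_weight(points)
    out = points.copy()
    if length != 0.0:
        axis = condyle - gonion
        axis = axis / np.linalg.norm(axis)
        out = out + (length * w)[:, None] * axis
    if angle_deg != 0.0:
        alpha = np.deg2rad(angle_deg) * w
        rel = out - gonion
        cos, sin = np.cos(alpha), np.sin(alpha)
        y, z = rel[:, 1].copy(), rel[:, 2].copy()
        rel[:, 1] = cos * y - sin * z
        rel[:, 2] = sin * y + cos * z
        out = gonion + rel
    return out


def _apply_bilateral(points: np.ndarray, right_fn) -> np.ndarray:
    """Apply a right-side warp and its mirror conjugate to the left side.

    The warp must be the identity on the midsagittal plane, which holds for
    all warps here (their weights vanish near x = 0).
    """
    out = points.copy()
    r = points[:, 0] >= 0.0
    out[r] = right_fn(points[r])
    flip = np.array([-1.0, 1.0, 1.0])
    out[~r] = right_fn(points[~r] * flip) * flip
    return out


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    return np.asarray(mesh.to_trimesh().vertex_normals, dtype=float)


def deform_reference(
    reference: tuple[TriangleMesh, LandmarkSet, LandmarkSet],
    factors: LatentFactors,
    seed: int | None = 0,
) -> SyntheticSpecimen:
    """Deform the reference by the latent factors, carrying landmarks through.

    Warps apply in order: global scaling about the centroid; ramus elongation
    and rotation about each gonion; arch V/U width warp; smooth right-side
    asymmetry warp; then seeded per-vertex Gaussian noise along vertex normals
    (the mesh only — landmarks stay noise-free). Identity factors return the
    reference bitwise.
    """
    mesh, tm, hm = reference
    pts = mesh.vertices.copy()
    lm_tm = tm.points.copy()
    lm_hm = hm.points.copy()

    def apply_all(fn) -> None:
        nonlocal pts, lm_tm, lm_hm
        pts, lm_tm, lm_hm = fn(pts), fn(lm_tm), fn(lm_hm)

    tm_names = tm.names

    if factors.size != 1.0:
        centroid = mesh.vertices.mean(axis=0)
        apply_all(lambda p: centroid + factors.size * (p - centroid))

    if factors.ramus_length != 0.0 or factors.ramus_angle != 0.0:
        gonion = lm_tm[tm_names.index("Right mandibular angle")].copy()
        condyle = lm_tm[tm_names.index("Right condylar head")].copy()
        apply_all(
            lambda p: _apply_bilateral(
                p,
                lambda q: _warp_ramus_right(
                    q, factors.ramus_length, factors.ramus_angle, gonion, condyle
                ),
            )
        )

    if factors.arch_shape != 0.0:

        def arch_warp(p: np.ndarray) -> np.ndarray:
            ynorm = _smoothstep((p[:, 1] + 20.0) / 70.0)
            out = p.copy()
            out[:, 0] = p[:, 0] * (1.0 + 0.25 * factors.arch_shape * ynorm)
            return out

        apply_all(arch_warp)

    if factors.asymmetry != 0.0:

        def asym_warp(p: np.ndarray) -> np.ndarray:
            s = _smoothstep(p[:, 0] / 10.0)
            d = np.stack(
                [
                    0.6 * np.sin(np.pi * p[:, 1] / 40.0),
                    0.5 * np.cos(np.pi * p[:, 2] / 30.0),
                    0.4 * np.sin(np.pi * (p[:, 0] + p[:, 1]) / 50.0),
                ],
                axis=1,
            )
            return p + factors.asymmetry * s[:, None] * d

        apply_all(asym_warp)

    out_mesh = TriangleMesh(pts, mesh.faces.copy())
    if factors.noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        normals = _vertex_normals(out_mesh)
        eps = rng.normal(0.0, factors.noise_sd, size=len(pts))
        out_mesh = TriangleMesh(pts + eps[:, None] * normals, mesh.faces.copy())

    return SyntheticSpecimen(
        surface=out_mesh,
        tm_landmarks=LandmarkSet(list(tm.names), lm_tm, Scheme.TM20),
        hm_landmarks=LandmarkSet(list(hm.names), lm_hm, Scheme.HM12),
        truth=factors,
    )


def sample_population(
    n: int,
    factor_sds: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    resolution: int = 2,
) -> list[SyntheticSpecimen]:
    """Draw a seeded cohort of specimens with Gaussian latent factors.

    Factors are drawn independently around the identity (size 1, all offsets
    0) with the given standard deviations; ``asymmetry`` uses the absolute
    value of its Gaussian draw to respect its non-negativity. Deterministic
    given ``seed``.
    """
    if n < 2:
        raise ValueError("a population needs n >= 2 specimens (PCA requires >= 2)")
    sds = dict(DEFAULT_FACTOR_SDS)
    if factor_sds is not None:
        unknown = set(factor_sds) - set(sds)
        if unknown:
            raise ValueError(f"unknown factor names: {sorted(unknown)}")
        sds.update(factor_sds)
    rng = np.random.default_rng(seed)
    draws = {k: rng.normal(0.0, 1.0, size=n) * sds[k] for k in
             ("size", "ramus_length", "ramus_angle", "arch_shape", "asymmetry")}
    noise_seeds = rng.integers(0, 2**31, size=n)
    reference = make_reference_mandible(resolution=resolution)
    population = []
    for i in range(n):
        factors = LatentFactors(
            size=1.0 + draws["size"][i],
            ramus_length=draws["ramus_length"][i],
            ramus_angle=draws["ramus_angle"][i],
            arch_shape=draws["arch_shape"][i],
            asymmetry=abs(draws["asymmetry"][i]),
            noise_sd=noise_sd,
        )
        population.append(deform_reference(reference, factors, seed=int(noise_seeds[i])))
    return population
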