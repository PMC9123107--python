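"""Synthetic paired lower-leg cohort with exact ground truth.

Stand-in for CT-derived surface models of paired cadaveric lower legs: each
pair holds an ipsilateral (template) tibia and fibula plus a contralateral
side that is, by construction, a mirror image with controlled low-amplitude
asymmetry — per-bone isotropic scale, band-limited radial shape noise, and
length jitter.  A known rigid displacement (shortening/lengthening plus
axial malrotation) can be injected into the contralateral distal fibula to
emulate a malunion with exact ground truth.

Bones are lofted tubes with analytic displacement fields for the landmarks
that anchor contralateral registration: tibial plateau flare, distal tibial
flare with medial-malleolus protrusion, fibular-notch concavity and anterior
tubercle; fibular head and distal lateral-malleolus bulge.  The parametric
construction keeps exact vertex-wise correspondence between sides, which the
pipeline uses for the correspondence-based zero-error reference pose.

Canonical construction frame (right leg): y runs distal → proximal along the
shaft, z medial → lateral (the fibula sits at +z), x = y × z anterior.  Left
pairs are the same geometry mirrored across the z = 0 plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anatomy import AnatomicalFrame, build_anatomical_frame
from .mesh_core import TriMesh, mirror_mesh, signed_volume
from .registration import RigidTransform

__all__ = [
    "CohortParams",
    "BonePairGroundTruth",
    "LowerLegPair",
    "generate_bone_pair",
    "inject_deformity",
    "generate_cohort",
]

#: mirror plane used for all left/right conversions (medial-lateral axis)
MIRROR_AXIS = "z"

#: cosine taper length (mm) joining the displaced distal fragment to the shaft
BLEND_ZONE_MM = 10.0

#: fraction of fibula length treated as the (possibly deformed) distal fragment
DISTAL_FRACTION = 0.25


@dataclass(frozen=True)
class CohortParams:
    """Generator settings.

    Lengths are mm.  ``scale_sigma`` is the s.d. of the per-bone isotropic
    contralateral scale factor around 1; ``shape_noise_mm`` the RMS amplitude
    of band-limited radial surface noise on the contralateral side;
    ``length_jitter_mm`` the s.d. of contralateral length jitter;
    ``fibula_shaft_noise_mm`` extra radial noise confined to the fibular
    shaft (proximal of the distal quarter), for cohorts whose asymmetry is
    concentrated there.  ``ring_spacing_mm`` and ``n_theta`` set the mesh
    density of the loft.
    """

    tibia_length: float = 360.0
    fibula_length: float = 350.0
    ring_spacing_mm: float = 3.0
    n_theta: int = 40
    scale_sigma: float = 0.01
    shape_noise_mm: float = 0.6
    length_jitter_mm: float = 2.0
    fibula_shaft_noise_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tibia_length > 100 and self.fibula_length > 100):
            raise ValueError("bone lengths must exceed 100 mm")
        if self.ring_spacing_mm <= 0 or self.n_theta < 8:
            raise ValueError("mesh density parameters out of range")
        for name in ("scale_sigma", "shape_noise_mm", "length_jitter_mm",
                     "fibula_shaft_noise_mm"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.shape_noise_mm > 3 or self.fibula_shaft_noise_mm > 3:
            raise ValueError("shape noise above 3 mm would destroy landmarks")


@dataclass(frozen=True)
class BonePairGroundTruth:
    """Construction-time ground truth stored with every synthetic pair.

    ``injected_translation_y``/``injected_rotation_y`` are expressed in the
    pooled right-leg report convention: a negative translation shifts the
    distal fragment distally (lengthening, reported as a *positive*
    translation error) and a positive rotation is external rotation (reported
    as a positive rotation error).
    """

    construction_frame: AnatomicalFrame
    true_mirror_transform: RigidTransform
    injected_translation_y: float
    injected_rotation_y: float
    asymmetry_params: dict
    seed: int
    has_vertex_correspondence: bool = True

    @property
    def expected_translation_error(self) -> float:
        return -self.injected_translation_y

    @property
    def expected_rotation_error(self) -> float:
        return self.injected_rotation_y


@dataclass(frozen=True)
class LowerLegPair:
    ipsi_tibia: TriMesh
    ipsi_fibula: TriMesh
    contra_tibia: TriMesh
    contra_fibula: TriMesh
    truth: BonePairGroundTruth
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


# ---------------------------------------------------------------------------
# parametric bone templates


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _angular_bump(theta: np.ndarray, theta0: float, sigma: float) -> np.ndarray:
    d = (theta - theta0 + np.pi) % (2.0 * np.pi) - np.pi
    return np.exp(-((d / sigma) ** 2))


def _tibia_radius(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Radial profile (mm) of the tibial template.

    Shaft radius 13 mm; proximal plateau flare to ~22 mm (the largest
    cross-section, which disambiguates distal vs proximal); distal flare
    carrying the medial malleolus (bump at -z), the fibular-notch concavity
    (groove at +z) and the anterior tubercle.
    """
    r = np.full(np.broadcast_shapes(t.shape, theta.shape), 13.0)
    r = r + 1.5 * np.cos(3.0 * theta + 0.9)  # triangular shaft cross-section
    r = r + 9.0 * _smoothstep((t - 0.82) / 0.15)
    r = r + 4.0 * _smoothstep((0.12 - t) / 0.12)
    r = r + 7.0 * np.exp(-(((t - 0.02) / 0.05) ** 2)) * _angular_bump(theta, -np.pi / 2, 0.55)
    r = r - 3.5 * np.exp(-(((t - 0.055) / 0.06) ** 2)) * _angular_bump(theta, np.pi / 2, 0.45)
    r = r + 2.5 * np.exp(-(((t - 0.07) / 0.05) ** 2)) * _angular_bump(theta, np.pi / 6, 0.40)
    return r


def _fibula_radius(t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Slender fibular shaft (6 mm) with proximal head flare and the distal
    lateral-malleolus bulge (emphasised laterally)."""
    r = np.full(np.broadcast_shapes(t.shape, theta.shape), 6.0)
    # ridged (anterior/interosseous) shaft cross-section with a slow helical
    # twist; without it the shaft is a surface of revolution and its axial
    # rotation would be unconstrained in registration
    r = r + 1.2 * np.cos(3.0 * theta - 0.5 - 0.8 * t)
    r = r + 3.0 * _smoothstep((t - 0.90) / 0.10)
    r = r + 2.0 * np.exp(-(((t - 0.045) / 0.07) ** 2))
    r = r + 3.0 * np.exp(-(((t - 0.05) / 0.08) ** 2)) * _angular_bump(theta, np.pi / 2, 0.7)
    return r


#: fibular shaft axis offset from the tibial axis (mm): slightly posterior
#: (-x) and clearly lateral (+z)
FIBULA_OFFSET = (-5.0, 16.0)

#: fibular distal end sits below the tibial plafond (mm)
FIBULA_Y0 = -8.0


def _loft_tube(radius_grid: np.ndarray, y_coords: np.ndarray, cx: float, cz: float,
               n_theta: int) -> TriMesh:
    """Closed tube mesh from a (n_rings, n_theta) radius grid.

    Rings lie in x-z planes at ``y_coords``; end caps are triangle fans.
    Winding gives outward normals (positive signed volume).
    """
    n_rings = radius_grid.shape[0]
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    verts = np.empty((n_rings * n_theta + 2, 3))
    for i in range(n_rings):
        sl = slice(i * n_theta, (i + 1) * n_theta)
        verts[sl, 0] = cx + radius_grid[i] * cos_t
        verts[sl, 1] = y_coords[i]
        verts[sl, 2] = cz + radius_grid[i] * sin_t
    bottom = n_rings * n_theta
    top = bottom + 1
    verts[bottom] = (cx, y_coords[0], cz)
    verts[top] = (cx, y_coords[-1], cz)

    faces = []
    for i in range(n_rings - 1):
        base0 = i * n_theta
        base1 = (i + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append((base0 + j, base1 + j, base1 + j1))
            faces.append((base0 + j, base1 + j1, base0 + j1))
    for j in range(n_theta):
        j1 = (j + 1) % n_theta
        faces.append((bottom, j, j1))
        faces.append((top, (n_rings - 1) * n_theta + j1, (n_rings - 1) * n_theta + j))
    mesh = TriMesh(verts, np.asarray(faces, dtype=np.int64))
    assert signed_volume(mesh) > 0
    return mesh


def _noise_field(rng: np.random.Generator, t: np.ndarray, theta: np.ndarray,
                 amplitude: float, window: np.ndarray | None = None) -> np.ndarray:
    """Band-limited (low-frequency) radial noise with the given RMS amplitude.

    Low axial/circumferential Fourier modes only, so millimetre-scale
    landmarks persist under the default amplitudes.  Coefficients are always
    drawn, keeping the random stream identical whether or not the amplitude
    is zero.
    """
    k_max, m_max = 2, 3
    coefs = rng.normal(size=(k_max + 1, m_max + 1, 4))
    f = np.zeros((len(t), len(theta)))
    tt = t[:, None]
    th = theta[None, :]
    for k in range(k_max + 1):
        ck, sk = np.cos(2 * np.pi * k * tt), np.sin(2 * np.pi * k * tt)
        for m in range(m_max + 1):
            cm, sm = np.cos(m * th), np.sin(m * th)
            c = coefs[k, m]
            f = f + c[0] * ck * cm + c[1] * ck * sm + c[2] * sk * cm + c[3] * sk * sm
    if amplitude == 0.0:
        return np.zeros_like(f)
    if window is not None:
        f = f * window[:, None]
    rms = float(np.sqrt(np.mean(f**2)))
    if rms == 0.0:
        return np.zeros_like(f)
    return f * (amplitude / rms)


def _build_bone(kind: str, params: CohortParams, scale: float, length_jitter: float,
                noise: np.ndarray | None) -> TriMesh:
    base_length = params.tibia_length if kind == "tibia" else params.fibula_length
    n_rings = max(8, int(round(base_length / params.ring_spacing_mm)) + 1)
    t = np.linspace(0.0, 1.0, n_rings)
    theta = np.arange(params.n_theta) * (2.0 * np.pi / params.n_theta)
    radius_fn = _tibia_radius if kind == "tibia" else _fibula_radius
    radius = scale * radius_fn(t[:, None], theta[None, :])
    if noise is not None:
        radius = np.maximum(radius + noise, 0.5)
    length = scale * base_length + length_jitter
    if kind == "tibia":
        cx, cz, y0 = 0.0, 0.0, 0.0
    else:
        cx, cz = FIBULA_OFFSET
        y0 = FIBULA_Y0
    y = y0 + t * length
    return _loft_tube(radius, y, cx, cz, params.n_theta)


def _grid_shape(kind: str, params: CohortParams) -> tuple[np.ndarray, np.ndarray]:
    base_length = params.tibia_length if kind == "tibia" else params.fibula_length
    n_rings = max(8, int(round(base_length / params.ring_spacing_mm)) + 1)
    return np.linspace(0.0, 1.0, n_rings), np.arange(params.n_theta) * (
        2.0 * np.pi / params.n_theta
    )


# ---------------------------------------------------------------------------
# pair and cohort generation


def generate_bone_pair(params: CohortParams | None = None, seed: int = 0,
                       side: str = "right") -> LowerLegPair:
    """Deterministically generate one paired lower leg.

    The ipsilateral side is the clean template; the contralateral side is its
    mirror image with per-bone scale, band-limited radial shape noise, and
    length jitter applied before mirroring, so exact vertex correspondence is
    preserved.  With all asymmetry parameters zero the contralateral meshes
    are exact mirror images of the ipsilateral ones.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)

    # the ipsilateral template
    ipsi = {kind: _build_bone(kind, params, 1.0, 0.0, None) for kind in ("tibia", "fibula")}

    contra = {}
    asym = {
        "scale_sigma": params.scale_sigma,
        "shape_noise_mm": params.shape_noise_mm,
        "length_jitter_mm": params.length_jitter_mm,
        "fibula_shaft_noise_mm": params.fibula_shaft_noise_mm,
    }
    for kind in ("tibia", "fibula"):
        scale = float(rng.normal(1.0, params.scale_sigma))
        jitter = float(rng.normal(0.0, params.length_jitter_mm))
        t, theta = _grid_shape(kind, params)
        noise = _noise_field(rng, t, theta, params.shape_noise_mm)
        if kind == "fibula":
            # extra asymmetry confined to the shaft, proximal of the distal
            # quarter and its blend margin
            window = _smoothstep((t - (DISTAL_FRACTION + 0.03)) / 0.10)
            noise = noise + _noise_field(rng, t, theta, params.fibula_shaft_noise_mm,
                                         window=window)
        else:
            rng.normal(size=(3, 4, 4))  # keep per-bone stream lengths equal
        contra[kind] = mirror_mesh(
            _build_bone(kind, params, scale, jitter, noise), MIRROR_AXIS
        )

    frame = build_anatomical_frame(ipsi["tibia"], ipsi["fibula"])
    truth = BonePairGroundTruth(
        construction_frame=frame,
        true_mirror_transform=RigidTransform.identity(),
        injected_translation_y=0.0,
        injected_rotation_y=0.0,
        asymmetry_params=asym,
        seed=seed,
    )
    meshes = dict(ipsi_tibia=ipsi["tibia"], ipsi_fibula=ipsi["fibula"],
                  contra_tibia=contra["tibia"], contra_fibula=contra["fibula"])
    if side == "left":
        meshes = {k: mirror_mesh(m, MIRROR_AXIS) for k, m in meshes.items()}
    return LowerLegPair(truth=truth, side=side, **meshes)


def inject_deformity(pair: LowerLegPair, translation_y: float,
                     rotation_y: float) -> LowerLegPair:
    """Displace the contralateral distal-quarter fibula by a known rigid motion.

    ``translation_y`` (mm) shifts the fragment along the shaft axis (negative
    = distal shift = lengthening of the restored fibula); ``rotation_y``
    (degrees) twists it about the fibular shaft axis through the fragment
    centroid, given in the pooled right-leg convention (positive = external
    rotation as recovered by the pipeline).  A cosine blend over
    ``BLEND_ZONE_MM`` proximal of the cut keeps the mesh connected; the
    distal fragment itself moves rigidly, so ground truth is exact there.
    """
    if abs(translation_y) > 10.0:
        raise ValueError("|translation_y| must be <= 10 mm")
    if abs(rotation_y) > 20.0:
        raise ValueError("|rotation_y| must be <= 20 degrees")

    fib = pair.contra_fibula
    y = fib.vertices[:, 1]
    ymin, ymax = float(y.min()), float(y.max())
    cut = ymin + DISTAL_FRACTION * (ymax - ymin)
    if cut + BLEND_ZONE_MM > ymax:
        raise ValueError("blend zone exceeds the fibula length")

    fragment = y <= cut
    centroid = fib.vertices[fragment].mean(axis=0)
    # a z-mirror flips the sense of rotations about y: conjugate so the
    # *reported* (right-leg convention) rotation equals rotation_y
    side_sign = 1.0 if pair.side == "right" else -1.0
    applied_deg = -side_sign * rotation_y
    motion = RigidTransform.from_rotvec(
        (0.0, applied_deg, 0.0), translation=(0.0, translation_y, 0.0), center=centroid
    )
    displaced = motion.apply(fib.vertices)

    w = np.zeros(len(y))
    w[fragment] = 1.0
    blend = (~fragment) & (y <= cut + BLEND_ZONE_MM)
    w[blend] = 0.5 * (1.0 + np.cos(np.pi * (y[blend] - cut) / BLEND_ZONE_MM))
    new_vertices = fib.vertices + w[:, None] * (displaced - fib.vertices)

    truth = replace(
        pair.truth,
        injected_translation_y=pair.truth.injected_translation_y + translation_y,
        injected_rotation_y=pair.truth.injected_rotation_y + rotation_y,
    )
    return replace(pair, contra_fibula=TriMesh(new_vertices, fib.faces), truth=truth)


def generate_cohort(n: int, params: CohortParams | None = None,
                    base_seed: int = 0) -> list[LowerLegPair]:
    """n independent pairs with seeds ``base_seed + i``, alternating sides
    (even index -> right, odd -> left)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or CohortParams()
    return [
        generate_bone_pair(params, seed=base_seed + i,
                           side="right" if i % 2 == 0 else "left")
        for i in range(n)
    ]
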