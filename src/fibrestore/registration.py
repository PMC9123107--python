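"""Rigid point-set registration.

Closed-form weighted least-squares pose (Kabsch/SVD with determinant
correction) and classic point-to-point iterative closest point (ICP) with
optional trimming of the worst correspondences.  Nearest neighbours are
exact (:class:`scipy.spatial.cKDTree`); ties resolve to the lowest point
index, so every run is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh_core import TriMesh

__all__ = [
    "RigidTransform",
    "ICPParams",
    "RegistrationResult",
    "DegenerateConfigurationError",
    "kabsch_solve",
    "icp_register",
    "apply_transform",
    "transform_difference",
]


class DegenerateConfigurationError(ValueError):
    """Point configuration does not determine a unique rigid pose."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation matrix + mm translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I)")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1, no reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0),
                    center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation given as an axis-angle vector in degrees, applied about
        ``center``, followed by ``translation``."""
        r = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True).as_matrix()
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - r @ c
        return cls(r, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))


@dataclass(frozen=True)
class ICPParams:
    """ICP settings: iteration cap, RMS-change stopping tolerance (mm),
    fraction of worst correspondences trimmed each iteration, and the
    initial pose estimate."""

    max_iter: int = 100
    rms_tolerance: float = 1e-4
    trim_fraction: float = 0.1
    init: RigidTransform | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rms_tolerance < 0:
            raise ValueError("rms_tolerance must be >= 0")
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")

    def with_init(self, init: RigidTransform) -> "ICPParams":
        return replace(self, init=init)


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    correspondences_used: int
    rms_history: tuple = field(default=(), repr=False)


def kabsch_solve(source_pts, target_pts, weights=None) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto paired targets.

    Minimises ``sum_i w_i ||R s_i + t - d_i||^2`` via SVD of the weighted
    cross-covariance, with the usual determinant correction so the solution
    is a proper rotation (never a reflection).
    """
    src = np.asarray(source_pts, dtype=float)
    dst = np.asarray(target_pts, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(src)
    if n < 3:
        raise DegenerateConfigurationError("need at least 3 point pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_s = w @ src
    mu_d = w @ dst
    s = src - mu_s
    d = dst - mu_d
    h = (s.T * w) @ d
    u, sing, vt = np.linalg.svd(h)
    if sing[1] <= 1e-12 * max(sing[0], 1e-30):
        raise DegenerateConfigurationError(
            "source points are (near-)collinear; rotation is not unique"
        )
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    r = vt.T @ diag @ u.T
    t = mu_d - r @ mu_s
    return RigidTransform(r, t)


def apply_transform(t: RigidTransform, geometry):
    """Apply a rigid transform to an (n, 3) point array or a TriMesh."""
    if isinstance(geometry, TriMesh):
        return TriMesh(t.apply(geometry.vertices), geometry.faces)
    return t.apply(geometry)


def icp_register(source_pts, target_pts, params: ICPParams | None = None) -> RegistrationResult:
    """Trimmed point-to-point ICP registering ``source_pts`` onto ``target_pts``.

    Alternates exact nearest-neighbour correspondence (source -> target),
    trimming of the worst ``trim_fraction`` pairs by distance, and a Kabsch
    solve.  With a fixed trim count the RMS residual over the kept pairs is
    non-increasing; iteration stops when the RMS change drops below
    ``rms_tolerance`` or at ``max_iter`` (then ``converged`` is False).
    """
    params = params or ICPParams()
    src = np.asarray(source_pts, dtype=float)
    dst = np.asarray(target_pts, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or dst.ndim != 2 or dst.shape[1] != 3:
        raise ValueError("point sets must be (n, 3) arrays")
    if len(src) < 10 or len(dst) < 10:
        raise ValueError("ICP needs at least 10 points in each set")

    tree = cKDTree(dst)
    n_keep = max(3, int(np.ceil((1.0 - params.trim_fraction) * len(src))))
    current = params.init or RigidTransform.identity()

    history: list[float] = []
    prev_rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        moved = current.apply(src)
        dists, nn = tree.query(moved, k=1)
        if params.trim_fraction > 0.0:
            keep = np.argsort(dists, kind="stable")[:n_keep]
        else:
            keep = slice(None)
        step = kabsch_solve(moved[keep], dst[nn][keep])
        current = step.compose(current)
        moved = current.apply(src)
        resid = np.linalg.norm(moved[keep] - dst[nn][keep], axis=1)
        rms = float(np.sqrt(np.mean(resid**2)))
        history.append(rms)
        if abs(prev_rms - rms) < params.rms_tolerance:
            converged = True
            break
        prev_rms = rms

    return RegistrationResult(
        transform=current,
        rms_residual=history[-1],
        iterations=iterations,
        converged=converged,
        correspondences_used=n_keep if params.trim_fraction > 0.0 else len(src),
        rms_history=tuple(history),
    )


def transform_difference(t1: RigidTransform, t2: RigidTransform, at_point=(0.0, 0.0, 0.0)):
    """(rotation angle deg, displacement mm at ``at_point``) between two poses."""
    delta = t1.compose(t2.inverse())
    p = np.asarray(at_point, dtype=float)
    return delta.rotation_angle_deg(), float(np.linalg.norm(t1.apply(p) - t2.apply(p)))
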