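"""Distal-fibula restoration and rigid-pose error decomposition.

The restoration mirrors the contralateral lower leg, extracts one of the
four registration segments from both sides, registers the mirrored segment
onto the ipsilateral side with trimmed ICP, and carries the mirrored
contralateral distal-quarter fibula with the resulting transform.  The
deviation between that restored pose and a zero-error reference pose (a
direct registration of the mirrored distal fibula onto the ipsilateral one)
is decomposed, in the anatomical frame, into the four accuracy metrics:

* translation error (mm, signed): displacement of the distal-fibula
  reference point along the anatomical y-axis; positive = lengthening
  (distal displacement), negative = shortening;
* rotation error (deg, signed): twist of the error rotation about the
  y-axis via swing-twist decomposition; positive = external rotation in the
  pooled right-leg convention;
* Euclidean distance (mm): norm of the reference-point displacement;
* Euler's angle (deg): the single geodesic rotation angle of the error
  rotation, i.e. the total 3D angular deviation.

The error transform is expressed at the distal-fibula centroid so that a
pure rotation of the fragment does not leak into the translation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .anatomy import (
    SEGMENTS,
    AnatomicalFrame,
    SegmentName,
    SegmentSpec,
    build_anatomical_frame,
    extract_segment,
    DEFAULT_SAMPLE_DENSITY,
)
from .mesh_core import TriMesh, mirror_mesh
from .registration import (
    ICPParams,
    RegistrationResult,
    RigidTransform,
    icp_register,
    kabsch_solve,
)

__all__ = [
    "FibulaErrorReport",
    "RestorationResult",
    "restore_distal_fibula",
    "reference_pose",
    "decompose_error",
    "frame_alignment",
    "swing_twist_angle_deg",
]


@dataclass(frozen=True)
class FibulaErrorReport:
    """The four accuracy metrics for one leg pair and one segment."""

    segment: SegmentName
    translation_error: float  # mm, signed; + lengthening / - shortening
    rotation_error: float  # deg, signed; + external / - internal rotation
    euclidean_distance: float  # mm, >= 0
    euler_angle: float  # deg, >= 0
    icp_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.euclidean_distance < 0 or self.euler_angle < 0:
            raise ValueError("distance and angle magnitudes must be >= 0")
        if self.euclidean_distance < abs(self.translation_error) - 1e-9:
            raise ValueError("Euclidean distance cannot undercut its y-component")
        if self.euler_angle < abs(self.rotation_error) - 1e-9:
            raise ValueError("Euler's angle cannot undercut the axial twist")


@dataclass(frozen=True)
class RestorationResult:
    """Restored distal fibula point set plus the segment transform and
    registration diagnostics."""

    restored_distal_fibula: np.ndarray
    transform: RigidTransform
    registration: RegistrationResult
    frame: AnatomicalFrame


def frame_alignment(source: AnatomicalFrame, target: AnatomicalFrame) -> RigidTransform:
    """Rigid transform carrying one anatomical frame onto another.

    Used as the ICP initialisation: mirrored contralateral bones start close
    to the ipsilateral target, so aligning the two OBB-derived frames is a
    sufficient coarse alignment for every segment.
    """
    r = target.rotation @ source.rotation.T
    t = target.origin - r @ source.origin
    return RigidTransform(r, t)


def restore_distal_fibula(
    ipsi_tibia: TriMesh,
    ipsi_fibula: TriMesh,
    contra_tibia: TriMesh,
    contra_fibula: TriMesh,
    spec: SegmentSpec | SegmentName,
    icp_params: ICPParams | None = None,
    mirror_axis: str = "z",
    density: float = DEFAULT_SAMPLE_DENSITY,
    seed: int = 0,
) -> RestorationResult:
    """Restore the ipsilateral distal fibula from the contralateral side.

    Mirrors the contralateral pair, extracts ``spec``'s segment from the
    mirrored pair and the corresponding region of the ipsilateral pair,
    registers mirrored → ipsilateral with trimmed ICP (initialised by
    anatomical-frame alignment), and returns the mirrored contralateral
    distal-quarter fibula samples carried by the resulting transform.
    """
    if isinstance(spec, SegmentName):
        spec = SEGMENTS[spec]
    if spec.name == SegmentName.FIBULA_DISTAL_25:
        raise ValueError("the distal 25% fibula is the evaluation region, "
                         "not a registration segment")
    icp_params = icp_params or ICPParams()

    mc_tibia = mirror_mesh(contra_tibia, mirror_axis)
    mc_fibula = mirror_mesh(contra_fibula, mirror_axis)

    frame_ipsi = build_anatomical_frame(ipsi_tibia, ipsi_fibula)
    frame_mc = build_anatomical_frame(mc_tibia, mc_fibula)

    source = extract_segment(mc_tibia, mc_fibula, spec, frame_mc,
                             density=density, seed=seed + 1)
    target = extract_segment(ipsi_tibia, ipsi_fibula, spec, frame_ipsi,
                             density=density, seed=seed)

    init = icp_params.init or frame_alignment(frame_mc, frame_ipsi)
    result = icp_register(source, target, icp_params.with_init(init))

    distal = extract_segment(mc_tibia, mc_fibula, SegmentName.FIBULA_DISTAL_25,
                             frame_mc, density=density, seed=seed + 1)
    return RestorationResult(
        restored_distal_fibula=result.transform.apply(distal),
        transform=result.transform,
        registration=result,
        frame=frame_ipsi,
    )


def reference_pose(
    ipsi_fibula_distal: np.ndarray,
    mirrored_contra_fibula_distal: np.ndarray,
    icp_params: ICPParams | None = None,
    correspondence: bool = False,
) -> RigidTransform:
    """Zero-error reference: pose that best superimposes the mirrored
    contralateral distal fibula onto the ipsilateral one.

    With ``correspondence=True`` the two arrays are matched point-for-point
    (synthetic pairs with stored vertex correspondence) and the closed-form
    Kabsch solution is used; otherwise a direct trimmed ICP is run, with the
    centroid offset as initialisation.
    """
    ipsi = np.asarray(ipsi_fibula_distal, dtype=float)
    mc = np.asarray(mirrored_contra_fibula_distal, dtype=float)
    if len(ipsi) == 0 or len(mc) == 0:
        raise ValueError("distal fibula regions must be non-empty")
    if correspondence:
        return kabsch_solve(mc, ipsi)
    icp_params = icp_params or ICPParams()
    init = icp_params.init or RigidTransform(
        np.eye(3), ipsi.mean(axis=0) - mc.mean(axis=0)
    )
    return icp_register(mc, ipsi, icp_params.with_init(init)).transform


def swing_twist_angle_deg(rotation: np.ndarray, axis: np.ndarray) -> float:
    """Signed twist (degrees) of a rotation about ``axis``.

    Swing-twist decomposition via quaternion projection: the quaternion's
    vector part is projected onto the axis and the twist recovered as
    ``2 atan2(v·a, w)``, wrapped to (-180, 180].  Right-hand-rule positive.
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    q = Rotation.from_matrix(np.asarray(rotation, dtype=float)).as_quat()  # x, y, z, w
    if q[3] < 0:  # canonical hemisphere so |twist| <= geodesic angle
        q = -q
    twist = 2.0 * np.arctan2(q[:3] @ a, q[3])
    deg = np.degrees(twist)
    if deg > 180.0:
        deg -= 360.0
    elif deg <= -180.0:
        deg += 360.0
    return float(deg)


def decompose_error(
    t_segment: RigidTransform,
    t_reference: RigidTransform,
    frame: AnatomicalFrame,
    ref_point,
    segment: SegmentName | None = None,
    icp_rms: float = float("nan"),
) -> FibulaErrorReport:
    """Decompose the restored-vs-reference pose deviation into the four
    accuracy metrics.

    The error transform ``T_err = T_segment ∘ T_reference^-1`` maps the true
    (reference-registered) distal fibula onto the restored one in
    *ipsilateral* coordinates, and is expressed at ``ref_point`` (the
    ipsilateral distal-fibula centroid): the reported displacement is
    ``d = T_err(ref_point) − ref_point``.  This ordering makes every metric
    invariant under a common rigid motion of the ipsilateral pair.  Sign
    conventions (right-leg pooled): translation error ``−(d·ŷ)`` so distal
    displacement (lengthening) is positive; rotation error is the
    swing-twist angle about ``+ŷ`` so external rotation is positive.
    """
    err = t_segment.compose(t_reference.inverse())
    p = np.asarray(ref_point, dtype=float)
    d = err.apply(p) - p
    y = frame.y_axis

    translation_error = float(-(d @ y))
    rotation_error = swing_twist_angle_deg(err.rotation, y)
    euclidean = float(np.linalg.norm(d))
    euler = err.rotation_angle_deg()
    return FibulaErrorReport(
        segment=segment if segment is not None else SegmentName.FIBULA_DISTAL_25,
        translation_error=translation_error,
        rotation_error=rotation_error,
        euclidean_distance=euclidean,
        euler_angle=euler,
        icp_rms=icp_rms,
    )
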