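"""Anatomical coordinate frame, bone length, and registration segments.

The frame follows the ISB-style convention for the lower leg: the origin is
the geometric center of the tibia (its OBB center), y points distal to
proximal along the anatomical tibial axis (the tibia's first OBB axis), z
points medial to lateral (toward the fibula), and x = y × z points posterior
to anterior.  The frame is right-handed by construction.

Segments are the four registration regions of the pipeline — distal 25%
tibia, distal 50% tibia, proximal 75% fibula, proximal 75% fibula plus the
whole tibia — and the distal 25% fibula evaluation region that the pipeline
scores but never registers on.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import ConvexHull

from .mesh_core import (
    TriMesh,
    oriented_bounding_box,
    sample_surface,
    surface_area,
    surface_centroid,
)

__all__ = [
    "AnatomicalFrame",
    "SegmentName",
    "SegmentSpec",
    "SEGMENTS",
    "REGISTRATION_SEGMENTS",
    "IllConditionedFrameError",
    "EmptySegmentError",
    "bone_length",
    "build_anatomical_frame",
    "extract_segment",
    "axial_extent",
    "DEFAULT_SAMPLE_DENSITY",
]

#: default surface sampling density, points per cm^2; correspondences are
#: sample-to-sample, so the density sets the correspondence noise floor and
#: with it the attainable pose precision
DEFAULT_SAMPLE_DENSITY = 100.0

#: fraction of the bone length used for the end slices whose cross-section
#: areas disambiguate distal vs proximal (the tibial plateau is the largest)
_END_SLICE_FRACTION = 0.10


class IllConditionedFrameError(ValueError):
    """Fibula centroid (nearly) on the tibial axis; frame is undefined."""


class EmptySegmentError(ValueError):
    """Segment selection produced no surface points."""


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed anatomical frame: origin (mm) and unit x/y/z axes."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        x = np.asarray(self.x_axis, dtype=np.float64).reshape(3)
        y = np.asarray(self.y_axis, dtype=np.float64).reshape(3)
        z = np.asarray(self.z_axis, dtype=np.float64).reshape(3)
        m = np.stack([x, y, z])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if not np.allclose(np.cross(x, y), z, atol=1e-9):
            raise ValueError("frame must be right-handed (x × y = z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", x)
        object.__setattr__(self, "y_axis", y)
        object.__setattr__(self, "z_axis", z)

    @property
    def rotation(self) -> np.ndarray:
        """World-from-local rotation; columns are the x, y, z axes."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def to_local(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation

    def to_world(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.origin


class SegmentName(str, Enum):
    TIBIA_25 = "tibia25"
    TIBIA_50 = "tibia50"
    FIBULA_75 = "fibula75"
    FIBULA_75_PLUS_TIBIA = "fibula75+tibia"
    FIBULA_DISTAL_25 = "fibula_distal25"

    def __str__(self) -> str:  # CLI/config spelling
        return self.value


@dataclass(frozen=True)
class SegmentSpec:
    """One registration (or evaluation) region.

    ``bones`` names the cropped bone; ``fraction`` of that bone's length is
    kept from the stated ``end``; ``include_whole_tibia`` adds the entire
    tibia (the "75% fibula and tibia" union segment).
    """

    name: SegmentName
    bone: str  # "tibia" | "fibula"
    fraction: float
    end: str  # "distal" | "proximal"
    include_whole_tibia: bool = False

    def __post_init__(self) -> None:
        if self.bone not in ("tibia", "fibula"):
            raise ValueError("bone must be 'tibia' or 'fibula'")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.end not in ("distal", "proximal"):
            raise ValueError("end must be 'distal' or 'proximal'")


SEGMENTS: dict[SegmentName, SegmentSpec] = {
    SegmentName.TIBIA_25: SegmentSpec(SegmentName.TIBIA_25, "tibia", 0.25, "distal"),
    SegmentName.TIBIA_50: SegmentSpec(SegmentName.TIBIA_50, "tibia", 0.50, "distal"),
    SegmentName.FIBULA_75: SegmentSpec(SegmentName.FIBULA_75, "fibula", 0.75, "proximal"),
    SegmentName.FIBULA_75_PLUS_TIBIA: SegmentSpec(
        SegmentName.FIBULA_75_PLUS_TIBIA, "fibula", 0.75, "proximal", include_whole_tibia=True
    ),
    SegmentName.FIBULA_DISTAL_25: SegmentSpec(
        SegmentName.FIBULA_DISTAL_25, "fibula", 0.25, "distal"
    ),
}

#: the four segments actually used for contralateral registration
REGISTRATION_SEGMENTS = (
    SegmentName.TIBIA_25,
    SegmentName.TIBIA_50,
    SegmentName.FIBULA_75,
    SegmentName.FIBULA_75_PLUS_TIBIA,
)


def bone_length(mesh: TriMesh) -> float:
    """Bone length (mm): the longest extent of the oriented bounding box."""
    return float(oriented_bounding_box(mesh).extents[0])


def _end_slice_area(points: np.ndarray, axis_proj: np.ndarray, lo: float, hi: float,
                    basis: np.ndarray) -> float:
    sel = (axis_proj >= lo) & (axis_proj <= hi)
    if sel.sum() < 3:
        return 0.0
    flat = points[sel] @ basis.T
    try:
        return float(ConvexHull(flat).volume)  # 2D hull "volume" is the area
    except Exception:
        return 0.0


def build_anatomical_frame(tibia: TriMesh, fibula: TriMesh) -> AnatomicalFrame:
    """Anatomical frame from a tibia/fibula pair of one leg.

    y is the tibial OBB first axis oriented distal → proximal: the end of
    the tibia with the larger cross-sectional hull area (the tibial plateau)
    is proximal.  z is the component of (fibula centroid − tibia centroid)
    orthogonal to y, i.e. medial → lateral; x = y × z.  For a left leg in
    native coordinates x would point posterior — the pipeline mirrors left
    pairs into the right-leg convention before calling this.
    """
    obb = oriented_bounding_box(tibia)
    y = obb.axes[0].copy()
    basis = obb.axes[1:]

    proj = tibia.vertices @ y
    pmin, pmax = proj.min(), proj.max()
    band = _END_SLICE_FRACTION * (pmax - pmin)
    area_low = _end_slice_area(tibia.vertices, proj, pmin, pmin + band, basis)
    area_high = _end_slice_area(tibia.vertices, proj, pmax - band, pmax, basis)
    if area_low > area_high:
        y = -y  # plateau (largest cross-section) must be at +y

    w = surface_centroid(fibula) - surface_centroid(tibia)
    w_perp = w - (w @ y) * y
    norm = np.linalg.norm(w_perp)
    if norm < 1.0:
        raise IllConditionedFrameError(
            "fibula centroid lies within 1 mm of the tibial axis; "
            "medial-lateral direction is undefined"
        )
    z = w_perp / norm
    x = np.cross(y, z)
    return AnatomicalFrame(origin=obb.center, x_axis=x, y_axis=y, z_axis=z)


def axial_extent(mesh: TriMesh, frame: AnatomicalFrame) -> tuple[float, float]:
    """(min, max) of the bone's vertices along the frame's y-axis."""
    proj = mesh.vertices @ frame.y_axis
    return float(proj.min()), float(proj.max())


def _cut_mask(y_coords: np.ndarray, ymin: float, ymax: float, fraction: float,
              end: str) -> np.ndarray:
    length = ymax - ymin
    if fraction >= 1.0:
        return np.ones(len(y_coords), dtype=bool)
    if end == "distal":
        return y_coords <= ymin + fraction * length
    return y_coords > ymax - fraction * length


def _samples_for(mesh: TriMesh, density: float, seed: int) -> np.ndarray:
    count = max(10, int(round(surface_area(mesh) / 100.0 * density)))  # mm^2 -> cm^2
    return sample_surface(mesh, count, np.random.default_rng(seed))


def extract_segment(
    tibia: TriMesh,
    fibula: TriMesh,
    spec: SegmentSpec | SegmentName,
    frame: AnatomicalFrame,
    density: float = DEFAULT_SAMPLE_DENSITY,
    seed: int = 0,
) -> np.ndarray:
    """Area-uniform surface sample points (world mm) of one segment.

    The cut plane sits at ``fraction`` × the bone's extent along the frame's
    y-axis, measured from the stated end.  Sampling is deterministic given
    ``seed`` and per-bone (tibia and fibula use independent substreams), so
    segment point sets nest (tibia25 ⊆ tibia50) and the proximal 75% and
    distal 25% fibula segments exactly partition the fibula samples.
    """
    if isinstance(spec, SegmentName):
        spec = SEGMENTS[spec]
    bone = tibia if spec.bone == "tibia" else fibula
    samples = _samples_for(bone, density, _bone_seed(seed, spec.bone))
    y = samples @ frame.y_axis
    ymin, ymax = axial_extent(bone, frame)
    pts = samples[_cut_mask(y, ymin, ymax, spec.fraction, spec.end)]
    if spec.include_whole_tibia:
        tib = _samples_for(tibia, density, _bone_seed(seed, "tibia"))
        pts = np.vstack([pts, tib]) if len(pts) else tib
    if len(pts) == 0:
        raise EmptySegmentError(f"segment {spec.name} selected no surface points")
    return pts


def _bone_seed(seed: int, bone: str) -> int:
    # independent, reproducible substream per bone role
    return int(np.random.SeedSequence([seed, 0 if bone == "tibia" else 1]).generate_state(1)[0])
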