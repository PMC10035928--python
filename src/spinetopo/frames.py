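"""Anatomical coordinate frames, rigid scan-to-MRI alignment, marker-patch
centroids, planar projection, and the landmark / demographics file formats.

Frame convention: the sagittal plane is parallel to the substrate surface, so
the antero-posterior axis is the substrate normal (posterior positive); the
cephalo-caudal axis runs from the mid-point of the posterior superior iliac
spine (PSIS) markers toward the L1 marker, projected into the substrate
plane; the lateral axis (subject-left positive) completes the right-handed
triad. The frame origin is the L1 marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .synthetic import (
    VALID_LABELS,
    VALID_SOURCES,
    VERTEBRAL_LABELS,
    LandmarkSet,
    SubjectDemographics,
)

Plane = Literal["sagittal", "coronal"]


class GeometryError(ValueError):
    """Degenerate geometric input (coincident points, parallel axes...)."""


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame, origin at the L1 marker."""

    origin: np.ndarray
    axis_lateral: np.ndarray  # +x, subject-left
    axis_anteroposterior: np.ndarray  # +y, posterior
    axis_cephalocaudal: np.ndarray  # +z, cephalad

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.column_stack(
            [self.axis_lateral, self.axis_anteroposterior, self.axis_cephalocaudal]
        )

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates (x lateral, y AP, z CC)."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation

    @classmethod
    def identity(cls, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "AnatomicalFrame":
        return cls(
            origin=np.asarray(origin, dtype=float),
            axis_lateral=np.array([1.0, 0.0, 0.0]),
            axis_anteroposterior=np.array([0.0, 1.0, 0.0]),
            axis_cephalocaudal=np.array([0.0, 0.0, 1.0]),
        )


def build_frame(
    l1_marker: Sequence[float],
    psis_left: Sequence[float],
    psis_right: Sequence[float],
    substrate_normal: Sequence[float] = (0.0, 1.0, 0.0),
) -> AnatomicalFrame:
    """Anatomical frame from the L1 marker, the PSIS pair and the substrate
    normal (pointing posteriorly off the lying surface)."""
    l1 = np.asarray(l1_marker, dtype=float)
    psis_mid = (np.asarray(psis_left, dtype=float) + np.asarray(psis_right, dtype=float)) / 2.0
    ap = _unit(substrate_normal, "substrate normal")
    line = l1 - psis_mid
    if np.linalg.norm(line) < 1e-9:
        raise GeometryError("L1 marker coincides with the PSIS mid-point")
    cc_raw = line - np.dot(line, ap) * ap  # project into the substrate plane
    if np.linalg.norm(cc_raw) < 1e-9:
        raise GeometryError("L1-PSIS line is parallel to the substrate normal")
    cc = _unit(cc_raw, "cephalo-caudal axis")
    lat = np.cross(ap, cc)
    return AnatomicalFrame(
        origin=l1, axis_lateral=lat, axis_anteroposterior=ap, axis_cephalocaudal=cc
    )


def frame_from_landmarks(
    landmarks: LandmarkSet,
    substrate_normal: Sequence[float] = (0.0, 1.0, 0.0),
) -> AnatomicalFrame:
    """Frame from a landmark set carrying L1 and both PSIS markers; falls
    back to an identity-oriented frame at L1 when the PSIS pair is absent."""
    l1 = landmarks.point("L1")
    if landmarks.has_label("PSIS_L") and landmarks.has_label("PSIS_R"):
        return build_frame(
            l1, landmarks.point("PSIS_L"), landmarks.point("PSIS_R"), substrate_normal
        )
    return AnatomicalFrame.identity(origin=l1)


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t (no scaling or shear)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (determinant -1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def align_scan_to_mri(
    scan: LandmarkSet, mri_fiducials: LandmarkSet
) -> tuple[RigidTransform, LandmarkSet]:
    """Least-squares rigid superposition (Kabsch, no scaling) of the scan
    markers onto the MRI fiducials over their shared labels.

    Returns the fitted transform (with its residual RMS over the shared
    labels) and the scan set mapped into the MRI frame. Collinear shared
    labels leave a rotation about the line unconstrained; that freedom is
    resolved by minimising the deviation of the mapped antero-posterior axis
    from the MRI AP axis, with a warning.
    """
    shared = [lb for lb in scan.labels if mri_fiducials.has_label(lb)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared labels, got {len(shared)}")
    A = np.vstack([mri_fiducials.point(lb) for lb in shared])  # target
    B = np.vstack([scan.point(lb) for lb in shared])  # moving
    a_c = A - A.mean(axis=0)
    b_c = B - B.mean(axis=0)

    sing = np.linalg.svd(a_c.T @ b_c, compute_uv=False)
    collinear = sing[1] <= max(1e-9 * sing[0], 1e-12)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on rank deficiency
        rot, _ = Rotation.align_vectors(a_c, b_c)
    R = rot.as_matrix()

    if collinear:
        warnings.warn(
            "shared labels are collinear; rotation about the line is "
            "unconstrained and was resolved toward the AP axis"
        )
        R = _resolve_collinear(R, a_c)

    t = A.mean(axis=0) - R @ B.mean(axis=0)
    resid = A - (B @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    transform = RigidTransform(rotation=R, translation=t, residual_rms=rms)

    aligned = scan.copy()
    aligned.coords = transform.apply(scan.coords)
    aligned.frame = mri_fiducials.frame
    return transform, aligned


def _resolve_collinear(R: np.ndarray, a_centered: np.ndarray) -> np.ndarray:
    """Compose a rotation about the (collinear) point line so the mapped AP
    axis deviates least from +y."""
    # line direction in the target frame
    u = a_centered[np.argmax(np.linalg.norm(a_centered, axis=1))]
    u = u / np.linalg.norm(u)
    y = np.array([0.0, 1.0, 0.0])
    v = R @ y
    v_perp = v - np.dot(v, u) * u
    if np.linalg.norm(v_perp) < 1e-12:
        return R
    e1 = v_perp / np.linalg.norm(v_perp)
    e2 = np.cross(u, e1)
    theta = np.arctan2(np.dot(e2, y), np.dot(e1, y))
    return Rotation.from_rotvec(theta * u).as_matrix() @ R


# ---------------------------------------------------------------------------
# Surface patches
# ---------------------------------------------------------------------------

@dataclass
class SurfacePatch:
    """Triangulated marker patch selected on a scanned surface."""

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.vertices.size == 0:
            raise ValueError("empty patch")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle index out of range")


def patch_centroid(
    patch: SurfacePatch, mode: Literal["vertex_mean", "area_weighted"] = "area_weighted"
) -> np.ndarray:
    """Centroid of a marker patch: plain vertex mean, or surface (area
    weighted) centroid over the triangle faces."""
    if mode == "vertex_mean":
        return patch.vertices.mean(axis=0)
    if mode != "area_weighted":
        raise ValueError(f"unknown mode {mode!r}")
    if len(patch.triangles) < 1:
        raise GeometryError("area_weighted mode needs at least one triangle")
    tri = patch.vertices[patch.triangles]  # (m, 3, 3)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    if total <= 0:
        raise GeometryError("patch has zero total area")
    centroids = tri.mean(axis=1)
    return (areas[:, None] * centroids).sum(axis=0) / total


def read_patch(path) -> SurfacePatch:
    """Minimal ASCII mesh table: lines ``v x y z`` and ``f i j k``
    (0-based vertex indices); blank lines and ``#`` comments ignored."""
    vertices, triangles = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split("#", 1)[0].split()
            if not parts:
                continue
            if parts[0] == "v" and len(parts) == 4:
                vertices.append([float(p) for p in parts[1:]])
            elif parts[0] == "f" and len(parts) == 4:
                triangles.append([int(p) for p in parts[1:]])
            else:
                raise ValueError(f"{path}: cannot parse line {ln}: {line.rstrip()}")
    return SurfacePatch(np.array(vertices), np.array(triangles).reshape(-1, 3))


# ---------------------------------------------------------------------------
# Planar projection
# ---------------------------------------------------------------------------

@dataclass
class PlanarSeries:
    """Ordered planar profile points (z cephalo-caudal, v in-plane value),
    cephalad first, with their vertebral labels."""

    subject_id: str
    source: str
    plane: Plane
    labels: list[str]
    z: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.labels) == self.z.size == self.v.size):
            raise ValueError("labels, z and v must have equal length")


def project_to_plane(
    landmarks: LandmarkSet, frame: AnatomicalFrame, plane: Plane
) -> PlanarSeries:
    """Project the vertebral chain into the sagittal (v = antero-posterior)
    or coronal (v = lateral) plane of an anatomical frame, preserving the
    cephalad-to-caudad ordering."""
    if plane not in ("sagittal", "coronal"):
        raise ValueError(f"unknown plane {plane!r}")
    local = frame.to_frame(landmarks.vertebral_coords())
    v = local[:, 1] if plane == "sagittal" else local[:, 0]
    return PlanarSeries(
        subject_id=landmarks.subject_id,
        source=landmarks.source,
        plane=plane,
        labels=landmarks.vertebral_labels(),
        z=local[:, 2],
        v=v,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["subject_id", "source", "session", "label", "x_mm", "y_mm", "z_mm"]
DEMOGRAPHICS_COLUMNS = ["subject_id", "gender", "age", "height_m", "weight_kg"]


def write_landmarks(sets: Iterable[LandmarkSet], path) -> None:
    """Write landmark sets to the project CSV schema
    (subject_id,source,session,label,x_mm,y_mm,z_mm; mm, UTF-8)."""
    rows = []
    for s in sets:
        for lb, (x, y, z) in zip(s.labels, s.coords):
            rows.append((s.subject_id, s.source, s.session, lb, x, y, z))
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_landmarks(path) -> list[LandmarkSet]:
    """Read and validate a landmark CSV; raises naming the offending row on
    unknown labels or sources, duplicates, or missing columns."""
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_label = df.loc[~df["label"].isin(VALID_LABELS)]
    if len(bad_label):
        i = bad_label.index[0]
        raise ValueError(
            f"{path}: unknown label {bad_label['label'].iloc[0]!r} at row {i + 2}"
        )
    bad_source = df.loc[~df["source"].isin(VALID_SOURCES)]
    if len(bad_source):
        i = bad_source.index[0]
        raise ValueError(
            f"{path}: unknown source {bad_source['source'].iloc[0]!r} at row {i + 2}"
        )
    dup = df.duplicated(subset=["subject_id", "source", "session", "label"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValueError(f"{path}: duplicate (subject, source, session, label) at row {i + 2}")

    sets: list[LandmarkSet] = []
    order = {lb: i for i, lb in enumerate(VERTEBRAL_LABELS)}
    for (sid, source, session), grp in df.groupby(
        ["subject_id", "source", "session"], sort=True
    ):
        grp = grp.copy()
        grp["_ord"] = grp["label"].map(lambda lb: order.get(lb, len(order)))
        grp = grp.sort_values(["_ord", "label"], kind="stable")
        sets.append(
            LandmarkSet(
                subject_id=str(sid),
                source=str(source),
                session=int(session),
                labels=list(grp["label"]),
                coords=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            )
        )
    return sets


def write_demographics(subjects: Iterable[SubjectDemographics], path) -> None:
    df = pd.DataFrame(
        [
            (s.subject_id, s.gender, s.age, s.height_m, s.weight_kg)
            for s in subjects
        ],
        columns=DEMOGRAPHICS_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_demographics(path) -> list[SubjectDemographics]:
    df = pd.read_csv(path)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        SubjectDemographics(
            subject_id=str(r.subject_id),
            gender=str(r.gender),
            age=int(r.age),
            height_m=float(r.height_m),
            weight_kg=float(r.weight_kg),
        )
        for r in df.itertuples()
    ]
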