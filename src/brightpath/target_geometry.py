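"""Coil-pose geometry: from brain target to scalp vertex and coil rotation.

The pipeline here converts a brain-space target into a deliverable TMS
pose. It builds the head-fixed NLR frame from the nasion (N) and the
left/right preauricular points (L, R): the origin O is the orthogonal
projection of N onto the line LR, the x-axis points to the nasion, the
y-axis to the left ear, and the z-axis toward the vertex. A rigid
least-squares (Kabsch) fit of the four landmark correspondences maps
anatomical coordinates into NLR space. The target is projected to the
nearest vertex of a scalp mesh; the coil z-axis is the outward surface
normal there, and the coil y-axis is chosen so that its projection onto
the NLR xy-plane makes a 45 degree angle with the midsagittal (x) axis.
The rotation is exported as a scalar-first unit quaternion (w >= 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation
from skimage import measure

__all__ = [
    "DegenerateLandmarksError",
    "LandmarkSet",
    "HeadModel",
    "NLRFrame",
    "CoilPose",
    "TargetPlan",
    "nlr_origin",
    "landmarks_in_nlr",
    "nlr_frame",
    "fit_rigid",
    "nearest_vertex",
    "vertex_normal",
    "coil_pose",
    "rotation_to_quaternion",
    "head_mesh_from_volume",
    "export_plan",
    "load_plan",
]

PLAN_SCHEMA = "brightpath-plan/1"
DEFAULT_COIL_ANGLE_DEG = 45.0


class DegenerateLandmarksError(ValueError):
    """Fiducials too close to collinear (or coincident) for frame construction."""


@dataclass
class LandmarkSet:
    """Nasion and preauricular fiducials in anatomical (T1) space, mm."""

    nasion: np.ndarray
    left_preauricular: np.ndarray
    right_preauricular: np.ndarray

    def __post_init__(self) -> None:
        for name in ("nasion", "left_preauricular", "right_preauricular"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, v)
        # non-collinearity: triangle area > 1 mm^2
        a = self.left_preauricular - self.nasion
        b = self.right_preauricular - self.nasion
        if 0.5 * np.linalg.norm(np.cross(a, b)) < 1.0:
            raise DegenerateLandmarksError(
                "nasion and preauricular points are (near-)collinear"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        data = json.loads(Path(path).read_text())
        return cls(data["nasion"], data["lpa"], data["rpa"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nasion": self.nasion.tolist(),
            "lpa": self.left_preauricular.tolist(),
            "rpa": self.right_preauricular.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class HeadModel:
    """Triangulated scalp mesh with fiducial landmarks, all in mm."""

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @classmethod
    def from_file(cls, path: str | Path, landmarks: LandmarkSet | None = None) -> "HeadModel":
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), landmarks)

    def to_file(self, path: str | Path) -> None:
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(str(path))


@dataclass
class NLRFrame:
    """Rigid map x_nlr = rotation @ x_t1 + translation into the NLR frame."""

    origin_t1: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


@dataclass
class CoilPose:
    """Coil placement in NLR space.

    ``rotation`` columns are the coil axes (c_x, c_y, c_z) expressed in
    NLR coordinates; c_z is the outward scalp normal. ``quaternion`` is
    scalar-first (w, x, y, z) with w >= 0.
    """

    scalp_vertex: np.ndarray
    rotation: np.ndarray
    quaternion: np.ndarray


@dataclass
class TargetPlan:
    """Everything needed to deliver one treatment target."""

    kind: str
    brain_target_mm: np.ndarray
    brain_target_voxel: tuple[int, int, int] | None
    scalp_vertex_nlr: np.ndarray
    rotation: np.ndarray
    quaternion: np.ndarray
    nlr_landmarks: dict[str, list[float]]
    peak_z: float | None = None
    provenance: dict | None = None


# ---------------------------------------------------------------------------
# NLR frame construction
# ---------------------------------------------------------------------------

def nlr_origin(landmarks: LandmarkSet) -> np.ndarray:
    """Orthogonal projection of the nasion onto the preauricular line.

    O = R + [((N-R).(L-R)) / |L-R|^2] (L-R). By construction (N-O) is
    perpendicular to (L-R).
    """
    n, l, r = landmarks.nasion, landmarks.left_preauricular, landmarks.right_preauricular
    lr = l - r
    norm2 = float(lr @ lr)
    if norm2 < 1.0:  # ears closer than 1 mm
        raise DegenerateLandmarksError("preauricular points nearly coincident")
    return r + ((n - r) @ lr) / norm2 * lr


def landmarks_in_nlr(landmarks: LandmarkSet) -> dict[str, np.ndarray]:
    """NLR coordinates of origin, nasion and both preauricular points.

    The origin maps to (0,0,0); the nasion to (+|N-O|, 0, 0); the left
    ear to (0, +|L-O|, 0); the right ear to (0, -|R-O|, 0).
    """
    o = nlr_origin(landmarks)
    d_n = np.linalg.norm(landmarks.nasion - o)
    if d_n < 1.0:
        raise DegenerateLandmarksError("nasion lies on the preauricular line")
    d_l = np.linalg.norm(landmarks.left_preauricular - o)
    d_r = np.linalg.norm(landmarks.right_preauricular - o)
    return {
        "origin": np.zeros(3),
        "nasion": np.array([d_n, 0.0, 0.0]),
        "left_preauricular": np.array([0.0, d_l, 0.0]),
        "right_preauricular": np.array([0.0, -d_r, 0.0]),
    }


def fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (Kabsch): R, t minimizing sum |R s + t - d|^2.

    The rotation is proper (det +1); a reflection in the SVD solution is
    corrected by flipping the smallest singular direction.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    # collinearity check: rank of centered source must be >= 2
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise ValueError("source points are collinear; rotation is not identifiable")
    h = src_c.T @ dst_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = dst.mean(axis=0) - rot @ src.mean(axis=0)
    return rot, t


def nlr_frame(landmarks: LandmarkSet) -> NLRFrame:
    """Rigid map from anatomical space into NLR space, fit on 4 landmarks."""
    nlr = landmarks_in_nlr(landmarks)
    o = nlr_origin(landmarks)
    src = np.stack([o, landmarks.nasion, landmarks.left_preauricular,
                    landmarks.right_preauricular])
    dst = np.stack([nlr["origin"], nlr["nasion"], nlr["left_preauricular"],
                    nlr["right_preauricular"]])
    rot, t = fit_rigid(src, dst)
    return NLRFrame(origin_t1=o, rotation=rot, translation=t)


# ---------------------------------------------------------------------------
# Mesh operations
# ---------------------------------------------------------------------------

def nearest_vertex(mesh: HeadModel, point: np.ndarray) -> int:
    """Index of the mesh vertex closest to ``point``; ties go to the lowest index."""
    if len(mesh.vertices) == 0:
        raise ValueError("empty mesh")
    d2 = np.sum((mesh.vertices - np.asarray(point, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))


def vertex_normal(mesh: HeadModel, index: int) -> np.ndarray:
    """Outward unit normal at a vertex: area-weighted mean of incident face normals.

    Outward means a positive dot product with (vertex - mesh centroid);
    the accumulated normal is flipped if needed.
    """
    incident = np.nonzero((mesh.faces == index).any(axis=1))[0]
    if incident.size == 0:
        raise ValueError(f"vertex {index} belongs to no face")
    tri = mesh.vertices[mesh.faces[incident]]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normal = cross.sum(axis=0)  # cross magnitude = 2*area, so this is area-weighted
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError(f"degenerate normal at vertex {index}")
    normal = normal / norm
    outward = mesh.vertices[index] - mesh.vertices.mean(axis=0)
    if normal @ outward < 0:
        normal = -normal
    return normal


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray, steps: int,
                      lam: float = 0.5) -> np.ndarray:
    """Uniform Laplacian smoothing: v += lam * (mean(neighbors) - v), repeated."""
    n = len(vertices)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    deg = np.bincount(i, minlength=n).astype(float)
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(steps):
        nbr_sum = np.zeros_like(v)
        np.add.at(nbr_sum, i, v[j])
        v += lam * (nbr_sum / deg[:, None] - v)
    return v


def head_mesh_from_volume(
    volume: np.ndarray,
    intensity_threshold: float | None = None,
    smoothing_steps: int = 100,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> HeadModel:
    """Isosurface of the thresholded head volume plus Laplacian smoothing.

    If ``intensity_threshold`` is None an automatic default is taken at
    the midpoint between the modal background intensity and the robust
    (99th percentile) foreground intensity. 100 smoothing steps is the
    default. Raising the threshold is the documented manual override when
    the extracted scalp looks noisy.
    """
    vol = np.asarray(volume, dtype=float)
    if intensity_threshold is None:
        lo = np.percentile(vol, 1)
        hi = np.percentile(vol, 99)
        intensity_threshold = 0.5 * (lo + hi)
    fg = vol > intensity_threshold
    if not fg.any():
        raise ValueError("no foreground voxels above the intensity threshold")
    verts, faces, _, _ = measure.marching_cubes(
        fg.astype(float), level=0.5, spacing=voxel_size
    )
    if smoothing_steps > 0:
        verts = _laplacian_smooth(verts, faces, smoothing_steps)
    return HeadModel(verts, faces)


# ---------------------------------------------------------------------------
# Coil orientation
# ---------------------------------------------------------------------------

def coil_pose(
    normal: np.ndarray,
    scalp_vertex: np.ndarray,
    angle_deg: float = DEFAULT_COIL_ANGLE_DEG,
) -> CoilPose:
    """Coil rotation at a scalp vertex given the outward surface normal (NLR space).

    c_z is the outward normal. c_y is the unit vector orthogonal to c_z
    whose projection onto the NLR xy-plane is a positive multiple of
    u = (cos a, sin a, 0) (a = 45 degrees by default, anterior-left; pass
    a negative angle for the mirrored solution), so the projected angle
    to the NLR x-axis equals the requested angle exactly. Writing
    c_y ~ (u_x, u_y, h), orthogonality to c_z fixes
    h = -(u_x z_1 + u_y z_2) / z_3. c_x = c_y x c_z completes a
    right-handed basis. When the normal is horizontal (z_3 ~ 0) and not
    perpendicular to u no such c_y exists; the mirrored in-plane
    direction is tried as a fallback before raising.
    """
    c_z = np.asarray(normal, dtype=float)
    c_z = c_z / np.linalg.norm(c_z)
    a = np.deg2rad(angle_deg)

    def tangent_with_projection(u2: np.ndarray) -> np.ndarray | None:
        s = u2 @ c_z[:2]
        if abs(c_z[2]) >= 1e-6:
            w = np.array([u2[0], u2[1], -s / c_z[2]])
        elif abs(s) < 1e-9:  # horizontal normal already perpendicular to u
            w = np.array([u2[0], u2[1], 0.0])
        else:
            return None
        return w / np.linalg.norm(w)

    c_y = tangent_with_projection(np.array([np.cos(a), np.sin(a)]))
    if c_y is None:
        logger_msg = "coil normal is horizontal and blocks the requested handle angle"
        c_y = tangent_with_projection(np.array([np.cos(a), -np.sin(a)]))
        if c_y is None:
            raise ValueError(logger_msg + "; mirrored fallback also degenerate")
    c_x = np.cross(c_y, c_z)
    rot = np.column_stack([c_x, c_y, c_z])
    return CoilPose(
        scalp_vertex=np.asarray(scalp_vertex, dtype=float),
        rotation=rot,
        quaternion=rotation_to_quaternion(rot),
    )


def rotation_to_quaternion(rotation: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion (w, x, y, z), w >= 0, for a proper rotation."""
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6) or np.linalg.det(rot) < 0:
        raise ValueError("matrix is not a proper rotation")
    q = Rotation.from_matrix(rot).as_quat()  # scipy: (x, y, z, w)
    q = np.array([q[3], q[0], q[1], q[2]])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotation_to_quaternion` (scalar-first input)."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


# ---------------------------------------------------------------------------
# Plan export
# ---------------------------------------------------------------------------

def plan_for_target(
    brain_target_mm: np.ndarray,
    mesh: HeadModel,
    landmarks: LandmarkSet,
    kind: str = "cgiTBS",
    angle_deg: float = DEFAULT_COIL_ANGLE_DEG,
    brain_target_voxel: tuple[int, int, int] | None = None,
    peak_z: float | None = None,
    provenance: dict | None = None,
) -> TargetPlan:
    """Full geometry chain: NLR frame -> scalp projection -> coil pose."""
    frame = nlr_frame(landmarks)
    target_nlr = frame.transform(np.asarray(brain_target_mm, dtype=float))
    verts_nlr = frame.transform(mesh.vertices)
    mesh_nlr = HeadModel(verts_nlr, mesh.faces)
    vid = nearest_vertex(mesh_nlr, target_nlr)
    normal = vertex_normal(mesh_nlr, vid)
    pose = coil_pose(normal, mesh_nlr.vertices[vid], angle_deg=angle_deg)
    nlr = landmarks_in_nlr(landmarks)
    return TargetPlan(
        kind=kind,
        brain_target_mm=np.asarray(brain_target_mm, dtype=float),
        brain_target_voxel=brain_target_voxel,
        scalp_vertex_nlr=pose.scalp_vertex,
        rotation=pose.rotation,
        quaternion=pose.quaternion,
        nlr_landmarks={k: v.tolist() for k, v in nlr.items()},
        peak_z=peak_z,
        provenance=provenance,
    )


def export_plan(plan: TargetPlan, path: str | Path) -> None:
    """Write a plan as versioned JSON; reloads round-trip bit-exactly."""
    for field_name in ("brain_target_mm", "scalp_vertex_nlr", "rotation", "quaternion"):
        if getattr(plan, field_name) is None:
            raise ValueError(f"plan incomplete: missing {field_name}")
    payload = {
        "schema": PLAN_SCHEMA,
        "kind": plan.kind,
        "brain_target_mm": np.asarray(plan.brain_target_mm).tolist(),
        "brain_target_voxel": list(plan.brain_target_voxel)
        if plan.brain_target_voxel is not None
        else None,
        "scalp_vertex_nlr": np.asarray(plan.scalp_vertex_nlr).tolist(),
        "rotation": np.asarray(plan.rotation).tolist(),
        "quaternion": np.asarray(plan.quaternion).tolist(),
        "nlr_landmarks": plan.nlr_landmarks,
        "peak_z": plan.peak_z,
        "provenance": plan.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_plan(path: str | Path) -> TargetPlan:
    data = json.loads(Path(path).read_text())
    if data.get("schema") != PLAN_SCHEMA:
        raise ValueError(f"unsupported plan schema: {data.get('schema')!r}")
    for key in ("brain_target_mm", "scalp_vertex_nlr", "rotation", "quaternion"):
        if data.get(key) is None:
            raise ValueError(f"plan file missing required field {key!r}")
    return TargetPlan(
        kind=data["kind"],
        brain_target_mm=np.array(data["brain_target_mm"]),
        brain_target_voxel=tuple(data["brain_target_voxel"])
        if data["brain_target_voxel"] is not None
        else None,
        scalp_vertex_nlr=np.array(data["scalp_vertex_nlr"]),
        rotation=np.array(data["rotation"]),
        quaternion=np.array(data["quaternion"]),
        nlr_landmarks=data["nlr_landmarks"],
        peak_z=data["peak_z"],
        provenance=data["provenance"],
    )
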