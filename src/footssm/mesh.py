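"""Mesh containers, I/O, mirroring, principal axes and rigid ICP alignment.

Coordinate convention (shared by every module in the package)
-------------------------------------------------------------
* +X anterior (toward the toes)
* +Y superior (up); the floor is the plane Y = 0
* +Z toward the lateral side of a right foot

The sagittal projection drops Z (keeps XY); the coronal projection drops X
(keeps YZ). Left feet are standardized to right-sided anatomy by negating Z
and flipping triangle winding (:func:`mirror_foot`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    DegenerateGeometryError,
    EmptyMeshError,
    FootSSMError,
    MeshIOError,
    UnsupportedFormatError,
)

#: The bones of the model (calcaneus through tibia), in the fixed bone-major
#: ordering used for particle flattening. Order is part of the
#: column-ordering contract.
BONE_NAMES: tuple[str, ...] = (
    "calcaneus",
    "cuboid",
    "cuneiform_intermediate",
    "cuneiform_lateral",
    "cuneiform_medial",
    "metatarsal_1",
    "metatarsal_2",
    "metatarsal_3",
    "metatarsal_4",
    "metatarsal_5",
    "navicular",
    "talus",
    "tibia",
)

SIDES = ("left", "right")

_SUPPORTED_EXTENSIONS = {".ply", ".stl", ".obj"}

_AXIS_NAMES = ("X (anterior)", "Y (superior)", "Z (lateral)")


def _as_points(points, name="points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array, got {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError(f"{name} contains non-finite values")
    return pts


@dataclass(frozen=True)
class BoneMesh:
    """One bone's triangulated surface with anatomical label and side.

    Vertices are in millimetres in the shared anatomical frame.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str
    side: str

    def __post_init__(self):
        verts = _as_points(self.vertices, "vertices")
        faces = np.asarray(self.faces, dtype=np.int64)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError(f"faces must be an (M, 3) array, got {faces.shape}")
        if len(verts) < 4:
            raise ValueError(f"bone mesh needs >= 4 vertices, got {len(verts)}")
        if faces.size == 0:
            raise EmptyMeshError(f"bone '{self.label}' has no faces")
        if faces.min() < 0 or faces.max() >= len(verts):
            raise ValueError(
                f"bone '{self.label}': face indices out of range [0, {len(verts)})"
            )
        # no degenerate (zero-area) triangles
        tri = verts[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if (areas <= 1e-12).any():
            raise DegenerateGeometryError(
                f"bone '{self.label}' has {int((areas <= 1e-12).sum())} zero-area faces"
            )
        if self.label not in BONE_NAMES:
            raise ValueError(f"unknown bone label '{self.label}'")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got '{self.side}'")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "faces", faces)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def signed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (mm^3)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class FootModel:
    """Fourteen :class:`BoneMesh` objects in a shared anatomical frame."""

    bones: Mapping[str, BoneMesh]
    side: str
    group: Optional[str] = None
    subject_id: Optional[str] = None
    ground_truth: Optional[object] = None  # synthetic.GroundTruth when generated

    def __post_init__(self):
        missing = [b for b in BONE_NAMES if b not in self.bones]
        if missing:
            raise ValueError(f"foot model missing bones: {missing}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got '{self.side}'")
        self.bones = {name: self.bones[name] for name in BONE_NAMES}

    def __getitem__(self, label: str) -> BoneMesh:
        return self.bones[label]

    def pooled_vertices(self) -> np.ndarray:
        """All 14 bones' vertices stacked in the fixed bone order."""
        return np.vstack([self.bones[b].vertices for b in BONE_NAMES])

    def transformed(self, transform: "RigidTransform") -> "FootModel":
        bones = {
            name: replace(bone, vertices=transform.apply(bone.vertices))
            for name, bone in self.bones.items()
        }
        return FootModel(
            bones=bones,
            side=self.side,
            group=self.group,
            subject_id=self.subject_id,
            ground_truth=self.ground_truth,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation det +1, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return _as_points(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# I/O


def read_mesh(path, label: str, side: str) -> BoneMesh:
    """Read a PLY/STL/OBJ surface mesh as a :class:`BoneMesh`.

    STL stores three vertices per facet; duplicated vertices are merged on
    load so connectivity is a shared-vertex triangle mesh in every format.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"unsupported mesh extension '{path.suffix}' (supported: "
            f"{sorted(_SUPPORTED_EXTENSIONS)})"
        )
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    try:
        raw = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize third-party errors
        raise MeshIOError(f"could not parse mesh file {path}: {exc}") from exc
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise EmptyMeshError(f"empty mesh in {path}")
    if path.suffix.lower() == ".stl":
        # facet soup -> welded mesh
        m = trimesh.Trimesh(verts, faces, process=False)
        m.merge_vertices()
        verts = np.asarray(m.vertices, dtype=float)
        faces = np.asarray(m.faces, dtype=np.int64)
    return BoneMesh(vertices=verts, faces=faces, label=label, side=side)


def write_mesh(mesh: BoneMesh, path) -> Path:
    """Write a bone mesh to PLY (default binary), STL or OBJ."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"unsupported mesh extension '{path.suffix}' (supported: "
            f"{sorted(_SUPPORTED_EXTENSIONS)})"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.as_trimesh().export(str(path))
    return path


# ---------------------------------------------------------------------------
# Mirroring


def mirror_foot(foot: FootModel) -> FootModel:
    """Mirror a left foot across the sagittal plane to right-sided anatomy.

    Z is negated and triangle winding flipped so surfaces stay outward
    oriented. Mirroring a right foot raises, preventing silent
    double-mirroring.
    """
    if foot.side != "left":
        raise FootSSMError(
            f"mirror_foot expects a left foot, got side='{foot.side}' "
            f"(subject {foot.subject_id})"
        )
    bones = {}
    for name, bone in foot.bones.items():
        verts = bone.vertices.copy()
        verts[:, 2] *= -1.0
        faces = bone.faces[:, [0, 2, 1]]
        bones[name] = BoneMesh(vertices=verts, faces=faces, label=name, side="right")
    return FootModel(
        bones=bones,
        side="right",
        group=foot.group,
        subject_id=foot.subject_id,
        ground_truth=foot.ground_truth,
    )


# ---------------------------------------------------------------------------
# Principal axes


def principal_axes(points, orientation_hint=(1.0, 0.0, 0.0)):
    """Covariance eigen-axes of a point set, ordered by descending variance.

    Returns ``(axes, centroid)`` where ``axes`` is a 3x3 array with rows
    axis1..axis3 (orthonormal, right-handed). The first axis is sign-flipped
    if needed so that ``dot(axis1, orientation_hint) >= 0``.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("principal axes need >= 3 points")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    if evals[0] <= 0 or evals[-1] / evals[0] < 1e-10:
        # name the deficient direction
        bad = axes[np.argmin(evals)] if evals[0] > 0 else np.array([np.nan] * 3)
        idx = int(np.argmax(np.abs(bad))) if np.isfinite(bad).all() else 2
        raise DegenerateGeometryError(
            f"rank-deficient point covariance: no extent along {_AXIS_NAMES[idx]} "
            f"direction (eigenvalues {evals})"
        )
    hint = np.asarray(orientation_hint, dtype=float)
    if float(axes[0] @ hint) < 0:
        axes[0] = -axes[0]
    # deterministic handedness: fix axis2 sign by a lexicographic rule,
    # axis3 completes the right-handed frame
    if axes[1][np.argmax(np.abs(axes[1]))] < 0:
        axes[1] = -axes[1]
    axes[2] = np.cross(axes[0], axes[1])
    return axes, centroid


# ---------------------------------------------------------------------------
# Rigid alignment


def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares proper rotation mapping centered source onto centered
    target (SVD orthogonal-Procrustes with reflection correction)."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    return Vt.T @ D @ U.T


def _check_noncollinear(pts: np.ndarray, name: str) -> None:
    if len(pts) < 3:
        raise DegenerateGeometryError(f"{name}: ICP needs >= 3 points")
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(f"{name}: points are collinear or coincident")


class IterativeClosestPoint:
    """Point-to-point rigid ICP, scikit-learn estimator style.

    Correspondence is single-direction nearest neighbor from (transformed)
    source vertices to target vertices; each iteration solves the rotation by
    the orthogonal-Procrustes closed form over the current pairs. Scaling is
    deliberately not estimated (size removal is reserved for the Procrustes
    stage of the shape model).

    Parameters
    ----------
    max_iter : maximum number of iterations (default 100).
    tol : stop when the RMS improvement falls below this value (mm).

    Attributes (after :meth:`fit`)
    ------------------------------
    transform_ : RigidTransform mapping source points onto the target.
    rms_ : final root-mean-square nearest-neighbor distance (mm).
    rms_history_ : RMS trace per iteration (non-increasing).
    n_iter_ : iterations run.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "IterativeClosestPoint":
        for k, v in params.items():
            if k not in ("max_iter", "tol"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, source, target) -> "IterativeClosestPoint":
        src = _as_points(source, "source")
        tgt = _as_points(target, "target")
        _check_noncollinear(src, "source")
        _check_noncollinear(tgt, "target")
        tree = cKDTree(tgt)
        transform = RigidTransform.identity()
        current = src
        history = []
        prev_rms = np.inf
        for _ in range(int(self.max_iter)):
            dists, idx = tree.query(current)
            rms = float(np.sqrt(np.mean(dists**2)))
            history.append(rms)
            if prev_rms - rms < self.tol:
                break
            prev_rms = rms
            pairs = tgt[idx]
            c_src = current.mean(axis=0)
            c_tgt = pairs.mean(axis=0)
            R = kabsch_rotation(current - c_src, pairs - c_tgt)
            t = c_tgt - R @ c_src
            step = RigidTransform(R, t)
            transform = step.compose(transform)
            current = step.apply(current)
        self.transform_ = transform
        self.rms_ = history[-1]
        self.rms_history_ = np.asarray(history)
        self.n_iter_ = len(history)
        return self


def icp_align(source, target, max_iter: int = 100, tol: float = 1e-6):
    """Functional wrapper: returns ``(RigidTransform, final_rms_mm)``."""
    icp = IterativeClosestPoint(max_iter=max_iter, tol=tol).fit(source, target)
    return icp.transform_, icp.rms_
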