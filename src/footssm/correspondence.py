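"""Particle systems, generalized Procrustes analysis and coordinate frames.

Correspondence strategy
-----------------------
Synthetic cohorts share fixed-topology bone templates, so correspondence
comes for free: particle *k* of a bone is the same template vertex in every
subject. :func:`extract_particles` subsamples template vertices with a fixed
per-bone index permutation, identical across subjects. For external meshes
that do not share topology, :func:`project_reference_particles` offers a
clearly-labeled nearest-point approximation (it projects a reference
subject's particles onto another subject's surface vertices); it is *not*
an optimized correspondence model.

Two coordinate frames drive the downstream statistics:

* **world** -- whole-foot generalized Procrustes (translation, scaling to
  unit centroid size, rotation) against the cohort mean. Relative bone pose
  within the foot is preserved, so between-group differences here mix bone
  shape and bone alignment.
* **local** -- each bone is additionally rigid-aligned (no scaling) across
  subjects to that bone's cohort mean. What remains is intrinsic bone shape.

The contrast between the two frames is what separates "alignment" from
"shape" differences in the per-particle significance maps.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import CorrespondenceError
from .mesh import BONE_NAMES, FootModel, kabsch_rotation

DEFAULT_PARTICLES_PER_BONE = 128


# --------------------------------------------------------------------------
# Particle systems


@dataclass
class ParticleSystem:
    """Ordered correspondence points for one subject.

    ``points`` holds raw mm coordinates per bone (bone label -> (n_b, 3)).
    ``world`` and ``local`` are filled by the Procrustes stages; world
    coordinates are dimensionless (unit centroid size), local coordinates
    live in the same normalized scale.
    """

    subject_id: str
    group: Optional[str]
    points: dict[str, np.ndarray]
    world: Optional[dict[str, np.ndarray]] = None
    local: Optional[dict[str, np.ndarray]] = None

    @property
    def counts(self) -> dict[str, int]:
        return {label: len(arr) for label, arr in self.points.items()}

    @property
    def centroid_size(self) -> float:
        stacked = self.stack("raw")
        centered = stacked - stacked.mean(axis=0)
        return float(np.sqrt((centered**2).sum()))

    def stack(self, frame: str = "raw") -> np.ndarray:
        source = {"raw": self.points, "world": self.world, "local": self.local}[frame]
        if source is None:
            raise CorrespondenceError(
                f"frame '{frame}' not computed for subject {self.subject_id}"
            )
        return np.vstack([source[label] for label in BONE_NAMES])


@dataclass(frozen=True)
class ShapeMatrix:
    """Subjects-by-coordinates matrix of flattened particle coordinates.

    Column ordering contract: bone-major (in :data:`footssm.mesh.BONE_NAMES`
    order), particle-minor, XYZ innermost.
    """

    data: np.ndarray
    frame: str
    layout: tuple[tuple[str, int], ...]
    subject_ids: tuple[str, ...]
    groups: tuple[Optional[str], ...]

    def __post_init__(self):
        if not np.isfinite(self.data).all():
            raise CorrespondenceError("shape matrix contains non-finite entries")
        total = 3 * sum(c for _, c in self.layout)
        if self.data.shape != (len(self.subject_ids), total):
            raise CorrespondenceError(
                f"shape matrix {self.data.shape} does not match layout "
                f"({len(self.subject_ids)} x {total})"
            )

    @property
    def n_particles(self) -> int:
        return sum(c for _, c in self.layout)

    def column_index(self, bone: str, particle: int, axis: int) -> int:
        """Invertible back-mapping (bone, particle, axis) -> column."""
        offset = 0
        for label, count in self.layout:
            if label == bone:
                if not 0 <= particle < count:
                    raise IndexError(f"particle {particle} out of range for {bone}")
                return 3 * (offset + particle) + axis
            offset += count
        raise KeyError(f"bone '{bone}' not in layout")

    def particle_label(self, flat_particle: int) -> tuple[str, int]:
        offset = 0
        for label, count in self.layout:
            if flat_particle < offset + count:
                return label, flat_particle - offset
            offset += count
        raise IndexError(f"particle index {flat_particle} out of range")

    def as_points(self) -> np.ndarray:
        """(n_subjects, n_particles, 3) view of the matrix."""
        return self.data.reshape(len(self.subject_ids), self.n_particles, 3)


def _particle_indices(label: str, n_vertices: int, count: int) -> np.ndarray:
    """Uniform stride over a fixed per-bone index permutation.

    The permutation is seeded from the bone label only, so every subject
    (and every run) selects the same template vertex ids.
    """
    if count > n_vertices:
        raise CorrespondenceError(
            f"requested {count} particles for '{label}' but the template has "
            f"only {n_vertices} vertices"
        )
    rng = np.random.default_rng(zlib.crc32(label.encode()))
    perm = rng.permutation(n_vertices)
    sel = perm[np.floor(np.arange(count) * n_vertices / count).astype(int)]
    return np.sort(sel)


def extract_particles(foot: FootModel, counts=DEFAULT_PARTICLES_PER_BONE) -> ParticleSystem:
    """Deterministically subsample template vertices as particles.

    ``counts`` is an int (same for every bone) or a dict bone -> int.
    The foot must be right-sided (mirror left feet first).
    """
    if foot.side != "right":
        raise CorrespondenceError(
            f"extract_particles expects right-sided feet; mirror subject "
            f"{foot.subject_id} first"
        )
    if isinstance(counts, int):
        counts = {label: counts for label in BONE_NAMES}
    points = {}
    for label in BONE_NAMES:
        verts = foot.bones[label].vertices
        idx = _particle_indices(label, len(verts), int(counts[label]))
        points[label] = verts[idx].copy()
    return ParticleSystem(
        subject_id=foot.subject_id or "unknown", group=foot.group, points=points
    )


def project_reference_particles(reference: ParticleSystem, foot: FootModel) -> ParticleSystem:
    """Approximate correspondence for external meshes (nearest vertex).

    Projects each reference particle onto the nearest vertex of the same
    bone in ``foot``. This is a convenience approximation for meshes without
    shared template topology -- it does not optimize correspondence quality.
    """
    from scipy.spatial import cKDTree

    if foot.side != "right":
        raise CorrespondenceError("project_reference_particles expects right-sided feet")
    points = {}
    for label in BONE_NAMES:
        verts = foot.bones[label].vertices
        tree = cKDTree(verts)
        _, idx = tree.query(reference.points[label])
        points[label] = verts[idx].copy()
    return ParticleSystem(
        subject_id=foot.subject_id or "unknown", group=foot.group, points=points
    )


def _check_layouts(systems: Sequence[ParticleSystem]) -> tuple[tuple[str, int], ...]:
    if len(systems) < 2:
        raise CorrespondenceError("need >= 2 subjects")
    ref = systems[0].counts
    for sys_ in systems[1:]:
        for label in BONE_NAMES:
            if sys_.counts.get(label) != ref.get(label):
                raise CorrespondenceError(
                    f"particle count mismatch for bone '{label}': subject "
                    f"{sys_.subject_id} has {sys_.counts.get(label)}, expected {ref.get(label)}"
                )
    return tuple((label, ref[label]) for label in BONE_NAMES)


# --------------------------------------------------------------------------
# Generalized Procrustes analysis


class GeneralizedProcrustes:
    """Generalized Procrustes alignment, scikit-learn estimator style.

    Iterative scheme: center every configuration, scale each to unit
    centroid size (if ``with_scaling``), rotate each to the current mean
    configuration (rotation-only orthogonal Procrustes), re-estimate and
    renormalize the mean; repeat until the mean moves less than ``tol``
    (Frobenius norm) or ``max_iter`` is reached. All steps are symmetric in
    the subjects, so the result is insensitive to subject ordering.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_ : (p, 3) mean configuration, zero centroid, unit centroid size.
    aligned_ : (n, p, 3) aligned configurations.
    scales_ : per-subject centroid sizes removed (1.0 when not scaling).
    n_iter_, converged_, objective_history_ : convergence diagnostics; the
        objective (sum of squared distances to the mean) is non-increasing.
    """

    def __init__(self, with_scaling: bool = True, tol: float = 1e-8, max_iter: int = 100):
        self.with_scaling = with_scaling
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "with_scaling": self.with_scaling,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "GeneralizedProcrustes":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X) -> "GeneralizedProcrustes":
        configs = np.asarray(X, dtype=float)
        if configs.ndim != 3 or configs.shape[2] != 3:
            raise ValueError(f"expected (n_subjects, n_points, 3), got {configs.shape}")
        n = len(configs)
        if n < 2:
            raise CorrespondenceError("GPA needs >= 2 subjects")
        configs = configs - configs.mean(axis=1, keepdims=True)
        sizes = np.sqrt((configs**2).sum(axis=(1, 2)))
        if (sizes <= 0).any():
            raise CorrespondenceError("a configuration has zero centroid size")
        if self.with_scaling:
            configs = configs / sizes[:, None, None]
            self.scales_ = sizes.copy()
        else:
            self.scales_ = np.ones(n)

        def _normalize(mean):
            mean = mean - mean.mean(axis=0)
            return mean / np.sqrt((mean**2).sum())

        mean = _normalize(configs.mean(axis=0))
        history = []
        converged = False
        for it in range(int(self.max_iter)):
            for i in range(n):
                R = kabsch_rotation(configs[i], mean)
                configs[i] = configs[i] @ R.T
            new_mean = _normalize(configs.mean(axis=0))
            history.append(float(((configs - new_mean) ** 2).sum()))
            delta = float(np.linalg.norm(new_mean - mean))
            mean = new_mean
            if delta < self.tol:
                converged = True
                break
        if not converged:
            import warnings

            warnings.warn(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last mean change {delta:.3e})",
                RuntimeWarning,
                stacklevel=2,
            )
        self.mean_ = mean
        self.aligned_ = configs
        self.n_iter_ = len(history)
        self.converged_ = converged
        self.objective_history_ = np.asarray(history)
        return self

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).aligned_


def generalized_procrustes(
    systems: Sequence[ParticleSystem], with_scaling: bool = True
) -> tuple[list[ParticleSystem], np.ndarray]:
    """Whole-foot GPA over a cohort of particle systems.

    Returns ``(systems, mean_configuration)`` where each returned system has
    its ``world`` frame filled in. Input systems are not modified.
    """
    layout = _check_layouts(systems)
    stacked = np.stack([s.stack("raw") for s in systems])
    gpa = GeneralizedProcrustes(with_scaling=with_scaling).fit(stacked)
    out = []
    for i, s in enumerate(systems):
        world = {}
        offset = 0
        for label, count in layout:
            world[label] = gpa.aligned_[i, offset : offset + count].copy()
            offset += count
        out.append(
            ParticleSystem(
                subject_id=s.subject_id,
                group=s.group,
                points={k: v.copy() for k, v in s.points.items()},
                world=world,
                local=s.local,
            )
        )
    return out, gpa.mean_


def per_bone_local_frames(systems: Sequence[ParticleSystem]) -> list[ParticleSystem]:
    """Rigid-only per-bone alignment of world coordinates.

    For each bone independently, every subject's particle set is aligned
    (translation + rotation, no scaling: whole-foot size was already
    removed, and per-bone scale is genuine shape signal) to the bone's
    cohort mean. The residual coordinates are the "local"/shape frame;
    world coordinates are left untouched.
    """
    layout = _check_layouts(systems)
    for s in systems:
        if s.world is None:
            raise CorrespondenceError(
                f"world frame missing for subject {s.subject_id}; run "
                "generalized_procrustes first"
            )
    out = [
        ParticleSystem(
            subject_id=s.subject_id,
            group=s.group,
            points={k: v.copy() for k, v in s.points.items()},
            world={k: v.copy() for k, v in s.world.items()},
            local={},
        )
        for s in systems
    ]
    for label, count in layout:
        if count < 3:
            raise CorrespondenceError(
                f"bone '{label}' has {count} particles; local alignment needs >= 3"
            )
        arr = np.stack([s.world[label] for s in systems])
        gpa = GeneralizedProcrustes(with_scaling=False).fit(arr)
        for i in range(len(systems)):
            out[i].local[label] = gpa.aligned_[i].copy()
    return out


def flatten(systems: Sequence[ParticleSystem], frame: str) -> ShapeMatrix:
    """Flatten a cohort into a :class:`ShapeMatrix` (see ordering contract)."""
    if frame not in ("world", "local", "raw"):
        raise CorrespondenceError(f"unknown frame '{frame}'")
    layout = _check_layouts(systems)
    rows = [s.stack(frame).reshape(-1) for s in systems]
    return ShapeMatrix(
        data=np.vstack(rows),
        frame=frame,
        layout=layout,
        subject_ids=tuple(s.subject_id for s in systems),
        groups=tuple(s.group for s in systems),
    )


def unflatten(matrix: ShapeMatrix, row: int) -> dict[str, np.ndarray]:
    """Inverse of :func:`flatten` for one subject row."""
    points = matrix.as_points()[row]
    out = {}
    offset = 0
    for label, count in matrix.layout:
        out[label] = points[offset : offset + count].copy()
        offset += count
    return out


# --------------------------------------------------------------------------
# Particle file I/O (plain-text XYZ per subject per bone + JSON index)


def write_particles(systems: Sequence[ParticleSystem], outdir, frame: str = "raw") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {"frame": frame, "subjects": []}
    for s in systems:
        entry = {"subject_id": s.subject_id, "group": s.group, "files": {}}
        source = {"raw": s.points, "world": s.world, "local": s.local}[frame]
        if source is None:
            raise CorrespondenceError(f"frame '{frame}' not computed for {s.subject_id}")
        for label in BONE_NAMES:
            rel = Path(s.subject_id) / f"{label}_{frame}.particles"
            path = outdir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            np.savetxt(path, source[label], fmt="%.9g")
            entry["files"][label] = str(rel)
        index["subjects"].append(entry)
    index_path = outdir / f"index_{frame}.json"
    index_path.write_text(json.dumps(index, indent=2, sort_keys=True))
    return index_path
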