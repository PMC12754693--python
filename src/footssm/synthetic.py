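"""Parametric synthetic foot cohorts with exactly known radiographic angles.

No public dataset of weight-bearing CT segmentations exists for this kind of
cohort, so every downstream stage is exercised on generated feet whose
Meary's angle (MA), hindfoot alignment angle (HAA) and calcaneal inclination
(CI) are planted by construction and therefore known to machine precision.

Anatomy is deliberately schematic -- each bone is a fixed-topology template
primitive (subdivided icosahedron scaled to an ellipsoid, or an extruded
pentagonal prism for the calcaneus) -- but the geometry is exact: with zero
surface noise, the radiographic operators in :mod:`footssm.radiographic`
recover the planted angles to < 1e-6 degrees (a fixed-point contract tested
in the suite).

Kinematic construction, in order (right foot):

1. CI: the calcaneus is pitched about the mediolateral axis so the sagittal
   slope of its inferior keel equals the planted CI. The pitch is solved as
   ``theta = atan(tan(CI) / cos(HAA))`` so the later coronal tilt leaves the
   sagittal projection exact.
2. MA: the metatarsal chain rotates rigidly in the sagittal plane about a
   common pivot so the first metatarsal's long axis sits at the planted MA
   relative to the (fixed) talar axis.
3. HAA: the calcaneus is tilted about the anteroposterior axis under a
   vertical tibia; valgus (heel lateral) is positive.

Left feet mirror the right-foot construction across the sagittal plane.
Per-subject shape noise is isotropic Gaussian, applied to template vertices
in the local frame *before* posing, so world-frame group differences remain
attributable to the planted angles.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh

from .errors import ConfigError, FootSSMError
from .mesh import BONE_NAMES, SIDES, BoneMesh, FootModel, read_mesh, write_mesh

# --------------------------------------------------------------------------
# Template primitives

#: Calcaneus cross-section polygon in the (z, y) plane, ordered around the
#: boundary; the single keel vertex at (0, 0) gives the bone a well-defined
#: inferior border line for the calcaneal-inclination measurement. The keel
#: extends posteriorly past the weight-bearing body, playing the role of the
#: plantar tuberosity.
_CALC_RING_ZY = np.array(
    [
        (0.0, 0.0),  # inferior keel
        (9.0, 8.0),
        (16.0, 28.0),
        (10.0, 50.0),
        (0.0, 55.0),  # superior ridge
        (-10.0, 50.0),
        (-16.0, 28.0),
        (-9.0, 8.0),
    ]
)
_CALC_U_MIN = -15.0  # posterior keel end (tuberosity region), mm
_CALC_U_MAX = 85.0  # anterior end, mm
_CALC_SEGMENTS = 28
_CALC_REAR_CAP = np.array([-18.0, 27.0, 0.0])
_CALC_FRONT_CAP = np.array([88.0, 27.0, 0.0])

#: Ellipsoid semi-axes (mm) for the remaining bones, in the template local
#: frame (x anterior, y superior, z lateral). Distinct semi-axes give each
#: longitudinal bone an unambiguous principal axis.
_ELLIPSOID_SEMI_AXES = {
    "cuboid": (15.0, 11.0, 13.0),
    "cuneiform_intermediate": (9.0, 12.0, 7.0),
    "cuneiform_lateral": (9.0, 11.0, 8.0),
    "cuneiform_medial": (11.0, 13.0, 8.0),
    "metatarsal_1": (32.0, 8.0, 9.0),
    "metatarsal_2": (34.0, 6.0, 7.0),
    "metatarsal_3": (33.0, 6.0, 7.0),
    "metatarsal_4": (32.0, 6.0, 7.0),
    "metatarsal_5": (30.0, 6.5, 7.5),
    "navicular": (9.0, 13.0, 19.0),
    "talus": (27.0, 13.0, 16.0),
    "tibia": (18.0, 78.0, 17.0),
}

#: Fixed talar longitudinal-axis pitch (degrees, sagittal; negative =
#: anterior end plantar). MA is planted relative to this axis.
TALAR_PITCH_DEG = -15.0

#: Metatarsal chain pivot and per-metatarsal offsets along the chain frame.
_MT_PIVOT = np.array([130.0, 42.0, 0.0])
_MT_OFFSETS = {
    "metatarsal_1": np.array([34.0, 0.0, -20.0]),
    "metatarsal_2": np.array([34.0, 1.0, -8.0]),
    "metatarsal_3": np.array([34.0, 1.5, 3.0]),
    "metatarsal_4": np.array([34.0, 1.0, 14.0]),
    "metatarsal_5": np.array([34.0, 0.0, 25.0]),
}

#: Fixed translations for bones whose pose does not depend on the planted
#: angles (mm, anatomical frame).
_STATIC_TRANSLATIONS = {
    "talus": np.array([60.0, 52.0, 0.0]),
    "tibia": np.array([55.0, 145.0, 0.0]),
    "navicular": np.array([95.0, 48.0, -8.0]),
    "cuboid": np.array([92.0, 28.0, 16.0]),
    "cuneiform_medial": np.array([115.0, 46.0, -16.0]),
    "cuneiform_intermediate": np.array([115.0, 44.0, -4.0]),
    "cuneiform_lateral": np.array([113.0, 42.0, 7.0]),
}
_CALC_TRANSLATION = np.array([0.0, 6.0, 0.0])


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _build_calcaneus_template() -> tuple[np.ndarray, np.ndarray]:
    """Extruded pentagonal prism with a posteriorly extended inferior keel.

    The vertex set is mirror-symmetric in z (so the vertex centroid lies at
    z = 0 exactly) and the inferior keel vertices are collinear, which makes
    the angle planting closed-form: any windowed plantar landmark is a
    convex combination of keel vertices and therefore stays on the keel
    line at every pose.
    """
    ring = _CALC_RING_ZY  # (z, y)
    m = len(ring)
    verts = [_CALC_REAR_CAP]
    for u in np.linspace(_CALC_U_MIN, _CALC_U_MAX, _CALC_SEGMENTS + 1):
        verts.append(np.column_stack([np.full(m, u), ring[:, 1], ring[:, 0]]))
    verts.append(_CALC_FRONT_CAP)
    vertices = np.vstack([np.atleast_2d(v) for v in verts])

    faces = []
    # rear cap fan (vertex 0 is the rear cap center; ring r starts at 1 + r*m)
    for k in range(m):
        faces.append([0, 1 + (k + 1) % m, 1 + k])
    n_rings = _CALC_SEGMENTS + 1
    for r in range(n_rings - 1):
        a0 = 1 + r * m
        b0 = 1 + (r + 1) * m
        for k in range(m):
            k1 = (k + 1) % m
            faces.append([a0 + k, a0 + k1, b0 + k1])
            faces.append([a0 + k, b0 + k1, b0 + k])
    cap = len(vertices) - 1
    last = 1 + (n_rings - 1) * m
    for k in range(m):
        faces.append([last + k, last + (k + 1) % m, cap])
    faces = np.asarray(faces, dtype=np.int64)

    # ensure outward orientation (positive enclosed volume)
    probe = trimesh.Trimesh(vertices.copy(), faces.copy(), process=False)
    if probe.volume < 0:
        faces = faces[:, [0, 2, 1]]
    return vertices, faces


@lru_cache(maxsize=None)
def bone_template(label: str) -> tuple[np.ndarray, np.ndarray]:
    """Template ``(vertices, faces)`` for one bone, in its local frame.

    Identical topology and vertex ordering for every generated foot: this is
    what gives the cohort cross-subject correspondence by construction.
    Arrays are returned read-only; copy before modifying.
    """
    if label == "calcaneus":
        verts, faces = _build_calcaneus_template()
    elif label in _ELLIPSOID_SEMI_AXES:
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        verts = np.asarray(sphere.vertices, dtype=float) * np.asarray(
            _ELLIPSOID_SEMI_AXES[label]
        )
        faces = np.asarray(sphere.faces, dtype=np.int64)
    else:
        raise KeyError(f"no template for bone '{label}'")
    verts.setflags(write=False)
    faces.setflags(write=False)
    return verts, faces


def template_vertex_counts() -> dict[str, int]:
    return {label: len(bone_template(label)[0]) for label in BONE_NAMES}


# --------------------------------------------------------------------------
# Ground truth and generator parameters


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters attached to a generated foot."""

    ma: float
    haa: float
    ci: float
    side: str
    scale: float

    def __post_init__(self):
        for name in ("ma", "haa", "ci", "scale"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"ground-truth {name} must be finite")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")


_TABLE_GROUPS = ("rectus", "cavus", "cai")


@dataclass
class GeneratorParams:
    """Cohort-level generator parameters.

    Defaults reproduce the study conditions: group sizes 28/29/23
    (rectus/cavus/CAI) with per-group radiographic angle distributions
    MA (0.2 +- 2.6, 17 +- 8.6, 12 +- 8.6) degrees,
    HAA (9.8 +- 3.4, 5.9 +- 4.1, 6.0 +- 3.9) degrees,
    CI (19 +- 3.6, 21 +- 3.1, 22 +- 3.1) degrees,
    modeled as independent normals. ``left_fraction`` defaults to the
    cohort-wide 46% left-sided feet. Surface noise (0.3 mm, sub-voxel for
    0.37 mm CT) and log-normal global scale jitter (sigma 0.05) are the
    generator's own realism choices.
    """

    group_names: tuple[str, ...] = _TABLE_GROUPS
    group_sizes: tuple[int, ...] = (28, 29, 23)
    ma_mean: tuple[float, ...] = (0.2, 17.0, 12.0)
    ma_sd: tuple[float, ...] = (2.6, 8.6, 8.6)
    haa_mean: tuple[float, ...] = (9.8, 5.9, 6.0)
    haa_sd: tuple[float, ...] = (3.4, 4.1, 3.9)
    ci_mean: tuple[float, ...] = (19.0, 21.0, 22.0)
    ci_sd: tuple[float, ...] = (3.6, 3.1, 3.1)
    left_fraction: float = 0.46
    noise_sd: float = 0.3
    scale_sd: float = 0.05
    seed: int = 0

    _FIELDS = (
        "group_names",
        "group_sizes",
        "ma_mean",
        "ma_sd",
        "haa_mean",
        "haa_sd",
        "ci_mean",
        "ci_sd",
        "left_fraction",
        "noise_sd",
        "scale_sd",
        "seed",
    )

    def validate(self) -> None:
        problems = []
        k = len(self.group_names)
        for name in ("group_sizes", "ma_mean", "ma_sd", "haa_mean", "haa_sd", "ci_mean", "ci_sd"):
            if len(getattr(self, name)) != k:
                problems.append(f"{name} must have {k} entries (one per group)")
        for name in ("ma_sd", "haa_sd", "ci_sd"):
            if any(s < 0 for s in getattr(self, name)):
                problems.append(f"{name} entries must be >= 0")
        if any(n < 2 for n in self.group_sizes):
            problems.append("group sizes must be >= 2 (downstream statistics undefined)")
        if not 0.0 <= self.left_fraction <= 1.0:
            problems.append("left_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.scale_sd < 0:
            problems.append("scale_sd must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed must be an integer")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict:
        return {
            name: (list(v) if isinstance(v := getattr(self, name), tuple) else v)
            for name in self._FIELDS
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        problems = [f"unknown generator key '{k}'" for k in data if k not in cls._FIELDS]
        if problems:
            raise ConfigError(problems)
        kwargs = {
            k: (tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in data.items()
        }
        params = cls(**kwargs)
        params.validate()
        return params


# --------------------------------------------------------------------------
# Foot construction


def _bone_poses(ma_deg: float, haa_deg: float, ci_deg: float):
    """Rotation/translation per bone implementing the kinematic construction."""
    phi = math.radians(haa_deg)
    # compensated pitch: after the coronal tilt, the sagittal-projected keel
    # slope must still be exactly tan(CI)
    theta = math.atan2(math.tan(math.radians(ci_deg)), math.cos(phi))
    theta_t = math.radians(TALAR_PITCH_DEG)
    theta_m = theta_t + math.radians(ma_deg)

    poses = {}
    poses["calcaneus"] = (_rot_x(-phi) @ _rot_z(theta), _CALC_TRANSLATION)
    poses["talus"] = (_rot_z(theta_t), _STATIC_TRANSLATIONS["talus"])
    for label, t in _STATIC_TRANSLATIONS.items():
        if label == "talus":
            continue
        poses[label] = (np.eye(3), t)
    R_chain = _rot_z(theta_m)
    for label, offset in _MT_OFFSETS.items():
        poses[label] = (R_chain, _MT_PIVOT + R_chain @ offset)
    return poses


def build_parametric_foot(
    ma: float,
    haa: float,
    ci: float,
    scale: float = 1.0,
    side: str = "right",
    noise_sd: float = 0.0,
    seed=0,
    group: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> FootModel:
    """Build one schematic foot with planted radiographic angles.

    ``seed`` is an int or a tuple of ints (a stream key). Deterministic:
    identical arguments (including ``seed``) give bitwise identical vertex
    arrays.
    """
    for name, value in (("ma", ma), ("haa", haa), ("ci", ci)):
        if not math.isfinite(value):
            raise ValueError(f"planted {name} must be finite, got {value}")
    if not (math.isfinite(scale) and scale > 0):
        raise ValueError(f"scale must be positive and finite, got {scale}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got '{side}'")

    seed_key = [int(s) for s in np.atleast_1d(seed)]
    rng = np.random.default_rng(seed_key + [23])
    poses = _bone_poses(ma, haa, ci)
    bones = {}
    for label in BONE_NAMES:
        tmpl_verts, tmpl_faces = bone_template(label)
        verts = np.array(tmpl_verts, dtype=float)
        if noise_sd > 0:
            verts = verts + rng.normal(0.0, noise_sd, size=verts.shape)
        R, t = poses[label]
        verts = verts @ R.T + t
        verts *= scale
        faces = np.array(tmpl_faces)
        if side == "left":
            verts[:, 2] *= -1.0
            faces = faces[:, [0, 2, 1]]
        bones[label] = BoneMesh(vertices=verts, faces=faces, label=label, side=side)
    return FootModel(
        bones=bones,
        side=side,
        group=group,
        subject_id=subject_id,
        ground_truth=GroundTruth(ma=ma, haa=haa, ci=ci, side=side, scale=scale),
    )


def sample_planted_parameters(params: GeneratorParams, subject_index: int, group_index: int):
    """Draw one subject's planted angles, side and scale.

    Each subject consumes an independent, reordering-stable substream keyed
    by ``(params.seed, subject_index)``, so cohorts with different seeds
    share no random draws.
    """
    rng = np.random.default_rng([params.seed, subject_index, 7])
    g = group_index
    ma = rng.normal(params.ma_mean[g], params.ma_sd[g])
    haa = rng.normal(params.haa_mean[g], params.haa_sd[g])
    ci = rng.normal(params.ci_mean[g], params.ci_sd[g])
    side = "left" if rng.random() < params.left_fraction else "right"
    scale = math.exp(rng.normal(0.0, params.scale_sd))
    return ma, haa, ci, side, scale


def sample_cohort(params: Optional[GeneratorParams] = None) -> list[FootModel]:
    """Sample a group-structured cohort of parametric feet.

    Per-subject (MA, HAA, CI) are drawn independently from the group's
    normal distributions; each foot is then built with
    :func:`build_parametric_foot`. Subjects are ordered group-major
    (rectus, cavus, CAI by default).
    """
    params = params if params is not None else GeneratorParams()
    params.validate()
    cohort = []
    idx = 0
    for g, (gname, size) in enumerate(zip(params.group_names, params.group_sizes)):
        for k in range(size):
            ma, haa, ci, side, scale = sample_planted_parameters(params, idx, g)
            foot = build_parametric_foot(
                ma=ma,
                haa=haa,
                ci=ci,
                scale=scale,
                side=side,
                noise_sd=params.noise_sd,
                seed=(params.seed, idx),
                group=gname,
                subject_id=f"{gname}_{k:03d}",
            )
            cohort.append(foot)
            idx += 1
    return cohort


# --------------------------------------------------------------------------
# Cohort I/O

_MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "side",
    "planted_ma",
    "planted_haa",
    "planted_ci",
    "scale",
    "bone",
    "path",
)


def write_cohort(cohort: Sequence[FootModel], outdir, fmt: str = "ply") -> Path:
    """Write one mesh file per bone plus a cohort manifest CSV.

    Returns the manifest path. ``fmt`` is ``ply`` (default), ``stl`` or
    ``obj``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for foot in cohort:
            if foot.subject_id is None:
                raise FootSSMError("cohort feet must have subject ids to be written")
            gt = foot.ground_truth
            for label in BONE_NAMES:
                rel = Path(foot.subject_id) / f"{label}.{fmt}"
                write_mesh(foot.bones[label], outdir / rel)
                writer.writerow(
                    [
                        foot.subject_id,
                        foot.group or "",
                        foot.side,
                        "" if gt is None else f"{gt.ma:.9g}",
                        "" if gt is None else f"{gt.haa:.9g}",
                        "" if gt is None else f"{gt.ci:.9g}",
                        "" if gt is None else f"{gt.scale:.9g}",
                        label,
                        str(rel),
                    ]
                )
    return manifest_path


def load_cohort(manifest_path) -> list[FootModel]:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled in
    the same manifest layout)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    rows_by_subject: dict[str, list[dict]] = {}
    order: list[str] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["subject_id"]
            if sid not in rows_by_subject:
                rows_by_subject[sid] = []
                order.append(sid)
            rows_by_subject[sid].append(row)
    cohort = []
    for sid in order:
        rows = rows_by_subject[sid]
        side = rows[0]["side"]
        group = rows[0]["group"] or None
        bones = {}
        for row in rows:
            bones[row["bone"]] = read_mesh(root / row["path"], row["bone"], side)
        gt = None
        if rows[0].get("planted_ma"):
            gt = GroundTruth(
                ma=float(rows[0]["planted_ma"]),
                haa=float(rows[0]["planted_haa"]),
                ci=float(rows[0]["planted_ci"]),
                side=side,
                scale=float(rows[0]["scale"] or 1.0),
            )
        cohort.append(
            FootModel(bones=bones, side=side, group=group, subject_id=sid, ground_truth=gt)
        )
    return cohort
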