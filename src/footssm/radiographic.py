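"""Computational radiographic measurements from 3-D bone meshes.

Clinical 2-D radiographic angles are derived directly from the 3-D surface
meshes by explicit operational definitions (no published formula exists for
the usual clinical toolchains, so these constructions are validated against
generator ground truth rather than against any external implementation):

* **Meary's angle (MA)**, sagittal: signed angle between the talar and
  first-metatarsal longitudinal axes (covariance principal axes,
  anterior-hinted) projected onto the sagittal plane. Positive when the
  talar axis points plantar of the metatarsal axis (apex-dorsal / cavus
  sense). Rectus feet cluster near 0.
* **Calcaneal inclination (CI)**, sagittal: pitch of the inferior calcaneal
  border, measured as the line between the plantar-most landmark of the
  posterior third and of the anterior third of the calcaneus (thirds by
  anterior-coordinate span), against the floor plane. Positive when the
  anterior end is higher.
* **Hindfoot alignment angle (HAA)**, coronal: signed angle between the
  tibial longitudinal axis (superior-hinted principal axis) and the
  calcaneal hindfoot axis (posterior-plantar tuberosity landmark to
  calcaneus centroid), projected onto the coronal plane. Valgus (distal end
  lateral) is positive.

Landmarks are windowed centroids: the centroid of all vertices within a
small fixed tolerance of the extreme along the defining direction. On the
template geometry the selected vertices are exactly collinear (keel) or
symmetric (tuberosity pad), so the noiseless angles are exact; under
surface noise the averaging keeps single-vertex jitter from dominating the
measurement.

The foot-type rule is deterministic in MA only: rectus for
-4.5 <= MA <= 4.5 (inclusive; the 4.5-degree cutoff absorbs rounding),
cavus for MA > 4.5, "other" below -4.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, FootSSMError
from .mesh import FootModel, mirror_foot, principal_axes

#: Windowed-centroid tolerance for the plantar landmarks of the inferior
#: calcaneal line and the plantar tuberosity landmark (mm above the
#: region's plantar minimum).
PLANTAR_WINDOW_MM = 2.5

RECTUS_MA_CUTOFF_DEG = 4.5


@dataclass(frozen=True)
class AngleMeasures:
    """Radiographic angles for one foot, in degrees.

    MA signed (positive = cavus/apex-dorsal), HAA signed (larger = more
    valgus), CI positive = anterosuperior calcaneal pitch.
    """

    ma: float
    haa: float
    ci: float

    def __post_init__(self):
        for name, bound in (("ma", 90.0), ("haa", 90.0)):
            v = getattr(self, name)
            if not math.isfinite(v) or abs(v) > bound:
                raise ValueError(f"{name} = {v} outside +-{bound} degrees")
        if not math.isfinite(self.ci) or not -90.0 <= self.ci <= 90.0:
            raise ValueError(f"ci = {self.ci} outside [-90, 90] degrees")

    def as_dict(self) -> dict[str, float]:
        return {"ma": self.ma, "haa": self.haa, "ci": self.ci}


def _require_right(foot: FootModel, op: str) -> FootModel:
    if foot.side != "right":
        raise FootSSMError(
            f"{op} expects right-sided anatomy; mirror subject "
            f"{foot.subject_id} first (or use measure_angles, which mirrors "
            "internally)"
        )
    return foot


def _sagittal_axis_angle(vertices: np.ndarray, label: str) -> float:
    """Sagittal-plane angle (degrees, atan2(y, x)) of a bone's longitudinal
    axis, anterior-hinted."""
    axes, _ = principal_axes(vertices, orientation_hint=(1.0, 0.0, 0.0))
    ax = axes[0]
    sag = np.array([ax[0], ax[1]])
    norm = np.linalg.norm(sag)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            f"{label}: longitudinal axis is orthogonal to the sagittal plane"
        )
    return math.degrees(math.atan2(sag[1], sag[0]))


def _wrap_deg(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def meary_angle(foot: FootModel) -> float:
    """Sagittal Meary's angle (degrees) between talar and first-metatarsal
    longitudinal axes; positive in the cavus (apex-dorsal) sense."""
    _require_right(foot, "meary_angle")
    theta_talus = _sagittal_axis_angle(foot["talus"].vertices, "talus")
    theta_mt1 = _sagittal_axis_angle(foot["metatarsal_1"].vertices, "metatarsal_1")
    return _wrap_deg(theta_mt1 - theta_talus)


def _plantar_landmark(verts: np.ndarray, x_lo: float, x_hi: float) -> np.ndarray:
    sel = verts[(verts[:, 0] >= x_lo) & (verts[:, 0] <= x_hi)]
    if len(sel) == 0:
        raise DegenerateGeometryError("calcaneal third contains no vertices")
    y_min = sel[:, 1].min()
    window = sel[sel[:, 1] <= y_min + PLANTAR_WINDOW_MM]
    return window.mean(axis=0)


def calcaneal_inclination(foot: FootModel) -> float:
    """Calcaneal inclination (degrees): sagittal pitch of the inferior
    calcaneal line against the floor plane; positive = anterior end higher."""
    _require_right(foot, "calcaneal_inclination")
    verts = foot["calcaneus"].vertices
    x_min, x_max = verts[:, 0].min(), verts[:, 0].max()
    span = x_max - x_min
    if span <= 0:
        raise DegenerateGeometryError("calcaneus has no anteroposterior extent")
    posterior = _plantar_landmark(verts, x_min, x_min + span / 3.0)
    anterior = _plantar_landmark(verts, x_max - span / 3.0, x_max)
    dx = anterior[0] - posterior[0]
    dy = anterior[1] - posterior[1]
    if dx <= 0:
        raise DegenerateGeometryError("inferior calcaneal line is not anterior-directed")
    return math.degrees(math.atan2(dy, dx))


def _tuberosity_landmark(verts: np.ndarray) -> np.ndarray:
    """Plantar process of the calcaneal tuberosity: the windowed plantar
    landmark of the posterior third (the weight-bearing heel point)."""
    x_min, x_max = verts[:, 0].min(), verts[:, 0].max()
    span = x_max - x_min
    if span <= 0:
        raise DegenerateGeometryError("calcaneus has no anteroposterior extent")
    return _plantar_landmark(verts, x_min, x_min + span / 3.0)


def hindfoot_alignment_angle(foot: FootModel) -> float:
    """Hindfoot alignment angle (degrees) in the coronal plane.

    Angle between the tibial longitudinal axis and the calcaneal hindfoot
    axis (posterior-plantar tuberosity landmark -> calcaneus centroid);
    positive when the distal (plantar) end of the calcaneal axis deviates
    laterally (valgus).
    """
    _require_right(foot, "hindfoot_alignment_angle")
    tib_axes, _ = principal_axes(
        foot["tibia"].vertices, orientation_hint=(0.0, 1.0, 0.0)
    )
    tib = tib_axes[0]
    calc_verts = foot["calcaneus"].vertices
    tuber = _tuberosity_landmark(calc_verts)
    centroid = calc_verts.mean(axis=0)
    v = centroid - tuber  # points proximally (distal end = tuberosity)
    v_cor = np.array([v[1], v[2]])
    t_cor = np.array([tib[1], tib[2]])
    if np.linalg.norm(v_cor) < 1e-6:
        raise DegenerateGeometryError("calcaneal hindfoot axis orthogonal to coronal plane")
    if np.linalg.norm(t_cor) < 1e-6:
        raise DegenerateGeometryError("tibial axis orthogonal to coronal plane")
    # angle from +Y, positive when the distal end sits lateral (+Z)
    alpha_calc = math.degrees(math.atan2(-v_cor[1], v_cor[0]))
    alpha_tib = math.degrees(math.atan2(-t_cor[1], t_cor[0]))
    return _wrap_deg(alpha_calc - alpha_tib)


def classify_foot_type(ma: float) -> str:
    """Foot type from Meary's angle: ``rectus`` for -4.5 <= MA <= 4.5
    (inclusive), ``cavus`` above, ``other`` below."""
    if not math.isfinite(ma):
        raise ValueError(f"MA must be finite, got {ma}")
    if ma > RECTUS_MA_CUTOFF_DEG:
        return "cavus"
    if ma >= -RECTUS_MA_CUTOFF_DEG:
        return "rectus"
    return "other"


def measure_angles(foot: FootModel) -> AngleMeasures:
    """All three radiographic angles for one foot.

    Left feet are mirrored to right-sided anatomy internally before
    measurement (sign conventions are therefore side-consistent: left varus
    maps to right varus).
    """
    if foot.side == "left":
        foot = mirror_foot(foot)
    return AngleMeasures(
        ma=meary_angle(foot),
        haa=hindfoot_alignment_angle(foot),
        ci=calcaneal_inclination(foot),
    )


# --------------------------------------------------------------------------
# Cohort tables


def pooled_group_stats(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """Pooled mean and SD of several groups from their summary statistics.

    ``mean = sum(n_i m_i) / sum(n_i)``;
    ``SD = sqrt(sum[(n_i - 1) s_i^2 + n_i (m_i - M)^2] / (sum(n_i) - 1))``.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds and ns must have equal lengths")
    if (ns < 2).any():
        raise ValueError("group sizes must be >= 2")
    if (sds < 0).any():
        raise ValueError("SDs must be >= 0")
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ss = float(((ns - 1) * sds**2 + ns * (means - grand) ** 2).sum())
    return grand, float(math.sqrt(ss / (total_n - 1)))


def measure_cohort(cohort: Sequence[FootModel]) -> pd.DataFrame:
    """Per-subject radiographic table: subject, group, side, MA, HAA, CI and
    the MA-based foot-type label."""
    rows = []
    for foot in cohort:
        angles = measure_angles(foot)
        rows.append(
            {
                "subject_id": foot.subject_id,
                "group": foot.group,
                "side": foot.side,
                "ma": angles.ma,
                "haa": angles.haa,
                "ci": angles.ci,
                "foot_type": classify_foot_type(angles.ma),
            }
        )
    return pd.DataFrame(rows)


def group_summary_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Group-wise mean/SD/min/max per angle plus a pooled all-data column."""
    rows = []
    groups = list(dict.fromkeys(measures["group"]))
    for angle in ("ma", "haa", "ci"):
        for group in groups:
            x = measures.loc[measures["group"] == group, angle].to_numpy(float)
            rows.append(
                {
                    "angle": angle,
                    "group": group,
                    "n": len(x),
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "min": x.min(),
                    "max": x.max(),
                }
            )
        allx = measures[angle].to_numpy(float)
        rows.append(
            {
                "angle": angle,
                "group": "all",
                "n": len(allx),
                "mean": allx.mean(),
                "sd": allx.std(ddof=1),
                "min": allx.min(),
                "max": allx.max(),
            }
        )
    return pd.DataFrame(rows)
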