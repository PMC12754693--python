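"""Configuration-driven orchestration of the full shape analysis.

Stages, in order:

``simulate``  generate (or load) the cohort of bone meshes
``measure``   radiographic angles + foot-type table
``ssm``       mirror -> whole-foot ICP -> particles -> GPA -> local frames
``stats``     PCA, parallel analysis, per-mode group statistics,
              radiographic Welch/Games-Howell/Hedges, per-particle
              Hotelling maps; assembles the report

When an output directory is configured, each stage writes its artifacts
plus a cache marker keyed by the configuration hash; re-running an
unchanged configuration reloads completed stages instead of recomputing
them. Every random step derives from the single configured seed, so a
re-run with identical config reproduces all numeric fields exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correspondence import (
    ParticleSystem,
    extract_particles,
    flatten,
    generalized_procrustes,
    per_bone_local_frames,
)
from .errors import ConfigError, FootSSMError
from .mesh import BONE_NAMES, FootModel, icp_align, mirror_foot
from .radiographic import group_summary_table, measure_cohort
from .stats import (
    ShapeModePCA,
    anova_oneway,
    eta_squared,
    games_howell,
    hedges_g,
    ks_normality,
    parallel_analysis,
    particle_significance_map,
    tukey_hsd,
    welch_anova,
)
from .synthetic import GeneratorParams, load_cohort, sample_cohort, write_cohort

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "measure", "ssm", "stats")


# --------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML/JSON mirrors these fields)."""

    input_mode: str = "synthetic"  # synthetic | mesh-directory
    mesh_manifest: Optional[str] = None
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    particles_per_bone: int = 128
    run_icp: bool = True
    icp_max_iter: int = 100
    icp_tol: float = 1e-6
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    n_permutations: int = 1000
    percentile: float = 95.0
    alpha: float = 0.05
    fdr_method: str = "bh"
    comparisons: tuple[tuple[str, str], ...] = (
        ("cai", "rectus"),
        ("cavus", "rectus"),
        ("cai", "cavus"),
    )
    outdir: Optional[str] = None
    seed: int = 0

    _FIELDS = (
        "input_mode",
        "mesh_manifest",
        "generator",
        "particles_per_bone",
        "run_icp",
        "icp_max_iter",
        "icp_tol",
        "gpa_tol",
        "gpa_max_iter",
        "n_permutations",
        "percentile",
        "alpha",
        "fdr_method",
        "comparisons",
        "outdir",
        "seed",
    )

    def validate(self) -> None:
        problems = []
        if self.input_mode not in ("synthetic", "mesh-directory"):
            problems.append(
                f"input_mode must be 'synthetic' or 'mesh-directory', got '{self.input_mode}'"
            )
        if self.input_mode == "mesh-directory" and not self.mesh_manifest:
            problems.append("mesh_manifest is required when input_mode='mesh-directory'")
        try:
            self.generator.validate()
        except ConfigError as exc:
            problems.extend(f"generator.{p}" for p in exc.problems)
        if self.particles_per_bone < 3:
            problems.append("particles_per_bone must be >= 3")
        for name in ("icp_tol", "gpa_tol"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("icp_max_iter", "gpa_max_iter"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.n_permutations < 100:
            problems.append("n_permutations must be >= 100")
        if not 0 < self.percentile < 100:
            problems.append("percentile must be in (0, 100)")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        if self.fdr_method != "bh":
            problems.append(f"fdr_method must be 'bh', got '{self.fdr_method}'")
        for pair in self.comparisons:
            if len(pair) != 2:
                problems.append(f"comparison {pair!r} must name exactly two groups")
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed must be an integer")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict:
        d = {}
        for name in self._FIELDS:
            v = getattr(self, name)
            if name == "generator":
                d[name] = v.to_dict()
            elif name == "comparisons":
                d[name] = [list(p) for p in v]
            else:
                d[name] = v
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        problems = [f"unknown config key '{k}'" for k in data if k not in cls._FIELDS]
        kwargs = {}
        gen = data.get("generator", {})
        try:
            kwargs["generator"] = (
                gen if isinstance(gen, GeneratorParams) else GeneratorParams.from_dict(gen)
            )
        except ConfigError as exc:
            problems.extend(f"generator.{p}" for p in exc.problems)
            kwargs["generator"] = GeneratorParams()
        for k, v in data.items():
            if k in ("generator",) or k not in cls._FIELDS:
                continue
            if k == "comparisons":
                v = tuple(tuple(p) for p in v)
            kwargs[k] = v
        config = cls(**kwargs)
        try:
            config.validate()
        except ConfigError as exc:
            problems.extend(exc.problems)
        if problems:
            raise ConfigError(problems)
        return config

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty file yields the full default configuration. Schema violations
    are reported exhaustively in a single :class:`ConfigError`.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError([f"config root must be a mapping, got {type(data).__name__}"])
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Cache


class _StageCache:
    def __init__(self, outdir: Optional[Path], config_hash: str):
        self.outdir = Path(outdir) if outdir else None
        self.hash = config_hash
        if self.outdir:
            (self.outdir / ".cache").mkdir(parents=True, exist_ok=True)

    def marker(self, stage: str) -> Optional[Path]:
        return self.outdir / ".cache" / f"{stage}.json" if self.outdir else None

    def is_valid(self, stage: str) -> bool:
        marker = self.marker(stage)
        if marker is None or not marker.exists():
            return False
        try:
            return json.loads(marker.read_text())["config_hash"] == self.hash
        except (json.JSONDecodeError, KeyError):
            return False

    def commit(self, stage: str, artifacts: Sequence[str] = ()) -> None:
        marker = self.marker(stage)
        if marker is not None:
            marker.write_text(
                json.dumps(
                    {"config_hash": self.hash, "artifacts": list(artifacts)}, indent=2
                )
            )


# --------------------------------------------------------------------------
# Report


@dataclass
class AnalysisReport:
    """Machine-readable end-to-end analysis summary."""

    n_subjects: int
    group_sizes: dict
    n_particles: int
    retained_modes: int
    percent_variance: list
    retained_percent_variance_total: float
    mode_stats: list
    radiographic_stats: dict
    radiographic_table: list
    particle_maps: dict
    provenance: dict
    timing: dict
    stages_skipped: list

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, include_timing: bool = True) -> str:
        d = self.to_dict()
        if not include_timing:
            d.pop("timing")
        return json.dumps(d, indent=2, sort_keys=True)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# --------------------------------------------------------------------------
# Pipeline


def _stage_simulate(config: RunConfig, cache: _StageCache, skipped: list) -> list[FootModel]:
    if config.input_mode == "mesh-directory":
        return load_cohort(config.mesh_manifest)
    generator = replace(config.generator, seed=config.seed)
    if cache.outdir and cache.is_valid("simulate"):
        logger.info("simulate: cache hit, loading cohort from %s", cache.outdir)
        skipped.append("simulate")
        return load_cohort(cache.outdir / "cohort" / "manifest.csv")
    cohort = sample_cohort(generator)
    if cache.outdir:
        manifest = write_cohort(cohort, cache.outdir / "cohort")
        cache.commit("simulate", [str(manifest)])
    return cohort


def _stage_measure(
    cohort: list[FootModel], config: RunConfig, cache: _StageCache, skipped: list
) -> pd.DataFrame:
    if cache.outdir and cache.is_valid("measure"):
        logger.info("measure: cache hit")
        skipped.append("measure")
        return pd.read_csv(cache.outdir / "measures.csv")
    measures = measure_cohort(cohort)
    if cache.outdir:
        path = cache.outdir / "measures.csv"
        measures.to_csv(path, index=False)
        cache.commit("measure", [str(path)])
    return measures


def _stage_ssm(
    cohort: list[FootModel], config: RunConfig, cache: _StageCache, skipped: list
):
    npz_path = cache.outdir / ".cache" / "ssm.npz" if cache.outdir else None
    if npz_path and cache.is_valid("ssm") and npz_path.exists():
        logger.info("ssm: cache hit")
        skipped.append("ssm")
        data = np.load(npz_path, allow_pickle=False)
        layout = [(b, int(c)) for b, c in zip(BONE_NAMES, data["counts"])]
        systems = []
        for i, sid in enumerate(data["subject_ids"]):
            points, world, local = {}, {}, {}
            offset = 0
            for label, count in layout:
                sl = slice(offset, offset + count)
                points[label] = data["raw"][i, sl]
                world[label] = data["world"][i, sl]
                local[label] = data["local"][i, sl]
                offset += count
            systems.append(
                ParticleSystem(
                    subject_id=str(sid),
                    group=str(data["groups"][i]),
                    points=points,
                    world=world,
                    local=local,
                )
            )
        return systems

    feet = [mirror_foot(f) if f.side == "left" else f for f in cohort]
    if config.run_icp:
        ref_idx = next(
            (i for i, f in enumerate(feet) if (f.group or "").lower() == "rectus"), 0
        )
        target = feet[ref_idx].pooled_vertices()
        aligned = []
        for i, foot in enumerate(feet):
            if i == ref_idx:
                aligned.append(foot)
                continue
            transform, rms = icp_align(
                foot.pooled_vertices(),
                target,
                max_iter=config.icp_max_iter,
                tol=config.icp_tol,
            )
            logger.debug("ICP %s -> reference: final RMS %.4f mm", foot.subject_id, rms)
            aligned.append(foot.transformed(transform))
        feet = aligned

    systems = [extract_particles(f, config.particles_per_bone) for f in feet]
    systems, _ = generalized_procrustes(systems, with_scaling=True)
    systems = per_bone_local_frames(systems)

    if npz_path:
        stack = lambda frame: np.stack([s.stack(frame) for s in systems])  # noqa: E731
        np.savez_compressed(
            npz_path,
            raw=stack("raw"),
            world=stack("world"),
            local=stack("local"),
            counts=np.array([systems[0].counts[b] for b in BONE_NAMES]),
            subject_ids=np.array([s.subject_id for s in systems]),
            groups=np.array([s.group or "" for s in systems]),
        )
        cache.commit("ssm", [str(npz_path)])
    return systems


def _mode_statistics(scores: np.ndarray, groups: np.ndarray, group_names, alpha: float):
    vectors = [scores[groups == g] for g in group_names]
    ks = {g: ks_normality(v)[1] for g, v in zip(group_names, vectors)}
    res = anova_oneway(vectors)
    tukey = tukey_hsd(vectors)
    eta, eta_label = eta_squared(res.ss_between, res.ss_total)
    return {
        "ks_p": ks,
        "anova_f": res.f,
        "anova_p": res.p,
        "tukey_p": {
            f"{group_names[i]}_vs_{group_names[j]}": p for (i, j), p in tukey.items()
        },
        "eta_squared": eta,
        "eta_squared_label": eta_label,
        "significant_pairs": [
            f"{group_names[i]}_vs_{group_names[j]}"
            for (i, j), p in tukey.items()
            if p < alpha
        ],
    }


def run_pipeline(config: RunConfig, until: str = "stats") -> AnalysisReport:
    """Execute the pipeline through ``until`` (a stage name) and return the
    analysis report. Errors are re-raised with the failing stage named."""
    if until not in _STAGES:
        raise ValueError(f"unknown stage '{until}' (stages: {_STAGES})")
    config.validate()
    chash = config.config_hash()
    cache = _StageCache(Path(config.outdir) if config.outdir else None, chash)
    timing: dict[str, float] = {}
    skipped: list[str] = []

    def _run(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except FootSSMError as exc:
            raise FootSSMError(f"stage '{stage}' failed: {exc}") from exc
        timing[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-8s done in %.2fs", stage, timing[stage])
        return result

    cohort = _run("simulate", _stage_simulate, config, cache, skipped)
    group_names = list(dict.fromkeys(f.group for f in cohort))
    group_sizes = {g: sum(1 for f in cohort if f.group == g) for g in group_names}
    logger.info("cohort: %d subjects, groups %s", len(cohort), group_sizes)

    measures = None
    if until in ("measure", "ssm", "stats"):
        measures = _run("measure", _stage_measure, cohort, config, cache, skipped)
    systems = None
    if until in ("ssm", "stats"):
        systems = _run("ssm", _stage_ssm, cohort, config, cache, skipped)

    retained = 0
    percent_variance: list[float] = []
    mode_stats: list[dict] = []
    radiographic_stats: dict = {}
    maps_summary: dict = {}
    if until == "stats":
        t0 = time.perf_counter()
        world = flatten(systems, "world")
        local = flatten(systems, "local")
        groups = np.array([s.group for s in systems])

        pca = ShapeModePCA().fit(world.data)
        retained = parallel_analysis(
            world.data,
            n_permutations=config.n_permutations,
            percentile=config.percentile,
            seed=config.seed,
        )
        percent_variance = [float(v) for v in pca.percent_variance_]
        logger.info(
            "PCA: %d modes, parallel analysis retains %d (%.1f%% of variance)",
            pca.n_modes_,
            retained,
            float(np.sum(pca.percent_variance_[:retained])),
        )
        for mode in range(retained):
            stats = _mode_statistics(
                pca.scores_[:, mode], groups, group_names, config.alpha
            )
            stats["mode"] = mode + 1
            stats["percent_variance"] = float(pca.percent_variance_[mode])
            mode_stats.append(stats)

        for angle in ("ma", "haa", "ci"):
            vectors = [
                measures.loc[measures["group"] == g, angle].to_numpy(float)
                for g in group_names
            ]
            fw, pw = welch_anova(vectors)
            gh = games_howell(vectors)
            radiographic_stats[angle] = {
                "welch_f": fw,
                "welch_p": pw,
                "games_howell_p": {
                    f"{group_names[i]}_vs_{group_names[j]}": p for (i, j), p in gh.items()
                },
                "hedges_g": {
                    f"{group_names[i]}_vs_{group_names[j]}": hedges_g(
                        vectors[i], vectors[j]
                    )
                    for (i, j), _ in gh.items()
                },
            }

        world_pts = world.as_points()
        local_pts = local.as_points()
        bones = [world.particle_label(k)[0] for k in range(world.n_particles)]
        for pair in config.comparisons:
            a, b = pair
            if a not in group_names or b not in group_names:
                logger.warning("skipping comparison %s: group not in cohort", pair)
                continue
            mask_a, mask_b = groups == a, groups == b
            smap = particle_significance_map(
                world_pts[mask_a],
                world_pts[mask_b],
                local_pts[mask_a],
                local_pts[mask_b],
                alpha=config.alpha,
                comparison=(a, b),
                particle_bones=bones,
            )
            maps_summary[f"{a}_vs_{b}"] = smap.percentages
            if cache.outdir:
                smap.to_frame().to_csv(
                    cache.outdir / f"particle_map_{a}_vs_{b}.csv", index=False
                )
        timing["stats"] = round(time.perf_counter() - t0, 3)
        logger.info("stage stats    done in %.2fs", timing["stats"])

    table = (
        group_summary_table(measures).to_dict(orient="records")
        if measures is not None
        else []
    )
    report = AnalysisReport(
        n_subjects=len(cohort),
        group_sizes=group_sizes,
        n_particles=(
            sum(systems[0].counts.values()) if systems else 0
        ),
        retained_modes=retained,
        percent_variance=_round_floats(percent_variance),
        retained_percent_variance_total=_round_floats(
            float(sum(percent_variance[:retained]))
        ),
        mode_stats=_round_floats(mode_stats),
        radiographic_stats=_round_floats(radiographic_stats),
        radiographic_table=_round_floats(table),
        particle_maps=_round_floats(maps_summary),
        provenance={
            "config_hash": chash,
            "seed": config.seed,
            "footssm_version": __version__,
        },
        timing=timing,
        stages_skipped=skipped,
    )
    if cache.outdir and until == "stats":
        (Path(config.outdir) / "report.json").write_text(report.to_json())
        cache.commit("stats", ["report.json"])
    return report
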