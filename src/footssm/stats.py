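"""PCA shape models, mode retention, and the group-comparison battery.

The analysis pipeline applies, in order:

* PCA of the flattened particle matrix (modes of variation);
* Horn-style parallel analysis to decide how many modes to retain,
  using column-permutation nulls at the 95th percentile;
* per retained mode: one-sample KS normality per group, one-way ANOVA with
  Tukey(-Kramer) post hoc and eta-squared effect size;
* for radiographic measures: Welch's ANOVA with Games-Howell post hoc and
  Hedges' g (robust to unequal group variances);
* per correspondence particle: two-sample Hotelling's T2 in the world and
  local frames with Benjamini-Hochberg FDR control, combined into a
  shape-vs-alignment classification map.

Effect-size benchmarks follow the conventional thresholds: eta-squared
0.01/0.06/0.14 and |g| 0.20/0.50/0.80 for small/medium/large.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import StatisticsError

logger = logging.getLogger(__name__)

ETA_SQUARED_BENCHMARKS = (("large", 0.14), ("medium", 0.06), ("small", 0.01))
HEDGES_G_BENCHMARKS = (("large", 0.80), ("medium", 0.50), ("small", 0.20))


def _as_groups(groups: Sequence, min_n: int = 2, min_groups: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < min_groups:
        raise StatisticsError(f"need >= {min_groups} groups, got {len(arrays)}")
    for i, a in enumerate(arrays):
        if len(a) < min_n:
            raise StatisticsError(f"group {i} has n={len(a)} < {min_n}")
        if not np.isfinite(a).all():
            raise StatisticsError(f"group {i} contains non-finite values")
    return arrays


# --------------------------------------------------------------------------
# PCA shape model


class ShapeModePCA:
    """PCA of a shape matrix, scikit-learn estimator style.

    Column-mean-centered thin SVD; at most ``n_subjects - 1`` non-null
    modes are kept (numerically null directions are trimmed). Scores are
    the centered data projected on the modes; the variance of mode *k*'s
    scores equals its eigenvalue.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_ : (p,) column means.
    components_ : (r, p) orthonormal modes, descending variance.
    explained_variance_ : (r,) eigenvalues (score variances, ddof=1).
    percent_variance_ : (r,) percent of total variance, sums to 100.
    scores_ : (n, r) per-subject mode scores.
    """

    def __init__(self, null_tol: float = 1e-12):
        self.null_tol = null_tol

    def get_params(self, deep: bool = True) -> dict:
        return {"null_tol": self.null_tol}

    def set_params(self, **params) -> "ShapeModePCA":
        for k, v in params.items():
            if k != "null_tol":
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X) -> "ShapeModePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
        n, p = X.shape
        if n < 3:
            raise StatisticsError(f"PCA needs >= 3 subjects, got {n}")
        if not np.isfinite(X).all():
            raise StatisticsError("shape matrix contains non-finite entries")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > self.null_tol * (s[0] if s.size and s[0] > 0 else 1.0)
        keep &= np.arange(len(s)) < n - 1
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        self.components_ = Vt
        self.explained_variance_ = s**2 / (n - 1)
        total = self.explained_variance_.sum()
        self.percent_variance_ = (
            100.0 * self.explained_variance_ / total if total > 0 else np.zeros_like(s)
        )
        self.scores_ = U * s
        self.n_samples_ = n
        self.n_features_ = p
        return self

    @property
    def n_modes_(self) -> int:
        return len(self.explained_variance_)

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).scores_

    def inverse_transform(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return scores @ self.components_ + self.mean_


def pca_fit(matrix) -> ShapeModePCA:
    """Fit a :class:`ShapeModePCA` on a ShapeMatrix or raw 2-D array."""
    data = getattr(matrix, "data", matrix)
    return ShapeModePCA().fit(data)


# --------------------------------------------------------------------------
# Parallel analysis


def parallel_analysis(
    X,
    n_permutations: int = 1000,
    percentile: float = 95.0,
    seed: Optional[int] = None,
) -> int:
    """Number of PCA modes to retain by permutation-based parallel analysis.

    Null eigenvalues come from independently row-permuting every column of
    the centered matrix (distribution-free, preserves marginal column
    distributions). A mode is retained when its observed eigenvalue strictly
    exceeds the ``percentile`` of the null eigenvalues at the same rank; the
    retained count is the longest such prefix.
    """
    X = np.asarray(getattr(X, "data", X), dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for a stable percentile")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        return 0
    rng = np.random.default_rng(seed)

    def _eigs(mat: np.ndarray) -> np.ndarray:
        # economical spectrum via the Gram matrix when p >> n
        if p > n:
            gram = mat @ mat.T
            vals = np.linalg.eigvalsh(gram)[::-1]
        else:
            vals = np.linalg.eigvalsh(mat.T @ mat)[::-1]
        return np.clip(vals, 0.0, None) / (n - 1)

    observed = _eigs(Xc)
    r = min(n - 1, p)
    observed = observed[:r]
    null = np.empty((n_permutations, r))
    for b in range(n_permutations):
        null[b] = _eigs(rng.permuted(Xc, axis=0))[:r]
    thresholds = np.percentile(null, percentile, axis=0)
    retained = 0
    for lam, thr in zip(observed, thresholds):
        if lam > thr:  # strict: ties are not retained
            retained += 1
        else:
            break
    return retained


class ParallelAnalysis:
    """Estimator wrapper around :func:`parallel_analysis`."""

    def __init__(
        self,
        n_permutations: int = 1000,
        percentile: float = 95.0,
        random_state: Optional[int] = None,
    ):
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "percentile": self.percentile,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ParallelAnalysis":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X) -> "ParallelAnalysis":
        self.n_retained_ = parallel_analysis(
            X,
            n_permutations=self.n_permutations,
            percentile=self.percentile,
            seed=self.random_state,
        )
        return self


# --------------------------------------------------------------------------
# Univariate battery


def ks_normality(scores, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test of normality with estimated mean/SD.

    Returns ``(statistic, p)``. With ``lilliefors=True`` the
    Lilliefors-corrected p-value (statsmodels) is used instead of the
    asymptotic KS distribution; the plain variant matches the conventional
    "KS test against a fitted normal".
    """
    x = np.asarray(scores, dtype=float).ravel()
    if len(x) < 5:
        raise StatisticsError(f"KS normality needs >= 5 values, got {len(x)}")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise StatisticsError("KS normality undefined for a zero-variance sample")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    ss_between: float
    ss_total: float
    df_between: int
    df_within: int

    @property
    def ss_within(self) -> float:
        return self.ss_total - self.ss_between


def anova_oneway(groups: Sequence) -> AnovaResult:
    """Classical equal-variance one-way ANOVA with explicit sums of squares."""
    arrays = _as_groups(groups)
    allx = np.concatenate(arrays)
    grand = allx.mean()
    ss_total = float(((allx - grand) ** 2).sum())
    if ss_total <= 0:
        raise StatisticsError("ANOVA undefined: all observations are equal (SS_total = 0)")
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    df_between = len(arrays) - 1
    df_within = len(allx) - len(arrays)
    if df_within < 1:
        raise StatisticsError("ANOVA needs residual degrees of freedom >= 1")
    ms_between = ss_between / df_between
    ms_within = (ss_total - ss_between) / df_within
    if ms_within <= 0:
        raise StatisticsError("ANOVA undefined: zero within-group variance")
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, ss_between, ss_total, df_between, df_within)


def tukey_hsd(groups: Sequence) -> dict[tuple[int, int], float]:
    """Tukey(-Kramer) studentized-range pairwise adjusted p-values.

    Unequal group sizes use the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``. Returns ``{(i, j): p}``.
    """
    arrays = _as_groups(groups)
    res = anova_oneway(arrays)
    ms_within = res.ss_within / res.df_within
    k = len(arrays)
    out = {}
    for i, j in combinations(range(k), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        se = math.sqrt(ms_within / 2.0 * (1.0 / ni + 1.0 / nj))
        q = abs(arrays[i].mean() - arrays[j].mean()) / se
        out[(i, j)] = float(sps.studentized_range.sf(q, k, res.df_within))
    return out


def eta_squared(ss_between: float, ss_total: float) -> tuple[float, str]:
    """Effect size eta^2 = SS_between / SS_total with its benchmark label."""
    if ss_total <= 0:
        raise StatisticsError("eta squared undefined for SS_total <= 0")
    value = ss_between / ss_total
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise StatisticsError(f"eta squared out of [0, 1]: {value}")
    value = min(value, 1.0)
    return float(value), effect_size_label(value, ETA_SQUARED_BENCHMARKS)


def effect_size_label(value: float, benchmarks) -> str:
    for label, threshold in benchmarks:
        if abs(value) >= threshold:
            return label
    return "negligible"


def welch_anova(groups: Sequence) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA. Returns ``(F, p)``.

    Weights ``w_i = n_i / s_i^2``; the denominator degrees of freedom follow
    the Welch-Satterthwaite approximation.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n = np.array([len(a) for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    if (v <= 0).any():
        raise StatisticsError("Welch ANOVA undefined with zero within-group variance")
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = num / den
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(sps.f.sf(f, k - 1, df2))
    return float(f), p


def games_howell(groups: Sequence) -> dict[tuple[int, int], float]:
    """Games-Howell pairwise adjusted p-values (unequal variances).

    Per pair: Welch t with Welch-Satterthwaite df, referred to the
    studentized range via ``q = t * sqrt(2)``. Returns ``{(i, j): p}``.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n = np.array([len(a) for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    if (v <= 0).any():
        raise StatisticsError("Games-Howell undefined with zero within-group variance")
    out = {}
    for i, j in combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        t = abs(m[i] - m[j]) / math.sqrt(se2)
        df = se2**2 / (
            (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
        )
        q = t * math.sqrt(2.0)
        out[(i, j)] = float(sps.studentized_range.sf(q, k, df))
    return out


def hedges_g(group_a, group_b) -> float:
    """Hedges' g: pooled-SD standardized mean difference with the small-sample
    correction ``J = 1 - 3 / (4(n_a + n_b) - 9)``."""
    a, b = _as_groups([group_a, group_b])
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise StatisticsError("Hedges g undefined with zero pooled variance")
    d = (a.mean() - b.mean()) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d * j)


# --------------------------------------------------------------------------
# Multivariate per-particle tests


def hotelling_t2_two_sample(coords_a, coords_b) -> tuple[float, float, float]:
    """Two-sample Hotelling's T^2 for (n, p) samples (p = 3 coordinates here).

    ``T2 = n_a n_b / (n_a + n_b) * d' S_pooled^-1 d``;
    ``F = T2 (n_a + n_b - p - 1) / (p (n_a + n_b - 2))`` with p-value from
    ``F(p, n_a + n_b - p - 1)``. Returns ``(T2, F, p_value)``.
    Raises :class:`StatisticsError` when the pooled covariance is singular.
    """
    A = np.atleast_2d(np.asarray(coords_a, dtype=float))
    B = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("samples must share dimensionality")
    na, nb, p = len(A), len(B), A.shape[1]
    if na + nb < p + 2:
        raise StatisticsError(
            f"Hotelling T2 needs n_a + n_b >= {p + 2} for p = {p}, got {na + nb}"
        )
    d = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A.T, ddof=1) if na > 1 else np.zeros((p, p))
    Sb = np.cov(B.T, ddof=1) if nb > 1 else np.zeros((p, p))
    S = ((na - 1) * np.atleast_2d(Sa) + (nb - 1) * np.atleast_2d(Sb)) / (na + nb - 2)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise StatisticsError(f"singular pooled covariance: {exc}") from exc
    if not np.isfinite(sol).all() or np.linalg.cond(S) > 1e12:
        raise StatisticsError("singular (ill-conditioned) pooled covariance")
    t2 = float(na * nb / (na + nb) * d @ sol)
    df2 = na + nb - p - 1
    f = t2 * df2 / (p * (na + nb - 2))
    pval = float(sps.f.sf(f, p, df2))
    return t2, float(f), pval


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(adjusted_p, significant_mask)`` with the mask at level
    ``alpha``. Adjusted p-values are monotone non-decreasing in rank.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise StatisticsError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


PARTICLE_CLASSES = ("none", "alignment_only", "shape_only", "alignment_and_shape")


@dataclass
class ParticleSignificanceMap:
    """Per-particle shape-vs-alignment classification for one group pair.

    ``classes`` holds one of :data:`PARTICLE_CLASSES` per particle.
    A particle significant in the world frame involves an *alignment*
    difference; significant in the local frame involves a *shape*
    difference; both frames -> alignment_and_shape. Percentages are class
    counts over the total particle count.
    """

    comparison: tuple[str, str]
    classes: np.ndarray
    p_world: np.ndarray
    p_world_adj: np.ndarray
    p_local: np.ndarray
    p_local_adj: np.ndarray
    alpha: float
    particle_bones: tuple[str, ...] = ()
    n_singular: int = 0

    @property
    def percentages(self) -> dict[str, float]:
        n = len(self.classes)
        return {
            cls: 100.0 * float((self.classes == cls).sum()) / n
            for cls in PARTICLE_CLASSES
        }

    @property
    def percent_significant(self) -> float:
        return 100.0 - self.percentages["none"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "particle": np.arange(len(self.classes)),
                "class": self.classes,
                "p_world": self.p_world,
                "p_world_adj": self.p_world_adj,
                "p_local": self.p_local,
                "p_local_adj": self.p_local_adj,
            }
        )
        if self.particle_bones:
            df.insert(1, "bone", list(self.particle_bones))
        return df


def _per_particle_pvalues(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, int]:
    n_particles = xa.shape[1]
    pvals = np.ones(n_particles)
    n_singular = 0
    for k in range(n_particles):
        try:
            _, _, pvals[k] = hotelling_t2_two_sample(xa[:, k], xb[:, k])
        except StatisticsError:
            pvals[k] = np.nan
            n_singular += 1
    return pvals, n_singular


def particle_significance_map(
    world_a,
    world_b,
    local_a,
    local_b,
    alpha: float = 0.05,
    comparison: tuple[str, str] = ("group_a", "group_b"),
    particle_bones: Sequence[str] = (),
) -> ParticleSignificanceMap:
    """Per-particle Hotelling's T2 maps in both frames with BH correction.

    Inputs are ``(n_subjects, n_particles, 3)`` arrays for each group in the
    world and local frames. FDR correction is applied separately within each
    frame across all particles. Particles with singular pooled covariance
    are logged and classified ``none`` rather than aborting the map.
    """
    arrays = [np.asarray(a, dtype=float) for a in (world_a, world_b, local_a, local_b)]
    shapes = {a.shape[1:] for a in arrays}
    if len(shapes) != 1:
        raise StatisticsError(f"particle layouts differ between frames/groups: {shapes}")
    wa, wb, la, lb = arrays
    p_world, sing_w = _per_particle_pvalues(wa, wb)
    p_local, sing_l = _per_particle_pvalues(la, lb)
    n_singular = sing_w + sing_l
    if n_singular:
        logger.warning(
            "%d particle tests had singular pooled covariance; classified 'none'",
            n_singular,
        )

    def _mask(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        adj = np.full_like(pvals, np.nan)
        mask = np.zeros(len(pvals), dtype=bool)
        valid = np.isfinite(pvals)
        if valid.any():
            adj[valid], mask[valid] = fdr_bh(pvals[valid], alpha=alpha)
        return adj, mask

    adj_w, sig_w = _mask(p_world)
    adj_l, sig_l = _mask(p_local)
    classes = np.full(len(p_world), "none", dtype=object)
    classes[sig_w & ~sig_l] = "alignment_only"
    classes[~sig_w & sig_l] = "shape_only"
    classes[sig_w & sig_l] = "alignment_and_shape"
    return ParticleSignificanceMap(
        comparison=tuple(comparison),
        classes=classes.astype(str),
        p_world=p_world,
        p_world_adj=adj_w,
        p_local=p_local,
        p_local_adj=adj_l,
        alpha=alpha,
        particle_bones=tuple(particle_bones),
        n_singular=n_singular,
    )


# --------------------------------------------------------------------------
# Mode-shape reconstruction


def reconstruct_mode_shape(
    model: ShapeModePCA, mode: int, sd_multiple: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean shape displaced along one mode by ``sd_multiple`` standard
    deviations.

    Returns ``(configuration, distances)`` where configuration is (p, 3) and
    distances is the per-particle Euclidean displacement from the mean (same
    units as the input coordinates).
    """
    if not 0 <= mode < model.n_modes_:
        raise IndexError(f"mode {mode} out of range [0, {model.n_modes_})")
    if abs(sd_multiple) > 3:
        raise ValueError("|sd_multiple| must be <= 3")
    vec = model.mean_ + sd_multiple * math.sqrt(
        model.explained_variance_[mode]
    ) * model.components_[mode]
    config = vec.reshape(-1, 3)
    mean_config = model.mean_.reshape(-1, 3)
    distances = np.linalg.norm(config - mean_config, axis=1)
    return config, distances
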