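"""Statistical battery: every statistic checked against an independent
oracle (closed form, permutation test, or a reference implementation)."""

import numpy as np
import pytest
from scipy import stats as sps

from footssm.errors import StatisticsError
from footssm.stats import (
    ShapeModePCA,
    anova_oneway,
    eta_squared,
    fdr_bh,
    games_howell,
    hedges_g,
    hotelling_t2_two_sample,
    ks_normality,
    parallel_analysis,
    particle_significance_map,
    reconstruct_mode_shape,
    tukey_hsd,
    welch_anova,
)


# --------------------------------------------------------------------------
# PCA


class TestShapeModePCA:
    def test_rank_one_data_single_mode(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=20)
        X = np.outer(rng.normal(size=10), direction)
        pca = ShapeModePCA().fit(X)
        assert pca.percent_variance_[0] == pytest.approx(100.0, abs=1e-9)
        assert pca.n_modes_ == 1

    def test_isotropic_gaussian_splits_variance_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 3))
        pca = ShapeModePCA().fit(X)
        for pct in pca.percent_variance_:
            assert pct == pytest.approx(100 / 3, abs=2.0)

    def test_model_invariants(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 60)) * np.linspace(3, 0.1, 60)
        pca = ShapeModePCA().fit(X)
        # eigenvalues descending and non-negative
        assert (np.diff(pca.explained_variance_) <= 1e-12).all()
        assert (pca.explained_variance_ >= 0).all()
        # modes orthonormal within 1e-9
        G = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(G, np.eye(pca.n_modes_), atol=1e-9)
        # percent variance sums to 100
        assert pca.percent_variance_.sum() == pytest.approx(100.0, abs=1e-6)
        # score variance equals eigenvalue
        np.testing.assert_allclose(
            pca.scores_.var(axis=0, ddof=1), pca.explained_variance_, atol=1e-9
        )
        # reconstruction reproduces the input
        np.testing.assert_allclose(
            pca.inverse_transform(pca.scores_), X, atol=1e-6
        )

    def test_agrees_with_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 12))
        mine = ShapeModePCA().fit(X)
        ref = PCA().fit(X)
        np.testing.assert_allclose(
            mine.explained_variance_, ref.explained_variance_[: mine.n_modes_], atol=1e-9
        )
        for k in range(mine.n_modes_):
            dot = abs(mine.components_[k] @ ref.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(StatisticsError, match=">= 3"):
            ShapeModePCA().fit(np.zeros((2, 5)))


# --------------------------------------------------------------------------
# Parallel analysis


class TestParallelAnalysis:
    def test_pure_noise_retains_at_most_one(self):
        """Null calibration: i.i.d. noise retains <= 1 mode in >= 95% of
        replicate runs."""
        rng = np.random.default_rng(4)
        hits = 0
        runs = 50
        for r in range(runs):
            X = rng.normal(size=(80, 300))
            k = parallel_analysis(X, n_permutations=120, seed=r)
            hits += k <= 1
        assert hits / runs >= 0.95

    def test_three_planted_factors_detected(self):
        rng = np.random.default_rng(5)
        n, p = 80, 200
        loadings = rng.normal(size=(3, p))
        factors = rng.normal(size=(n, 3)) * 10.0
        X = factors @ loadings + rng.normal(size=(n, p))
        assert parallel_analysis(X, n_permutations=200, seed=0) == 3

    def test_zero_matrix_retains_nothing(self):
        assert parallel_analysis(np.zeros((10, 5)), n_permutations=100, seed=0) == 0

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError, match="n_permutations"):
            parallel_analysis(np.zeros((10, 5)), n_permutations=10)


# --------------------------------------------------------------------------
# KS normality


class TestKSNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(6).normal(size=1000)
        stat, p = ks_normality(x)
        assert 0 <= stat <= 1
        assert p > 0.05

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(7).uniform(size=1000)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_lilliefors_variant_is_stricter(self):
        x = np.random.default_rng(8).normal(size=200)
        _, p_plain = ks_normality(x)
        _, p_lf = ks_normality(x, lilliefors=True)
        assert p_lf <= p_plain + 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(StatisticsError, match=">= 5"):
            ks_normality([1.0, 2.0])
        with pytest.raises(StatisticsError, match="zero-variance"):
            ks_normality(np.ones(10))


# --------------------------------------------------------------------------
# ANOVA / Tukey / eta squared


class TestAnova:
    def test_all_equal_observations_error(self):
        with pytest.raises(StatisticsError, match="SS_total"):
            anova_oneway([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        res = anova_oneway([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t**2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_equal_group_means_give_zero_f(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_against_scipy_f_oneway(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1.3, n) for m, n in ((0, 12), (0.4, 9), (1.0, 15))]
        res = anova_oneway(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)


class TestTukey:
    def test_two_group_case_equals_pooled_t(self):
        """q = t * sqrt(2) identity: with two groups the Tukey p equals the
        pooled t-test p within 1e-6."""
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 14), rng.normal(0.8, 1, 10)
        p_tukey = tukey_hsd([a, b])[(0, 1)]
        _, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_extreme_separation(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(100, 1, 10)]
        p = tukey_hsd(groups)
        assert p[(0, 2)] < 1e-6 and p[(1, 2)] < 1e-6
        assert p[(0, 1)] > 0.05

    def test_against_statsmodels_unequal_n(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(13)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 28), (0.5, 2, 29), (0.2, 1.5, 23))]
        mine = tukey_hsd(groups)
        y = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], [28, 29, 23])
        ref = pairwise_tukeyhsd(y, labels).pvalues  # pairs in order (0,1),(0,2),(1,2)
        np.testing.assert_allclose(
            [mine[(0, 1)], mine[(0, 2)], mine[(1, 2)]], ref, atol=1e-8
        )

    def test_familywise_error_rate_calibrated(self):
        """Simulation oracle: under the complete null the probability of any
        significant pair stays within the binomial 95% CI of alpha=0.05."""
        rng = np.random.default_rng(14)
        n_sims = 1000
        hits = 0
        for _ in range(n_sims):
            groups = [rng.normal(size=12) for _ in range(3)]
            hits += any(p < 0.05 for p in tukey_hsd(groups).values())
        rate = hits / n_sims
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert 0.05 - half <= rate <= 0.05 + half


class TestEtaSquared:
    def test_closed_forms_and_labels(self):
        assert eta_squared(5.0, 5.0) == (1.0, "large")
        assert eta_squared(0.0, 5.0) == (0.0, "negligible")
        value, label = eta_squared(0.09, 1.0)
        assert value == pytest.approx(0.09) and label == "medium"
        assert eta_squared(0.30, 1.0)[1] == "large"
        assert eta_squared(0.02, 1.0)[1] == "small"

    def test_zero_total_rejected(self):
        with pytest.raises(StatisticsError):
            eta_squared(0.0, 0.0)


# --------------------------------------------------------------------------
# Welch / Games-Howell / Hedges


class TestWelch:
    def test_two_groups_equal_welch_t(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 20), rng.normal(0.6, 2.5, 14)
        f, p = welch_anova([a, b])
        t, p_t = sps.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(p_t, abs=1e-9)
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_close_to_classical_f_under_homoscedasticity(self):
        """With equal in-sample variances (n = 50/group) Welch's F matches
        the classical F within 2% (the residual is the Welch denominator
        correction, ~0.7% here); with merely equal population variances the
        agreement is looser but bounded."""
        rng = np.random.default_rng(16)
        groups = [rng.normal(m, 1.0, 50) for m in (0, 0.3, 0.6)]
        standardized = [
            (g - g.mean()) / g.std(ddof=1) + g.mean() for g in groups
        ]
        fw, _ = welch_anova(standardized)
        fc = anova_oneway(standardized).f
        assert fw == pytest.approx(fc, rel=0.02)
        fw2, _ = welch_anova(groups)
        fc2 = anova_oneway(groups).f
        assert fw2 == pytest.approx(fc2, rel=0.25)

    def test_type_one_error_calibrated(self):
        """>= 93% of complete-null simulations keep p > 0.05."""
        rng = np.random.default_rng(17)
        n_sims = 1000
        keep = sum(
            welch_anova([rng.normal(size=15) for _ in range(3)])[1] > 0.05
            for _ in range(n_sims)
        )
        assert keep / n_sims >= 0.93

    def test_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(18)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 28), (0.5, 2, 29), (0.2, 1.5, 23))]
        f, p = welch_anova(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(list("abc"), [28, 29, 23])}
        )
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticsError):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])


class TestGamesHowell:
    def test_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(19)
        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 28), (0.7, 2, 29), (0.2, 1.5, 23))]
        mine = games_howell(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(list("abc"), [28, 29, 23])}
        )
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        np.testing.assert_allclose(
            [mine[(0, 1)], mine[(0, 2)], mine[(1, 2)]],
            ref["pval"].to_numpy(),
            atol=1e-6,
        )

    def test_two_group_reduces_to_welch(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 18)
        p_gh = games_howell([a, b])[(0, 1)]
        _, p_w = sps.ttest_ind(a, b, equal_var=False)
        assert p_gh == pytest.approx(p_w, abs=1e-9)


class TestHedgesG:
    def test_equal_means_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert hedges_g(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_correction_closed_form(self):
        # n_a = n_b = 2 -> J = 1 - 3/7
        a, b = np.array([0.0, 1.0]), np.array([1.0, 2.0])
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d = (a.mean() - b.mean()) / sp
        assert hedges_g(a, b) == pytest.approx(d * (1 - 3 / 7), abs=1e-12)

    def test_correction_factor_at_n40(self):
        """Cohen's d of 1.0 with n = 20 + 20 shrinks by J = 1 - 3/151."""
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        # construct exact d = 1 by shifting b by one pooled SD
        sp = np.sqrt(((19 * a.var(ddof=1)) + 19 * b.var(ddof=1)) / 38)
        b = b - b.mean() + a.mean() - sp
        assert hedges_g(a, b) == pytest.approx(1 - 3 / 151, abs=1e-9)

    def test_against_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(22)
        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1.4, 18)
        assert hedges_g(a, b) == pytest.approx(
            pg.compute_effsize(a, b, eftype="hedges"), abs=1e-12
        )

    def test_zero_pooled_variance(self):
        with pytest.raises(StatisticsError):
            hedges_g([1.0, 1.0], [1.0, 1.0])


# --------------------------------------------------------------------------
# Hotelling T2 / FDR / significance map


class TestHotelling:
    def test_identical_samples(self):
        x = np.random.default_rng(23).normal(size=(10, 3))
        t2, f, p = hotelling_t2_two_sample(x, x)
        assert t2 == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_one_dimension_equals_squared_t(self):
        rng = np.random.default_rng(24)
        a, b = rng.normal(0, 1, (12, 1)), rng.normal(1, 1, (9, 1))
        t2, _, p = hotelling_t2_two_sample(a, b)
        t, p_t = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert t2 == pytest.approx(t**2, abs=1e-9)
        assert p == pytest.approx(p_t, abs=1e-12)

    def test_against_permutation_oracle(self):
        """Parametric p within 0.02 of a 10,000-draw permutation p."""
        rng = np.random.default_rng(25)
        a = rng.normal(0, 1, (15, 3))
        b = rng.normal(0.55, 1, (12, 3))
        t2_obs, _, p_param = hotelling_t2_two_sample(a, b)
        pooled = np.vstack([a, b])
        n_perm = 10000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled))
            t2_p, _, _ = hotelling_t2_two_sample(pooled[perm[:15]], pooled[perm[15:]])
            count += t2_p >= t2_obs
        p_perm = count / n_perm
        assert abs(p_param - p_perm) <= 0.02

    def test_singular_covariance_rejected(self):
        a = np.zeros((5, 3))
        a[:, 0] = np.arange(5)
        b = a + 0.1
        with pytest.raises(StatisticsError, match="singular"):
            hotelling_t2_two_sample(a, b)

    def test_too_small_samples_rejected(self):
        rng = np.random.default_rng(26)
        with pytest.raises(StatisticsError):
            hotelling_t2_two_sample(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestFdrBH:
    def test_hand_computed_step_up(self):
        p_adj, sig = fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert sig.all()

    def test_all_ones_nothing_significant(self):
        _, sig = fdr_bh(np.ones(10), alpha=0.05)
        assert not sig.any()

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(27)
        p = rng.uniform(size=50)
        p_adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(StatisticsError):
            fdr_bh([0.5, 1.5])
        with pytest.raises(StatisticsError):
            fdr_bh([0.5, -0.1])

    def test_null_false_discovery_rate_bounded(self):
        """BH guarantee: expected false-discovery proportion <= alpha under
        independent uniform nulls."""
        rng = np.random.default_rng(28)
        fdp = []
        for _ in range(500):
            p = rng.uniform(size=50)
            _, sig = fdr_bh(p, alpha=0.05)
            fdp.append(sig.mean() if sig.any() else 0.0)
        assert np.mean(fdp) <= 0.05 + 0.01


class TestSignificanceMap:
    def _two_groups(self, ma_b=0.0, n=8, noise=0.1, seed=0):
        from footssm.correspondence import (
            extract_particles,
            flatten,
            generalized_procrustes,
            per_bone_local_frames,
        )
        from footssm.synthetic import build_parametric_foot

        feet = []
        for g, ma in (("a", 0.0), ("b", ma_b)):
            for k in range(n):
                feet.append(
                    build_parametric_foot(
                        ma, 5, 20, 1.0, "right", noise, seed=seed * 1000 + len(feet),
                        group=g, subject_id=f"{g}{k}",
                    )
                )
        systems = [extract_particles(f, 8) for f in feet]
        systems, _ = generalized_procrustes(systems)
        systems = per_bone_local_frames(systems)
        world = flatten(systems, "world").as_points()
        local = flatten(systems, "local").as_points()
        groups = np.array([s.group for s in systems])
        mat = flatten(systems, "world")
        bones = [mat.particle_label(k)[0] for k in range(mat.n_particles)]
        return world, local, groups, bones

    def test_identical_groups_all_none(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=(10, 20, 3))
        smap = particle_significance_map(x, x, x, x)
        assert smap.percentages["none"] == 100.0

    def test_null_relabeling_calibrated(self):
        """Random split of one homogeneous cohort: flagged fraction <= 7%
        in each frame, averaged across seeds."""
        world, local, groups, bones = self._two_groups(ma_b=0.0, n=10, seed=3)
        rng = np.random.default_rng(30)
        rates = []
        for _ in range(8):
            perm = rng.permutation(len(groups))
            half = len(groups) // 2
            a, b = perm[:half], perm[half:]
            smap = particle_significance_map(
                world[a], world[b], local[a], local[b]
            )
            rates.append(smap.percent_significant)
        assert np.mean(rates) <= 7.0

    def test_planted_pose_shift_is_alignment_only(self):
        """Rigid first-ray pose shift with identical bone shapes: flagged
        metatarsal-1 particles are alignment_only; shape_only stays ~0."""
        world, local, groups, bones = self._two_groups(ma_b=10.0, n=10, noise=0.05, seed=4)
        smap = particle_significance_map(
            world[groups == "a"],
            world[groups == "b"],
            local[groups == "a"],
            local[groups == "b"],
            particle_bones=bones,
        )
        mt1 = np.array([b == "metatarsal_1" for b in bones])
        mt1_classes = smap.classes[mt1]
        assert (mt1_classes == "alignment_only").mean() > 0.8
        assert smap.percentages["shape_only"] <= 1.0

    def test_layout_mismatch_rejected(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=(8, 10, 3))
        y = rng.normal(size=(8, 12, 3))
        with pytest.raises(StatisticsError, match="layout"):
            particle_significance_map(x, x, y, y)

    def test_percentages_partition(self):
        world, local, groups, _ = self._two_groups(ma_b=6.0, n=8, seed=5)
        smap = particle_significance_map(
            world[groups == "a"], world[groups == "b"],
            local[groups == "a"], local[groups == "b"],
        )
        assert sum(smap.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        df = smap.to_frame()
        assert len(df) == len(smap.classes)


class TestReconstructModeShape:
    def _model(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(20, 30)) * np.linspace(4, 0.2, 30)
        return ShapeModePCA().fit(X)

    def test_zero_multiple_is_mean(self):
        model = self._model()
        config, dist = reconstruct_mode_shape(model, 0, 0.0)
        np.testing.assert_allclose(config.reshape(-1), model.mean_, atol=1e-12)
        np.testing.assert_allclose(dist, 0, atol=1e-12)

    def test_symmetric_displacement(self):
        model = self._model()
        _, d_plus = reconstruct_mode_shape(model, 1, 2.0)
        _, d_minus = reconstruct_mode_shape(model, 1, -2.0)
        np.testing.assert_allclose(d_plus, d_minus, atol=1e-9)

    def test_projection_identity(self):
        """The +1 sigma reconstruction projects back to a score of
        sqrt(eigenvalue) on that mode and ~0 elsewhere."""
        model = self._model()
        config, _ = reconstruct_mode_shape(model, 2, 1.0)
        scores = model.transform(config.reshape(1, -1))[0]
        lam = model.explained_variance_[2]
        assert scores[2] == pytest.approx(np.sqrt(lam), abs=1e-6)
        others = np.delete(scores, 2)
        np.testing.assert_allclose(others, 0, atol=1e-6)

    def test_bounds(self):
        model = self._model()
        with pytest.raises(IndexError):
            reconstruct_mode_shape(model, 99, 1.0)
        with pytest.raises(ValueError):
            reconstruct_mode_shape(model, 0, 3.5)
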