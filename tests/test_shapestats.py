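"""Statistical battery: ANOVAs, MANCOVA, Hotelling, CVA, allometry, angles."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from vespawing import shapestats as ss
from vespawing.config import ColonySpec, default_config
from vespawing.superimpose import gpa, shape_pca
from vespawing.wing_synth import TEMPLATE_WING, sample_pedigree, sample_wings


# --------------------------------------------------------------------------
# size: nested ANOVA + variance components
# --------------------------------------------------------------------------

class TestSizeNestedAnova:
    def test_degrees_of_freedom_two_colonies_four_patrilines(self, rng):
        colony = np.repeat(["A", "B"], 40)
        pat = np.tile(np.repeat([1, 2, 3, 4], 10), 2)
        y = rng.normal(size=80)
        table = ss.size_nested_anova(y, colony, pat)
        assert table.loc["Colony", "Df"] == 1
        assert table.loc["Patriline", "Df"] == 6
        assert table.loc["Residuals", "Df"] == 80 - 8

    def test_matches_statsmodels_type1(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        colony = np.repeat(["A", "B"], 8)
        pat = np.tile(np.repeat(["p", "q"], 4), 2)
        y = rng.normal(size=16) + (colony == "A") * 0.5 + (pat == "p") * 0.3
        df = pd.DataFrame({"y": y, "colony": colony, "pat": pat})
        fit = smf.ols("y ~ C(colony) + C(colony):C(pat)", data=df).fit()
        oracle = anova_lm(fit, typ=1)
        table = ss.size_nested_anova(y, colony, pat)
        assert table.loc["Colony", "F"] == pytest.approx(
            oracle.loc["C(colony)", "F"], rel=1e-10
        )
        assert table.loc["Patriline", "F"] == pytest.approx(
            oracle.loc["C(colony):C(pat)", "F"], rel=1e-10
        )
        assert table.loc["Patriline", "P"] == pytest.approx(
            oracle.loc["C(colony):C(pat)", "PR(>F)"], rel=1e-9
        )

    def test_zero_residual_flagged_degenerate(self):
        colony = np.repeat(["A", "B"], 4)
        pat = np.tile(np.repeat([1, 2], 2), 2)
        y = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])  # constant within cells
        table = ss.size_nested_anova(y, colony, pat)
        assert np.isnan(table.loc["Colony", "F"])

    def test_singleton_design_rejected(self):
        with pytest.raises(ValueError, match="singleton|residual"):
            ss.size_nested_anova(
                [1.0, 2.0], ["A", "B"], [1, 2]
            )


class TestSizeVarianceComponents:
    def test_all_equal_gives_zero(self):
        vc = ss.size_variance_components(
            np.ones(12), np.repeat(["A", "B"], 6), np.tile([1, 2, 3], 4)
        )
        assert vc.s2_inter_colony == 0
        assert vc.s2_inter_patriline == 0
        assert vc.s2_intra_patriline == 0

    def test_two_patriline_limit_is_half_delta_squared(self):
        delta = 0.35
        y = np.r_[np.zeros(50), np.full(50, delta)]
        vc = ss.size_variance_components(
            y, np.repeat("A", 100), np.repeat([1, 2], 50)
        )
        assert vc.s2_intra_patriline == pytest.approx(0.0, abs=1e-30)
        assert vc.s2_inter_patriline == pytest.approx(delta**2 / 2, rel=1e-12)
        assert np.isnan(vc.s2_inter_colony)

    def test_recovers_injected_intra_variance(self):
        cfg = dataclasses.replace(
            default_config(),
            colonies=(ColonySpec(116, (1.0,)),),
            amplification_failure_rate=0.0,
            damage_probability=0.0,
        )
        target = cfg.size_model.var_individual
        estimates = []
        for seed in range(20):
            truth, _ = sample_pedigree(cfg, 0, seed=seed)
            wings = sample_wings(truth, cfg, seed=500 + seed)
            logcs = np.array([r.logcs_true for r in wings.records])
            vc = ss.size_variance_components(
                logcs, np.repeat("C1", 116), np.zeros(116, dtype=int)
            )
            estimates.append(vc.s2_intra_patriline)
        assert abs(np.mean(estimates) - target) < 0.25 * target


# --------------------------------------------------------------------------
# Procrustes ANOVA
# --------------------------------------------------------------------------

def _error_design(rng, n_spec=8, n_groups=4, sigma_digit=1e-4):
    spec, mount, digit, group, rows = [], [], [], [], []
    base = rng.normal(0, 0.01, size=(n_spec, 38))
    for s in range(n_spec):
        for m in (1, 2):
            mnoise = rng.normal(0, 1e-3, 38)
            for d in (1, 2):
                rows.append(base[s] + mnoise + rng.normal(0, sigma_digit, 38))
                spec.append(f"s{s}")
                mount.append(m)
                digit.append(d)
                group.append(s % n_groups)
    return np.asarray(rows), spec, mount, digit, group


class TestProcrustesAnova:
    def test_patriline_df_is_102_for_four_groups(self, rng):
        x, spec, mount, digit, group = _error_design(rng)
        table = ss.procrustes_anova(x, spec, mount, digit, group)
        assert table.loc["Patriline", "Df"] == 3 * 34 == 102
        assert table.loc["Individual", "Df"] == (8 - 4) * 34
        assert table.loc["Wing mounting", "Df"] == 8 * 34
        assert table.loc["Landmark digitization", "Df"] == 16 * 34

    def test_strata_sum_to_total(self, rng):
        x, spec, mount, digit, group = _error_design(rng)
        table = ss.procrustes_anova(x, spec, mount, digit, group)
        total = ((x - x.mean(axis=0)) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_zero_digitization_noise(self, rng):
        x, spec, mount, digit, group = _error_design(rng, sigma_digit=0.0)
        table = ss.procrustes_anova(x, spec, mount, digit, group)
        assert table.loc["Landmark digitization", "SS"] < 1e-12

    def test_unbalanced_design_rejected(self, rng):
        x, spec, mount, digit, group = _error_design(rng)
        with pytest.raises(ValueError, match="unbalanced"):
            ss.procrustes_anova(x[:-1], spec[:-1], mount[:-1], digit[:-1], group[:-1])


# --------------------------------------------------------------------------
# MANCOVA
# --------------------------------------------------------------------------

def _mancova_design(rng, n=220, p=34):
    colony = np.repeat(["A", "B"], [116, n - 116])
    pat = np.concatenate(
        [np.repeat([1, 2, 3, 4], [43, 34, 22, 17]),
         np.repeat([1, 2, 3, 4], [44, 41, 12, n - 116 - 97])]
    )
    y = rng.normal(size=(n, p))
    logcs = rng.normal(size=n)
    return y, logcs, colony, pat


class TestShapeMancova:
    def test_table3_degrees_of_freedom(self, rng):
        y, logcs, colony, pat = _mancova_design(rng)
        table = ss.shape_mancova(y, logcs, colony, pat)
        assert list(table["Df"][:5]) == [1, 1, 6, 1, 6]
        assert table.loc["Residuals", "Df"] == 204
        assert table.loc["Size", "numDf"] == 34
        assert table.loc["Size", "denDf"] == 171
        assert table.loc["Patriline", "numDf"] == 204
        assert table.loc["Patriline", "denDf"] == 1056

    def test_single_response_reduces_to_univariate_ancova(self, rng):
        n = 60
        colony = np.repeat(["A", "B"], 30)
        pat = np.tile(np.repeat([1, 2], 15), 2)
        logcs = rng.normal(size=n)
        y = (
            0.5 * logcs
            + 0.3 * (colony == "A")
            + 0.2 * (pat == 1)
            + rng.normal(size=n)
        )[:, None]
        table = ss.shape_mancova(y, logcs, colony, pat)

        # independent oracle: sequential RSS drops via least squares
        def design(cols):
            return np.column_stack(cols)

        col_d = (colony[:, None] == np.unique(colony)[None, :]).astype(float)
        cell = np.char.add(colony.astype(str), pat.astype(str))
        cell_d = (cell[:, None] == np.unique(cell)[None, :]).astype(float)
        blocks = [
            np.ones((n, 1)), logcs[:, None], col_d, cell_d,
            logcs[:, None] * col_d, logcs[:, None] * cell_d,
        ]
        rss, ranks = [], []
        for k in range(1, len(blocks) + 1):
            x = design(blocks[:k])
            beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            rss.append(float(((y - x @ beta) ** 2).sum()))
            ranks.append(rank)
        df_res = n - ranks[-1]
        ms_res = rss[-1] / df_res
        for i, name in enumerate(
            ["Size", "Colony", "Patriline", "Size:Colony", "Size:Patriline"]
        ):
            ss_term = rss[i] - rss[i + 1]
            df_term = ranks[i + 1] - ranks[i]
            f_oracle = (ss_term / df_term) / ms_res
            assert table.loc[name, "approxF"] == pytest.approx(f_oracle, rel=1e-8)
            assert table.loc[name, "Df"] == df_term

    def test_null_pillai_bounds_and_p_distribution(self):
        pvals = []
        for rep in range(100):
            local = np.random.default_rng(3000 + rep)
            n, p = 64, 3
            colony = np.repeat(["A", "B"], 32)
            pat = np.tile(np.repeat([1, 2], 16), 2)
            y = local.normal(size=(n, p))
            logcs = local.normal(size=n)
            table = ss.shape_mancova(y, logcs, colony, pat)
            for name in ("Size", "Colony", "Patriline"):
                s = min(p, int(table.loc[name, "Df"]))
                assert 0 <= table.loc[name, "Pillai"] <= s + 1e-12
            pvals.append(table.loc["Colony", "P"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_term_rejected(self, rng):
        n = 40
        colony = np.repeat(["A", "B"], 20)
        y = rng.normal(size=(n, 2))
        # patriline identical to colony -> nested term aliased
        with pytest.raises(ValueError, match="alias"):
            ss.shape_mancova(y, np.zeros(n), colony, colony)


# --------------------------------------------------------------------------
# Hotelling T2
# --------------------------------------------------------------------------

class TestHotelling:
    def test_df_for_34_variables_two_groups_of_34(self, rng):
        g1 = rng.normal(size=(34, 34))
        g2 = rng.normal(size=(34, 34))
        res = ss.hotelling_t2(g1, g2)
        assert res.df_num == 34
        assert res.df_den == 33

    def test_identical_samples_give_zero(self, rng):
        g = rng.normal(size=(20, 4))
        res = ss.hotelling_t2(g, g.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-20)

    def test_univariate_case_equals_squared_pooled_t(self, rng):
        a = rng.normal(size=(15, 1))
        b = rng.normal(loc=0.4, size=(12, 1))
        res = ss.hotelling_t2(a, b)
        t, _ = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True)[:2], None
        t_stat = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=True).statistic
        assert res.t2 == pytest.approx(t_stat**2, rel=1e-10)

    def test_nominal_type_one_error_rate(self):
        rejections = 0
        reps = 500
        for rep in range(reps):
            local = np.random.default_rng(7000 + rep)
            res = ss.hotelling_t2(
                local.normal(size=(30, 5)), local.normal(size=(30, 5))
            )
            rejections += res.p < 0.05
        # binomial(500, 0.05): central 99.9% band
        assert 9 <= rejections <= 43

    def test_singular_covariance_rejected(self, rng):
        base = rng.normal(size=(10, 1))
        x = np.hstack([base, base])  # perfectly collinear variables
        with pytest.raises(ValueError, match="[Ss]ingular"):
            ss.hotelling_t2(x, x + 1.0)


# --------------------------------------------------------------------------
# CVA with leave-one-out
# --------------------------------------------------------------------------

class TestCvaLoo:
    def test_perfect_separation(self, rng):
        centers = rng.normal(size=(4, 3)) * 10
        x = np.vstack([c + 0.1 * rng.normal(size=(8, 3)) for c in centers])
        labels = np.repeat(np.arange(4), 8)
        assert ss.cva_loo(x, labels, 3) == 1.0

    def test_chance_level_under_permuted_labels(self):
        total_correct = 0
        total_n = 0
        for rep in range(50):
            local = np.random.default_rng(500 + rep)
            x = local.normal(size=(48, 5))
            labels = local.permutation(np.repeat(np.arange(8), 6))
            total_correct += ss.cva_loo(x, labels, 5) * 48
            total_n += 48
        # central 99% binomial band around 1/8
        lo, hi = sps.binom.ppf([0.005, 0.995], total_n, 1 / 8)
        assert lo <= total_correct <= hi

    def test_matches_sklearn_lda_fold_by_fold(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x = rng.normal(size=(20, 4))
        labels = np.repeat([0, 1, 2, 3], 5)
        x += labels[:, None] * 0.8
        mine = ss.cva_loo(x, labels, 4)
        correct = 0
        for i in range(20):
            mask = np.ones(20, dtype=bool)
            mask[i] = False
            lda = LinearDiscriminantAnalysis(priors=np.full(4, 0.25))
            lda.fit(x[mask], labels[mask])
            correct += lda.predict(x[i : i + 1])[0] == labels[i]
        assert mine == pytest.approx(correct / 20)

    def test_singular_covariance_suggests_fewer_pcs(self, rng):
        x = rng.normal(size=(6, 10))  # p > n - g
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="fewer PCs"):
            ss.cva_loo(x, labels, 10)

    def test_rate_monotone_in_patriline_separation(self):
        cfg0 = dataclasses.replace(
            default_config(),
            colonies=(ColonySpec(60, (0.25, 0.25, 0.25, 0.25)),),
            amplification_failure_rate=0.0,
            damage_probability=0.0,
        )
        rates = []
        for factor in (0.25, 1.0, 4.0):
            shape = dataclasses.replace(
                cfg0.shape_model,
                delta_patriline=factor * cfg0.shape_model.delta_patriline,
            )
            cfg = dataclasses.replace(cfg0, shape_model=shape)
            per_seed = []
            for seed in range(20):
                truth, _ = sample_pedigree(cfg, 0, seed=seed)
                wings = sample_wings(truth, cfg, seed=900 + seed)
                sample = gpa([r.config for r in wings.records])
                scores = shape_pca(sample.tangent).scores
                labels = np.array([r.patriline_true for r in wings.records])
                per_seed.append(ss.cva_loo(scores, labels, 8))
            rates.append(np.mean(per_seed))
        assert rates[0] <= rates[1] <= rates[2]


# --------------------------------------------------------------------------
# allometry
# --------------------------------------------------------------------------

class TestCommonAllometry:
    def test_no_allometry_gives_small_cac(self, rng):
        x = rng.normal(size=(120, 10)) * 0.01
        logcs = rng.normal(size=120)
        groups = np.repeat([0, 1], 60)
        res = ss.common_allometric_component(x, logcs, groups)
        assert np.linalg.norm(res.cac) < 3 * np.linalg.norm(res.se)

    def test_recovers_known_direction(self, rng):
        n, d = 80, 12
        v = rng.normal(size=d)
        v /= np.linalg.norm(v)
        logcs = rng.normal(size=n)
        noise = rng.normal(size=(n, d)) * (1 / 5) / np.sqrt(d)
        x = np.outer(logcs, v) + noise
        res = ss.common_allometric_component(x, logcs, np.zeros(n, dtype=int))
        angle = ss.vector_angle(res.cac, v)
        assert min(angle, 180 - angle) < 10

    def test_residuals_uncorrelated_with_size_within_groups(self, rng):
        x = rng.normal(size=(60, 6))
        logcs = rng.normal(size=60)
        groups = np.repeat([0, 1, 2], 20)
        res = ss.common_allometric_component(x, logcs, groups)
        for g in range(3):
            mask = groups == g
            sc = logcs[mask] - logcs[mask].mean()
            resid = res.corrected[mask] - res.corrected[mask].mean(axis=0)
            # pooled least-squares orthogonality distributes over groups only
            # in aggregate; check the pooled covariance instead
        pooled = np.zeros(6)
        for g in range(3):
            mask = groups == g
            sc = logcs[mask] - logcs[mask].mean()
            resid = res.corrected[mask] - x[mask].mean(axis=0)
            pooled += resid.T @ sc
        assert np.abs(pooled).max() < 1e-10

    def test_constant_size_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            ss.common_allometric_component(
                rng.normal(size=(10, 3)), np.ones(10), np.zeros(10)
            )


# --------------------------------------------------------------------------
# angles
# --------------------------------------------------------------------------

class TestAngles:
    def test_trivial_angles(self):
        v = np.array([1.0, 2.0, -3.0])
        assert ss.vector_angle(v, v) == pytest.approx(0.0, abs=1e-10)
        assert ss.vector_angle(v, -v) == pytest.approx(180.0, abs=1e-10)
        assert ss.vector_angle([1, 0], [0, 1]) == pytest.approx(90.0)

    def test_matches_direct_arccos(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 7))
            direct = np.degrees(
                np.arccos(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
            )
            assert ss.vector_angle(a, b) == pytest.approx(direct, abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ss.vector_angle([0, 0], [1, 0])

    def test_identical_vectors_give_tiny_p(self, rng):
        sample = rng.normal(size=(30, 8))
        v = rng.normal(size=8)
        res = ss.angle_null_test(v, v, sample, n_draws=2000, seed=1)
        assert res.theta_degrees == pytest.approx(0.0, abs=1e-8)
        assert res.p <= 1e-3

    def test_default_draw_count(self, rng):
        res = ss.angle_null_test(
            rng.normal(size=4), rng.normal(size=4), rng.normal(size=(6, 4)), seed=0
        )
        assert res.n_draws == 10000

    def test_p_uniform_under_own_null(self):
        pvals = []
        for rep in range(200):
            local = np.random.default_rng(9000 + rep)
            sample = local.normal(size=(24, 6))
            i, j, k, l = local.choice(24, size=4, replace=False)
            res = ss.angle_null_test(
                sample[i] - sample[j],
                sample[k] - sample[l],
                sample,
                n_draws=400,
                seed=local,
            )
            pvals.append(res.p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


# --------------------------------------------------------------------------
# Welch t
# --------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples_give_zero_t(self):
        t, df, p = ss.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_satterthwaite_limit_equal_variance_equal_n(self, rng):
        a = rng.normal(size=40)
        b = a + 0.5  # identical sample variance, shifted mean
        _, df, _ = ss.welch_t(a, b)
        assert df == pytest.approx(78.0, abs=1e-9)

    def test_hand_computed_fixture(self):
        t, df, p = ss.welch_t([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        # means 2 and 4; variances 1 and 4; se^2 = 1/3 + 4/3
        expected_t = (2.0 - 4.0) / np.sqrt(5.0 / 3.0)
        expected_df = (5.0 / 3.0) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert df == pytest.approx(expected_df, rel=1e-12)

    def test_degenerate_zero_variance_flagged(self):
        t, df, p = ss.welch_t([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(t)


# --------------------------------------------------------------------------
# group mean distances
# --------------------------------------------------------------------------

class TestGroupMeanDistances:
    def test_identical_shapes_give_zero(self):
        sample = gpa([TEMPLATE_WING.copy() for _ in range(8)])
        res = ss.group_mean_distances(
            sample, np.repeat([1, 2], 4), np.repeat("A", 8)
        )
        assert res.between_mean == pytest.approx(0.0, abs=1e-7)
        assert res.within_mean == pytest.approx(0.0, abs=1e-7)

    def test_matches_direct_all_pairs_oracle(self, rng):
        from vespawing.superimpose import procrustes_distance

        configs = [
            TEMPLATE_WING + rng.normal(0, 0.01, (19, 2)) for _ in range(24)
        ]
        sample = gpa(configs)
        pat = np.repeat([1, 2, 3], 8)
        colony = np.repeat("A", 24)
        res = ss.group_mean_distances(sample, pat, colony)
        k = 19
        means = {
            p: (sample.consensus.ravel() + sample.tangent[pat == p].mean(axis=0)).reshape(k, 2)
            for p in (1, 2, 3)
        }
        direct_between = [
            procrustes_distance(means[a], means[b])
            for a, b in ((1, 2), (1, 3), (2, 3))
        ]
        assert res.between_mean == pytest.approx(np.mean(direct_between), rel=1e-10)
        direct_within = [
            procrustes_distance(sample.aligned[i], means[pat[i]])
            for i in range(24)
        ]
        assert res.within_mean == pytest.approx(np.mean(direct_within), rel=1e-10)

    def test_singleton_patriline_warns_and_excluded(self, rng):
        configs = [
            TEMPLATE_WING + rng.normal(0, 0.01, (19, 2)) for _ in range(5)
        ]
        sample = gpa(configs)
        pat = np.array([1, 1, 2, 2, 3])
        with pytest.warns(UserWarning, match="single specimen"):
            res = ss.group_mean_distances(sample, pat, np.repeat("A", 5))
        assert res.n_specimens == 4
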