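"""Statistical layer: partial Spearman, ANCOVA, t / Fisher tests, outlier rule."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nigrastar.cohort import default_cohort_spec, simulate_cohort
from nigrastar.stats import (
    COVARIATE_SETS,
    ancova_compare,
    build_correlation_table,
    build_group_table,
    detect_cholesterol_outliers,
    fisher_exact_2x2,
    spearman_partial,
    two_sample_t,
    two_sample_t_from_stats,
)


def matrix_inversion_partial(x, y, z):
    """Oracle: partial correlation from the 3x3 Spearman matrix."""
    r_xy = sps.spearmanr(x, y).statistic
    r_xz = sps.spearmanr(x, z).statistic
    r_yz = sps.spearmanr(y, z).statistic
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


class TestSpearmanPartial:
    def test_perfect_concordance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        res = spearman_partial(x, x.copy())
        assert res.rho == 1.0 and res.p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_discordance(self):
        x = np.arange(10.0)
        assert spearman_partial(x, -x).rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_matrix_inversion_oracle_one_covariate(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 8))
            res = spearman_partial(x, y, z[:, None])
            assert res.rho == pytest.approx(matrix_inversion_partial(x, y, z),
                                            abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 30))
        Z = rng.normal(size=(30, 3))
        a = spearman_partial(x, y, Z)
        b = spearman_partial(np.exp(x), y**3, Z)
        assert b.rho == pytest.approx(a.rho, abs=1e-12)
        assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_k0_equals_plain_spearman(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=(2, 41))
        res = spearman_partial(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert res.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic,
                                        abs=1e-12)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        n = 39
        df = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=["x", "y", "a", "b", "c"])
        res = spearman_partial(df["x"], df["y"], df[["a", "b", "c"]].values)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b", "c"],
                                    method="spearman")
        pcol = [c for c in ref.columns if c.startswith("p")][0]
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="k"):
            spearman_partial([1, 2, 3], [1, 2, 3], np.ones((3, 1)))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_partial(np.ones(10), np.arange(10.0))

    def test_collinear_covariates_rejected_with_names(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=(2, 20))
        z = rng.normal(size=20)
        Z = np.column_stack([z, 2 * z + 1])
        with pytest.raises(ValueError, match="cov2"):
            spearman_partial(x, y, Z, covariate_names=("cov1", "cov2"))


class TestAncova:
    def test_no_difference_when_outcomes_identical(self):
        y = np.tile(np.arange(10.0), 2)
        g = np.repeat(["a", "b"], 10)
        res = ancova_compare(y, g)
        assert res.adjusted_difference == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_group_effect(self):
        rng = np.random.default_rng(16)
        n = 10**4
        g = np.repeat(["control", "PD"], n)
        age = rng.normal(60, 8, 2 * n)
        y = 30 + 0.2 * age + np.where(g == "PD", 4.5, 0.0) + rng.normal(0, 3, 2 * n)
        res = ancova_compare(y, g, age[:, None], covariate_names=("age",))
        assert res.adjusted_difference == pytest.approx(4.5, abs=0.1)
        assert res.n_case == n and res.n_control == n

    def test_without_covariates_matches_pooled_t(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(0, 1, 25), rng.normal(0.4, 1, 30)
        res = ancova_compare(np.concatenate([x, y]),
                             np.repeat(["a", "b"], [25, 30]))
        t, p = two_sample_t(y, x)
        assert res.p == pytest.approx(p, abs=1e-6)
        assert res.adjusted_difference == pytest.approx(y.mean() - x.mean(),
                                                        abs=1e-9)

    def test_invariant_to_affine_covariate_rescaling(self):
        rng = np.random.default_rng(18)
        n = 60
        g = np.repeat(["a", "b"], n // 2)
        Z = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + Z @ [0.5, -0.3]
        a = ancova_compare(y, g, Z)
        b = ancova_compare(y, g, Z * [100.0, 0.01] + [5.0, -7.0])
        assert b.adjusted_difference == pytest.approx(a.adjusted_difference,
                                                      abs=1e-8)
        assert b.p == pytest.approx(a.p, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10.0)
        g = np.repeat(["a", "b"], 5)
        Z = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            ancova_compare(y, g, Z)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_summary_stat_variant_on_age_comparison(self):
        # group means 60.7 / 59.6 years, SD 8.3 / 6.7, n 40 / 29: the
        # pooled-t p from these rounded summaries is ~0.56
        t, p = two_sample_t_from_stats(60.7, 8.3, 40, 59.6, 6.7, 29)
        assert p == pytest.approx(0.5586, abs=1e-3)

    def test_shift_scale_invariance_of_t(self):
        rng = np.random.default_rng(19)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 1, 20)
        t1, _ = two_sample_t(x, y)
        t2, _ = two_sample_t(3 + 2 * x, 3 + 2 * y)
        assert t2 == pytest.approx(t1, abs=1e-10)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


def enumerate_fisher_p(table):
    """Oracle: enumerate all tables with the observed margins."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = sps.hypergeom.pmf(k, n, r1, c1)
        if pk <= obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestFisherExact:
    def test_gender_table(self):
        assert fisher_exact_2x2([[17, 23], [17, 12]]) == pytest.approx(
            0.227, abs=5e-4
        )

    def test_statin_table(self):
        assert fisher_exact_2x2([[9, 31], [6, 23]]) == pytest.approx(
            1.000, abs=1e-9
        )

    def test_zero_row_gives_p_one(self):
        assert fisher_exact_2x2([[0, 0], [5, 7]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_agrees_with_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(20)
        tables = [[[17, 23], [17, 12]], [[9, 31], [6, 23]], [[1, 9], [9, 1]]]
        tables += [rng.integers(0, 16, (2, 2)).tolist() for _ in range(30)]
        for T in tables:
            if sum(T[0]) == 0 or sum(T[1]) == 0:
                continue
            assert fisher_exact_2x2(T) == pytest.approx(
                enumerate_fisher_p(T), abs=1e-9
            ), T


class TestCholesterolOutliers:
    def test_extreme_pd_value_flagged(self):
        rng = np.random.default_rng(21)
        tc = rng.normal(195, 36, 40)
        tc = (tc - tc.mean()) / tc.std(ddof=1) * 36 + 195  # exact moments
        tc[0] = 290.0
        df = pd.DataFrame({"group": "PD", "total_chol": tc})
        flags = detect_cholesterol_outliers(df, 2.0)
        assert flags.iloc[0]

    def test_borderline_control_value(self):
        # Construct a 29-subject control group whose mean is exactly 201
        # and SD exactly 39 *including* a 285 mg/dL subject; the rule
        # flags it because 285 > 201 + 2*39 = 279.
        rng = np.random.default_rng(22)
        z = rng.normal(size=28)
        z = (z - z.mean()) / np.sqrt((z**2).sum() - z.sum() ** 2 / 28)
        rest_mean = (29 * 201 - 285) / 28
        ss_rest = 28 * 39**2 - (285 - 201) ** 2  # target sum of (x-201)^2
        a = np.sqrt(ss_rest - 28 * (rest_mean - 201) ** 2)
        tc = np.concatenate([[285.0], rest_mean + a * z])
        assert tc.mean() == pytest.approx(201.0, abs=1e-9)
        assert tc.std(ddof=1) == pytest.approx(39.0, abs=1e-9)
        df = pd.DataFrame({"group": "control", "total_chol": tc})
        flags = detect_cholesterol_outliers(df, 2.0)
        assert flags.iloc[0] and flags.sum() >= 1

    def test_homogeneous_group_flags_nothing(self):
        df = pd.DataFrame({"group": "PD", "total_chol": np.full(10, 200.0)})
        assert not detect_cholesterol_outliers(df).any()

    def test_small_group_rejected(self):
        df = pd.DataFrame({"group": ["PD", "PD"], "total_chol": [1.0, 2.0]})
        with pytest.raises(ValueError):
            detect_cholesterol_outliers(df)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(replace(default_cohort_spec(), seed=42))


class TestTableBuilders:
    def test_correlation_table_shape_complete(self, cohort):
        table, log = build_correlation_table(cohort)
        # PD basic: 4 ROIs x (2 lipids + 3 clinical); PD extended: 4 x 2
        # lipids; control basic: 4 x 2 lipids (no clinical data)
        pd_basic = table.query("group=='PD' and covariate_set=='basic'")
        pd_ext = table.query("group=='PD' and covariate_set=='extended'")
        ctrl = table.query("group=='control'")
        assert len(pd_basic) == 20
        assert len(pd_ext) == 8
        assert len(ctrl) == 8 and set(ctrl["covariate_set"]) == {"basic"}
        assert table["rho"].notna().all()
        assert table["rho"].between(-1, 1).all()
        assert (table["significant"] == (table["p"] < 0.05)).all()

    def test_outlier_exclusion_logged_and_applied(self, cohort):
        from nigrastar.cohort import inject_outliers

        spiked = inject_outliers(cohort, 2, 3.5, seed=1)
        table, log = build_correlation_table(spiked)
        assert len(log["outliers_excluded"]) >= 2
        max_n = table.query("group=='PD'")["n"].max()
        assert max_n < (cohort["group"] == "PD").sum()

    def test_group_table_fields_and_tests(self, cohort):
        t1 = build_group_table(cohort)
        assert set(t1["field"]) == {
            "age", "gender", "statin", "total_chol", "ldl_chol",
            "r2star_SN", "r2star_caudate", "r2star_putamen", "r2star_GP",
        }
        assert t1["p"].between(0, 1).all()
        assert (t1.loc[t1["field"] == "gender", "test"] == "fisher").all()
        assert (t1.loc[t1["field"] == "r2star_SN", "test"] == "ancova").all()
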