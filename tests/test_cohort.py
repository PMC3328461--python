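"""Synthetic cohort generator: marginals, copula calibration, outliers."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nigrastar.cohort import (
    CLINICAL_VARS,
    CohortSpec,
    CorrTarget,
    LATENT_VARS,
    SubjectRecord,
    default_cohort_spec,
    inject_outliers,
    simulate_cohort,
    spearman_to_latent,
    spec_from_yaml,
    spec_to_yaml,
)
from nigrastar.stats import (
    COVARIATE_SETS,
    _encode_covariates,
    detect_cholesterol_outliers,
    spearman_partial,
)


class TestSpearmanToLatent:
    def test_independence_maps_to_zero(self):
        assert spearman_to_latent(0.0) == 0.0

    def test_monotone_and_approaches_one(self):
        xs = np.linspace(0, 0.999, 50)
        ys = [spearman_to_latent(x) for x in xs]
        assert np.all(np.diff(ys) > 0)
        assert ys[-1] == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_value(self):
        assert spearman_to_latent(-0.429) == pytest.approx(
            2 * np.sin(np.pi * -0.429 / 6), abs=1e-15
        )
        assert spearman_to_latent(-0.429) == pytest.approx(-0.44548, abs=1e-4)

    def test_monte_carlo_spearman_of_latent_bivariate_normal(self):
        # 1e6-draw oracle: a bivariate normal at the converted Pearson
        # correlation has sample Spearman at the original target.
        rho_s = -0.429
        lat = spearman_to_latent(rho_s)
        rng = np.random.default_rng(123)
        z = rng.multivariate_normal([0, 0], [[1, lat], [lat, 1]], size=10**6)
        est = sps.spearmanr(z[:, 0], z[:, 1]).statistic
        assert est == pytest.approx(rho_s, abs=0.003)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            spearman_to_latent(bad)


def _null_spec(n):
    spec = default_cohort_spec()
    loadings = {v: {"age": 0.0, "gender": 0.0, "statin": 0.0}
                for v in LATENT_VARS}
    return replace(spec, n_pd=n, n_control=0, targets=(), structural={},
                   loadings=loadings, seed=77)


class TestSimulateCohort:
    def test_null_structure_partial_spearman_near_zero(self):
        n = 10**4
        df = simulate_cohort(_null_spec(n))
        Z = _encode_covariates(df, COVARIATE_SETS["basic"])
        bound = 3.0 / np.sqrt(n - 3)
        for roi, var in [("SN", "total_chol"), ("GP", "ldl_chol"),
                         ("putamen", "updrs3")]:
            res = spearman_partial(df[f"r2star_{roi}"], df[var], Z)
            assert abs(res.rho) < bound

    def test_marginal_calibration_within_one_percent(self):
        n = 10**5
        spec = replace(default_cohort_spec(), n_pd=n, n_control=0, seed=5)
        df = simulate_cohort(spec)
        for var, (mean, sd) in spec.pd_marginals.items():
            col = f"r2star_{var}" if f"r2star_{var}" in df else var
            assert df[col].mean() == pytest.approx(mean, rel=0.01), var
            if var == "duration":
                # lognormal sample SD is noisy (excess kurtosis ~58 at
                # cv=1.12): compare against a 3-standard-error band
                kurt = sps.lognorm.stats(
                    np.sqrt(np.log1p((sd / mean) ** 2)), moments="k"
                ) + 3
                se_sd = sd * np.sqrt((kurt - 1) / (4 * n))
                assert abs(df[col].std() - sd) < 3 * se_sd
            else:
                assert df[col].std() == pytest.approx(sd, rel=0.01), var

    def test_group_sizes_proportions_and_missingness(self):
        df = simulate_cohort(replace(default_cohort_spec(), seed=3))
        assert (df["group"] == "PD").sum() == 40
        assert (df["group"] == "control").sum() == 29
        ctrl = df[df["group"] == "control"]
        assert ctrl[list(CLINICAL_VARS)].isna().all().all()
        assert df[df["group"] == "PD"][list(CLINICAL_VARS)].notna().all().all()
        assert set(df["gender"]) <= {"F", "M"}
        assert df["updrs3"].dropna().min() >= 0
        assert df["duration"].dropna().min() >= 0
        assert df["total_chol"].min() > 0

    def test_seed_determinism(self):
        spec = replace(default_cohort_spec(), seed=9)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_cohort(replace(spec, seed=10))
        assert not a["total_chol"].equals(c["total_chol"])

    def test_partial_spearman_rmse_shrinks_with_n(self):
        target = -0.429
        rmse = []
        for n in (100, 1000, 10000):
            est = []
            for s in range(10):
                df = simulate_cohort(replace(default_cohort_spec(), n_pd=n,
                                             n_control=0, seed=300 + s))
                Z = _encode_covariates(df, COVARIATE_SETS["basic"])
                est.append(spearman_partial(df["r2star_SN"], df["total_chol"],
                                            Z).rho)
            rmse.append(np.sqrt(np.mean((np.array(est) - target) ** 2)))
        assert rmse[2] < rmse[1] < rmse[0]
        assert rmse[2] < 0.02

    def test_control_group_correlations_null(self):
        df = simulate_cohort(replace(default_cohort_spec(), n_pd=0,
                                     n_control=10**4, seed=21))
        Z = _encode_covariates(df, COVARIATE_SETS["basic"])
        res = spearman_partial(df["r2star_SN"], df["total_chol"], Z)
        assert abs(res.rho) < 3.0 / np.sqrt(len(df) - 3)

    def test_non_positive_definite_targets_rejected(self):
        bad = (
            CorrTarget("SN", "total_chol", 0.95),
            CorrTarget("SN", "ldl_chol", -0.95),
        )
        spec = replace(default_cohort_spec(), targets=bad)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_cohort(spec)

    def test_subject_record_round_trip(self):
        df = simulate_cohort(replace(default_cohort_spec(), seed=2))
        rec = SubjectRecord.from_row(df.iloc[0])
        assert rec.group == "PD" and rec.updrs3 is not None
        assert set(rec.roi_r2star) == {"SN", "caudate", "putamen", "GP"}
        rec_c = SubjectRecord.from_row(df[df["group"] == "control"].iloc[0])
        assert rec_c.updrs3 is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(replace(default_cohort_spec(), n_pd=0,
                                    n_control=0))

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = default_cohort_spec()
        p = tmp_path / "cohort.yaml"
        spec_to_yaml(spec, p)
        back = spec_from_yaml(p)
        assert back.targets == spec.targets
        assert back.pd_marginals == {k: tuple(v) for k, v
                                     in spec.pd_marginals.items()}
        pd.testing.assert_frame_equal(simulate_cohort(back),
                                      simulate_cohort(spec))


class TestInjectOutliers:
    def test_identity_when_k_zero(self):
        df = simulate_cohort(replace(default_cohort_spec(), seed=4))
        out = inject_outliers(df, 0, 2.64)
        pd.testing.assert_frame_equal(out.drop(columns="chol_outlier_injected"),
                                      df)

    def test_magnitude_places_value_near_290(self):
        # PD group calibrated at 195 +/- 36: mean + 2.64 SD ~ 290 mg/dL
        df = simulate_cohort(replace(default_cohort_spec(), n_pd=4000,
                                     n_control=0, seed=6))
        out = inject_outliers(df, 1, 2.64, group="PD", seed=1)
        val = out.loc[out["chol_outlier_injected"], "total_chol"].iloc[0]
        assert val == pytest.approx(290.0, abs=5.0)

    def test_injected_subject_flagged_by_two_sd_rule(self):
        for seed in range(5):
            df = simulate_cohort(replace(default_cohort_spec(), seed=seed))
            out = inject_outliers(df, 2, 2.64, seed=seed)
            flags = detect_cholesterol_outliers(out, 2.0)
            assert flags[out["chol_outlier_injected"]].all()

    def test_ldl_rescaled_proportionally(self):
        df = simulate_cohort(replace(default_cohort_spec(), seed=8))
        out = inject_outliers(df, 1, 2.64, group="PD", seed=3)
        i = out.index[out["chol_outlier_injected"]][0]
        ratio_tc = out.at[i, "total_chol"] / df.at[i, "total_chol"]
        ratio_ldl = out.at[i, "ldl_chol"] / df.at[i, "ldl_chol"]
        assert ratio_ldl == pytest.approx(ratio_tc, rel=1e-12)

    def test_k_exceeding_cohort_rejected(self):
        df = simulate_cohort(replace(default_cohort_spec(), seed=4))
        with pytest.raises(ValueError):
            inject_outliers(df, len(df) + 1, 2.0)
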