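import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eggchamber import stats as st


def ols_oracle(X, y):
    """Closed-form normal-equations solution with classical t p-values."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    pvals = 2 * sps.t.sf(np.abs(beta / se), dof)
    return beta, pvals


def make_two_genotype_data(n=200, slope_gap=0.5, intercept_gap=0.0,
                           sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    size = rng.uniform(0, 1, n)
    geno = np.repeat(["a", "b"], n // 2)
    g = (geno == "b").astype(float)
    y = 1.0 + 2.0 * size + intercept_gap * g + slope_gap * size * g
    y = y + rng.normal(0, sigma, n)
    return pd.DataFrame({"y": y, "germline_area": size, "genotype": geno})


class TestLoess:
    def test_recovers_noiseless_line(self):
        x = np.linspace(0, 1, 60)
        fit = st.loess_curve(x, 2 * x)
        assert np.allclose(fit.fitted, 2 * fit.grid, atol=1e-6)

    def test_constant_input_gives_flat_curve(self):
        x = np.linspace(0, 1, 30)
        fit = st.loess_curve(x, np.full(30, 3.5))
        assert np.allclose(fit.fitted, 3.5, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.loess_curve(np.arange(5.0), np.arange(5.0))

    def test_ci_band_brackets_fit(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 80)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 80)
        fit = st.loess_curve(x, y, n_boot=100)
        assert np.all(fit.ci_high > fit.ci_low)
        # the band tracks the fit (smoothing bias can shift it slightly at
        # high-curvature grid points)
        inside = (fit.ci_low <= fit.fitted) & (fit.fitted <= fit.ci_high)
        assert inside.mean() > 0.9

    def test_phase1_contact_plateau(self, wt_cohort_table):
        t = wt_cohort_table
        fit = st.loess_curve(
            t["germline_area"].to_numpy(), t["prop_fc_on_oocyte"].to_numpy()
        )
        phase1 = fit.fitted[fit.grid < 6500]
        assert 0.14 <= phase1.mean() <= 0.22
        late = fit.fitted[fit.grid > 25000].mean()
        assert late > phase1.mean() + 0.2  # rises through phase 2


class TestCompareGenotypes:
    def test_matches_normal_equations_oracle(self):
        df = make_two_genotype_data(slope_gap=0.5)
        res = st.compare_genotypes(df, "y")
        g = (df["genotype"] == "b").astype(float).to_numpy()
        size = df["germline_area"].to_numpy()
        X = np.column_stack([np.ones(len(df)), size, g, size * g])
        beta, pvals = ols_oracle(X, df["y"].to_numpy())
        assert res.used_interaction
        keys = ["intercept", "germline_size", "genotype",
                "germline_size:genotype"]
        ours = np.array([res.coefficients[k] for k in keys])
        assert np.allclose(ours, beta, rtol=1e-8)
        ours_p = np.array([res.p_values[k] for k in keys])
        assert np.allclose(ours_p, pvals, rtol=1e-6, atol=1e-12)

    def test_interaction_recovered_within_two_se(self):
        df = make_two_genotype_data(n=200, slope_gap=0.5, sigma=0.1, seed=1)
        res = st.compare_genotypes(df, "y")
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["germline_area"],
                (df["genotype"] == "b").astype(float),
                df["germline_area"] * (df["genotype"] == "b"),
            ]
        )
        _, _ = ols_oracle(X, df["y"].to_numpy())
        est = res.coefficients["germline_size:genotype"]
        resid_dof = len(df) - 4
        # SE from the oracle fit
        XtX_inv = np.linalg.inv(X.T @ X)
        resid = df["y"].to_numpy() - X @ np.linalg.lstsq(X, df["y"], rcond=None)[0]
        se = np.sqrt(resid @ resid / resid_dof * XtX_inv[3, 3])
        assert abs(est - 0.5) < 2 * se

    def test_null_split_rarely_keeps_interaction(self):
        kept = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = make_two_genotype_data(n=200, slope_gap=0.0, sigma=0.1,
                                        seed=seed)
            if st.compare_genotypes(df, "y").used_interaction:
                kept += 1
        assert kept <= 0.2 * n_seeds  # nominal rate is alpha = 0.05

    def test_zero_noise_intercept_gap_recovered_exactly(self):
        df = make_two_genotype_data(n=80, slope_gap=0.0, intercept_gap=0.7,
                                    sigma=0.0, seed=2)
        res = st.compare_genotypes(df, "y")
        assert not res.used_interaction
        assert res.coefficients["genotype"] == pytest.approx(0.7, abs=1e-10)

    def test_single_genotype_rejected(self):
        df = make_two_genotype_data()
        df["genotype"] = "a"
        with pytest.raises(ValueError):
            st.compare_genotypes(df, "y")

    def test_interaction_type1_error_calibrated(self):
        # direct closed-form replication of the interaction test under the null
        rng = np.random.default_rng(0)
        n, reps, alpha = 60, 1500, 0.05
        rejections = 0
        size = np.linspace(0, 1, n)
        g = np.tile([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), size, g, size * g])
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        for _ in range(reps):
            y = 1.0 + size + rng.normal(0, 0.2, n)
            beta = H @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - 4)
            tstat = beta[3] / np.sqrt(s2 * XtX_inv[3, 3])
            if 2 * sps.t.sf(abs(tstat), n - 4) < alpha:
                rejections += 1
        rate = rejections / reps
        assert 0.03 <= rate <= 0.075


class TestCriticalSizeAnova:
    def test_effect_above_critical_size_only(self):
        rng = np.random.default_rng(4)
        n = 160
        size = rng.uniform(0, 2, n)
        geno = np.repeat(["a", "b"], n // 2)
        effect = 1.0 * ((geno == "b") & (size > 1.0))
        y = size + effect + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"y": y, "germline_area": size, "genotype": geno})
        out = st.critical_size_anova(df, 1.0, "y")
        inter = out.loc[out["term"] == "C(group):C(geno)", "PR(>F)"].iloc[0]
        assert inter < 0.01
        below = out.loc[out["term"] == "genotype within below", "p_sidak"].iloc[0]
        above = out.loc[out["term"] == "genotype within above", "p_sidak"].iloc[0]
        assert above < 0.01 and below > 0.05

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        n = 80
        size = rng.uniform(0, 2, n)
        geno = np.repeat(["a", "b"], n // 2)
        y = size + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "germline_area": size, "genotype": geno})
        out = st.critical_size_anova(df, 1.0, "y")
        # oracle: direct cell-mean two-way sums of squares (balanced-form,
        # type II via residual comparison of nested linear models)
        grp = (size > 1.0).astype(int)
        gn = (geno == "b").astype(int)

        def rss(cols):
            X = np.column_stack([np.ones(n)] + cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        inter_col = (grp * gn).astype(float)
        rss_full = rss([grp.astype(float), gn.astype(float), inter_col])
        rss_nointer = rss([grp.astype(float), gn.astype(float)])
        ss_inter = rss_nointer - rss_full
        got = out.loc[out["term"] == "C(group):C(geno)", "sum_sq"].iloc[0]
        assert got == pytest.approx(ss_inter, rel=1e-8)

    def test_degenerate_grouping_rejected(self):
        df = make_two_genotype_data(n=40)
        with pytest.raises(ValueError):
            st.critical_size_anova(df, -1.0, "y")  # every area above critical


class TestAngleVsEya:
    def test_two_point_line(self):
        df = pd.DataFrame(
            {"interface_angle": [85.0, 95.0, 90.0],
             "eya_mean_at_ncob": [62.0, 82.0, 72.0]}
        )
        fit = st.angle_vs_eya(df)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.eya_at_90 == pytest.approx(72.0, abs=1e-9)

    def test_synthetic_cohort_recovers_zero_point(self):
        rng = np.random.default_rng(9)
        E = rng.uniform(30, 120, 80)
        angle = 90 + 0.5 * (E - 72) + rng.normal(0, 1.0, 80)
        fit = st.angle_vs_eya(
            pd.DataFrame({"interface_angle": angle, "eya_mean_at_ncob": E})
        )
        assert fit.eya_at_90 == pytest.approx(72.0, abs=2.0)

    def test_flat_angles_flagged_undefined(self):
        df = pd.DataFrame(
            {"interface_angle": [90.0] * 5,
             "eya_mean_at_ncob": [50, 60, 70, 80, 90]}
        )
        fit = st.angle_vs_eya(df)
        assert fit.undefined and np.isnan(fit.eya_at_90)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        E = rng.uniform(30, 120, 50)
        angle = 90 + 0.4 * (E - 72) + rng.normal(0, 0.5, 50)
        base = st.angle_vs_eya(
            pd.DataFrame({"interface_angle": angle, "eya_mean_at_ncob": E})
        )
        shifted = st.angle_vs_eya(
            pd.DataFrame({"interface_angle": angle, "eya_mean_at_ncob": E + 13})
        )
        assert shifted.eya_at_90 - base.eya_at_90 == pytest.approx(13.0,
                                                                   abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            st.angle_vs_eya(
                pd.DataFrame({"interface_angle": [90.0],
                              "eya_mean_at_ncob": [70.0]})
            )
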