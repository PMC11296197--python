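"""Sex comparisons, GLMs, varimax, dichromatism and repeatability."""

import math

import numpy as np
import pandas as pd
import pytest

from spongesaxs import (
    glm_backward_reintroduce,
    male_residual_dichromatism,
    paired_hue_comparison,
    pearson_matrix,
    repeatability,
    sex_mean_variance_tests,
    sex_standardize,
    varimax_orthogonalize,
)


def make_table(males, females, column="x"):
    return pd.DataFrame({
        "sex": ["M"] * len(males) + ["F"] * len(females),
        column: list(males) + list(females),
    })


class TestSexStandardize:
    def test_symmetric_triples(self):
        df = sex_standardize(make_table([1, 2, 3], [10, 20, 30]), ["x"])
        np.testing.assert_allclose(df.loc[df.sex == "M", "x_z"], [-1, 0, 1])
        np.testing.assert_allclose(df.loc[df.sex == "F", "x_z"], [-1, 0, 1])

    def test_per_sex_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        df = make_table(rng.normal(5, 2, 40), rng.normal(-3, 7, 25))
        out = sex_standardize(df, ["x"])
        for sex in ("M", "F"):
            z = out.loc[out.sex == sex, "x_z"]
            assert abs(z.mean()) < 1e-10
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_column_raises(self):
        df = make_table([1, 1, 1], [2, 2, 2])
        with pytest.raises(ValueError, match="'x'"):
            sex_standardize(df, ["x"])


class TestSexMeanVarianceTests:
    def test_identical_groups(self):
        df = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t_res, f_res = sex_mean_variance_tests(df, "x")
        assert t_res.statistic == pytest.approx(0.0)
        assert t_res.p_value == pytest.approx(1.0)
        assert f_res.statistic == pytest.approx(1.0)

    def test_hand_evaluated_pooled_t(self):
        # pooled var = 1/3, se = sqrt(1/6), |t| = 10*sqrt(6)
        df = make_table([0, 0, 1, 1], [10, 10, 11, 11])
        t_res, _ = sex_mean_variance_tests(df, "x")
        assert abs(t_res.statistic) == pytest.approx(10 * math.sqrt(6), rel=1e-12)
        assert t_res.df == 6

    def test_variance_ratio_orientation_and_df(self):
        rng = np.random.default_rng(2)
        df = make_table(rng.normal(0, 1, 53), rng.normal(0, 2, 29))
        _, f_res = sex_mean_variance_tests(df, "x")
        assert f_res.statistic >= 1.0
        assert f_res.df == (28, 52)  # larger variance (females) in numerator

    def test_f_test_power_under_sd_ratio_two(self):
        rejections = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            df = make_table(rng.normal(0, 1, 53), rng.normal(0, 2, 29))
            _, f_res = sex_mean_variance_tests(df, "x")
            rejections += f_res.p_value < 0.05
        assert rejections / 500 >= 0.80

    def test_t_invariant_to_affine_rescale(self):
        rng = np.random.default_rng(3)
        df = make_table(rng.normal(0, 1, 20), rng.normal(1, 1, 15))
        t1, f1 = sex_mean_variance_tests(df, "x")
        df2 = df.assign(x=3.5 * df.x + 100.0)
        t2, f2 = sex_mean_variance_tests(df2, "x")
        assert t2.statistic == pytest.approx(t1.statistic, rel=1e-10)
        assert f2.statistic == pytest.approx(f1.statistic, rel=1e-10)

    def test_missing_sex_raises(self):
        df = pd.DataFrame({"sex": ["M"] * 5, "x": range(5)})
        with pytest.raises(ValueError):
            sex_mean_variance_tests(df, "x")


class TestPearsonMatrix:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
        r, p = pearson_matrix(df, ["a", "b", "c"])
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert r.equals(r.T)

    def test_estimator_unbiased_at_moderate_correlation(self):
        # bivariate normal, rho = 0.55, n = 82: mean r-hat within 0.03
        rho, estimates = 0.55, []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 82)
            df = pd.DataFrame(xy, columns=["a", "b"])
            r, _ = pearson_matrix(df, ["a", "b"])
            estimates.append(r.loc["a", "b"])
        assert np.mean(estimates) == pytest.approx(rho, abs=0.03)

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant"):
            pearson_matrix(df, ["a", "b"])


class TestGlmBackwardReintroduce:
    def null_frame(self, rng, n=82):
        return pd.DataFrame({
            "sex": ["M"] * 53 + ["F"] * 29,
            "x": rng.normal(size=n), "z": rng.normal(size=n),
        })

    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(11)
        df = self.null_frame(rng)
        df["y"] = 2.0 * df.x + rng.normal(0, 0.1, len(df))
        tab = glm_backward_reintroduce(df, "y", ["x", "z", "x:sex"])
        retained = set(tab.loc[tab.retained, "term"])
        assert retained == {"x"}
        assert tab.set_index("term").loc["x", "F"] > 1e3
        assert (tab.set_index("term").loc[["z", "x:sex"], "F"] < 5).all()

    def test_perfect_fit_gives_huge_f(self):
        rng = np.random.default_rng(12)
        df = self.null_frame(rng)
        df["y"] = df.x
        tab = glm_backward_reintroduce(df, "y", ["x", "z"])
        row = tab.set_index("term").loc["x"]
        assert row.F > 1e10 and row.p < 1e-12

    def test_alpha_one_keeps_full_model(self):
        rng = np.random.default_rng(13)
        df = self.null_frame(rng)
        df["y"] = rng.normal(size=len(df))
        tab = glm_backward_reintroduce(df, "y", ["x", "z", "sex", "x:sex"], alpha=1.0)
        assert tab.retained.all()

    def test_alpha_zero_returns_intercept_only(self):
        rng = np.random.default_rng(14)
        df = self.null_frame(rng)
        df["y"] = 2 * df.x + rng.normal(size=len(df))
        tab = glm_backward_reintroduce(df, "y", ["x", "z"], alpha=0.0)
        assert not tab.retained.any()

    def test_marginality_keeps_main_while_interaction_significant(self):
        rng = np.random.default_rng(15)
        df = self.null_frame(rng)
        sex_num = (df.sex == "M").astype(float)
        df["y"] = 3.0 * df.x * sex_num + rng.normal(0, 0.5, len(df))
        tab = glm_backward_reintroduce(df, "y", ["x", "sex", "x:sex"])
        retained = set(tab.loc[tab.retained, "term"])
        assert "x:sex" in retained
        assert {"x", "sex"} <= retained  # mains protected by their interaction

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(16)
        df = self.null_frame(rng)
        df["w"] = df.x  # aliased copy
        df["y"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="rank-deficient"):
            glm_backward_reintroduce(df, "y", ["x", "w"], alpha=1.0)

    def test_reintroduced_terms_report_df_of_final_model_plus_one(self):
        rng = np.random.default_rng(17)
        df = self.null_frame(rng)
        df["y"] = 2 * df.x + rng.normal(0, 0.1, len(df))
        tab = glm_backward_reintroduce(df, "y", ["x", "z"]).set_index("term")
        assert tab.loc["x", "df2"] == len(df) - 2  # final model: intercept + x
        assert tab.loc["z", "df2"] == len(df) - 3  # reintroduced alongside x


class TestVarimaxOrthogonalize:
    def test_already_orthogonal_columns_reproduced(self):
        rng = np.random.default_rng(21)
        raw = rng.normal(size=(60, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        df = pd.DataFrame(q * math.sqrt(59), columns=["a", "b"])
        scores, loadings = varimax_orthogonalize(df, ["a", "b"])
        # scores match the standardized inputs up to sign/order
        corr = np.corrcoef(df.to_numpy().T, scores.to_numpy().T)[:2, 2:]
        assert sorted(np.abs(corr).max(axis=1).round(6)) == [1.0, 1.0]

    def test_correlated_pair_decorrelated(self):
        rng = np.random.default_rng(22)
        xy = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], 200)
        df = pd.DataFrame(xy, columns=["a", "b"])
        scores, _ = varimax_orthogonalize(df, ["a", "b"])
        assert abs(np.corrcoef(scores.RC1, scores.RC2)[0, 1]) < 1e-8

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        df["b"] += 0.8 * df["a"]
        df["d"] -= 0.5 * df["c"]
        scores, loadings = varimax_orthogonalize(df, list("abcd"))
        L = loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)
        cov = np.corrcoef(scores.to_numpy().T)
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            varimax_orthogonalize(df, ["a", "b"])


class TestMaleResidualDichromatism:
    def test_shared_regression_line_gives_null_result(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"sex": ["M"] * 53 + ["F"] * 29, "x": rng.normal(size=82)})
        df["y"] = 1.5 + 2.0 * df.x  # both sexes exactly on the male line
        res, resid = male_residual_dichromatism(df, "y", ["x"])
        assert res.statistic == 0.0 and res.p_value == 1.0
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_constructed_female_offset_detected(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame({"sex": ["M"] * 53 + ["F"] * 29, "x": rng.normal(size=82)})
        df["y"] = 2.0 * df.x + rng.normal(0, 0.5, 82)
        df.loc[df.sex == "F", "y"] += 5.0
        res, resid = male_residual_dichromatism(df, "y", ["x"])
        assert resid[df.sex == "F"].mean() == pytest.approx(5.0, abs=0.5)
        assert res.p_value < 1e-6

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(40000 + seed)
            df = pd.DataFrame({
                "sex": ["M"] * 53 + ["F"] * 29,
                "x": rng.normal(size=82), "y": rng.normal(size=82),
            })
            res, _ = male_residual_dichromatism(df, "y", ["x"])
            rejections += res.p_value < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.03)

    def test_too_few_males_raises(self):
        df = pd.DataFrame({"sex": ["M", "M", "F", "F"], "x": [1, 2, 3, 4],
                           "y": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="male"):
            male_residual_dichromatism(df, "y", ["x", "x"][:1] * 3)


class TestPairedHueComparison:
    def test_perfect_prediction_all_null(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({
            "sex": ["M"] * 10 + ["F"] * 8,
            "hue": rng.normal(380, 10, 18),
        })
        df["predicted_hue"] = df.hue
        out = paired_hue_comparison(df)
        assert out["mean_difference"] == {"F": 0.0, "M": 0.0}
        for res in out["per_sex"].values():
            assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constructed_female_overestimation(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({
            "sex": ["M"] * 53 + ["F"] * 29,
            "hue": rng.normal(370, 8, 82),
        })
        df["predicted_hue"] = df.hue
        df.loc[df.sex == "F", "predicted_hue"] += 8.0
        out = paired_hue_comparison(df)
        assert out["mean_difference"]["F"] == pytest.approx(8.0)
        assert out["mean_difference"]["M"] == pytest.approx(0.0)
        assert out["interaction"].p_value < 1e-10

    def test_missing_prediction_raises(self):
        df = pd.DataFrame({"sex": ["M", "F"], "hue": [370.0, 380.0],
                           "predicted_hue": [371.0, np.nan]})
        with pytest.raises(ValueError, match="predicted_hue"):
            paired_hue_comparison(df)

    def test_null_interaction_rejection_rate(self):
        rejections = 0
        n_sims = 500
        for seed in range(n_sims):
            rng = np.random.default_rng(50000 + seed)
            df = pd.DataFrame({
                "sex": ["M"] * 53 + ["F"] * 29,
                "hue": rng.normal(370, 5, 82),
            })
            df["predicted_hue"] = df.hue + rng.normal(0, 2, 82)
            out = paired_hue_comparison(df)
            rejections += out["interaction"].p_value < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)


class TestRepeatability:
    def rounds(self, rng, n_m=24, n_f=24, noise=0.0):
        sexes = ["M"] * n_m + ["F"] * n_f
        latent = rng.normal(size=len(sexes))
        r1 = pd.DataFrame({"sample": range(len(sexes)), "sex": sexes,
                           "q1": latent + rng.normal(0, noise, len(sexes))})
        r2 = pd.DataFrame({"sample": range(len(sexes)), "sex": sexes,
                           "q1": latent + rng.normal(0, noise, len(sexes))})
        return r1, r2

    def test_identical_rounds_give_unit_correlation(self):
        rng = np.random.default_rng(51)
        r1, _ = self.rounds(rng)
        out = repeatability(r1, r1.copy(), ["q1"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_mean_correlation_tracks_generating_icc(self):
        # latent/noise variances set for between-round correlation 0.7
        target, estimates = 0.7, []
        for seed in range(300):
            rng = np.random.default_rng(60000 + seed)
            noise = math.sqrt((1 - target) / target)
            r1, r2 = self.rounds(rng, noise=noise)
            estimates.append(repeatability(r1, r2, ["q1"]).loc[0, "r"])
        assert np.mean(estimates) == pytest.approx(target, abs=0.05)

    def test_sex_difference_in_repeatability_detected(self):
        """Males correlating ~0.97 vs females ~0.74 between rounds.

        The Fisher-z comparison of the per-sex correlations detects the
        difference reliably; the pooled-variance slope-interaction test is
        directional but much weaker here because the male residual spread
        is far smaller than the female one, which violates the pooled
        model's equal-variance assumption.
        """
        glm_detections, fisher_detections, interaction_ts = 0, 0, []
        n_sims = 300
        for seed in range(n_sims):
            rng = np.random.default_rng(70000 + seed)
            latent = rng.normal(size=48)
            noise_m = math.sqrt((1 - 0.97) / 0.97)
            noise_f = math.sqrt((1 - 0.74) / 0.74)
            sd = np.where(np.arange(48) < 24, noise_m, noise_f)
            sexes = ["M"] * 24 + ["F"] * 24
            r1 = pd.DataFrame({"sample": range(48), "sex": sexes,
                               "q1": latent + rng.normal(0, 1, 48) * sd})
            r2 = pd.DataFrame({"sample": range(48), "sex": sexes,
                               "q1": latent + rng.normal(0, 1, 48) * sd})
            out = repeatability(r1, r2, ["q1"])
            glm_detections += out.loc[0, "p_interaction"] < 0.05
            fisher_detections += out.loc[0, "p_fisher"] < 0.05
            interaction_ts.append(math.copysign(
                math.sqrt(out.loc[0, "F_interaction"]), out.loc[0, "z_fisher"]
            ))
        assert fisher_detections / n_sims >= 0.50
        assert glm_detections / n_sims > 0.05  # above the null rate
        assert abs(np.mean(interaction_ts)) > 1.0  # directional signal present

    def test_r_by_sex_reported(self):
        rng = np.random.default_rng(52)
        r1, r2 = self.rounds(rng, noise=0.3)
        out = repeatability(r1, r2, ["q1"])
        assert set(out.loc[0, "r_by_sex"]) == {"M", "F"}

    def test_no_overlap_raises(self):
        r1 = pd.DataFrame({"sample": [1, 2], "sex": ["M", "F"], "q1": [1.0, 2.0]})
        r2 = pd.DataFrame({"sample": [3, 4], "sex": ["M", "F"], "q1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="overlap"):
            repeatability(r1, r2, ["q1"])
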