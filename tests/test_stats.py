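"""Statistical layer: GLM link selection, proportion models and diagnostics,
marginal means, agreement limits, variance components and PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from seedpe.stats import (
    VarianceComponents,
    bland_altman,
    emm_pairwise,
    estimate_variance_components,
    fit_count_model,
    fit_proportion_model,
    hosmer_lemeshow,
    nagelkerke_r2,
    pca_biplot,
    repeatability,
    select_count_model,
    twgss,
)


def linear_design(n_rep=10, noise_sd=0.0, seed=0, slope=46.0, method_offset=-4.0):
    """Balanced factorial with a common linear mass response."""
    rng = np.random.default_rng(seed)
    rows = []
    for v in ("A", "B", "C"):
        for m in ("belt_thresher", "impact_dehuller"):
            for mass in (1, 2, 3, 4, 5):
                for _ in range(n_rep):
                    mu = (
                        10.0
                        + {"A": 0, "B": 12, "C": -8}[v]
                        + (method_offset if m == "impact_dehuller" else 0.0)
                        + slope * mass
                    )
                    rows.append(
                        {
                            "variety": v,
                            "processing_method": m,
                            "legume_fruit_pod_mass_g": float(mass),
                            "total_objects": mu + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestCountModel:
    def test_noiseless_linear_fit_is_exact(self):
        df = linear_design(n_rep=2, noise_sd=0.0)
        fit = fit_count_model(df, "gaussian_identity")
        assert fit.coefficients["legume_fruit_pod_mass_g"] == pytest.approx(46.0)
        assert fit.coefficients["Intercept"] == pytest.approx(10.0)
        resid = df["total_objects"] - fit.fitted
        assert np.sqrt((resid**2).mean()) == pytest.approx(0.0, abs=1e-8)

    def test_gaussian_wins_on_gaussian_linear_data(self):
        df = linear_design(n_rep=10, noise_sd=8.0, seed=3)
        holdout = np.random.default_rng(4).random(len(df)) < 0.25
        fit, comparison = select_count_model(df, holdout)
        assert fit.link == "gaussian_identity"
        tbl = comparison.set_index("link")
        assert tbl.loc["gaussian_identity", "rmse"] <= tbl.loc["poisson_log", "rmse"]

    def test_method_offset_recovered_within_ci(self):
        """A -4 method effect is covered by its 95% CI in >=8 of 10
        independent simulations (nominal coverage 95%)."""
        name = "C(processing_method)[T.impact_dehuller]"
        hits = 0
        for s in range(10):
            df = linear_design(n_rep=20, noise_sd=6.0, seed=50 + s, method_offset=-4.0)
            fit = fit_count_model(df, "gaussian_identity")
            est = fit.coefficients[name]
            se = fit.result.bse[name]
            hits += est - 1.96 * se <= -4.0 <= est + 1.96 * se
        assert hits >= 8

    def test_collinear_design_names_aliased_terms(self):
        df = linear_design(n_rep=2, noise_sd=1.0)
        df["mass_copy"] = df["legume_fruit_pod_mass_g"]
        with pytest.raises(ValueError, match="aliased"):
            fit_count_model(
                df,
                "gaussian_identity",
                formula="total_objects ~ legume_fruit_pod_mass_g + mass_copy",
            )


def proportion_design(b_mass=0.0, n=200, seed=0, base_logit=-0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        v = ["A", "B", "C"][i % 3]
        m = ["belt_thresher", "impact_dehuller"][i % 2]
        mass = 1 + (i % 5)
        eta = base_logit + b_mass * mass
        p = 1 / (1 + np.exp(-eta))
        total = int(rng.integers(40, 120))
        y = rng.binomial(total, p)
        rows.append(
            {
                "variety": v,
                "processing_method": m,
                "legume_fruit_pod_mass_g": float(mass),
                "p_ip": y / total,
                "total_objects": float(total),
            }
        )
    return pd.DataFrame(rows)


class TestProportionModel:
    def test_null_lrt_p_uniform(self):
        """Under no factor effects the LRT p-values are ~Uniform(0,1)."""
        from scipy.stats import kstest

        pvals = []
        for s in range(400):
            df = proportion_design(b_mass=0.0, n=60, seed=s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_proportion_model(df, "p_ip")
            pvals.append(fit.extra["lrt_p"])
        assert kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_positive_mass_slope_recovered(self):
        hits = 0
        for s in range(100):
            df = proportion_design(b_mass=0.2, n=120, seed=1000 + s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_proportion_model(df, "p_ip")
            hits += fit.coefficients["legume_fruit_pod_mass_g"] > 0
        assert hits >= 95

    def test_complete_separation_flagged(self):
        df = proportion_design(n=40, seed=2)
        df["p_ip"] = 1.0  # all successes
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_proportion_model(df, "p_ip")
        assert fit.extra["separation"]

    def test_model_beats_null_on_real_signal(self, trait_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_proportion_model(trait_table, "p_ip")
        assert fit.extra["lrt_p"] < 1e-10
        assert fit.extra["nagelkerke_r2"] > 0.5
        assert not fit.extra["separation"]


class TestHosmerLemeshow:
    def test_perfect_calibration(self):
        totals = np.full(50, 10.0)
        probs = np.tile([0.1, 0.3, 0.5, 0.7, 0.9], 10)
        observed = totals * probs  # O == E in every group
        chi2, df, p = hosmer_lemeshow(observed, totals, probs, g=5)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_is_g_minus_two(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.2, 0.8, 200)
        totals = np.full(200, 20.0)
        observed = rng.binomial(20, probs).astype(float)
        _, df, _ = hosmer_lemeshow(observed, totals, probs, g=10)
        assert df == 8

    def test_three_group_hand_oracle(self):
        # groups: p=0.3 (O=2), p=0.5 (O=5), p=0.7 (O=8), 10 trials each
        probs = np.repeat([0.3, 0.5, 0.7], 10)
        totals = np.ones(30)
        observed = np.zeros(30)
        observed[:2] = 1  # 2 successes in group 1
        observed[10:15] = 1  # 5 in group 2
        observed[20:28] = 1  # 8 in group 3
        chi2, df, _ = hosmer_lemeshow(observed, totals, probs, g=3)
        expected = (2 - 3) ** 2 / (3 * 0.7) + 0.0 + (8 - 7) ** 2 / (7 * 0.3)
        assert chi2 == pytest.approx(expected)
        assert df == 1

    def test_too_few_distinct_values_reduces_g(self):
        probs = np.repeat([0.3, 0.5, 0.7], 10)
        totals = np.ones(30)
        with pytest.warns(UserWarning, match="reducing g"):
            hosmer_lemeshow(totals * probs, totals, probs, g=10)


class TestNagelkerke:
    def test_limits(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0
        assert nagelkerke_r2(0.0, -70.0, 100) == pytest.approx(1.0)

    def test_closed_form_value(self):
        val = nagelkerke_r2(-60.0, -100 * np.log(2), 100)
        assert val == pytest.approx(0.2266, abs=5e-4)

    def test_monotone_in_model_likelihood(self):
        vals = [nagelkerke_r2(ll, -80.0, 120) for ll in (-80, -60, -40, -20)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 1 for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-90.0, -80.0, 100)
        with pytest.raises(ValueError):
            nagelkerke_r2(0.0, 0.0, 100)


class TestEmmPairwise:
    def test_balanced_one_factor_means_equal_group_means(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "variety": np.repeat(["A", "B", "C"], 30),
                "processing_method": "belt_thresher",
                "legume_fruit_pod_mass_g": 1.0,
                "total_objects": np.concatenate(
                    [rng.normal(mu, 2, 30) for mu in (50, 60, 45)]
                ),
            }
        )
        fit = fit_count_model(
            df, "gaussian_identity", formula="total_objects ~ C(variety)"
        )
        emm, contrasts = emm_pairwise(fit, df, "variety")
        group_means = df.groupby("variety")["total_objects"].mean()
        for _, row in emm.iterrows():
            assert row["emmean"] == pytest.approx(group_means[row["variety"]])
        assert len(contrasts) == 3

    def test_identical_groups_contrast_zero(self):
        df = pd.DataFrame(
            {
                "variety": np.repeat(["A", "B"], 20),
                "total_objects": np.tile([9.0, 11.0], 20),  # identical groups
            }
        )
        fit = fit_count_model(
            df, "gaussian_identity", formula="total_objects ~ C(variety)"
        )
        _, contrasts = emm_pairwise(fit, df, "variety")
        assert contrasts.loc[0, "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_logit_backtransform_recovers_probabilities(self):
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame(
            {
                "variety": np.repeat(["A", "B"], n),
                "processing_method": "belt_thresher",
                "legume_fruit_pod_mass_g": 1.0,
                "p_ip": np.concatenate(
                    [rng.binomial(50, p, n) / 50 for p in (0.3, 0.6)]
                ),
                "total_objects": 50.0,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_proportion_model(df, "p_ip", formula_rhs="C(variety)")
        emm, contrasts = emm_pairwise(fit, df, "variety")
        means = emm.set_index("variety")["emmean"]
        assert means["A"] == pytest.approx(0.3, abs=0.02)
        assert means["B"] == pytest.approx(0.6, abs=0.02)
        assert contrasts.loc[0, "p_adjusted"] < 1e-6

    def test_bonferroni_fallback_labeled(self):
        df = pd.DataFrame(
            {
                "variety": np.tile(["A", "B", "C"], 15),
                "total_objects": np.random.default_rng(2).normal(10, 1, 45),
            }
        )
        fit = fit_count_model(
            df, "gaussian_identity", formula="total_objects ~ C(variety)"
        )
        _, contrasts = emm_pairwise(fit, df, "variety", adjust="bonferroni")
        assert (contrasts["adjustment"] == "bonferroni").all()


class TestBlandAltman:
    def test_identical_vectors(self):
        m, lo, hi = bland_altman([1, 2, 3], [1, 2, 3])
        assert (m, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        m, lo, hi = bland_altman([1, 2, 3], [4, 5, 6])
        assert m == pytest.approx(3.0)
        assert lo == pytest.approx(3.0) and hi == pytest.approx(3.0)

    def test_symmetric_differences(self):
        m, lo, hi = bland_altman([0, 0], [-1, 1])
        assert m == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert lo == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1], [1])


class TestRepeatability:
    def test_pure_genetic_variance(self):
        vc = VarianceComponents(1, 0, 0, 0, r=10, e=10)
        assert repeatability(vc) == 1.0

    def test_no_genetic_variance(self):
        vc = VarianceComponents(0, 1, 1, 1, r=10, e=10)
        assert repeatability(vc) == 0.0

    def test_hand_computed_value(self):
        vc = VarianceComponents(2, 1, 1, 4, r=10, e=10)
        assert repeatability(vc) == pytest.approx(2 / 2.24)

    def test_monotone_in_replication(self):
        vals = [
            repeatability(VarianceComponents(2, 1, 1, 4, r=r, e=e))
            for r, e in [(1, 1), (2, 2), (5, 5), (50, 50), (1000, 1000)]
        ]
        assert vals == sorted(vals)
        assert vals[-1] > 0.99

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-1, 0, 0, 1, r=1, e=1)


def simulate_gxe(s2=(4.0, 1.0, 1.0, 2.0), G=8, E=6, r=4, seed=0):
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0, np.sqrt(s2[0]), G)
    e_eff = rng.normal(0, np.sqrt(s2[1]), E)
    ge_eff = rng.normal(0, np.sqrt(s2[2]), (G, E))
    rows = []
    for g in range(G):
        for e in range(E):
            for _ in range(r):
                rows.append(
                    {
                        "variety": f"g{g}",
                        "environment": f"e{e}",
                        "y": 10 + g_eff[g] + e_eff[e] + ge_eff[g, e]
                        + rng.normal(0, np.sqrt(s2[3])),
                    }
                )
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_reml_agrees_with_moments_on_balanced_data(self):
        df = simulate_gxe(seed=3)
        reml = estimate_variance_components(df, "y", method="reml")
        mom = estimate_variance_components(df, "y", method="moments")
        for f in ("sigma2_g", "sigma2_e", "sigma2_gxe", "sigma2_resid"):
            assert getattr(reml, f) == pytest.approx(getattr(mom, f), abs=0.15)

    def test_zero_noise_gives_unit_repeatability(self):
        df = simulate_gxe(s2=(4.0, 0.0, 0.0, 1e-12), seed=4)
        vc = estimate_variance_components(df, "y", method="moments")
        assert vc.sigma2_resid == pytest.approx(0.0, abs=1e-6)
        assert repeatability(vc) > 0.999

    def test_single_environment_not_identifiable(self):
        df = simulate_gxe(E=1, seed=5)
        with pytest.raises(ValueError, match="environments"):
            estimate_variance_components(df, "y", method="moments")

    def test_pe_repeatability_high_on_default_generator(self, trait_table):
        tr = trait_table.copy()
        tr["environment"] = (
            tr["processing_method"] + ":" + tr["nominal_mass_g"].astype(str)
        )
        vc = estimate_variance_components(tr, "pe", "variety", "environment")
        assert vc.e == 10 and vc.r == 10
        assert repeatability(vc) > 0.9


class TestTwgss:
    def test_points_at_centroid(self):
        pts = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        assert twgss(pts, np.array(["a", "a", "b"])) == 0.0

    def test_two_point_class(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert twgss(pts, np.array(["a", "a"])) == pytest.approx(2.0)

    def test_merging_separated_classes_never_decreases(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (20, 2))
        b = rng.normal(10, 1, (20, 2))
        pts = np.vstack([a, b])
        split = twgss(pts, np.repeat(["a", "b"], 20))
        merged = twgss(pts, np.repeat(["a"], 40))
        assert merged >= split

    def test_trace_covariance_identity(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(15, 3))
        labels = np.array([0] * 7 + [1] * 8)
        expected = sum(
            (len(grp) - 1) * np.trace(np.cov(grp.T))
            for grp in (pts[:7], pts[7:])
        )
        assert twgss(pts, labels) == pytest.approx(expected)


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_biplot(df)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, trait_table):
        cols = ["p_ip", "p_ws", "p_ss", "pe", "pe_ws", "pe_ss", "nopgs", "nopgm"]
        res = pca_biplot(trait_table[cols])
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20000, 9)))
        res = pca_biplot(df)
        assert np.allclose(res.variance_explained, 1 / 9, atol=0.01)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        r1, r2 = pca_biplot(df), pca_biplot(df * 1.0)
        assert np.allclose(r1.loadings.to_numpy(), r2.loadings.to_numpy())
        for k in r1.loadings.columns:
            j = r1.loadings[k].abs().idxmax()
            assert r1.loadings.loc[j, k] > 0

    def test_zero_variance_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [0.0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_biplot(df)
        assert res.dropped_columns == ["b"]
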