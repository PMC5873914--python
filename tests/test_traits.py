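"""Outlier rule, REML variance components, BLUP shrinkage, random-effect LRTs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fvtqtl.traits import (
    estimate_genotype_means,
    filter_outliers,
    fit_variance_components,
    random_effects_table,
    shrunken_mean,
    significance_code,
)
from fvtqtl.traits import test_random_effect as lrt_random_effect


class TestOutlierFilter:
    def test_single_extreme_value_removed(self):
        # thirty 0s + one 10: z of the 10 is 5.39 under full-sample mean/SD
        x = np.array([0.0] * 30 + [10.0])
        z = abs(10.0 - x.mean()) / x.std(ddof=1)
        assert z == pytest.approx(5.39, abs=5e-3)
        kept, removed = filter_outliers(x)
        assert list(removed) == [30]
        assert kept.size == 30 and np.all(kept == 0.0)

    def test_all_within_three_sd(self):
        kept, removed = filter_outliers([1, 2, 3, 4, 5])
        assert removed.size == 0 and kept.size == 5

    def test_zero_sd_keeps_everything(self):
        kept, removed = filter_outliers([7.0, 7.0, 7.0])
        assert removed.size == 0

    def test_single_pass_not_iterated(self):
        # after removing the big outlier, 4.0 would fall outside 3 SD of the
        # remainder; a single pass must keep it
        x = np.array([0.0] * 50 + [4.0, 100.0])
        kept, removed = filter_outliers(x)
        assert 4.0 in kept and 100.0 not in kept

    def test_too_short(self):
        with pytest.raises(ValueError):
            filter_outliers([1.0])


def balanced_one_way(ng=24, m=4, sg=2.0, se=1.2, seed=11):
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0, sg, ng)
    rows = [
        (f"g{i:02d}", f"b{j}", 10 + g_eff[i] + rng.normal(0, se))
        for i in range(ng) for j in range(m)
    ]
    return pd.DataFrame(rows, columns=["genotype", "block", "value"])


class TestREML:
    def test_matches_anova_closed_form_balanced(self):
        df = balanced_one_way()
        fit = fit_variance_components(df, "value", ["genotype"])
        y = df.pivot(index="genotype", columns="block", values="value").to_numpy()
        m = y.shape[1]
        msb = m * np.var(y.mean(axis=1), ddof=1)
        msw = float(np.mean(np.var(y, axis=1, ddof=1)))
        assert fit.variances["genotype"] == pytest.approx(
            max((msb - msw) / m, 0.0), rel=1e-5
        )
        assert fit.variances["residual"] == pytest.approx(msw, rel=1e-5)

    def test_cross_checked_against_statsmodels(self):
        import statsmodels.api as sm

        df = balanced_one_way(ng=15, m=3, seed=12)
        fit = fit_variance_components(df, "value", ["genotype"])
        md = sm.MixedLM.from_formula("value ~ 1", groups="genotype", data=df)
        ref = md.fit(reml=True)
        assert fit.variances["genotype"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert fit.variances["residual"] == pytest.approx(ref.scale, rel=1e-3)

    def test_blups_match_balanced_shrinkage_formula(self):
        df = balanced_one_way(ng=20, m=4, seed=13)
        fit = fit_variance_components(df, "value", ["genotype"])
        sg2, se2 = fit.variances["genotype"], fit.variances["residual"]
        raw = df.groupby("genotype")["value"].mean()
        grand = df["value"].mean()
        bl = fit.blups("genotype")
        for g in raw.index:
            expected = shrunken_mean(raw[g], grand, sg2, se2, 4)
            assert fit.intercept + bl[g] == pytest.approx(expected, abs=1e-3)


class TestGenotypeMeans:
    def test_worked_shrinkage_example(self):
        # sigma_g^2 = sigma_e^2 = 4, m = 4 reps: lambda = 0.8
        assert shrunken_mean(10.0, 8.0, 4.0, 4.0, 4) == pytest.approx(9.6)

    def test_shrunken_between_raw_and_grand(self):
        df = balanced_one_way(ng=18, m=3, seed=14)
        means, vc = estimate_genotype_means(df)
        grand = df["value"].mean()
        inside = (
            (means["shrunken_mean"] - grand).abs()
            <= (means["raw_mean"] - grand).abs() + 1e-6
        )
        assert inside.all()
        assert all(v >= 0 for v in vc.values())

    def test_near_zero_residual_gives_raw_means(self):
        df = balanced_one_way(ng=12, m=4, sg=3.0, se=1e-4, seed=15)
        means, _ = estimate_genotype_means(df)
        np.testing.assert_allclose(
            means["shrunken_mean"], means["raw_mean"], atol=1e-3
        )

    def test_no_genetic_variance_collapses_to_grand_mean(self):
        df = balanced_one_way(ng=30, m=4, sg=0.0, se=1.0, seed=16)
        means, _ = estimate_genotype_means(df)
        grand = df["value"].mean()
        shrink = (means["shrunken_mean"] - grand).abs()
        raw = (means["raw_mean"] - grand).abs()
        assert shrink.mean() < 0.35 * raw.mean()

    def test_degenerate_designs_rejected(self):
        df = balanced_one_way(ng=5, m=3)
        with pytest.raises(ValueError):
            estimate_genotype_means(df[df["genotype"] == "g00"])
        one_block = df[df["block"] == "b0"]
        with pytest.raises(ValueError):
            estimate_genotype_means(one_block)


def reml_loglik_via_contrasts(y, V):
    """Independent REML oracle: density of error contrasts K y where the
    rows of K span the orthogonal complement of the intercept."""
    n = y.size
    ones = np.ones((n, 1)) / np.sqrt(n)
    q, _ = np.linalg.qr(np.eye(n) - ones @ ones.T)
    K = q[:, : n - 1].T
    return stats.multivariate_normal.logpdf(K @ y, cov=K @ V @ K.T)


class TestRandomEffectLRT:
    def test_chisq_matches_brute_force_likelihoods(self):
        # 8-observation toy set: 4 genotypes x 2 reps
        rng = np.random.default_rng(17)
        df = pd.DataFrame({
            "genotype": np.repeat([f"g{i}" for i in range(4)], 2),
            "value": rng.normal(0, 1, 8) + np.repeat(rng.normal(0, 2, 4), 2),
        })
        full = fit_variance_components(df, "value", ["genotype"])
        t = lrt_random_effect(df, "value", ["genotype"], "genotype")

        y = df["value"].to_numpy()
        Z = pd.get_dummies(df["genotype"]).to_numpy(float)
        V_full = (full.variances["genotype"] * Z @ Z.T
                  + full.variances["residual"] * np.eye(8))
        ll_full = reml_loglik_via_contrasts(y, V_full)
        s2_null = float(np.var(y, ddof=1))
        ll_null = reml_loglik_via_contrasts(y, s2_null * np.eye(8))
        assert t.chisq == pytest.approx(2 * (ll_full - ll_null), abs=1e-3)

    def test_null_genotype_variance_gives_small_chisq(self):
        rng = np.random.default_rng(18)
        chis = []
        for rep in range(10):
            df = pd.DataFrame({
                "genotype": np.repeat([f"g{i}" for i in range(15)], 4),
                "block": list(np.tile([f"b{j}" for j in range(4)], 15)),
                "value": rng.normal(0, 1, 60),
            })
            t = lrt_random_effect(df, "value", ["genotype", "block"],
                                   "genotype")
            chis.append(t.chisq)
        assert np.median(chis) < 1.0
        assert stats.chi2.sf(np.median(chis), 1) > 0.3

    def test_interaction_power_with_injected_gxe(self):
        # genotype x year SD equal to residual SD: LRT should flag the
        # interaction in nearly all replicates at this size
        rng = np.random.default_rng(19)
        hits = 0
        reps = 10
        for _ in range(reps):
            ng, ny, m = 20, 2, 2
            gx = rng.normal(0, 1.0, (ng, ny))
            rows = []
            for i in range(ng):
                for yidx in range(ny):
                    for k in range(m):
                        rows.append((f"g{i}", f"y{yidx}",
                                     gx[i, yidx] + rng.normal(0, 1.0)))
            df = pd.DataFrame(rows, columns=["genotype", "year", "value"])
            t = lrt_random_effect(
                df, "value", ["genotype", "year", ("genotype", "year")],
                ("genotype", "year"),
            )
            hits += t.pvalue < 0.05
        assert hits >= int(0.75 * reps)

    def test_non_nested_spec_rejected(self):
        df = balanced_one_way(ng=6, m=2)
        with pytest.raises(ValueError):
            lrt_random_effect(df, "value", ["genotype"], "block")

    def test_report_layout(self):
        df = balanced_one_way(ng=10, m=3, seed=20)
        rep = random_effects_table(df, "value", ["genotype", "block"])
        assert list(rep.columns) == ["effect", "chisq", "df", "pvalue", "signif"]
        assert set(rep["effect"]) == {"genotype", "block"}
        assert (rep["chisq"] >= 0).all()

    def test_significance_codes(self):
        assert significance_code(0.0001) == "***"
        assert significance_code(0.004) == "**"
        assert significance_code(0.04) == "*"
        assert significance_code(0.07) == "."
        assert significance_code(0.5) == "NS"
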