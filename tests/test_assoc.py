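import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from partbias import assoc, combine, popsim


def _random_gwas_data(seed, n=2500, m=8):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, rng.uniform(0.15, 0.5, m), size=(n, m))
    sex = rng.integers(0, 2, n)
    y = rng.binomial(1, 0.25 + 0.1 * sex)
    return G, sex, y


class TestLogisticGwas:
    def test_two_by_two_closed_form(self):
        # carrier-coded table: a=40, b=10, c=30, d=20
        g = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(40), np.zeros(10), np.ones(30), np.zeros(20)].astype(int)
        res = assoc.logistic_gwas(y, g[:, None], min_count=1)
        assert abs(res.beta[0] - np.log(40 * 20 / (10 * 30))) < 1e-6
        assert abs(res.beta[0] - 0.9808) < 1e-4
        assert abs(res.se[0] - np.sqrt(1 / 40 + 1 / 10 + 1 / 30 + 1 / 20)) < 1e-6
        assert abs(res.se[0] - 0.4564) < 1e-4

    @pytest.mark.parametrize("with_sex_covariate", [False, True])
    def test_matches_reference_glm(self, with_sex_covariate):
        G, sex, y = _random_gwas_data(0)
        cov = sex if with_sex_covariate else None
        res = assoc.logistic_gwas(y, G, covariates=cov, min_count=1)
        for j in range(G.shape[1]):
            X = np.column_stack(
                [np.ones(len(y)), G[:, j]] + ([sex] if with_sex_covariate else [])
            )
            ref = sm.Logit(y, X).fit(disp=0)
            assert abs(res.beta[j] - ref.params[1]) < 1e-6
            assert abs(res.se[j] - ref.bse[1]) < 1e-6

    def test_continuous_covariate_path_matches_reference(self):
        """A non-binary covariate forces the individual-level IRLS path;
        results must still match the reference GLM."""
        G, sex, y = _random_gwas_data(1, n=800, m=4)
        age = np.random.default_rng(2).normal(0, 1, 800)
        res = assoc.logistic_gwas(y, G, covariates=age, min_count=1)
        for j in range(G.shape[1]):
            X = np.column_stack([np.ones(800), G[:, j], age])
            ref = sm.Logit(y, X).fit(disp=0)
            assert abs(res.beta[j] - ref.params[1]) < 1e-6
            assert abs(res.se[j] - ref.bse[1]) < 1e-6

    def test_exchangeable_null_beta_small(self, rng):
        G, _, y = _random_gwas_data(3, n=4000, m=6)
        y = rng.permutation(y)
        res = assoc.logistic_gwas(y, G)
        assert (res.beta.abs() < 4 * res.se).all()

    def test_monomorphic_and_sparse_variants_flagged(self):
        rng = np.random.default_rng(4)
        n = 500
        G = np.column_stack(
            [
                np.ones(n, dtype=int),                     # monomorphic
                rng.binomial(2, 0.3, n),                   # fine
                np.r_[np.ones(2, dtype=int), np.zeros(n - 2, dtype=int)],  # sparse
            ]
        )
        y = rng.integers(0, 2, n)
        res = assoc.logistic_gwas(y, G, min_count=5)
        assert list(res.status) == ["monomorphic", "ok", "low_count"]
        infl = assoc.inflation_summary(res)
        assert infl.n_variants == 1

    def test_wald_identity(self):
        G, sex, y = _random_gwas_data(5)
        res = assoc.logistic_gwas(y, G, covariates=sex)
        ok = res[res.status == "ok"]
        assert np.allclose(ok.chi2, (ok.beta / ok.se) ** 2, atol=1e-10)
        assert (ok.se > 0).all()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        G = rng.binomial(2, rng.uniform(0.2, 0.5, 400), size=(3000, 400))
        y = rng.integers(0, 2, 3000)
        res = assoc.logistic_gwas(y, G)
        pvals = res[res.status == "ok"].p.to_numpy()
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError):
            assoc.logistic_gwas(np.array([0, 1, 2]), np.zeros((3, 1)))


class TestLinearGwas:
    def test_perfect_fit_flagged(self):
        g = np.random.default_rng(7).binomial(2, 0.4, 200)
        res = assoc.linear_gwas(3.0 * g, g[:, None].astype(float))
        assert res.status[0] == "zero_residual"

    def test_null_mean_chi2(self):
        rng = np.random.default_rng(8)
        G = rng.binomial(2, rng.uniform(0.2, 0.5, 1000), size=(500, 1000)).astype(float)
        y = rng.normal(0, 1, 500)
        res = assoc.linear_gwas(y, G)
        assert abs(res.chi2.mean() - 1.0) < 4 * np.sqrt(2 / 1000)

    def test_linear_to_logistic_scale_factor(self):
        """At prevalence 0.5 and small effect, linear beta ~ 0.25 x logistic
        beta (the logistic density at p = 0.5)."""
        rng = np.random.default_rng(9)
        n = 200_000
        g = rng.binomial(2, 0.3, n)
        y = rng.binomial(1, 0.5 + 0.02 * (g - 0.6))
        lin = assoc.linear_gwas(y, g[:, None].astype(float))
        log = assoc.logistic_gwas(y, g[:, None])
        assert lin.beta[0] == pytest.approx(0.25 * log.beta[0], rel=0.05)

    def test_zero_variance_outcome_rejected(self):
        with pytest.raises(ValueError):
            assoc.linear_gwas(np.ones(10), np.zeros((10, 1)))


class TestCohortLevelScans:
    def test_sex_gwas_requires_participation_and_both_sexes(self):
        cfg = popsim.PopulationConfig(200, 3, maf=0.3, seed=10)
        cohort = popsim.simulate_cohort(cfg)
        with pytest.raises(ValueError):
            assoc.run_sex_gwas(cohort)
        cohort.participation = (cohort.sex == 1).astype(np.int8)
        with pytest.raises(ValueError):
            assoc.run_sex_gwas(cohort)

    def test_sex_gwas_emits_summary(self, cohort_with_participation):
        cohort, _ = cohort_with_participation
        res, infl = assoc.run_sex_gwas(cohort)
        assert len(res) == cohort.n_variants
        assert infl.n_variants > 0 and infl.ratio > 0

    def test_trait_gwas_modes(self, cohort_with_participation):
        cohort, _ = cohort_with_participation
        rng = np.random.default_rng(11)
        cohort.traits["flip"] = rng.integers(0, 2, cohort.n_individuals).astype(np.int8)
        comb = assoc.run_trait_gwas(cohort, "flip", mode="combined")
        strat = assoc.run_trait_gwas(cohort, "flip", mode="stratified")
        assert set(comb.stratum) == {"combined"}
        assert set(strat.stratum) == {"female", "male"}
        assert len(strat) == 2 * cohort.n_variants
        with pytest.raises(ValueError):
            assoc.run_trait_gwas(cohort, "flip", mode="bogus")

    def test_small_stratum_flagged(self):
        cfg = popsim.PopulationConfig(300, 3, maf=0.3, male_fraction=0.05, seed=12)
        cohort = popsim.simulate_cohort(cfg)
        cohort.traits["t"] = np.random.default_rng(13).integers(
            0, 2, 300
        ).astype(np.int8)
        cohort.participation = np.ones(300, dtype=np.int8)
        strat = assoc.run_trait_gwas(cohort, "t", mode="stratified", min_stratum=50)
        male_rows = strat[strat.stratum == "male"]
        assert (male_rows.status == "small_stratum").all()
        # a variant with one valid stratum meta-analyzes to that stratum
        meta = combine.meta_analyze(strat)
        fem = strat[strat.stratum == "female"].reset_index(drop=True)
        ok = fem.status == "ok"
        assert np.allclose(meta.beta[ok], fem.beta[ok])
        assert np.allclose(meta.se[ok], fem.se[ok])


class TestSumstatsIO:
    def test_roundtrip_12_significant_digits(self, tmp_path):
        G, sex, y = _random_gwas_data(14)
        res = assoc.logistic_gwas(y, G, covariates=sex)
        res.loc[0, ["beta", "se", "chi2", "p"]] = np.nan
        res.loc[0, "status"] = "monomorphic"
        path = tmp_path / "sumstats.tsv"
        assoc.write_sumstats(res, path)
        back = assoc.read_sumstats(path)
        assert list(back.columns) == assoc.GWAS_COLUMNS
        for col in ("beta", "se", "chi2", "p"):
            a, b = res[col].to_numpy(), back[col].to_numpy()
            both = np.isfinite(a) & np.isfinite(b)
            assert np.array_equal(np.isfinite(a), np.isfinite(b))
            assert np.allclose(a[both], b[both], rtol=1e-11, atol=0)
        assert list(back.status) == list(res.status)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"variant_id": ["v0"], "beta": [0.1]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError):
            assoc.read_sumstats(path)
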