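import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qstkit.env_assoc import (
    environmental_distance,
    he_env_correlation,
    mmrr,
    pairwise_qst,
    soil_pca,
    standardize,
    trait_env_model,
)
from qstkit.synthetic_data import SimDesign, simulate_phenotypes
from conftest import nested_trait_data


class TestSoilPCA:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = soil_pca(df)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_standardization_postcondition(self, rng):
        df = pd.DataFrame(rng.normal(10, 5, size=(8, 4)), columns=list("abcd"))
        z = standardize(df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_eigenvalues_match_direct_oracle(self):
        df = pd.DataFrame({
            "a": [1.0, 2.0, 4.0, 3.0],
            "b": [2.0, 1.0, 5.0, 2.0],
            "c": [0.5, 0.7, 0.2, 0.9],
        })
        res = soil_pca(df)
        corr = np.corrcoef(standardize(df).to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(res.pct_variance, evals / evals.sum() * 100, atol=1e-8)

    def test_scores_uncorrelated(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 5)))
        res = soil_pca(df)
        c = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        off = c[np.triu_indices_from(c, k=1)]
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = soil_pca(df)
        assert "const" not in res.loadings.index


class TestClineModels:
    def test_strong_slope_detected_and_intercept_equivariance(self):
        d = SimDesign(n_pop=22, lineage_partition=(11, 11), pc1_slope=1.0, seed=30)
        pops = d.population_ids()
        # shuffle scores across populations so the cline is not confounded
        # with lineage membership
        pc = pd.Series(
            np.random.default_rng(99).permutation(np.linspace(-2, 2, 22)), index=pops
        )
        df = simulate_phenotypes(d, pc1=pc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res, slopes = trait_env_model(df, "trait1", pc, variant="overall")
        assert slopes.loc["pc", "p"] < 0.05
        # adding a constant to the trait shifts only the intercept
        df2 = df.copy()
        df2["trait1"] = df2["trait1"] + 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2, slopes2 = trait_env_model(df2, "trait1", pc, variant="overall")
        # numerically identical up to REML optimizer tolerance
        assert slopes2.loc["pc", "estimate"] == pytest.approx(
            slopes.loc["pc", "estimate"], rel=1e-2
        )

    def test_per_treatment_variant_reports_interaction(self):
        d = SimDesign(n_pop=10, lineage_partition=(5, 5), seed=31)
        pc = pd.Series(np.linspace(-1, 1, 10), index=d.population_ids())
        df = simulate_phenotypes(d, pc1=pc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, slopes = trait_env_model(df, "trait1", pc,
                                        variant="per-treatment", treatment="T0")
        assert any(n.startswith("pc:lineage") for n in slopes.index)

    def test_missing_pc_score_raises(self, rng):
        df = nested_trait_data(rng)
        pc = pd.Series([0.0], index=["pop0"])
        with pytest.raises(ValueError, match="no PC score"):
            trait_env_model(df, "y", pc)


class TestHeCorrelation:
    def test_perfect_correlation(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, p = he_env_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        he = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        pc = pd.Series([2.0, 4.0, 5.0, 9.0], index=list("abcd"))
        r, p = he_env_correlation(he, pc)
        rr, pp = stats.pearsonr(he, pc)
        assert (r, p) == (pytest.approx(rr), pytest.approx(pp))

    def test_null_p_uniform(self):
        rng = np.random.default_rng(32)
        pvals = []
        for _ in range(500):
            he = pd.Series(rng.normal(size=22))
            pc = pd.Series(rng.normal(size=22))
            pvals.append(he_env_correlation(he, pc)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            he_env_correlation(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))


class TestPairwiseQst:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(33)
        vals = []
        for _ in range(20):
            df = nested_trait_data(rng, n_pop=2, n_fam=5, n_off=5, v_ap=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = pairwise_qst(df, "y")
            vals.append(m.iloc[0, 1])
        # occasional 2-group REML non-convergence yields missing entries
        assert np.nanmedian(vals) < 0.1

    def test_symmetric_zero_diagonal(self, rng):
        df = nested_trait_data(rng, n_pop=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pairwise_qst(df, "y")
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 0.0)

    def test_balanced_pair_matches_anova_oracle(self):
        rng = np.random.default_rng(34)
        df = nested_trait_data(rng, n_pop=2, n_fam=6, n_off=8,
                               v_ap=3.0, v_wp=0.5, v_res=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pairwise_qst(df, "y")
        # balanced nested ANOVA components
        n_off, n_fam, k = 8, 6, 2
        fam = df.groupby(["population_id", "seed_family_id"])["y"].mean()
        popm = df.groupby("population_id")["y"].mean()
        grand = df["y"].mean()
        msp = n_off * n_fam * ((popm - grand) ** 2).sum() / (k - 1)
        msf = n_off * ((fam - fam.index.get_level_values(0).map(popm)) ** 2).sum() / (
            k * (n_fam - 1)
        )
        msw = (
            (df.set_index(["population_id", "seed_family_id"])["y"] - fam).pow(2).sum()
            / (k * n_fam * (n_off - 1))
        )
        s2f = max((msf - msw) / n_off, 0.0)
        s2p = max((msp - msf) / (n_off * n_fam), 0.0)
        oracle = s2p / (s2p + 2 * s2f)
        assert m.iloc[0, 1] == pytest.approx(oracle, abs=1e-3)

    def test_insufficient_families_missing(self, rng):
        df = nested_trait_data(rng, n_pop=3)
        df = df[~((df.population_id == "pop0") & (df.seed_family_id != "pop0_f0"))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pairwise_qst(df, "y")
        assert np.isnan(m.loc["pop0", "pop1"])


class TestMMRR:
    @staticmethod
    def random_sym(rng, n, ids):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_identity_predictor(self, rng):
        dep = self.random_sym(rng, 6, list("ABCDEF"))
        res = mmrr(dep, {"x": dep}, n_perm=99, seed=0)
        assert res.coefficients.loc["x", "coefficient"] == pytest.approx(1.0)
        assert res.coefficients.loc["x", "p"] == pytest.approx(1 / 100)

    def test_coefficients_match_normal_equations(self, rng):
        ids = list("abcde")
        dep = self.random_sym(rng, 5, ids)
        p1 = self.random_sym(rng, 5, ids)
        p2 = self.random_sym(rng, 5, ids)
        res = mmrr(dep, {"u": p1, "v": p2}, n_perm=9, seed=0,
                   standardize_matrices=False)
        i, j = np.tril_indices(5, -1)
        X = np.column_stack([np.ones(10), p1.to_numpy()[i, j], p2.to_numpy()[i, j]])
        beta = np.linalg.solve(X.T @ X, X.T @ dep.to_numpy()[i, j])
        np.testing.assert_allclose(res.coefficients["coefficient"], beta, atol=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(35)
        ids = [f"p{i}" for i in range(7)]
        pred = self.random_sym(rng, 7, ids)
        pvals = []
        for _ in range(300):
            dep = self.random_sym(rng, 7, ids)
            res = mmrr(dep, {"x": pred}, n_perm=99, seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.coefficients.loc["x", "p"])
        # discrete (m+1)-point null; compare against its own discrete CDF
        assert stats.kstest(pvals, lambda q: np.clip(np.floor(q * 100) / 100, 0, 1)).pvalue > 0.01

    def test_collinear_predictors_named(self, rng):
        ids = list("abcde")
        p1 = self.random_sym(rng, 5, ids)
        dep = self.random_sym(rng, 5, ids)
        with pytest.raises(ValueError, match="u.*v|collinear"):
            mmrr(dep, {"u": p1, "v": p1 * 1.0}, n_perm=9, seed=0)

    def test_too_few_populations(self, rng):
        ids = list("abc")
        dep = self.random_sym(rng, 3, ids)
        with pytest.raises(ValueError, match="at least 4"):
            mmrr(dep, {"x": dep}, n_perm=9)


class TestEnvironmentalDistance:
    def test_identical_rows_zero(self):
        soil = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [3.0, 3.0, 1.0]},
                            index=["p1", "p2", "p3"])
        d = environmental_distance(soil)
        assert d.loc["p1", "p2"] == pytest.approx(0.0)

    def test_hand_computed_euclidean(self):
        soil = pd.DataFrame({
            "a": [0.0, 2.0, 1.0, 4.0],
            "b": [1.0, 0.0, 3.0, 2.0],
            "c": [5.0, 1.0, 2.0, 0.0],
        }, index=list("wxyz"))
        z = standardize(soil).to_numpy()
        expected = np.sqrt(((z[0] - z[1]) ** 2).sum())
        d = environmental_distance(soil)
        assert d.loc["w", "x"] == pytest.approx(expected)
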