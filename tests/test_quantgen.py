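import warnings

import numpy as np
import pandas as pd
import pytest

from qstkit.quantgen import (
    ChainConfig,
    ModelSpec,
    NestedVarianceModel,
    QstModel,
    estimate_qst,
    fit_lmm_gibbs,
    fit_lmm_reml,
    posthoc_contrasts,
    qst_from_components,
)
from qstkit.synthetic_data import SimDesign, simulate_phenotypes
from conftest import nested_trait_data

FAST = ChainConfig(2600, 600, 10)  # 200 retained draws, ample for unit tests


def one_way_data(rng, n_groups=50, n_per=20, v_among=2.0, v_res=1.0):
    """Balanced one-way layout expressed as populations with two families."""
    rows = []
    for g in range(n_groups):
        eff = rng.normal(0, np.sqrt(v_among))
        for i in range(n_per):
            rows.append({
                "individual_id": f"g{g}_{i}",
                "population_id": f"g{g}",
                "seed_family_id": f"g{g}_f{i % 2}",
                "treatment": "T0",
                "y": eff + rng.normal(0, np.sqrt(v_res)),
            })
    return pd.DataFrame(rows)


def anova_components(df, value="y"):
    """Method-of-moments components for the balanced one-way layout."""
    groups = df.groupby("population_id")[value]
    k = groups.ngroups
    n = groups.size().iloc[0]
    grand = df[value].mean()
    msb = n * ((groups.mean() - grand) ** 2).sum() / (k - 1)
    msw = groups.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum() / (k * (n - 1))
    return (msb - msw) / n, msw


class TestGibbsSampler:
    def test_recovers_anova_components(self, rng):
        df = one_way_data(rng)
        spec = ModelSpec("y", fixed=(), random=("population", "family"))
        res = fit_lmm_gibbs(spec, df, chain=FAST, seed=1)
        v_among, v_res = anova_components(df)
        assert res.vcomp["population"] == pytest.approx(v_among, rel=0.15)
        # family here is a pure subdivision with no real effect; residual
        # mass splits between family and residual draws
        assert res.vcomp["family"] + res.vcomp["residual"] == pytest.approx(v_res, rel=0.15)

    def test_null_structure_concentrates_at_zero(self, rng):
        df = nested_trait_data(rng, n_pop=20, v_ap=0.0, v_wp=0.0, v_res=0.01)
        res = fit_lmm_gibbs(ModelSpec("y", fixed=()), df, chain=FAST, seed=2)
        assert res.vcomp["population"] < 0.05 * res.vcomp["residual"] + 1e-3

    def test_same_seed_bit_identical(self, rng):
        df = nested_trait_data(rng)
        spec = ModelSpec("y", fixed=())
        a = fit_lmm_gibbs(spec, df, chain=FAST, seed=7)
        b = fit_lmm_gibbs(spec, df, chain=FAST, seed=7)
        pd.testing.assert_frame_equal(a.posterior, b.posterior)

    def test_retained_draw_count_and_positivity(self, rng):
        df = nested_trait_data(rng)
        res = fit_lmm_gibbs(ModelSpec("y", fixed=()), df,
                            chain=ChainConfig(1300, 300, 10), seed=3)
        assert len(res.posterior) == 100
        assert (res.posterior[["population", "family", "residual"]] > 0).all().all()

    def test_aliased_fixed_effect_named(self, rng):
        df = nested_trait_data(rng, treatments=("T0", "T70"))
        df["copy"] = df["treatment"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="aliased"):
            NestedVarianceModel.from_dataframe(
                df, ModelSpec("y", fixed=("treatment", "copy"))
            )


class TestREML:
    def test_balanced_nested_equals_anova(self, rng):
        df = nested_trait_data(rng, n_pop=15, n_fam=5, n_off=6,
                               v_ap=2.0, v_wp=1.0, v_res=0.5)
        res = fit_lmm_reml(ModelSpec("y", fixed=()), df)
        # balanced nested ANOVA closed form
        n_off, n_fam = 6, 5
        fam_means = df.groupby(["population_id", "seed_family_id"])["y"].mean()
        pop_means = df.groupby("population_id")["y"].mean()
        grand = df["y"].mean()
        k = len(pop_means)
        msp = n_off * n_fam * ((pop_means - grand) ** 2).sum() / (k - 1)
        msf = n_off * (
            (fam_means - fam_means.index.get_level_values(0).map(pop_means)) ** 2
        ).sum() / (k * (n_fam - 1))
        cell = df.set_index(["population_id", "seed_family_id"])["y"]
        msw = ((cell - cell.index.map(fam_means)) ** 2).sum() / (k * n_fam * (n_off - 1))
        s2_res = msw
        s2_fam = (msf - msw) / n_off
        s2_pop = (msp - msf) / (n_off * n_fam)
        assert res.vcomp["residual"] == pytest.approx(s2_res, rel=1e-4)
        assert res.vcomp["family"] == pytest.approx(s2_fam, rel=1e-4)
        assert res.vcomp["population"] == pytest.approx(s2_pop, rel=1e-4)

    def test_zero_variance_hits_boundary(self, rng):
        # every population carries an identical copy of the same family data,
        # so the among-population variance is exactly zero by construction
        one = nested_trait_data(rng, n_pop=1, n_fam=4, n_off=5, v_ap=0.0)
        copies = []
        for p in range(6):
            c = one.copy()
            for col in ("individual_id", "population_id", "seed_family_id"):
                c[col] = c[col].str.replace("pop0", f"pop{p}", regex=False)
            copies.append(c)
        df = pd.concat(copies, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lmm_reml(ModelSpec("y", fixed=()), df)
        assert res.vcomp["population"] == pytest.approx(0.0, abs=1e-6)

    def test_reml_and_gibbs_agree_on_average(self):
        rng = np.random.default_rng(5)
        rels = []
        for _ in range(30):
            s = int(rng.integers(2**31 - 1))
            df = simulate_phenotypes(
                SimDesign(n_pop=12, lineage_partition=(12,), seed=s)
            )
            model = NestedVarianceModel.from_dataframe(df, ModelSpec("trait1"))
            gib = model.fit_gibbs(chain=FAST, seed=s + 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rem = model.fit_reml()
            for c in ("population", "family", "residual"):
                if rem.vcomp[c] > 1e-6:
                    rels.append(abs(gib.vcomp[c] - rem.vcomp[c]) / rem.vcomp[c])
        assert np.mean(rels) < 0.10

    def test_label_permutation_leaves_reml_unchanged(self, rng):
        df = nested_trait_data(rng, n_pop=8)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_lmm_reml(ModelSpec("y", fixed=()), df)
        b = fit_lmm_reml(ModelSpec("y", fixed=()), shuffled)
        for c in ("population", "family", "residual"):
            assert a.vcomp[c] == pytest.approx(b.vcomp[c], rel=1e-5, abs=1e-8)


class TestQst:
    @pytest.mark.parametrize(
        "v_ap, v_wp, expected",
        [(0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (2.0, 1.0, 0.5)],
    )
    def test_ratio(self, v_ap, v_wp, expected):
        assert qst_from_components(v_ap, v_wp) == expected

    def test_undefined_and_invalid(self):
        assert np.isnan(qst_from_components(0.0, 0.0))
        with pytest.raises(ValueError):
            qst_from_components(-1.0, 1.0)

    def test_draws_bounded_and_near_truth(self):
        df = simulate_phenotypes(SimDesign(seed=12))
        res = QstModel(df, "trait1").fit(seed=13, chain=FAST)
        assert ((res.draws >= 0) & (res.draws <= 1)).all()
        assert res.median == pytest.approx(1 / 3, abs=0.15)
        lo, hi = res.ci
        assert lo < res.median < hi

    def test_null_v_ap_gives_small_qst(self):
        df = simulate_phenotypes(SimDesign(v_ap=0.0, seed=14))
        res = QstModel(df, "trait1").fit(seed=15, chain=FAST)
        assert res.median < 0.1

    def test_per_treatment_guards(self):
        df = simulate_phenotypes(SimDesign(seed=16))
        with pytest.raises(ValueError, match="treatment"):
            QstModel(df, "trait1", "per-treatment", treatment="T999")
        out = estimate_qst(df, "trait1", "per-treatment", seed=17, chain=FAST)
        assert set(out) == {"T0", "T70", "T150"}

    def test_small_lineage_refused(self):
        df = simulate_phenotypes(SimDesign(seed=18))  # partition (8, 11, 3)
        with pytest.raises(ValueError, match="4"):
            QstModel(df, "trait1", "per-lineage", lineage="L3")
        out = estimate_qst(df, "trait1", "per-lineage", seed=19, chain=FAST)
        assert set(out) == {"L1", "L2"}


class TestPosthoc:
    def test_three_levels_three_rows(self):
        df = simulate_phenotypes(SimDesign(seed=20, treatment_effects=(0.0, 3.0, 6.0)))
        model = NestedVarianceModel.from_dataframe(df, ModelSpec("trait1"))
        res = model.fit_gibbs(chain=FAST, seed=21)
        table = posthoc_contrasts(res, "treatment")
        assert len(table) == 3
        assert table["significant"].all()

    def test_reml_contrasts_with_holm(self):
        df = simulate_phenotypes(SimDesign(seed=22, treatment_effects=(0.0, 0.0, 5.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NestedVarianceModel.from_dataframe(df, ModelSpec("trait1")).fit_reml()
        table = posthoc_contrasts(res, "treatment")
        big = table[(table.level_1 == "T0") & (table.level_2 == "T150")]
        assert big["p_holm"].iloc[0] < 0.01

    def test_null_contrast_mostly_insignificant(self):
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(25):
            s = int(rng.integers(2**31 - 1))
            df = simulate_phenotypes(
                SimDesign(n_pop=8, lineage_partition=(8,), treatment_effects=(0.0, 0.0, 0.0), seed=s)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = NestedVarianceModel.from_dataframe(df, ModelSpec("trait1")).fit_reml()
            hits += posthoc_contrasts(res, "treatment")["significant"].any()
        assert hits <= 6  # nominal familywise 5%; generous binomial slack

    def test_single_level_factor_empty(self, rng):
        df = nested_trait_data(rng)
        res = NestedVarianceModel.from_dataframe(
            df, ModelSpec("y", fixed=("treatment",))
        )
        # 'treatment' has one level -> no contrast rows
        fit = res.fit_gibbs(chain=ChainConfig(600, 100, 5), seed=1)
        assert posthoc_contrasts(fit, "treatment").empty
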