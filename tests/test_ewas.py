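"""EWAS screens, Stouffer combination, selection and summary rules."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methclock.errors import ComputationError, ValidationError
from methclock.ewas import (
    ewas_covariate,
    region_distribution,
    screen_numeric_trait,
    select_top_cpgs,
    set_overlap,
    stouffer_meta,
)


def _random_betas(n_cpgs, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(n_cpgs, n_samples)),
        index=pd.Index([f"cpg{i:04d}" for i in range(n_cpgs)], name="cpg_id"),
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )


class TestScreenNumericTrait:
    def test_self_correlated_probe_tops_the_table(self):
        betas = _random_betas(20, 30)
        trait = betas.iloc[0].to_numpy()
        table = screen_numeric_trait(betas, trait)
        assert table.loc["cpg0000", "statistic"] == pytest.approx(1.0)
        assert table.loc["cpg0000", "p"] < 1e-12

    def test_closed_form_r_half_n_27(self):
        # r = 0.5 at n = 27: t = 2.886751, two-sided p = 0.0079127
        n = 27
        rng = np.random.default_rng(5)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=n)
        e -= e.mean() + x * (e @ x) / n  # orthogonalize
        e /= e.std()
        y = 0.5 * x + math.sqrt(0.75) * e  # exact sample correlation 0.5
        beta_row = 0.5 + 0.1 * y
        betas = pd.DataFrame([beta_row], index=pd.Index(["cpg0"], name="cpg_id"))
        table = screen_numeric_trait(betas, x)
        assert table.loc["cpg0", "statistic"] == pytest.approx(0.5, abs=1e-12)
        assert table.loc["cpg0", "p"] == pytest.approx(0.007912738358, rel=1e-6)
        assert table.loc["cpg0", "z"] == pytest.approx(2.65577076, rel=1e-6)

    def test_agrees_with_scipy_pearsonr(self):
        betas = _random_betas(50, 25, seed=3)
        trait = np.random.default_rng(4).normal(size=25)
        table = screen_numeric_trait(betas, trait)
        for cpg in ["cpg0000", "cpg0007", "cpg0049"]:
            ref = stats.pearsonr(betas.loc[cpg], trait)
            assert table.loc[cpg, "statistic"] == pytest.approx(ref.statistic)
            assert table.loc[cpg, "p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_calibration_at_permissive_threshold(self):
        betas = _random_betas(2000, 40, seed=9)
        trait = np.random.default_rng(10).normal(size=40)
        table = screen_numeric_trait(betas, trait)
        frac = (table["p"] < 0.005).mean()
        tol = 3 * math.sqrt(0.005 * 0.995 / 2000)
        assert abs(frac - 0.005) <= tol

    def test_constant_probe_flagged(self):
        betas = _random_betas(5, 20)
        betas.iloc[2] = 0.4
        table = screen_numeric_trait(betas, np.arange(20.0))
        assert table.loc["cpg0002", "flagged"]
        assert table.loc["cpg0002", "p"] == 1.0
        assert table.loc["cpg0002", "z"] == 0.0

    def test_constant_trait_rejected(self):
        with pytest.raises(ComputationError):
            screen_numeric_trait(_random_betas(5, 10), np.full(10, 3.0))


class TestEwasCovariate:
    def test_injected_group_effect_ranks_top(self):
        rng = np.random.default_rng(2)
        n = 60
        group = np.repeat([0, 1], n // 2)
        betas = _random_betas(500, n, seed=2)
        betas.iloc[0] = np.clip(0.4 + 0.2 * group + rng.normal(0, 0.02, n), 0, 1)
        table = ewas_covariate(betas, group)
        rank = (table["z"].abs() >= abs(table.loc["cpg0000", "z"])).mean()
        assert rank <= 0.01

    def test_matches_correlation_screen_without_covariates(self):
        # simple regression t-test == correlation t-test
        betas = _random_betas(100, 30, seed=6)
        group = np.random.default_rng(7).integers(0, 2, 30)
        a = ewas_covariate(betas, group)
        b = screen_numeric_trait(betas, group.astype(float))
        assert np.max(np.abs(a["p"] - b["p"])) < 1e-10

    def test_age_covariate_removes_confounded_age_signal(self):
        # group correlated with age; age CpGs should drop in rank once adjusted
        rng = np.random.default_rng(8)
        n = 80
        age = rng.uniform(0, 15, n)
        group = (age > np.median(age)).astype(int)
        betas = _random_betas(300, n, seed=8)
        for i in range(10):  # age CpGs, not group CpGs
            betas.iloc[i] = np.clip(0.2 + 0.04 * age + rng.normal(0, 0.03, n), 0, 1)
        raw = ewas_covariate(betas, group)
        adj = ewas_covariate(betas, group, covariates=pd.DataFrame({"age": age}))
        age_ids = [f"cpg{i:04d}" for i in range(10)]
        raw_rank = raw["z"].abs().rank(ascending=False)[age_ids].mean()
        adj_rank = adj["z"].abs().rank(ascending=False)[age_ids].mean()
        assert adj_rank > raw_rank

    def test_null_group_p_values_uniform(self):
        betas = _random_betas(2000, 40, seed=12)
        group = np.random.default_rng(13).integers(0, 2, 40)
        table = ewas_covariate(betas, group)
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_collinear_design_named(self):
        betas = _random_betas(10, 20)
        group = np.repeat([0, 1], 10)
        cov = pd.DataFrame({"dup": group.astype(float)})
        with pytest.raises(ValidationError, match="collinear"):
            ewas_covariate(betas, group, covariates=cov)


class TestStouffer:
    def test_single_stratum_identity(self):
        z = pd.DataFrame({"blood": [1.3, -0.2, 4.0]})
        out = stouffer_meta(z)
        assert np.allclose(out, z["blood"])

    def test_two_equal_strata_closed_form(self):
        z = pd.DataFrame({"a": [1.96], "b": [1.96]})
        assert stouffer_meta(z).iloc[0] == pytest.approx(2.7718585822512662)

    def test_opposite_signs_cancel(self):
        z = pd.DataFrame({"a": [2.5], "b": [-2.5]})
        assert stouffer_meta(z).iloc[0] == pytest.approx(0.0)

    def test_k_identical_strata_scale_by_sqrt_k(self):
        for k in (2, 3, 5):
            z = pd.DataFrame({f"t{i}": [1.1, -0.7] for i in range(k)})
            out = stouffer_meta(z)
            assert np.allclose(out, np.array([1.1, -0.7]) * math.sqrt(k), atol=1e-10)

    def test_missing_stratum_renormalized(self):
        z = pd.DataFrame({"a": [2.0, 2.0], "b": [2.0, np.nan]})
        out = stouffer_meta(z)
        assert out.iloc[0] == pytest.approx(4.0 / math.sqrt(2))
        assert out.iloc[1] == pytest.approx(2.0)

    def test_sqrt_n_weights(self):
        z = pd.DataFrame({"a": [1.0], "b": [1.0]})
        out = stouffer_meta(z, weights=[math.sqrt(90), math.sqrt(10)])
        expected = (math.sqrt(90) + math.sqrt(10)) / math.sqrt(100)
        assert out.iloc[0] == pytest.approx(expected)


class TestSelectTopCpgs:
    def _table(self, ps, zs=None, ids=None):
        n = len(ps)
        ids = ids or [f"cpg{i:04d}" for i in range(n)]
        zs = zs if zs is not None else np.linspace(5, 1, n)
        return pd.DataFrame(
            {"statistic": zs, "z": zs, "p": ps},
            index=pd.Index(ids, name="cpg_id"),
        )

    def test_strict_threshold(self):
        table = self._table([0.001, 0.004, 0.005, 0.01, 0.5])
        out = select_top_cpgs(table)
        assert set(out.index) == {"cpg0000", "cpg0001"}

    def test_per_direction_cap(self):
        n = 600
        table = self._table([0.001] * n, zs=np.linspace(10, 1, n))
        out = select_top_cpgs(table, max_per_direction=500)
        assert len(out) == 500
        assert out["z"].min() >= np.sort(table["z"])[99]  # the 500 largest kept

    def test_directions_capped_independently(self):
        zs = np.concatenate([np.linspace(5, 2, 30), -np.linspace(5, 2, 20)])
        table = self._table([0.001] * 50, zs=zs)
        out = select_top_cpgs(table, max_per_direction=10)
        assert (out["direction"] == 1).sum() == 10
        assert (out["direction"] == -1).sum() == 10

    def test_empty_result_allowed(self):
        out = select_top_cpgs(self._table([0.5, 0.9]))
        assert len(out) == 0

    def test_invariant_to_row_order(self):
        table = self._table([0.001] * 20, zs=np.linspace(4, 2, 20))
        shuffled = table.sample(frac=1, random_state=1)
        a = select_top_cpgs(table, max_per_direction=5)
        b = select_top_cpgs(shuffled, max_per_direction=5)
        pd.testing.assert_frame_equal(a, b)


class TestRegionDistribution:
    def test_set_equal_to_background_matches_proportions(self, toy_annotation):
        out = region_distribution(toy_annotation["cpg_id"], toy_annotation)
        assert np.allclose(out["foreground_prop"], out["background_prop"])

    def test_promoter_enrichment_exact_hypergeometric(self, toy_annotation):
        # 4 of 5 promoters, background 10/100:
        # P(X>=4) = (C(10,4)C(90,1) + C(10,5)) / C(100,5)
        fg = toy_annotation["cpg_id"][:4].tolist() + ["cpg050"]
        out = region_distribution(fg, toy_annotation)
        expected = (math.comb(10, 4) * math.comb(90, 1) + math.comb(10, 5)) / math.comb(100, 5)
        assert out.loc["promoter", "p_enrichment"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.5438479e-4, rel=1e-6)

    def test_empty_set_gives_zero_counts(self, toy_annotation):
        out = region_distribution([], toy_annotation)
        assert (out["foreground_count"] == 0).all()
        assert "p_enrichment" not in out.columns

    def test_unannotated_members_rejected(self, toy_annotation):
        with pytest.raises(ValidationError, match="ghost"):
            region_distribution(["ghost"], toy_annotation)


class TestSetOverlap:
    def test_disjoint_sets(self):
        out = set_overlap({"A": {1, 2, 3}, "B": {4, 5, 6, 7}})
        assert out == {frozenset({"A"}): 3, frozenset({"B"}): 4}

    def test_identical_sets(self):
        out = set_overlap({"A": {1, 2, 3, 4, 5}, "B": {1, 2, 3, 4, 5}})
        assert out == {frozenset({"A", "B"}): 5}

    def test_three_way_exclusive_counts(self):
        out = set_overlap({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}})
        assert out == {
            frozenset({"A"}): 1,
            frozenset({"B"}): 1,
            frozenset({"A", "B"}): 1,
            frozenset({"A", "B", "C"}): 1,
        }

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(0)
        sets = {n: set(rng.integers(0, 50, 20).tolist()) for n in "ABCD"}
        out = set_overlap(sets)
        assert sum(out.values()) == len(set().union(*sets.values()))

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            set_overlap({"A": {1}})
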