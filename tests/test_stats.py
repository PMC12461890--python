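import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from _oracles import anova_ss_oracle, pearson_oracle
from vacquant.stats import (
    DesignError,
    correlation_matrix,
    critical_r,
    sqrt_transform,
    tukey_oneway,
    two_way_anova,
    validation_report,
)


def balanced_table(n_genotypes=2, n_raters=6, n_cell=30, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genotypes):
        for r in range(n_raters):
            base = 5.0 + (shift[g] if shift is not None else 0.0)
            for _ in range(n_cell):
                rows.append(
                    {
                        "section_id": f"s{len(rows)}",
                        "genotype": f"g{g}",
                        "rater_id": f"r{r}",
                        "percent": float(
                            np.clip(base + rng.normal(0, 1.5), 0, 100)
                        ),
                    }
                )
    return pd.DataFrame(rows)


class TestSqrtTransform:
    def test_values_and_composition(self):
        table = balanced_table(n_cell=2, seed=1)
        table.loc[0, "percent"] = 25.0
        table.loc[1, "percent"] = 0.0
        out = sqrt_transform(table)
        assert out.loc[0, "percent"] == 5.0
        assert out.loc[1, "percent"] == 0.0
        twice = sqrt_transform(out)
        np.testing.assert_allclose(
            twice["percent"], table["percent"] ** 0.25, atol=1e-12
        )
        # input table untouched
        assert table.loc[0, "percent"] == 25.0


class TestTwoWayAnova:
    def test_all_equal_observations_give_zero_f_and_eta(self):
        table = balanced_table(n_cell=3)
        table["percent"] = 7.0
        res = two_way_anova(table)
        for effect in ("genotype", "rater", "interaction"):
            assert res.table.loc[effect, "F"] == pytest.approx(0.0, abs=1e-10)
            assert res.table.loc[effect, "eta_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_pure_additive_shift_has_zero_interaction(self):
        # 2x2 with n=3 per cell, built from exact additive effects
        rows = []
        for gi, ga in enumerate([0.0, 4.0]):
            for ri, rb in enumerate([0.0, 1.5]):
                for k in range(3):
                    rows.append(
                        {
                            "section_id": f"s{gi}{ri}{k}",
                            "genotype": f"g{gi}",
                            "rater_id": f"r{ri}",
                            "percent": 10.0 + ga + rb + [0.0, 0.5, -0.5][k],
                        }
                    )
        res = two_way_anova(pd.DataFrame(rows))
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ss_oracle(self, seed):
        table = balanced_table(n_genotypes=2, n_raters=6, n_cell=30, seed=seed,
                               shift=[0.0, 2.0])
        res = two_way_anova(table)
        oracle = anova_ss_oracle(
            table["percent"].to_numpy(),
            table["genotype"].to_numpy(),
            table["rater_id"].to_numpy(),
        )
        ss_a, ss_b, ss_ab, ss_resid, ss_total = oracle["ss"]
        t = res.table
        assert t.loc["genotype", "sum_sq"] == pytest.approx(ss_a, rel=1e-8)
        assert t.loc["rater", "sum_sq"] == pytest.approx(ss_b, rel=1e-8)
        assert t.loc["interaction", "sum_sq"] == pytest.approx(ss_ab, rel=1e-8)
        assert t.loc["residual", "sum_sq"] == pytest.approx(ss_resid, rel=1e-8)
        assert tuple(t["df"][:3]) == oracle["df"][:3]
        assert t.loc["residual", "df"] == 348  # 360 - 12, the reference shape
        np.testing.assert_allclose(t["F"][:3], oracle["F"], rtol=1e-8)
        # eta squared components and residual share sum to one
        assert t["eta_sq"].sum() == pytest.approx(1.0, rel=1e-10)

    def test_unbalanced_design_rejected_with_cell_counts(self):
        table = balanced_table(n_cell=3)
        table = table.iloc[:-1]
        with pytest.raises(DesignError, match="cell counts"):
            two_way_anova(table)

    def test_single_factor_level_rejected(self):
        table = balanced_table(n_genotypes=1, n_cell=3)
        with pytest.raises(DesignError):
            two_way_anova(table)


class TestCorrelationMatrix:
    def wide_to_long(self, wide, genotype="g"):
        rows = []
        for sec, row in wide.iterrows():
            for rater, val in row.items():
                rows.append(
                    {
                        "section_id": sec,
                        "genotype": genotype,
                        "rater_id": rater,
                        "percent": val,
                    }
                )
        return pd.DataFrame(rows)

    def test_affine_related_raters_have_r_one(self, rng):
        x = rng.random(10) * 20
        wide = pd.DataFrame(
            {"a": x, "b": 2.5 * x + 1.0}, index=[f"s{i}" for i in range(10)]
        )
        out = correlation_matrix(self.wide_to_long(wide))
        assert out.r.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert out.r.loc["a", "a"] == 1.0
        assert (out.n.values == 10).all()

    def test_matches_textbook_pearson_oracle(self, rng):
        wide = pd.DataFrame(
            rng.random((12, 6)) * 30,
            index=[f"s{i}" for i in range(12)],
            columns=[f"v{i}" for i in range(6)],
        )
        out = correlation_matrix(self.wide_to_long(wide))
        for a in wide.columns:
            for b in wide.columns:
                want = pearson_oracle(wide[a].to_numpy(), wide[b].to_numpy())
                if a == b:
                    want = 1.0
                assert out.r.loc[a, b] == pytest.approx(want, abs=1e-12)
        pd.testing.assert_frame_equal(out.r, out.r.T)

    def test_zero_variance_rater_flagged_not_fatal(self, rng):
        wide = pd.DataFrame(
            {"a": rng.random(8), "flat": np.ones(8)},
            index=[f"s{i}" for i in range(8)],
        )
        out = correlation_matrix(self.wide_to_long(wide))
        assert np.isnan(out.r.loc["a", "flat"])
        assert out.r.loc["flat", "flat"] == 1.0

    def test_human_average_vs_classifier(self, rng):
        truth = 5.0 + rng.random(15) * 20
        wide = pd.DataFrame(
            {
                "volunteer1": truth + rng.normal(0, 1, 15),
                "volunteer2": truth + rng.normal(0, 1, 15),
                "classifier": truth + rng.normal(0, 0.2, 15),
            },
            index=[f"s{i}" for i in range(15)],
        ).clip(0, 100)
        out = correlation_matrix(self.wide_to_long(wide))
        avg = wide[["volunteer1", "volunteer2"]].mean(axis=1)
        want = pearson_oracle(avg.to_numpy(), wide["classifier"].to_numpy())
        assert out.human_avg_vs_classifier == pytest.approx(want, abs=1e-12)

    def test_by_genotype_returns_one_matrix_per_group(self, rng):
        wide_a = pd.DataFrame(
            rng.random((6, 3)), index=[f"a{i}" for i in range(6)],
            columns=["r1", "r2", "classifier"],
        )
        wide_b = pd.DataFrame(
            rng.random((6, 3)), index=[f"b{i}" for i in range(6)],
            columns=["r1", "r2", "classifier"],
        )
        long = pd.concat(
            [self.wide_to_long(wide_a, "ctrl"), self.wide_to_long(wide_b, "tau")]
        )
        out = correlation_matrix(long, by_genotype=True)
        assert set(out) == {"ctrl", "tau"}
        assert (out["ctrl"].n.values == 6).all()


class TestCriticalR:
    def test_t_quantile_formula_at_28_df(self):
        # independent check: integrate the t density to verify the quantile
        for alpha, tails in [(0.05, "two"), (0.01, "two")]:
            r = critical_r(alpha, 28, tails)
            t = r * np.sqrt(28 / (1 - r**2))
            tail_mass, _ = integrate.quad(lambda u: sps.t.pdf(u, 28), t, np.inf)
            assert 2 * tail_mass == pytest.approx(alpha, rel=1e-6)
        assert critical_r(0.05, 28) == pytest.approx(0.3610, abs=5e-4)
        assert critical_r(0.01, 28) == pytest.approx(0.4629, abs=5e-4)

    def test_monotonic_in_df_and_alpha_limit(self):
        assert critical_r(0.05, 10) > critical_r(0.05, 100)
        assert critical_r(0.999, 50) < 0.001
        assert critical_r(0.01, 28) > critical_r(0.05, 28)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            critical_r(0.0, 10)
        with pytest.raises(ValueError):
            critical_r(0.05, 0)
        with pytest.raises(ValueError):
            critical_r(0.05, 10, tails="three")


class TestTukeyOneway:
    def test_clear_separation_detected(self, rng):
        values = np.concatenate(
            [rng.normal(m, 0.5, 8) for m in (1.0, 1.2, 8.0)]
        )
        groups = np.repeat(["ctrl", "wt", "mut"], 8)
        f_stat, p, tukey = tukey_oneway(values, groups)
        assert p < 0.001
        from itertools import combinations

        summary = dict(zip(combinations(tukey.groupsunique, 2), tukey.reject))
        assert summary[("ctrl", "mut")]
        assert not summary[("ctrl", "wt")]


def test_validation_report_contains_all_statistics():
    # a proper crossed design: every rater scores every section
    rng = np.random.default_rng(3)
    rows = []
    for g, base in [("ctrl", 2.0), ("tau", 8.0)]:
        for s in range(10):
            truth = base + rng.normal(0, 1.0)
            for rater in ("r0", "r1", "classifier"):
                rows.append(
                    {
                        "section_id": f"{g}{s}",
                        "genotype": g,
                        "rater_id": rater,
                        "percent": float(np.clip(truth + rng.normal(0, 0.5), 0, 100)),
                    }
                )
    report = validation_report(pd.DataFrame(rows))
    assert "Genotype: F(1," in report
    assert "eta2" in report
    assert "critical r at p = 0.05" in report
    assert "human average vs classifier" in report
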