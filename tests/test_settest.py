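"""Set-level Welch test, Z baseline, q-values and the normality diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpprage.settest import (
    normality_diagnostic,
    prage_set_test,
    qvalues,
    welch_statistic,
    zmethod_set_test,
)
from snpprage.types import GeneSetCollection


def _measures(values, prefix="G"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestWelchStatistic:
    def test_matches_independent_welch_oracle(self):
        x = np.array([1.0, 1.5, 2.0, 2.5])
        y = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        t, df = welch_statistic(x, y)
        oracle = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(oracle.statistic, rel=1e-12)
        assert df == pytest.approx(oracle.df, rel=1e-12)

    def test_satterthwaite_df_equal_groups(self, rng):
        # equal variances and sizes: df = 2(N-1) exactly
        x = rng.standard_normal(12)
        y = x + 5.0  # same variance
        _, df = welch_statistic(x, y)
        assert df == pytest.approx(2 * (12 - 1))

    def test_identical_groups_give_t_zero(self):
        x = np.array([1.0, 2, 3, 4, 5])
        t, _ = welch_statistic(x, x[::-1])
        assert t == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_statistic(np.ones(5), np.ones(4))


class TestPrageSetTest:
    def _sets(self, members):
        return GeneSetCollection(sets={"S1": members})

    def test_identical_distributions_p_half(self):
        vals = _measures([1.0, 2, 3, 4, 5, 5, 4, 3, 2, 1])
        res = prage_set_test(
            vals, self._sets([f"G{i}" for i in range(5)]), min_set_size=2, scale="natural"
        )
        assert res.loc[0, "statistic"] == pytest.approx(0.0)
        assert res.loc[0, "pvalue"] == pytest.approx(0.5)

    def test_welch_values_on_natural_scale(self):
        vals = pd.Series(
            [1.0, 1.5, 2.0, 2.5, 2.0, 3.0, 4.0, 5.0, 6.0],
            index=[f"G{i}" for i in range(9)],
        )
        res = prage_set_test(
            vals, self._sets(["G0", "G1", "G2", "G3"]), min_set_size=2, scale="natural"
        )
        t_o, df_o = welch_statistic(vals.values[:4], vals.values[4:])
        assert res.loc[0, "statistic"] == pytest.approx(t_o)
        assert res.loc[0, "df"] == pytest.approx(df_o)
        assert res.loc[0, "pvalue"] == pytest.approx(stats.t.cdf(t_o, df_o))

    def test_affine_invariance_natural_scale(self, rng):
        vals = _measures(rng.uniform(0.2, 3, 40))
        sets = self._sets([f"G{i}" for i in range(12)])
        a = prage_set_test(vals, sets, scale="natural")
        b = prage_set_test(vals * 3.5 + 1.0, sets, scale="natural")
        for col in ("statistic", "df", "pvalue"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col], rel=1e-10)

    def test_scaling_invariance_log_scale(self, rng):
        vals = _measures(rng.uniform(0.2, 3, 40))
        sets = self._sets([f"G{i}" for i in range(12)])
        a = prage_set_test(vals, sets, scale="log")
        b = prage_set_test(vals * 7.0, sets, scale="log")
        for col in ("statistic", "df", "pvalue"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col], rel=1e-10)

    def test_log_scale_rejects_enriched_small_measures(self, rng):
        null = rng.uniform(0.5, 1.5, 60)
        enriched = rng.uniform(0.01, 0.1, 15)
        vals = _measures(np.r_[enriched, null])
        res = prage_set_test(vals, self._sets([f"G{i}" for i in range(15)]))
        assert res.loc[0, "pvalue"] < 0.001

    def test_small_set_flagged_and_excluded_from_qvalues(self, rng):
        vals = _measures(rng.uniform(0.2, 3, 30))
        sets = GeneSetCollection(sets={"small": ["G0", "G1", "G2"], "big": [f"G{i}" for i in range(3, 18)]})
        res = prage_set_test(vals, sets, min_set_size=10).set_index("set_id")
        assert bool(res.loc["small", "flagged_small"])
        assert np.isnan(res.loc["small", "qvalue"])
        assert np.isfinite(res.loc["big", "qvalue"])

    def test_global_comparison_variant(self, rng):
        vals = _measures(rng.uniform(0.2, 3, 30))
        sets = self._sets([f"G{i}" for i in range(12)])
        res_c = prage_set_test(vals, sets, comparison="complement")
        res_g = prage_set_test(vals, sets, comparison="global")
        assert res_c.loc[0, "statistic"] != res_g.loc[0, "statistic"]

    def test_null_calibration_under_iid_measures(self, rng):
        """Under the global null the fraction of sets with p < alpha stays
        within 3 Monte-Carlo SE of alpha."""
        n_rep, n_genes = 1000, 60
        members = [f"G{i}" for i in range(15)]
        sets = self._sets(members)
        rejections = {0.05: 0, 0.01: 0}
        for _ in range(n_rep):
            vals = _measures(rng.uniform(0.01, 1.0, n_genes) * 5)
            p = prage_set_test(vals, sets).loc[0, "pvalue"]
            for a in rejections:
                rejections[a] += p < a
        for a, hits in rejections.items():
            band = 3 * np.sqrt(a * (1 - a) / n_rep)
            assert abs(hits / n_rep - a) < band


class TestZMethod:
    def test_set_at_global_mean_gives_z_zero(self):
        vals = pd.Series([1.0, 2.0, 3.0] * 10, index=[f"G{i}" for i in range(30)])
        sets = GeneSetCollection(sets={"S": ["G0", "G1", "G2"]})  # mean 2 = global mean
        res = zmethod_set_test(vals, sets, min_set_size=2)
        assert res.loc[0, "statistic"] == pytest.approx(0.0)
        assert res.loc[0, "pvalue"] == pytest.approx(0.5)

    def test_location_shift_gives_expected_z(self, rng):
        """One set of N=25 genes shifted by 0.4 against standard-normal
        measures: E[Z] = 0.4 * sqrt(25) = 2.0."""
        zs = []
        sets = GeneSetCollection(sets={"S": [f"G{i}" for i in range(25)]})
        for _ in range(1000):
            vals = rng.standard_normal(2000)
            vals[:25] += 0.4
            series = pd.Series(vals, index=[f"G{i}" for i in range(2000)])
            zs.append(zmethod_set_test(series, sets).loc[0, "statistic"])
        assert np.mean(zs) == pytest.approx(2.0, abs=0.1)

    def test_singleton_collection_rejected(self):
        vals = pd.Series([1.0], index=["G0"])
        with pytest.raises(ValueError):
            zmethod_set_test(vals, GeneSetCollection(sets={"S": ["G0"]}))

    def test_constant_measures_rejected(self):
        vals = pd.Series(np.ones(20), index=[f"G{i}" for i in range(20)])
        with pytest.raises(ValueError, match="SD"):
            zmethod_set_test(vals, GeneSetCollection(sets={"S": ["G0", "G1"]}))


class TestQvalues:
    def test_single_pvalue(self):
        q = qvalues([0.04])
        assert q[0] <= 0.04

    def test_identical_pvalues_share_q(self):
        q = qvalues([0.2] * 10)
        assert np.allclose(q, q[0])

    def test_storey_pi0_one_equals_bh_oracle(self):
        p = np.array([0.001, 0.01, 0.5, 0.9])
        q = qvalues(p, pi0=1.0)
        # direct step-up oracle
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_monotone_and_nested_thresholding(self, rng):
        p = rng.uniform(0.001, 1, 200)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert set(np.flatnonzero(q <= 0.01)) <= set(np.flatnonzero(q <= 0.05))
        assert (q <= 1).all() and (q >= 0).all()

    def test_empty_input(self):
        assert qvalues([]).size == 0

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])


class TestNormalityDiagnostic:
    def test_clt_holds_for_size_twenty_normal_measures(self, rng):
        rejected = 0
        reps = 20
        for i in range(reps):
            vals = pd.Series(
                np.exp(-rng.standard_normal(500)), index=[f"G{i}" for i in range(500)]
            )
            out = normality_diagnostic(vals, set_sizes=(20,), n_draws=300, seed=i)
            rejected += out[20]["shapiro_p"] < 0.01
        assert rejected <= 1  # >= 95% pass rate

    def test_small_sets_of_skewed_measures_degrade(self, rng):
        """Strongly right-skewed measures: size-5 sets fail the normality
        check more often than size-20 sets (the CLT rate contrast)."""
        rej = {5: 0, 20: 0}
        for i in range(15):
            vals = pd.Series(rng.exponential(size=100), index=[f"G{i}" for i in range(100)])
            out = normality_diagnostic(
                vals, set_sizes=(5, 20), n_draws=300, seed=100 + i, scale="natural"
            )
            for s in rej:
                rej[s] += out[s]["shapiro_p"] < 0.01
        assert rej[5] > rej[20]

    def test_constant_measures_degenerate(self):
        vals = pd.Series(np.ones(50), index=[f"G{i}" for i in range(50)])
        with pytest.raises(ValueError, match="degenerate"):
            normality_diagnostic(vals, set_sizes=(5,), n_draws=100)

    def test_set_size_exceeding_gene_count_rejected(self, rng):
        vals = pd.Series(rng.uniform(0.1, 1, 10), index=[f"G{i}" for i in range(10)])
        with pytest.raises(ValueError, match="exceeds"):
            normality_diagnostic(vals, set_sizes=(20,), n_draws=100)

    def test_qq_data_shapes(self, rng):
        vals = pd.Series(rng.uniform(0.1, 1, 60), index=[f"G{i}" for i in range(60)])
        out = normality_diagnostic(vals, set_sizes=(10,), n_draws=150, seed=0)
        assert out[10]["sample_q"].shape == (150,)
        assert out[10]["theoretical_q"].shape == (150,)
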