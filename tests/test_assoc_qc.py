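"""Marker QC and the per-SNP association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snpprage as sp
from snpprage.assoc import snp_logistic_scan, trend_test
from snpprage.qc import NoMarkersError, hwe_pvalues, qc_filter, snp_maf

from conftest import genotypes_from_counts, make_genotypes


def _pheno(status, **covars):
    return sp.PhenotypeTable(status=np.asarray(status), covariates=pd.DataFrame(covars) if covars else None)


class TestQcFilter:
    def test_monomorphic_snp_excluded_as_low_maf(self):
        g = make_genotypes(np.column_stack([np.zeros(40), np.tile([0, 1, 2, 1], 10)]))
        kept, log = qc_filter(g, maf_min=0.01, miss_max=0.05, hwe_alpha=1e-6)
        assert kept.n_snps == 1
        assert log.iloc[0]["snp_id"] == "rs1"
        assert "low_maf" in log.iloc[0]["reason"]

    def test_exact_hwe_proportions_retained(self):
        # 200 samples with counts (50, 100, 50): chi-square = 0 exactly
        col = genotypes_from_counts(50, 100, 50)
        assert hwe_pvalues(col[:, None])[0] == pytest.approx(1.0)
        g = make_genotypes(col[:, None])
        kept, log = qc_filter(g, 0.01, 0.05, 1e-6)
        assert kept.n_snps == 1 and log.empty

    def test_default_thresholds_filter_each_rule(self, rng):
        n = 400
        good = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        rare = rng.binomial(2, 0.004, size=(n, 1)).astype(float)
        rare[0, 0] = 1.0  # not monomorphic, still MAF < 0.01
        missing = good.copy()
        missing[: int(0.2 * n), 0] = np.nan
        hwe_bad = np.concatenate([np.zeros(n // 2), np.full(n - n // 2, 2.0)])[:, None]
        g = make_genotypes(np.hstack([good, rare, missing, hwe_bad]))
        kept, log = qc_filter(g, maf_min=0.01, miss_max=0.05, hwe_alpha=1e-6)
        assert list(kept.snp_ids) == ["rs1"]
        reasons = dict(zip(log["snp_id"], log["reason"]))
        assert "low_maf" in reasons["rs2"]
        assert "high_missing" in reasons["rs3"]
        assert "hwe_deviation" in reasons["rs4"]

    def test_idempotent(self, rng):
        dos = rng.binomial(2, rng.uniform(0.05, 0.5, size=30), size=(300, 30)).astype(float)
        dos[rng.random(dos.shape) < 0.02] = np.nan
        g = make_genotypes(dos)
        once, _ = qc_filter(g, 0.05, 0.05, 0.01)
        twice, log2 = qc_filter(once, 0.05, 0.05, 0.01)
        assert twice.n_snps == once.n_snps and log2.empty

    def test_all_excluded_raises(self):
        g = make_genotypes(np.zeros((20, 3)))
        with pytest.raises(NoMarkersError):
            qc_filter(g, 0.01, 0.05, 1e-6)

    def test_bad_threshold_rejected(self):
        g = make_genotypes(np.tile([0.0, 1, 2, 1], (10, 1)).T.reshape(40, 1))
        with pytest.raises(ValueError, match="maf_min"):
            qc_filter(g, maf_min=0.0, miss_max=0.05, hwe_alpha=1e-6)

    def test_hwe_uses_controls_only_with_phenotype(self):
        # controls in perfect HWE, cases wildly deviant: SNP must survive
        controls = genotypes_from_counts(50, 100, 50)
        cases = np.concatenate([np.zeros(100), np.full(100, 2.0)])
        g = make_genotypes(np.concatenate([cases, controls])[:, None])
        ph = _pheno(np.r_[np.ones(200, int), np.zeros(200, int)])
        kept, _ = qc_filter(g, 0.01, 0.05, 0.01, phenotype=ph)
        assert kept.n_snps == 1
        with pytest.raises(NoMarkersError):
            qc_filter(g, 0.01, 0.05, 0.01)  # pooled HWE fails without phenotype


class TestTrendScan:
    def test_monomorphic_flagged_without_pvalue(self):
        g = make_genotypes(np.column_stack([np.ones(40), np.tile([0, 1, 2, 1], 10)]))
        ph = _pheno(np.tile([0, 1], 20))
        for fast in (True, False):
            res = snp_logistic_scan(g, ph, fast=fast)
            assert res.loc[0, "status_flag"] == "monomorphic"
            assert np.isnan(res.loc[0, "pvalue"])
            assert res.loc[1, "status_flag"] == "ok"

    def test_trend_matches_contingency_table_oracle(self):
        # cases (10, 20, 10) / controls (20, 20, 0) by genotype 0/1/2
        cases, controls = (10, 20, 10), (20, 20, 0)
        g_col, y = [], []
        for x, (r, s) in enumerate(zip(cases, controls)):
            g_col += [x] * (r + s)
            y += [1] * r + [0] * s
        chi2, pval, _ = trend_test(np.array(g_col, float)[:, None], np.array(y))

        # independent oracle: textbook Cochran-Armitage formula on the 2x3 table
        x = np.array([0.0, 1.0, 2.0])
        r = np.array(cases, float)
        n = r + np.array(controls, float)
        N, R = n.sum(), r.sum()
        num = N * (N * (r * x).sum() - R * (n * x).sum()) ** 2
        den = R * (N - R) * (N * (n * x**2).sum() - ((n * x).sum()) ** 2)
        chi2_oracle = num / den
        assert chi2[0] == pytest.approx(chi2_oracle, rel=1e-12)
        assert pval[0] == pytest.approx(stats.chi2.sf(chi2_oracle, 1), rel=1e-12)

    def test_null_pvalues_uniform(self, rng):
        n, p = 500, 200
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
        y = rng.integers(0, 2, n)
        res = snp_logistic_scan(make_genotypes(dos), _pheno(y), fast=True)
        ks = stats.kstest(res["pvalue"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_fast_and_full_agree_without_covariates(self, rng):
        n, p = 600, 25
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(float)
        y = rng.integers(0, 2, n)
        g, ph = make_genotypes(dos), _pheno(y)
        fast = snp_logistic_scan(g, ph, fast=True)["pvalue"].to_numpy()
        full = snp_logistic_scan(g, ph, fast=False)["pvalue"].to_numpy()
        assert np.all(np.abs(fast - full) / full < 0.10)

    def test_pvalue_invariant_to_allele_flip(self, rng):
        n, p = 300, 10
        dos = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = rng.integers(0, 2, n)
        a = snp_logistic_scan(make_genotypes(dos), _pheno(y), fast=True)
        b = snp_logistic_scan(make_genotypes(2.0 - dos), _pheno(y), fast=True)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-10)

    def test_separation_flagged(self):
        dose = np.r_[np.zeros(20), np.full(20, 2.0)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = snp_logistic_scan(make_genotypes(dose[:, None]), _pheno(y), fast=False)
        assert res.loc[0, "status_flag"] == "separation"
        assert np.isnan(res.loc[0, "pvalue"])

    def test_collinear_covariate_named(self, rng):
        dos = rng.binomial(2, 0.3, size=(60, 2)).astype(float)
        age = rng.uniform(40, 70, 60)
        ph = _pheno(rng.integers(0, 2, 60), age=age, age2=2 * age)
        with pytest.raises(ValueError, match="age2"):
            snp_logistic_scan(make_genotypes(dos), ph, fast=False)

    def test_covariate_adjustment_runs(self, rng):
        dos = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        ph = _pheno(
            rng.integers(0, 2, 200),
            age=rng.uniform(40, 70, 200),
            area=rng.choice(["A", "B"], 200),
        )
        res = snp_logistic_scan(make_genotypes(dos), ph, fast=False)
        assert (res["status_flag"] == "ok").all()
        assert res["pvalue"].between(0, 1).all()

    def test_missing_dosages_complete_case(self, rng):
        dos = rng.binomial(2, 0.4, size=(200, 1)).astype(float)
        y = rng.integers(0, 2, 200)
        miss = dos.copy()
        miss[:50, 0] = np.nan
        p_complete = trend_test(dos[50:], y[50:])[1][0]
        p_missing = trend_test(miss, y)[1][0]
        assert p_missing == pytest.approx(p_complete, rel=1e-12)

    def test_one_class_phenotype_rejected(self, rng):
        g = make_genotypes(rng.binomial(2, 0.3, size=(20, 1)).astype(float))
        with pytest.raises(ValueError):
            snp_logistic_scan(g, _pheno(np.ones(20, int)), fast=True)


def test_snp_maf_handles_missing():
    col = np.array([0, 1, 2, np.nan, 1, 0], float)[:, None]
    assert snp_maf(col)[0] == pytest.approx(0.4)
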