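"""Per-SNP additive association scan.

Two modes produce the SNP-level p-values that the gene/set summaries consume:

* ``fast=True`` — the 1-df Cochran-Armitage trend (score) test without
  covariates, fully vectorised over SNPs.  Used inside simulation loops.
* ``fast=False`` — per-SNP logistic regression of case status on dosage plus
  covariates; the Wald 1-df p-value for the dosage term is reported.

Either way each SNP yields one record with a status flag: ``ok`` (tested),
``monomorphic`` (no variation, not tested) or ``separation`` (logistic fit
perfectly separates the classes; p omitted).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import GenotypeMatrix, PhenotypeTable

__all__ = ["snp_logistic_scan", "trend_test", "SCAN_COLUMNS"]

SCAN_COLUMNS = ["snp_id", "beta_hat", "statistic", "pvalue", "status_flag"]


def trend_test(dosages: np.ndarray, status: np.ndarray):
    """Vectorised Cochran-Armitage trend test (additive scores 0/1/2).

    Missing dosages are handled per SNP by complete-case analysis.  Returns
    ``(chi2, pvalue, beta_one_step)`` arrays; entries are NaN for monomorphic
    SNPs.  ``beta_one_step`` is the one-step Newton estimate of the log odds
    ratio from the null (score / information), a cheap stand-in for the MLE.
    """
    y = np.asarray(status, dtype=float)[:, None]
    D = np.asarray(dosages, dtype=float)
    valid = np.isfinite(D)
    Dz = np.where(valid, D, 0.0)

    n = valid.sum(axis=0).astype(float)
    sy = (y * valid).sum(axis=0)
    sg = Dz.sum(axis=0)
    sg2 = (Dz**2).sum(axis=0)
    syg = (Dz * y).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        u = syg - sy * sg / n                      # score for the dosage term
        var_g = sg2 - sg**2 / n
        var_y = sy - sy**2 / n
        info = var_y / n * var_g                   # null Fisher information
        chi2 = u**2 / info
        beta1 = u / info
    degenerate = (var_g <= 0) | (var_y <= 0) | (n < 2)
    chi2 = np.where(degenerate, np.nan, chi2)
    pval = stats.chi2.sf(chi2, df=1)
    return chi2, pval, np.where(degenerate, np.nan, beta1)


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categoricals to dummies and check for collinearity."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=range(0))
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    arr = X.to_numpy(dtype=float)
    ones = np.ones((arr.shape[0], 1))
    for k in range(arr.shape[1]):
        sub = np.hstack([ones, arr[:, : k + 1]])
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            raise ValueError(
                f"covariate column {X.columns[k]!r} is collinear with the "
                "intercept/preceding covariates"
            )
    return X


def snp_logistic_scan(
    g: GenotypeMatrix, ph: PhenotypeTable, fast: bool = False
) -> pd.DataFrame:
    """Scan every SNP for additive association with case/control status.

    Returns a DataFrame with columns ``snp_id, beta_hat, statistic, pvalue,
    status_flag`` (one row per SNP, input order).  ``statistic`` is the 1-df
    chi-square (fast mode) or the Wald z (full mode).
    """
    ph.check_both_classes()
    counts = np.bincount(np.asarray(ph.status), minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples in each phenotype class")
    if g.n_samples != ph.n_samples:
        raise ValueError("genotype and phenotype sample counts differ")

    if fast:
        chi2, pval, beta1 = trend_test(g.dosages, ph.status)
        flags = np.where(np.isnan(chi2), "monomorphic", "ok")
        return pd.DataFrame(
            {
                "snp_id": g.snp_ids,
                "beta_hat": beta1,
                "statistic": chi2,
                "pvalue": pval,
                "status_flag": flags,
            }
        )

    X_cov = _covariate_design(ph.covariates)
    y = np.asarray(ph.status, dtype=float)
    records = []
    for j in range(g.n_snps):
        dose = g.dosages[:, j]
        keep = np.isfinite(dose)
        d = dose[keep]
        if d.size < 2 or np.ptp(d) == 0:
            records.append((g.snp_ids[j], np.nan, np.nan, np.nan, "monomorphic"))
            continue
        X = np.column_stack([np.ones(keep.sum()), d] + (
            [X_cov.to_numpy(dtype=float)[keep]] if X_cov.shape[1] else []
        ))
        rec = _fit_one_logit(y[keep], X, g.snp_ids[j])
        records.append(rec)
    return pd.DataFrame(records, columns=SCAN_COLUMNS)


def _fit_one_logit(y, X, snp_id):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            return (snp_id, np.nan, np.nan, np.nan, "separation")
    beta = res.params[1]
    se = res.bse[1]
    # runaway estimate or exploding SE => quasi/complete separation
    if not np.isfinite(se) or se > 100 or abs(beta) > 50 or not res.mle_retvals.get("converged", True):
        return (snp_id, np.nan, np.nan, np.nan, "separation")
    z = beta / se
    return (snp_id, beta, z, 2 * stats.norm.sf(abs(z)), "ok")
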