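"""Pooled p-value ("general causal contribution") analysis.

The per-pair primary MR p-values (IVW, or Wald ratio for single-instrument
pairs) are pooled and compared with the uniform null: departure is
quantified by the genomic-control-style inflation factor λ (slope of a
through-origin regression of observed on expected chi-square(1) order
statistics), tested for by a Kolmogorov–Smirnov test against Uniform(0,1),
and guarded against small-sample optimism by a permutation test that
shuffles the assignment of outcome associations to instrument SNPs within
every pair and re-pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import MIN_PVALUE, HarmonizedPair

__all__ = [
    "PooledResult", "ks_uniform", "inflation_lambda", "permutation_null",
    "pooled_result", "stratified_rerun", "classify_tiers", "qq_table",
]

_TIER_ORDER = ["NS", "nominal", "single_disease", "study_wide"]


@dataclass(frozen=True, slots=True)
class PooledResult:
    """λ with CI, KS uniformity p and optional permutation p's for one
    stratum of pooled per-pair p-values."""

    lambda_hat: float
    lambda_ci: tuple[float, float]
    ks_p: float
    n_pvalues: int
    permutation_p_lambda: float | None = None
    permutation_p_ks: float | None = None
    stratum: str = "all"


def _clean(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if np.any(p <= 0.0):
        p = np.clip(p, MIN_PVALUE, 1.0)
    if np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def ks_uniform(pvalues) -> tuple[float, float]:
    """Two-sided KS test of the p-values against Uniform(0,1).

    Returns (D statistic, p-value); requires at least 5 p-values.
    """
    p = _clean(pvalues)
    if len(p) < 5:
        raise ValueError("KS test not evaluable with fewer than 5 p-values")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def inflation_lambda(pvalues) -> tuple[float, tuple[float, float]]:
    """Inflation factor λ by chi-square regression.

    Each p is converted to its 1-df chi-square quantile; the sorted observed
    statistics are regressed through the origin on the expected 1-df order
    statistics (quantiles at (i-1/2)/n).  λ is the slope; the 95% CI comes
    from the regression slope's standard error.
    """
    p = _clean(pvalues)
    n = len(p)
    if n < 5:
        raise ValueError("lambda not evaluable with fewer than 5 p-values")
    obs = np.sort(stats.chi2.isf(p, df=1))
    exp = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
    see = float((exp * exp).sum())
    lam = float((exp * obs).sum() / see)
    resid = obs - lam * exp
    se = float(np.sqrt((resid * resid).sum() / (n - 1) / see))
    return lam, (lam - 1.96 * se, lam + 1.96 * se)


def pooled_result(pvalues, stratum: str = "all",
                  permutation_p_lambda: float | None = None,
                  permutation_p_ks: float | None = None) -> PooledResult:
    """λ, CI and KS p for one stratum of p-values."""
    p = _clean(pvalues)
    lam, ci = inflation_lambda(p)
    _, ks_p = ks_uniform(p)
    return PooledResult(lam, ci, ks_p, len(p), permutation_p_lambda,
                        permutation_p_ks, stratum)


def _ks_statistic_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise two-sided KS D against Uniform(0,1) for a 2-D array."""
    b, n = p.shape
    s = np.sort(p, axis=1)
    i = np.arange(1, n + 1)
    d_plus = (i / n - s).max(axis=1)
    d_minus = (s - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def _ivw_p_rows(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW two-sided p for each row of (by, sy) against fixed bx.

    Multiplicative random-effects se floored at 1, matching the primary
    estimator.
    """
    k = bx.shape[-1]
    w = bx**2 / sy**2
    sw = w.sum(axis=1)
    beta = (w * (by / bx)).sum(axis=1) / sw
    q = (w * (by / bx - beta[:, None]) ** 2).sum(axis=1)
    se = np.sqrt(1.0 / sw)
    if k > 1:
        se = se * np.maximum(1.0, np.sqrt(q / (k - 1)))
    return np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), MIN_PVALUE, 1.0)


def permutation_null(pair_set: Sequence[HarmonizedPair], B: int,
                     seed: int | np.random.Generator | None = None,
                     scope: str = "within_pair"
                     ) -> tuple[float, float, PooledResult]:
    """Permutation test of pooled inflation.

    Each of ``B`` permutations shuffles the assignment of outcome
    associations (beta_out, se_out) to instrument SNPs within every pair —
    breaking the instrument-outcome linkage while preserving the marginal
    distributions — recomputes every IVW p, then λ and the KS statistic.
    With ``scope='global'`` outcome records are shuffled across the pooled
    SNPs of all pairs instead.  Returns (permutation_p_lambda,
    permutation_p_ks, observed PooledResult); permutation p's use the
    add-one rule, so the minimum attainable value is 1/(B+1).
    """
    if B < 100:
        raise ValueError("use at least 100 permutations")
    pairs = [p for p in pair_set if p.n_snp >= 2]
    if len(pairs) < 5:
        raise ValueError("need at least 5 pairs with >= 2 instruments")
    if scope not in ("within_pair", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)

    obs_p = []
    arrays = []
    for pr in pairs:
        bx, sx, by, sy = pr.arrays()
        arrays.append((bx, by, sy))
        obs_p.append(float(_ivw_p_rows(bx[None, :], by[None, :], sy[None, :])[0]))
    observed = pooled_result(obs_p, stratum="observed")
    d_obs, _ = ks_uniform(obs_p)

    if scope == "global":
        pool_bx = np.concatenate([a[0] for a in arrays])
        pool_by = np.concatenate([a[1] for a in arrays])
        pool_sy = np.concatenate([a[2] for a in arrays])
        sizes = [len(a[0]) for a in arrays]

    perm_p = np.empty((B, len(pairs)))
    if scope == "within_pair":
        for j, (bx, by, sy) in enumerate(arrays):
            k = len(bx)
            idx = np.argsort(rng.random((B, k)), axis=1)
            perm_p[:, j] = _ivw_p_rows(bx[None, :], by[idx], sy[idx])
    else:
        n_pool = len(pool_by)
        for b in range(B):
            order = rng.permutation(n_pool)
            start = 0
            for j, k in enumerate(sizes):
                sel = order[start:start + k]
                start += k
                perm_p[b, j] = _ivw_p_rows(arrays[j][0][None, :],
                                           pool_by[sel][None, :],
                                           pool_sy[sel][None, :])[0]

    exp = stats.chi2.ppf((np.arange(1, len(pairs) + 1) - 0.5) / len(pairs), df=1)
    see = (exp * exp).sum()
    obs_chi = np.sort(stats.chi2.isf(perm_p, df=1), axis=1)
    lam_perm = (obs_chi * exp).sum(axis=1) / see
    d_perm = _ks_statistic_rows(perm_p)

    p_lambda = (1 + int((lam_perm >= observed.lambda_hat).sum())) / (B + 1)
    p_ks = (1 + int((d_perm >= d_obs).sum())) / (B + 1)
    return p_lambda, p_ks, observed


def stratified_rerun(results: pd.DataFrame, mode: str,
                     stratum_label: str | None = None,
                     heterogeneity_alpha: float = 0.05) -> PooledResult:
    """Re-pool after a sensitivity-driven exclusion.

    ``results`` is the per-pair results table with columns ``pvalue``
    (primary MR p), ``cochran_p`` and ``pvalue_outlier_corrected`` (primary p
    recomputed after MR-PRESSO outlier removal; equal to ``pvalue`` when no
    outlier was found).  ``mode='remove_heterogeneous'`` drops whole pairs
    with Cochran p < 0.05; ``mode='remove_outlier_snps'`` substitutes the
    outlier-corrected p's.
    """
    _reject_duplicates(results)
    if mode == "remove_heterogeneous":
        het = results["cochran_p"].notna() & (results["cochran_p"]
                                              < heterogeneity_alpha)
        pvals = results.loc[~het, "pvalue"].dropna()
        label = stratum_label or "heterogeneity-removed"
    elif mode == "remove_outlier_snps":
        col = results["pvalue_outlier_corrected"].fillna(results["pvalue"])
        pvals = col.dropna()
        label = stratum_label or "outlier-removed"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(pvals) < 5:
        raise ValueError(f"stratum {label!r} left with fewer than 5 p-values")
    return pooled_result(pvals.to_numpy(), stratum=label)


def _reject_duplicates(results: pd.DataFrame) -> None:
    if {"exposure_id", "outcome_id"} <= set(results.columns):
        dup = results.duplicated(["exposure_id", "outcome_id"])
        if dup.any():
            raise ValueError("duplicate exposure-outcome pairs in results")


def classify_tiers(results: pd.DataFrame, n_pairs_dti: int, n_pairs_roi: int
                   ) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Assign significance tiers and build the MR-vs-heterogeneity overlap.

    Tiers per pair (on the primary MR p): NS; nominal (p < 0.05);
    single_disease (p < 0.05 / #exposures of the pair's class); study_wide
    (p < 0.05 / #enumerated pairs of the class, ``n_pairs_dti`` or
    ``n_pairs_roi``).  Returns (tier labels, row-normalized cross-tabulation
    of MR tier x heterogeneity tier, raw counts).
    """
    _reject_duplicates(results)
    n_pairs = {"dti": n_pairs_dti, "roi": n_pairs_roi}

    def tier_of(p: float, klass: str, n_expo: int) -> str:
        if not np.isfinite(p):
            return "NS"
        if p < 0.05 / max(n_pairs.get(klass, n_pairs_dti), 1):
            return "study_wide"
        if p < 0.05 / max(n_expo, 1):
            return "single_disease"
        if p < 0.05:
            return "nominal"
        return "NS"

    n_expo_by_class = results.groupby("exposure_class")["exposure_id"].nunique()
    mr_tier = pd.Series(index=results.index, dtype=object)
    het_tier = pd.Series(index=results.index, dtype=object)
    for i, row in results.iterrows():
        klass = row.get("exposure_class", "dti")
        n_expo = int(n_expo_by_class.get(klass, 1))
        mr_tier[i] = tier_of(row["pvalue"] if pd.notna(row["pvalue"])
                             else np.nan, klass, n_expo)
        hp = row.get("cochran_p", np.nan)
        het_tier[i] = tier_of(hp if pd.notna(hp) else np.nan, klass, n_expo)

    counts = pd.crosstab(mr_tier, het_tier).reindex(
        index=_TIER_ORDER, columns=_TIER_ORDER, fill_value=0)
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    normalized = counts.div(row_sums, axis=0)
    return mr_tier.rename("tier"), normalized, counts


def qq_table(pvalues, stratum: str = "all") -> pd.DataFrame:
    """Plot-ready QQ table: expected vs observed -log10 p per rank."""
    p = np.sort(_clean(pvalues))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "stratum": stratum,
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p),
    })
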