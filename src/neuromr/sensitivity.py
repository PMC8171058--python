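"""Heterogeneity, pleiotropy, outlier and direction diagnostics.

For each harmonized exposure-outcome pair the battery comprises: Cochran's Q
around the IVW estimate (modified second-order weights by default), Rucker's
Q around the Egger line, the Egger intercept, the simulation-based MR-PRESSO
global test with per-SNP outlier detection and outlier-corrected
re-estimation, leave-one-out IVW, reverse-direction MR, and a funnel-plot
table for directional-pleiotropy inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators as est
from .estimators import (InsufficientInstrumentsError, MREstimate, _clip_p,
                         _ivw_arrays, _egger_arrays, _pair_arrays)
from .summary_io import GwasTable, HarmonizedPair, LDSource, harmonize_pair, \
    select_instruments

__all__ = [
    "SensitivityReport", "PressoResult", "ReverseMRResult",
    "cochran_q", "rucker_q", "mr_presso", "leave_one_out", "reverse_mr",
    "funnel_data", "sensitivity_report",
]


@dataclass(frozen=True, slots=True)
class PressoResult:
    """MR-PRESSO global/outlier/distortion verdict for one pair.

    ``status`` is 'ok' or 'not_evaluable' (fewer than 4 instruments).  A
    global p with zero simulated exceedances is reported as 1/n_sim (an
    upper bound), never 0.
    """

    global_p: float | None
    outliers: list[str]
    distortion_p: float | None
    corrected_ivw: MREstimate | None
    status: str


@dataclass(frozen=True, slots=True)
class ReverseMRResult:
    """Reverse-direction MR (disorder as exposure, imaging trait as outcome)."""

    estimate: MREstimate | None
    directionality_ok: bool | None  # True when reverse IVW p > 0.05
    n_instruments: int
    status: str  # 'ok' | 'not_testable'


@dataclass
class SensitivityReport:
    """Full diagnostic battery for one exposure-outcome pair."""

    cochran_q: float | None = None
    cochran_df: int | None = None
    cochran_p: float | None = None
    rucker_q: float | None = None
    rucker_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    presso: PressoResult | None = None
    loo_estimates: pd.DataFrame | None = None
    reverse: ReverseMRResult | None = None
    flags: dict = field(default_factory=dict)

    @property
    def presso_global_p(self) -> float | None:
        return self.presso.global_p if self.presso else None

    @property
    def presso_outliers(self) -> list[str]:
        return self.presso.outliers if self.presso else []


def cochran_q(pair, ivw_beta: float | None = None,
              modified: bool = True) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around the IVW estimate.

    With ``modified=True`` (default) the weights use the second-order ratio
    variance (se_out² + beta_pooled²·se_exp²)/beta_exp², iteratively
    re-evaluated at the pooled estimate; with ``modified=False`` the plain
    first-order weights beta_exp²/se_out² are used and ``ivw_beta`` (when
    given) fixes the centre.  Returns (Q, df, p) with p from chi-square k-1.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    k = len(bx)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    r = by / bx
    if not modified:
        w = bx**2 / sy**2
        beta = ivw_beta if ivw_beta is not None else float((w * r).sum() / w.sum())
    else:
        beta = ivw_beta if ivw_beta is not None else \
            float((bx**2 / sy**2 * r).sum() / (bx**2 / sy**2).sum())
        for _ in range(50):
            w = bx**2 / (sy**2 + beta**2 * sx**2)
            new = float((w * r).sum() / w.sum())
            if abs(new - beta) < 1e-12:
                beta = new
                break
            beta = new
        w = bx**2 / (sy**2 + beta**2 * sx**2)
    q = float((w * (r - beta) ** 2).sum())
    df = k - 1
    return q, df, _clip_p(stats.chi2.sf(q, df))


def rucker_q(pair, egger_fit: tuple[float, float] | None = None
             ) -> tuple[float, float]:
    """Rucker's Q: weighted residual sum of squares around the Egger line.

    Returns (Q', p) with p from chi-square k-2.  Always <= the first-order
    Cochran Q, which is the same quantity constrained through the origin.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("Rucker's Q requires >= 3 instruments")
    if egger_fit is not None:
        slope, intercept = egger_fit
        sgn = np.where(bx < 0, -1.0, 1.0)
        resid = by * sgn - intercept - slope * bx * sgn
        q = float(((1.0 / sy**2) * resid**2).sum())
    else:
        _, _, _, _, q, _ = _egger_arrays(bx, sx, by, sy)
    return q, _clip_p(stats.chi2.sf(q, k - 2))


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW point estimates, O(k) via running sums."""
    wx2 = w * bx * bx
    wxy = w * bx * by
    return (wxy.sum() - wxy) / (wx2.sum() - wx2)


def mr_presso(pair, n_sim: int = 2500, signif: float = 0.05,
              seed: int | np.random.Generator | None = None) -> PressoResult:
    """MR-PRESSO global pleiotropy test, outlier search and correction.

    The observed statistic is the weighted leave-one-out residual sum of
    squares RSS = Σ w_i (beta_out_i - ivw_{-i}·beta_exp_i)², w_i = 1/se_out².
    The null is built by drawing outcome betas from the no-pleiotropy model
    (mean ivw_{-i}·beta_exp_i, sd se_out_i) ``n_sim`` times and recomputing
    the same statistic; the global p is the exceedance fraction.  Per-SNP
    outlier p-values use the same exceedance logic on individual residual
    contributions, Bonferroni-corrected over k.  Detected outliers are
    removed and the IVW re-estimated; the distortion p compares the observed
    estimate shift with shifts from removing random same-size SNP subsets.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    k = len(bx)
    if k < 4:
        return PressoResult(None, [], None, None, "not_evaluable")
    snp_ids = (pair.snps["snp_id"].astype(str).tolist()
               if isinstance(pair, HarmonizedPair)
               else [str(i) for i in range(k)])
    rng = np.random.default_rng(seed)

    w = 1.0 / sy**2
    b_loo = _loo_slopes(bx, by, w)
    resid = by - b_loo * bx
    contrib_obs = w * resid**2
    rss_obs = float(contrib_obs.sum())

    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, k))
    wxy = w * bx * by_sim
    wx2 = w * bx * bx
    b_loo_sim = (wxy.sum(axis=1, keepdims=True) - wxy) / (wx2.sum() - wx2)
    resid_sim = by_sim - b_loo_sim * bx
    contrib_sim = w * resid_sim**2
    rss_sim = contrib_sim.sum(axis=1)

    exceed = int((rss_sim >= rss_obs).sum())
    global_p = max(exceed, 1) / n_sim  # never 0; floor at 1/n_sim

    p_snp = np.maximum((contrib_sim >= contrib_obs).mean(axis=0), 1.0 / n_sim)
    p_snp_bonf = np.minimum(1.0, p_snp * k)
    outlier_mask = p_snp_bonf < signif
    outliers = [snp_ids[i] for i in np.where(outlier_mask)[0]]

    corrected = None
    distortion_p = None
    if outliers and (~outlier_mask).sum() >= 2:
        keep = ~outlier_mask
        corrected = est.ivw((bx[keep], sx[keep], by[keep], sy[keep]))
        b_all = float((w * bx * by).sum() / (w * bx * bx).sum())
        d_obs = corrected.beta - b_all
        n_out = int(outlier_mask.sum())
        d_null = np.empty(n_sim)
        for b_i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            m = np.ones(k, dtype=bool)
            m[drop] = False
            b_sub, _, _ = _ivw_arrays(bx[m], sx[m], by[m], sy[m],
                                      random_effects=False)
            d_null[b_i] = b_sub - b_all
        distortion_p = (1 + int((np.abs(d_null) >= abs(d_obs)).sum())) / (n_sim + 1)
    return PressoResult(float(global_p), outliers, distortion_p, corrected, "ok")


def leave_one_out(pair) -> pd.DataFrame:
    """IVW re-estimated omitting each SNP in turn.

    Returns a frame with one row per omitted SNP: snp_id, beta, se, pvalue.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    snp_ids = (pair.snps["snp_id"].astype(str).tolist()
               if isinstance(pair, HarmonizedPair)
               else [str(i) for i in range(k)])
    rows = []
    for i in range(k):
        m = np.ones(k, dtype=bool)
        m[i] = False
        e = est.ivw((bx[m], sx[m], by[m], sy[m]))
        rows.append((snp_ids[i], e.beta, e.se, e.pvalue))
    return pd.DataFrame(rows, columns=["snp_id", "beta", "se", "pvalue"])


def reverse_mr(outcome_gwas: GwasTable, exposure_gwas: GwasTable,
               p_threshold: float = 5e-8, ld: LDSource | None = None,
               r2_threshold: float = 0.001) -> ReverseMRResult:
    """MR with the roles swapped: the disorder becomes the exposure.

    A non-significant reverse IVW p (> 0.05) supports the forward
    directionality.  With a single reverse instrument the Wald ratio is
    used; with none the verdict is 'not_testable'.
    """
    instruments = select_instruments(outcome_gwas, p_threshold, ld, r2_threshold)
    if not instruments:
        return ReverseMRResult(None, None, 0, "not_testable")
    pair = harmonize_pair(outcome_gwas, exposure_gwas, instruments)
    if pair.n_snp == 0:
        return ReverseMRResult(None, None, 0, "not_testable")
    if pair.n_snp == 1:
        r = pair.snps.iloc[0]
        e = est.wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
    else:
        e = est.ivw(pair)
    return ReverseMRResult(e, bool(e.pvalue > 0.05), pair.n_snp, "ok")


def funnel_data(pair) -> tuple[pd.DataFrame, dict]:
    """Plot-ready funnel table: per-SNP ratio vs precision (1/se_ratio).

    The reference dict carries the IVW estimate and, when estimable, the
    Egger slope as vertical reference lines.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    if len(bx) < 1:
        raise InsufficientInstrumentsError("funnel table needs >= 1 SNP")
    r = by / bx
    prec = np.abs(bx) / sy
    df = pd.DataFrame({"ratio": r, "precision": prec})
    if isinstance(pair, HarmonizedPair):
        df.insert(0, "snp_id", pair.snps["snp_id"].to_numpy())
    refs: dict = {}
    if len(bx) >= 2:
        refs["ivw"] = _ivw_arrays(bx, sx, by, sy)[0]
    if len(bx) >= 3:
        refs["egger"] = _egger_arrays(bx, sx, by, sy)[0]
    return df, refs


def sensitivity_report(pair: HarmonizedPair, n_presso_sim: int = 2500,
                       presso_signif: float = 0.05,
                       seed: int | np.random.Generator | None = None,
                       outcome_gwas: GwasTable | None = None,
                       exposure_gwas: GwasTable | None = None,
                       ld: LDSource | None = None,
                       heterogeneity_alpha: float = 0.05) -> SensitivityReport:
    """Run the full diagnostic battery; stages lacking enough instruments
    are reported as None rather than aborting."""
    rep = SensitivityReport()
    k = pair.n_snp
    if k >= 2:
        q, df, p = cochran_q(pair)
        rep.cochran_q, rep.cochran_df, rep.cochran_p = q, df, p
    if k >= 3:
        rep.rucker_q, rep.rucker_p = rucker_q(pair)
        _, intercept = est.egger(pair)
        rep.egger_intercept = intercept.beta
        rep.egger_intercept_p = intercept.pvalue
        rep.loo_estimates = leave_one_out(pair)
    rep.presso = mr_presso(pair, n_sim=n_presso_sim, signif=presso_signif,
                           seed=seed)
    if outcome_gwas is not None and exposure_gwas is not None:
        rep.reverse = reverse_mr(outcome_gwas, exposure_gwas, ld=ld)
    rep.flags = {
        "heterogeneous": (rep.cochran_p is not None
                          and rep.cochran_p < heterogeneity_alpha),
        "pleiotropic": (rep.egger_intercept_p is not None
                        and rep.egger_intercept_p < 0.05),
        "bidirectional": (rep.reverse is not None
                          and rep.reverse.directionality_ok is False),
    }
    return rep
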