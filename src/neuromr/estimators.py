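"""Causal-effect estimators for one harmonized exposure-outcome pair.

Implements the standard two-sample MR toolbox: the single-SNP Wald ratio,
inverse-variance-weighted (IVW) meta-analysis of per-SNP ratios, MR-Egger
regression (slope + pleiotropy intercept), the weighted median and weighted
mode estimators, the SMR chi-square test, and the HEIDI test separating a
single shared causal variant from linkage of distinct variants.

All multi-SNP estimators consume a :class:`~neuromr.summary_io.HarmonizedPair`
or the equivalent (beta_exp, se_exp, beta_out, se_out) arrays.  Inverse-
variance weights use the first-order delta approximation
se(ratio_i) = se_out_i / |beta_exp_i|, so IVW coincides with a zero-intercept
weighted regression of outcome on exposure betas with weights 1/se_out².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import MIN_PVALUE, HarmonizedPair

__all__ = [
    "MREstimate", "OddsRatioResult", "HeidiResult",
    "InsufficientInstrumentsError", "UndefinedRatioError", "ScaleError",
    "wald_ratio", "ivw", "egger", "weighted_median", "weighted_mode",
    "smr_test", "heidi_test", "to_odds_ratio",
]

_Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(ZeroDivisionError):
    """Wald ratio undefined because the exposure effect is zero."""


class ScaleError(ValueError):
    """Estimate is not on the log-odds scale required for an odds ratio."""


@dataclass(frozen=True, slots=True)
class MREstimate:
    """One method's causal-effect estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must be in (0, 1]")


@dataclass(frozen=True, slots=True)
class OddsRatioResult:
    """Exponentiated estimate for a binary outcome."""

    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    percent_change: float


@dataclass(frozen=True, slots=True)
class HeidiResult:
    """HEIDI heterogeneity-in-dependent-instruments verdict.

    ``status`` is 'ok' when evaluable; 'not_evaluable' (pvalue None) when
    fewer than 3 usable companion SNPs exist.  Small p indicates linkage of
    distinct causal variants rather than a single shared signal.
    """

    pvalue: float | None
    n_companions: int
    status: str


def _clip_p(p: float) -> float:
    return float(min(1.0, max(MIN_PVALUE, p)))


def _norm_p(z: float) -> float:
    return _clip_p(2.0 * stats.norm.sf(abs(z)))


def _pair_arrays(pair) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pair, HarmonizedPair):
        return pair.arrays()
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in pair)
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# single-SNP estimators


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    The standard error uses the first-order delta method
    se_out / |beta_exp| (exposure-side noise ignored), the convention under
    which IVW reduces to an inverse-variance meta-analysis of ratios.
    """
    if se_exp <= 0 or se_out <= 0:
        raise ValueError("standard errors must be positive")
    if beta_exp == 0:
        raise UndefinedRatioError("beta_exp is zero; Wald ratio undefined")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald_ratio", beta, se, beta - _Z95 * se,
                      beta + _Z95 * se, _norm_p(beta / se), 1)


def smr_test(beta_exp: float, se_exp: float, beta_out: float,
             se_out: float) -> MREstimate:
    """Summary-data-based MR test for a single top instrument.

    T = z_exp² z_out² / (z_exp² + z_out²) referred to chi-square(1); the point
    estimate is the Wald ratio.  Unlike the plain Wald test, T accounts for
    sampling noise on both the exposure and outcome sides.
    """
    wr = wald_ratio(beta_exp, se_exp, beta_out, se_out)
    z_exp = beta_exp / se_exp
    z_out = beta_out / se_out
    denom = z_exp**2 + z_out**2
    t_smr = 0.0 if denom == 0 else z_exp**2 * z_out**2 / denom
    p = _clip_p(stats.chi2.sf(t_smr, df=1))
    return MREstimate("smr", wr.beta, wr.se, wr.ci_low, wr.ci_high, p, 1)


# ---------------------------------------------------------------------------
# multi-SNP estimators (array kernels + public wrappers)


def _ivw_arrays(bx, sx, by, sy, random_effects: bool = True):
    """Return (beta, se, Q).  Weights are 1/se(ratio)² first-order."""
    r = by / bx
    w = bx**2 / sy**2
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    q = float((w * (r - beta) ** 2).sum())
    se = math.sqrt(1.0 / sw)
    if random_effects and len(bx) > 1:
        se *= max(1.0, math.sqrt(q / (len(bx) - 1)))
    return beta, se, q


def ivw(pair, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    Equivalent to the slope of a zero-intercept weighted regression of
    beta_out on beta_exp with weights 1/se_out².  By default a multiplicative
    random-effects model scales the se by max(1, sqrt(Q/(k-1))); pass
    ``random_effects=False`` for the fixed-effect variant.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    if len(bx) < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 instruments")
    beta, se, _ = _ivw_arrays(bx, sx, by, sy, random_effects)
    return MREstimate("ivw", beta, se, beta - _Z95 * se, beta + _Z95 * se,
                      _norm_p(beta / se), len(bx))


def _egger_arrays(bx, sx, by, sy):
    """Return (slope, se_slope, intercept, se_int, q_rucker, df).

    Orients every SNP so beta_exp >= 0, then fits a free-intercept weighted
    regression with weights 1/se_out²; se's scaled by
    max(1, sqrt(Q_rucker/(k-2))).
    """
    sgn = np.where(bx < 0, -1.0, 1.0)
    x = bx * sgn
    y = by * sgn
    w = 1.0 / sy**2
    sw = w.sum()
    sx_ = (w * x).sum()
    sy_ = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx_**2
    slope = (sw * sxy - sx_ * sy_) / denom
    intercept = (sxx * sy_ - sx_ * sxy) / denom
    resid = y - intercept - slope * x
    q_rucker = float((w * resid**2).sum())
    df = len(bx) - 2
    scale = max(1.0, math.sqrt(q_rucker / df))
    se_slope = math.sqrt(sw / denom) * scale
    se_int = math.sqrt(sxx / denom) * scale
    return float(slope), se_slope, float(intercept), se_int, q_rucker, df


def egger(pair) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    The slope is the pleiotropy-robust causal estimate under the InSIDE
    assumption; the intercept estimates the average directional pleiotropic
    effect.  p-values and CIs use the t distribution with k-2 df.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("Egger requires at least 3 instruments")
    slope, se_s, intercept, se_i, _, df = _egger_arrays(bx, sx, by, sy)
    tmul = float(stats.t.ppf(0.975, df))

    def _est(name, b, se):
        p = _clip_p(2.0 * stats.t.sf(abs(b / se), df))
        return MREstimate(name, b, se, b - tmul * se, b + tmul * se, p, k)

    return _est("egger_slope", slope, se_s), _est("egger_intercept", intercept, se_i)


def _weighted_median_est(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Percentile-interpolated weighted median of per-SNP ratios."""
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / w.sum()
    below = np.where(cum < 0.5)[0]
    if len(below) == 0:
        return float(b[0])
    j = below[-1]
    if j == len(b) - 1:
        return float(b[-1])
    return float(b[j] + (b[j + 1] - b[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j]))


def weighted_median(pair, n_boot: int = 1000,
                    seed: int | np.random.Generator | None = None) -> MREstimate:
    """Weighted median of per-SNP ratios; consistent with >=50% valid weight.

    The se comes from a parametric bootstrap: per-SNP betas are resampled
    from their normal sampling distributions and the median recomputed,
    keeping the original inverse-variance weights.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    r = by / bx
    w = bx**2 / sy**2
    beta = _weighted_median_est(r, w)
    rng = np.random.default_rng(seed)
    bxb = rng.normal(bx, sx, size=(n_boot, len(bx)))
    byb = rng.normal(by, sy, size=(n_boot, len(bx)))
    boots = np.empty(n_boot)
    rb = byb / bxb
    for i in range(n_boot):
        boots[i] = _weighted_median_est(rb[i], w)
    se = float(boots.std(ddof=1))
    return MREstimate("weighted_median", beta, se, beta - _Z95 * se,
                      beta + _Z95 * se, _norm_p(beta / se), len(bx))


_MODE_GRID = 512


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a weighted normal-kernel density over per-SNP ratios.

    Bandwidth is phi times the modified Silverman rule
    0.9 * min(sd, mad) * k^(-1/5) used by the weighted-mode literature.
    """
    return float(_mode_estimates_batch(ratios[None, :], weights, phi)[0])


def _mode_estimates_batch(ratios: np.ndarray, weights: np.ndarray,
                          phi: float, chunk: int = 128) -> np.ndarray:
    """Vectorized weighted-KDE argmax for each row of a (B, k) ratio matrix."""
    b, k = ratios.shape
    sd = ratios.std(axis=1, ddof=1)
    mad = stats.median_abs_deviation(ratios, axis=1, scale="normal")
    s = 0.9 * np.where(mad > 0, np.minimum(sd, mad), sd) / k**0.2
    h = np.maximum(1e-8, s * phi)
    # pad the grid by 3 bandwidths, capped at the data span so that huge
    # bandwidths keep enough grid resolution for a stable argmax
    span = ratios.max(axis=1) - ratios.min(axis=1)
    pad = 3 * np.where(span > 0, np.minimum(h, span), h)
    lo = ratios.min(axis=1) - pad
    hi = ratios.max(axis=1) + pad
    step = np.linspace(0.0, 1.0, _MODE_GRID)
    out = np.empty(b)
    for start in range(0, b, chunk):
        end = min(start + chunk, b)
        grid = lo[start:end, None] + (hi - lo)[start:end, None] * step[None, :]
        z = (grid[:, :, None] - ratios[start:end, None, :]) \
            / h[start:end, None, None]
        dens = np.exp(-0.5 * z**2) @ weights
        idx = np.argmax(dens, axis=1)
        out[start:end] = grid[np.arange(end - start), idx]
    return out


def weighted_mode(pair, bandwidth_phi: float = 1.0, n_boot: int = 1000,
                  seed: int | np.random.Generator | None = None) -> MREstimate:
    """Weighted mode of per-SNP ratios (kernel-density argmax).

    Consistent when the largest weight-share of instruments is valid
    (ZEMPA).  se by the same parametric bootstrap as the weighted median.
    """
    bx, sx, by, sy = _pair_arrays(pair)
    if len(bx) < 3:
        raise InsufficientInstrumentsError("weighted mode requires >= 3 instruments")
    r = by / bx
    w = bx**2 / sy**2
    w = w / w.sum()
    beta = _mode_estimate(r, w, bandwidth_phi)
    rng = np.random.default_rng(seed)
    bxb = rng.normal(bx, sx, size=(n_boot, len(bx)))
    byb = rng.normal(by, sy, size=(n_boot, len(bx)))
    boots = _mode_estimates_batch(byb / bxb, w, bandwidth_phi)
    # robust spread of the bootstrap distribution, per the source construction
    se = float(stats.median_abs_deviation(boots, scale="normal"))
    return MREstimate("weighted_mode", beta, se, beta - _Z95 * se,
                      beta + _Z95 * se, _norm_p(beta / se), len(bx))


# ---------------------------------------------------------------------------
# HEIDI


def heidi_test(region: pd.DataFrame | HarmonizedPair, ld_corr: np.ndarray,
               top: str | None = None, companion_p: float = 1.6e-3,
               r2_bounds: tuple[float, float] = (0.05, 0.9),
               max_companions: int = 20) -> HeidiResult:
    """Heterogeneity-in-dependent-instruments test around a top SNP.

    ``region`` holds harmonized records for the top SNP and nearby SNPs in
    LD with it; ``ld_corr`` is the signed LD correlation matrix aligned with
    the region rows.  Companion SNPs (exposure p below ``companion_p``, r² to
    the top SNP within ``r2_bounds``, at most ``max_companions``) each yield
    a deviation d_i = ratio_i - ratio_top; under a single shared causal
    variant all deviations are zero in expectation.  The statistic is
    d' V⁻¹ d with V from the delta method and LD, referred to chi-square
    with one df per companion.
    """
    snps = region.snps if isinstance(region, HarmonizedPair) else region
    bx = snps["beta_exp"].to_numpy(float)
    sx = snps["se_exp"].to_numpy(float)
    by = snps["beta_out"].to_numpy(float)
    sy = snps["se_out"].to_numpy(float)
    p_exp = snps["p_exp"].to_numpy(float)
    ids = snps["snp_id"].astype(str).tolist()
    ld_corr = np.asarray(ld_corr, dtype=float)
    if ld_corr.shape != (len(ids), len(ids)):
        raise ValueError("ld_corr must be square and aligned with region rows")

    t = ids.index(top) if top is not None else int(np.argmin(p_exp))
    r2_to_top = ld_corr[t] ** 2
    lo, hi = r2_bounds
    cand = [i for i in range(len(ids))
            if i != t and p_exp[i] < companion_p and lo <= r2_to_top[i] <= hi]
    cand.sort(key=lambda i: p_exp[i])
    cand = cand[:max_companions]
    if len(cand) < 3:
        return HeidiResult(None, len(cand), "not_evaluable")

    idx = [t] + cand
    b = by[idx] / bx[idx]
    # delta-method covariance of the ratio vector under LD correlation
    r = ld_corr[np.ix_(idx, idx)]
    inv_x = 1.0 / bx[idx]
    cov_out = r * np.outer(sy[idx] * inv_x, sy[idx] * inv_x)
    cov_exp = r * np.outer(b * sx[idx] * inv_x, b * sx[idx] * inv_x)
    c = cov_out + cov_exp
    m = len(cand)
    d = b[1:] - b[0]
    v = c[1:, 1:] - c[1:, [0]] - c[[0], 1:] + c[0, 0]
    t_stat = float(d @ np.linalg.pinv(v, rcond=1e-10) @ d)
    p = _clip_p(stats.chi2.sf(t_stat, df=m))
    return HeidiResult(p, m, "ok")


# ---------------------------------------------------------------------------
# scale transforms


def to_odds_ratio(est: MREstimate, trait_type: str = "binary") -> OddsRatioResult:
    """Exponentiate a log-odds estimate into an odds ratio with 95% CI.

    ``percent_change`` is 100·(OR-1): negative for protective effects.
    """
    if trait_type != "binary":
        raise ScaleError("odds ratios are defined only for binary outcomes")
    or_ = math.exp(est.beta)
    return OddsRatioResult(or_, math.exp(est.ci_low), math.exp(est.ci_high),
                           100.0 * (or_ - 1.0))
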