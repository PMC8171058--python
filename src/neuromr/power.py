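"""Instrument strength (R², F) and study power for a binary outcome.

Per-instrument variance explained follows the summary-statistic identity

    R² = 2·EAF·(1-EAF)·β² / (2·EAF·(1-EAF)·β² + 2·EAF·(1-EAF)·N·se(β)²)

whose allele-frequency factor cancels algebraically, leaving
β²/(β² + N·se²) — the fallback used when EAF is unreported (as in most
disorder GWAS).  F = R²·(N-2)/(1-R²) is the weak-instrument diagnostic
(F > 10 conventional).  Overall power for a binary outcome uses the closed
form of the published two-sample MR power calculator for case-control
outcomes, with a default assumed OR of 1.3 at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import GwasTable, VariantAssociation

__all__ = ["PowerReport", "MissingDataError", "instrument_r2", "f_statistic",
           "binary_outcome_power", "power_report"]


class MissingDataError(ValueError):
    """Required field (sample size) absent; power not evaluable."""


def _r2_full(eaf: float, beta: float, se: float, n: float) -> float:
    """Verbatim evaluation of the variance-explained formula with the EAF
    factor kept in numerator and denominator."""
    h = 2.0 * eaf * (1.0 - eaf)
    return h * beta**2 / (h * beta**2 + h * n * se**2)


def instrument_r2(v: VariantAssociation, allow_eaf_fallback: bool = True) -> float:
    """Variance in the exposure explained by one instrument.

    Uses the EAF form when the frequency is present; otherwise (and when
    ``allow_eaf_fallback``) the algebraically identical β²/(β² + N·se²)
    form.  Raises :class:`MissingDataError` when the sample size is absent
    or EAF is absent with the fallback disabled.
    """
    if v.n is None:
        raise MissingDataError(f"{v.snp_id}: sample size required for R²")
    if v.eaf is not None:
        return _r2_full(v.eaf, v.beta, v.se, v.n)
    if not allow_eaf_fallback:
        raise MissingDataError(f"{v.snp_id}: EAF absent and fallback disabled")
    return v.beta**2 / (v.beta**2 + v.n * v.se**2)


def f_statistic(r2: float, n: float) -> float:
    """F = R²·(N-2)/(1-R²); requires N > 2 and R² in [0, 1)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    return r2 * (n - 2.0) / (1.0 - r2)


def binary_outcome_power(r2_total: float, n_outcome: float, case_fraction: float,
                         assumed_or: float = 1.3, alpha: float = 0.05) -> float:
    """Power of a two-sample MR study with a case-control outcome.

    Closed form of the published MR power calculator for binary outcomes:
    with case fraction K and assumed odds ratio OR per exposure SD, the
    attenuated risk-difference effect is b = K·(OR/(1 + K·(OR-1)) - 1), its
    variance v = (K·(1-K) - b²)/(N·R²), and power is the chi-square(1)
    tail beyond the α critical value at non-centrality b²/v.
    """
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must be in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if r2_total <= 0.0:
        return alpha  # no instrument information: rejection at the type-I rate
    k = case_fraction
    b = k * (assumed_or / (1.0 + k * (assumed_or - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b**2) / (n_outcome * r2_total)
    ncp = b**2 / v
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


@dataclass
class PowerReport:
    """Instrument strength and power for one exposure-outcome pair."""

    r2_per_snp: np.ndarray
    r2_total: float
    f_per_snp: np.ndarray
    f_overall: float
    power: float
    assumed_or: float
    alpha: float
    n_outcome: float
    case_fraction: float
    eaf_fallback_used: bool

    @property
    def f_min(self) -> float:
        return float(self.f_per_snp.min()) if len(self.f_per_snp) else float("nan")


def power_report(exposure: GwasTable, instruments: Sequence[str],
                 n_outcome: float, case_fraction: float,
                 assumed_or: float = 1.3, alpha: float = 0.05) -> PowerReport:
    """Per-instrument R²/F and overall power for one pair.

    R² sums over instruments (approximately independent after clumping);
    the overall F uses the total R² at the exposure sample size.
    """
    recs = [exposure.get(s) for s in instruments]
    if not recs:
        raise MissingDataError("no instruments supplied")
    fallback = any(r.eaf is None for r in recs)
    r2 = np.array([instrument_r2(r) for r in recs])
    n_exp = np.array([r.n for r in recs], dtype=float)
    if np.any(np.isnan(n_exp)):
        raise MissingDataError("instrument sample sizes required")
    f = np.array([f_statistic(x, n) for x, n in zip(r2, n_exp)])
    r2_total = float(r2.sum())
    f_overall = f_statistic(min(r2_total, 1.0 - 1e-15), float(n_exp.mean()))
    pw = binary_outcome_power(r2_total, n_outcome, case_fraction,
                              assumed_or, alpha)
    return PowerReport(r2, r2_total, f, f_overall, pw, assumed_or, alpha,
                       n_outcome, case_fraction, fallback)
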