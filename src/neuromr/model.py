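"""Model/Results interface over the MR estimator toolbox.

`MendelianRandomization` is constructed from a harmonized exposure-outcome
pair (or built directly from two GWAS tables); `fit()` returns an
:class:`MRResults` carrying every requested estimate with its uncertainty,
the sensitivity battery, odds-ratio transforms and a text `summary()`.

    >>> model = MendelianRandomization.from_gwas(exposure, outcome)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import MREstimate, OddsRatioResult
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_io import GwasTable, HarmonizedPair, LDSource, harmonize_pair, \
    select_instruments

__all__ = ["MendelianRandomization", "MRResults"]


class MendelianRandomization:
    """Two-sample MR model for one harmonized exposure-outcome pair.

    The primary estimator follows the study convention: IVW when at least
    two instruments survive harmonization, the Wald ratio when exactly one
    does.
    """

    def __init__(self, pair: HarmonizedPair, outcome_type: str = "binary"):
        if pair.n_snp == 0:
            raise ValueError("harmonized pair has no instruments")
        self.pair = pair
        self.outcome_type = outcome_type

    # ------------------------------------------------------------------
    # constructors

    @classmethod
    def from_gwas(cls, exposure: GwasTable, outcome: GwasTable,
                  p_threshold: float = 5e-8, ld: LDSource | None = None,
                  r2_threshold: float = 0.001) -> "MendelianRandomization":
        """Select instruments from the exposure GWAS, harmonize, build."""
        instruments = select_instruments(exposure, p_threshold, ld, r2_threshold)
        if not instruments:
            raise ValueError(
                f"{exposure.trait_id}: no strong instrument at p < {p_threshold}")
        pair = harmonize_pair(exposure, outcome, instruments)
        if pair.n_snp == 0:
            raise ValueError("no instrument survived harmonization")
        return cls(pair, outcome_type=outcome.trait_type)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    snp_ids: Sequence[str] | None = None,
                    exposure_id: str = "exposure", outcome_id: str = "outcome",
                    outcome_type: str = "binary") -> "MendelianRandomization":
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(len(beta_exp))]
        snps = pd.DataFrame({
            "snp_id": list(snp_ids), "beta_exp": beta_exp,
            "se_exp": np.asarray(se_exp, dtype=float),
            "p_exp": np.ones(len(beta_exp)),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
        })
        return cls(HarmonizedPair(exposure_id, outcome_id, snps),
                   outcome_type=outcome_type)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure_id: str = "exposure",
                       outcome_id: str = "outcome",
                       outcome_type: str = "binary") -> "MendelianRandomization":
        """Build from a frame with the six harmonized per-SNP columns."""
        return cls(HarmonizedPair(exposure_id, outcome_id,
                                  df.reset_index(drop=True)),
                   outcome_type=outcome_type)

    # ------------------------------------------------------------------

    @property
    def n_snp(self) -> int:
        return self.pair.n_snp

    def default_methods(self, include_weighted_mode: bool = False) -> list[str]:
        """Method set under the study's reporting profile."""
        if self.n_snp == 1:
            return ["wald_ratio", "smr"]
        methods = ["ivw"]
        if self.n_snp >= 3:
            methods += ["egger", "weighted_median"]
            if include_weighted_mode:
                methods.append("weighted_mode")
        return methods

    def fit(self, methods: Sequence[str] | None = None, n_boot: int = 1000,
            bandwidth_phi: float = 1.0, seed: int | None = None,
            random_effects: bool = True,
            include_weighted_mode: bool = False) -> "MRResults":
        """Estimate the causal effect by every requested method.

        ``seed`` drives the parametric bootstraps of the weighted median and
        weighted mode.
        """
        if methods is None:
            methods = self.default_methods(include_weighted_mode)
        rng = np.random.default_rng(seed)
        pair = self.pair
        first = pair.snps.iloc[0]
        out: dict[str, MREstimate] = {}
        for m in methods:
            if m == "wald_ratio":
                out[m] = est.wald_ratio(first["beta_exp"], first["se_exp"],
                                        first["beta_out"], first["se_out"])
            elif m == "smr":
                out[m] = est.smr_test(first["beta_exp"], first["se_exp"],
                                      first["beta_out"], first["se_out"])
            elif m == "ivw":
                out[m] = est.ivw(pair, random_effects=random_effects)
            elif m == "egger":
                out["egger_slope"], out["egger_intercept"] = est.egger(pair)
            elif m == "weighted_median":
                out[m] = est.weighted_median(pair, n_boot=n_boot, seed=rng)
            elif m == "weighted_mode":
                out[m] = est.weighted_mode(pair, bandwidth_phi=bandwidth_phi,
                                           n_boot=n_boot, seed=rng)
            else:
                raise ValueError(f"unknown method {m!r}")
        return MRResults(self, out)


@dataclass
class MRResults:
    """Estimates and diagnostics from a fitted MR model."""

    model: MendelianRandomization
    estimates: dict[str, MREstimate]
    _sensitivity: SensitivityReport | None = field(default=None, repr=False)

    # ------------------------------------------------------------------
    # statsmodels-flavoured accessors

    @property
    def params(self) -> pd.Series:
        return pd.Series({m: e.beta for m, e in self.estimates.items()},
                         name="beta")

    @property
    def bse(self) -> pd.Series:
        return pd.Series({m: e.se for m, e in self.estimates.items()}, name="se")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({m: e.pvalue for m, e in self.estimates.items()},
                         name="pvalue")

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: (e.ci_low, e.ci_high) for m, e in self.estimates.items()},
            index=["ci_low", "ci_high"]).T

    @property
    def primary(self) -> MREstimate:
        """IVW for multi-instrument pairs, the Wald ratio for single-SNP."""
        if "ivw" in self.estimates:
            return self.estimates["ivw"]
        return self.estimates["wald_ratio"]

    @property
    def primary_method(self) -> str:
        return "ivw" if "ivw" in self.estimates else "wald_ratio"

    def odds_ratios(self) -> pd.DataFrame:
        rows = {}
        for m, e in self.estimates.items():
            if m == "egger_intercept":
                continue
            o: OddsRatioResult = est.to_odds_ratio(e, self.model.outcome_type)
            rows[m] = (o.odds_ratio, o.or_ci_low, o.or_ci_high, o.percent_change)
        return pd.DataFrame(rows, index=["odds_ratio", "or_ci_low",
                                         "or_ci_high", "percent_change"]).T

    def sensitivity(self, n_presso_sim: int = 2500, seed: int | None = None,
                    **kwargs) -> SensitivityReport:
        """Run (and cache) the sensitivity battery on the fitted pair."""
        if self._sensitivity is None:
            self._sensitivity = sensitivity_report(
                self.model.pair, n_presso_sim=n_presso_sim, seed=seed, **kwargs)
        return self._sensitivity

    def to_frame(self) -> pd.DataFrame:
        """One row per method: the machine-readable estimate table."""
        rows = [(m, e.beta, e.se, e.ci_low, e.ci_high, e.pvalue, e.n_snp)
                for m, e in self.estimates.items()]
        return pd.DataFrame(rows, columns=["method", "beta", "se", "ci_low",
                                           "ci_high", "pvalue", "n_snp"])

    def summary(self) -> str:
        pair = self.model.pair
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 70,
            f"exposure: {pair.exposure_id}    outcome: {pair.outcome_id}",
            f"instruments: {pair.n_snp}   primary method: {self.primary_method}",
            "-" * 70,
            f"{'method':<18}{'beta':>9}{'se':>9}{'95% CI':>21}{'p':>11}",
            "-" * 70,
        ]
        for m, e in self.estimates.items():
            ci = f"[{e.ci_low: .3f}, {e.ci_high: .3f}]"
            lines.append(f"{m:<18}{e.beta:>9.3f}{e.se:>9.3f}{ci:>21}"
                         f"{e.pvalue:>11.3g}")
        if self.model.outcome_type == "binary":
            o = est.to_odds_ratio(self.primary)
            lines += ["-" * 70,
                      f"primary OR: {o.odds_ratio:.2f} "
                      f"[{o.or_ci_low:.2f}, {o.or_ci_high:.2f}]  "
                      f"({o.percent_change:+.0f}% risk change)"]
        lines.append("=" * 70)
        return "\n".join(lines)
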