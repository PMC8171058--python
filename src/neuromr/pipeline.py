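"""End-to-end study orchestration.

Enumerate every exposure-outcome pair, run instrument selection ->
harmonization -> estimation -> sensitivity -> power, then pool the per-pair
p-values for the inflation analysis — deterministically under a single
global seed.  Per-pair and per-stage seeds are derived from the global seed
by a stable blake2 hash of the (stage, pair) labels, so any stage can be
re-run in isolation and reproduce.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import estimators as est
from .model import MendelianRandomization
from .power import MissingDataError, power_report
from .sensitivity import mr_presso, reverse_mr, sensitivity_report, \
    funnel_data, leave_one_out
from .simulate import StudyCollection
from .summary_io import GwasTable, HarmonizedPair, LDSource, harmonize_pair, \
    select_instruments, read_gwas_table

logger = logging.getLogger(__name__)

__all__ = ["StudySettings", "StudyConfig", "StudyResult", "run_study",
           "report_top_findings", "derive_seed"]


def derive_seed(global_seed: int, *parts: object) -> int:
    """Stable per-stage seed: blake2s of 'global/part/part/...' mod 2^31."""
    key = "/".join([str(global_seed), *[str(p) for p in parts]])
    digest = hashlib.blake2s(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class StudySettings:
    """Thresholds, method toggles and seeds for one study run.

    Defaults are the study's analysis choices: instrument p < 5e-8, clumping
    r² < 0.001, 2500 MR-PRESSO simulations, 1000 inflation permutations, and
    Bonferroni tiers at 0.05 / #exposures and 0.05 / #pairs.
    """

    seed: int
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    n_presso_sim: int = 2500
    presso_signif: float = 0.05
    n_boot: int = 1000
    run_reverse: bool = True
    run_permutation: bool = False
    permutation_B: int = 1000
    permutation_targets: tuple[str, ...] = ("BP", "AN")
    include_weighted_mode: bool = False
    pool_primary: str = "both"  # 'both' (IVW + Wald ratio) | 'ivw_only'
    study_wide_denominator: str = "enumerated"  # | 'tested'
    assumed_or: float = 1.3
    power_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    default_case_fraction: float = 0.33

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pool_primary not in ("both", "ivw_only"):
            raise ValueError("pool_primary must be 'both' or 'ivw_only'")
        if self.study_wide_denominator not in ("enumerated", "tested"):
            raise ValueError("study_wide_denominator must be "
                             "'enumerated' or 'tested'")


_ROW_COLS = [
    "exposure_id", "outcome_id", "exposure_class", "status", "n_instruments",
    "primary_method", "beta", "se", "ci_low", "ci_high", "pvalue",
    "beta_egger", "p_egger", "egger_intercept", "egger_intercept_p",
    "beta_wmedian", "p_wmedian", "beta_wmode", "p_wmode", "beta_smr", "p_smr",
    "cochran_q", "cochran_p", "rucker_q", "rucker_p",
    "presso_global_p", "presso_n_outliers", "presso_distortion_p",
    "pvalue_outlier_corrected", "reverse_p", "directionality_ok",
    "r2_total", "f_overall", "power",
]


@dataclass
class StudyResult:
    """Bundle of everything one study run produced."""

    results: pd.DataFrame
    pooled: dict[str, agg.PooledResult]
    tiers: pd.Series | None
    overlap_normalized: dict[str, pd.DataFrame]
    overlap_counts: dict[str, pd.DataFrame]
    counts: dict
    pairs: dict[tuple[str, str], HarmonizedPair]
    settings: StudySettings

    def pooled_table(self) -> pd.DataFrame:
        rows = []
        for key, pr in self.pooled.items():
            rows.append((key, pr.stratum, pr.lambda_hat, pr.lambda_ci[0],
                         pr.lambda_ci[1], pr.ks_p, pr.n_pvalues,
                         pr.permutation_p_lambda, pr.permutation_p_ks))
        return pd.DataFrame(rows, columns=[
            "key", "stratum", "lambda", "lambda_ci_low", "lambda_ci_high",
            "ks_p", "n_pvalues", "perm_p_lambda", "perm_p_ks"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results = self.results.copy()
        if self.tiers is not None:
            results["tier"] = self.tiers
        results.to_csv(outdir / "results.tsv", sep="\t", index=False)
        self.pooled_table().to_csv(outdir / "pooled.tsv", sep="\t", index=False)
        for klass, tab in self.overlap_counts.items():
            tab.to_csv(outdir / f"overlap_counts_{klass}.tsv", sep="\t")
        for klass, tab in self.overlap_normalized.items():
            tab.to_csv(outdir / f"overlap_normalized_{klass}.tsv", sep="\t")
        if self.pairs:
            frames = []
            for (e, o), pair in self.pairs.items():
                f = pair.snps[HarmonizedPair.HARMONIZED_COLS].copy()
                f.insert(0, "outcome_id", o)
                f.insert(0, "exposure_id", e)
                frames.append(f)
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "instruments.tsv", sep="\t", index=False)
        manifest = {
            "settings": asdict(self.settings),
            "counts": self.counts,
            "artifacts": sorted(p.name for p in outdir.glob("*.tsv")),
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["settings"], sort_keys=True).encode()
        ).hexdigest()[:16]
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _nan_row(e: str, o: str, klass: str, status: str) -> dict:
    row = {c: np.nan for c in _ROW_COLS}
    row.update(exposure_id=e, outcome_id=o, exposure_class=klass,
               status=status, n_instruments=0, primary_method="")
    return row


def _analyze_pair(exposure: GwasTable, outcome: GwasTable, klass: str,
                  instruments: list[str], settings: StudySettings,
                  case_fraction: float, ld: LDSource | None
                  ) -> tuple[dict, HarmonizedPair | None]:
    e_id, o_id = exposure.trait_id, outcome.trait_id
    if not instruments:
        return _nan_row(e_id, o_id, klass, "no_strong_instrument"), None
    pair = harmonize_pair(exposure, outcome, instruments)
    if pair.n_snp == 0:
        return _nan_row(e_id, o_id, klass, "no_instrument_after_harmonization"), None

    model = MendelianRandomization(pair, outcome_type=outcome.trait_type)
    fit_seed = derive_seed(settings.seed, "fit", e_id, o_id)
    res = model.fit(n_boot=settings.n_boot, seed=fit_seed,
                    include_weighted_mode=settings.include_weighted_mode)
    sens = sensitivity_report(
        pair, n_presso_sim=settings.n_presso_sim,
        presso_signif=settings.presso_signif,
        seed=derive_seed(settings.seed, "presso", e_id, o_id),
        heterogeneity_alpha=settings.heterogeneity_alpha)

    primary = res.primary
    row = _nan_row(e_id, o_id, klass, "ok")
    row.update(n_instruments=pair.n_snp, primary_method=res.primary_method,
               beta=primary.beta, se=primary.se, ci_low=primary.ci_low,
               ci_high=primary.ci_high, pvalue=primary.pvalue)
    for name, (bcol, pcol) in {
        "egger_slope": ("beta_egger", "p_egger"),
        "weighted_median": ("beta_wmedian", "p_wmedian"),
        "weighted_mode": ("beta_wmode", "p_wmode"),
        "smr": ("beta_smr", "p_smr"),
    }.items():
        if name in res.estimates:
            row[bcol] = res.estimates[name].beta
            row[pcol] = res.estimates[name].pvalue
    if "egger_intercept" in res.estimates:
        row["egger_intercept"] = res.estimates["egger_intercept"].beta
        row["egger_intercept_p"] = res.estimates["egger_intercept"].pvalue

    row.update(cochran_q=sens.cochran_q, cochran_p=sens.cochran_p,
               rucker_q=sens.rucker_q, rucker_p=sens.rucker_p)
    presso = sens.presso
    if presso is not None and presso.status == "ok":
        row["presso_global_p"] = presso.global_p
        row["presso_n_outliers"] = len(presso.outliers)
        row["presso_distortion_p"] = presso.distortion_p
        row["pvalue_outlier_corrected"] = (
            presso.corrected_ivw.pvalue if presso.corrected_ivw is not None
            else primary.pvalue)
    else:
        row["pvalue_outlier_corrected"] = primary.pvalue

    if settings.run_reverse:
        rev = reverse_mr(outcome, exposure, settings.p_threshold, ld,
                         settings.r2_threshold)
        if rev.status == "ok":
            row["reverse_p"] = rev.estimate.pvalue
            row["directionality_ok"] = rev.directionality_ok

    try:
        pw = power_report(exposure, pair.snps["snp_id"].tolist(),
                          n_outcome=float(outcome.data["n"].iloc[0])
                          if outcome.data["n"].notna().any() else 50_000.0,
                          case_fraction=case_fraction,
                          assumed_or=settings.assumed_or,
                          alpha=settings.power_alpha)
        row.update(r2_total=pw.r2_total, f_overall=pw.f_overall, power=pw.power)
    except MissingDataError:
        logger.warning("%s-%s: power not evaluable (missing EAF/N)", e_id, o_id)
    return row, pair


def run_study(study: StudyCollection, settings: StudySettings,
              ld: LDSource | None = None,
              case_fractions: Mapping[str, float] | None = None) -> StudyResult:
    """Execute the full pipeline over every enumerated pair.

    Pairs that fail individually are recorded with an error status and never
    abort the run.  Deterministic under ``settings.seed``.
    """
    case_fractions = dict(case_fractions or {})
    truth = study.truth
    if truth is None or truth.empty:
        rows = [(e, o, "dti") for e in study.exposures for o in study.outcomes]
        truth = pd.DataFrame(rows, columns=["exposure_id", "outcome_id",
                                            "exposure_class"])

    instrument_cache: dict[str, list[str]] = {}
    rows: list[dict] = []
    pairs: dict[tuple[str, str], HarmonizedPair] = {}

    for rec in truth.itertuples(index=False):
        e_id, o_id, klass = rec.exposure_id, rec.outcome_id, rec.exposure_class
        exposure = study.exposures[e_id]
        outcome = study.outcomes[o_id]
        if e_id not in instrument_cache:
            instrument_cache[e_id] = select_instruments(
                exposure, settings.p_threshold, ld, settings.r2_threshold,
                settings.window_kb)
        cf = case_fractions.get(o_id, settings.default_case_fraction)
        try:
            row, pair = _analyze_pair(exposure, outcome, klass,
                                      instrument_cache[e_id], settings, cf, ld)
        except Exception as exc:  # noqa: BLE001 — a pair must not abort the study
            logger.exception("pair %s-%s failed", e_id, o_id)
            row, pair = _nan_row(e_id, o_id, klass, f"error:{exc}"), None
        rows.append(row)
        if pair is not None:
            pairs[(e_id, o_id)] = pair

    results = pd.DataFrame(rows, columns=_ROW_COLS)
    counts = _summarize_counts(results)

    pooled: dict[str, agg.PooledResult] = {}
    classes = sorted(results["exposure_class"].dropna().unique())
    for klass in classes:
        sub = results[results["exposure_class"] == klass]
        analyzed = sub[sub["status"] == "ok"]
        if settings.pool_primary == "ivw_only":
            analyzed = analyzed[analyzed["primary_method"] == "ivw"]
        _pool_strata(pooled, analyzed, klass, "all", settings)
        for disease in sorted(sub["outcome_id"].unique()):
            dsub = analyzed[analyzed["outcome_id"] == disease]
            _pool_strata(pooled, dsub, klass, disease, settings)
            if (settings.run_permutation
                    and disease in settings.permutation_targets):
                dpairs = [pairs[(e, o)] for e, o in
                          zip(dsub["exposure_id"], dsub["outcome_id"])
                          if (e, o) in pairs and pairs[(e, o)].n_snp >= 2]
                key = f"{klass}/{disease}/original"
                if key in pooled and len(dpairs) >= 5:
                    ppl, ppk, _ = agg.permutation_null(
                        dpairs, settings.permutation_B,
                        seed=derive_seed(settings.seed, "perm", klass, disease))
                    pr = pooled[key]
                    pooled[key] = agg.PooledResult(
                        pr.lambda_hat, pr.lambda_ci, pr.ks_p, pr.n_pvalues,
                        ppl, ppk, pr.stratum)

    tiers, overlap_norm, overlap_cnt = None, {}, {}
    ok = results[results["status"] == "ok"]
    if len(ok):
        denom = {}
        for klass in classes:
            sub = results[results["exposure_class"] == klass]
            if settings.study_wide_denominator == "enumerated":
                denom[klass] = len(sub)
            else:
                denom[klass] = int((sub["status"] == "ok").sum())
        tiers_all, _, _ = agg.classify_tiers(
            ok, n_pairs_dti=denom.get("dti", len(ok)),
            n_pairs_roi=denom.get("roi", len(ok)))
        tiers = tiers_all.reindex(results.index).fillna("NS")
        for klass in classes:
            sub = ok[ok["exposure_class"] == klass]
            if len(sub):
                _, overlap_norm[klass], overlap_cnt[klass] = agg.classify_tiers(
                    sub, n_pairs_dti=denom.get("dti", len(ok)),
                    n_pairs_roi=denom.get("roi", len(ok)))

    logger.info("study complete: %s", counts)
    return StudyResult(results, pooled, tiers, overlap_norm, overlap_cnt,
                       counts, pairs, settings)


def _pool_strata(pooled: dict, sub: pd.DataFrame, klass: str, label: str,
                 settings: StudySettings) -> None:
    pvals = sub["pvalue"].dropna()
    if len(pvals) >= 5:
        pooled[f"{klass}/{label}/original"] = agg.pooled_result(
            pvals.to_numpy(), stratum=f"{klass}/{label}/original")
        for mode, tag in (("remove_heterogeneous", "heterogeneity-removed"),
                          ("remove_outlier_snps", "outlier-removed")):
            try:
                pooled[f"{klass}/{label}/{tag}"] = agg.stratified_rerun(
                    sub, mode, stratum_label=f"{klass}/{label}/{tag}",
                    heterogeneity_alpha=settings.heterogeneity_alpha)
            except ValueError:
                pass


def _summarize_counts(results: pd.DataFrame) -> dict:
    counts: dict = {}
    for klass in sorted(results["exposure_class"].dropna().unique()):
        sub = results[results["exposure_class"] == klass]
        counts[klass] = {
            "enumerated": int(len(sub)),
            "analyzed": int((sub["status"] == "ok").sum()),
            "excluded": int((sub["status"] != "ok").sum()),
        }
    return counts


def report_top_findings(bundle: StudyResult, max_p: float | None = None,
                        tier: str = "single_disease") -> dict[str, dict]:
    """Forest-, leave-one-out- and funnel-ready tables for top pairs.

    A pair qualifies if its primary p is below ``max_p`` (when given) or its
    tier is at/above ``tier``.  The forest table has one Wald-ratio row per
    SNP plus a final IVW meta row; OR columns are the exponentiated betas.
    """
    order = {t: i for i, t in enumerate(["NS", "nominal", "single_disease",
                                         "study_wide"])}
    res = bundle.results
    if max_p is not None:
        mask = res["pvalue"] < max_p
    else:
        if bundle.tiers is None:
            raise ValueError("no tiers available; pass max_p")
        mask = bundle.tiers.map(order).fillna(0) >= order[tier]
    out: dict[str, dict] = {}
    for _, row in res[mask & (res["status"] == "ok")].iterrows():
        key = (row["exposure_id"], row["outcome_id"])
        pair = bundle.pairs.get(key)
        if pair is None:
            continue
        rows = []
        for _, s in pair.snps.iterrows():
            w = est.wald_ratio(s["beta_exp"], s["se_exp"],
                               s["beta_out"], s["se_out"])
            rows.append((s["snp_id"], "wald_ratio", w.beta, w.ci_low,
                         w.ci_high, w.pvalue))
        iv = (est.ivw(pair) if pair.n_snp >= 2
              else est.wald_ratio(*pair.snps.iloc[0][["beta_exp", "se_exp",
                                                      "beta_out", "se_out"]]))
        rows.append(("(meta)", iv.method, iv.beta, iv.ci_low, iv.ci_high,
                     iv.pvalue))
        forest = pd.DataFrame(rows, columns=["snp_id", "method", "beta",
                                             "ci_low", "ci_high", "pvalue"])
        for c in ("beta", "ci_low", "ci_high"):
            forest[f"or_{c}"] = np.exp(forest[c])
        entry = {"forest": forest,
                 "egger_reference": (est.egger(pair)[0].beta
                                     if pair.n_snp >= 3 else None)}
        if pair.n_snp >= 3:
            entry["leave_one_out"] = leave_one_out(pair)
        fd, refs = funnel_data(pair)
        entry["funnel"] = fd
        entry["funnel_refs"] = refs
        out[f"{key[0]}-{key[1]}"] = entry
    return out


# ---------------------------------------------------------------------------
# file-based configuration


@dataclass
class StudyConfig:
    """File-backed study description (YAML), for CLI runs.

    ``exposures``/``outcomes`` map trait ids to {file, type, class,
    case_fraction}; thresholds and seeds live under ``settings``.
    """

    exposures: dict
    outcomes: dict
    settings: StudySettings
    ld_file: str | None = None
    output_dir: str = "mr_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        st = StudySettings(**raw.get("settings", {}))
        cfg = cls(exposures=raw["exposures"], outcomes=raw["outcomes"],
                  settings=st, ld_file=raw.get("ld_file"),
                  output_dir=raw.get("output_dir", "mr_results"))
        base = Path(path).parent
        for manifest in (cfg.exposures, cfg.outcomes):
            for tid, entry in manifest.items():
                f = base / entry["file"]
                if not f.exists():
                    raise FileNotFoundError(f"{tid}: {f} not found")
                entry["file"] = str(f)
        return cfg

    _DEFAULT_MAP = {"snp_id": "snp_id", "effect_allele": "effect_allele",
                    "other_allele": "other_allele", "effect": "beta",
                    "se": "se", "pvalue": "pvalue", "eaf": "eaf", "n": "n"}

    def load(self) -> tuple[StudyCollection, dict, LDSource | None]:
        """Read every referenced table; returns (collection, case_fractions,
        ld source)."""
        exposures, outcomes = {}, {}
        rows = []
        for tid, entry in self.exposures.items():
            t = read_gwas_table(entry["file"],
                                entry.get("column_map", self._DEFAULT_MAP),
                                entry.get("type", "continuous"),
                                effect_is=entry.get("effect_is", "beta"))
            t.trait_id = tid
            exposures[tid] = t
        cfs = {}
        for tid, entry in self.outcomes.items():
            t = read_gwas_table(entry["file"],
                                entry.get("column_map", self._DEFAULT_MAP),
                                entry.get("type", "binary"),
                                effect_is=entry.get("effect_is", "beta"))
            t.trait_id = tid
            outcomes[tid] = t
            if "case_fraction" in entry:
                cfs[tid] = float(entry["case_fraction"])
        for e_id, entry in self.exposures.items():
            for o_id in outcomes:
                rows.append((e_id, o_id, entry.get("class", "dti"), np.nan,
                             True))
        truth = pd.DataFrame(rows, columns=["exposure_id", "outcome_id",
                                            "exposure_class", "causal_beta",
                                            "has_instrument"])
        ld = LDSource.read(self.ld_file) if self.ld_file else None
        return StudyCollection(exposures, outcomes, truth), cfs, ld
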