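"""Reading, validation and harmonization of GWAS summary statistics.

The unit of input is a GWAS summary-statistic table: one row per SNP with an
identifier, the two alleles, an effect size (beta on the log-odds scale for
binary traits, or an odds ratio that is log-transformed at ingestion), its
standard error, a p-value, and optionally the effect-allele frequency and the
sample size.  From two such tables — one for an exposure (e.g. a white-matter
DTI parameter) and one for an outcome (e.g. a psychiatric disorder) — this
module selects approximately independent genome-wide-significant instruments
and aligns the per-SNP effects onto a common effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_PVALUE",
    "VariantAssociation",
    "GwasTable",
    "HarmonizedPair",
    "LDSource",
    "read_gwas_table",
    "select_instruments",
    "harmonize_pair",
]

#: Floor applied to p-values of exactly 0 before any log/quantile transform.
MIN_PVALUE: float = float(np.finfo(float).tiny)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: Canonical column order of the in-memory summary-statistic frame.
_CANON_COLS = ["snp_id", "effect_allele", "other_allele", "beta", "se",
               "pvalue", "eaf", "n"]


class ConfigurationError(ValueError):
    """A column mapping or study configuration is incomplete or inconsistent."""


class EmptyTableError(ValueError):
    """No valid rows survived ingestion."""


@dataclass(frozen=True, slots=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-allele effect on the trait (log-odds for binary
    traits); ``eaf`` is the effect-allele frequency, absent in many disorder
    GWAS; ``n`` is the association sample size.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must be in (0, 1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError("eaf must be in (0, 1) when present")
        if self.n is not None and self.n <= 0:
            raise ValueError("n must be a positive integer when present")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC


@dataclass
class GwasTable:
    """A full summary-statistic table for one trait.

    ``data`` holds one row per SNP in canonical columns
    (snp_id, effect_allele, other_allele, beta, se, pvalue, eaf, n) with
    snp_id unique.  Binary traits carry beta on the log-odds scale.
    """

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    data: pd.DataFrame
    n_dropped_invalid: int = 0
    n_dropped_duplicate: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.data["snp_id"].duplicated().any():
            raise ValueError("snp_id must be unique within a GwasTable")

    def __len__(self) -> int:
        return len(self.data)

    def get(self, snp_id: str) -> VariantAssociation:
        row = self.data.loc[self.data["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        return VariantAssociation(
            snp_id=r["snp_id"], effect_allele=r["effect_allele"],
            other_allele=r["other_allele"], beta=float(r["beta"]),
            se=float(r["se"]), pvalue=float(r["pvalue"]),
            eaf=None if pd.isna(r["eaf"]) else float(r["eaf"]),
            n=None if pd.isna(r["n"]) else int(r["n"]),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedPair:
    """Allele-aligned per-SNP effect pairs for one exposure-outcome pair.

    ``snps`` has columns snp_id, beta_exp, se_exp, p_exp, beta_out, se_out;
    every row survived allele reconciliation (palindromic SNPs are kept under
    a forward-strand assumption).  An empty frame means the pair is excluded
    downstream.
    """

    exposure_id: str
    outcome_id: str
    snps: pd.DataFrame
    n_dropped_mismatch: int = 0
    palindromic_kept: int = 0

    HARMONIZED_COLS = ["snp_id", "beta_exp", "se_exp", "p_exp",
                       "beta_out", "se_out"]

    def __post_init__(self) -> None:
        missing = [c for c in self.HARMONIZED_COLS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"harmonized frame missing columns {missing}")
        if len(self.snps):
            if not (self.snps["se_exp"] > 0).all() or not (self.snps["se_out"] > 0).all():
                raise ValueError("harmonized standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        s = self.snps
        return (s["beta_exp"].to_numpy(float), s["se_exp"].to_numpy(float),
                s["beta_out"].to_numpy(float), s["se_out"].to_numpy(float))

    def subset(self, keep: Sequence[bool] | Sequence[int]) -> "HarmonizedPair":
        sub = self.snps.iloc[np.asarray(keep)] if np.asarray(keep).dtype != bool \
            else self.snps.loc[np.asarray(keep)]
        return HarmonizedPair(self.exposure_id, self.outcome_id,
                              sub.reset_index(drop=True),
                              self.n_dropped_mismatch, self.palindromic_kept)

    def drop_snps(self, snp_ids: Iterable[str]) -> "HarmonizedPair":
        drop = set(snp_ids)
        sub = self.snps[~self.snps["snp_id"].isin(drop)].reset_index(drop=True)
        return HarmonizedPair(self.exposure_id, self.outcome_id, sub,
                              self.n_dropped_mismatch, self.palindromic_kept)

    def to_tsv(self, path: str | Path) -> None:
        out = self.snps[self.HARMONIZED_COLS].copy()
        out.insert(0, "outcome_id", self.outcome_id)
        out.insert(0, "exposure_id", self.exposure_id)
        out.to_csv(path, sep="\t", index=False)


class LDSource:
    """Pairwise linkage-disequilibrium (r²) lookups.

    Backed either by a square correlation/r² matrix with a SNP-id header, or
    by a long table of (snp_a, snp_b, r2) rows; pairs absent from a long
    table are treated as unlinked (r² = 0).  Optional SNP positions enable
    window-restricted clumping.
    """

    def __init__(self, r2: pd.DataFrame | None = None,
                 pair_table: pd.DataFrame | None = None,
                 positions: Mapping[str, tuple[str, int]] | None = None,
                 values_are_r: bool = False):
        if (r2 is None) == (pair_table is None):
            raise ConfigurationError("supply exactly one of r2 matrix or pair table")
        self._positions = dict(positions) if positions else None
        if r2 is not None:
            mat = r2.astype(float)
            if list(mat.index) != list(mat.columns):
                mat.index = mat.columns
            if values_are_r:
                mat = mat ** 2
            self._mat = mat
            self._pairs = None
        else:
            tab = pair_table.copy()
            tab.columns = ["snp_a", "snp_b", "r2"][: len(tab.columns)]
            vals = tab["r2"].astype(float)
            if values_are_r:
                vals = vals ** 2
            self._pairs = {}
            for a, b, v in zip(tab["snp_a"], tab["snp_b"], vals):
                key = (a, b) if a <= b else (b, a)
                self._pairs[key] = float(v)
            self._mat = None

    @classmethod
    def from_matrix(cls, mat: pd.DataFrame | np.ndarray,
                    snp_ids: Sequence[str] | None = None,
                    values_are_r: bool = False,
                    positions: Mapping[str, tuple[str, int]] | None = None) -> "LDSource":
        if isinstance(mat, np.ndarray):
            if snp_ids is None:
                raise ConfigurationError("snp_ids required with a bare matrix")
            mat = pd.DataFrame(mat, index=list(snp_ids), columns=list(snp_ids))
        return cls(r2=mat, values_are_r=values_are_r, positions=positions)

    @classmethod
    def from_table(cls, table: pd.DataFrame, values_are_r: bool = False,
                   positions: Mapping[str, tuple[str, int]] | None = None) -> "LDSource":
        return cls(pair_table=table, values_are_r=values_are_r, positions=positions)

    @classmethod
    def read(cls, path: str | Path, **kwargs) -> "LDSource":
        """Read a 3-column pair table or a square matrix (id header) from disk."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] == 3 and df.shape[0] != df.shape[1] - 1:
            return cls.from_table(df, **kwargs)
        return cls(r2=df.set_index(df.columns[0]) if df.shape[0] == df.shape[1] - 1
                   else df, **kwargs)

    @property
    def has_positions(self) -> bool:
        return self._positions is not None

    def position(self, snp_id: str) -> tuple[str, int] | None:
        return self._positions.get(snp_id) if self._positions else None

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._mat is not None:
            if a in self._mat.index and b in self._mat.columns:
                return float(self._mat.loc[a, b])
            return 0.0
        key = (a, b) if a <= b else (b, a)
        return self._pairs.get(key, 0.0)

    def submatrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Dense r² matrix over the given SNPs (1 on the diagonal)."""
        ids = list(snp_ids)
        out = np.eye(len(ids))
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                out[i, j] = out[j, i] = self.r2(a, ids[j])
        return out


def read_gwas_table(path: str | Path, column_map: Mapping[str, str],
                    trait_type: str, effect_is: str = "beta",
                    sep: str | None = None) -> GwasTable:
    """Read a delimited summary-statistic table into a :class:`GwasTable`.

    ``column_map`` maps canonical names (snp_id, effect_allele, other_allele,
    effect, se, pvalue, and optionally eaf, n) to file columns.  ``effect_is``
    declares whether the effect column holds betas or odds ratios; odds
    ratios are log-transformed.  Rows with missing or invalid se/p are
    dropped and counted.
    """
    mandatory = ["snp_id", "effect_allele", "other_allele", "effect", "se", "pvalue"]
    missing = [k for k in mandatory if k not in column_map]
    if missing:
        raise ConfigurationError(f"column_map missing mandatory keys: {missing}")
    if effect_is not in ("beta", "or"):
        raise ConfigurationError(f"effect_is must be 'beta' or 'or', got {effect_is!r}")

    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    absent = [v for v in column_map.values() if v not in raw.columns]
    if absent:
        raise ConfigurationError(f"mapped columns absent from file: {absent}")

    df = pd.DataFrame({
        "snp_id": raw[column_map["snp_id"]].astype(str),
        "effect_allele": raw[column_map["effect_allele"]].astype(str).str.upper(),
        "other_allele": raw[column_map["other_allele"]].astype(str).str.upper(),
        "beta": pd.to_numeric(raw[column_map["effect"]], errors="coerce"),
        "se": pd.to_numeric(raw[column_map["se"]], errors="coerce"),
        "pvalue": pd.to_numeric(raw[column_map["pvalue"]], errors="coerce"),
    })
    df["eaf"] = (pd.to_numeric(raw[column_map["eaf"]], errors="coerce")
                 if "eaf" in column_map else np.nan)
    df["n"] = (pd.to_numeric(raw[column_map["n"]], errors="coerce")
               if "n" in column_map else np.nan)

    if effect_is == "or":
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(df["beta"])

    df.loc[df["pvalue"] == 0.0, "pvalue"] = MIN_PVALUE
    valid = (
        df["beta"].notna() & np.isfinite(df["beta"])
        & df["se"].notna() & (df["se"] > 0)
        & df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("%s: dropped %d invalid rows", path, n_invalid)
    df = df.loc[valid]

    # duplicate ids: keep the row with the smallest p
    n_dup = int(df["snp_id"].duplicated().sum())
    if n_dup:
        logger.info("%s: resolving %d duplicate snp_id rows by smallest p", path, n_dup)
        df = df.sort_values("pvalue", kind="stable").drop_duplicates("snp_id")
        df = df.sort_index()

    if df.empty:
        raise EmptyTableError(f"no valid rows in {path}")

    trait_id = Path(path).stem
    return GwasTable(trait_id=trait_id, trait_type=trait_type,
                     data=df[_CANON_COLS].reset_index(drop=True),
                     n_dropped_invalid=n_invalid, n_dropped_duplicate=n_dup)


def select_instruments(gwas: GwasTable, p_threshold: float = 5e-8,
                       ld: LDSource | None = None, r2_threshold: float = 0.001,
                       window_kb: float = 10_000.0) -> list[str]:
    """Select genome-wide-significant, approximately independent instruments.

    SNPs with p below ``p_threshold`` are greedily clumped: the remaining SNP
    with the smallest p is kept, and every other surviving SNP with
    r² ≥ ``r2_threshold`` to it (within ``window_kb`` when positions are
    available) is removed.  Returns kept SNPs in ascending-p order; an empty
    list marks the trait as having no strong instrument.
    """
    sig = gwas.data.loc[gwas.data["pvalue"] < p_threshold]
    if sig.empty:
        return []
    order = sig.sort_values(["pvalue", "snp_id"], kind="stable")["snp_id"].tolist()
    if ld is None:
        return order

    kept: list[str] = []
    removed: set[str] = set()
    use_window = ld.has_positions
    for snp in order:
        if snp in removed:
            continue
        kept.append(snp)
        for other in order:
            if other == snp or other in removed:
                continue
            if use_window:
                pa, pb = ld.position(snp), ld.position(other)
                if pa is not None and pb is not None:
                    if pa[0] != pb[0] or abs(pa[1] - pb[1]) > window_kb * 1000:
                        continue
            if ld.r2(snp, other) >= r2_threshold:
                removed.add(other)
    return kept


def _reconcile(ea_e: str, oa_e: str, ea_o: str, oa_o: str) -> tuple[str, bool] | None:
    """How to align an outcome record onto the exposure's allele orientation.

    Returns (kind, flip) where kind is 'direct'/'palindromic'/'complement'
    and flip says whether the outcome beta changes sign; None if the allele
    pairs are irreconcilable.
    """
    if (ea_e, oa_e) in _PALINDROMIC:
        # palindromic SNP: strand is ambiguous; keep under forward-strand
        # assumption, direct match or swap only
        if (ea_o, oa_o) == (ea_e, oa_e):
            return "palindromic", False
        if (ea_o, oa_o) == (oa_e, ea_e):
            return "palindromic", True
        return None
    if (ea_o, oa_o) == (ea_e, oa_e):
        return "direct", False
    if (ea_o, oa_o) == (oa_e, ea_e):
        return "direct", True
    cea, coa = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
    if (cea, coa) == (ea_e, oa_e):
        return "complement", False
    if (cea, coa) == (oa_e, ea_e):
        return "complement", True
    return None


def harmonize_pair(exposure: GwasTable, outcome: GwasTable,
                   instruments: Sequence[str]) -> HarmonizedPair:
    """Align outcome effects onto the exposure's effect alleles.

    Instruments absent from the outcome table are dropped (counted); allele
    pairs matching after swap have the outcome beta negated; strand
    complements are resolved; palindromic SNPs are kept under a
    forward-strand assumption; irreconcilable pairs are dropped and counted.
    """
    exp = exposure.data.set_index("snp_id")
    out = outcome.data.set_index("snp_id")
    rows, n_dropped, n_palin = [], 0, 0
    for snp in instruments:
        if snp not in exp.index:
            raise KeyError(f"instrument {snp!r} not in exposure table")
        if snp not in out.index:
            n_dropped += 1
            continue
        e, o = exp.loc[snp], out.loc[snp]
        rec = _reconcile(e["effect_allele"], e["other_allele"],
                         o["effect_allele"], o["other_allele"])
        if rec is None:
            n_dropped += 1
            continue
        kind, flip = rec
        if kind == "palindromic":
            n_palin += 1
        beta_out = -float(o["beta"]) if flip else float(o["beta"])
        rows.append((snp, float(e["beta"]), float(e["se"]), float(e["pvalue"]),
                     beta_out, float(o["se"])))
    if n_dropped:
        logger.info("%s-%s: dropped %d instruments during harmonization",
                    exposure.trait_id, outcome.trait_id, n_dropped)
    snps = pd.DataFrame(rows, columns=HarmonizedPair.HARMONIZED_COLS)
    return HarmonizedPair(exposure.trait_id, outcome.trait_id, snps,
                          n_dropped_mismatch=n_dropped, palindromic_kept=n_palin)
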