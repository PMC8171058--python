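"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of the real study inputs — a
UK-Biobank-scale continuous imaging exposure GWAS (N ≈ 17,700) paired with
consortium-scale binary disorder GWAS — without simulating individual-level
genotypes.  Per SNP j with minor-allele frequency MAF_j:

* the true exposure effect γ_j comes from a two-component mixture
  (exactly-zero null + a large-effect normal component whose scale is solved
  so the expected number of genome-wide-significant SNPs matches a request);
* observed exposure beta = γ_j + noise, se = 1/sqrt(2·MAF(1-MAF)·N_exp)
  (standardized-trait approximation);
* the true outcome effect is Γ_j = b·γ_j + α_j where b is the causal effect
  and α_j a configurable horizontal-pleiotropy term (absent, balanced,
  directional, or correlated with γ — the latter violating InSIDE);
* observed outcome beta = Γ_j + noise, with binary outcomes on the log-odds
  scale and se additionally scaled by 1/sqrt(case_fraction·(1-case_fraction)).

p-values are the exact two-sided normal tail of beta/se, so the
(beta, se, p) triple is internally consistent by construction.  A fixed seed
fully determines every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .summary_io import MIN_PVALUE, GwasTable

__all__ = [
    "SimConfig", "SimTruth", "StudyCollection",
    "simulate_pair", "simulate_study_collection", "simulate_ld",
    "DTI_TRACTS", "DTI_PARAMETERS", "DISORDERS",
]

#: Two-sided genome-wide significance threshold used throughout.
GWS_P = 5e-8
_Z_GWS = float(stats.norm.isf(GWS_P / 2))

#: 22 white-matter tract labels (21 tracts + overall mean) and the 5 DTI
#: parameters, giving the 110 exposure labels of a full DTI study.
DTI_TRACTS = ["Mean", "ACR", "ALIC", "BCC", "CGC", "CGH", "CST", "EC", "FX",
              "FXST", "GCC", "IFO", "PCR", "PLIC", "PTR", "RLIC", "SCC",
              "SCR", "SFO", "SLF", "SS", "UNC"]
DTI_PARAMETERS = ["FA", "AxD", "MD", "RD", "MO"]

#: The 12 binary neuropsychiatric outcome labels.
DISORDERS = ["AD", "ADHD", "AN", "ANX", "ASD", "BP",
             "INS", "MD", "OCD", "PTSD", "SCZ", "TS"]

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SimConfig:
    """Generative parameters for one exposure-outcome pair.

    Defaults reproduce the study's typical conditions: a continuous imaging
    exposure with N = 17,706, a binary disorder outcome with N = 50,000 and
    a third of the sample being cases, a handful of strong instruments, and
    no pleiotropy.
    """

    seed: int
    n_snps: int = 200
    n_instruments: int = 10
    n_exp: int = 17_706
    n_out: int = 50_000
    causal_beta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violated
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0  # fraction of SNPs carrying pleiotropy
    n_outliers: int = 0
    outlier_shift: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    outcome_type: str = "binary"  # continuous | binary
    case_fraction: float = 0.33
    n_outcome_instruments: int = 0  # outcome-specific loci (own architecture)
    reverse_beta: float = 0.0  # outcome -> exposure causal effect
    ld_blocks: tuple[int, float] | None = None  # (block_size, within_r)
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    snp_prefix: str = "rs"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "inside_violated"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.outcome_type == "binary" and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if self.pleiotropy_sd < 0 or self.outlier_shift < 0 or self.n_outliers < 0:
            raise ValueError("scales and counts must be non-negative")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if self.n_outliers and self.n_outliers > max(self.n_instruments, 1):
            raise ValueError("n_outliers cannot exceed the instrument count")
        if self.ld_blocks is not None:
            size, r = self.ld_blocks
            if size < 1 or not abs(r) < 1:
                raise ValueError("ld_blocks must be (size >= 1, |r| < 1)")


@dataclass
class SimTruth:
    """Ground truth behind one simulated pair."""

    causal_beta: float
    per_snp_pleiotropy: np.ndarray
    outlier_ids: list[str]
    gamma: np.ndarray = field(default=None)  # true per-SNP exposure effects
    snp_ids: list[str] = field(default_factory=list)


@dataclass
class StudyCollection:
    """A full synthetic study: labelled exposures x disorders with truth.

    ``truth`` has one row per enumerated exposure-outcome pair with columns
    exposure_id, outcome_id, exposure_class (dti|roi), causal_beta,
    has_instrument.
    """

    exposures: dict[str, GwasTable]
    outcomes: dict[str, GwasTable]
    truth: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.truth)


def _solve_instrument_scale(se: np.ndarray, n_target: float) -> float:
    """Scale tau of the large-effect component so that the expected number
    of SNPs with p < 5e-8 among the component's members equals n_target."""
    se = np.atleast_1d(np.asarray(se, dtype=float))

    def expected(tau: float) -> float:
        return float(np.sum(2 * stats.norm.sf(_Z_GWS * se / np.sqrt(tau**2 + se**2))))
    hi = 50 * float(np.max(se))
    lo = 1e-6 * float(np.min(se))
    if expected(hi) < n_target:  # cannot reach the target even at huge scale
        return hi
    return float(optimize.brentq(lambda t: expected(t) - n_target, lo, hi,
                                 xtol=1e-12))


def _mixture_gamma(rng: np.random.Generator, se: np.ndarray,
                   n_instruments: int) -> np.ndarray:
    """Draw true exposure effects: null SNPs at zero, a small large-effect
    set sized 1.5x the requested instrument count with scale solved so the
    expected significant count matches the request."""
    n = len(se)
    gamma = np.zeros(n)
    if n_instruments <= 0:
        return gamma
    n_large = min(n, int(np.ceil(1.5 * n_instruments)))
    large = rng.choice(n, size=n_large, replace=False)
    tau = _solve_instrument_scale(se[large], float(n_instruments))
    gamma[large] = rng.normal(0.0, tau, size=n_large)
    return gamma


def _pleiotropy(rng: np.random.Generator, mode: str, sd: float,
                gamma: np.ndarray, fraction: float = 1.0) -> np.ndarray:
    if mode == "none" or sd == 0.0:
        return np.zeros_like(gamma)
    n = len(gamma)
    if mode == "balanced":
        alpha = rng.normal(0.0, sd, size=n)
    elif mode == "directional":
        # mean-shifted relative to the instrument's orientation, so the
        # per-SNP ratios are shifted consistently (the bias IVW cannot
        # average away but the weighted median resists)
        sign = np.where(gamma != 0, np.sign(gamma),
                        rng.choice([-1.0, 1.0], size=n))
        alpha = sign * rng.normal(sd, sd, size=n)
    else:  # inside_violated: pleiotropy correlated with instrument strength
        g_sd = gamma[gamma != 0].std() if np.any(gamma != 0) else 1.0
        alpha = sd * gamma / g_sd + rng.normal(0.0, sd / 2, size=n)
    if fraction < 1.0:
        alpha[rng.random(n) >= fraction] = 0.0
    return alpha


def _block_noise(rng: np.random.Generator, n: int, block_size: int,
                 within_r: float, scale: np.ndarray) -> np.ndarray:
    """Sampling noise with block-constant correlation ``within_r``."""
    z = rng.standard_normal(n)
    if within_r == 0.0 or block_size <= 1:
        return scale * z
    out = np.empty(n)
    for start in range(0, n, block_size):
        end = min(start + block_size, n)
        shared = rng.standard_normal()
        out[start:end] = (np.sqrt(within_r) * shared
                          + np.sqrt(1 - within_r) * z[start:end])
    return scale * out


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, MIN_PVALUE, 1.0)


def simulate_pair(config: SimConfig) -> tuple[GwasTable, GwasTable, SimTruth]:
    """Generate one exposure GWAS, one outcome GWAS and the ground truth.

    Outcome tables carry randomized allele orientation (swaps, strand
    complements on non-palindromic SNPs) so harmonization is exercised; the
    harmonized effects are invariant to these representation changes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp_ids = [f"{config.snp_prefix}{j + 1:06d}" for j in range(n)]

    if config.ld_blocks is not None:
        bs, r = config.ld_blocks
        # share MAF within a block so the correlated-noise scale is common
        n_blocks = -(-n // bs)
        maf_b = rng.uniform(*config.maf_range, size=n_blocks)
        maf = np.repeat(maf_b, bs)[:n]
    else:
        maf = rng.uniform(*config.maf_range, size=n)

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out)
    if config.outcome_type == "binary":
        se_out = se_out / np.sqrt(config.case_fraction * (1 - config.case_fraction))

    gamma = _mixture_gamma(rng, se_exp, config.n_instruments)
    alpha = _pleiotropy(rng, config.pleiotropy_mode, config.pleiotropy_sd,
                        gamma, config.pleiotropy_fraction)

    # outcome-specific genetic architecture: loci affecting the disorder
    # directly (and the exposure only through reverse causality)
    delta = np.zeros(n)
    if config.n_outcome_instruments > 0:
        free = np.where(gamma == 0.0)[0]
        n_oi = min(len(free), int(np.ceil(1.5 * config.n_outcome_instruments)))
        oi = rng.choice(free, size=n_oi, replace=False)
        tau_o = _solve_instrument_scale(se_out[oi],
                                        float(config.n_outcome_instruments))
        delta[oi] = rng.normal(0.0, tau_o, size=n_oi)
        gamma = gamma + config.reverse_beta * delta

    big = np.abs(gamma) / se_exp  # strongest true instruments host outliers
    outlier_idx = np.argsort(-big, kind="stable")[: config.n_outliers] \
        if config.n_outliers else np.array([], dtype=int)
    gamma_t = gamma
    capital_gamma = config.causal_beta * gamma + delta + alpha
    if config.n_outliers:
        capital_gamma = capital_gamma.copy()
        capital_gamma[outlier_idx] += config.outlier_shift

    if config.ld_blocks is not None:
        bs, r = config.ld_blocks
        corr = simulate_ld(n, bs, r, seed=config.seed)
        # marginal effects at linked SNPs pick up the causal SNP's signal
        gamma_t = corr @ gamma
        capital_gamma = config.causal_beta * gamma_t + corr @ delta + alpha
        if config.n_outliers:
            capital_gamma[outlier_idx] += config.outlier_shift
        noise_exp = _block_noise(rng, n, bs, r, se_exp)
        noise_out = _block_noise(rng, n, bs, r, se_out)
    else:
        noise_exp = rng.normal(0.0, se_exp)
        noise_out = rng.normal(0.0, se_out)

    beta_exp = gamma_t + noise_exp
    beta_out = capital_gamma + noise_out

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    exp_df = pd.DataFrame({
        "snp_id": snp_ids, "effect_allele": ea, "other_allele": oa,
        "beta": beta_exp, "se": se_exp, "pvalue": _two_sided_p(beta_exp, se_exp),
        "eaf": maf, "n": config.n_exp,
    })

    # outcome orientation: random swaps (sign flip) and, for non-palindromic
    # SNPs, random strand complements — harmonization must undo both
    swap = rng.random(n) < 0.3
    palin = np.array([(a, b) in _PALINDROMIC for a, b in zip(ea, oa)])
    comp = (rng.random(n) < 0.2) & ~palin
    ea_o, oa_o = ea.copy(), oa.copy()
    beta_out_rep = beta_out.copy()
    ea_o[swap], oa_o[swap] = oa[swap], ea[swap]
    beta_out_rep[swap] = -beta_out_rep[swap]
    ea_o = np.array([_COMPLEMENT[a] if c else a for a, c in zip(ea_o, comp)])
    oa_o = np.array([_COMPLEMENT[a] if c else a for a, c in zip(oa_o, comp)])

    out_df = pd.DataFrame({
        "snp_id": snp_ids, "effect_allele": ea_o, "other_allele": oa_o,
        "beta": beta_out_rep, "se": se_out,
        "pvalue": _two_sided_p(beta_out_rep, se_out),
        "eaf": np.nan, "n": config.n_out,
    })

    exposure = GwasTable(config.exposure_id, "continuous", exp_df)
    outcome = GwasTable(config.outcome_id, config.outcome_type, out_df)
    truth = SimTruth(
        causal_beta=config.causal_beta, per_snp_pleiotropy=alpha,
        outlier_ids=[snp_ids[i] for i in outlier_idx],
        gamma=gamma_t, snp_ids=list(snp_ids),
    )
    return exposure, outcome, truth


def simulate_ld(n_snps: int, block_size: int, within_r: float,
                seed: int | None = None) -> np.ndarray:
    """Block-diagonal LD correlation matrix (constant r within each block).

    Constant-correlation blocks with |r| < 1 are positive definite, so the
    full matrix is a valid correlation matrix.  ``seed`` is accepted for API
    symmetry; the construction is deterministic.
    """
    if not abs(within_r) < 1:
        raise ValueError("|within_r| must be < 1")
    mat = np.eye(n_snps)
    if within_r == 0.0 or block_size <= 1:
        return mat
    for start in range(0, n_snps, block_size):
        end = min(start + block_size, n_snps)
        mat[start:end, start:end] = within_r
        np.fill_diagonal(mat[start:end, start:end], 1.0)
    return mat


def _dti_labels(n_dti: int) -> list[str]:
    full = [f"{t}.{p}" for t in DTI_TRACTS for p in DTI_PARAMETERS]
    if n_dti <= len(full):
        return full[:n_dti]
    return full + [f"DTI_{k:03d}" for k in range(len(full), n_dti)]


def simulate_study_collection(
    n_dti: int, n_roi: int, n_disorders: int, fraction_causal: float,
    seed: int, *, n_snps_per_exposure: int = 120, n_instruments: int = 8,
    fraction_no_instrument: float = 67 / 1320,
    fraction_no_instrument_roi: float | None = 239 / 1212,
    causal_effect: float = 0.15,
    n_exp_dti: int = 17_706, n_exp_roi: int = 19_629, n_out: int = 50_000,
    case_fraction: float = 0.33,
) -> StudyCollection:
    """Simulate a full labelled study: (DTI + ROI exposures) x disorders.

    Each exposure owns a disjoint SNP panel; each disorder's outcome table is
    the union of all panels.  A ``fraction_causal`` of enumerated pairs get a
    true causal effect of magnitude ``causal_effect`` with random sign; a
    ``fraction_no_instrument`` of exposures (``fraction_no_instrument_roi``
    for the volumetric class, which has far sparser instruments in real
    data) are generated without any genome-wide-significant SNP to exercise
    the exclusion path.
    """
    if min(n_disorders, n_dti + n_roi) < 1:
        raise ValueError("need at least one exposure and one disorder")
    rng = np.random.default_rng(seed)

    exposure_meta: list[tuple[str, str, int]] = []  # (label, class, n_exp)
    for lbl in _dti_labels(n_dti):
        exposure_meta.append((lbl, "dti", n_exp_dti))
    for k in range(n_roi):
        exposure_meta.append((f"ROI_{k + 1:03d}", "roi", n_exp_roi))

    disorders = (DISORDERS[:n_disorders] if n_disorders <= len(DISORDERS)
                 else DISORDERS + [f"D{k:02d}" for k in range(len(DISORDERS),
                                                              n_disorders)])

    exposures: dict[str, GwasTable] = {}
    out_frames: dict[str, list[pd.DataFrame]] = {d: [] for d in disorders}
    truth_rows = []

    if fraction_no_instrument_roi is None:
        fraction_no_instrument_roi = fraction_no_instrument

    for e_idx, (label, klass, n_exp) in enumerate(exposure_meta):
        f_no = (fraction_no_instrument_roi if klass == "roi"
                else fraction_no_instrument)
        no_inst = rng.random() < f_no
        n_inst = 0 if no_inst else n_instruments
        base = SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)), n_snps=n_snps_per_exposure,
            n_instruments=n_inst, n_exp=n_exp, n_out=n_out,
            causal_beta=0.0, case_fraction=case_fraction,
            exposure_id=label, outcome_id="placeholder",
            snp_prefix=f"rs{e_idx:03d}_",
        )
        sub = np.random.default_rng(base.seed)
        n = base.n_snps
        snp_ids = [f"{base.snp_prefix}{j + 1:06d}" for j in range(n)]
        maf = sub.uniform(*base.maf_range, size=n)
        se_exp = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_exp)
        se_out = 1.0 / np.sqrt(2 * maf * (1 - maf) * n_out
                               * case_fraction * (1 - case_fraction))
        gamma = _mixture_gamma(sub, se_exp, n_inst)
        beta_exp = gamma + sub.normal(0.0, se_exp)
        pair_idx = sub.integers(0, len(_ALLELE_PAIRS), size=n)
        ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
        oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
        exposures[label] = GwasTable(label, "continuous", pd.DataFrame({
            "snp_id": snp_ids, "effect_allele": ea, "other_allele": oa,
            "beta": beta_exp, "se": se_exp,
            "pvalue": _two_sided_p(beta_exp, se_exp),
            "eaf": maf, "n": n_exp,
        }))

        for d in disorders:
            causal = rng.random() < fraction_causal
            b = float(rng.choice([-1.0, 1.0]) * causal_effect) if causal else 0.0
            beta_out = b * gamma + rng.normal(0.0, se_out)
            out_frames[d].append(pd.DataFrame({
                "snp_id": snp_ids, "effect_allele": ea, "other_allele": oa,
                "beta": beta_out, "se": se_out,
                "pvalue": _two_sided_p(beta_out, se_out),
                "eaf": np.nan, "n": n_out,
            }))
            truth_rows.append((label, d, klass, b, not no_inst))

    outcomes = {d: GwasTable(d, "binary",
                             pd.concat(frames, ignore_index=True))
                for d, frames in out_frames.items()}
    truth = pd.DataFrame(truth_rows, columns=[
        "exposure_id", "outcome_id", "exposure_class", "causal_beta",
        "has_instrument"])
    return StudyCollection(exposures=exposures, outcomes=outcomes, truth=truth)
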