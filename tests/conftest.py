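import numpy as np
import pandas as pd
import pytest

from neuromr.summary_io import GwasTable, HarmonizedPair


def random_instance(seed: int, k: int = 10):
    """Random harmonized-pair arrays with strong instruments."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.2, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.005, 0.01, k)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.01, 0.03, k)
    return bx, sx, by, sy


def make_pair(bx, sx, by, sy, exposure_id="E", outcome_id="O") -> HarmonizedPair:
    k = len(bx)
    snps = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(k)],
        "beta_exp": np.asarray(bx, float), "se_exp": np.asarray(sx, float),
        "p_exp": np.ones(k),
        "beta_out": np.asarray(by, float), "se_out": np.asarray(sy, float),
    })
    return HarmonizedPair(exposure_id, outcome_id, snps)


def make_gwas(trait_id, snp_ids, ea, oa, beta, se, pvalue, eaf=None, n=None,
              trait_type="continuous") -> GwasTable:
    k = len(snp_ids)
    return GwasTable(trait_id, trait_type, pd.DataFrame({
        "snp_id": snp_ids, "effect_allele": ea, "other_allele": oa,
        "beta": beta, "se": se, "pvalue": pvalue,
        "eaf": eaf if eaf is not None else [np.nan] * k,
        "n": n if n is not None else [np.nan] * k,
    }))


@pytest.fixture
def simple_pair() -> HarmonizedPair:
    return make_pair(*random_instance(0, k=8))
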