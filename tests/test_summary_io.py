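"""Ingestion, instrument selection/clumping and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from neuromr.simulate import SimConfig, simulate_ld, simulate_pair
from neuromr.summary_io import (ConfigurationError, EmptyTableError, GwasTable,
                                LDSource, MIN_PVALUE, VariantAssociation,
                                harmonize_pair, read_gwas_table,
                                select_instruments)
from conftest import make_gwas

MAP = {"snp_id": "snp", "effect_allele": "a1", "other_allele": "a2",
       "effect": "eff", "se": "se", "pvalue": "p"}


def _write(tmp_path, rows, name="gwas.tsv",
           header="snp\ta1\ta2\teff\tse\tp"):
    f = tmp_path / name
    f.write_text("\n".join([header] + rows) + "\n")
    return f


class TestReadGwasTable:
    def test_odds_ratios_are_log_transformed(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t1.0\t0.1\t0.5",
                              "rs2\tA\tG\t2.0\t0.1\t0.5",
                              "rs3\tA\tG\t0.5\t0.1\t0.5"])
        t = read_gwas_table(f, MAP, "binary", effect_is="or")
        assert np.allclose(t.data["beta"], [0.0, np.log(2), -np.log(2)])

    def test_invalid_se_row_dropped_and_counted(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t0.1\t0.0\t0.5",
                              "rs2\tA\tG\t0.1\t0.1\t0.5"])
        t = read_gwas_table(f, MAP, "continuous")
        assert len(t) == 1 and t.n_dropped_invalid == 1

    def test_round_trip_is_lossless(self, tmp_path):
        exp, _, _ = simulate_pair(SimConfig(seed=3, n_snps=1000))
        out = tmp_path / "sim.tsv"
        exp.to_tsv(out)
        back = read_gwas_table(
            out, {"snp_id": "snp_id", "effect_allele": "effect_allele",
                  "other_allele": "other_allele", "effect": "beta",
                  "se": "se", "pvalue": "pvalue", "eaf": "eaf", "n": "n"},
            "continuous")
        pd.testing.assert_frame_equal(back.data, exp.data, check_dtype=False)

    def test_zero_pvalue_floored(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t0.1\t0.01\t0.0"])
        t = read_gwas_table(f, MAP, "continuous")
        assert t.data["pvalue"].iloc[0] == MIN_PVALUE

    def test_duplicate_ids_keep_smallest_p(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t0.1\t0.01\t0.5",
                              "rs1\tA\tG\t0.2\t0.01\t1e-9"])
        t = read_gwas_table(f, MAP, "continuous")
        assert len(t) == 1 and t.data["beta"].iloc[0] == 0.2
        assert t.n_dropped_duplicate == 1

    def test_missing_mandatory_column_raises(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t0.1\t0.01\t0.5"])
        with pytest.raises(ConfigurationError):
            read_gwas_table(f, {k: v for k, v in MAP.items() if k != "se"},
                            "continuous")

    def test_zero_valid_rows_raises(self, tmp_path):
        f = _write(tmp_path, ["rs1\tA\tG\t0.1\t0\t0.5"])
        with pytest.raises(EmptyTableError):
            read_gwas_table(f, MAP, "continuous")


class TestVariantAssociation:
    @pytest.mark.parametrize("kwargs", [
        dict(se=0.0), dict(pvalue=0.0), dict(pvalue=1.5),
        dict(other_allele="A"), dict(effect_allele="N"), dict(eaf=1.0),
    ])
    def test_invariants_enforced(self, kwargs):
        base = dict(snp_id="rs1", effect_allele="A", other_allele="G",
                    beta=0.1, se=0.01, pvalue=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VariantAssociation(**base)

    def test_palindromic_detection(self):
        v = VariantAssociation("rs1", "A", "T", 0.1, 0.01, 0.5)
        assert v.is_palindromic


class TestSelectInstruments:
    def test_p_threshold_only(self):
        t = make_gwas("E", ["a", "b", "c"], "AAA", "GGG",
                      [0.1] * 3, [0.01] * 3, [1e-9, 1e-10, 0.5])
        assert select_instruments(t) == ["b", "a"]

    def test_greedy_dominance_in_ld(self):
        t = make_gwas("E", ["a", "b"], "AA", "GG", [0.1] * 2, [0.01] * 2,
                      [1e-10, 1e-9])
        ld = LDSource.from_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]),
                                  snp_ids=["a", "b"])
        assert select_instruments(t, ld=ld) == ["a"]

    def test_no_significant_snp_gives_empty_list(self):
        t = make_gwas("E", ["a"], ["A"], ["G"], [0.1], [0.1], [0.5])
        assert select_instruments(t) == []

    def test_clumped_set_matches_brute_force_oracle(self):
        # 50 SNPs in LD blocks of 5; oracle re-runs greedy clumping naively
        # and checks maximal-greedy validity on the returned set
        rng = np.random.default_rng(9)
        n = 50
        ids = [f"rs{i}" for i in range(n)]
        corr = simulate_ld(n, block_size=5, within_r=0.9)
        p = rng.uniform(0, 1e-8, n)
        t = make_gwas("E", ids, ["A"] * n, ["G"] * n, [0.1] * n, [0.01] * n, p)
        ld = LDSource.from_matrix(corr**2, snp_ids=ids)
        kept = select_instruments(t, ld=ld, r2_threshold=0.001)

        # brute-force greedy oracle
        order = sorted(range(n), key=lambda i: p[i])
        oracle, removed = [], set()
        for i in order:
            if ids[i] in removed:
                continue
            oracle.append(ids[i])
            for j in order:
                if ids[j] not in removed and j != i \
                        and corr[i, j] ** 2 >= 0.001:
                    removed.add(ids[j])
        assert kept == oracle
        # validity: no kept pair in LD; every removed SNP tagged by a better kept
        idx = {s: i for i, s in enumerate(ids)}
        for a in kept:
            for b in kept:
                if a != b:
                    assert corr[idx[a], idx[b]] ** 2 < 0.001
        for s in ids:
            if s not in kept:
                assert any(corr[idx[s], idx[ksnp]] ** 2 >= 0.001
                           and p[idx[ksnp]] <= p[idx[s]] for ksnp in kept)


class TestHarmonizePair:
    def _tables(self, ea_o, oa_o, beta_o):
        exp = make_gwas("E", ["rs1"], ["A"], ["G"], [0.1], [0.01], [1e-9])
        out = make_gwas("O", ["rs1"], [ea_o], [oa_o], [beta_o], [0.02], [0.5])
        return exp, out

    def test_allele_swap_flips_outcome_beta(self):
        exp, out = self._tables("G", "A", 0.05)
        pair = harmonize_pair(exp, out, ["rs1"])
        assert pair.snps["beta_out"].iloc[0] == pytest.approx(-0.05)

    def test_strand_complement_resolved(self):
        exp, out = self._tables("T", "C", 0.05)  # complement of A/G
        pair = harmonize_pair(exp, out, ["rs1"])
        assert pair.snps["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_palindromic_kept_forward_strand(self):
        exp = make_gwas("E", ["rs1"], ["A"], ["T"], [0.1], [0.01], [1e-9])
        out = make_gwas("O", ["rs1"], ["A"], ["T"], [0.02], [0.02], [0.5])
        pair = harmonize_pair(exp, out, ["rs1"])
        assert pair.palindromic_kept == 1
        assert pair.snps["beta_out"].iloc[0] == pytest.approx(0.02)

    def test_irreconcilable_alleles_dropped_and_counted(self):
        exp, out = self._tables("A", "C", 0.05)
        pair = harmonize_pair(exp, out, ["rs1"])
        assert pair.n_snp == 0 and pair.n_dropped_mismatch == 1

    def test_missing_instrument_dropped_with_count(self):
        exp = make_gwas("E", ["rs1"], ["A"], ["G"], [0.1], [0.01], [1e-9])
        out = make_gwas("O", ["rs9"], ["A"], ["G"], [0.1], [0.01], [0.5])
        pair = harmonize_pair(exp, out, ["rs1"])
        assert pair.n_snp == 0 and pair.n_dropped_mismatch == 1

    def test_harmonization_is_idempotent(self):
        exp, out, _ = simulate_pair(SimConfig(seed=5, n_snps=50,
                                              n_instruments=5))
        inst = select_instruments(exp)
        pair = harmonize_pair(exp, out, inst)
        # rebuild an outcome table already aligned to the exposure alleles
        aligned = exp.data.set_index("snp_id").loc[pair.snps["snp_id"]]
        out2 = GwasTable("O2", "binary", pd.DataFrame({
            "snp_id": pair.snps["snp_id"].to_numpy(),
            "effect_allele": aligned["effect_allele"].to_numpy(),
            "other_allele": aligned["other_allele"].to_numpy(),
            "beta": pair.snps["beta_out"].to_numpy(),
            "se": pair.snps["se_out"].to_numpy(),
            "pvalue": np.full(pair.n_snp, 0.5), "eaf": np.nan, "n": np.nan,
        }))
        pair2 = harmonize_pair(exp, out2, pair.snps["snp_id"].tolist())
        assert np.allclose(pair2.snps["beta_out"], pair.snps["beta_out"])
        assert pair2.n_dropped_mismatch == 0

    def test_orientation_consistency(self):
        """Flipping both alleles and the beta sign of every outcome record
        leaves the harmonized effects unchanged."""
        exp, out, _ = simulate_pair(SimConfig(seed=6, n_snps=80,
                                              n_instruments=6))
        inst = select_instruments(exp)
        pair = harmonize_pair(exp, out, inst)
        flipped = out.data.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        pair2 = harmonize_pair(exp, GwasTable("O", "binary", flipped), inst)
        pd.testing.assert_frame_equal(pair.snps, pair2.snps)


class TestLDSource:
    def test_pair_table_symmetric_lookup_and_default_zero(self):
        tab = pd.DataFrame({"snp_a": ["a"], "snp_b": ["b"], "r2": [0.4]})
        ld = LDSource.from_table(tab)
        assert ld.r2("a", "b") == ld.r2("b", "a") == 0.4
        assert ld.r2("a", "c") == 0.0
        assert ld.r2("a", "a") == 1.0

    def test_r_values_squared_on_request(self):
        ld = LDSource.from_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]),
                                  snp_ids=["a", "b"], values_are_r=True)
        assert ld.r2("a", "b") == pytest.approx(0.25)
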