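"""Estimator arithmetic, oracle equivalence and invariance properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuromr.estimators import (InsufficientInstrumentsError, ScaleError,
                                UndefinedRatioError, egger, heidi_test, ivw,
                                smr_test, to_odds_ratio, wald_ratio,
                                weighted_median, weighted_mode,
                                _mode_estimate)
from conftest import make_pair, random_instance


class TestWaldRatio:
    def test_direct_arithmetic(self):
        e = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)

    def test_null_numerator(self):
        e = wald_ratio(0.1, 0.02, 0.0, 0.01)
        assert e.beta == 0.0 and e.pvalue == 1.0

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.02, 0.05, 0.01)

    def test_single_snp_equals_forced_ivw(self):
        bx, sx, by, sy = random_instance(1, k=1)
        w = wald_ratio(bx[0], sx[0], by[0], sy[0])
        beta_ivw = (bx**2 / sy**2 * (by / bx)).sum() / (bx**2 / sy**2).sum()
        assert w.beta == pytest.approx(beta_ivw, abs=1e-14)


class TestIVW:
    def test_two_identical_ratios(self):
        e = ivw(([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02]))
        assert e.beta == pytest.approx(0.5)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(([0.1], [0.01], [0.05], [0.02]))

    def test_random_effects_never_deflate_se(self):
        bx, sx, by, sy = random_instance(4, k=12)
        fe = ivw((bx, sx, by, sy), random_effects=False)
        re = ivw((bx, sx, by, sy))
        assert re.se >= fe.se

    def test_matches_wls_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        for seed in range(100):
            bx, sx, by, sy = random_instance(seed, k=8)
            e = ivw((bx, sx, by, sy))
            fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert e.beta == pytest.approx(fit.params[0], abs=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.linspace(0.05, 0.2, 6)
        by = 0.03 + 0.7 * bx
        slope, intercept = egger((bx, [0.01] * 6, by, [0.02] * 6))
        assert slope.beta == pytest.approx(0.7, abs=1e-10)
        assert intercept.beta == pytest.approx(0.03, abs=1e-10)

    def test_matches_wls_oracle_after_orientation(self):
        sm = pytest.importorskip("statsmodels.api")
        for seed in range(100):
            bx, sx, by, sy = random_instance(seed + 500, k=9)
            slope, intercept = egger((bx, sx, by, sy))
            sgn = np.where(bx < 0, -1.0, 1.0)
            x = np.column_stack([np.ones(len(bx)), bx * sgn])
            fit = sm.WLS(by * sgn, x, weights=1.0 / sy**2).fit()
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_middle_element_equal_weights(self):
        e = weighted_median(([1.0, 1.0, 1.0], [0.01] * 3,
                             [0.1, 0.5, 0.9], [0.02] * 3),
                            n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.5)

    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        e = weighted_median((bx, [0.0001] * 3, 0.3 * bx, [0.0001] * 3),
                            n_boot=200, seed=0)
        assert e.beta == pytest.approx(0.3, abs=1e-6)
        assert e.se < 0.01


class TestWeightedMode:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        e = weighted_mode((bx, [0.0001] * 3, 0.3 * bx, [0.0001] * 3),
                          n_boot=50, seed=0)
        assert e.beta == pytest.approx(0.3, abs=1e-3)

    def test_majority_cluster_wins_against_grid_oracle(self):
        rng = np.random.default_rng(3)
        ratios = np.concatenate([rng.normal(0.3, 0.01, 7),
                                 rng.normal(1.0, 0.01, 3)])
        w = np.ones(10) / 10
        est = _mode_estimate(ratios, w, 1.0)
        assert 0.2 < est < 0.4
        # fine-grid oracle: densities evaluated directly
        sd = ratios.std(ddof=1)
        mad = stats.median_abs_deviation(ratios, scale="normal")
        h = 0.9 * min(sd, mad) / 10**0.2
        grid = np.linspace(-0.5, 1.5, 20001)
        dens = (w * np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2)).sum(1)
        assert abs(grid[np.argmax(dens)] - est) < 0.02

    def test_infinite_bandwidth_approaches_weighted_mean(self):
        bx, sx, by, sy = random_instance(11, k=10)
        e = weighted_mode((bx, sx, by, sy), bandwidth_phi=1e6, n_boot=50,
                          seed=0)
        r = by / bx
        w = bx**2 / sy**2
        wmean = (w * r).sum() / w.sum()
        span = r.max() - r.min()
        assert abs(e.beta - wmean) < 0.05 * span


class TestSMR:
    def test_symmetric_case(self):
        # z_exp = z_out = 2 -> T = 16/8 = 2
        e = smr_test(0.2, 0.1, 0.2, 0.1)
        assert e.pvalue == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_strong_instrument_limit_recovers_outcome_p(self):
        e = smr_test(1.0, 1e-9, 0.05, 0.02)
        z_out = 0.05 / 0.02
        assert e.pvalue == pytest.approx(stats.chi2.sf(z_out**2, 1), rel=1e-6)


class TestHeidi:
    def _region(self, k, by):
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(k)],
            "beta_exp": np.full(k, 0.1), "se_exp": np.full(k, 0.005),
            "p_exp": np.full(k, 1e-10),
            "beta_out": by, "se_out": np.full(k, 0.01)})

    def test_identical_ratios_give_large_p(self):
        k = 8
        corr = np.full((k, k), 0.5)
        np.fill_diagonal(corr, 1.0)
        res = heidi_test(self._region(k, np.full(k, 0.05)), corr)
        assert res.status == "ok" and res.pvalue > 0.9

    def test_too_few_companions_not_evaluable(self):
        k = 3
        res = heidi_test(self._region(k, np.full(k, 0.05)), np.eye(k))
        assert res.status == "not_evaluable" and res.pvalue is None

    def test_two_causal_variants_detected(self):
        """Companions fed by a second independent causal variant in LD
        deviate from the top SNP's ratio; HEIDI should reject."""
        sig = 0
        n_eval = 0
        for s in range(100):
            rng = np.random.default_rng(4000 + s)
            k = 12
            corr = np.full((k, k), 0.5)
            np.fill_diagonal(corr, 1.0)
            chol = np.linalg.cholesky(corr)
            sx = np.full(k, 0.007)
            sy = np.full(k, 0.01)
            g = np.zeros(k)
            g[0] = 0.12
            gamma = corr @ g
            g2 = np.zeros(k)
            g2[6] = 0.15
            cap = 0.4 * gamma + corr @ g2
            bx = gamma + sx * (chol @ rng.standard_normal(k))
            by = cap + sy * (chol @ rng.standard_normal(k))
            region = pd.DataFrame({
                "snp_id": [f"s{i}" for i in range(k)], "beta_exp": bx,
                "se_exp": sx, "p_exp": 2 * stats.norm.sf(np.abs(bx / sx)),
                "beta_out": by, "se_out": sy})
            res = heidi_test(region, corr)
            if res.status == "ok":
                n_eval += 1
                sig += res.pvalue < 0.05
        assert n_eval > 80 and sig / n_eval > 0.5


class TestOddsRatio:
    def test_headline_transforms(self):
        e = ivw(([0.1, 0.1], [0.01] * 2, [-0.048, -0.048], [0.02] * 2))
        assert e.beta == pytest.approx(-0.48)
        o = to_odds_ratio(e)
        assert round(o.odds_ratio, 2) == 0.62

    def test_null_effect(self):
        e = wald_ratio(0.1, 0.01, 0.0, 0.02)
        o = to_odds_ratio(e)
        assert o.odds_ratio == 1.0 and o.percent_change == 0.0

    def test_continuous_outcome_rejected(self):
        e = wald_ratio(0.1, 0.01, 0.05, 0.02)
        with pytest.raises(ScaleError):
            to_odds_ratio(e, trait_type="continuous")


class TestInvariances:
    @pytest.mark.parametrize("seed", range(20))
    def test_scale_equivariance(self, seed):
        """Multiplying exposure betas and ses by c divides estimates by c."""
        bx, sx, by, sy = random_instance(seed, k=8)
        c = 2.5
        for f in (ivw, lambda p: egger(p)[0],
                  lambda p: weighted_median(p, n_boot=50, seed=0)):
            a = f((bx, sx, by, sy)).beta
            b = f((c * bx, c * sx, by, sy)).beta
            assert b == pytest.approx(a / c, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_orientation_invariance(self, seed):
        """Flipping the sign of both betas of any SNP subset changes
        nothing."""
        bx, sx, by, sy = random_instance(seed + 40, k=8)
        flip = np.random.default_rng(seed).random(8) < 0.5
        s = np.where(flip, -1.0, 1.0)
        for f in (ivw, lambda p: egger(p)[0], lambda p: egger(p)[1],
                  lambda p: weighted_median(p, n_boot=50, seed=0)):
            a = f((bx, sx, by, sy)).beta
            b = f((s * bx, sx, s * by, sy)).beta
            assert b == pytest.approx(a, abs=1e-10)
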