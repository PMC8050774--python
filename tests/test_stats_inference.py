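"""Moderated t-test, prior estimation, and BH adjustment."""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from silaf import bh_adjust, moderated_t_test, significance_table
from silaf.stats_inference import _trigamma_inverse, estimate_prior


def _null_matrix(n_features=500, n=4, d0=4.0, s0_sq=0.04, seed=0, effect=0.0,
                 n_effect=0):
    """Features with scaled inverse-chi-square variances; optional spike-ins."""
    rng = np.random.default_rng(seed)
    sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n_features)
    vals = rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(n_features, n))
    if n_effect:
        signs = rng.choice([-1.0, 1.0], size=n_effect)
        vals[:n_effect] += (effect * signs)[:, None]
    return pd.DataFrame(vals, index=[f"f{i}" for i in range(n_features)],
                        columns=[f"rep{j}" for j in range(n)])


class TestModeratedT:
    def test_d0_zero_reproduces_ordinary_t(self):
        df = _null_matrix(200, seed=1)
        res = moderated_t_test(df, prior_df=0.0)
        mean = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        t_plain = mean / (sd / np.sqrt(df.shape[1]))
        assert np.allclose(res["t_mod"], t_plain, rtol=1e-12)
        p_plain = 2 * stats.t.sf(np.abs(t_plain), df.shape[1] - 1)
        assert np.allclose(res["p"], p_plain, rtol=1e-12)

    def test_infinite_prior_df_gives_complete_shrinkage(self):
        df = _null_matrix(200, seed=2)
        res = moderated_t_test(df, prior_df=np.inf)
        assert np.allclose(res["s2_post"], res["s0_sq"].iloc[0])

    def test_shrinkage_direction(self):
        df = _null_matrix(500, seed=3)
        res = moderated_t_test(df)
        s0 = res["s0_sq"].iloc[0]
        low = res["s2"] < s0
        assert (res.loc[low, "s2_post"] > res.loc[low, "s2"]).all()
        assert (res.loc[~low, "s2_post"] < res.loc[~low, "s2"]).all()
        # posterior variance always lies between s2 and the prior
        assert ((res["s2_post"] - res[["s2"]].min(axis=1).clip(upper=s0) >= -1e-15)
                & (res["s2_post"] <= np.maximum(res["s2"], s0) + 1e-15)).all()

    def test_p_monotone_in_abs_t_for_fixed_df(self):
        df = _null_matrix(300, seed=4)
        res = moderated_t_test(df).dropna(subset=["p"])
        order = res["t_mod"].abs().sort_values().index
        assert (np.diff(res.loc[order, "p"].to_numpy()) <= 1e-15).all()

    def test_features_with_too_few_replicates_untested(self):
        df = _null_matrix(50, seed=5)
        df.iloc[0, 1:] = np.nan
        res = moderated_t_test(df)
        assert np.isnan(res.iloc[0]["p"])
        assert res["p"].notna().sum() == 49

    def test_all_constant_features_error_advises_noise_floor(self):
        df = pd.DataFrame(np.ones((10, 4)))
        with pytest.raises(ValueError, match="noise floor"):
            moderated_t_test(df)

    def test_prior_estimate_recovers_generating_hyperparameters(self):
        df = _null_matrix(20000, seed=6, d0=5.0, s0_sq=0.09)
        d0, s0_sq = estimate_prior(df.var(axis=1, ddof=1).to_numpy(),
                                   np.full(len(df), 3.0))
        assert d0 == pytest.approx(5.0, rel=0.15)
        assert s0_sq == pytest.approx(0.09, rel=0.05)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.01, 0.5, 2.0, 40.0):
            x = float(polygamma(1, y))
            assert _trigamma_inverse(x) == pytest.approx(y, rel=1e-7)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_reference_implementation(self, tmp_path):
        """Independent oracle: Bioconductor limma's eBayes on the same matrix
        reproduces our moderated t, p, and hyperparameters to 1e-10."""
        df = _null_matrix(60, seed=7, effect=1.0, n_effect=6)
        mat = tmp_path / "mat.csv"
        out = tmp_path / "limma.csv"
        df.to_csv(mat)
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.csv("{mat}", row.names=1))
        fit <- eBayes(lmFit(m, design=matrix(1, ncol(m), 1)))
        write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1],
                             d0=fit$df.prior, s0=fit$s2.prior), "{out}")
        """
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(out, index_col=0)
        res = moderated_t_test(df)
        assert np.allclose(res["t_mod"], ref["t"], rtol=1e-10)
        assert np.allclose(res["p"], ref["p"], rtol=1e-10)
        assert res["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res["s0_sq"].iloc[0] == pytest.approx(ref["s0"].iloc[0], rel=1e-6)


class TestBHAdjust:
    def test_step_up_by_hand(self):
        # p(i) * m / i = {0.04, 0.04, 0.04, 0.04} after cumulative min
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_reports_index(self):
        with pytest.raises(ValueError, match="index 2"):
            bh_adjust([0.5, 0.1, 0.0])

    def test_adjusted_never_below_raw_and_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()

    def test_matches_brute_force_and_statsmodels_on_random_vectors(self):
        """Dual oracle on 1000 random vectors: an explicit
        sort/multiply/cummin/unsort reference and statsmodels' fdr_bh."""
        from statsmodels.stats.multitest import multipletests

        def brute(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            adj = [min(p[order[i]] * m / (i + 1), 1.0) for i in range(m)]
            for i in range(m - 2, -1, -1):
                adj[i] = min(adj[i], adj[i + 1])
            out = [0.0] * m
            for i, o in enumerate(order):
                out[o] = adj[i]
            return out

        rng = np.random.default_rng(9)
        for trial in range(1000):
            p = rng.uniform(1e-12, 1, size=rng.integers(1, 40))
            ours = bh_adjust(p)
            assert np.allclose(ours, brute(list(p)), rtol=0, atol=0), trial
            if trial % 50 == 0:
                assert np.allclose(
                    ours, multipletests(p, method="fdr_bh")[1], rtol=1e-12)


class TestSignificanceTable:
    def test_up_down_counts(self):
        res = pd.DataFrame({"mean_log2fc": [1.0, -1.0, 0.3],
                            "p_adj": [0.005, 0.005, 0.5]})
        _, counts = significance_table(res, threshold=0.01)
        assert counts["up"] == 1 and counts["down"] == 1

    def test_empty_results(self):
        res = pd.DataFrame({"mean_log2fc": [], "p_adj": []})
        _, counts = significance_table(res, threshold=0.01)
        assert counts["up"] == 0 and counts["down"] == 0


def test_null_calibration_smoke():
    """On null features the moderated test is approximately uniform."""
    df = _null_matrix(1000, seed=10)
    res = moderated_t_test(df)
    rate = float((res["p"] < 0.05).mean())
    assert 0.02 < rate < 0.08
    assert (res["p_adj"] < 0.05).mean() <= 0.05
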