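"""Moderated-t differential expression, BH-FDR, and signature selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import fishcmap as fc
from fishcmap.iodata import ValidationError
from fishcmap.rogl import ConditionMeta
from fishcmap.signature import ProbeStats, fit_prior_variance

from conftest import two_group_inputs


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: adjusted p_i = min over j>=rank(i) of p_(j)*n/j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for k in range(n - 1, -1, -1):
        running = min(running, p[order[k]] * n / (k + 1))
        adj[order[k]] = running
    return adj


def _stats_from_table(p, logfc=None, n_probes=None):
    n = len(p)
    table = pd.DataFrame(
        {
            "logfc": logfc if logfc is not None else np.ones(n),
            "t": np.zeros(n),
            "p_value": p,
            "fdr": fc.benjamini_hochberg(np.asarray(p, float)),
            "n_treated": 4,
            "n_control": 4,
        },
        index=[f"P{i:05d}" for i in range(n)],
    )
    return ProbeStats(
        table=table, n_probes=n_probes or n, method="moderated",
        prior_df=4.0, prior_var=0.25, meta=ConditionMeta(chemical="A"),
    )


class TestBenjaminiHochberg:
    def test_hand_worked_four_pvalues(self):
        np.testing.assert_allclose(
            fc.benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=50))
    def test_matches_stepup_oracle(self, p):
        p = np.array(p)
        np.testing.assert_allclose(fc.benjamini_hochberg(p), bh_stepup_oracle(p), rtol=1e-12)

    def test_fdr_at_least_raw_p_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        fdr = fc.benjamini_hochberg(p)
        assert np.all(fdr >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)


class TestModeratedT:
    def test_identical_groups_give_null_stats(self):
        rng = np.random.default_rng(1)
        g = rng.normal(8, 1, (30, 3))
        x = np.hstack([g, g])  # treated group == control group, column for column
        matrix, samples, treated = two_group_inputs(x, n_treated=3)
        st_ = fc.differential_stats(matrix, samples, treated)
        np.testing.assert_allclose(st_.table["logfc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(st_.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(st_.table["fdr"], 1.0, atol=1e-12)

    def test_zero_prior_df_recovers_ordinary_pooled_t(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (10, 9))
        matrix, samples, treated = two_group_inputs(x, n_treated=4)
        st_ = fc.differential_stats(matrix, samples, treated, prior_df=0.0)
        # independent closed-form two-sample pooled t
        a, b = x[:, :4], x[:, 4:]
        sp2 = (a.var(axis=1, ddof=1) * 3 + b.var(axis=1, ddof=1) * 4) / 7
        t_oracle = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / 4 + 1 / 5))
        np.testing.assert_allclose(st_.table["t"], t_oracle, rtol=1e-10)
        np.testing.assert_allclose(
            st_.table["p_value"], 2 * sps.t.sf(np.abs(t_oracle), 7), rtol=1e-10
        )

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(3)
        s2 = 0.2 * rng.chisquare(4, 500) / 4
        df = np.full(500, 6.0)
        d0, s0 = fit_prior_variance(s2, df)
        assert 0 < d0 < np.inf
        post = (d0 * s0 + df * s2) / (d0 + df)
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_infinite_prior_df_collapses_to_prior(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.5, (50, 8))
        matrix, samples, treated = two_group_inputs(x, n_treated=4)
        st_ = fc.differential_stats(matrix, samples, treated, prior_df=np.inf)
        mean = x[:, :4].mean(axis=1) - x[:, 4:].mean(axis=1)
        expected = mean / (np.sqrt(st_.prior_var) * np.sqrt(0.5))
        np.testing.assert_allclose(st_.table["t"], expected, rtol=1e-10)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (20, 9))
        x[:, :4] *= 2.0  # unequal variances
        matrix, samples, treated = two_group_inputs(x, n_treated=4)
        st_ = fc.differential_stats(matrix, samples, treated, method="welch")
        t_ref, p_ref = sps.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=False)
        np.testing.assert_allclose(st_.table["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(st_.table["p_value"], p_ref, rtol=1e-10)

    def test_insufficient_replication_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (5, 2))
        matrix, samples, treated = two_group_inputs(x, n_treated=1)
        with pytest.raises(ValidationError, match=">= 2"):
            fc.differential_stats(matrix, samples, treated)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_agrees_with_limma_oracle(self, tmp_path):
        """Independent cross-check against the Bioconductor eBayes moderated t."""
        rng = np.random.default_rng(42)
        n, n1, n2 = 80, 4, 4
        sd = np.sqrt(0.25 * rng.chisquare(5, n) / 5)
        x = rng.normal(0, 1, (n, n1 + n2)) * sd[:, None]
        x[:8, :n1] += 1.0
        matrix, samples, treated = two_group_inputs(x, n_treated=n1)
        fc.write_expression_matrix(matrix, tmp_path / "mx.tsv")
        script = tmp_path / "run.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path / "mx.tsv"}", row.names=1))\n'
            f'design <- cbind(Intercept=1, Treat=c(rep(1,{n1}), rep(0,{n2})))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.table(data.frame(t=fit$t[,"Treat"], p=fit$p.value[,"Treat"]),\n'
            f'            "{tmp_path / "out.tsv"}", sep="\\t", quote=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        st_ = fc.differential_stats(matrix, samples, treated)
        np.testing.assert_allclose(st_.table["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(st_.table["p_value"], ref["p"], rtol=1e-6)


class TestSelectSignature:
    def test_below_minimum_raises_no_signature(self):
        p = np.concatenate([[1e-6, 1e-5, 1e-4], np.full(97, 0.9)])
        with pytest.raises(fc.NoSignatureError):
            fc.select_signature(_stats_from_table(p), min_size=4)

    def test_truncation_keeps_lowest_fdr(self):
        p = np.linspace(1e-8, 1e-4, 600)
        stats_ = _stats_from_table(np.concatenate([p, np.full(100, 0.9)]))
        sig = fc.select_signature(stats_, max_size=500, fdr_cutoff=0.05)
        assert sig.m == 500
        kept = stats_.table.loc[list(sig.probe_ids), "fdr"]
        dropped = stats_.table["fdr"].drop(list(sig.probe_ids))
        assert kept.max() <= dropped.min() + 1e-15

    def test_negative_logfc_gets_negative_sign(self):
        p = np.array([1e-6, 1e-6, 1e-6, 1e-6, 0.9])
        logfc = np.array([0.5, -0.8, 1.0, -0.2, 0.0])
        sig = fc.select_signature(_stats_from_table(p, logfc=logfc))
        assert dict(zip(sig.probe_ids, sig.signs))["P00001"] == -1

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(9)
        p = np.round(rng.uniform(0, 0.01, 50), 3)  # heavy ties
        logfc = rng.normal(0, 1, 50)
        s1 = fc.select_signature(_stats_from_table(p, logfc=logfc), max_size=20)
        s2 = fc.select_signature(_stats_from_table(p, logfc=logfc), max_size=20)
        assert list(s1.probe_ids) == list(s2.probe_ids)


class TestImpactMetrics:
    def test_rti_fraction_of_platform(self):
        p = np.concatenate([np.full(10, 1e-9), np.full(90, 0.99)])
        m = fc.impact_metrics(_stats_from_table(p, n_probes=10_000))
        assert m.n_deg == 10 and m.rti == pytest.approx(0.001)

    def test_no_degs_mean_undefined(self):
        m = fc.impact_metrics(_stats_from_table(np.full(50, 0.9)))
        assert m.n_deg == 0 and m.rti == 0.0 and m.mean_abs_logfc is None

    def test_mean_abs_logfc_over_degs_only(self):
        p = np.array([1e-9, 1e-9, 0.9])
        logfc = np.array([0.5, -0.3, 9.0])
        m = fc.impact_metrics(_stats_from_table(p, logfc=logfc))
        assert m.mean_abs_logfc == pytest.approx(0.4)
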