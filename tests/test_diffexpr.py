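"""Moderated-t machinery: group stats, prior estimation, shrinkage, power."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import synaptomito as sm
from synaptomito.diffexpr import absent_protein_calls
from synaptomito.quantify import GroupDesign, ProteinMatrix


def _matrix(x1, x2, g1="WT", g2="KO"):
    x1, x2 = np.atleast_2d(x1), np.atleast_2d(x2)
    n1, n2 = x1.shape[1], x2.shape[1]
    samples = [f"{g1}{i}" for i in range(n1)] + [f"{g2}{i}" for i in range(n2)]
    log2 = pd.DataFrame(np.hstack([x1, x2]),
                        index=[f"P{i}" for i in range(x1.shape[0])],
                        columns=samples)
    pm = ProteinMatrix(log2=log2, n_peptides=pd.Series(2, index=log2.index))
    design = GroupDesign(group=pd.Series([g1] * n1 + [g2] * n2, index=samples))
    return pm, design


class TestGroupStats:
    def test_constant_groups(self):
        pm, design = _matrix([[1.0, 1, 1]], [[2.0, 2, 2]])
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        assert gs.loc["P0", "log2fc"] == pytest.approx(1.0)
        assert gs.loc["P0", "s2_g"] == pytest.approx(0.0)
        assert gs.loc["P0", "df_g"] == 4

    def test_known_arithmetic(self):
        pm, design = _matrix([[0.0, 1, 2]], [[3.0, 4, 5]])
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        assert gs.loc["P0", "log2fc"] == pytest.approx(3.0)
        assert gs.loc["P0", "s2_g"] == pytest.approx(1.0)
        assert gs.loc["P0", "df_g"] == 4

    def test_variances_follow_chi_square(self):
        # protein-level normal noise: s2 * df / sigma^2 ~ chi2(df)
        cfg = sm.PeptideSimConfig(
            n_proteins=2000, replicate_sd=0.2, peptide_sd=0.0,
            sample_offset_sd=0.0, effect_log2=0.0, q_fail_rate=0.0, seed=5,
        )
        pt, design, _ = sm.simulate_peptides(cfg)
        pm = sm.rollup_proteins(sm.filter_peptides(pt, design))
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        scaled = gs["s2_g"].values * 10 / 0.2**2
        assert stats.kstest(scaled, "chi2", args=(10,)).pvalue > 0.01

    def test_absent_protein_flagged_with_floor_fold_change(self):
        x1 = np.array([[20.0, 20, 20], [15.0, 15, 15]])
        x2 = np.array([[np.nan, np.nan, np.nan], [15.0, 15, 15]])
        pm, design = _matrix(x1, x2)
        calls = absent_protein_calls(pm, design, "WT", "KO")
        assert list(calls["protein_id"]) == ["P0"]
        assert calls.iloc[0]["absent_in"] == "KO"
        # fold-change vs the KO floor (min observed in KO samples = 15)
        assert calls.iloc[0]["log2fc_vs_floor"] == pytest.approx(15 - 20)


class TestPrior:
    def test_identical_variances_give_infinite_d0(self):
        pr = sm.estimate_prior(np.array([0.5, 0.5]), np.array([4.0, 4.0]))
        assert np.isinf(pr.d0)
        assert pr.s0_sq > 0

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            sm.estimate_prior(np.zeros(20), np.full(20, 4.0))

    def test_single_scaled_chi2_hits_infinite_branch(self):
        rng = np.random.default_rng(12)
        s2 = rng.chisquare(4, 5000) / 4
        pr = sm.estimate_prior(s2, 4.0)
        assert np.isinf(pr.d0) or pr.d0 > 50
        assert pr.s0_sq == pytest.approx(1.0, abs=0.05)


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(20, 0.3, size=(100, 6))
        x2 = rng.normal(20, 0.3, size=(100, 6))
        pm, design = _matrix(x1, x2)
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        de = sm.moderated_t(gs, sm.PriorEstimate(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = stats.ttest_ind(x2, x1, axis=1)
        assert np.allclose(de["t_mod"].values, t_ref, atol=1e-10)
        assert np.allclose(de["p"].values, p_ref, atol=1e-10)

    def test_d0_infinite_uses_prior_variance(self):
        rng = np.random.default_rng(8)
        pm, design = _matrix(rng.normal(0, 1, (50, 6)), rng.normal(0, 1, (50, 6)))
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        de = sm.moderated_t(gs, sm.PriorEstimate(d0=np.inf, s0_sq=0.7))
        assert np.allclose(de["s2_post"].values, 0.7)
        # equal n: |t| ordering equals |log2fc| ordering
        order_t = np.argsort(np.abs(de["t_mod"].values))
        order_fc = np.argsort(np.abs(de["log2fc"].values))
        assert np.array_equal(order_t, order_fc)

    def test_posterior_variance_monotone_and_shrinks_toward_prior(self):
        s2 = np.linspace(0.01, 2.0, 50)
        gs = pd.DataFrame(
            {"log2fc": 1.0, "s2_g": s2, "df_g": 10.0, "n1": 6, "n2": 6}
        )
        de = sm.moderated_t(gs, sm.PriorEstimate(d0=4.0, s0_sq=0.5))
        post = de["s2_post"].values
        assert np.all(np.diff(post) > 0)
        lo = np.minimum(s2, 0.5)
        hi = np.maximum(s2, 0.5)
        assert np.all((post >= lo) & (post <= hi))

    def test_moderation_beats_plain_t_at_small_n(self):
        # planted effect 0.2 log2, protein sd ~0.13, 6 vs 6; heterogeneous
        # true variances from the scaled-F model the moderation assumes
        rng = np.random.default_rng(21)
        n_prot, reps = 300, 50
        mod_hits = plain_hits = 0
        for _ in range(reps):
            sigma2 = 0.13**2 * 4 / rng.chisquare(4, n_prot)
            x1 = rng.normal(0, np.sqrt(sigma2)[:, None], (n_prot, 6))
            x2 = rng.normal(0, np.sqrt(sigma2)[:, None], (n_prot, 6))
            x2[: n_prot // 10] += 0.2
            pm, design = _matrix(x1, x2)
            de = sm.differential_expression(pm, design, "WT", "KO")
            mod_hits += int((de["p"].values[: n_prot // 10] < 0.01).sum())
            t, p = stats.ttest_ind(x2, x1, axis=1)
            plain_hits += int((p[: n_prot // 10] < 0.01).sum())
        assert mod_hits > plain_hits


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's eBayes on the same small matrix."""
        rng = np.random.default_rng(33)
        sigma2 = 0.02 * 4 / rng.chisquare(4, 120)
        x1 = 20 + rng.normal(0, np.sqrt(sigma2)[:, None], (120, 6))
        x2 = 20 + rng.normal(0, np.sqrt(sigma2)[:, None], (120, 6))
        x2[:20] += 0.3
        pm, design = _matrix(x1, x2)
        de = sm.differential_expression(pm, design, "WT", "KO")
        gs = sm.fit_group_stats(pm, design, "WT", "KO")
        prior = sm.estimate_prior(gs["s2_g"].values, gs["df_g"].values)

        mat_file = tmp_path / "mat.tsv"
        pm.log2.to_csv(mat_file, sep="\t")
        script = tmp_path / "ebayes.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_file}", row.names=1, check.names=FALSE))
            design <- cbind(Intercept=1, KO=c(rep(0,6), rep(1,6)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"KO"], p=fit$p.value[,"KO"],
                              s2post=fit$s2.post, d0=fit$df.prior, s0=fit$s2.prior)
            write.csv(out, "{tmp_path / 'limma.csv'}")
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        assert np.allclose(de["t_mod"].values, ref["t"].values, rtol=1e-6, atol=1e-8)
        assert np.allclose(de["p"].values, ref["p"].values, rtol=1e-6, atol=1e-12)
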