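"""Moderated-t shrinkage fit, probeset collapse, BH-FDR and DEG calls."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from epiloci.degx import (
    EBHyperparams,
    ExpressionMatrix,
    bh_fdr,
    call_degs,
    collapse_probesets,
    estimate_hyperparams,
    fit_moderated_t,
    read_expression,
)


def _expr(values, n1=3, n2=3, probe_ids=None):
    values = np.asarray(values, dtype=float)
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    probes = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probes, name="probeset"),
                            columns=samples),
        group=pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples),
        probe_to_gene={p: p.split("_")[0] for p in probes},
    )


def _simulate(rng, n_probes, d0=4.0, s0_sq=0.05, n1=3, n2=3, lfc=None):
    sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=n_probes)
    lfc = np.zeros(n_probes) if lfc is None else lfc
    x1 = rng.normal(0.0, np.sqrt(sigma_sq)[:, None], size=(n_probes, n1))
    x2 = rng.normal(lfc[:, None], np.sqrt(sigma_sq)[:, None], size=(n_probes, n2))
    return _expr(np.hstack([x1, x2]), n1, n2)


class TestModeratedT:
    def test_zero_prior_df_equals_classical_pooled_t(self, rng):
        expr = _simulate(rng, 200)
        res, _ = fit_moderated_t(expr, prior_df=0)
        x = expr.values.to_numpy()
        t_classic = stats.ttest_ind(x[:, 3:], x[:, :3], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_classic.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], t_classic.pvalue, atol=1e-10)

    def test_hyperparameter_recovery(self, rng):
        expr = _simulate(rng, 8000, d0=4.0, s0_sq=0.05)
        _, hp = fit_moderated_t(expr)
        assert hp.d0 == pytest.approx(4.0, rel=0.25)
        assert hp.s0_sq == pytest.approx(0.05, rel=0.10)

    def test_posterior_variance_is_convex_combination(self, rng):
        expr = _simulate(rng, 500)
        res, hp = fit_moderated_t(expr)
        d = 4  # residual df for 3+3
        s_tilde = (hp.d0 * hp.s0_sq + d * res["s_sq"]) / (hp.d0 + d)
        lo = np.minimum(hp.s0_sq, res["s_sq"])
        hi = np.maximum(hp.s0_sq, res["s_sq"])
        assert ((s_tilde >= lo - 1e-12) & (s_tilde <= hi + 1e-12)).all()

    def test_rank_invariance_under_global_rescaling(self, rng):
        expr = _simulate(rng, 300, lfc=rng.normal(0, 0.5, 300))
        res1, _ = fit_moderated_t(expr)
        scaled = _expr(expr.values.to_numpy() * 3.7)
        res2, _ = fit_moderated_t(scaled)
        order1 = np.argsort(-res1["t_mod"].abs().to_numpy())
        order2 = np.argsort(-res2["t_mod"].abs().to_numpy())
        np.testing.assert_array_equal(order1, order2)

    def test_infinite_d0_limit_collapses_to_prior_variance(self, rng):
        expr = _simulate(rng, 100)
        hp = EBHyperparams(d0=1e8, s0_sq=0.04)
        res, _ = fit_moderated_t(expr, hyperparams=hp)
        d = 4
        s_tilde = (1e8 * 0.04 + d * res["s_sq"]) / (1e8 + d)
        np.testing.assert_allclose(s_tilde, 0.04, rtol=1e-5)
        t_limit = res["log_fc"] / np.sqrt(0.04 * (2 / 3))
        np.testing.assert_allclose(res["t_mod"], t_limit, rtol=1e-5)

    def test_negative_moment_estimate_gives_infinite_d0(self):
        # identical sample variances: no dispersion at all beyond what the
        # chi-square already implies -> negative trigamma target -> d0 = inf
        hp = estimate_hyperparams(np.full(100, 0.05), d_resid=4)
        assert math.isinf(hp.d0)
        # and the prior scale then satisfies the d0 -> inf closed form
        expected = math.exp(math.log(0.05) - special.digamma(2.0) + math.log(2.0))
        assert hp.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_probeset_flagged_and_shrunk(self):
        vals = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                         [0.0, 1.0, 2.0, 1.0, 3.0, 2.0],
                         [5.0, 6.0, 4.0, 7.0, 8.0, 9.0]])
        res, hp = fit_moderated_t(_expr(vals))
        assert bool(res["zero_var"].iloc[0])
        assert np.isfinite(res["t_mod"].iloc[0])

    def test_too_few_probesets_error(self):
        with pytest.raises(ValueError, match="probesets"):
            fit_moderated_t(_expr([[1.0, 2.0, 1.5, 3.0, 2.0, 2.5]]))

    def test_all_null_pvalues_uniform(self, rng):
        expr = _simulate(rng, 3000)
        res, _ = fit_moderated_t(expr)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_matches_limma_on_small_matrix(self, rng, tmp_path):
        expr = _simulate(rng, 120, d0=4.0, s0_sq=0.05,
                         lfc=rng.normal(0, 0.8, 120))
        expr.values.to_csv(tmp_path / "x.tsv", sep="\t")
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
            design <- cbind(1, c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, commandArgs(TRUE)[2], sep="\t", quote=FALSE)
            """
        )
        out = tmp_path / "limma.tsv"
        subprocess.run(["Rscript", str(script), str(tmp_path / "x.tsv"), str(out)],
                       check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        res, hp = fit_moderated_t(expr)
        assert hp.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert hp.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6)


class TestCollapse:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["probeset", "log_fc", "s_sq", "t_mod",
                                           "df_total", "p", "zero_var"])

    def test_most_significant_probeset_kept(self):
        res = self._results([("g1_a", 1.0, 0.1, 3.0, 8, 0.01, False),
                             ("g1_b", 0.5, 0.1, 1.0, 8, 0.2, False)])
        out = collapse_probesets(res, {"g1_a": "G1", "g1_b": "G1"})
        assert len(out) == 1 and out["probeset"].iloc[0] == "g1_a"

    def test_single_probeset_identity(self):
        res = self._results([("g1_a", 1.0, 0.1, 3.0, 8, 0.01, False)])
        out = collapse_probesets(res, {"g1_a": "G1"})
        assert out["probeset"].tolist() == ["g1_a"]

    def test_tie_on_p_larger_abs_t_wins_any_order(self):
        rows = [("pA", 1.0, 0.1, -4.0, 8, 0.05, False),
                ("pB", 1.0, 0.1, 2.0, 8, 0.05, False)]
        m = {"pA": "G", "pB": "G"}
        for perm in (rows, rows[::-1]):
            out = collapse_probesets(self._results(perm), m)
            assert out["probeset"].iloc[0] == "pA"

    def test_unmapped_probesets_dropped(self):
        res = self._results([("known", 1.0, 0.1, 3.0, 8, 0.01, False),
                             ("orphan", 1.0, 0.1, 3.0, 8, 0.01, False)])
        out = collapse_probesets(res, {"known": "G"})
        assert out["gene"].tolist() == ["G"]


class TestFdrAndCalls:
    def bh_oracle(self, p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    def test_worked_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60))).clip(1e-12, 1.0)
            np.testing.assert_allclose(bh_fdr(p), self.bh_oracle(p), atol=1e-12)

    def test_monotone_and_capped(self, rng):
        p = rng.random(100).clip(1e-12, 1.0)
        q = bh_fdr(p)
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_deg_threshold_is_strict(self):
        # single gene: fdr == p; a gene at exactly the threshold is NOT a DEG
        df = pd.DataFrame({"gene": ["a"], "log_fc": [1.0], "p": [0.05]})
        called = call_degs(df, fdr_threshold=0.05)
        assert not called["is_deg"].iloc[0]
        called = call_degs(df.assign(p=[0.049]), fdr_threshold=0.05)
        assert called["is_deg"].iloc[0]

    def test_fc_ratio_scale(self):
        df = pd.DataFrame({"gene": ["a", "b", "c"], "log_fc": [0.0, 1.0, -0.5],
                           "p": [0.5, 0.5, 0.5]})
        called = call_degs(df)
        np.testing.assert_allclose(called["fc_ratio"], [1.0, 2.0, 2 ** -0.5])


class TestExpressionIO:
    def test_round_trip_with_gene_column(self, tmp_path):
        vals = pd.DataFrame(
            [[1.0, 2.0, 1.5, 3.0, 2.5, 2.0], [0.5, 0.7, 0.6, 0.9, 1.0, 0.8]],
            index=pd.Index(["p1", "p2"], name="probeset"),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = vals.copy()
        out.insert(0, "gene", ["G1", "G2"])
        path = tmp_path / "expr.tsv"
        out.to_csv(path, sep="\t")
        groups = {c: ("pre" if c.startswith("a") else "post") for c in vals.columns}
        expr = read_expression(path, groups)
        pd.testing.assert_frame_equal(expr.values, vals)
        assert expr.probe_to_gene == {"p1": "G1", "p2": "G2"}

    def test_missing_group_assignment_rejected(self, tmp_path):
        vals = pd.DataFrame([[1.0, 2.0, 1.5, 3.0]],
                            index=pd.Index(["p1"], name="probeset"),
                            columns=["a1", "a2", "b1", "b2"])
        path = tmp_path / "expr.tsv"
        vals.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="without group"):
            read_expression(path, {"a1": "g1", "a2": "g1", "b1": "g2"})

    def test_group_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            _expr(np.ones((3, 6)), n1=6, n2=0)
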