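"""Fisher enrichment with the any-cell-type baseline, and binned fold change."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from conftest import random_overlap_matrix
from epiloci.enrich import binned_fold_change, celltype_enrichment, fisher_exact
from epiloci.loci import assemble_loci
from epiloci.overlap import incidence_to_matrix


def fisher_oracle(a, b, c, d, alternative="two-sided"):
    """Exact hypergeometric enumeration conditional on the margins."""
    r1, n1 = a + b, a + c
    N = a + b + c + d
    denom = comb(N, n1)
    support = range(max(0, n1 - (N - r1)), min(r1, n1) + 1)
    probs = {x: comb(r1, x) * comb(N - r1, n1 - x) / denom for x in support}
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    cutoff = probs[a] * (1.0 + 1e-7)
    return sum(p for p in probs.values() if p <= cutoff)


class TestFisherExact:
    def test_worked_example(self):
        or_, p = fisher_exact(3, 1, 1, 3)
        assert or_ == 9.0
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_symmetric_table(self):
        or_, p = fisher_exact(2, 2, 2, 2)
        assert or_ == 1.0 and p == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            for alt in ("two-sided", "greater"):
                _, p = fisher_exact(int(a), int(b), int(c), int(d), alternative=alt)
                assert p == pytest.approx(fisher_oracle(a, b, c, d, alt), rel=1e-9)

    def test_transpose_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 10, size=4))
            assert fisher_exact(a, b, c, d) == pytest.approx(fisher_exact(a, c, b, d))

    def test_odds_ratio_corner_cases(self):
        or_, _ = fisher_exact(3, 0, 1, 3)
        assert math.isinf(or_)
        or_, _ = fisher_exact(0, 3, 3, 1)
        assert or_ == 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact(0, 0, 1, 1)
        with pytest.raises(ValueError, match=">= 0"):
            fisher_exact(-1, 1, 1, 1)
        with pytest.raises(ValueError, match="alternative"):
            fisher_exact(1, 1, 1, 1, alternative="less")


class TestCelltypeEnrichment:
    def _matrix_with_counts(self):
        """53 suggestive baseline markers, 30 overlapping the tested cell type."""
        rows = []
        ids = []
        sugg = []
        k = 0
        def add(n, a_flag, other_flag, s_flag):
            nonlocal k
            for _ in range(n):
                rows.append([a_flag, other_flag])
                ids.append(f"m{k}")
                sugg.append(s_flag)
                k += 1
        add(30, True, False, True)    # suggestive, overlap tested ct
        add(23, False, True, True)    # suggestive, overlap only the other ct
        add(100, True, False, False)  # non-suggestive, overlap tested ct
        add(250, False, True, False)  # non-suggestive, overlap only other
        add(40, False, False, True)   # suggestive, no overlap (outside baseline)
        inc = pd.DataFrame(rows, columns=["tested", "other"],
                           index=pd.Index(ids, name="id"))
        return incidence_to_matrix(inc), pd.Series(sugg, index=inc.index)

    def test_counts_and_baseline(self):
        om, sugg = self._matrix_with_counts()
        res = celltype_enrichment(om, sugg).set_index("cell_type")
        row = res.loc["tested"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (30, 23, 100, 250)
        assert row["n_suggestive_markers"] == 53
        assert row["b"] == 53 - 30

    def test_bonferroni_single_cell_type(self):
        # one testable cell type: its own overlap IS the whole baseline, so
        # the table is degenerate (b = d = 0), p = 1 and p_bonf = p
        inc = pd.DataFrame({"only": [True, True, False, True]},
                           index=pd.Index(list("wxyz"), name="id"))
        om = incidence_to_matrix(inc)
        sugg = pd.Series([True, False, True, False], index=inc.index)
        res = celltype_enrichment(om, sugg)
        assert len(res) == 1
        assert res["p"].iloc[0] == 1.0
        assert res["p_bonf"].iloc[0] == res["p"].iloc[0]

    def test_bonferroni_counts_only_testable_celltypes(self):
        om, sugg = self._matrix_with_counts()
        inc = om.incidence.copy()
        inc["empty"] = False
        om2 = incidence_to_matrix(inc)
        res = celltype_enrichment(om2, sugg).set_index("cell_type")
        assert "empty" not in res.index  # contributes no test
        # Bonferroni denominator is 2 (tested, other), not 3
        assert res["p_bonf"]["tested"] == pytest.approx(
            min(1.0, res["p"]["tested"] * 2)
        )

    def test_empty_baseline_errors(self):
        inc = pd.DataFrame({"a": [False, False]}, index=pd.Index(["x", "y"], name="id"))
        with pytest.raises(ValueError, match="baseline"):
            celltype_enrichment(incidence_to_matrix(inc),
                                pd.Series([True, False], index=inc.index))

    def test_n_loci_counts_loci_contributing_to_a(self):
        om, sugg = self._matrix_with_counts()
        markers = pd.DataFrame(
            {"id": om.incidence.index,
             "chrom": "1",
             "pos": np.arange(len(om.incidence)) * 10_000 + 1,
             "p": np.where(sugg, 1e-6, 0.5)}
        )
        loci = assemble_loci(markers[sugg.to_numpy()])
        res = celltype_enrichment(om, sugg, loci=loci).set_index("cell_type")
        # markers are 10 kb apart so all suggestive markers form one locus
        assert res.loc["tested", "n_loci"] == 1

    def test_any_other_baseline_mode(self):
        # rows: (tested, other); strict mode drops rows overlapping only "tested"
        rows = [(True, True)] * 4 + [(True, False)] * 3 + [(False, True)] * 5
        sugg_flags = [True, True, False, False, True, True, False, True, True, False, False, False]
        inc = pd.DataFrame(rows, columns=["tested", "other"],
                           index=pd.Index([f"m{i}" for i in range(len(rows))], name="id"))
        om = incidence_to_matrix(inc)
        sugg = pd.Series(sugg_flags, index=inc.index)
        res = celltype_enrichment(om, sugg, baseline="any_other").set_index("cell_type")
        # baseline for "tested" = rows overlapping "other" (9 rows);
        # a counts suggestive rows overlapping tested among them -> the 2 (T,T) sugg rows
        assert res.loc["tested", "a"] == 2
        assert res.loc["tested", "n_suggestive_markers"] == 4  # sugg rows in that baseline
        # default mode uses the full 12-row any-overlap baseline instead
        res_any = celltype_enrichment(om, sugg).set_index("cell_type")
        assert res_any.loc["tested", "n_suggestive_markers"] == 6


class TestBinnedFoldChange:
    def _setup(self, rng):
        om = random_overlap_matrix(rng, 600, ["ct1", "ct2"], rate=0.4)
        p = pd.Series(10 ** -(rng.random(600) * 5), index=om.incidence.index)
        return om, p

    def test_reference_bin_fc_is_one(self, rng):
        om, p = self._setup(rng)
        fc = binned_fold_change(p, om)
        ref = fc[(fc["bin_lo"] == 0.0)]
        for _, row in ref.iterrows():
            if row["proportion"] > 0:
                assert row["fold_change"] == pytest.approx(1.0)

    def test_fc_arithmetic(self):
        # reference bin proportion 0.3, top bin proportion 0.6 -> FC 2
        ids = [f"m{i}" for i in range(20)]
        inc = pd.DataFrame({"ct": [True] * 3 + [False] * 7 + [True] * 6 + [False] * 4},
                           index=pd.Index(ids, name="id"))
        inc["pad"] = ~inc["ct"]  # make every marker any-overlap
        om = incidence_to_matrix(inc)
        p = pd.Series([0.5] * 10 + [5e-5] * 10, index=inc.index)
        fc = binned_fold_change(p, om)
        top = fc[(fc["cell_type"] == "ct") & (fc["bin_lo"] == 4.0)]
        assert top["proportion"].iloc[0] == pytest.approx(0.6)
        assert top["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_last_bin_open_ended(self, rng):
        om, p = self._setup(rng)
        fc = binned_fold_change(p, om)
        assert np.isinf(fc["bin_hi"].max())

    def test_empty_reference_bin_errors(self, rng):
        om, _ = self._setup(rng)
        p = pd.Series(np.full(600, 1e-3), index=om.incidence.index)
        with pytest.raises(ValueError, match="reference bin"):
            binned_fold_change(p, om)

    def test_empty_bins_flagged_undefined(self):
        ids = ["a", "b"]
        inc = pd.DataFrame({"ct": [True, True]}, index=pd.Index(ids, name="id"))
        om = incidence_to_matrix(inc)
        p = pd.Series([0.5, 1e-3], index=inc.index)  # bin [1,2) and [2,3) empty
        fc = binned_fold_change(p, om)
        gap = fc[(fc["bin_lo"] == 1.0)]
        assert not gap["defined"].iloc[0] and math.isnan(gap["proportion"].iloc[0])

    def test_planted_monotone_trend_yields_nondecreasing_fc(self, rng):
        # log-linear planted overlap trend in -log10 p for one cell type
        n = 4000
        nlp = rng.random(n) * 5
        base = 0.25
        slope = 0.12
        prob = np.clip(base + slope * nlp, 0, 0.9)
        inc = pd.DataFrame(
            {"planted": rng.random(n) < prob, "flat": rng.random(n) < 0.4,
             "pad": np.ones(n, dtype=bool)},
            index=pd.Index([f"m{i}" for i in range(n)], name="id"),
        )
        om = incidence_to_matrix(inc)
        p = pd.Series(10.0 ** -nlp, index=inc.index)
        fc = binned_fold_change(p, om)
        vals = fc[(fc["cell_type"] == "planted") & fc["defined"]]
        fcs = vals.sort_values("bin_lo")["fold_change"].to_numpy()
        # allow small sampling wiggle: each bin within 15% of the running max
        assert all(fcs[i + 1] > fcs[: i + 1].max() * 0.85 for i in range(len(fcs) - 1))
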