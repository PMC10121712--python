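"""Hypergeometric machinery, regulon replication, 2x2 concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snstates import (
    Regulon,
    deg_concordance,
    hypergeom_overlap,
    regulon_replication,
    summarize_gwas_genes,
)
from snstates.replication import calls_to_table


class TestHypergeomOverlap:
    def test_tf_concordance_matches_both_printed_values(self):
        """The cross-cohort TF concordance with a 896-TF universe, 222
        discovery and 190 replication TFs sharing 122: point probability
        9.08e-41, upper tail 9.98e-41."""
        ot = hypergeom_overlap(M=896, n=222, N=190, k=122)
        assert ot.p_point == pytest.approx(9.08e-41, rel=0.01)
        assert ot.p_tail == pytest.approx(9.98e-41, rel=0.01)

    def test_direct_combinatorics_small_universe(self):
        assert hypergeom_overlap(4, 2, 2, 1).p_point == pytest.approx(4 / 6)
        assert hypergeom_overlap(4, 2, 2, 2).p_point == pytest.approx(1 / 6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)  # k > min(n, N)
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 9, 9, 7)  # k < n + N - M
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 11, 5, 2)  # n > M

    def test_point_le_tail_le_one(self):
        ot = hypergeom_overlap(50, 20, 10, 5)
        assert 0 < ot.p_point <= ot.p_tail <= 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_pmf_sums_to_one_over_full_support(self, data):
        M = data.draw(st.integers(2, 60))
        n = data.draw(st.integers(0, M))
        N = data.draw(st.integers(0, M))
        lo, hi = max(0, n + N - M), min(n, N)
        total = sum(hypergeom_overlap(M, n, N, k).p_point for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_tail_equals_brute_force_enumeration(self, data):
        M = data.draw(st.integers(2, 25))
        n = data.draw(st.integers(1, M))
        N = data.draw(st.integers(1, M))
        lo, hi = max(0, n + N - M), min(n, N)
        k = data.draw(st.integers(lo, hi))
        brute = sum(
            math.comb(N, kk) * math.comb(M - N, n - kk) for kk in range(k, hi + 1)
        ) / math.comb(M, n)
        assert hypergeom_overlap(M, n, N, k).p_tail == pytest.approx(brute, rel=1e-9)


def _regs(tag, tfs, targets_per=50, universe=None, rng=None):
    out = []
    for i, tf in enumerate(tfs):
        if rng is not None and universe is not None:
            targets = list(rng.choice(universe, targets_per, replace=False))
        else:
            targets = [f"T{i}_{j}" for j in range(targets_per)]
        out.append(Regulon(tf, targets, cohort=tag))
    return out


class TestRegulonReplication:
    def test_disjoint_tf_sets_give_empty_table_with_overall_test(self):
        disc = _regs("d", [f"TFd{i}" for i in range(5)])
        repl = _regs("r", [f"TFr{i}" for i in range(5)])
        res = regulon_replication(disc, repl, de_gene_list=[], gene_universe_size=1000)
        assert len(res.table) == 0
        assert res.tf_concordance.k == 0

    def test_identical_cohorts_fully_replicate(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(8561)]
        tfs = [f"TF{i}" for i in range(10)]
        disc = _regs("d", tfs, universe=universe, rng=rng)
        repl = [Regulon(r.tf, list(r.targets), "r") for r in disc]
        res = regulon_replication(disc, repl, de_gene_list=tfs, gene_universe_size=8561)
        assert len(res.table) == 10
        assert (res.table.q < 1e-20).all()

    def test_strictly_more_than_two_intersecting_targets_required(self):
        universe = [f"g{i}" for i in range(100)]
        shared2 = ["g0", "g1"]
        shared3 = ["g0", "g1", "g2"]
        disc = [
            Regulon("TFA", shared2 + ["g10", "g11"], "d"),
            Regulon("TFB", shared3 + ["g20"], "d"),
        ]
        repl = [
            Regulon("TFA", shared2 + ["g30", "g31"], "r"),
            Regulon("TFB", shared3 + ["g40"], "r"),
        ]
        res = regulon_replication(
            disc, repl, de_gene_list=["TFA", "TFB"], gene_universe_size=100
        )
        assert res.table.tf.tolist() == ["TFB"]
        assert res.table.k_intersecting.iloc[0] == 3

    def test_output_invariant_to_regulon_order(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(500)]
        tfs = [f"TF{i}" for i in range(6)]
        disc = _regs("d", tfs, universe=universe, rng=rng)
        repl = [Regulon(r.tf, list(r.targets), "r") for r in disc]
        res_a = regulon_replication(disc, repl, tfs, 500)
        res_b = regulon_replication(disc[::-1], repl[::-1], tfs, 500)
        pd.testing.assert_frame_equal(res_a.table, res_b.table)


class TestDegConcordance:
    def test_perfect_agreement_table(self):
        odds, p = deg_concordance([[10, 0], [0, 10]])
        assert odds == np.inf
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_flagged(self):
        odds, p = deg_concordance([[0, 0], [5, 10]])
        assert math.isnan(odds) and p == 1.0

    def test_conditional_mle_matches_known_value(self):
        # conditional MLE for this table is well below the sample OR
        odds, _ = deg_concordance([[10, 2], [3, 15]])
        sample_or = (10 * 15) / (2 * 3)
        assert 0 < odds < sample_or * 1.2
        # cross-check against the noncentral hypergeometric mean identity
        dist = stats.nchypergeom_fisher(30, 12, 13, odds)
        assert dist.mean() == pytest.approx(10, abs=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            a = rng.random(40) < 0.3
            b = rng.random(40) < 0.3
            pvals.append(deg_concordance(calls_to_table(a, b))[1])
        # discrete conservative p-values: check no inflation at the tail
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.07


class TestSummarizeGwasGenes:
    def _inputs(self):
        de = pd.DataFrame(
            {
                "gene": ["BIN1", "BIN1", "PLCG2", "TREM2"],
                "cell_type": ["microglia"] * 4,
                "cell_state": ["mic.0", "mic.1", "mic.0", "mic.2"],
                "contrast": ["state_vs_rest", "state_vs_state", "state_vs_rest", "state_vs_rest"],
                "estimate": [np.log(2), -0.3, -0.3, 0.5],
                "q": [0.01, 0.01, 0.01, 0.01],
            }
        )
        sizes = pd.DataFrame(
            {
                "cell_type": ["microglia"] * 3,
                "cell_state": ["mic.0", "mic.1", "mic.2"],
                "fraction": [0.5, 0.46, 0.04],
            }
        )
        expr = pd.DataFrame(
            {
                "gene": ["BIN1", "PLCG2", "TREM2"],
                "cell_type": ["microglia"] * 3,
                "mean_expression": [10.0, 1.0, 5.0],
            }
        )
        return de, sizes, expr

    def test_small_state_and_negative_one_vs_rest_rules(self):
        de, sizes, expr = self._inputs()
        out = summarize_gwas_genes(de, sizes, expr)
        # TREM2: only hit is against a 4% state -> excluded entirely
        assert "TREM2" not in set(out.gene)
        # PLCG2: negative one-vs-rest hit -> dropped
        assert "PLCG2" not in set(out.gene)
        # BIN1: positive one-vs-rest ln2 -> log2FC 1; negative pairwise kept as |.|
        row = out[out.gene == "BIN1"].iloc[0]
        assert row.max_abs_log2fc == pytest.approx(1.0)
        assert row.log10_mean_expression == pytest.approx(1.0)

    def test_negative_pairwise_hits_survive(self):
        de, sizes, expr = self._inputs()
        de = de[de.contrast == "state_vs_state"]
        out = summarize_gwas_genes(de, sizes, expr)
        assert out[out.gene == "BIN1"].max_abs_log2fc.iloc[0] == pytest.approx(
            0.3 * np.log2(np.e)
        )
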