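import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from oracles import (
    enumerate_overlap_tail,
    exact_binomial_cmf,
    exact_binomial_upper,
    exact_hypergeom_tail,
)
from ploidyseq.counts import CountTable
from ploidyseq.de import (
    ReplicatesInconsistentError,
    binomial_cmf,
    call_candidates,
    combined_ranking,
    fold_change,
    overlap_significance,
    overlap_top_candidates,
    reciprocal_pvalues,
    select_top_n,
    summarize_de,
)
from ploidyseq.simulate import (
    SimulationConfig,
    simulate_count_pair,
    simulate_frequency_profile,
)


class TestBinomialCmf:
    def test_small_exact_values(self):
        assert binomial_cmf(2, 10, 0.5) == pytest.approx(56 / 1024, rel=1e-12)
        assert binomial_cmf(0, 10, 0.1) == pytest.approx(0.9**10, rel=1e-12)
        assert binomial_cmf(10, 10, 0.37) == 1.0

    @given(st.integers(1, 2000), st.data())
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_exact_summation(self, n, data):
        k = data.draw(st.integers(0, n))
        f = Fraction(data.draw(st.integers(0, 64)), 64)
        exact = float(exact_binomial_cmf(k, n, f))
        got = binomial_cmf(k, n, float(f))
        assert got == pytest.approx(exact, rel=1e-9, abs=1e-300)

    def test_numerically_stable_at_large_n(self):
        # lower tail at n=1e8 (mean 1000, sd ~31.6) stays finite, ordered
        # and close to the normal approximation
        p1 = binomial_cmf(900, 100_000_000, 1e-5)   # z ~ -3.15
        p2 = binomial_cmf(950, 100_000_000, 1e-5)   # z ~ -1.57
        assert 0 < p1 < p2 < 0.5
        assert p1 == pytest.approx(8.2e-4, rel=0.3)
        deep = binomial_cmf(400, 100_000_000, 1e-5)
        assert 0 < deep < 1e-60

    @pytest.mark.parametrize("k,n,f", [(11, 10, 0.5), (-1, 10, 0.5),
                                       (2, 10, 1.5), (2, 10, -0.1)])
    def test_domain_errors(self, k, n, f):
        with pytest.raises(ValueError):
            binomial_cmf(k, n, f)


class TestReciprocalPvalues:
    def test_equal_counts_are_not_called(self):
        p_th, p_ht = reciprocal_pvalues(100, 10**6, 100, 10**6)
        assert p_th > 0.05 and p_ht > 0.05

    def test_fourfold_drop_is_called(self):
        p_th, p_ht = reciprocal_pvalues(100, 10**6, 25, 10**6)
        assert p_th < 0.001 and p_ht < 0.001
        # oracle cross-check on the reciprocal tail at reduced depth
        exact = exact_binomial_upper(10, 10_000, Fraction(25, 100_000))
        got = reciprocal_pvalues(10, 10_000, 25, 100_000)[1]
        assert got == pytest.approx(float(exact), rel=1e-9)

    def test_zero_count_gene_closed_form(self):
        p_th, p_ht = reciprocal_pvalues(0, 10**6, 50, 10**6)
        assert p_th == 0.0
        assert p_ht == pytest.approx((1 - 5e-5) ** 10**6, rel=1e-6)

    def test_zero_reference_frequency_conventions(self):
        # both counts zero: lower tails include everything
        assert reciprocal_pvalues(0, 1000, 0, 1000) == (1.0, 1.0)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_sample_swap(self, k_a, k_b):
        """Swapping haploid and tetraploid exchanges the two p-values
        (when a direction exists; ties have no direction to flip)."""
        assume(k_a != k_b)
        p1 = reciprocal_pvalues(k_a, 10_000, k_b, 10_000)
        p2 = reciprocal_pvalues(k_b, 10_000, k_a, 10_000)
        assert p1[0] == pytest.approx(p2[1], rel=1e-12)
        assert p1[1] == pytest.approx(p2[0], rel=1e-12)

    def test_monotone_along_each_tail(self):
        """Moving k_t away from N_t*f_h never increases the tail p."""
        down = [reciprocal_pvalues(100, 10**6, k, 10**6)[0]
                for k in range(100, 20, -5)]
        assert all(a >= b for a, b in zip(down, down[1:]))
        up = [reciprocal_pvalues(100, 10**6, k, 10**6)[0]
              for k in range(101, 200, 5)]
        assert all(a >= b for a, b in zip(up, up[1:]))

    def test_zero_library_total_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_pvalues(0, 0, 5, 100)


class TestFoldChange:
    def test_basic_ratios(self):
        assert fold_change(100, 10**6, 25, 10**6) == pytest.approx(0.25)
        assert fold_change(77, 10**6, 77, 10**6) == pytest.approx(1.0)

    def test_pseudocount_only_replaces_zero(self):
        assert fold_change(0, 10**6, 50, 10**6) == pytest.approx(100.0)
        assert fold_change(50, 10**6, 0, 10**6) == pytest.approx(0.01)


class TestCallCandidates:
    def test_planted_repressed_gene_recovered(self, toy_pair):
        repressed, induced = call_candidates(*toy_pair)
        assert [r.gene_id for r in repressed] == ["gene_down"]
        assert induced == []
        rec = repressed[0]
        assert rec.passes and rec.direction == "repressed-in-tetraploid"
        assert rec.fold == pytest.approx(0.25)

    def test_low_expression_gene_never_called(self):
        hap = CountTable("h", "1n", {"g": 14.0}, 10**6)
        tet = CountTable("t", "4n", {"g": 0.0}, 10**6)
        repressed, induced = call_candidates(hap, tet)
        assert repressed == [] and induced == []

    def test_invalid_alpha_rejected(self, toy_pair):
        with pytest.raises(ValueError):
            call_candidates(*toy_pair, alpha=1.1)

    def test_ranking_orders_and_tie_break(self):
        hap = CountTable("h", "1n",
                         {"a": 400.0, "b": 400.0, "c": 100.0}, 10**6)
        tet = CountTable("t", "4n",
                         {"a": 100.0, "b": 100.0, "c": 700.0}, 10**6)
        repressed, induced = call_candidates(hap, tet)
        assert [r.gene_id for r in repressed] == ["a", "b"]  # tie -> lexicon
        assert [r.gene_id for r in induced] == ["c"]
        combined = combined_ranking(repressed, induced)
        assert combined[0].gene_id == "c"  # |log2 7| > |log2 0.25|

    def test_null_pass_rate_small_and_overlap_cleans_up(self):
        """The per-pair plug-in test is anti-conservative under the null
        (it treats the reference frequency as known, so its effective
        z-threshold is inflated by ~sqrt(2)); the false calls stay at the
        few-percent level and are removed by the replicate-overlap stage,
        which is exactly the role the overlap plays in the design."""
        from ploidyseq.de import run_de_pipeline

        config = SimulationConfig(seed=11, n_genes=4000, n_de=0,
                                  depth_per_sample=400_000, freq_log_sd=1.0)
        freqs = simulate_frequency_profile(config)
        pairs = [
            simulate_count_pair(freqs, {}, (400_000, 400_000), seed=s)
            for s in (11, 12)
        ]
        for hap, tet in pairs:
            repressed, induced = call_candidates(hap, tet)
            assert 0 < (len(repressed) + len(induced)) / 4000 <= 0.05
        result = run_de_pipeline(pairs)
        assert result["final_repressed"] == []
        assert result["final_induced"] == []


class TestOverlap:
    def test_full_overlap_small_population_enumeration(self):
        got = overlap_significance(5, 5, 5, 10)
        assert got == pytest.approx(1 / 252, rel=1e-12)
        assert float(enumerate_overlap_tail(5, 5, 5, 10)) == \
            pytest.approx(got, rel=1e-12)

    def test_trivial_tails(self):
        assert overlap_significance(0, 3, 3, 10) == 1.0
        assert overlap_significance(1, 1, 1, 100) == pytest.approx(0.01)

    @given(st.integers(2, 9), st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_exhaustive_enumeration(self, population, data):
        n_a = data.draw(st.integers(1, population))
        n_b = data.draw(st.integers(1, population))
        m = data.draw(st.integers(0, min(n_a, n_b)))
        exact = float(enumerate_overlap_tail(m, n_a, n_b, population))
        assert overlap_significance(m, n_a, n_b, population) == \
            pytest.approx(exact, rel=1e-9)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance(6, 5, 5, 10)

    def test_top_candidate_intersection(self):
        ids = [f"g{i:02d}" for i in range(20)]
        same = overlap_top_candidates(ids, ids, 10, 5000)
        assert len(same.overlap) == 10
        disjoint = overlap_top_candidates(ids[:10], ids[10:], 10, 5000)
        assert disjoint.overlap == [] and disjoint.p_overlap == 1.0
        mixed = overlap_top_candidates(ids[:10], ids[:5] + ids[15:20],
                                       10, 5000)
        assert len(mixed.overlap) >= 5

    def test_top_n_domain(self):
        with pytest.raises(ValueError):
            overlap_top_candidates(["a"], ["a"], 0, 10)


class TestSelectTopN:
    def test_identical_lists_select_largest_grid_value(self):
        ids = [f"g{i:02d}" for i in range(20)]
        sel = select_top_n(ids, ids, population=5000,
                           grid=(5, 10, 15, 20, 25))
        assert sel.top_n == 20
        assert len(sel.curve) == 4  # 25 infeasible
        enum = exact_hypergeom_tail(5, 5, 5, 5000)
        assert sel.curve[0][2] == pytest.approx(float(enum), rel=1e-9)

    def test_independent_lists_raise(self):
        rng = np.random.default_rng(3)
        pop = [f"g{i}" for i in range(5000)]
        a = list(rng.choice(pop, 50, replace=False))
        b = list(rng.choice(pop, 50, replace=False))
        with pytest.raises(ReplicatesInconsistentError):
            select_top_n(a, b, population=5000, grid=(10, 20, 50))

    def test_single_grid_point_closed_form(self):
        ids = [f"g{i}" for i in range(5)]
        sel = select_top_n(ids, ids, population=1000, grid=(5,))
        exact = float(exact_hypergeom_tail(5, 5, 5, 1000))
        assert sel.p_overlap == pytest.approx(exact, rel=1e-9)
        assert exact < 1e-10


class TestSummarizeDe:
    def _pairs(self, folds):
        pairs = []
        for i, fold in enumerate(folds):
            hap = CountTable(f"h{i}", "1n", {"g": 100.0}, 10**6)
            tet = CountTable(f"t{i}", "4n", {"g": 100.0 * fold}, 10**6)
            pairs.append((hap, tet))
        return pairs

    def test_mean_and_sample_sd(self):
        rows = summarize_de(["g"], self._pairs([0.2, 0.3]))
        assert rows[0]["mean_fold"] == pytest.approx(0.25)
        assert rows[0]["sd_fold"] == pytest.approx(0.070710678, rel=1e-6)

    def test_equal_folds_have_zero_sd(self):
        rows = summarize_de(["g"], self._pairs([0.5, 0.5]))
        assert rows[0]["sd_fold"] == 0.0

    def test_single_pair_flagged(self):
        rows = summarize_de(["g"], self._pairs([0.5]))
        assert rows[0]["sd_fold"] == 0.0 and not rows[0]["sd_defined"]

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError):
            summarize_de(["absent"], self._pairs([0.5]))
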