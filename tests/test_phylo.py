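import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastevo.io_formats import parse_newick
from plastevo.phylo import (PhyloError, compile_tree, concatenate,
                            fit_gene_rate, fitch_steps, fitch_steps_matrix,
                            jc69_loglik, leaf_state_masks,
                            normalize_relative_rates, optimize_branch_lengths)
from plastevo.synthetic import SimConfig, simulate_dataset


def brute_force_parsimony(ctree, states: dict[str, str]) -> int:
    """Minimum changes over all internal (and missing-leaf) labelings."""
    internal = [i for i in range(ctree.n_nodes) if ctree.children[i]]
    free_leaves = [i for i in range(ctree.n_leaves)
                   if states.get(ctree.taxa[i], "-") in "-N"]
    free = internal + free_leaves
    fixed = {i: states[ctree.taxa[i]] for i in range(ctree.n_leaves)
             if i not in free_leaves}
    best = math.inf
    for combo in itertools.product("ACGT", repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        changes = sum(1 for i in range(ctree.n_nodes)
                      if ctree.parent[i] >= 0
                      and assign[i] != assign[ctree.parent[i]])
        best = min(best, changes)
    return best


QUARTET = compile_tree(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))


class TestFitch:
    def test_known_quartet_column(self):
        assert fitch_steps(QUARTET, {"A": "A", "B": "C", "C": "A", "D": "A"}) == 1

    def test_identical_leaves_zero(self):
        assert fitch_steps(QUARTET, {t: "G" for t in "ABCD"}) == 0

    def test_all_missing_zero(self):
        assert fitch_steps(QUARTET, {t: "-" for t in "ABCD"}) == 0

    def test_leaf_absent_from_tree_raises(self):
        with pytest.raises(PhyloError):
            fitch_steps(QUARTET, {"A": "A", "Z": "C"})

    @given(st.lists(st.sampled_from("ACGT-N"), min_size=6, max_size=6))
    def test_matches_brute_force_on_six_leaves(self, column):
        ctree = compile_tree(parse_newick("(((a,b),(c,d)),(e,f));"))
        states = dict(zip(ctree.taxa, column))
        assert fitch_steps(ctree, states) == brute_force_parsimony(ctree, states)

    def test_matrix_variant_agrees_with_scalar(self, rng):
        ctree = compile_tree(parse_newick("(((a,b),(c,d)),(e,f));"))
        cols = ["".join(rng.choice(list("ACGT-"), size=6)) for _ in range(50)]
        rows = {t: "".join(c[i] for c in cols)
                for i, t in enumerate(ctree.taxa)}
        steps = fitch_steps_matrix(ctree, leaf_state_masks(rows, ctree))
        for k, col in enumerate(cols):
            assert steps[k] == fitch_steps(ctree, dict(zip(ctree.taxa, col)))


class TestJc69:
    def test_two_taxon_same_state_closed_form(self):
        t = 0.37
        ctree = compile_tree(parse_newick(f"(A:{t/2},B:{t/2});"))
        ll = jc69_loglik(ctree, {"A": "A", "B": "A"})
        expected = math.log(0.25) + math.log(0.25 + 0.75 * math.exp(-4 * t / 3))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_different_state_closed_form(self):
        t = 0.8
        ctree = compile_tree(parse_newick(f"(A:{t/2},B:{t/2});"))
        ll = jc69_loglik(ctree, {"A": "A", "B": "G"})
        expected = math.log(0.25) + math.log(0.25 - 0.25 * math.exp(-4 * t / 3))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_zero_distance_identical_site(self):
        ctree = compile_tree(parse_newick("(A:0.0,B:0.0);"))
        assert jc69_loglik(ctree, {"A": "C", "B": "C"}) == \
            pytest.approx(math.log(0.25), abs=1e-12)

    def test_rerooting_invariance_pulley_principle(self):
        rows = {"A": "ACGTAC", "B": "ACGTTC", "C": "AGGTAC", "D": "ACGAAC"}
        t1 = compile_tree(parse_newick(
            "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.25);"))
        t2 = compile_tree(parse_newick(
            "((A:0.1,B:0.2):0.3,(C:0.3,D:0.15):0.0);"))
        t3 = compile_tree(parse_newick(
            "(A:0.0,(B:0.2,((C:0.3,D:0.15):0.3):0.0):0.1);"))
        lls = [jc69_loglik(t, rows) for t in (t1, t2, t3)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-10)
        assert lls[0] == pytest.approx(lls[2], abs=1e-10)

    def test_gaps_are_missing_data(self):
        ctree = compile_tree(parse_newick("(A:0.1,B:0.1);"))
        # site with one gap carries no pairwise information: logL = ln(1/4)
        assert jc69_loglik(ctree, {"A": "A", "B": "-"}) == \
            pytest.approx(math.log(0.25), abs=1e-12)

    def test_negative_branch_length_raises(self):
        ctree = compile_tree(parse_newick("(A:0.1,B:0.1);"))
        with pytest.raises(PhyloError):
            jc69_loglik(ctree, {"A": "A", "B": "A"},
                        lengths=np.array([-0.1, 0.1, 0.0]))

    def test_noise_on_true_lengths_lowers_likelihood(self):
        cfg = SimConfig(seed=3, n_taxa=8, n_genes=1,
                        gene_length_codons=(200, 200))
        ds = simulate_dataset(cfg)
        rows = {r.id: r.residues for r in ds.genes[list(ds.genes)[0]]}
        fitted = optimize_branch_lengths(ds.tree, rows, tol=1e-3)
        base = jc69_loglik(fitted, rows)
        rng = np.random.default_rng(0)
        for _ in range(3):
            noisy = fitted.lengths * rng.uniform(0.3, 3.0, fitted.lengths.shape)
            assert jc69_loglik(fitted, rows, lengths=noisy) < base


class TestGeneRate:
    def test_multiplier_recovery_and_ratio(self):
        cfg = SimConfig(seed=9, n_taxa=12, n_genes=2,
                        gene_length_codons=(250, 250),
                        per_gene_rate_multipliers=[0.5, 2.0])
        ds = simulate_dataset(cfg)
        genes = list(ds.genes)
        res = []
        for g in genes:
            rows = {r.id: r.residues for r in ds.genes[g]}
            res.append(fit_gene_rate(ds.tree, g, rows))
        ratio = res[1].rate_scaler / res[0].rate_scaler
        assert 2.0 < ratio < 8.0    # true ratio 4, sampling noise allowed

    def test_invariant_gene_flagged_no_signal(self):
        ctree = compile_tree(parse_newick("((a:.1,b:.1):.1,(c:.1,d:.1):.1);"))
        rows = {t: "ATGAAATTT" for t in "abcd"}
        res = fit_gene_rate(ctree, "g", rows)
        assert res.flag == "no_signal"

    def test_all_gap_gene_rate_is_null(self):
        ctree = compile_tree(parse_newick("((a:.1,b:.1):.1,(c:.1,d:.1):.1);"))
        rows = {t: "---" for t in "abcd"}
        res = fit_gene_rate(ctree, "g", rows)
        assert res.rate_scaler is None
        assert res.flag == "all_gap"

    def test_relative_rates_mean_one(self):
        from plastevo.phylo import GeneRateResult
        res = [GeneRateResult("a", 0.5), GeneRateResult("b", 2.0),
               GeneRateResult("c", None, flag="all_gap")]
        normalize_relative_rates(res)
        vals = [r.relative_rate for r in res if r.relative_rate is not None]
        assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)


class TestConcatenate:
    def test_widths_and_partitions(self):
        g1 = {t: "A" * 300 for t in "ab"}
        g2 = {t: "C" * 150 for t in "ab"}
        sm = concatenate({"g1": g1, "g2": g2}, ["g1", "g2"])
        assert sm.n_cols == 450
        assert sm.partitions == {"g1": (0, 300), "g2": (300, 450)}

    def test_empty_gene_list_raises(self):
        with pytest.raises(PhyloError):
            concatenate({}, [])

    def test_round_trip_recovers_gene_rows(self, small_dataset):
        from plastevo.codon_align import align_codon

        alns = {g: align_codon(recs, gene=g)
                for g, recs in small_dataset.pristine.items()}
        order = sorted(alns)
        sm = concatenate(alns, order)
        for g in order:
            expect = {r.id: r.residues for r in alns[g].records}
            assert sm.gene_rows(g) == expect

    def test_missing_taxon_padded_or_raises(self):
        g1 = {"a": "AAA", "b": "AAA"}
        g2 = {"a": "CCC"}
        sm = concatenate({"g1": g1, "g2": g2}, ["g1", "g2"])
        assert sm.rows["b"] == "AAA---"
        with pytest.raises(PhyloError):
            concatenate({"g1": g1, "g2": g2}, ["g1", "g2"], pad_missing=False)
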