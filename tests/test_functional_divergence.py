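"""Parsimony site counts, the Type-I mixture fit, and the Type-II classifier."""

import itertools

import numpy as np
import pytest

from cladevol.functional_divergence import (AMINO_ACIDS, ClusterPair,
                                            SiteCountTable, _log_shared,
                                            _type1_loglik, count_table,
                                            empirical_pp_cutoff, fit_type1,
                                            fit_type2,
                                            site_substitution_counts)
from cladevol.seq_prep import ProteinAlignment
from cladevol.synthetic_data import simulate_type1, simulate_type2
from cladevol.trees import LabeledTree


def brute_force_parsimony(arrays, states):
    """Oracle: enumerate interior labelings over the observed state set."""
    observed = sorted({int(s) for s in states if s >= 0}) or [0]
    interior = [n for n in arrays.postorder if arrays.children[n]]
    best = None
    for assign in itertools.product(observed, repeat=len(interior)):
        state_of = dict(zip(interior, assign))
        for n in arrays.postorder:
            if not arrays.children[n]:
                state_of[n] = int(states[arrays.leaf_index[n]])
        changes = 0
        for n in arrays.postorder:
            p = arrays.parent[n]
            if p >= 0 and state_of[n] >= 0 and state_of[n] != state_of[p]:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best


@pytest.fixture
def six_taxon_tree():
    return LabeledTree.from_newick(
        "(((s1:1,s2:1):1,(s3:1,s4:1):1):1,(s5:1,s6:1):2);"
    )


class TestSiteCounts:
    def test_invariant_column_has_zero_changes(self, six_taxon_tree):
        aln = ProteinAlignment(
            [f"s{i}" for i in range(1, 7)], ["A"] * 6
        )
        counts = site_substitution_counts(
            aln, six_taxon_tree, {f"s{i}" for i in range(1, 7)}
        )
        assert counts.tolist() == [0]

    def test_balanced_split_single_internal_change(self):
        tree = LabeledTree.from_newick("((s1:1,s2:1):1,(s3:1,s4:1):1);")
        aln = ProteinAlignment(["s1", "s2", "s3", "s4"],
                               ["A", "A", "C", "C"])
        counts = site_substitution_counts(
            aln, tree, {"s1", "s2", "s3", "s4"}
        )
        assert counts.tolist() == [1]

    def test_matches_bruteforce_on_random_columns(self, six_taxon_tree):
        rng = np.random.default_rng(11)
        taxa = [f"s{i}" for i in range(1, 7)]
        rows = ["".join(rng.choice(list("ACDE"), size=15)) for _ in taxa]
        aln = ProteinAlignment(taxa, rows)
        cluster = set(taxa)
        counts = site_substitution_counts(aln, six_taxon_tree, cluster)
        sub = six_taxon_tree.subtree(cluster)
        arrays = sub.to_arrays(taxa_order=sub.taxa)
        from cladevol.functional_divergence import _aa_states

        states = _aa_states(
            ProteinAlignment(sub.taxa, [aln.row(t) for t in sub.taxa])
        )
        for c in range(aln.n_columns):
            assert counts[c] == brute_force_parsimony(arrays, states[:, c])

    def test_small_cluster_rejected(self, six_taxon_tree):
        aln = ProteinAlignment(["s1", "s2"], ["A", "A"])
        with pytest.raises(ValueError, match=">= 3"):
            site_substitution_counts(aln, six_taxon_tree, {"s1", "s2"})

    def test_count_table_drops_gap_columns(self):
        tree = LabeledTree.from_newick(
            "((s1:1,(s2:1,s3:1):1):1,(s4:1,(s5:1,s6:1):1):1);"
        )
        taxa = [f"s{i}" for i in range(1, 7)]
        rows = ["AC-", "ACA", "ACA", "ACA", "ACA", "ACA"]
        aln = ProteinAlignment(taxa, rows)
        pair = ClusterPair("left", {"s1", "s2", "s3"},
                           "right", {"s4", "s5", "s6"})
        table = count_table(aln, tree, pair)
        assert table.site_index.tolist() == [0, 1]


class TestType1Fit:
    def test_null_likelihood_matches_closed_form(self):
        # lnL at theta=0 equals the shared-rate bivariate NB directly
        tab, _ = simulate_type1(100, theta=0.3, seed=0)
        x1 = tab.counts1.astype(float)
        x2 = tab.counts2.astype(float)
        params = [np.log(0.7), np.log(1.3), np.log(2.1)]
        lnl, _, _ = _type1_loglik(params, x1, x2, free_theta=False)
        direct = float(np.sum(_log_shared(x1, x2, 0.7, 1.3, 2.1)))
        assert lnl == pytest.approx(direct, abs=1e-8)

    def test_duplicated_cluster_gives_theta_near_zero(self):
        rng = np.random.default_rng(2)
        lam = rng.gamma(0.5, 2.0, size=400)
        c = rng.poisson(2.0 * lam)
        tab = SiteCountTable(c, c, np.arange(400))
        est = fit_type1(tab)
        assert est.theta <= 0.05

    def test_posterior_mean_tracks_theta(self):
        tab, _ = simulate_type1(500, theta=0.6, seed=3)
        est = fit_type1(tab)
        assert np.mean(est.pp) == pytest.approx(est.theta, abs=0.05)

    def test_degenerate_all_zero_cluster_rejected(self):
        tab = SiteCountTable(np.zeros(50, dtype=int),
                             np.ones(50, dtype=int), np.arange(50))
        with pytest.raises(ValueError, match="degenerate"):
            fit_type1(tab)

    def test_few_sites_warns(self):
        tab, _ = simulate_type1(20, theta=0.2, seed=4)
        with pytest.warns(UserWarning, match="unstable"):
            fit_type1(tab)


class TestEmpiricalCutoff:
    def test_nonsignificant_fit_removes_nothing(self):
        tab, _ = simulate_type1(200, theta=0.0, seed=5)
        cutoff, removed = empirical_pp_cutoff(tab)
        if removed:  # a rare false positive still terminates quickly
            assert len(removed) < 20
        else:
            assert np.isnan(cutoff)

    def test_terminates_within_site_budget(self):
        tab, _ = simulate_type1(120, theta=0.8, alpha=0.5, d1=3, d2=3, seed=6)
        cutoff, removed = empirical_pp_cutoff(tab, max_removals=25)
        assert len(removed) <= 25
        assert all(0 <= c < 120 for c in removed)


class TestType2Fit:
    def test_zero_radical_sites_gives_zero_theta(self):
        aln, tree, pair, _ = simulate_type2(
            300, theta2=0.0, background_fractions=(0.7, 0.0, 0.3), seed=7
        )
        res = fit_type2(aln, tree, pair)
        assert res.theta2 == pytest.approx(0.0, abs=1e-9)
        assert res.category_counts["CR"] == 0

    def test_all_radical_sites_gives_theta_one(self):
        aln, tree, pair, _ = simulate_type2(200, theta2=1.0, seed=8)
        res = fit_type2(aln, tree, pair)
        assert res.theta2 >= 0.9

    def test_radical_sites_are_reported(self):
        aln, tree, pair, truth = simulate_type2(300, theta2=0.3, seed=9)
        res = fit_type2(aln, tree, pair)
        planted = set(np.flatnonzero(truth == "T2"))
        assert planted <= set(res.radical_sites)

    def test_no_fixed_sites_is_error(self):
        taxa1 = [f"one{i}" for i in range(1, 5)]
        taxa2 = [f"two{i}" for i in range(1, 5)]
        rng = np.random.default_rng(10)
        rows = ["".join(rng.choice(list(AMINO_ACIDS), size=30))
                for _ in range(8)]
        from cladevol.synthetic_data import balanced_clade_tree

        tree = LabeledTree.from_newick(
            f"({balanced_clade_tree(taxa1, 0.3)}:0.2,"
            f"{balanced_clade_tree(taxa2, 0.3)}:0.2);"
        )
        aln = ProteinAlignment(taxa1 + taxa2, rows)
        pair = ClusterPair("one", set(taxa1), "two", set(taxa2))
        with pytest.raises(ValueError, match="no fixed sites"):
            fit_type2(aln, tree, pair)

    def test_clusters_must_be_disjoint_and_monophyletic(self):
        with pytest.raises(ValueError, match="disjoint"):
            ClusterPair("a", {"x", "y", "z"}, "b", {"z", "u", "v"})
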