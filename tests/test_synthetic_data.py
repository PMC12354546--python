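"""Determinism and distributional sanity of the simulators."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cladevol.clock_rates import GTRSpec
from cladevol.codon_selection import CODON_INDEX, CodonModelSpec
from cladevol.convergence_pcoc import ConvergenceScenario, default_profiles
from cladevol.synthetic_data import (OMEGA_PRESET_FOUR_CLASS,
                                     OMEGA_PRESET_THREE_CLASS, THETA_PRESETS,
                                     make_study_fixture,
                                     simulate_clock_alignment,
                                     simulate_codon_alignment,
                                     simulate_convergent_alignment,
                                     simulate_type1,
                                     simulate_type1_alignment,
                                     simulate_type2)
from cladevol.trees import LabeledTree


@pytest.fixture(scope="module")
def fixture():
    return make_study_fixture(seed=0, n_chameleon=2, n_agamid=2,
                              n_pleurodont=4, n_mammal=4)


class TestStudyFixture:
    def test_clades_are_monophyletic(self, fixture):
        for name in ("chameleon", "agamid", "acrodont", "pleurodont",
                     "mammal", "iguania"):
            assert fixture.tree3.is_monophyletic(set(fixture.clades[name]))

    def test_ladder_class_counts(self, fixture):
        assert fixture.tree2.n_classes == 2
        assert fixture.tree3.n_classes == 3
        assert fixture.tree4.n_classes == 4
        assert fixture.chronogram.n_classes == 3
        assert fixture.chronogram4.n_classes == 4

    def test_ladder_labelings_strictly_nested(self, fixture):
        # every finer class maps edges into exactly one coarser class
        for coarse, fine in ((fixture.tree2, fixture.tree3),
                             (fixture.tree3, fixture.tree4)):
            sig_c = {}
            for node in coarse.tree.preorder_node_iter():
                if node.parent_node:
                    leaves = frozenset(
                        lf.taxon.label for lf in node.leaf_iter())
                    sig_c[leaves] = node.edge.class_id
            mapping = {}
            for node in fine.tree.preorder_node_iter():
                if not node.parent_node:
                    continue
                leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
                mapping.setdefault(node.edge.class_id, set()).add(
                    sig_c[leaves])
            for fine_class, coarse_classes in mapping.items():
                assert len(coarse_classes) == 1

    def test_depth_is_one_substitution_at_neutral_rate(self):
        fx = make_study_fixture(seed=0)
        arrays = fx.tree3.to_arrays()
        # root-to-tip path length for a mammal tip
        depths = {}
        for node in arrays.postorder[::-1]:
            p = arrays.parent[node]
            depths[node] = arrays.lengths[node] + (
                depths[p] if p >= 0 else 0.0
            )
        tip_depths = [depths[n] for n in range(arrays.n_nodes)
                      if arrays.leaf_index[n] >= 0]
        assert np.allclose(tip_depths, 1.0, atol=1e-6)

    def test_presets_document_study_estimates(self):
        assert OMEGA_PRESET_THREE_CLASS == (0.33, 0.46, 0.40)
        assert OMEGA_PRESET_FOUR_CLASS == (0.26, 0.42, 0.60, 0.29)
        assert THETA_PRESETS == (0.74, 0.80)


class TestCodonSimulator:
    def test_seed_reproducibility(self, fixture, uniform_codon_spec):
        a = simulate_codon_alignment(fixture.tree3, uniform_codon_spec,
                                     30, seed=9)
        b = simulate_codon_alignment(fixture.tree3, uniform_codon_spec,
                                     30, seed=9)
        assert a.rows == b.rows
        c = simulate_codon_alignment(fixture.tree3, uniform_codon_spec,
                                     30, seed=10)
        assert a.rows != c.rows

    def test_omega_zero_forbids_amino_acid_change(self, fixture):
        spec = CodonModelSpec(2.0, [0.0], np.full(61, 1 / 61))
        aln = simulate_codon_alignment(fixture.tree3, spec, 40, seed=1)
        proteins = {p for p in aln.to_protein().rows}
        assert len(proteins) == 1

    def test_long_branch_stationarity(self):
        tree = LabeledTree.from_newick("(x:0.0,y:25.0);")
        pi = np.full(61, 1 / 61)
        spec = CodonModelSpec(2.0, [0.5], pi)
        aln = simulate_codon_alignment(tree, spec, 50000, seed=2)
        row = aln.row("y")
        counts = np.zeros(61)
        for i in range(0, len(row), 3):
            counts[CODON_INDEX[row[i:i + 3]]] += 1
        freqs = counts / counts.sum()
        tv = 0.5 * np.abs(freqs - pi).sum()
        assert tv < 0.05


class TestType1Simulator:
    def test_shared_rates_correlate_counts(self):
        tab, _ = simulate_type1(500, theta=0.0, alpha=0.5, seed=3)
        rho = spearmanr(tab.counts1, tab.counts2).statistic
        assert rho > 0.5

    def test_independent_rates_decorrelate_counts(self):
        tab, _ = simulate_type1(1000, theta=1.0, alpha=0.5, seed=4)
        rho = spearmanr(tab.counts1, tab.counts2).statistic
        assert abs(rho) < 0.15

    def test_seed_reproducibility(self):
        a, ta = simulate_type1(100, theta=0.4, seed=5)
        b, tb = simulate_type1(100, theta=0.4, seed=5)
        assert np.array_equal(a.counts1, b.counts1)
        assert np.array_equal(ta, tb)

    def test_planted_sites_marked(self):
        tab, truth = simulate_type1(200, theta=0.0, seed=6, n_planted=15)
        assert (truth == "P").sum() == 15


class TestTypeIAlignmentSimulator:
    def test_reproducible_and_taxa_complete(self, fixture):
        a1, t1 = simulate_type1_alignment(
            fixture.tree3, set(fixture.clades["acrodont"]), 50, seed=7
        )
        a2, t2 = simulate_type1_alignment(
            fixture.tree3, set(fixture.clades["acrodont"]), 50, seed=7
        )
        assert a1.rows == a2.rows
        assert np.array_equal(t1, t2)
        assert sorted(a1.taxa) == sorted(fixture.tree3.taxa)


class TestType2Simulator:
    def test_theta_zero_has_no_excess_radical_sites(self):
        aln, tree, pair, truth = simulate_type2(400, theta2=0.0, seed=8)
        assert (truth == "T2").sum() == 0

    def test_seed_reproducibility(self):
        a1, _, _, t1 = simulate_type2(100, theta2=0.3, seed=9)
        a2, _, _, t2 = simulate_type2(100, theta2=0.3, seed=9)
        assert a1.rows == a2.rows
        assert np.array_equal(t1, t2)


class TestConvergentSimulator:
    def test_zero_fraction_is_all_background(self, fixture):
        scenario = ConvergenceScenario(
            fixture.tree3,
            {"acrodont": set(fixture.clades["acrodont"]),
             "mammal": set(fixture.clades["mammal"])},
        )
        _, truth = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.0, 50, seed=10
        )
        assert truth.sum() == 0

    def test_seed_reproducibility(self, fixture):
        scenario = ConvergenceScenario(
            fixture.tree3,
            {"acrodont": set(fixture.clades["acrodont"]),
             "mammal": set(fixture.clades["mammal"])},
        )
        a1, t1 = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.2, 40, seed=11
        )
        a2, t2 = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.2, 40, seed=11
        )
        assert a1.rows == a2.rows
        assert np.array_equal(t1, t2)


class TestClockSimulator:
    def test_zero_rates_give_identical_sequences(self, fixture):
        gtr = GTRSpec(np.ones(6), np.full(4, 0.25))
        aln = simulate_clock_alignment(
            fixture.chronogram, np.array([0.0]), gtr, 30, seed=12
        )
        assert len(set(aln.rows)) == 1

    def test_seed_reproducibility(self, fixture):
        gtr = GTRSpec(np.ones(6), np.full(4, 0.25))
        a = simulate_clock_alignment(
            fixture.chronogram, np.array([0.002]), gtr, 50, seed=13
        )
        b = simulate_clock_alignment(
            fixture.chronogram, np.array([0.002]), gtr, 50, seed=13
        )
        assert a.rows == b.rows
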