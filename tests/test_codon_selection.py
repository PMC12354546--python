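"""GY94 rate matrix, pruning likelihood, branch-model fits and LRTs."""

import numpy as np
import pytest
from scipy.stats import chi2

from cladevol._pruning import PruningModel, compress_patterns
from cladevol.codon_selection import (CODON_INDEX, SENSE_CODONS,
                                      CodonModelSpec, LRTResult, ModelFit,
                                      codon_log_likelihood, codon_states,
                                      f3x4_frequencies, fit_branch_model,
                                      gy94_rate_matrix,
                                      likelihood_ratio_test,
                                      transition_matrix, _eigens_for)
from cladevol.seq_prep import CodonAlignment
from cladevol.trees import LabeledTree


class TestGY94Matrix:
    def test_rows_sum_to_zero(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_unit_expected_rate(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        pi = uniform_codon_spec.codon_frequencies
        assert -(pi @ np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance_neutral_uniform(self):
        pi = np.full(61, 1 / 61)
        spec = CodonModelSpec(1.0, [1.0], pi)
        Q = gy94_rate_matrix(spec)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-15

    def test_entry_ratio_transition_vs_transversion(self):
        # TTT->TTC: synonymous transition (Phe->Phe, T<->C)
        # TTT->TTA: nonsynonymous transversion (Phe->Leu, T<->A)
        pi = np.full(61, 1 / 61)
        kappa, omega = 3.0, 0.2
        spec = CodonModelSpec(kappa, [omega], pi)
        Q = gy94_rate_matrix(spec)
        i = CODON_INDEX["TTT"]
        ratio = Q[i, CODON_INDEX["TTC"]] / Q[i, CODON_INDEX["TTA"]]
        expected = kappa * pi[CODON_INDEX["TTC"]] / (
            omega * pi[CODON_INDEX["TTA"]]
        )
        assert ratio == pytest.approx(expected)

    def test_multi_step_entries_zero(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["CCT"]] == 0.0
        assert Q[CODON_INDEX["AAA"], CODON_INDEX["GGG"]] == 0.0


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61))

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.7, 5.0])
    def test_rows_sum_to_one(self, uniform_codon_spec, t):
        Q = gy94_rate_matrix(uniform_codon_spec)
        P = transition_matrix(Q, t)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_chapman_kolmogorov(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        rng = np.random.default_rng(3)
        for _ in range(3):
            s, t = rng.uniform(0.05, 2.0, size=2)
            direct = transition_matrix(Q, s + t)
            composed = transition_matrix(Q, s) @ transition_matrix(Q, t)
            assert np.abs(direct - composed).max() < 1e-8

    def test_eigendecomposition_matches_expm(self, uniform_codon_spec):
        Q = gy94_rate_matrix(uniform_codon_spec)
        pi = uniform_codon_spec.codon_frequencies
        eig = _eigens_for(2.0, np.array([0.4]), pi)[0]
        assert np.abs(eig.transition(0.7) - transition_matrix(Q, 0.7)).max() \
            < 1e-10


class TestPruningLikelihood:
    def test_identical_taxa_zero_lengths_gives_log_pi(self):
        tree = LabeledTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = CodonAlignment(["A", "B", "C", "D"], ["ATGAAA"] * 4)
        pi = np.full(61, 1 / 61)
        spec = CodonModelSpec(2.0, [0.4], pi)
        lnl = codon_log_likelihood(aln, tree, spec)
        expected = sum(
            np.log(pi[CODON_INDEX[c]]) for c in ("ATG", "AAA")
        )
        assert lnl == pytest.approx(expected, abs=1e-8)

    def test_matches_bruteforce_enumeration(
        self, quartet_tree, quartet_codon_alignment, uniform_codon_spec
    ):
        arrays = quartet_tree.to_arrays(
            taxa_order=quartet_codon_alignment.taxa
        )
        patterns, weights = compress_patterns(
            codon_states(quartet_codon_alignment)
        )
        model = PruningModel(arrays, patterns, weights, 61)
        pi = uniform_codon_spec.codon_frequencies
        eig = _eigens_for(2.0, np.array([0.4]), pi)[0]
        P = {int(e): eig.transition(arrays.lengths[e])
             for e in arrays.edges}
        assert model.loglik(P, pi) == pytest.approx(
            model.loglik_bruteforce(P, pi), abs=1e-8
        )

    def test_rerooting_invariance(self, uniform_codon_spec):
        # pulley principle: reversible one-class model is root-invariant
        aln = CodonAlignment(
            ["A", "B", "C", "D"],
            ["ATGAAACCC", "ATGAAGCCA", "ATGAACCAG", "ATGAATCCC"],
        )
        spec = uniform_codon_spec
        t1 = LabeledTree.from_newick(
            "((A:0.10,B:0.20):0.05,(C:0.15,D:0.10):0.07);"
        )
        # rerooted along the internal edge: same unrooted topology/lengths
        t3 = LabeledTree.from_newick(
            "((A:0.10,B:0.20):0.12,(C:0.15,D:0.10):0.0);"
        )
        l1 = codon_log_likelihood(aln, t1, spec)
        l3 = codon_log_likelihood(aln, t3, spec)
        assert l1 == pytest.approx(l3, abs=1e-8)

    def test_taxon_mismatch_is_error(self, quartet_tree, uniform_codon_spec):
        aln = CodonAlignment(["A", "B", "C", "X"], ["ATG"] * 4)
        with pytest.raises(ValueError, match="taxa"):
            codon_log_likelihood(aln, quartet_tree, uniform_codon_spec)

    def test_stop_codon_rejected(self, quartet_tree, uniform_codon_spec):
        aln = CodonAlignment(["A", "B", "C", "D"],
                             ["TAA", "ATG", "ATG", "ATG"])
        with pytest.raises(ValueError, match="stop"):
            codon_log_likelihood(aln, quartet_tree, uniform_codon_spec)


class TestBranchModelFit:
    def test_gaps_treated_as_missing(
        self, quartet_tree, quartet_codon_alignment, uniform_codon_spec
    ):
        # dropping an all-present column changes lnl; a gap column only
        # contributes the marginal over its missing entry
        lnl = codon_log_likelihood(
            quartet_codon_alignment, quartet_tree, uniform_codon_spec
        )
        assert np.isfinite(lnl)

    def test_two_ratio_never_below_one_ratio(self, quartet_tree):
        rng = np.random.default_rng(5)
        codons = [c for c in SENSE_CODONS if "N" not in c]
        rows = [
            "".join(rng.choice(codons, size=20)) for _ in range(4)
        ]
        aln = CodonAlignment(["A", "B", "C", "D"], rows)
        tree = LabeledTree.from_newick(
            "((A#1:0.10,B#1:0.20)#1:0.05,(C:0.15,D:0.10):0.07);"
        )
        fit1 = fit_branch_model(aln, tree.unrooted(), 1, n_starts=1)
        fit2 = fit_branch_model(aln, tree, 2, warm_start=fit1, n_starts=1)
        assert fit2.lnl >= fit1.lnl - 1e-6

    def test_wrong_class_count_is_error(self, quartet_tree,
                                        quartet_codon_alignment):
        with pytest.raises(ValueError, match="classes"):
            fit_branch_model(quartet_codon_alignment, quartet_tree, 3)

    def test_free_ratio_assigns_class_per_branch(
        self, quartet_tree, quartet_codon_alignment
    ):
        fit = fit_branch_model(
            quartet_codon_alignment, quartet_tree, "free",
            n_starts=1, maxiter=30,
        )
        arrays = quartet_tree.to_arrays()
        assert fit.n_classes == len(arrays.edges)


class TestLikelihoodRatioTest:
    def _fit(self, name, lnl, k):
        return ModelFit(
            model_name=name, lnl=lnl, kappa=2.0,
            omega_by_class=np.full(k, 0.4), branch_lengths={},
            n_free_params=10 + k, converged=True, n_iter=5, n_classes=k,
        )

    def test_equal_likelihoods_give_p_one(self):
        res = likelihood_ratio_test(
            self._fit("one-ratio", -100.0, 1), self._fit("two-ratio", -100.0, 2)
        )
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_tail_matches_384(self):
        res = likelihood_ratio_test(
            self._fit("one-ratio", -100.0, 1),
            self._fit("two-ratio", -100.0 + 3.84 / 2, 2),
        )
        assert res.df == 1
        assert res.p_value == pytest.approx(0.05, abs=2e-3)

    def test_p_monotone_in_df(self):
        p1 = likelihood_ratio_test(
            self._fit("one-ratio", -100.0, 1),
            self._fit("two-ratio", -98.0, 2),
        ).p_value
        p2 = likelihood_ratio_test(
            self._fit("one-ratio", -100.0, 1),
            self._fit("three-ratio", -98.0, 3),
        ).p_value
        assert p2 > p1

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = likelihood_ratio_test(
                self._fit("one-ratio", -99.0, 1),
                self._fit("two-ratio", -99.5, 2),
            )
        assert res.statistic == 0.0

    def test_non_nested_order_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(
                self._fit("three-ratio", -99.0, 3),
                self._fit("two-ratio", -98.0, 2),
            )

    def test_boundary_mixture_halves_tail(self):
        null = self._fit("one-ratio", -100.0, 1)
        alt = self._fit("two-ratio", -98.0, 2)
        plain = likelihood_ratio_test(null, alt)
        mixed = likelihood_ratio_test(null, alt, boundary_mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class TestFrequencies:
    def test_f3x4_sums_to_one(self, quartet_codon_alignment):
        pi = f3x4_frequencies(quartet_codon_alignment)
        assert pi.sum() == pytest.approx(1.0)
        assert pi.min() > 0

    def test_f3x4_reflects_positional_composition(self):
        aln = CodonAlignment(["a", "b"], ["ATGATG", "ATGATG"])
        pi = f3x4_frequencies(aln)
        # ATG should dominate: A at pos1, T at pos2, G at pos3
        assert pi[CODON_INDEX["ATG"]] == pytest.approx(pi.max())
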