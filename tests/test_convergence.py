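"""Profile substitution model and PCOC-style site posteriors."""

import numpy as np
import pytest

from cladevol.convergence_pcoc import (ConvergenceScenario, ProfileSet,
                                       default_profiles,
                                       detect_convergent_sites,
                                       profile_substitution_model,
                                       site_posteriors, threshold_summary)
from cladevol.seq_prep import ProteinAlignment
from cladevol.synthetic_data import (make_study_fixture,
                                     simulate_convergent_alignment)


@pytest.fixture(scope="module")
def fixture():
    return make_study_fixture(seed=0, n_chameleon=2, n_agamid=2,
                              n_pleurodont=4, n_mammal=4)


@pytest.fixture(scope="module")
def scenario(fixture):
    return ConvergenceScenario(
        fixture.tree3,
        {"acrodont": set(fixture.clades["acrodont"]),
         "mammal": set(fixture.clades["mammal"])},
    )


class TestProfileModel:
    def test_uniform_profile_has_equal_rates(self):
        Q = profile_substitution_model(np.full(20, 1 / 20))
        off = Q[~np.eye(20, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_stationarity(self):
        profiles = default_profiles()
        for k in range(profiles.k):
            pi = profiles.frequencies[k]
            Q = profile_substitution_model(pi)
            assert np.abs(pi @ Q).max() < 1e-12
            assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_unit_expected_rate(self):
        pi = default_profiles().frequencies[0]
        Q = profile_substitution_model(pi)
        assert -(pi @ np.diag(Q)) == pytest.approx(1.0)

    def test_zero_entries_rejected(self):
        pi = np.zeros(20)
        pi[0] = 1.0
        with pytest.raises(ValueError, match="> 0"):
            profile_substitution_model(pi)

    def test_long_branch_reaches_stationary_frequencies(self):
        from cladevol._pruning import ReversibleEigen

        pi = default_profiles().frequencies[6]  # "positive"
        Q = profile_substitution_model(pi)
        eig = ReversibleEigen.from_q(Q, pi)
        P = eig.transition(50.0)
        assert np.abs(P - pi[None, :]).max() < 1e-8

    def test_forced_rows_sum_to_change_probability(self):
        pi = default_profiles().frequencies[0]
        Q = profile_substitution_model(pi)
        from cladevol._pruning import ReversibleEigen

        t = 0.4
        eig = ReversibleEigen.from_q(Q, pi)
        P = eig.transition(t)
        q = -np.diag(Q)
        forced = P.copy()
        np.fill_diagonal(forced, np.diag(P) - np.exp(-q * t))
        assert np.allclose(forced.sum(axis=1), 1 - np.exp(-q * t))
        assert forced.min() >= -1e-12


class TestScenario:
    def test_needs_two_foreground_clades(self, fixture):
        with pytest.raises(ValueError, match=">= 2"):
            ConvergenceScenario(
                fixture.tree3,
                {"acrodont": set(fixture.clades["acrodont"])},
            )

    def test_foreground_clades_must_be_disjoint(self, fixture):
        with pytest.raises(ValueError, match="disjoint"):
            ConvergenceScenario(
                fixture.tree3,
                {"a": set(fixture.clades["acrodont"]),
                 "b": set(fixture.clades["chameleon"])},
            )

    def test_transition_edges_are_clade_stems(self, fixture, scenario):
        arrays = fixture.tree3.to_arrays()
        sets = arrays.leafsets()
        stems = {sets[e] for e in scenario.transition_edges}
        assert frozenset(fixture.clades["acrodont"]) in stems
        assert frozenset(fixture.clades["mammal"]) in stems


class TestSitePosteriors:
    def test_joint_posteriors_sum_to_one(self, fixture, scenario):
        aln, _ = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.2, 20, seed=1
        )
        for r in site_posteriors(aln, fixture.tree3, scenario):
            assert sum(r.pp_joint) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_background_column_not_convergent(self, fixture,
                                                        scenario):
        taxa = fixture.tree3.taxa
        aln = ProteinAlignment(taxa, ["D"] * len(taxa))
        r = site_posteriors(aln, fixture.tree3, scenario)[0]
        assert r.pp_pcoc < 0.5

    def test_separable_convergent_column_scores_high(self, fixture,
                                                     scenario):
        # foreground clades cycle through K/R (positive profile), the
        # background through D/E (negative): a clean profile shift with a
        # required change on both stems
        taxa = fixture.tree3.taxa
        fg = set(fixture.clades["acrodont"]) | set(fixture.clades["mammal"])
        fg_res, bg_res = "KR", "DE"
        i = j = 0
        col = []
        for t in taxa:
            if t in fg:
                col.append(fg_res[i % 2]); i += 1
            else:
                col.append(bg_res[j % 2]); j += 1
        aln = ProteinAlignment(taxa, col)
        r = site_posteriors(aln, fixture.tree3, scenario)[0]
        assert r.pp_pcoc >= 0.95
        assert r.best_profile_pair == ("negative", "positive")

    def test_all_gap_foreground_clade_is_flagged(self, fixture, scenario):
        taxa = fixture.tree3.taxa
        mamm = set(fixture.clades["mammal"])
        col = ["-" if t in mamm else "A" for t in taxa]
        aln = ProteinAlignment(taxa, col)
        r = site_posteriors(aln, fixture.tree3, scenario)[0]
        assert any("mammal" in f for f in r.flags)


class TestDetection:
    def test_counts_monotone_in_threshold(self, fixture, scenario):
        aln, _ = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.15, 60, seed=2
        )
        df = detect_convergent_sites(aln, fixture.tree3, scenario,
                                     threshold=0.8)
        summary = threshold_summary(df, aln, thresholds=(0.8, 0.9, 0.95))
        counts = summary["n_sites"].tolist()
        assert counts[0] >= counts[1] >= counts[2]

    def test_threshold_range_validated(self, fixture, scenario):
        aln, _ = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.1, 5, seed=3
        )
        with pytest.raises(ValueError, match="threshold"):
            detect_convergent_sites(aln, fixture.tree3, scenario,
                                    threshold=0.4)

    def test_percentage_uses_average_ungapped_length(self, fixture,
                                                     scenario):
        aln, _ = simulate_convergent_alignment(
            fixture.tree3, scenario, default_profiles(), 0.3, 40, seed=4
        )
        df = detect_convergent_sites(aln, fixture.tree3, scenario,
                                     threshold=0.8)
        summary = threshold_summary(df, aln, thresholds=(0.8,))
        n = summary.loc[0, "n_sites"]
        assert summary.loc[0, "pct_of_avg_length"] == pytest.approx(
            100.0 * n / 40
        )


class TestProfileSet:
    def test_default_set_is_valid(self):
        p = default_profiles()
        assert p.k == 10
        assert np.allclose(p.frequencies.sum(axis=1), 1.0)
        assert p.frequencies.min() > 0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProfileSet(["x"], np.full((1, 20), 0.04))
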