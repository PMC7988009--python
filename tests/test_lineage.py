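"""Unit tests for the two-state lineage switching model."""

from __future__ import annotations

import numpy as np
import pytest

from episwitch.lineage import (
    NR,
    R,
    DegenerateChainError,
    LineageTree,
    SwitchingRates,
    TreeStructureError,
    UnidentifiableError,
    fit_switching_rates,
    fitch_parsimony,
    predict_fraction_decay,
    relatedness_concordance,
    simulate_lineages,
    stationary_fraction,
    transition_matrix,
    tree_log_likelihood,
    study_scale_design,
)

from _oracles import (
    brute_force_log_likelihood,
    brute_force_min_switches,
    count_switches,
)
from conftest import cherry, make_tree, random_trees


class TestRatesAndMatrix:
    def test_transition_matrix_entries(self, paper_rates):
        T = transition_matrix(paper_rates)
        assert np.allclose(T, [[0.99, 0.01], [0.055, 0.945]])
        assert np.allclose(T.sum(axis=1), 1.0)

    @pytest.mark.parametrize(
        "p_on,p_off,expected",
        [(0.0, 0.0, np.eye(2)), (0.5, 0.5, np.full((2, 2), 0.5))],
    )
    def test_transition_matrix_degenerate(self, p_on, p_off, expected):
        assert np.allclose(transition_matrix(SwitchingRates(p_on, p_off)), expected)

    def test_stationary_fraction_closed_form(self, paper_rates):
        f = stationary_fraction(paper_rates)
        assert f == pytest.approx(0.01 / 0.065)
        # fixed point of the transition matrix
        v = np.array([1 - f, f]) @ transition_matrix(paper_rates)
        assert v[1] == pytest.approx(f)

    @pytest.mark.parametrize(
        "p_on,p_off,expected", [(0.2, 0.2, 0.5), (0.0, 0.3, 0.0), (0.4, 0.0, 1.0)]
    )
    def test_stationary_fraction_cases(self, p_on, p_off, expected):
        assert stationary_fraction(SwitchingRates(p_on, p_off)) == expected

    def test_stationary_degenerate_chain(self):
        with pytest.raises(DegenerateChainError):
            stationary_fraction(SwitchingRates(0.0, 0.0))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SwitchingRates(-0.1, 0.5)
        with pytest.raises(ValueError):
            SwitchingRates(0.1, 0.5, ci_on=(0.2, 0.3))  # point outside CI


class TestTreeStructure:
    def test_orphan_parent_rejected(self):
        with pytest.raises(TreeStructureError, match="missing parent"):
            LineageTree.from_records(
                [dict(node_id="a", parent_id="ghost", generation=1,
                      fate="terminal_observed", leaf_status="R")]
            )

    def test_divided_needs_two_children(self):
        with pytest.raises(TreeStructureError, match="children"):
            LineageTree.from_records(
                [
                    dict(node_id="a", parent_id="ROOT", generation=0,
                         fate="divided", leaf_status="NA"),
                    dict(node_id="b", parent_id="a", generation=1,
                         fate="terminal_observed", leaf_status="R"),
                ]
            )

    def test_status_on_internal_node_rejected(self):
        recs = cherry().to_records()
        recs[0]["leaf_status"] = "responder"
        with pytest.raises(TreeStructureError, match="cannot carry"):
            LineageTree.from_records(recs)

    def test_generation_consistency_enforced(self):
        recs = cherry().to_records()
        recs[1]["generation"] = 5
        with pytest.raises(TreeStructureError, match="generation"):
            LineageTree.from_records(recs)


class TestSimulation:
    def test_no_switching_preserves_state(self):
        trees = simulate_lineages(SwitchingRates(0, 0), 1.0, 20, 4, seed=1)
        for t in trees:
            assert np.all(t.status[t.observed_leaves] == R)

    def test_forced_flip_one_generation(self):
        trees = simulate_lineages(SwitchingRates(1, 1), 1.0, 20, 1, seed=1)
        for t in trees:
            assert np.all(t.status[t.observed_leaves] == NR)

    def test_stationary_leaf_fraction(self, paper_rates):
        f_ss = stationary_fraction(paper_rates)
        trees = simulate_lineages(paper_rates, f_ss, 3000, 5, seed=42)
        leaf = np.concatenate([t.status[t.observed_leaves] for t in trees])
        se = np.sqrt(f_ss * (1 - f_ss) / len(leaf))
        # leaves within a tree are correlated, so allow a few fold the iid SE
        assert abs(leaf.mean() - f_ss) < 6 * se

    def test_generation_invariant_fraction(self, paper_rates):
        """At stationary initialization the responder fraction is flat in g."""
        f_ss = stationary_fraction(paper_rates)
        trees = simulate_lineages(paper_rates, f_ss, 2000, 4, seed=7)
        # pool all cells (hidden + observed states are not stored per
        # generation, so use observed leaves of per-depth simulations)
        for g in (1, 3):
            tg = simulate_lineages(paper_rates, f_ss, 3000, g, seed=g)
            leaf = np.concatenate([t.status[t.observed_leaves] for t in tg])
            assert abs(leaf.mean() - f_ss) < 0.03

    def test_deterministic_given_seed(self, paper_rates):
        a = simulate_lineages(paper_rates, 0.2, 30, 4, death_prob=0.2, seed=9)
        b = simulate_lineages(paper_rates, 0.2, 30, 4, death_prob=0.2, seed=9)
        assert all(x.to_records() == y.to_records() for x, y in zip(a, b))

    def test_invalid_arguments(self, paper_rates):
        with pytest.raises(ValueError):
            simulate_lineages(paper_rates, 1.5, 10, 3)
        with pytest.raises(ValueError):
            simulate_lineages(paper_rates, 0.5, 0, 3)

    def test_study_scale_division_count(self, paper_rates):
        """The study-scale design yields ~273 divisions on average."""
        design = study_scale_design()
        divs = []
        for s in range(30):
            trees = simulate_lineages(paper_rates, 0.15, seed=s, **design)
            divs.append(sum(t.n_divisions for t in trees))
        assert 230 < np.mean(divs) < 320


class TestLikelihood:
    def test_single_observed_leaf_is_root_prob(self, paper_rates):
        t = LineageTree.from_records(
            [dict(node_id="a", parent_id="ROOT", generation=0,
                  fate="terminal_observed", leaf_status="R")]
        )
        assert tree_log_likelihood(t, paper_rates, 0.3) == pytest.approx(np.log(0.3))

    def test_cherry_hand_enumeration(self, paper_rates):
        """pi (1-p_off)^2 + (1-pi) p_on^2 for two responder daughters."""
        t = cherry("R", "R")
        pi = 0.3
        expected = pi * (1 - 0.055) ** 2 + (1 - pi) * 0.01**2
        assert tree_log_likelihood(t, paper_rates, pi) == pytest.approx(
            np.log(expected), abs=1e-12
        )

    def test_all_unknown_leaves_marginalize_to_one(self, paper_rates):
        recs = [
            dict(node_id="a", parent_id="ROOT", generation=0, fate="divided",
                 leaf_status="NA"),
            dict(node_id="b", parent_id="a", generation=1, fate="died",
                 leaf_status="NA"),
            dict(node_id="c", parent_id="a", generation=1, fate="left_fov",
                 leaf_status="NA"),
        ]
        t = LineageTree.from_records(recs)
        assert tree_log_likelihood(t, paper_rates, 0.42) == pytest.approx(0.0)

    def test_impossible_data_gives_minus_inf(self):
        t = cherry("R", "N")
        assert tree_log_likelihood(t, SwitchingRates(0, 0), 0.5) == -np.inf

    def test_pruning_equals_brute_force(self):
        """Exact marginalization agrees with hidden-state enumeration."""
        rng = np.random.default_rng(11)
        for t in random_trees(40, seed=3, max_generations=4):
            p_on, p_off = rng.uniform(0.01, 0.6, 2)
            pi = rng.uniform(0.1, 0.9)
            got = tree_log_likelihood(t, SwitchingRates(p_on, p_off), pi)
            want = brute_force_log_likelihood(t, p_on, p_off, pi)
            assert got == pytest.approx(want, abs=1e-9)


class TestFitting:
    def test_zero_observed_switching_pins_to_boundary(self):
        trees = [make_tree(["R"] * 8, "r") for _ in range(3)] + [
            make_tree(["N"] * 8, f"n{i}") for i in range(17)
        ]
        fit = fit_switching_rates(trees, root_dist_mode="free", ci_method="none")
        assert fit.p_on < 1e-4 and fit.p_off < 1e-4
        assert fit.boundary_on and fit.boundary_off

    def test_all_censored_unidentifiable(self, paper_rates):
        recs = [
            dict(node_id="a", parent_id="ROOT", generation=0, fate="died",
                 leaf_status="NA"),
        ]
        t = LineageTree.from_records(recs)
        with pytest.raises(UnidentifiableError):
            fit_switching_rates([t])

    def test_symmetric_rates_recover_half_stationary(self):
        rates = SwitchingRates(0.2, 0.2)
        trees = simulate_lineages(rates, 0.5, 400, 4, seed=21)
        fit = fit_switching_rates(trees, root_dist_mode="stationary",
                                  ci_method="none")
        assert stationary_fraction(fit.rates) == pytest.approx(0.5, abs=0.06)

    def test_recovery_smoke(self, paper_rates):
        f_ss = stationary_fraction(paper_rates)
        trees = simulate_lineages(paper_rates, f_ss, 500, 5, seed=5)
        fit = fit_switching_rates(trees, root_dist_mode="stationary",
                                  ci_method="profile")
        assert fit.p_on == pytest.approx(0.01, abs=0.008)
        assert fit.p_off == pytest.approx(0.055, abs=0.02)
        assert fit.ci_on[0] <= fit.p_on <= fit.ci_on[1]
        assert fit.ci_off[0] <= fit.p_off <= fit.ci_off[1]

    def test_bootstrap_ci_contains_point(self, paper_rates):
        f_ss = stationary_fraction(paper_rates)
        trees = simulate_lineages(paper_rates, f_ss, 80, 4, seed=6)
        fit = fit_switching_rates(trees, root_dist_mode="stationary",
                                  ci_method="bootstrap", seed=1, n_bootstrap=60)
        assert fit.ci_on[0] <= fit.p_on <= fit.ci_on[1]
        assert fit.ci_off[0] <= fit.p_off <= fit.ci_off[1]


class TestDecayPrediction:
    def test_initial_value(self, paper_rates):
        pred = predict_fraction_decay(paper_rates, 0.65, 0)
        assert pred.fraction[0] == 0.65

    def test_matches_matrix_iteration(self, paper_rates):
        """Closed form equals generation-by-generation matrix iteration."""
        pred = predict_fraction_decay(paper_rates, 0.65, 30)
        v = np.array([0.35, 0.65])
        T = transition_matrix(paper_rates)
        for g in range(31):
            assert pred.fraction[g] == pytest.approx(v[1], abs=1e-14)
            v = v @ T
        assert pred.fraction[30] == pytest.approx(0.220, abs=5e-4)

    def test_monotone_toward_stationary(self, paper_rates):
        pred = predict_fraction_decay(paper_rates, 0.65, 150)
        f_ss = stationary_fraction(paper_rates)
        assert np.all(np.diff(pred.fraction) < 0)
        assert pred.fraction[-1] == pytest.approx(f_ss, abs=1e-4)

    def test_band_envelope_contains_point_prediction(self, paper_rates):
        rates = SwitchingRates(0.01, 0.055, ci_on=(0.005, 0.015),
                               ci_off=(0.045, 0.065))
        pred = predict_fraction_decay(rates, 0.65, 30, band="rate_ci_envelope")
        assert np.all(pred.band_low <= pred.fraction + 1e-12)
        assert np.all(pred.fraction <= pred.band_high + 1e-12)

    def test_oscillatory_regime_warns(self):
        with pytest.warns(UserWarning, match="oscillation"):
            predict_fraction_decay(SwitchingRates(0.7, 0.6), 0.5, 5)


class TestFitchParsimony:
    def test_discordant_cherry(self):
        res = fitch_parsimony(cherry("R", "N"))
        assert res.min_switches == 1

    def test_uniform_leaves_no_switches(self):
        res = fitch_parsimony(make_tree(["R"] * 8))
        assert res.min_switches == 0
        assert np.all(res.assignment == 1)

    def test_two_clade_split_is_one_switch_root_tie(self):
        res = fitch_parsimony(make_tree(["R", "R", "N", "N"]))
        assert res.min_switches == 1
        assert res.root_states == (0, 1)  # tie reported, NR first
        assert res.root_ambiguous

    def test_matches_exhaustive_minimum(self):
        """Fitch count equals the brute-force minimum over labelings."""
        for t in random_trees(50, seed=8, max_generations=3):
            res = fitch_parsimony(t)
            assert res.min_switches == brute_force_min_switches(t)

    def test_returned_assignment_achieves_minimum(self):
        for t in random_trees(25, seed=13, max_generations=3, death_prob=0.0):
            res = fitch_parsimony(t)
            assert count_switches(t, res.assignment) == res.min_switches


class TestRelatednessConcordance:
    def test_perfect_heritability(self):
        trees = simulate_lineages(SwitchingRates(0, 0), 0.5, 50, 3, seed=2)
        table = relatedness_concordance(trees)
        got = table["p_responder"].dropna()
        assert np.allclose(got, 1.0)

    def test_single_discordant_cherry(self):
        table = relatedness_concordance([cherry("R", "N")])
        assert table.loc["sister", "p_responder"] == 0.0
        assert table.loc["sister", "n_pairs"] == 1

    def test_concordance_decays_with_relation_distance(self, paper_rates):
        f_ss = stationary_fraction(paper_rates)
        trees = simulate_lineages(paper_rates, f_ss, 3000, 4, seed=17)
        tab = relatedness_concordance(trees)
        assert (
            tab.loc["sister", "p_responder"]
            >= tab.loc["cousin", "p_responder"] - 0.02
            >= tab.loc["extended", "p_responder"] - 0.04
        )
        # relatives are far more concordant than the population baseline
        assert tab.loc["sister", "p_responder"] > 3 * f_ss

    def test_no_responders_warns_empty(self):
        with pytest.warns(UserWarning, match="no observed responder"):
            table = relatedness_concordance([cherry("N", "N")])
        assert table["n_pairs"].sum() == 0
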