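"""Mk1 likelihoods, marginal reconstruction, and clade classification."""

import math

import numpy as np
import pandas as pd
import pytest

from chemophylo.ancestral_reconstruction import (Phylogeny,
                                                 character_log_likelihood,
                                                 classify_character,
                                                 count_origins, estimate_rate,
                                                 fitch_states, marginal_asr,
                                                 mk_transition, read_newick,
                                                 run_asr)
from chemophylo.character_coding import CharacterMatrix
from conftest import (oracle_mk_loglik, oracle_mk_marginal,
                      phylogeny_from_newick, random_phylogeny)


class TestNewick:
    def test_parse_counts_nodes(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1):0.0;\n")
        phylo = read_newick(p)
        assert phylo.tip_labels == {"A", "B", "C", "D"}
        internal = [n for n in phylo.tree.preorder_node_iter()
                    if not n.is_leaf()]
        assert len(internal) == 3

    def test_duplicate_tip_label_errors(self, tmp_path):
        p = tmp_path / "d.nwk"
        p.write_text("((A:1,A:1):1,B:2);\n")
        with pytest.raises(ValueError, match="unique"):
            read_newick(p)

    def test_round_trip_topology_and_lengths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.5,B:1.25):0.75,(C:1,D:2):1.5);\n")
        phylo = read_newick(p)
        out = tmp_path / "o.nwk"
        phylo.write(out)
        again = read_newick(out)
        d1 = {l.taxon.label: l.distance_from_root()
              for l in phylo.tree.leaf_node_iter()}
        d2 = {l.taxon.label: l.distance_from_root()
              for l in again.tree.leaf_node_iter()}
        assert d1 == pytest.approx(d2)

    def test_zero_branch_replaced_with_epsilon(self, tmp_path, caplog):
        p = tmp_path / "z.nwk"
        p.write_text("((A:0.0,B:1):1,C:2);\n")
        with caplog.at_level("WARNING", logger="chemophylo"):
            phylo = read_newick(p)
        a = phylo.tree.find_node_with_taxon_label("A")
        assert a.edge.length > 0

    def test_non_monophyletic_clade_errors(self):
        with pytest.raises(ValueError, match="monophyletic"):
            phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);",
                                  {"bad": {"A", "C"}})


class TestTransition:
    def test_zero_time_is_identity(self):
        assert np.allclose(mk_transition(1.3, 0.0), np.eye(2))

    def test_long_time_reaches_stationary_half(self):
        assert np.allclose(mk_transition(1.0, 1e6), np.full((2, 2), 0.5))

    def test_closed_form_quarter_flip(self):
        # e^(-2qt) = 0.5
        q, t = math.log(2) / 2, 1.0
        assert np.allclose(mk_transition(q, t),
                           [[0.75, 0.25], [0.25, 0.75]], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(10):
            p = mk_transition(rng.uniform(0.01, 5), rng.uniform(0, 3))
            assert np.allclose(p.sum(axis=1), 1.0)


class TestLikelihood:
    def test_cherry_with_no_change_is_root_prior(self):
        phylo = phylogeny_from_newick("(A:1,B:1);")
        ll = character_log_likelihood(phylo, {"A": 1, "B": 1}, 1e-9)
        assert math.exp(ll) == pytest.approx(0.5, abs=1e-6)

    def test_cherry_quarter_flip_enumeration(self):
        phylo = phylogeny_from_newick("(A:1,B:1);")
        q = math.log(2) / 2  # flip probability 0.25
        ll = character_log_likelihood(phylo, {"A": 1, "B": 1}, q)
        assert math.exp(ll) == pytest.approx(0.5 * (0.75**2 + 0.25**2),
                                             abs=1e-12)

    def test_tip_rotation_invariance(self, rng):
        phylo = phylogeny_from_newick("((A:0.3,B:0.7):0.4,(C:1.1,D:0.2):0.6);")
        rotated = phylogeny_from_newick("((D:0.2,C:1.1):0.6,(B:0.7,A:0.3):0.4);")
        states = {"A": 1, "B": 0, "C": 1, "D": 0}
        assert character_log_likelihood(phylo, states, 0.9) \
            == pytest.approx(character_log_likelihood(rotated, states, 0.9),
                             abs=1e-12)

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_pruning_matches_enumeration(self, n_tips):
        rng = np.random.default_rng(n_tips)
        for _ in range(10):
            phylo = random_phylogeny(rng, n_tips)
            states = {f"t{i}": int(rng.integers(0, 2)) for i in range(n_tips)}
            q = float(rng.uniform(0.05, 3.0))
            assert abs(character_log_likelihood(phylo, states, q)
                       - oracle_mk_loglik(phylo, states, q)) < 1e-10

    def test_missing_tip_state_errors(self):
        phylo = phylogeny_from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing"):
            character_log_likelihood(phylo, {"A": 1}, 0.5)


class TestRateEstimation:
    def test_local_optimality_of_fit(self, rng):
        phylo = random_phylogeny(rng, 8)
        states = pd.Series({f"t{i}": int(rng.integers(0, 2)) for i in range(8)})
        fit = estimate_rate(phylo, states)
        if not fit.at_boundary:
            ll = character_log_likelihood(phylo, states.to_dict(), fit.q_hat)
            assert ll >= character_log_likelihood(phylo, states.to_dict(),
                                                  fit.q_hat * 0.5) - 1e-9
            assert ll >= character_log_likelihood(phylo, states.to_dict(),
                                                  fit.q_hat * 2.0) - 1e-9

    def test_constant_character_pinned_at_boundary(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fit = estimate_rate(phylo, pd.Series({"A": 1, "B": 1, "C": 1, "D": 1}))
        assert fit.at_boundary


class TestMarginals:
    def test_low_rate_all_present_root_is_present(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        probs, _ = marginal_asr(phylo, {"A": 1, "B": 1, "C": 1, "D": 1}, 1e-6)
        root = probs.index[-1]
        assert probs.loc[root, 1] == pytest.approx(1.0, abs=1e-4)

    def test_symmetric_cherry_splits_evenly(self):
        phylo = phylogeny_from_newick("(A:1,B:1);")
        probs, map_states = marginal_asr(phylo, {"A": 0, "B": 1}, 0.7)
        root = probs.index[-1]
        assert probs.loc[root, 0] == pytest.approx(0.5, abs=1e-12)
        assert map_states[root] == 0  # tie resolves to absent

    def test_matches_enumeration_on_four_tip_trees(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            phylo = random_phylogeny(rng, 4)
            states = {f"t{i}": int(rng.integers(0, 2)) for i in range(4)}
            q = float(rng.uniform(0.1, 2.0))
            probs, _ = marginal_asr(phylo, states, q)
            for name in probs.index:
                if name.startswith("node"):
                    assert probs.loc[name, 1] == pytest.approx(
                        oracle_mk_marginal(phylo, states, q, name), abs=1e-10)

    def test_marginals_sum_to_one(self, rng):
        phylo = random_phylogeny(rng, 6)
        states = {f"t{i}": int(rng.integers(0, 2)) for i in range(6)}
        probs, _ = marginal_asr(phylo, states, 0.5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestOriginsAndCalls:
    def test_counts_on_hand_labeled_trees(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        all_zero = pd.Series({"A": 0, "B": 0, "C": 0, "D": 0,
                              "node2": 0, "node5": 0, "node6": 0})
        assert count_origins(phylo, all_zero) == (0, 0)
        one_gain = all_zero.copy()
        one_gain[["A", "B", "node2"]] = 1
        assert count_origins(phylo, one_gain) == (1, 0)
        two_clades = one_gain.copy()
        two_clades[["C", "D", "node5"]] = 1
        assert count_origins(phylo, two_clades) == (2, 0)

    def test_single_gain_is_synapomorphy(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);",
                                      {"AB": {"A", "B"}})
        states = pd.Series({"A": 1, "B": 1, "C": 0, "D": 0})
        _, mp = marginal_asr(phylo, states, 0.1)
        g, l = count_origins(phylo, mp)
        assert classify_character(phylo, "AB", states, mp, g, l) \
            == "synapomorphy_present"

    def test_second_origin_makes_homoplasy(self):
        phylo = phylogeny_from_newick(
            "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", {"AB": {"A", "B"}})
        states = pd.Series({"A": 1, "B": 1, "C": 0, "D": 1, "E": 0})
        _, mp = marginal_asr(phylo, states, 0.1)
        g, l = count_origins(phylo, mp)
        assert g == 2
        assert classify_character(phylo, "AB", states, mp, g, l) \
            == "homoplasy_present"

    def test_uniform_absence_with_single_loss_is_synapomorphy_absent(self):
        # the outgroup weight makes presence clearly ancestral
        phylo = phylogeny_from_newick(
            "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", {"AB": {"A", "B"}})
        states = pd.Series({"A": 0, "B": 0, "C": 1, "D": 1, "E": 1})
        _, mp = marginal_asr(phylo, states, 0.1)
        g, l = count_origins(phylo, mp)
        assert classify_character(phylo, "AB", states, mp, g, l) \
            == "synapomorphy_absent"

    def test_polymorphic_clade_is_uninformative(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);",
                                      {"AB": {"A", "B"}})
        states = pd.Series({"A": 1, "B": 0, "C": 0, "D": 0})
        _, mp = marginal_asr(phylo, states, 0.1)
        g, l = count_origins(phylo, mp)
        assert classify_character(phylo, "AB", states, mp, g, l) \
            == "uninformative"

    def test_fitch_minimal_changes_on_hand_case(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        lab = fitch_states(phylo, {"A": 1, "B": 1, "C": 0, "D": 0})
        g, l = count_origins(phylo, lab)
        assert g + l == 1  # parsimony score of this pattern


class TestRunASR:
    def test_report_shape_and_ubiquitous_listing(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);",
                                      {"AB": {"A", "B"}, "CD": {"C", "D"}})
        states = pd.DataFrame(
            {"everywhere": [1, 1, 1, 1],
             "ab_marker": [1, 1, 0, 0],
             "noise": [1, 0, 1, 0]}, index=["A", "B", "C", "D"])
        matrix = CharacterMatrix(states)
        results, report = run_asr(phylo, matrix)
        assert len(results) == 3
        assert report.attrs["ubiquitous"] == ["everywhere"]
        by_char = {r.character: r for r in results}
        assert by_char["everywhere"].clade_calls == {}
        assert by_char["ab_marker"].clade_calls["AB"] == "synapomorphy_present"

    def test_matrix_genus_missing_from_tree_errors(self):
        phylo = phylogeny_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        matrix = CharacterMatrix(pd.DataFrame({"c": [1, 0]},
                                              index=["A", "Zed"]))
        with pytest.raises(ValueError, match="Zed"):
            run_asr(phylo, matrix)

    def test_tree_pruned_to_sampled_genera(self):
        phylo = phylogeny_from_newick(
            "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", {"AB": {"A", "B"}})
        matrix = CharacterMatrix(pd.DataFrame(
            {"m": [1, 1, 0, 0]}, index=["A", "B", "D", "E"]))
        results, report = run_asr(phylo, matrix)
        assert results[0].clade_calls["AB"] == "synapomorphy_present"
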