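"""Network construction, library annotation, and solvent overlap."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chemophylo.molecular_networking import (build_network, components,
                                             extraction_overlap,
                                             library_search, pairwise_scores,
                                             read_network, write_network)
from chemophylo.spectra_io import FeatureTable, Spectrum
from chemophylo.spectral_similarity import SimilarityParams
from chemophylo.synthetic_data import (SimulationConfig,
                                       simulate_compound_families)


@pytest.fixture(scope="module")
def planted_spectra():
    cfg = SimulationConfig(seed=7, n_compound_families=4, members_per_family=4)
    return simulate_compound_families(cfg)


class TestPairwiseScores:
    def test_edges_only_within_planted_families(self, planted_spectra):
        spectra, family_of, _ = planted_spectra
        edges = pairwise_scores(spectra)
        assert edges, "expected within-family edges"
        for u, v, score, n in edges:
            assert family_of[u] == family_of[v]
            assert score > 0.7 and n >= 4

    def test_component_count_equals_family_count(self, planted_spectra):
        spectra, family_of, _ = planted_spectra
        edges = pairwise_scores(spectra)
        g = nx.Graph()
        g.add_nodes_from(s.feature_id for s in spectra)
        g.add_edges_from((u, v) for u, v, *_ in edges)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        families = {frozenset(f for f, fam in family_of.items() if fam == name)
                    for name in set(family_of.values())}
        assert comps == families

    def test_impossible_threshold_gives_no_edges(self, planted_spectra):
        spectra, _, _ = planted_spectra
        p = SimilarityParams(min_cosine=1.0 + 1e-9)
        assert pairwise_scores(spectra, p) == []

    def test_duplicated_spectrum_edge_scores_one(self, rng):
        from conftest import random_spectrum
        s = random_spectrum(rng, "x", n_peaks=8, precursor=700.0)
        twin = Spectrum("y", s.precursor_mz, mode=s.mode, peaks=s.peaks)
        edges = pairwise_scores([s, twin])
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(1.0, abs=1e-9)

    def test_raising_min_cosine_is_monotone(self, planted_spectra):
        spectra, _, _ = planted_spectra
        loose = {(u, v) for u, v, *_ in
                 pairwise_scores(spectra, SimilarityParams(min_cosine=0.7))}
        tight = {(u, v) for u, v, *_ in
                 pairwise_scores(spectra, SimilarityParams(min_cosine=0.9))}
        assert tight <= loose

    def test_input_order_invariance(self, planted_spectra):
        spectra, _, _ = planted_spectra
        fwd = pairwise_scores(spectra)
        rev = pairwise_scores(list(reversed(spectra)))
        assert sorted(fwd) == sorted(rev)


class TestBuildNetwork:
    def make_table(self, fids, areas, samples):
        return FeatureTable(
            pd.DataFrame(areas, index=fids, columns=samples),
            pd.DataFrame({"mz": [100.0] * len(fids), "rt": [1.0] * len(fids)},
                         index=fids))

    def make_meta(self, samples, clades):
        meta = pd.DataFrame({"species": samples, "genus": samples,
                             "clade": clades,
                             "solvent": ["hydroethanolic"] * len(samples),
                             "mode": ["positive"] * len(samples)},
                            index=samples)
        return meta

    def test_pie_chart_is_clade_share_of_area(self):
        table = self.make_table(["f1", "f2"], [[3.0, 0.0], [1.0, 0.0]],
                                ["sa", "sb"])
        meta = self.make_meta(["sa", "sb"], ["A", "B"])
        g = build_network([("f1", "f2", 0.9, 5)], table, meta)
        assert len(components(g)) == 1
        assert json.loads(g.nodes["f1"]["clade_abundance"]) == {"A": 1.0}
        assert g.nodes["f1"]["node_size"] == 3.0

    def test_zero_area_feature_flagged(self):
        table = self.make_table(["f1"], [[0.0, 0.0]], ["sa", "sb"])
        meta = self.make_meta(["sa", "sb"], ["A", "B"])
        g = build_network([], table, meta)
        assert g.nodes["f1"]["zero_area"]
        assert json.loads(g.nodes["f1"]["clade_abundance"]) == {}

    def test_unknown_feature_in_scores_errors(self):
        table = self.make_table(["f1"], [[1.0]], ["sa"])
        meta = self.make_meta(["sa"], ["A"])
        with pytest.raises(ValueError, match="ghost"):
            build_network([("f1", "ghost", 0.9, 5)], table, meta)

    def test_optional_topk_and_component_size_pruning(self):
        # star: hub f0 linked to 3 spokes with distinct scores
        table = self.make_table([f"f{i}" for i in range(4)],
                                [[1.0]] * 4, ["sa"])
        meta = self.make_meta(["sa"], ["A"])
        scores = [("f0", "f1", 0.9, 5), ("f0", "f2", 0.8, 5),
                  ("f0", "f3", 0.75, 5)]
        g = build_network(scores, table, meta, top_k_neighbors=2)
        assert set(map(frozenset, g.edges)) \
            == {frozenset({"f0", "f1"}), frozenset({"f0", "f2"})}
        g2 = build_network(scores, table, meta, max_component_size=2)
        assert max(len(c) for c in components(g2)) <= 2
        # weakest edges were the ones removed
        assert frozenset({"f0", "f1"}) in set(map(frozenset, g2.edges))

    def test_blank_filter_drops_contaminants(self):
        table = self.make_table(["f1", "f2"], [[0.1, 5.0], [5.0, 0.1]],
                                ["blank1", "real1"])
        meta = self.make_meta(["blank1", "real1"], ["blank", "A"])
        g = build_network([], table, meta, blank_fraction=0.5)
        assert "f1" in g and "f2" not in g


class TestLibrarySearch:
    def test_identical_entry_scores_one(self, rng):
        from conftest import random_spectrum
        q = random_spectrum(rng, "q", n_peaks=8, precursor=600.0)
        lib = Spectrum("L1", q.precursor_mz, mode="positive", peaks=q.peaks,
                       annotation={"class": "Flavonoids"})
        [hit] = library_search([q], [lib])
        assert hit.library_compound_id == "L1"
        assert hit.score == pytest.approx(1.0, abs=1e-9)
        assert hit.annotation == {"class": "Flavonoids"}

    def test_sub_threshold_score_gives_no_hit(self):
        q = Spectrum("q", 400.0, peaks=[(100.0, 1), (150.0, 1), (210.0, 1),
                                        (260.0, 1)])
        lib = Spectrum("L", 400.0, peaks=[(100.0, 1), (150.0, 1), (300.0, 1),
                                          (350.0, 1)])
        # only 2 of 4 peaks match: score 0.5 < 0.7
        assert library_search([q], [lib]) == []

    def test_best_of_two_candidates_wins(self, rng):
        from conftest import random_spectrum
        q = random_spectrum(rng, "q", n_peaks=8, precursor=600.0)
        exact = Spectrum("good", q.precursor_mz, mode="positive", peaks=q.peaks)
        worse_peaks = q.peaks.copy()
        worse_peaks[0, 0] += 5.0  # breaks one match
        worse = Spectrum("worse", q.precursor_mz, mode="positive",
                         peaks=worse_peaks)
        [hit] = library_search([q], [worse, exact])
        assert hit.library_compound_id == "good"

    def test_empty_library(self, rng):
        from conftest import random_spectrum
        assert library_search([random_spectrum(rng)], []) == []

    def test_precursor_tolerance_gate(self, rng):
        from conftest import random_spectrum
        q = random_spectrum(rng, "q", n_peaks=8, precursor=600.0)
        far = Spectrum("far", q.precursor_mz + 1.0, mode="positive",
                       peaks=q.peaks)
        assert library_search([q], [far]) == []


class TestExtractionOverlap:
    def table_from(self, detected, all_ids, sample="s"):
        areas = pd.DataFrame(
            {sample: [1.0 if f in detected else 0.0 for f in all_ids]},
            index=all_ids)
        meta = pd.DataFrame({"mz": 100.0, "rt": 1.0}, index=all_ids)
        return FeatureTable(areas, meta)

    def test_half_shared(self):
        ids = ["f1", "f2", "f3", "f4"]
        out = extraction_overlap({
            "etoac": self.table_from({"f1", "f2", "f3"}, ids),
            "hydro": self.table_from({"f2", "f3", "f4"}, ids)})
        row = out.set_index("region")
        assert row.loc["etoac&hydro", "count"] == 2
        assert row.loc["etoac&hydro", "percent"] == pytest.approx(50.0)

    def test_identical_tables_fully_shared(self):
        ids = ["f1", "f2"]
        t = self.table_from({"f1", "f2"}, ids)
        out = extraction_overlap({"a": t, "b": t}).set_index("region")
        assert out.loc["a&b", "percent"] == pytest.approx(100.0)

    def test_disjoint_tables_share_nothing(self):
        ids = ["f1", "f2"]
        out = extraction_overlap({
            "a": self.table_from({"f1"}, ids),
            "b": self.table_from({"f2"}, ids)}).set_index("region")
        assert out.loc["a&b", "percent"] == pytest.approx(0.0)


class TestNetworkIO:
    def small_net(self):
        g = nx.Graph()
        g.add_node("f1", precursor_mz=400.123456, rt=1.0, node_size=10.0,
                   zero_area=False, clade_abundance='{"A": 1.0}', annotation="")
        g.add_node("f2", precursor_mz=500.5, rt=2.0, node_size=3.0,
                   zero_area=False, clade_abundance='{"B": 1.0}', annotation="")
        g.add_node("f3", precursor_mz=600.0, rt=3.0, node_size=1.0,
                   zero_area=True, clade_abundance="{}", annotation="")
        g.add_edge("f1", "f2", cosine=0.876543, n_matched=5)
        return g

    @pytest.mark.parametrize("fmt", ["graphml", "edge_tsv"])
    def test_round_trip_edges(self, fmt, tmp_path):
        g = self.small_net()
        path = tmp_path / f"net.{fmt}"
        write_network(g, path, fmt)
        back = read_network(path, fmt)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for u, v in g.edges:
            assert back.edges[u, v]["cosine"] == pytest.approx(
                g.edges[u, v]["cosine"], abs=1e-6)
            assert back.edges[u, v]["n_matched"] == g.edges[u, v]["n_matched"]

    def test_graphml_preserves_node_attributes(self, tmp_path):
        g = self.small_net()
        write_network(g, tmp_path / "n.graphml", "graphml")
        back = read_network(tmp_path / "n.graphml", "graphml")
        assert set(back.nodes) == set(g.nodes)
        for n in g.nodes:
            assert back.nodes[n]["precursor_mz"] == pytest.approx(
                g.nodes[n]["precursor_mz"], abs=1e-6)
            assert back.nodes[n]["clade_abundance"] == g.nodes[n]["clade_abundance"]

    def test_empty_network_is_valid(self, tmp_path):
        g = nx.Graph()
        write_network(g, tmp_path / "e.graphml", "graphml")
        assert read_network(tmp_path / "e.graphml").number_of_nodes() == 0

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_network(nx.Graph(), tmp_path / "x", "gexf")
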