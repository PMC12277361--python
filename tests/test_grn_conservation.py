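"""Orthogroup-space edge mapping, conservation strata, permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from stressnet.core_io import DEGTable, OrthogroupMap
from stressnet.grn_conservation import (
    OGEdgeSet,
    conserved_edges,
    edge_enrichment,
    export_graphml,
    map_edges_to_og,
    stress_specific_edges,
)


@pytest.fixture
def toy_ogmap():
    return OrthogroupMap(
        assignments={
            ("A", "a_tf"): "OGT",
            ("B", "b_tf"): "OGT",
            ("C", "c_tf"): "OGT",
            ("A", "a_g1"): "OG1",
            ("A", "a_g1b"): "OG1",
            ("B", "b_g1"): "OG1",
            ("C", "c_g1"): "OG1",
            ("A", "a_g2"): "OG2",
            ("B", "b_g2"): "OG2",
        }
    )


def _edge_table(pairs):
    return pd.DataFrame([{"tf": tf, "target": tg, "weight": 1.0} for tf, tg in pairs])


class TestMapEdgesToOg:
    def test_basic_mapping(self, toy_ogmap):
        out = map_edges_to_og({"A": _edge_table([("a_tf", "a_g1")])}, toy_ogmap)
        assert ("OGT", "OG1") in out.edges
        assert out.species_support(("OGT", "OG1")) == {"A"}

    def test_two_realizations_collapse(self, toy_ogmap):
        out = map_edges_to_og(
            {"A": _edge_table([("a_tf", "a_g1"), ("a_tf", "a_g1b")])}, toy_ogmap
        )
        assert len(out.edges) == 1
        assert len(out.edges[("OGT", "OG1")]["A"]) == 2

    def test_unmapped_endpoint_goes_to_leftovers(self, toy_ogmap):
        out = map_edges_to_og(
            {"A": _edge_table([("a_tf", "orphan")])}, toy_ogmap
        )
        assert out.edges == {}
        assert len(out.leftovers) == 1
        assert out.leftovers["target"].iloc[0] == "orphan"


class TestConservedEdges:
    def _og_edges(self, toy_ogmap):
        return map_edges_to_og(
            {
                "A": _edge_table([("a_tf", "a_g1"), ("a_tf", "a_g2")]),
                "B": _edge_table([("b_tf", "b_g1")]),
                "C": _edge_table([("c_tf", "c_g1")]),
            },
            toy_ogmap,
        )

    def test_strata_counts(self, toy_ogmap):
        og_edges = self._og_edges(toy_ogmap)
        assert og_edges.strata_counts(3) == {1: 1, 2: 0, 3: 1}

    def test_min_species_filter(self, toy_ogmap):
        og_edges = self._og_edges(toy_ogmap)
        assert set(conserved_edges(og_edges, 2).edges) == {("OGT", "OG1")}
        assert set(conserved_edges(og_edges, 3).edges) == {("OGT", "OG1")}
        # min_species=1 returns the union; counts are monotone
        assert set(conserved_edges(og_edges, 1).edges) == set(og_edges.edges)
        sizes = [len(conserved_edges(og_edges, m).edges) for m in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)


def _deg(species, experiment, level, up=(), down=()):
    rows = [
        {"gene": g, "log2FC": 2.0, "p_adj": 0.01, "direction": "up"} for g in up
    ] + [
        {"gene": g, "log2FC": -2.0, "p_adj": 0.01, "direction": "down"} for g in down
    ]
    return DEGTable(
        table=pd.DataFrame(rows, columns=["gene", "log2FC", "p_adj", "direction"]),
        species=species,
        experiment=experiment,
        level=level,
    )


class TestStressSpecificEdges:
    CATS = {("phosphate", "0%"): "deficient", ("nitrogen", "0%"): "deficient"}

    def _conserved(self, toy_ogmap):
        return conserved_edges(
            map_edges_to_og(
                {
                    "A": _edge_table([("a_tf", "a_g1")]),
                    "B": _edge_table([("b_tf", "b_g1")]),
                },
                toy_ogmap,
            ),
            min_species=2,
        )

    def test_matching_pattern_in_two_species(self, toy_ogmap):
        degs = {
            "A": {("phosphate", "0%"): _deg("A", "phosphate", "0%", up=("a_tf", "a_g1"))},
            "B": {("phosphate", "0%"): _deg("B", "phosphate", "0%", up=("b_tf", "b_g1"))},
        }
        edges, tfs = stress_specific_edges(self._conserved(toy_ogmap), degs, self.CATS)
        assert len(edges) == 1
        row = edges.iloc[0]
        assert (row["experiment"], row["category"]) == ("phosphate", "deficient")
        assert (row["tf_direction"], row["target_direction"]) == ("up", "up")
        assert set(tfs["tf"]) == {"a_tf", "b_tf"}

    def test_tf_direction_mismatch_excluded(self, toy_ogmap):
        degs = {
            "A": {("phosphate", "0%"): _deg("A", "phosphate", "0%", up=("a_tf", "a_g1"))},
            "B": {("phosphate", "0%"): _deg("B", "phosphate", "0%", up=("b_g1",), down=("b_tf",))},
        }
        edges, _ = stress_specific_edges(self._conserved(toy_ogmap), degs, self.CATS)
        assert edges.empty

    def test_different_categories_excluded(self, toy_ogmap):
        degs = {
            "A": {("phosphate", "0%"): _deg("A", "phosphate", "0%", up=("a_tf", "a_g1"))},
            "B": {("nitrogen", "0%"): _deg("B", "nitrogen", "0%", up=("b_tf", "b_g1"))},
        }
        edges, _ = stress_specific_edges(self._conserved(toy_ogmap), degs, self.CATS)
        assert edges.empty

    def test_target_only_mode(self, toy_ogmap):
        degs = {
            "A": {("phosphate", "0%"): _deg("A", "phosphate", "0%", up=("a_g1",))},
            "B": {("phosphate", "0%"): _deg("B", "phosphate", "0%", up=("b_g1",))},
        }
        strict, _ = stress_specific_edges(self._conserved(toy_ogmap), degs, self.CATS)
        assert strict.empty
        loose, _ = stress_specific_edges(
            self._conserved(toy_ogmap), degs, self.CATS, require_both_endpoints=False
        )
        assert len(loose) == 1
        assert loose["tf_direction"].iloc[0] == "any"

    def test_stress_specific_subset_of_conserved(self, toy_ogmap):
        degs = {
            "A": {("phosphate", "0%"): _deg("A", "phosphate", "0%", up=("a_tf", "a_g1"))},
            "B": {("phosphate", "0%"): _deg("B", "phosphate", "0%", up=("b_tf", "b_g1"))},
        }
        conserved = self._conserved(toy_ogmap)
        edges, _ = stress_specific_edges(conserved, degs, self.CATS)
        keys = set(zip(edges["tf_og"], edges["target_og"]))
        assert keys <= set(conserved.edges)


class TestEdgeEnrichment:
    def test_enrichment_ratio_arithmetic(self):
        """observed / permuted_mean is reported as the enrichment score."""
        rng = np.random.default_rng(0)
        # two species sharing an orthology of 40 single-copy OGs
        assignments = {}
        for i in range(40):
            assignments[("A", f"a{i}")] = f"OG{i}"
            assignments[("B", f"b{i}")] = f"OG{i}"
        ogmap = OrthogroupMap(assignments=assignments)
        edges = {
            "A": _edge_table([(f"a{i}", f"a{i+10}") for i in range(8)]),
            "B": _edge_table([(f"b{i}", f"b{i+10}") for i in range(8)]),
        }
        out = edge_enrichment(edges, ogmap, n_perm=200, seed=1)
        row = out[out["scope"] == "A|B"].iloc[0]
        assert row["observed"] == 8
        assert row["enrichment"] == pytest.approx(
            row["observed"] / row["permuted_mean"]
        )
        assert row["significant"]

    def test_planted_conserved_edges_enriched(self, demo_study, demo_degs):
        """Top-edge networks of the synthetic study show significant
        orthology-level conservation driven by the planted edges."""
        from stressnet.grn import infer_grn, top_edges

        tops = {}
        for sp in demo_study.config.species:
            union = set()
            for d in demo_degs[sp].values():
                union |= d.genes()
            tfs = [t for t in demo_study.tfs.tfs_of(sp) if t in union]
            expr = demo_study.tpm[sp].values.loc[sorted(union)]
            edges = infer_grn(expr, tfs, n_trees=100, seed=3, method="FAST-ET")
            tops[sp] = top_edges(edges, 0.05)
        out = edge_enrichment(tops, demo_study.ogmap, n_perm=500, seed=4)
        row = out[out["scope"] == "all"].iloc[0]
        assert row["enrichment"] > 1
        assert row["significant"]

    def test_scrambled_orthology_collapses_enrichment(self, demo_study, demo_degs):
        """Permuting the true gene->OG map destroys the conserved signal."""
        from stressnet.grn import infer_grn, top_edges

        tops = {}
        for sp in demo_study.config.species:
            union = set()
            for d in demo_degs[sp].values():
                union |= d.genes()
            tfs = [t for t in demo_study.tfs.tfs_of(sp) if t in union]
            expr = demo_study.tpm[sp].values.loc[sorted(union)]
            edges = infer_grn(expr, tfs, n_trees=100, seed=3, method="FAST-ET")
            tops[sp] = top_edges(edges, 0.05)
        rng = np.random.default_rng(9)
        scrambled = {}
        by_species = {}
        for (sp, g), og in demo_study.ogmap.assignments.items():
            by_species.setdefault(sp, []).append((g, og))
        for sp, pairs in by_species.items():
            genes = [g for g, _ in pairs]
            ogs = [og for _, og in pairs]
            rng.shuffle(ogs)
            for g, og in zip(genes, ogs):
                scrambled[(sp, g)] = og
        out = edge_enrichment(tops, OrthogroupMap(assignments=scrambled),
                              n_perm=300, seed=5)
        row = out[out["scope"] == "all"].iloc[0]
        # a single seed's ratio is noisy (small counts); the signal test is
        # that the observed count sits inside its own permutation null
        assert row["p_perm"] > 0.05
        assert not row["significant"]


def test_graphml_export_round_trip(tmp_path):
    import networkx as nx

    edges = pd.DataFrame(
        [
            {"tf_og": "OGT", "target_og": "OG1", "category": "deficient",
             "n_species": 2},
        ]
    )
    path = tmp_path / "net.graphml"
    export_graphml(edges, path)
    g = nx.read_graphml(path)
    assert g.has_edge("OGT", "OG1")
    assert g.edges["OGT", "OG1"]["category"] == "deficient"
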