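"""TF target-function scoring, R(m,g), and reference-species matching."""

import numpy as np
import pandas as pd
import pytest

from stressnet.core_io import BinHierarchy
from stressnet.tf_function import (
    default_lexicon,
    family_terms,
    read_lexicon,
    reference_function_match,
    regulatory_strength,
    tf_bin_network,
    write_lexicon,
)


def _bins(spec: dict, species="A") -> BinHierarchy:
    h = BinHierarchy()
    for code, genes in spec.items():
        for g in genes:
            h.add_gene(species, g, code, f"bin {code}")
    return h


def _tops(spec: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tf": tf, "target": t, "weight": 1.0} for tf, targets in spec.items() for t in targets]
    )


class TestTfBinNetwork:
    def test_target_coverage_ratio(self):
        bins = _bins({"1.1.1.1": ["g1", "g2", "g3", "g4"]})
        tf_bins = tf_bin_network(
            {"A": ["tf1"]}, {"A": _tops({"tf1": ["g1", "g2", "x"]})}, bins
        )
        row = tf_bins[tf_bins["bin_code"] == "1.1.1.1"].iloc[0]
        assert row["normalized"] == pytest.approx(0.5)

    def test_no_targets_in_bin_omitted(self):
        bins = _bins({"1.1.1.1": ["g1"], "2.1.1.1": ["h1"]})
        tf_bins = tf_bin_network(
            {"A": ["tf1"]}, {"A": _tops({"tf1": ["g1"]})}, bins
        )
        assert "2.1.1.1" not in set(tf_bins["bin_code"])

    def test_emitted_at_every_level(self):
        bins = _bins({"1.2.3.1": ["g1", "g2"]})
        tf_bins = tf_bin_network(
            {"A": ["tf1"]}, {"A": _tops({"tf1": ["g1"]})}, bins
        )
        assert set(tf_bins["bin_level"]) == {1, 2, 3, 4}

    def test_family_term_inner_sum(self):
        """Two family TFs at 0.5 and 0.25 coverage with T_i=2 give 0.375."""
        bins = _bins({"1.1.1.1": ["g1", "g2", "g3", "g4"]})
        tf_bins = tf_bin_network(
            {"A": ["tf1", "tf2"]},
            {"A": _tops({"tf1": ["g1", "g2"], "tf2": ["g3"]})},
            bins,
        )
        terms = family_terms(
            tf_bins,
            {("A", "tf1"): "WRKY", ("A", "tf2"): "WRKY"},
            {("A", "WRKY"): 2},
        )
        val = terms[terms["bin_code"] == "1.1.1.1"]["term"].iloc[0]
        assert val == pytest.approx((0.5 + 0.25) / 2)


class TestRegulatoryStrength:
    def _terms(self, vals: dict) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": sp, "family": "WRKY", "bin_code": "1", "bin_level": 1,
                 "term": v}
                for sp, v in vals.items()
            ]
        )

    def test_hand_evaluated_mean(self):
        terms = self._terms({"A": 0.375, "B": 1.0})
        out = regulatory_strength(terms, ["A", "B", "C"])
        assert out["R"].iloc[0] == pytest.approx((0.375 + 1.0 + 0.0) / 3)

    def test_full_coverage_upper_bound(self):
        terms = self._terms({"A": 1.0, "B": 1.0, "C": 1.0})
        out = regulatory_strength(terms, ["A", "B", "C"])
        assert out["R"].iloc[0] == pytest.approx(1.0)

    def test_family_absent_everywhere_omitted(self):
        out = regulatory_strength(
            pd.DataFrame(columns=["species", "family", "bin_code", "bin_level", "term"]),
            ["A", "B", "C"],
        )
        assert out.empty

    def test_shrink_s_variant(self):
        terms = self._terms({"A": 0.6})
        out = regulatory_strength(
            terms, ["A", "B", "C"], shrink_s=True,
            conserved_counts={("A", "WRKY"): 2},
        )
        assert out["R"].iloc[0] == pytest.approx(0.6)
        assert out["S"].iloc[0] == 1

    def test_duplicating_a_species_does_not_inflate(self):
        """R is a mean over species, not a sum."""
        terms3 = self._terms({"A": 0.3, "B": 0.6, "C": 0.9})
        r3 = regulatory_strength(terms3, ["A", "B", "C"])["R"].iloc[0]
        dup = pd.concat([terms3, self._terms({"D": 0.3})], ignore_index=True)
        dup.loc[dup["species"] == "D", "term"] = 0.6  # duplicate of B
        r4 = regulatory_strength(dup, ["A", "B", "C", "D"])["R"].iloc[0]
        assert abs(r4 - r3) < 0.2
        assert r4 == pytest.approx((0.3 + 0.6 + 0.9 + 0.6) / 4)

    def test_matches_double_loop_oracle(self, demo_study, demo_degs):
        """R(m,g) equals a from-scratch loop over (species, TF, target)."""
        from stressnet.grn import infer_grn, top_edges

        study = demo_study
        tops, conserved = {}, {}
        for sp in study.config.species:
            union = set()
            for d in demo_degs[sp].values():
                union |= d.genes()
            tfs = [t for t in study.tfs.tfs_of(sp) if t in union]
            expr = study.tpm[sp].values.loc[sorted(union)]
            tops[sp] = top_edges(
                infer_grn(expr, tfs, n_trees=50, seed=1, method="FAST-ET"), 0.05
            )
            conserved[sp] = tfs  # treat every present TF as conserved
        fams = {
            (r.species, r.gene_id): r.family
            for r in study.tfs.table.itertuples(index=False)
        }
        counts = {}
        for sp in study.config.species:
            for tf in conserved[sp]:
                key = (sp, fams[(sp, tf)])
                counts[key] = counts.get(key, 0) + 1
        tf_bins = tf_bin_network(conserved, tops, study.bins)
        terms = family_terms(tf_bins, fams, counts)
        strength = regulatory_strength(terms, list(study.config.species))
        # oracle: direct double loop for 20 sampled (family, bin) rows
        targets_of = {
            sp: {tf: set(g["target"]) for tf, g in tops[sp].groupby("tf")}
            for sp in tops
        }
        sample = strength.sample(min(20, len(strength)), random_state=0)
        for row in sample.itertuples(index=False):
            per_species = []
            for sp in study.config.species:
                fam_tfs = [tf for tf in conserved[sp] if fams[(sp, tf)] == row.family]
                if not fam_tfs:
                    per_species.append(0.0)
                    continue
                total = 0.0
                members = study.bins.gene_set(sp, row.bin_code)
                for tf in fam_tfs:
                    t = len(targets_of[sp].get(tf, set()) & members)
                    total += t / len(members)
                per_species.append(total / len(fam_tfs))
            assert row.R == pytest.approx(np.mean(per_species))


class TestReferenceFunctionMatch:
    def _besthits(self, rows):
        return pd.DataFrame(
            rows, columns=["species", "gene_id", "ref_gene_id", "function_terms"]
        )

    def test_phosphate_starvation_match(self):
        tf_cats = {("A", "tf1"): {"phosphate|deficient"}}
        hits = self._besthits(
            [("A", "tf1", "REF1", ["cellular response to phosphate starvation"])]
        )
        matrix, summary = reference_function_match(tf_cats, hits, n_perm=100, seed=0)
        assert matrix["match"].iloc[0]
        assert summary["observed"] == 1

    def test_unrelated_annotation_no_match(self):
        tf_cats = {("A", "tf1"): {"nitrogen|deficient"}}
        hits = self._besthits([("A", "tf1", "REF1", ["response to light"])])
        matrix, _ = reference_function_match(tf_cats, hits, n_perm=100, seed=0)
        assert not matrix["match"].iloc[0]

    def test_perfect_table_is_enriched(self):
        lex = default_lexicon()
        cats = ["nitrogen|deficient", "phosphate|deficient", "potassium|deficient",
                "temperature|surplus", "photoperiod|deficient"]
        tf_cats = {("A", f"tf{i}"): {cats[i % 5]} for i in range(15)}
        hits = self._besthits(
            [
                ("A", f"tf{i}", f"REF{i}", [lex[cats[i % 5]][0]])
                for i in range(15)
            ]
        )
        _, summary = reference_function_match(tf_cats, hits, n_perm=1000, seed=1)
        assert summary["observed"] == 15
        assert summary["enrichment"] > 1
        assert summary["p_perm"] == pytest.approx(1 / 1001)

    def test_shuffled_hits_not_enriched(self):
        rng = np.random.default_rng(0)
        lex = default_lexicon()
        cats = ["nitrogen|deficient", "phosphate|deficient", "potassium|deficient",
                "temperature|surplus", "photoperiod|deficient"]
        tf_cats = {("A", f"tf{i}"): {cats[i % 5]} for i in range(30)}
        terms = [lex[cats[i % 5]][0] for i in range(30)]
        rng.shuffle(terms)
        hits = self._besthits(
            [("A", f"tf{i}", f"REF{i}", [terms[i]]) for i in range(30)]
        )
        _, summary = reference_function_match(tf_cats, hits, n_perm=500, seed=2)
        assert 0.5 <= summary["enrichment"] <= 1.6
        assert summary["p_perm"] > 0.05

    def test_identity_permutation_reproduces_observed(self):
        """A permutation that moves nothing counts exactly the observed matches."""
        tf_cats = {
            ("A", "tf1"): {"phosphate|deficient"},
            ("A", "tf2"): {"nitrogen|deficient"},
        }
        hits = self._besthits(
            [
                ("A", "tf1", "R1", ["phosphate starvation"]),
                ("A", "tf2", "R2", ["response to light"]),
            ]
        )
        m1, s1 = reference_function_match(tf_cats, hits, n_perm=50, seed=0)
        m2, s2 = reference_function_match(tf_cats, hits, n_perm=50, seed=0)
        assert s1["observed"] == s2["observed"] == int(m1["match"].sum())

    def test_tf_without_best_hit_dropped(self):
        tf_cats = {("A", "tf1"): {"phosphate|deficient"}, ("A", "tf2"): {"nitrogen|deficient"}}
        hits = self._besthits([("A", "tf1", "R1", ["phosphate starvation"])])
        with pytest.warns(UserWarning, match="without a best hit"):
            matrix, summary = reference_function_match(tf_cats, hits, n_perm=50, seed=0)
        assert summary["n_tfs"] == 1
        assert list(matrix["tf"]) == ["tf1"]

    def test_min_function_filter(self):
        tf_cats = {("A", "tf1"): {"phosphate|deficient"}}
        hits = self._besthits([("A", "tf1", "R1", ["phosphate starvation"])])
        _, summary = reference_function_match(
            tf_cats, hits, n_perm=50, seed=0,
            min_functions=5, tf_function_counts={("A", "tf1"): 3},
        )
        assert summary["n_tfs"] == 0


def test_lexicon_round_trip(tmp_path):
    lex = default_lexicon()
    write_lexicon(lex, tmp_path / "lex.tsv")
    assert read_lexicon(tmp_path / "lex.tsv") == lex
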