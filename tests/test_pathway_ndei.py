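"""Bin over-representation, NDEI and function-pair conservation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stressnet.core_io import BinHierarchy, DEGTable
from stressnet.pathway_ndei import (
    bin_significance,
    cluster_by_jaccard,
    compute_bin_counts,
    compute_ndei,
    conserved_function_pairs,
    ndei_correlation,
    significance_status_matrix,
    significance_table,
)


def _deg(genes_up, genes_down, species="A", experiment="nitrogen", level="0%"):
    rows = [
        {"gene": g, "log2FC": 2.0, "p_adj": 0.01, "direction": "up"}
        for g in genes_up
    ] + [
        {"gene": g, "log2FC": -2.0, "p_adj": 0.01, "direction": "down"}
        for g in genes_down
    ]
    return DEGTable(
        table=pd.DataFrame(rows, columns=["gene", "log2FC", "p_adj", "direction"]),
        species=species,
        experiment=experiment,
        level=level,
    )


def _bins(spec: dict, species="A") -> BinHierarchy:
    h = BinHierarchy()
    for code, genes in spec.items():
        for g in genes:
            h.add_gene(species, g, code, f"bin {code}")
    return h


class TestBinSignificance:
    def test_exact_combinatorial_example(self):
        """N=100, K=10, n=5, x=5 gives p = C(10,5)/C(100,5)."""
        universe = {f"g{i}" for i in range(100)}
        degs_up = [f"g{i}" for i in range(10)]
        bins = _bins({"1": [f"g{i}" for i in range(5)]})
        deg = _deg(degs_up, [])
        out = bin_significance(deg, bins, universe, "up")
        expected = math.comb(10, 5) / math.comb(100, 5)
        assert out.loc[out["bin_code"] == "1", "p_raw"].iloc[0] == pytest.approx(expected)

    def test_upper_tail_matches_enumeration_oracle(self):
        """Hypergeometric sf agrees with brute-force enumeration on random draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            N = int(rng.integers(10, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            degs_up = list(rng.choice(universe, K, replace=False))
            members = list(rng.choice(universe, n, replace=False))
            x = len(set(degs_up) & set(members))
            bins = _bins({"1": members})
            out = bin_significance(_deg(degs_up, []), bins, set(universe), "up")
            p = out.loc[out["bin_code"] == "1", "p_raw"].iloc[0]
            # brute force: sum over j >= x of C(K,j) C(N-K,n-j) / C(N,n)
            brute = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(x, min(K, n) + 1)
            ) / math.comb(N, n)
            assert p == pytest.approx(brute, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        bins = _bins({"1": ["g0", "g1"]})
        out = bin_significance(_deg(["g10", "g11"], []), bins, universe, "up")
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_no_degs_gives_p_one_everywhere(self):
        universe = {f"g{i}" for i in range(20)}
        bins = _bins({"1": ["g0", "g1"], "2": ["g2"]})
        out = bin_significance(_deg([], []), bins, universe, "up")
        assert (out["p_raw"] == 1.0).all()

    def test_both_direction_class(self):
        """A bin significant up and down in one condition is labelled both."""
        universe = {f"g{i}" for i in range(200)}
        bin_genes = [f"g{i}" for i in range(20)]
        bins = _bins({"1": bin_genes})
        deg = _deg(bin_genes[:10], bin_genes[10:])
        sig = significance_table({("nitrogen", "0%"): deg}, bins, universe)
        status = significance_status_matrix(sig)
        assert status.loc["1", "nitrogen:0%"] == "both"

    def test_bin_as_deg_set_attains_minimal_p(self):
        universe = {f"g{i}" for i in range(50)}
        bin_genes = [f"g{i}" for i in range(8)]
        bins = _bins({"1": bin_genes})
        out = bin_significance(_deg(bin_genes, []), bins, universe, "up")
        minimal = 1 / math.comb(50, 8)
        assert out["p_raw"].iloc[0] == pytest.approx(minimal)


class TestNdei:
    @pytest.mark.parametrize(
        "U,D,B,expected",
        [(3, 1, 10, 0.2), (4, 4, 9, 0.0), (10, 0, 10, 1.0), (0, 7, 7, -1.0)],
    )
    def test_formula(self, U, D, B, expected):
        counts = pd.DataFrame(
            [{"condition": "c", "experiment": "e", "level_label": "l",
              "bin_code": "1", "bin_level": 1, "U": U, "D": D, "B": B}]
        )
        assert compute_ndei(counts).loc["1", "c"] == pytest.approx(expected)

    def test_matches_brute_force_recount(self, demo_study, demo_degs):
        """NDEI equals a per-gene recount for every synthetic bin/condition."""
        sp = demo_study.config.species[0]
        counts = compute_bin_counts(demo_degs[sp], demo_study.bins, sp)
        ndei = compute_ndei(counts)
        rng = np.random.default_rng(0)
        rows = counts.sample(200, random_state=1)
        for row in rows.itertuples(index=False):
            deg = demo_degs[sp][(row.experiment, row.level_label)]
            members = demo_study.bins.gene_set(sp, row.bin_code)
            up = sum(1 for g in deg.genes("up") if g in members)
            down = sum(1 for g in deg.genes("down") if g in members)
            assert ndei.loc[row.bin_code, row.condition] == pytest.approx(
                (up - down) / len(members)
            )

    def test_values_bounded(self, demo_study, demo_degs):
        sp = demo_study.config.species[0]
        ndei = compute_ndei(compute_bin_counts(demo_degs[sp], demo_study.bins, sp))
        vals = ndei.to_numpy()
        assert np.nanmin(vals) >= -1.0 and np.nanmax(vals) <= 1.0

    def test_sign_matches_planted_direction(self, demo_study, demo_degs):
        """Bins holding planted-up orthogroups get positive NDEI under the stress."""
        truth = demo_study.truth
        sp = demo_study.config.species[0]
        counts = compute_bin_counts(demo_degs[sp], demo_study.bins, sp)
        ndei = compute_ndei(counts)
        checked = 0
        signed: list[float] = []
        for (exp, cat, direction), ogs in truth.conserved_ogs.items():
            for og in ogs:
                genes = demo_study.ogmap.members_of_species(og, sp)
                bins_of = set.union(*(demo_study.bins.bins_of_gene(sp, g) for g in genes))
                terminal = [b for b in bins_of if BinHierarchy.level(b) == 4]
                conds = [
                    f"{e}:{l}"
                    for (e, l, c) in [
                        (r.experiment, r.level, r.category)
                        for r in demo_study.counts[sp].design.drop_duplicates(
                            ["experiment", "level"]
                        ).itertuples(index=False)
                    ]
                    if e == exp and c == cat
                ]
                sign = 1 if direction == "up" else -1
                signed.extend(
                    ndei.loc[b, cond] * sign for b in terminal for cond in conds
                )
                checked += 1
        assert checked > 0
        # another planted gene sharing a small bin can dilute single entries;
        # the dominant planted direction must still carry the sign overall
        signed = np.array(signed)
        assert signed.mean() > 0
        # exact-zero entries (U == D cancellation) are neutral, not wrong
        assert np.mean(signed < 0) <= 0.1


class TestNdeiCorrelation:
    def test_identical_and_negated_vectors(self):
        ndei = pd.DataFrame(
            {
                "c1": [0.1, 0.1, -0.1],
                "c2": [0.5, 0.5, -0.5],
                "c3": [-0.2, -0.2, 0.2],
                "c4": [0.9, 0.9, -0.9],
            },
            index=["1", "2", "3"],
        )
        edges = ndei_correlation(ndei, bin_level=1).set_index(["bin_a", "bin_b"])
        assert edges.loc[("1", "2"), "pcc"] == pytest.approx(1.0)
        assert edges.loc[("1", "3"), "pcc"] == pytest.approx(-1.0)
        assert edges.loc[("1", "2"), "sign"] == "positive"
        assert edges.loc[("1", "3"), "sign"] == "negative"

    def test_matches_hand_pcc(self):
        a = np.array([0.1, 0.4, -0.3, 0.2])
        b = np.array([0.0, 0.5, -0.1, -0.2])
        ndei = pd.DataFrame([a, b], index=["1", "2"], columns=list("wxyz"))
        edges = ndei_correlation(ndei, bin_level=1)
        hand = ((a - a.mean()) * (b - b.mean())).mean() / (a.std() * b.std())
        assert edges["pcc"].iloc[0] == pytest.approx(hand)

    def test_constant_vector_excluded(self):
        ndei = pd.DataFrame(
            {"c1": [0.1, 0.2], "c2": [0.1, 0.5], "c3": [0.1, -0.3]},
            index=["1", "2"],
        )
        assert len(ndei_correlation(ndei, bin_level=1)) == 0

    def test_too_few_conditions_skipped(self):
        ndei = pd.DataFrame(
            {"c1": [0.1, 0.2], "c2": [0.3, 0.5]}, index=["1", "2"]
        )
        assert len(ndei_correlation(ndei, bin_level=1, min_conditions=3)) == 0


def _sig_frame(species, entries):
    """entries: list of (condition, bin, direction) significant hits."""
    rows = []
    for cond, code, direction in entries:
        exp, lvl = cond.split(":")
        rows.append(
            {
                "species": species,
                "condition": cond,
                "experiment": exp,
                "level_label": lvl,
                "bin_code": code,
                "bin_level": 1,
                "direction": direction,
                "p_adj": 0.001,
                "significant": True,
            }
        )
    return pd.DataFrame(rows)


class TestConservedFunctionPairs:
    def _three_species_tables(self, conditions):
        entries = [(c, b, "up") for c in conditions for b in ("1", "2")]
        return {sp: _sig_frame(sp, entries) for sp in ("A", "B", "C")}

    def test_pair_kept_at_five_conditions(self):
        conds = ["nitrogen:0%", "phosphate:0%", "potassium:0%", "nitrogen:25%", "phosphate:25%"]
        out = conserved_function_pairs(
            self._three_species_tables(conds), min_species=3, min_conditions=5
        )
        assert len(out) == 1
        assert out["conserved_condition_count"].iloc[0] == 5

    def test_two_species_dropped_at_min_three(self):
        conds = ["nitrogen:0%", "phosphate:0%", "potassium:0%", "nitrogen:25%", "phosphate:25%"]
        tables = self._three_species_tables(conds)
        tables["C"] = _sig_frame("C", [])
        assert conserved_function_pairs(tables, min_species=3, min_conditions=5).empty
        # but the same data passes at min_species=2 (both thresholds are knobs)
        out = conserved_function_pairs(tables, min_species=2, min_conditions=5)
        assert len(out) == 1
        assert out["species_support"].iloc[0] == "A;B"

    def test_direction_must_match(self):
        conds = ["nitrogen:0%"] * 1
        entries_up = [("nitrogen:0%", "1", "up"), ("nitrogen:0%", "2", "down")]
        tables = {sp: _sig_frame(sp, entries_up) for sp in ("A", "B", "C")}
        assert conserved_function_pairs(tables, min_species=3, min_conditions=1).empty


def test_cluster_by_jaccard_orders_rows():
    mat = pd.DataFrame(
        {"c1": [1, 1, 0], "c2": [1, 1, 0], "c3": [0, 0, 1]},
        index=["a", "b", "c"],
    )
    linkage_matrix, labels = cluster_by_jaccard(mat)
    assert labels == ["a", "b", "c"]
    assert linkage_matrix.shape == (2, 4)
    # a and b are identical -> merged first at distance 0
    assert linkage_matrix[0, 2] == pytest.approx(0.0)
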