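"""Cross-species GRN comparison in orthogroup space.

Retained TF -> target edges of each species' network are lifted to
orthogroup (OG) pairs; an OG-level edge is conserved when realized in the
retained networks of at least two species. Conserved edges are further
restricted to stress-specific ones — both endpoint genes differentially
expressed under the same surplus/deficient stress category with the same
direction pattern in at least two species — and the TFs of the surviving
edges form the stress-specific conserved TF roster. Significance of the
conserved-edge count comes from shuffling the gene -> orthogroup
assignment within each species (preserving network topology and OG sizes):
enrichment = observed / mean permuted, significant when BH-adjusted
p < 0.05 and enrichment > 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import Category, DEGTable, OrthogroupMap
from .diffexp import bh_adjust

__all__ = [
    "OGEdgeSet",
    "map_edges_to_og",
    "conserved_edges",
    "stress_specific_edges",
    "edge_enrichment",
    "export_graphml",
]


@dataclass
class OGEdgeSet:
    """Directed OG-level edges with their per-species gene realizations.

    ``edges[(tf_og, target_og)][species]`` lists the concrete
    (tf_gene, target_gene) pairs realizing the edge in that species'
    retained network; ``leftovers`` records gene-level edges that could
    not be mapped because an endpoint has no orthogroup.
    """

    edges: dict[tuple[str, str], dict[str, list[tuple[str, str]]]]
    leftovers: pd.DataFrame

    def species_support(self, key: tuple[str, str]) -> set[str]:
        return set(self.edges.get(key, {}))

    def strata_counts(self, n_species: int) -> dict[int, int]:
        counts = {k: 0 for k in range(1, n_species + 1)}
        for realizations in self.edges.values():
            counts[len(realizations)] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tf_og, tg_og), realizations in sorted(self.edges.items()):
            rows.append(
                {
                    "tf_og": tf_og,
                    "target_og": tg_og,
                    "n_species": len(realizations),
                    "species_support": ";".join(sorted(realizations)),
                    "realizations": ";".join(
                        f"{sp}:{tf}->{tg}"
                        for sp in sorted(realizations)
                        for tf, tg in realizations[sp]
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["tf_og", "target_og", "n_species", "species_support", "realizations"],
        )


def map_edges_to_og(
    edges_per_species: Mapping[str, pd.DataFrame], ogmap: OrthogroupMap
) -> OGEdgeSet:
    """Lift retained gene-level edges to orthogroup pairs.

    An OG edge exists for a species iff at least one retained gene-level
    edge realizes it; several realizations collapse onto one OG edge.
    """
    edges: dict[tuple[str, str], dict[str, list[tuple[str, str]]]] = {}
    leftover_rows = []
    for species, table in edges_per_species.items():
        for row in table.itertuples(index=False):
            tf_og = ogmap.og_of(species, row.tf)
            tg_og = ogmap.og_of(species, row.target)
            if tf_og is None or tg_og is None:
                leftover_rows.append(
                    {"species": species, "tf": row.tf, "target": row.target}
                )
                continue
            edges.setdefault((tf_og, tg_og), {}).setdefault(species, []).append(
                (row.tf, row.target)
            )
    leftovers = pd.DataFrame(leftover_rows, columns=["species", "tf", "target"])
    return OGEdgeSet(edges=edges, leftovers=leftovers)


def conserved_edges(og_edges: OGEdgeSet, min_species: int = 2) -> OGEdgeSet:
    """OG edges realized in at least ``min_species`` species."""
    kept = {
        key: realizations
        for key, realizations in og_edges.edges.items()
        if len(realizations) >= min_species
    }
    return OGEdgeSet(edges=kept, leftovers=og_edges.leftovers)


def _deg_direction(
    deg_tables: Mapping[tuple[str, str], DEGTable],
    gene: str,
    conditions: Sequence[tuple[str, str]],
) -> dict[str, set[tuple[str, str]]]:
    """Directions (with supporting conditions) a gene shows among conditions."""
    out: dict[str, set[tuple[str, str]]] = {}
    for cond in conditions:
        deg = deg_tables.get(cond)
        if deg is None:
            continue
        for direction in ("up", "down"):
            if gene in deg.genes(direction):
                out.setdefault(direction, set()).add(cond)
    return out


def stress_specific_edges(
    conserved: OGEdgeSet,
    deg_tables: Mapping[str, Mapping[tuple[str, str], DEGTable]],
    categories: Mapping[tuple[str, str], str],
    min_species: int = 2,
    require_both_endpoints: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conserved edges whose endpoints respond to the same stress category.

    An edge is stress-specific for a category (experiment, surplus|deficient)
    when, in at least ``min_species`` of its supporting species, a
    realization has the TF and the target both DE under some condition of
    that category with the same (TF-direction, target-direction) pattern
    across those species. With ``require_both_endpoints=False`` only the
    target must be DE (the TF's direction slot is then "any").

    Returns (edge table, stress-specific conserved TF roster).
    """
    cat_conditions: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for cond, cat in categories.items():
        if cat in (Category.DEFICIENT.value, Category.SURPLUS.value):
            cat_conditions.setdefault((cond[0], cat), []).append(cond)
    edge_rows = []
    tf_rows = []
    for (tf_og, tg_og), realizations in sorted(conserved.edges.items()):
        for (exp, cat), conds in sorted(cat_conditions.items()):
            # pattern -> supporting species and their realizing gene pairs
            by_pattern: dict[tuple[str, str], dict[str, list[tuple[str, str]]]] = {}
            for species, pairs in realizations.items():
                degs = deg_tables.get(species, {})
                for tf_gene, tg_gene in pairs:
                    tf_dirs = _deg_direction(degs, tf_gene, conds)
                    tg_dirs = _deg_direction(degs, tg_gene, conds)
                    for tg_dir, tg_conds in tg_dirs.items():
                        if require_both_endpoints:
                            for tf_dir, tf_conds in tf_dirs.items():
                                if tf_conds & tg_conds:
                                    by_pattern.setdefault(
                                        (tf_dir, tg_dir), {}
                                    ).setdefault(species, []).append((tf_gene, tg_gene))
                        else:
                            by_pattern.setdefault(("any", tg_dir), {}).setdefault(
                                species, []
                            ).append((tf_gene, tg_gene))
            for pattern, support in sorted(by_pattern.items()):
                if len(support) < min_species:
                    continue
                edge_rows.append(
                    {
                        "tf_og": tf_og,
                        "target_og": tg_og,
                        "experiment": exp,
                        "category": cat,
                        "tf_direction": pattern[0],
                        "target_direction": pattern[1],
                        "n_species": len(support),
                        "species_support": ";".join(sorted(support)),
                    }
                )
                for species, pairs in support.items():
                    for tf_gene, _ in pairs:
                        tf_rows.append(
                            {
                                "species": species,
                                "tf": tf_gene,
                                "tf_og": tf_og,
                                "experiment": exp,
                                "category": cat,
                            }
                        )
    edge_df = pd.DataFrame(
        edge_rows,
        columns=[
            "tf_og",
            "target_og",
            "experiment",
            "category",
            "tf_direction",
            "target_direction",
            "n_species",
            "species_support",
        ],
    )
    tf_df = pd.DataFrame(
        tf_rows, columns=["species", "tf", "tf_og", "experiment", "category"]
    ).drop_duplicates(ignore_index=True)
    return edge_df, tf_df


def _conserved_count(
    edge_ogs: Mapping[str, list[tuple[str, str]]], min_species: int
) -> int:
    """Count OG pairs present in >= min_species species' OG-edge sets."""
    tally: dict[tuple[str, str], int] = {}
    for og_pairs in edge_ogs.values():
        for pair in set(og_pairs):
            tally[pair] = tally.get(pair, 0) + 1
    return sum(1 for n in tally.values() if n >= min_species)


def edge_enrichment(
    edges_per_species: Mapping[str, pd.DataFrame],
    ogmap: OrthogroupMap,
    n_perm: int = 1000,
    seed: int = 0,
    min_species: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation enrichment of conserved OG-edge counts.

    Each permutation shuffles the gene -> orthogroup assignment within
    every species (preserving each network's topology and each species'
    OG size spectrum) and recounts conserved edges. One row per species
    pair plus an all-species row at ``min_species``; enrichment =
    observed / mean permuted, p by the plus-one estimator, BH across rows;
    significant requires p_adj < alpha and enrichment > 1.
    """
    rng = np.random.default_rng(seed)
    species = sorted(edges_per_species)
    # per species: assigned genes, their OG labels, and the gene-level edges
    genes_of = {sp: sorted(ogmap.genes_of_species(sp)) for sp in species}
    for sp in species:
        ogs = {ogmap.og_of(sp, g) for g in genes_of[sp]}
        if len(ogs) == len(genes_of[sp]):
            warnings.warn(
                f"all orthogroups of {sp} are singletons: permutation null is weak"
            )
    labels = {
        sp: np.array([ogmap.og_of(sp, g) for g in genes_of[sp]], dtype=object)
        for sp in species
    }
    index_of = {sp: {g: i for i, g in enumerate(genes_of[sp])} for sp in species}
    raw_edges = {
        sp: [
            (row.tf, row.target)
            for row in edges_per_species[sp].itertuples(index=False)
        ]
        for sp in species
    }

    def og_pairs(sp: str, mapping: np.ndarray) -> list[tuple[str, str]]:
        idx = index_of[sp]
        out = []
        for tf, tg in raw_edges[sp]:
            i, j = idx.get(tf), idx.get(tg)
            if i is None or j is None:
                continue
            out.append((mapping[i], mapping[j]))
        return out

    observed_pairs = {sp: og_pairs(sp, labels[sp]) for sp in species}

    scopes: list[tuple[str, list[str], int]] = [
        (f"{a}|{b}", [a, b], 2) for a, b in itertools.combinations(species, 2)
    ]
    if len(species) > 2:
        scopes.append(("all", species, min_species))
        scopes.append(("all_strict", species, len(species)))

    observed = {
        name: _conserved_count({sp: observed_pairs[sp] for sp in grp}, ms)
        for name, grp, ms in scopes
    }
    perm_counts = {name: np.zeros(n_perm) for name, _, _ in scopes}
    for it in range(n_perm):
        shuffled = {
            sp: og_pairs(sp, labels[sp][rng.permutation(len(labels[sp]))])
            for sp in species
        }
        for name, grp, ms in scopes:
            perm_counts[name][it] = _conserved_count(
                {sp: shuffled[sp] for sp in grp}, ms
            )
    rows = []
    for name, _grp, ms in scopes:
        perm = perm_counts[name]
        mean_perm = float(perm.mean())
        enr = observed[name] / mean_perm if mean_perm > 0 else np.inf
        p = (1 + int((perm >= observed[name]).sum())) / (1 + n_perm)
        rows.append(
            {
                "scope": name,
                "min_species": ms,
                "observed": observed[name],
                "permuted_mean": mean_perm,
                "enrichment": enr,
                "p_perm": p,
                "n_perm": n_perm,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (out["enrichment"] > 1)
    return out


def export_graphml(edges: pd.DataFrame, path, source: str = "tf_og",
                   target: str = "target_og") -> None:
    """Write an edge table as a directed GraphML graph.

    All remaining columns become edge attributes (NaNs dropped); node ids
    come from the ``source``/``target`` columns.
    """
    graph = nx.DiGraph()
    for row in edges.itertuples(index=False):
        attrs = {
            k: v
            for k, v in row._asdict().items()
            if k not in (source, target) and not (isinstance(v, float) and np.isnan(v))
        }
        graph.add_edge(getattr(row, source), getattr(row, target), **attrs)
    nx.write_graphml(graph, path)
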