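"""Functional-bin statistics: over-representation tests, NDEI, correlation.

NDEI (Normalized Differential Expression Index) summarizes how a functional
bin responds to a stress: (U - D) / B, where U and D are the numbers of up-
and downregulated genes of the bin under that stress and B is the bin size.
+1 means every bin gene is up, -1 every gene down, 0 a balanced (or absent)
response. Bin-level significance uses the hypergeometric upper tail
(survival function) of the DEG/bin overlap, per direction, BH-corrected.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core_io import BinHierarchy, DEGTable
from .diffexp import bh_adjust

__all__ = [
    "compute_bin_counts",
    "bin_significance",
    "significance_table",
    "compute_ndei",
    "ndei_correlation",
    "conserved_function_pairs",
    "significance_status_matrix",
    "cluster_by_jaccard",
]


def compute_bin_counts(
    deg_tables: Mapping[tuple[str, str], DEGTable],
    bins: BinHierarchy,
    species: str,
    level: int | None = None,
) -> pd.DataFrame:
    """Per (condition, bin) up/down DEG counts and bin sizes.

    Long table with columns condition, experiment, level_label, bin_code,
    bin_level, U, D, B. Bins with B = 0 are absent by construction.
    """
    rows = []
    codes = bins.bin_codes(level=level)
    for (exp, lvl), deg in deg_tables.items():
        up = deg.genes("up")
        down = deg.genes("down")
        for code in codes:
            members = bins.gene_set(species, code)
            if not members:
                continue
            rows.append(
                {
                    "condition": f"{exp}:{lvl}",
                    "experiment": exp,
                    "level_label": lvl,
                    "bin_code": code,
                    "bin_level": BinHierarchy.level(code),
                    "U": len(up & members),
                    "D": len(down & members),
                    "B": len(members),
                }
            )
    return pd.DataFrame(rows)


def bin_significance(
    deg: DEGTable,
    bins: BinHierarchy,
    universe: set[str],
    direction: str,
    level: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail p per bin for one condition and direction.

    p = P(X >= x) with population N = |universe|, successes K = DEGs of
    ``direction`` in the universe, draws n = bin genes in the universe and
    x = their overlap. Bins with no tested genes are skipped; K = 0 gives
    p = 1 for every bin.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    degs = deg.genes(direction) & universe
    N, K = len(universe), len(degs)
    rows = []
    for code in bins.bin_codes(level=level):
        members = bins.gene_set(deg.species, code) & universe
        n = len(members)
        if n == 0:
            continue
        x = len(members & degs)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append(
            {
                "bin_code": code,
                "bin_level": BinHierarchy.level(code),
                "direction": direction,
                "x": x,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": p,
            }
        )
    return pd.DataFrame(rows)


def significance_table(
    deg_tables: Mapping[tuple[str, str], DEGTable],
    bins: BinHierarchy,
    universe: set[str],
    alpha: float = 0.05,
    level: int | None = None,
) -> pd.DataFrame:
    """Bin over-representation for every condition, both directions.

    BH correction spans all bins and both directions within one condition.
    A bin significant both up and down in a condition is the "both" class;
    :func:`significance_status_matrix` surfaces it.
    """
    out = []
    for (exp, lvl), deg in deg_tables.items():
        parts = [
            bin_significance(deg, bins, universe, d, level=level)
            for d in ("up", "down")
        ]
        tab = pd.concat([p for p in parts if len(p)], ignore_index=True)
        if tab.empty:
            continue
        tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
        tab["significant"] = tab["p_adj"] < alpha
        tab.insert(0, "condition", f"{exp}:{lvl}")
        tab.insert(1, "experiment", exp)
        tab.insert(2, "level_label", lvl)
        tab.insert(0, "species", deg.species)
        out.append(tab)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def significance_status_matrix(sig: pd.DataFrame) -> pd.DataFrame:
    """Bin x condition status matrix: 'up', 'down', 'both' or '' (n.s.)."""
    piv = {}
    for (code, cond), grp in sig.groupby(["bin_code", "condition"]):
        dirs = set(grp.loc[grp["significant"], "direction"])
        status = "both" if dirs == {"up", "down"} else (dirs.pop() if dirs else "")
        piv.setdefault(code, {})[cond] = status
    return pd.DataFrame(piv).T.fillna("").sort_index()


def compute_ndei(bin_counts: pd.DataFrame) -> pd.DataFrame:
    """NDEI = (U - D) / B as a bins x conditions matrix.

    Entries for bins with B = 0 never appear (compute_bin_counts drops
    them); values are in [-1, 1] by construction.
    """
    counts = bin_counts.copy()
    counts["ndei"] = (counts["U"] - counts["D"]) / counts["B"]
    return counts.pivot_table(
        index="bin_code", columns="condition", values="ndei", sort=True
    )


def ndei_correlation(
    ndei: pd.DataFrame,
    bin_level: int,
    alpha: float = 0.05,
    min_conditions: int = 3,
) -> pd.DataFrame:
    """Pearson correlation between same-level bins across conditions.

    Pairs with fewer than ``min_conditions`` jointly defined conditions or
    a constant NDEI vector are skipped; p-values use the t-approximation
    with n - 2 df, BH-corrected across pairs.
    """
    codes = [c for c in ndei.index if BinHierarchy.level(c) == bin_level]
    rows = []
    sub = ndei.loc[codes]
    for i, a in enumerate(codes):
        va = sub.loc[a]
        for b in codes[i + 1 :]:
            vb = sub.loc[b]
            ok = va.notna() & vb.notna()
            n = int(ok.sum())
            if n < min_conditions:
                continue
            x, y = va[ok].to_numpy(), vb[ok].to_numpy()
            if x.max() == x.min() or y.max() == y.min():
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r_cl = min(max(r, -1.0), 1.0)
            if abs(r_cl) == 1.0:
                p = 0.0
            else:
                t = r_cl * np.sqrt((n - 2) / (1 - r_cl**2))
                p = float(2 * stats.t.sf(abs(t), n - 2))
            rows.append(
                {
                    "bin_a": a,
                    "bin_b": b,
                    "n_conditions": n,
                    "pcc": r,
                    "p_raw": p,
                    "sign": "positive" if r >= 0 else "negative",
                }
            )
    edges = pd.DataFrame(rows)
    if len(edges):
        edges["p_adj"] = bh_adjust(edges["p_raw"].to_numpy())
        edges["significant"] = edges["p_adj"] < alpha
    return edges


def conserved_function_pairs(
    sig_tables: Mapping[str, pd.DataFrame],
    categories: Mapping[tuple[str, str], str] | None = None,
    min_species: int = 3,
    min_conditions: int = 5,
    bin_level: int | None = 1,
) -> pd.DataFrame:
    """Bin pairs co-directionally significant across species.

    For every stress category, a condition supports a pair (a, b) when both
    bins are significantly over-represented in the same direction in at
    least ``min_species`` species under that condition; pairs kept when the
    supporting-condition count reaches ``min_conditions``. The count doubles
    as the edge-thickness attribute of a function-pair network.

    ``categories`` maps (experiment, level) to a category label; without it
    all conditions form one "all" category.
    """
    # per (condition, direction, species): set of significant bins
    sig_bins: dict[tuple[str, str, str], set[str]] = {}
    conditions: set[tuple[str, str]] = set()
    for species, tab in sig_tables.items():
        if tab.empty:
            continue
        t = tab[tab["significant"]]
        if bin_level is not None:
            t = t[t["bin_level"] == bin_level]
        for row in t.itertuples(index=False):
            key = (row.condition, row.direction, species)
            sig_bins.setdefault(key, set()).add(row.bin_code)
            conditions.add((row.experiment, row.level_label))
    species_list = list(sig_tables)
    support: dict[tuple[str, str, str], list[tuple[str, str, set[str]]]] = {}
    for (exp, lvl) in sorted(conditions):
        cond = f"{exp}:{lvl}"
        cat = categories.get((exp, lvl), "all") if categories else "all"
        for direction in ("up", "down"):
            per_species = {
                s: sig_bins.get((cond, direction, s), set()) for s in species_list
            }
            # candidate pairs from any single species' significant set
            candidates: set[tuple[str, str]] = set()
            for bins_ in per_species.values():
                ordered = sorted(bins_)
                for i, a in enumerate(ordered):
                    for b in ordered[i + 1 :]:
                        candidates.add((a, b))
            for a, b in candidates:
                supp = {s for s, bs in per_species.items() if a in bs and b in bs}
                if len(supp) >= min_species:
                    support.setdefault((a, b, cat), []).append(
                        (cond, direction, supp)
                    )
    rows = []
    for (a, b, cat), hits in sorted(support.items()):
        if len(hits) < min_conditions:
            continue
        all_species: set[str] = set()
        for _, _, supp in hits:
            all_species |= supp
        rows.append(
            {
                "bin_a": a,
                "bin_b": b,
                "category": cat,
                "conserved_condition_count": len(hits),
                "conditions": ";".join(f"{c}|{d}" for c, d, _ in hits),
                "species_support": ";".join(sorted(all_species)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin_a",
            "bin_b",
            "category",
            "conserved_condition_count",
            "conditions",
            "species_support",
        ],
    )


def cluster_by_jaccard(binary_matrix: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage hierarchical clustering on Jaccard distances.

    Presentation utility for ordering a bin x condition significance matrix;
    returns (scipy linkage matrix, row labels).
    """
    mat = binary_matrix.astype(bool).to_numpy()
    dist = pdist(mat, metric="jaccard")
    return linkage(dist, method="average"), list(binary_matrix.index)
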