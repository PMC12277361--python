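"""Biological functions of stress-specific conserved TFs.

A TF's predicted functions are the functional bins of its retained target
genes, normalized by bin size. Per species, the normalized values of all
conserved TFs of a family are summed and divided by the family's conserved
TF count; the regulatory strength R(m, g) of family g for bin m is the
average of these species terms across the S species. Functional
conservation against a reference species is tested by matching each TF's
DE stress categories to the annotated functions of its reference best hit
through an editable category -> term lexicon, with significance from
permuting which stress profile each TF carries.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import BinHierarchy
from .diffexp import bh_adjust

__all__ = [
    "tf_bin_network",
    "family_terms",
    "regulatory_strength",
    "default_lexicon",
    "read_lexicon",
    "write_lexicon",
    "reference_function_match",
]


def tf_bin_network(
    conserved_tfs: Mapping[str, Sequence[str]],
    top_edges: Mapping[str, pd.DataFrame],
    bins: BinHierarchy,
    levels: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Bin-size-normalized target coverage per conserved TF and bin.

    For TF j and bin m: t_j(m) / B(m), where t_j(m) is the number of j's
    retained targets assigned to m and B(m) the bin's gene count in that
    species. Emitted at every requested bin level (a target in a terminal
    bin counts for all its ancestors); zero-coverage rows are omitted.
    Bins with B(m) = 0 never appear.
    """
    rows = []
    for species, tfs in conserved_tfs.items():
        table = top_edges.get(species)
        if table is None:
            continue
        targets_of = {
            tf: set(grp["target"]) for tf, grp in table.groupby("tf", sort=True)
        }
        for tf in sorted(set(tfs)):
            targets = targets_of.get(tf, set())
            if not targets:
                continue
            for code in bins.bin_codes():
                if BinHierarchy.level(code) not in levels:
                    continue
                members = bins.gene_set(species, code)
                if not members:
                    continue
                t = len(targets & members)
                if t == 0:
                    continue
                rows.append(
                    {
                        "species": species,
                        "tf": tf,
                        "bin_code": code,
                        "bin_level": BinHierarchy.level(code),
                        "n_targets_in_bin": t,
                        "bin_size": len(members),
                        "normalized": t / len(members),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "tf",
            "bin_code",
            "bin_level",
            "n_targets_in_bin",
            "bin_size",
            "normalized",
        ],
    )


def family_terms(
    tf_bins: pd.DataFrame,
    families: Mapping[tuple[str, str], str],
    conserved_counts: Mapping[tuple[str, str], int],
) -> pd.DataFrame:
    """Per-species family term: (sum_j t_j(m,g)/B(m)) / T_i.

    ``families`` maps (species, tf) to its family; ``conserved_counts``
    gives T_i, the number of conserved TFs of family g in species i
    (the denominator counts every conserved family member, whether or not
    it has targets in the bin).
    """
    if tf_bins.empty:
        return pd.DataFrame(columns=["species", "family", "bin_code", "bin_level", "term"])
    t = tf_bins.copy()
    t["family"] = [
        families.get((row.species, row.tf)) for row in t.itertuples(index=False)
    ]
    t = t[t["family"].notna()]
    agg = (
        t.groupby(["species", "family", "bin_code", "bin_level"], as_index=False)[
            "normalized"
        ]
        .sum()
        .rename(columns={"normalized": "summed"})
    )
    agg["T_i"] = [
        conserved_counts.get((row.species, row.family), 0)
        for row in agg.itertuples(index=False)
    ]
    agg = agg[agg["T_i"] > 0]
    agg["term"] = agg["summed"] / agg["T_i"]
    return agg[["species", "family", "bin_code", "bin_level", "term"]]


def regulatory_strength(
    terms: pd.DataFrame,
    species: Sequence[str],
    shrink_s: bool = False,
    conserved_counts: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """R(m, g): cross-species mean of the per-species family terms.

    By default S is the full species count and a species without conserved
    TFs of the family contributes a zero term (keeps R comparable across
    families); with ``shrink_s=True`` S counts only species where the
    family has conserved TFs (requires ``conserved_counts``). Families
    absent everywhere are omitted.
    """
    if terms.empty:
        return pd.DataFrame(columns=["family", "bin_code", "bin_level", "R", "S"])
    rows = []
    for (family, code, lvl), grp in terms.groupby(
        ["family", "bin_code", "bin_level"], sort=True
    ):
        per_species = dict(zip(grp["species"], grp["term"]))
        if shrink_s:
            if conserved_counts is None:
                raise ValueError("shrink_s requires conserved_counts")
            present = [
                s for s in species if conserved_counts.get((s, family), 0) > 0
            ]
            if not present:
                continue
            r = float(np.mean([per_species.get(s, 0.0) for s in present]))
            s_used = len(present)
        else:
            r = float(np.mean([per_species.get(s, 0.0) for s in species]))
            s_used = len(species)
        rows.append(
            {"family": family, "bin_code": code, "bin_level": lvl, "R": r, "S": s_used}
        )
    return pd.DataFrame(rows, columns=["family", "bin_code", "bin_level", "R", "S"])


# ---------------------------------------------------------------------------
# reference-species functional conservation


def default_lexicon() -> dict[str, list[str]]:
    """Stress category -> reference function-term patterns (editable TSV).

    Patterns are case-insensitive substrings matched against a best hit's
    annotated function terms; the miscellaneous bucket collects terms with
    no category of their own.
    """
    return {
        "nitrogen|deficient": ["nitrogen starvation", "nitrate"],
        "nitrogen|surplus": ["nitrogen", "nitrate"],
        "phosphate|deficient": ["phosphate starvation", "phosphate"],
        "phosphate|surplus": ["phosphate"],
        "potassium|deficient": ["potassium starvation", "potassium"],
        "potassium|surplus": ["potassium"],
        "temperature|surplus": ["heat", "response to heat"],
        "temperature|deficient": ["cold", "response to cold"],
        "light_intensity|surplus": ["high light", "response to light"],
        "light_intensity|deficient": ["low light", "response to light"],
        "photoperiod|surplus": ["photoperiod", "response to light"],
        "photoperiod|deficient": ["photoperiod", "response to light"],
    }


def write_lexicon(lexicon: Mapping[str, Sequence[str]], path) -> None:
    rows = [
        {"category": cat, "term_pattern": pat}
        for cat, pats in lexicon.items()
        for pat in pats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lexicon(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.category, []).append(row.term_pattern)
    return out


def _matches(categories: set[str], terms: Sequence[str],
             lexicon: Mapping[str, Sequence[str]]) -> bool:
    for cat in categories:
        for pattern in lexicon.get(cat, []):
            for term in terms:
                if pattern.lower() in term.lower():
                    return True
    return False


def reference_function_match(
    tf_categories: Mapping[tuple[str, str], set[str]],
    besthits: pd.DataFrame,
    lexicon: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_functions: int = 5,
    tf_function_counts: Mapping[tuple[str, str], int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Match TF stress categories against reference best-hit functions.

    ``tf_categories`` maps (species, tf) to its DE stress categories
    (strings "experiment|category"); ``besthits`` has columns species,
    gene_id, ref_gene_id, function_terms (list). TFs regulating fewer than
    ``min_functions`` level-1 bins (per ``tf_function_counts``, if given)
    are excluded, as are TFs without a best hit (with a warning).

    Permutations shuffle which stress-category profile each TF carries
    while the best hits and their functions stay fixed; the identity
    permutation reproduces the observed count. Returns (match matrix,
    summary with observed, permuted_mean, enrichment, p_perm and BH p_adj).
    """
    lexicon = lexicon or default_lexicon()
    hit_of = {
        (row.species, row.gene_id): (row.ref_gene_id, list(row.function_terms))
        for row in besthits.itertuples(index=False)
    }
    keys = sorted(tf_categories)
    if tf_function_counts is not None:
        keys = [k for k in keys if tf_function_counts.get(k, 0) >= min_functions]
    missing = [k for k in keys if k not in hit_of]
    if missing:
        warnings.warn(f"{len(missing)} TF(s) without a best hit dropped")
    keys = [k for k in keys if k in hit_of]
    if not keys:
        return pd.DataFrame(), {
            "observed": 0, "permuted_mean": np.nan, "enrichment": np.nan,
            "p_perm": np.nan, "p_adj": np.nan, "n_perm": n_perm, "n_tfs": 0,
        }
    profiles = [frozenset(tf_categories[k]) for k in keys]
    terms = [hit_of[k][1] for k in keys]

    def count(assignment: Sequence[int]) -> int:
        return sum(
            _matches(set(profiles[a]), terms[i], lexicon)
            for i, a in enumerate(assignment)
        )

    identity = list(range(len(keys)))
    observed = count(identity)
    rng = np.random.default_rng(seed)
    perm_counts = np.array(
        [count(rng.permutation(len(keys))) for _ in range(n_perm)], dtype=float
    )
    mean_perm = float(perm_counts.mean())
    enrichment = observed / mean_perm if mean_perm > 0 else np.inf
    p = (1 + int((perm_counts >= observed).sum())) / (1 + n_perm)
    p_adj = float(bh_adjust(np.array([p]))[0])
    matrix = pd.DataFrame(
        {
            "species": [k[0] for k in keys],
            "tf": [k[1] for k in keys],
            "ref_gene": [hit_of[k][0] for k in keys],
            "functions": [";".join(t) for t in terms],
            "categories": [";".join(sorted(p)) for p in profiles],
            "match": [
                _matches(set(profiles[i]), terms[i], lexicon)
                for i in range(len(keys))
            ],
        }
    )
    summary = {
        "observed": int(observed),
        "permuted_mean": mean_perm,
        "enrichment": float(enrichment),
        "p_perm": float(p),
        "p_adj": p_adj,
        "n_perm": int(n_perm),
        "n_tfs": len(keys),
    }
    return matrix, summary
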