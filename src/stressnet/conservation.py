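"""Jaccard similarity of stress responses, permutation nulls, conserved OGs.

Within a species, similarity between two stress conditions is the Jaccard
index (JI) of their DEG sets, up- and downregulation separately. Across
species, DEG sets are first lifted to orthogroup space (a DE gene marks its
orthogroup DE). Significance comes from a size-matched resampling null:
each permutation draws random sets of the observed sizes from each side's
universe, and p = (1 + #{JI_perm >= JI_obs}) / (1 + n_perm), BH-corrected
across all pairs of a matrix.

A conserved orthogroup is one differentially expressed in all species, in
the same direction, under the same surplus/deficient category of the same
experiment.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Category, DEGTable, OrthogroupMap
from .diffexp import bh_adjust

__all__ = [
    "jaccard",
    "degs_to_og_sets",
    "permutation_significance",
    "conservation_matrix",
    "conserved_orthogroups",
    "upset_counts",
]


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 (untestable, not similar)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def degs_to_og_sets(
    deg_tables: Mapping[tuple[str, str], DEGTable],
    ogmap: OrthogroupMap,
    species: str,
) -> dict[tuple[str, str], dict[str, set[str]]]:
    """Lift per-condition DEG sets to orthogroup space.

    A gene's DE status marks its orthogroup as DE in that direction; genes
    without an orthogroup contribute nothing. An orthogroup whose member
    genes disagree within the species is recorded for each direction
    supported by at least one gene.
    """
    out: dict[tuple[str, str], dict[str, set[str]]] = {}
    for key, deg in deg_tables.items():
        per_dir: dict[str, set[str]] = {"up": set(), "down": set()}
        for direction in ("up", "down"):
            for gene in deg.genes(direction):
                og = ogmap.og_of(species, gene)
                if og is not None:
                    per_dir[direction].add(og)
        out[key] = per_dir
    return out


def _permuted_ji(
    rng: np.random.Generator,
    size_a: int,
    size_b: int,
    universe_a: set,
    universe_b: set,
    n_perm: int,
) -> np.ndarray:
    """JI of size-matched random sets drawn from each universe.

    The overlap of uniform draws has a closed sampling form: the number of
    A-draws landing in the shared region is hypergeometric, likewise for B,
    and the overlap given both is hypergeometric again — sampled in three
    stages, identical in distribution to materializing the random sets.
    """
    na, nb = len(universe_a), len(universe_b)
    if size_a > na or size_b > nb:
        raise ValueError("universe smaller than the observed set size")
    m = len(universe_a & universe_b)
    x = rng.hypergeometric(m, na - m, size_a, size=n_perm) if size_a and m else np.zeros(n_perm, dtype=int)
    y = rng.hypergeometric(m, nb - m, size_b, size=n_perm) if size_b and m else np.zeros(n_perm, dtype=int)
    overlap = np.zeros(n_perm, dtype=int)
    both = (x > 0) & (y > 0)
    if both.any():
        overlap[both] = rng.hypergeometric(x[both], m - x[both], y[both])
    union = size_a + size_b - overlap
    with np.errstate(invalid="ignore"):
        ji = np.where(union > 0, overlap / np.maximum(union, 1), 0.0)
    return ji


def permutation_significance(
    observed_ji: float,
    set_sizes: tuple[int, int],
    universes: tuple[set, set],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Plus-one permutation p-value for one observed JI.

    p = (1 + #{JI_perm >= JI_obs}) / (1 + n_perm); never exactly zero.
    """
    rng = np.random.default_rng(seed)
    ji = _permuted_ji(rng, set_sizes[0], set_sizes[1], universes[0], universes[1], n_perm)
    exceed = int((ji >= observed_ji - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)


def conservation_matrix(
    sets: Mapping[tuple, set],
    universes: Mapping[tuple, set],
    n_perm: int = 1000,
    seed: int = 0,
    pairs: Sequence[tuple[tuple, tuple]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """JI with permutation significance for every pair of labelled sets.

    ``sets`` maps a label (e.g. (species, condition, direction)) to a
    gene/OG set; ``universes`` gives each label's eligible universe. By
    default all unordered label pairs are tested; pass ``pairs`` to
    restrict (e.g. cross-species pairs only). BH correction spans the
    whole matrix. Pairs where both sets are empty are flagged untestable.
    """
    rng = np.random.default_rng(seed)
    labels = list(sets)
    if pairs is None:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    rows = []
    for a, b in pairs:
        sa, sb = sets[a], sets[b]
        ji = jaccard(sa, sb)
        untestable = not (sa or sb)
        if untestable:
            p = np.nan
        else:
            perm = _permuted_ji(rng, len(sa), len(sb), universes[a], universes[b], n_perm)
            p = (1 + int((perm >= ji - 1e-12).sum())) / (1 + n_perm)
        rows.append(
            {
                "a": "|".join(map(str, a)) if isinstance(a, tuple) else str(a),
                "b": "|".join(map(str, b)) if isinstance(b, tuple) else str(b),
                "n_a": len(sa),
                "n_b": len(sb),
                "jaccard": ji,
                "p_perm": p,
                "untestable": untestable,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    return out


def conserved_orthogroups(
    og_de: Mapping[tuple[str, tuple[str, str]], dict[str, set[str]]],
    categories: Mapping[tuple[str, str], str],
    species: Sequence[str] | None = None,
) -> dict[tuple[str, str, str], set[str]]:
    """Orthogroups DE in every species, same direction, same stress category.

    ``og_de`` maps (species, (experiment, level)) to per-direction OG sets;
    ``categories`` maps (experiment, level) to its category. An OG belongs
    to (experiment, category, direction) when every species has at least
    one condition of that experiment and category with the OG DE in that
    direction. Only surplus/deficient categories are considered.
    """
    if species is None:
        species = sorted({sp for sp, _ in og_de})
    keys = sorted(
        {
            (cond[0], categories[cond])
            for _, cond in og_de
            if categories.get(cond) in (Category.DEFICIENT.value, Category.SURPLUS.value)
        }
    )
    result: dict[tuple[str, str, str], set[str]] = {}
    for exp, cat in keys:
        for direction in ("up", "down"):
            per_species = []
            for sp in species:
                union: set[str] = set()
                for (sp2, cond), dirs in og_de.items():
                    if sp2 == sp and cond[0] == exp and categories.get(cond) == cat:
                        union |= dirs.get(direction, set())
                per_species.append(union)
            conserved = set.intersection(*per_species) if per_species else set()
            if conserved:
                result[(exp, cat, direction)] = conserved
    return result


def upset_counts(
    conserved: Mapping[tuple[str, str, str], set[str]]
) -> pd.DataFrame:
    """Combination counts: how many OGs share each exact membership pattern.

    One row per observed combination of (experiment, category, direction)
    memberships, with the member count — the numbers an upset plot shows.
    """
    membership: dict[str, set[str]] = {}
    for key, ogs in conserved.items():
        label = "|".join(key)
        for og in ogs:
            membership.setdefault(og, set()).add(label)
    combos: dict[tuple[str, ...], int] = {}
    for og, labels in membership.items():
        combo = tuple(sorted(labels))
        combos[combo] = combos.get(combo, 0) + 1
    rows = [
        {"combination": " & ".join(combo), "degree": len(combo), "n_orthogroups": n}
        for combo, n in sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "degree", "n_orthogroups"])
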