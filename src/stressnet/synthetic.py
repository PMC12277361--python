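"""Synthetic multi-species stress-transcriptomics study with known ground truth.

Emulates a three-species hydroponic stress survey: seven stress experiments
(nutrient dilution series, temperature, light intensity, photoperiod, light
quality) with three biological replicates per condition, negative-binomial
counts around condition-specific means, a many-to-many orthology, a 4-level
functional bin hierarchy, TF families, and planted structure — per-condition
differentially expressed genes, orthogroup responses conserved across all
species of a surplus/deficient category, and TF->target regulatory couplings
realized consistently across species.

Generation is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    BinHierarchy,
    Category,
    ExpressionMatrix,
    OrthogroupMap,
    TFTable,
    annotate_categories,
    classify_condition,
    write_bins,
    write_design,
    write_expression,
    write_orthogroups,
)

__all__ = [
    "ExperimentDesign",
    "StudyConfig",
    "PlantedTruth",
    "SyntheticStudy",
    "default_experiments",
    "demo_experiments",
    "generate_study",
    "plant_conserved_edges",
    "write_study",
    "simulate_grn_expression",
]

TF_FAMILIES = ["WRKY", "AP2/ERF", "GARP", "GRF", "MYB", "bZIP", "NAC", "bHLH"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Levels of one stress experiment axis and its control level."""

    levels: tuple[str, ...]
    control: str


def default_experiments() -> dict[str, ExperimentDesign]:
    """The full study design: 31 conditions over seven stress axes."""
    return {
        "nitrogen": ExperimentDesign(("0%", "25%", "50%", "100%", "150%"), "100%"),
        "phosphate": ExperimentDesign(("0%", "25%", "50%", "100%", "150%"), "100%"),
        "potassium": ExperimentDesign(("0%", "25%", "50%", "100%", "150%"), "100%"),
        "temperature": ExperimentDesign(("20C", "25C", "30C", "35C"), "25C"),
        "light_intensity": ExperimentDesign(("67", "135", "202.5", "268"), "202.5"),
        "photoperiod": ExperimentDesign(("8h", "12h", "20h", "24h"), "20h"),
        "light_quality": ExperimentDesign(("4:1:1", "4:1:0", "3:1:1", "3:1:0"), "4:1:1"),
    }


def demo_experiments() -> dict[str, ExperimentDesign]:
    """A reduced two-axis design (10 conditions) for quick end-to-end runs."""
    return {
        "nitrogen": ExperimentDesign(("0%", "25%", "50%", "100%", "150%"), "100%"),
        "phosphate": ExperimentDesign(("0%", "25%", "50%", "100%", "150%"), "100%"),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the synthetic study.

    Defaults are the desk-scale study conditions: 3 species x 500 genes
    (20 of them TFs) x 3 replicates, NB dispersion 0.1, planted effects of
    |log2FC| = 2 (4-fold), regulatory coupling beta = 0.8.
    """

    species: tuple[str, ...] = ("speciesA", "speciesB", "speciesC")
    n_genes: int = 500
    n_tfs: int = 20
    replicates: int = 3
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (10.0, 1e4)
    planted_log2fc: float = 2.0
    degs_per_condition: int = 25  # per direction, per condition, per species
    frac_conserved_og: float = 0.1
    n_conserved_edges: int = 10
    conserved_edge_species: int = 3
    n_grn_edges_per_tf: int = 8
    beta: float = 0.8
    orthology_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_level1_bins: int = 8
    bin_branching: int = 3
    bin_depth: int = 4
    experiments: Mapping[str, ExperimentDesign] = field(
        default_factory=default_experiments
    )


@dataclass
class PlantedTruth:
    """Exactly what was planted, keyed the way downstream stages report.

    ``degs[(species, experiment, level)]`` maps gene -> planted log2FC;
    ``grn_edges[species]`` lists (tf_gene, target_gene, sign) couplings;
    ``conserved_ogs[(experiment, category, direction)]`` is an orthogroup
    set; ``conserved_edges`` lists OG-level edges with their per-species
    gene realizations and DE-direction pattern.
    """

    degs: dict[tuple[str, str, str], dict[str, float]] = field(default_factory=dict)
    grn_edges: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    conserved_ogs: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)
    conserved_edges: list[dict] = field(default_factory=list)

    def deg_set(self, species: str, experiment: str, level: str) -> set[str]:
        return set(self.degs.get((species, experiment, level), {}))

    def to_jsonable(self) -> dict:
        return {
            "degs": {
                "|".join(k): v for k, v in sorted(self.degs.items())
            },
            "grn_edges": {
                sp: [list(e) for e in edges] for sp, edges in self.grn_edges.items()
            },
            "conserved_ogs": {
                "|".join(k): sorted(v) for k, v in sorted(self.conserved_ogs.items())
            },
            "conserved_edges": self.conserved_edges,
        }


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    counts: dict[str, ExpressionMatrix]
    tpm: dict[str, ExpressionMatrix]
    ogmap: OrthogroupMap
    bins: BinHierarchy
    bin_rows: pd.DataFrame
    tfs: TFTable
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# generation


def _build_design(config: StudyConfig, species: str) -> pd.DataFrame:
    rows = []
    for exp, dsn in config.experiments.items():
        for level in dsn.levels:
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{species}.{exp}.{level}.r{rep}",
                        "species": species,
                        "experiment": exp,
                        "level": level,
                        "replicate": rep,
                        "control": int(level == dsn.control),
                    }
                )
    return annotate_categories(pd.DataFrame(rows))


def _build_orthology(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], OrthogroupMap]:
    """Gene ids per species plus a mixed orthology.

    TFs form single-copy orthogroups across all species. Non-TF genes are a
    mix of single-copy groups, groups with a duplication in one species, and
    species-specific (unassigned) genes, in the configured proportions.
    """
    sp = list(config.species)
    genes = {s: [f"{s}_g{i:04d}" for i in range(config.n_genes)] for s in sp}
    assignments: dict[tuple[str, str], str] = {}
    for k in range(config.n_tfs):
        og = f"OGTF{k:04d}"
        for s in sp:
            assignments[(s, genes[s][k])] = og
    frac_single, frac_dup, frac_specific = config.orthology_mix
    n_rest = config.n_genes - config.n_tfs
    pools = {s: list(genes[s][config.n_tfs :]) for s in sp}
    n_keep = int(round((1.0 - frac_specific) * n_rest))
    k = 0
    while all(len(pools[s]) > n_rest - n_keep for s in sp):
        og = f"OG{k:06d}"
        dup_species = sp[k % len(sp)] if (k % 10) < round(frac_dup * 10) else None
        feasible = all(
            len(pools[s]) - (2 if s == dup_species else 1) >= n_rest - n_keep - 1
            for s in sp
        )
        if not feasible:
            break
        for s in sp:
            take = 2 if s == dup_species else 1
            for _ in range(take):
                assignments[(s, pools[s].pop(0))] = og
        k += 1
    return genes, OrthogroupMap(assignments=assignments)


def _build_bins(
    config: StudyConfig, genes: dict[str, list[str]], ogmap: OrthogroupMap,
    rng: np.random.Generator,
) -> tuple[BinHierarchy, pd.DataFrame]:
    """Assign every gene to one terminal bin (and its ancestors).

    Orthologous genes share a terminal bin so functional responses cohere
    across species.
    """
    terminals: list[str] = []

    def grow(prefix: str, depth: int) -> None:
        if depth == config.bin_depth:
            terminals.append(prefix)
            return
        for c in range(1, config.bin_branching + 1):
            grow(f"{prefix}.{c}", depth + 1)

    for r in range(1, config.n_level1_bins + 1):
        grow(str(r), 1)
    og_bin: dict[str, str] = {}
    for og in ogmap.orthogroup_ids:
        og_bin[og] = terminals[int(rng.integers(len(terminals)))]
    hierarchy = BinHierarchy()
    rows = []
    for s in config.species:
        for gene in genes[s]:
            og = ogmap.og_of(s, gene)
            code = og_bin[og] if og else terminals[int(rng.integers(len(terminals)))]
            hierarchy.add_gene(s, gene, code, f"bin {code}")
            rows.append(
                {"species": s, "gene_id": gene, "bin_code": code, "bin_name": f"bin {code}"}
            )
    return hierarchy, pd.DataFrame(rows)


def _condition_list(config: StudyConfig) -> list[tuple[str, str, str]]:
    """(experiment, level, category) for every condition of the design."""
    out = []
    for exp, dsn in config.experiments.items():
        for level in dsn.levels:
            if level == dsn.control:
                cat = Category.CONTROL.value
            else:
                try:
                    cat = classify_condition(exp, level, dsn.control).value
                except ValueError:
                    cat = Category.OTHER.value
            out.append((exp, level, cat))
    return out


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study with planted, recoverable truth.

    Raises ``ValueError`` for infeasible configurations (more planted DEGs
    than genes, more conserved edges than eligible orthogroups). Planted
    conserved responses and regulatory-edge endpoints are drawn from genes
    with base mean >= 100 so every planted target is statistically
    detectable at three replicates; the gene population at large keeps the
    full log-uniform base-mean range.
    """
    config = config or StudyConfig()
    if 2 * config.degs_per_condition + config.n_tfs > config.n_genes:
        raise ValueError("more planted DEGs per condition than available genes")
    rng = np.random.default_rng(seed)
    sp = list(config.species)
    genes, ogmap = _build_orthology(config, rng)
    bins, bin_rows = _build_bins(config, genes, ogmap, rng)
    tfs = TFTable(
        pd.DataFrame(
            [
                {
                    "species": s,
                    "gene_id": genes[s][k],
                    "family": TF_FAMILIES[k % len(TF_FAMILIES)],
                }
                for s in sp
                for k in range(config.n_tfs)
            ]
        )
    )
    conditions = _condition_list(config)
    stress_conditions = [c for c in conditions if c[2] != Category.CONTROL.value]
    truth = PlantedTruth()
    gene_index = {s: {g: i for i, g in enumerate(genes[s])} for s in sp}
    cond_index = {(e, l): j for j, (e, l, _) in enumerate(conditions)}

    # base means: population log-uniform over the configured range; TFs on
    # the well-expressed stratum so regulator profiles are measurable
    lo, hi = config.base_mean_range
    detect_floor = min(100.0, hi)
    base = {s: np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_genes)) for s in sp}
    for s in sp:
        base[s][: config.n_tfs] = np.exp(
            rng.uniform(np.log(detect_floor), np.log(hi), config.n_tfs)
        )

    # eligible orthogroups for conserved planting: present in every species,
    # not TF groups, all members above the detectability floor
    def _detectable(og: str) -> bool:
        return all(
            base[s][gene_index[s][g]] >= detect_floor
            for s in sp
            for g in ogmap.members_of_species(og, s)
        )

    multi_ogs = sorted(
        og
        for og in ogmap.ogs_with_species(sp)
        if not og.startswith("OGTF") and _detectable(og)
    )
    n_cons_og = int(round(config.frac_conserved_og * len(multi_ogs)))
    rng.shuffle(multi_ogs)
    conserved_og_pool = multi_ogs[:n_cons_og]
    edge_target_pool = multi_ogs[n_cons_og : n_cons_og + config.n_conserved_edges]
    if len(edge_target_pool) < config.n_conserved_edges:
        raise ValueError("insufficient multi-species orthogroups for planted edges")
    background_pool = {
        s: [
            g
            for g in genes[s][config.n_tfs :]
            if ogmap.og_of(s, g) not in set(conserved_og_pool) | set(edge_target_pool)
        ]
        for s in sp
    }

    # log2 effect per (species, gene, condition)
    effects = {
        s: np.zeros((config.n_genes, len(conditions))) for s in sp
    }

    def plant(s: str, gene: str, exp: str, level: str, lfc: float) -> None:
        effects[s][gene_index[s][gene], cond_index[(exp, level)]] += lfc

    # 1. background per-condition DEGs, independent per species
    for s in sp:
        for exp, level, _cat in stress_conditions:
            picks = rng.choice(
                len(background_pool[s]), 2 * config.degs_per_condition, replace=False
            )
            for i, p in enumerate(picks):
                lfc = config.planted_log2fc if i < config.degs_per_condition else -config.planted_log2fc
                plant(s, background_pool[s][p], exp, level, lfc)

    # 2. conserved orthogroup responses: same direction, same category,
    # every species, planted in every condition of that category
    # categories eligible for conserved planting need >= 2 stress conditions
    # so every planted response has redundant chances of detection
    cat_counts: dict[tuple[str, str], int] = {}
    for e, _l, c in stress_conditions:
        if c in (Category.DEFICIENT.value, Category.SURPLUS.value):
            cat_counts[(e, c)] = cat_counts.get((e, c), 0) + 1
    categories = sorted(k for k, n in cat_counts.items() if n >= 2)
    for og in conserved_og_pool:
        exp, cat = categories[int(rng.integers(len(categories)))]
        direction = "up" if rng.random() < 0.5 else "down"
        lfc = config.planted_log2fc * (1 if direction == "up" else -1)
        for e2, level, c2 in stress_conditions:
            if e2 == exp and c2 == cat:
                for s in sp:
                    for gene in ogmap.members_of_species(og, s):
                        plant(s, gene, e2, level, lfc)
        truth.conserved_ogs.setdefault((exp, cat, direction), set()).add(og)

    # 3. TF activity: every TF orthogroup is DE in a random subset of
    # conditions (shared pattern across species so TF-level conservation
    # is possible), giving each TF expression variance for the GRN stage
    tf_conditions: dict[int, list[int]] = {}
    for k in range(config.n_tfs):
        n_active = int(rng.integers(3, 7))
        active = rng.choice(len(stress_conditions), n_active, replace=False)
        tf_conditions[k] = list(active)
        for j in active:
            exp, level, _ = stress_conditions[int(j)]
            sign = 1 if rng.random() < 0.5 else -1
            for s in sp:
                plant(s, genes[s][k], exp, level, sign * config.planted_log2fc)

    # 4. planted conserved regulatory edges: TF OG -> target OG, realized in
    # the first `conserved_edge_species` species under one shared deficient
    # (or surplus) condition category
    deficient_cats = [c for c in categories if c[1] == Category.DEFICIENT.value] or categories
    chosen_sp = sp[: config.conserved_edge_species]
    for i, target_og in enumerate(edge_target_pool):
        k = int(rng.integers(config.n_tfs))
        tf_og = f"OGTF{k:04d}"
        exp, cat = deficient_cats[int(rng.integers(len(deficient_cats)))]
        sign = 1 if rng.random() < 0.5 else -1
        tf_dir = "up"
        tg_dir = "up" if sign > 0 else "down"
        realizations = {}
        for s in chosen_sp:
            tf_gene = genes[s][k]
            targets = sorted(ogmap.members_of_species(target_og, s))
            for e2, level, c2 in stress_conditions:
                if e2 == exp and c2 == cat:
                    plant(s, tf_gene, e2, level, config.planted_log2fc)
                    for tg in targets:
                        plant(s, tg, e2, level, sign * config.planted_log2fc)
            realizations[s] = {"tf": tf_gene, "targets": targets}
            truth.grn_edges.setdefault(s, [])
            for tg in targets:
                truth.grn_edges[s].append((tf_gene, tg, sign))
        truth.conserved_edges.append(
            {
                "tf_og": tf_og,
                "target_og": target_og,
                "species": list(chosen_sp),
                "experiment": exp,
                "category": cat,
                "pattern": [tf_dir, tg_dir],
                "sign": sign,
                "realizations": realizations,
            }
        )

    # 5. additional within-species regulatory couplings (targets follow
    # their TF's condition profile, scaled by +-beta) for edge-ranking tests
    for s in sp:
        truth.grn_edges.setdefault(s, [])
        used = {t for _tf, t, _sg in truth.grn_edges[s]}
        free = [g for g in background_pool[s] if g not in used]
        rng.shuffle(free)
        pos = 0
        for k in range(config.n_tfs):
            tf_gene = genes[s][k]
            tf_profile = effects[s][gene_index[s][tf_gene]]
            spread = float(tf_profile.std())
            if spread == 0:
                continue
            z = (tf_profile - tf_profile.mean()) / spread
            for _ in range(config.n_grn_edges_per_tf):
                if pos >= len(free):
                    break
                target = free[pos]
                pos += 1
                sign = 1 if rng.random() < 0.5 else -1
                row = gene_index[s][target]
                effects[s][row] += sign * config.beta * z
                truth.grn_edges[s].append((tf_gene, target, sign))

    # planted DEG truth: the exact contrast the caller estimates — effect
    # at a condition minus effect at its experiment's control, kept at the
    # |log2FC| >= 1 DEG definition
    control_j = {
        exp: cond_index[(exp, dsn.control)] for exp, dsn in config.experiments.items()
    }
    for s in sp:
        for (exp, level, _cat) in stress_conditions:
            delta = effects[s][:, cond_index[(exp, level)]] - effects[s][:, control_j[exp]]
            hits = {
                genes[s][i]: float(delta[i])
                for i in np.nonzero(np.abs(delta) >= 1.0)[0]
            }
            if hits:
                truth.degs[(s, exp, level)] = hits

    # 6. sample counts and TPM
    counts: dict[str, ExpressionMatrix] = {}
    tpm: dict[str, ExpressionMatrix] = {}
    for s in sp:
        design = _build_design(config, s)
        mu_cond = base[s][:, None] * np.power(2.0, effects[s])  # genes x conditions
        cols = {}
        for _, row in design.iterrows():
            j = cond_index[(row["experiment"], row["level"])]
            mu = mu_cond[:, j]
            n_nb = 1.0 / config.dispersion
            p_nb = n_nb / (n_nb + mu)
            cols[row["sample_id"]] = rng.negative_binomial(n_nb, p_nb)
        cdf = pd.DataFrame(cols, index=genes[s])
        counts[s] = ExpressionMatrix(values=cdf, design=design, unit="counts")
        libsize = cdf.sum(axis=0)
        tdf = cdf / libsize.replace(0, np.nan) * 1e6
        tpm[s] = ExpressionMatrix(values=tdf.fillna(0.0), design=design.copy(), unit="TPM")

    study = SyntheticStudy(
        config=config,
        seed=seed,
        counts=counts,
        tpm=tpm,
        ogmap=ogmap,
        bins=bins,
        bin_rows=bin_rows,
        tfs=tfs,
        truth=truth,
    )
    # planted log2-effect matrices (genes x conditions) for introspection
    study.effects = effects
    study.conditions = conditions
    study.base_means = base
    return study


def plant_conserved_edges(
    study: SyntheticStudy, n_edges: int, n_species_conserved: int, seed: int
) -> SyntheticStudy:
    """Regenerate the study with a different conserved-edge planting.

    Generation is a pure function of (config, seed), so replanting means
    rebuilding with the edge parameters swapped; with
    ``n_species_conserved=1`` the planted edges are invisible to the
    conservation stage (a negative control).
    """
    if n_species_conserved > len(study.config.species):
        raise ValueError("cannot conserve edges across more species than exist")
    config = dataclasses.replace(
        study.config,
        n_conserved_edges=n_edges,
        conserved_edge_species=n_species_conserved,
    )
    return generate_study(config, seed)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study as the pipeline's TSV input set plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in study.config.species:
        write_expression(study.counts[s], outdir / f"{s}.counts.tsv")
        write_expression(study.tpm[s], outdir / f"{s}.tpm.tsv")
        write_design(study.counts[s].design, outdir / f"{s}.design.tsv")
    write_orthogroups(study.ogmap, outdir / "orthogroups.tsv")
    write_bins(study.bin_rows, outdir / "bins.tsv")
    study.tfs.table.to_csv(outdir / "tfs.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(study.truth.to_jsonable(), indent=1, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# small stand-alone regulatory simulation for edge-ranking checks


def simulate_grn_expression(
    n_tfs: int = 20,
    n_targets: int = 200,
    n_samples: int = 60,
    beta: float = 0.8,
    edges_per_target: int = 1,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[tuple[str, str]]]:
    """Gaussian toy expression where each target tracks a few TFs.

    Returns (samples x genes DataFrame, tf names, true (tf, target) edges).
    TF profiles are iid standard normal; each target is a +-beta-weighted
    sum of its regulators plus unit-variance noise.
    """
    rng = np.random.default_rng(seed)
    tf_names = [f"TF{i:03d}" for i in range(n_tfs)]
    tg_names = [f"T{i:04d}" for i in range(n_targets)]
    tf_expr = rng.normal(size=(n_samples, n_tfs))
    targets = np.zeros((n_samples, n_targets))
    edges = []
    for j in range(n_targets):
        regs = rng.choice(n_tfs, edges_per_target, replace=False)
        signs = rng.choice([-1.0, 1.0], edges_per_target)
        for r, sg in zip(regs, signs):
            targets[:, j] += sg * beta * tf_expr[:, r]
            edges.append((tf_names[int(r)], tg_names[j]))
        targets[:, j] += rng.normal(scale=noise_sd, size=n_samples)
    data = pd.DataFrame(
        np.hstack([tf_expr, targets]), columns=tf_names + tg_names
    )
    return data, tf_names, edges
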