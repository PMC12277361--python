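"""End-to-end orchestration: stages, run directory layout, manifest.

Stages run in dependency order (de -> ndei/bins -> conservation -> grn ->
grn-conservation -> tf-function). Each enabled stage writes its TSV/JSON
outputs into the run directory; prerequisites of an enabled stage that are
themselves disabled are still computed in memory, so toggling a late stage
off never changes an earlier stage's outputs. Reruns with an identical
config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import (
    conservation_matrix,
    conserved_orthogroups,
    degs_to_og_sets,
    upset_counts,
)
from .core_io import (
    Category,
    DEGTable,
    ExpressionMatrix,
    OrthogroupMap,
    read_bins,
    read_design,
    read_expression,
    read_orthogroups,
    read_tf_table,
    read_besthits,
    sample_similarity,
)
from .diffexp import call_degs
from .grn import assign_sign, infer_grn, top_edges
from .grn_conservation import (
    conserved_edges,
    edge_enrichment,
    export_graphml,
    map_edges_to_og,
    stress_specific_edges,
)
from .pathway_ndei import (
    compute_bin_counts,
    compute_ndei,
    conserved_function_pairs,
    ndei_correlation,
    significance_table,
)
from .synthetic import StudyConfig, demo_experiments, generate_study, write_study
from .tf_function import (
    default_lexicon,
    family_terms,
    reference_function_match,
    regulatory_strength,
    tf_bin_network,
    write_lexicon,
)

__all__ = ["RunConfig", "PipelineState", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("stressnet")

ALL_STAGES = ("de", "ndei", "conserve", "grn", "grn-conserve", "tf-function")


@dataclass
class RunConfig:
    """Validated knobs of one pipeline run; recorded verbatim in the manifest."""

    outdir: str
    data_dir: str | None = None  # study TSVs (write_study layout); None => demo
    demo: bool = False
    demo_scale: str = "demo"  # "demo" (10 conditions) or "full" (31)
    seed: int = 0
    species: tuple[str, ...] | None = None
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    top_edge_fraction: float = 0.05
    min_species_pairs: int = 3
    min_conditions_pairs: int = 5
    grn_min_species: int = 2
    n_perm: int = 1000
    n_trees: int = 1000
    grn_method: str = "FAST-ET"
    stages: tuple[str, ...] = ALL_STAGES
    deg_tables: str | None = None  # directory of precomputed DEG TSVs
    besthits: str | None = None  # reference best-hit TSV

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not self.demo and self.data_dir is None:
            raise ValueError("data_dir is required unless demo mode is on")
        if self.demo and self.data_dir is not None:
            raise ValueError("demo mode generates its own inputs; drop data_dir")
        for name in ("fc_threshold", "top_edge_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if "conserve" in self.stages and not self.demo:
            if not (Path(self.data_dir) / "orthogroups.tsv").exists():
                raise ValueError("conservation stage enabled but orthogroups.tsv missing")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        if d.get("species"):
            d["species"] = list(d["species"])
        # the run directory is wherever the manifest lives; leaving it out
        # keeps manifests byte-identical across relocated reruns
        d.pop("outdir")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineState:
    """Lazy in-memory products shared between stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)

    # -- inputs -----------------------------------------------------------

    @cached_property
    def inputs_dir(self) -> Path:
        cfg = self.config
        if cfg.demo:
            study_cfg = StudyConfig(
                experiments=demo_experiments()
            ) if cfg.demo_scale == "demo" else StudyConfig()
            study = generate_study(study_cfg, seed=cfg.seed)
            path = self.outdir / "inputs"
            write_study(study, path)
            return path
        return Path(cfg.data_dir)

    @cached_property
    def species(self) -> list[str]:
        if self.config.species:
            return list(self.config.species)
        return sorted(
            p.name.removesuffix(".counts.tsv")
            for p in self.inputs_dir.glob("*.counts.tsv")
        )

    @cached_property
    def counts(self) -> dict[str, ExpressionMatrix]:
        out = {}
        for sp in self.species:
            design = read_design(self.inputs_dir / f"{sp}.design.tsv")
            out[sp] = read_expression(
                self.inputs_dir / f"{sp}.counts.tsv", design, unit="counts"
            )
        return out

    @cached_property
    def tpm(self) -> dict[str, ExpressionMatrix]:
        out = {}
        for sp in self.species:
            design = read_design(self.inputs_dir / f"{sp}.design.tsv")
            out[sp] = read_expression(
                self.inputs_dir / f"{sp}.tpm.tsv", design, unit="TPM"
            )
        return out

    @cached_property
    def ogmap(self) -> OrthogroupMap:
        return read_orthogroups(self.inputs_dir / "orthogroups.tsv")

    @cached_property
    def bins(self):
        return read_bins(self.inputs_dir / "bins.tsv")

    @cached_property
    def tfs(self):
        return read_tf_table(self.inputs_dir / "tfs.tsv")

    @cached_property
    def categories(self) -> dict[tuple[str, str], str]:
        cats: dict[tuple[str, str], str] = {}
        for sp in self.species:
            for row in self.counts[sp].design.itertuples(index=False):
                cats[(row.experiment, str(row.level))] = row.category
        return cats

    # -- differential expression ------------------------------------------

    @cached_property
    def de_results(self) -> dict[str, dict]:
        """Per species: DEG tables per condition and the tested universe."""
        cfg = self.config
        out: dict[str, dict] = {}
        for sp in self.species:
            counts = self.counts[sp]
            degs: dict[tuple[str, str], DEGTable] = {}
            universe: set[str] = set()
            design = counts.design
            for (exp, level), grp in design.groupby(
                ["experiment", "level"], sort=True
            ):
                if (grp["category"] == Category.CONTROL.value).any():
                    continue
                if cfg.deg_tables is not None:
                    from .core_io import read_deg_table

                    path = Path(cfg.deg_tables) / f"{sp}.{exp}.{level}.deg.tsv"
                    degs[(str(exp), str(level))] = read_deg_table(
                        path, sp, str(exp), str(level),
                        cfg.fc_threshold, cfg.p_threshold,
                    )
                    universe.update(counts.gene_ids)
                    continue
                deg, contrast = call_degs(
                    counts, str(exp), str(level), cfg.fc_threshold, cfg.p_threshold
                )
                degs[(str(exp), str(level))] = deg
                tested = contrast.table[contrast.table["p_raw"].notna()]
                universe.update(tested["gene"])
            out[sp] = {"degs": degs, "universe": universe}
        return out

    @cached_property
    def bin_sig(self) -> dict[str, pd.DataFrame]:
        return {
            sp: significance_table(
                self.de_results[sp]["degs"],
                self.bins,
                self.de_results[sp]["universe"],
                alpha=self.config.p_threshold,
            )
            for sp in self.species
        }

    # -- GRN ---------------------------------------------------------------

    @cached_property
    def grn_edges(self) -> dict[str, dict[str, pd.DataFrame]]:
        """Per species: full weighted edge list and the signed top fraction."""
        cfg = self.config
        out = {}
        for i, sp in enumerate(self.species):
            deg_union: set[str] = set()
            for deg in self.de_results[sp]["degs"].values():
                deg_union |= deg.genes()
            tf_list = [t for t in self.tfs.tfs_of(sp) if t in deg_union]
            expr = self.tpm[sp].values.loc[sorted(deg_union)]
            edges = infer_grn(
                expr, tf_list, n_trees=cfg.n_trees, seed=cfg.seed + 1000 * (i + 1),
                method=cfg.grn_method,
            )
            top = assign_sign(top_edges(edges, cfg.top_edge_fraction), expr)
            out[sp] = {"all": edges, "top": top}
        return out

    @cached_property
    def og_edges(self):
        return map_edges_to_og(
            {sp: self.grn_edges[sp]["top"] for sp in self.species}, self.ogmap
        )

    @cached_property
    def conserved_edge_set(self):
        return conserved_edges(self.og_edges, self.config.grn_min_species)

    @cached_property
    def stress_specific(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return stress_specific_edges(
            self.conserved_edge_set,
            {sp: self.de_results[sp]["degs"] for sp in self.species},
            self.categories,
            min_species=self.config.grn_min_species,
        )


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _stage_de(state: PipelineState) -> None:
    rows = []
    for sp in state.species:
        for (exp, level), deg in state.de_results[sp]["degs"].items():
            t = deg.table.copy()
            t.insert(0, "species", sp)
            t.insert(1, "experiment", exp)
            t.insert(2, "level", level)
            rows.append(t)
        sim = sample_similarity(state.tpm[sp])
        sim.index.name = "sample_id"
        out = state.outdir / "sample_similarity" / f"{sp}.tsv"
        out.parent.mkdir(parents=True, exist_ok=True)
        sim.to_csv(out, sep="\t")
        universe = pd.DataFrame(
            {"species": sp, "gene": sorted(state.de_results[sp]["universe"])}
        )
        _write(universe, state.outdir / "tested_universe" / f"{sp}.tsv")
    _write(pd.concat(rows, ignore_index=True), state.outdir / "degs.tsv")


def _stage_ndei(state: PipelineState) -> None:
    ndei_rows, counts_rows, corr_rows = [], [], []
    for sp in state.species:
        counts = compute_bin_counts(
            state.de_results[sp]["degs"], state.bins, sp
        )
        counts.insert(0, "species", sp)
        counts_rows.append(counts)
        ndei = compute_ndei(counts)
        long = ndei.reset_index().melt(
            id_vars="bin_code", var_name="condition", value_name="ndei"
        ).dropna()
        long.insert(0, "species", sp)
        ndei_rows.append(long)
        for level in (1, 2):
            corr = ndei_correlation(ndei, bin_level=level)
            if len(corr):
                corr.insert(0, "species", sp)
                corr.insert(1, "bin_level", level)
                corr_rows.append(corr)
    _write(pd.concat(counts_rows, ignore_index=True), state.outdir / "bin_counts.tsv")
    _write(pd.concat(ndei_rows, ignore_index=True), state.outdir / "ndei.tsv")
    sig = pd.concat(
        [t for t in state.bin_sig.values() if len(t)], ignore_index=True
    )
    _write(sig, state.outdir / "bin_significance.tsv")
    if corr_rows:
        _write(pd.concat(corr_rows, ignore_index=True), state.outdir / "ndei_correlation.tsv")
    pairs = conserved_function_pairs(
        state.bin_sig,
        categories=state.categories,
        min_species=min(state.config.min_species_pairs, len(state.species)),
        min_conditions=state.config.min_conditions_pairs,
    )
    _write(pairs, state.outdir / "function_pairs.tsv")


def _stage_conserve(state: PipelineState) -> None:
    cfg = state.config
    # within-species JI on DEG sets
    within_frames = []
    for si, sp in enumerate(state.species):
        degs = state.de_results[sp]["degs"]
        universe = state.de_results[sp]["universe"]
        for direction in ("up", "down"):
            sets = {
                (sp, f"{e}:{l}", direction): degs[(e, l)].genes(direction)
                for (e, l) in degs
            }
            universes = {k: universe for k in sets}
            mat = conservation_matrix(
                sets, universes, n_perm=cfg.n_perm, seed=cfg.seed + 17 * si
            )
            mat.insert(0, "scope", "within")
            mat.insert(1, "direction", direction)
            within_frames.append(mat)
    # across-species JI on orthogroup sets
    og_sets = {
        sp: degs_to_og_sets(state.de_results[sp]["degs"], state.ogmap, sp)
        for sp in state.species
    }
    across_frames = []
    for direction in ("up", "down"):
        sets, universes, pairs = {}, {}, []
        for sp in state.species:
            sp_universe = {
                og
                for og in state.ogmap.orthogroup_ids
                if state.ogmap.members_of_species(og, sp)
            }
            for cond, dirs in og_sets[sp].items():
                key = (sp, f"{cond[0]}:{cond[1]}", direction)
                sets[key] = dirs[direction]
                universes[key] = sp_universe
        keys = list(sets)
        pairs = [
            (a, b)
            for i, a in enumerate(keys)
            for b in keys[i + 1 :]
            if a[0] != b[0]
        ]
        mat = conservation_matrix(
            sets, universes, n_perm=cfg.n_perm, seed=cfg.seed + 31, pairs=pairs
        )
        mat.insert(0, "scope", "across")
        mat.insert(1, "direction", direction)
        across_frames.append(mat)
    _write(pd.concat(within_frames + across_frames, ignore_index=True),
           state.outdir / "conservation_matrix.tsv")
    og_de = {
        (sp, cond): dirs for sp in state.species for cond, dirs in og_sets[sp].items()
    }
    conserved = conserved_orthogroups(og_de, state.categories, state.species)
    rows = [
        {"experiment": e, "category": c, "direction": d, "orthogroup": og}
        for (e, c, d), ogs in sorted(conserved.items())
        for og in sorted(ogs)
    ]
    _write(
        pd.DataFrame(rows, columns=["experiment", "category", "direction", "orthogroup"]),
        state.outdir / "conserved_orthogroups.tsv",
    )
    _write(upset_counts(conserved), state.outdir / "upset_counts.tsv")


def _stage_grn(state: PipelineState) -> None:
    for sp in state.species:
        edges = state.grn_edges[sp]
        _write(edges["all"], state.outdir / "grn" / f"{sp}.edges.tsv")
        _write(edges["top"], state.outdir / "grn" / f"{sp}.top_edges.tsv")


def _stage_grn_conserve(state: PipelineState) -> None:
    cfg = state.config
    _write(state.og_edges.to_frame(), state.outdir / "og_edges.tsv")
    _write(state.og_edges.leftovers, state.outdir / "og_edges_leftovers.tsv")
    cons = state.conserved_edge_set
    frame = cons.to_frame()
    strata = state.og_edges.strata_counts(len(state.species))
    _write(frame, state.outdir / "conserved_edges.tsv")
    _write(
        pd.DataFrame(
            [{"n_species": k, "n_edges": v} for k, v in sorted(strata.items())]
        ),
        state.outdir / "conserved_edge_strata.tsv",
    )
    edge_df, tf_df = state.stress_specific
    _write(edge_df, state.outdir / "stress_specific_edges.tsv")
    _write(tf_df, state.outdir / "conserved_tfs.tsv")
    enr = edge_enrichment(
        {sp: state.grn_edges[sp]["top"] for sp in state.species},
        state.ogmap,
        n_perm=cfg.n_perm,
        seed=cfg.seed + 97,
        min_species=cfg.grn_min_species,
    )
    _write(enr, state.outdir / "enrichment.tsv")
    nets = state.outdir / "networks"
    nets.mkdir(parents=True, exist_ok=True)
    if len(edge_df):
        for (exp, cat), grp in edge_df.groupby(["experiment", "category"]):
            export_graphml(grp, nets / f"{exp}_{cat}.graphml")


def _stage_tf_function(state: PipelineState) -> None:
    cfg = state.config
    edge_df, tf_df = state.stress_specific
    conserved_tfs = {
        sp: sorted(tf_df.loc[tf_df["species"] == sp, "tf"].unique())
        for sp in state.species
    }
    tf_bins = tf_bin_network(
        conserved_tfs, {sp: state.grn_edges[sp]["top"] for sp in state.species},
        state.bins,
    )
    _write(tf_bins, state.outdir / "tf_bin_network.tsv")
    fams = {
        (row.species, row.gene_id): row.family
        for row in state.tfs.table.itertuples(index=False)
    }
    counts = {
        (sp, fam): sum(1 for tf in conserved_tfs[sp] if fams.get((sp, tf)) == fam)
        for sp in state.species
        for fam in {fams.get((sp, tf)) for tf in conserved_tfs[sp]}
        if fam is not None
    }
    terms = family_terms(tf_bins, fams, counts)
    _write(terms, state.outdir / "family_terms.tsv")
    strength = regulatory_strength(terms, state.species)
    _write(strength, state.outdir / "regulatory_strength.tsv")
    lexicon = default_lexicon()
    write_lexicon(lexicon, state.outdir / "lexicon.tsv")
    tf_categories: dict[tuple[str, str], set[str]] = {}
    for row in tf_df.itertuples(index=False):
        tf_categories.setdefault((row.species, row.tf), set()).add(
            f"{row.experiment}|{row.category}"
        )
    lvl1 = tf_bins[tf_bins["bin_level"] == 1]
    func_counts = {
        (sp, tf): len(grp["bin_code"].unique())
        for (sp, tf), grp in lvl1.groupby(["species", "tf"])
    } if len(lvl1) else {}
    if cfg.besthits is not None:
        besthits = read_besthits(cfg.besthits)
    else:
        # synthetic stand-in best-hit table: each conserved TF maps to a
        # pseudo reference gene annotated with the lexicon terms of its own
        # DE categories, a perfectly concordant reference
        rows = []
        for (sp, tf), cats in sorted(tf_categories.items()):
            terms_ = sorted({pat for c in cats for pat in lexicon.get(c, [])})
            rows.append(
                {
                    "species": sp,
                    "gene_id": tf,
                    "ref_gene_id": f"REF_{tf}",
                    "function_terms": terms_ or ["uncharacterized"],
                }
            )
        besthits = pd.DataFrame(
            rows, columns=["species", "gene_id", "ref_gene_id", "function_terms"]
        )
    matrix, summary = reference_function_match(
        tf_categories,
        besthits,
        lexicon,
        n_perm=cfg.n_perm,
        seed=cfg.seed + 211,
        min_functions=1 if cfg.besthits is None else 5,
        tf_function_counts=func_counts,
    )
    _write(matrix, state.outdir / "function_match.tsv")
    (state.outdir / "function_match_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )


_STAGE_FN = {
    "de": _stage_de,
    "ndei": _stage_ndei,
    "conserve": _stage_conserve,
    "grn": _stage_grn,
    "grn-conserve": _stage_grn_conserve,
    "tf-function": _stage_tf_function,
}


def run_pipeline(config: RunConfig) -> PipelineState:
    """Run all enabled stages and write the manifest.

    A stage failure aborts the run with the stage named; a ``failed`` marker
    file records the stage and cause while earlier outputs are kept.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    state = PipelineState(config)
    try:
        _ = state.inputs_dir  # materialize inputs (and the demo study) first
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s: start", stage)
            try:
                _STAGE_FN[stage](state)
            except Exception as exc:
                (outdir / "failed").write_text(f"{stage}: {exc}\n")
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s: done", stage)
        manifest = {
            "version": __version__,
            "config": config.to_jsonable(),
            "seed": config.seed,
            "input_checksums": {
                p.name: _sha256(p) for p in sorted(state.inputs_dir.glob("*.tsv"))
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    finally:
        log.removeHandler(handler)
        handler.close()
    return state
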