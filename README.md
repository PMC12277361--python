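# stressnet

Cross-species comparative transcriptomics of abiotic stress for people who
have expression matrices from several plant species under matched stress
surveys (nutrient dilution series, temperature, light regimes) and want to
know which transcriptional responses — and which regulatory interactions —
are conserved across species.

The package implements, as a tested library plus CLI:

- **DEG calling** against per-experiment controls at the standard rule
  |log2FC| ≥ 1 and BH-adjusted p ≤ 0.05 (a moderated-t stand-in for quick
  runs; external DEG tables, e.g. from DESeq2, are injected verbatim for
  real data);
- **Pathway statistics**: hypergeometric over-representation of DEGs in a
  hierarchical functional-bin ontology, and the Normalized Differential
  Expression Index, NDEI(σ, m) = (U − D)/B — the net fraction of bin *m*'s
  genes moving up (+1: all up) or down (−1: all down) under stress σ — with
  Pearson-correlation networks between bins and cross-species conserved
  function pairs;
- **Conservation testing**: Jaccard-index similarity of DEG sets within a
  species and of differentially expressed orthogroups across species, with
  a 1000-permutation size-matched null (plus-one p, BH across the matrix);
  conserved orthogroups = DE in *all* species, same direction, same
  surplus/deficient stress category, with upset combination counts;
- **GRN inference** per species in the GENIE3 style — one random-forest
  regression per target with TFs as candidate regulators, edge weight =
  variance-reduction importance, top 5% of non-zero edges retained,
  activator/repressor sign from the TF–target expression correlation —
  including a numba-compiled Extra-Trees engine fast enough for multi-seed
  benchmarks;
- **Conserved regulatory edges**: GRN edges lifted to orthogroup space,
  conserved when realized in ≥ 2 species, stress-specific when both
  endpoints are co-directionally DE under the same category; significance
  by orthology-permutation enrichment (score = observed/permuted mean,
  significant iff BH p < 0.05 *and* score > 1);
- **TF function**: the regulatory strength
  R(m, g) = (1/S) Σ_i [ Σ_j t_j(m,g)/B(m) ] / T_i of TF family *g* over
  bin *m*, and a permutation test matching conserved TFs' stress
  categories against reference-species best-hit annotations;
- **A synthetic study generator** (3 species × 31 conditions × 3
  replicates, negative-binomial counts, many-to-many orthology, planted
  DEGs/conserved responses/regulatory edges) whose ground truth every
  stage is tested to recover.

## Worked example

```python
from stressnet import generate_study, StudyConfig
from stressnet.synthetic import demo_experiments
from stressnet.diffexp import call_degs, call_all_degs
from stressnet.pathway_ndei import compute_bin_counts, compute_ndei
from stressnet.conservation import degs_to_og_sets, conserved_orthogroups

study = generate_study(StudyConfig(experiments=demo_experiments()), seed=7)

deg, contrast = call_degs(study.counts["speciesA"], "phosphate", "0%")
print(f"{len(deg.table)} DEGs ({len(deg.genes('up'))} up, {len(deg.genes('down'))} down)")

degs = {sp: call_all_degs(study.counts[sp]) for sp in study.config.species}
ndei = compute_ndei(compute_bin_counts(degs["speciesA"], study.bins, "speciesA"))

cats = {(r.experiment, str(r.level)): r.category
        for r in study.counts["speciesA"].design.itertuples(index=False)}
og_de = {(sp, cond): d for sp in degs
         for cond, d in degs_to_og_sets(degs[sp], study.ogmap, sp).items()}
conserved = conserved_orthogroups(og_de, cats, list(study.config.species))
for key, ogs in sorted(conserved.items()):
    print(key, len(ogs))
```

prints

```
111 DEGs (64 up, 47 down)
('nitrogen', 'deficient', 'down') 30
('nitrogen', 'deficient', 'up') 31
('nitrogen', 'surplus', 'down') 8
('nitrogen', 'surplus', 'up') 6
('phosphate', 'deficient', 'down') 20
('phosphate', 'deficient', 'up') 27
('phosphate', 'surplus', 'down') 7
('phosphate', 'surplus', 'up') 6
```

— phosphate starvation (0% P) removes all phosphate from the medium, and
111 of the 500 genes respond more than two-fold with BH-adjusted p ≤ 0.05;
the conserved-orthogroup tallies say, e.g., that 27 orthologous gene
groups are upregulated under phosphate deficiency in all three species,
the set a cross-species follow-up would start from.

The same analysis end to end, from the shell, on a freshly generated
synthetic study:

```
stressnet run-all --demo --seed 7 --out runs/demo
```

writes `degs.tsv`, `ndei.tsv`, `bin_significance.tsv`,
`conservation_matrix.tsv`, `conserved_orthogroups.tsv`, per-species GRN
edge tables, `conserved_edges.tsv`, `stress_specific_edges.tsv`,
`enrichment.tsv`, `regulatory_strength.tsv`, GraphML networks per stress
category, and a manifest with seeds and input checksums. Reruns with the
same seed and config are byte-identical. For real data, point `--data` at
a directory of expression/design/orthogroup/bin/TF TSVs (see
`docs/methods.md` for formats) and `--deg-table` at externally computed
DEG tables.

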