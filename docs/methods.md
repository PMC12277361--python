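# Methods

`stressnet` implements a cross-species comparative analysis of abiotic-stress
transcriptomes: differential expression against per-experiment controls,
functional-bin statistics (hypergeometric over-representation and the
Normalized Differential Expression Index), Jaccard-index conservation of
stress responses with permutation nulls, tree-ensemble gene regulatory
network (GRN) inference with orthology-aware conserved-edge detection, a
TF-family regulatory-strength score, and a reference-species
functional-conservation test. This note records the models, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Study design and condition classification

The analysis assumes a multi-species hydroponic stress survey: several
experiment axes (nutrient dilution series such as 0/25/50/100/150% nitrogen,
phosphate and potassium; temperature; light intensity; photoperiod; light
quality), each with a designated control level per species, and three
biological replicates per condition. A stress level above its experiment's
control is *surplus*, below is *deficient*; levels are compared numerically
after stripping units (`150%`, `35C`, `8h`). Light-quality ratios (`4:1:0`)
have no order, are categorized *other*, and are excluded from
surplus/deficient-matched conservation, which requires the dichotomy.
Control levels are resolved per species because real designs use different
controls per species (e.g. different control temperatures); a design table
may flag the control row explicitly, and `100%` is assumed for percentage
axes otherwise.

## Differential expression stand-in

For real data the intended caller is an external negative-binomial GLM
framework whose table of per-gene log2 fold changes and BH-adjusted
p-values is injected verbatim (`--deg-table`). The built-in caller exists so
the pipeline is exercisable end to end on synthetic counts, and makes three
deliberate choices:

- **Normalization.** Counts are scaled to CPM, then the contrast's columns
  are rescaled by median-of-ratios size factors (median ratio to the
  geometric-mean profile over genes expressed in all samples). Total-count
  scaling alone suffers composition bias: a handful of strongly induced
  abundant genes inflates a library and makes every other gene look
  downregulated, which measurably broke false-discovery control on the
  synthetic study.
- **Test.** Welch's t on log2(CPM + 1), with empirical-Bayes variance
  moderation: per-gene group variances are squeezed toward a lowess trend
  of log-variance on mean abundance, with a prior df fitted by the classic
  moments-of-log-variances recipe, and the prior df augments the
  Welch–Satterthwaite df. A plain Welch t at 3-vs-3 cannot survive BH
  correction (its p-values bottom out near 1e-2); moderation is what every
  small-sample RNA-seq caller does, in the simplest transparent form.
- **Thresholds.** A gene is a DEG iff |log2FC| >= 1 and BH-adjusted
  p <= 0.05; the `DEGTable` type enforces this invariant structurally.
  Genes under 1 mean CPM in both groups are untested. The pseudocount is
  1 CPM.

This stand-in is a testing device, not a replacement for a dispersion-
shrinking NB model on real data.

## Bin statistics and NDEI

Functional bins form a 4-level hierarchy of dot-separated codes; a gene
assigned to a bin belongs to every ancestor. Over-representation of a
condition's DEGs in a bin uses the hypergeometric upper tail (survival
function) on the overlap, separately for up- and downregulation, with the
universe equal to the species' tested genes; BH correction spans all bins
and both directions within one condition. A bin significant in both
directions forms the "both" class.

NDEI(σ, m) = (U − D)/B, with U and D the bin's up/down DEG counts under
stress σ and B the bin's gene count in that species; it is bounded in
[−1, 1] and undefined for empty bins. Function-function association is the
Pearson correlation of two same-level bins' NDEI vectors across a species'
conditions (t-approximation p-values, n−2 df, BH across pairs; constant
vectors and pairs with fewer than 3 shared conditions are skipped). A bin
pair is called a conserved function pair for a stress category when both
bins are significantly DE co-directionally in at least `min_species`
species under the same condition, in at least `min_conditions` conditions;
both thresholds are parameters because the stringent display filter
(3 species, >= 5 conditions) and the definitional one (>= 2 species)
are both legitimate.

## Jaccard conservation and conserved orthogroups

Within a species, JI = |A∩B|/|A∪B| between condition DEG sets, per
direction; across species, DEG sets are lifted to orthogroups first (a DE
gene marks its orthogroup; paralogs that disagree within a species mark
the orthogroup for each supported direction). Two empty sets give JI = 0
and the pair is flagged untestable. Significance comes from a size-matched
resampling null — each permutation draws random sets of the observed sizes
from each side's universe — with the plus-one estimator
p = (1 + #{JI_perm >= JI_obs})/(1 + n_perm), n_perm = 1000, BH across the
matrix. The permuted JI is sampled exactly through a three-stage
hypergeometric decomposition of the overlap instead of materializing the
sets, which is distribution-identical (property-tested) and orders of
magnitude faster. Because JI is discrete, permutation p-values are
super-uniform when the sets are small; the calibration checks use sets
large enough (hundreds of elements) that discreteness is negligible.

A conserved orthogroup for (experiment, category, direction) is one DE in
that direction in *all* species under some condition of that category of
that experiment. The deficient category pools all sub-control levels.
Combination counts over category memberships (upset counts) are reported.
The across-species JI universe is the set of orthogroups with members in
the respective species, not all genes (configurable).

## GRN inference and conservation

GRNs follow the GENIE3 scheme: for each target gene (the species' DEG
union, TPM values), a tree ensemble regresses the target's unit-variance
profile on all TF profiles (a TF never regresses on itself), and the edge
weight is the ensemble's *unnormalized* variance-reduction importance —
normalizing importances per target would grant a pure-noise target the
same total weight as a well-explained one and corrupt the global ranking.
Three engines share this contract: sklearn random forests (1000 trees,
sqrt feature sampling — the published defaults), sklearn extremely
randomized trees, and a numba-compiled Extra-Trees kernel (the pipeline
default) that reproduces the sklearn ranking (Spearman ≈ 0.94 on planted
benchmarks) at ~17× the speed. Networks keep the top 5% of non-zero-weight
edges, globally ranked with a deterministic lexicographic tie-break and a
ceiling rule so small networks are never empty; per-target ranking is
available as an option. Edge sign is the Pearson correlation of TF and
target TPM: positive = activator, negative = repressor, zero or constant
profiles = unsigned.

Retained edges are lifted to orthogroup pairs; an OG edge is conserved
when realized in >= 2 species (the 1/2/3-species strata are reported). A
conserved edge is *stress-specific* for a category when, in >= 2 supporting
species, a realization has both endpoint genes DE under a condition of
that category with the same (TF, target) direction pattern; requiring only
the target's DE status is exposed as a flag. TFs of surviving edges are
the stress-specific conserved TFs. Significance of a conserved-edge count:
permutations shuffle the gene→orthogroup assignment within each species
(preserving every network's topology and each species' OG size spectrum),
enrichment = observed / mean(permuted), plus-one p, BH across species
pairs; significance requires both BH p < 0.05 and enrichment > 1. One
caveat this null does not remove: if the regulator sets themselves are
orthologous across species (as they are in real genomes), edges
concentrate on shared TF orthogroups and produce baseline conservation
above the fully shuffled null — observed enrichment measures regulator
*and* target conservation jointly.

## TF function and the regulatory-strength score

A conserved TF's predicted functions are the bins of its retained targets,
normalized by bin size: t_j(m)/B(m), emitted at every bin level for
concentric-network export. Per species, family g's term for bin m is
(Σ_j t_j(m,g)/B(m)) / T_i over the family's conserved TFs; the
regulatory strength R(m, g) is the arithmetic mean of these terms across
the S species. In the score's formal statement the summand is the per-TF
target count t_j — read so because the sum over the family's TFs is
otherwise vacuous; an oracle test pins this interpretation. By default S
is the full species count and species lacking the family contribute zero
(keeping R comparable across families); shrinking S to species where the
family is present is a flag. R is a mean, not a sum, so duplicating a
species cannot inflate it.

The reference-species test maps each conserved TF's DE stress categories
to its best hit's annotated function terms through an editable lexicon
(category → case-insensitive term patterns, e.g. phosphate-deficient ↔
"phosphate starvation"); a TF matches if any category pattern hits any
term. TFs regulating fewer than five level-1 bins, or lacking a best hit,
are excluded. Significance permutes which stress profile each TF carries
(1000 times, hits fixed; the identity permutation reproduces the observed
count), with enrichment and plus-one p as above. Without a supplied
best-hit table the pipeline's demo constructs a synthetic, perfectly
concordant stand-in table from the TFs' own categories — it demonstrates
the machinery, not a biological result.

## Synthetic study generator

The generator emulates the study design rather than the sequencing: 3
species × 500 genes (20 TFs in eight families) × three replicates over
the full 31-condition design (a 10-condition two-axis variant serves quick
runs). Counts are negative binomial with dispersion 0.1 (typical bulk
RNA-seq overdispersion) around condition-specific means; base means are
log-uniform on [10, 1e4]; TPM is the column normalization of the same
counts to 1e6. Orthology is ~70% single-copy 1:1:1 groups, ~20% with a
duplication in one species, ~10% species-specific genes; TFs are
single-copy orthologs. Bins form an 8-root, branching-3, depth-4
hierarchy; orthologous genes share a terminal bin.

Planted structure, all recorded in a truth manifest: (i) per-condition
background DEGs (25 up + 25 down per condition per species, |log2FC| = 2);
(ii) conserved orthogroup responses — ~10% of eligible multi-species
orthogroups each DE in one direction in every species across all
conditions of one stress category; (iii) TF activity patterns shared
across species; (iv) conserved regulatory edges — TF-orthogroup →
target-orthogroup pairs realized as concrete gene pairs in each chosen
species with co-directional DE under a shared category; and (v) per-species
regulatory couplings in which a target's log2 mean tracks its TF's
condition profile z-score with coefficient ±0.8. DEG truth is derived
from the final effect matrix as effect(condition) − effect(control), at
the |log2FC| >= 1 definition, because couplings shift control conditions
too.

Two detectability guarantees make the planted truth a *recoverable*
target rather than a lottery: planted conserved responses and edge
endpoints sit on genes with base mean >= 100 (a 4-fold change on a
10-count gene is not reliably detectable at three replicates), and
conserved planting uses only categories with >= 2 conditions so every
response has redundant detection trials. The general gene population keeps
the full base-mean range. Generation is a pure function of (config, seed)
through one counter-based stream; identical inputs give byte-identical
files.

What the generator does not emulate: read-level noise, gene length and GC
effects, batch effects, correlated biological replicates, unannotated
genes, or orthology errors. Passing recovery tests therefore show the
statistics and bookkeeping are correct at realistic effect sizes and
replication — not that the pipeline's conclusions on real tissue are
robust to those artifacts; for real data the external DEG-table route and
a real orthology are the intended inputs.

## Problem sizes and numerical choices

Recovery experiments run at the sizes the package documents as its
benchmark conditions: the full 31-condition study for single-study
recovery (DEG sensitivity/FDP, GRN AUROC at 100 trees with the compiled
kernel, conserved-orthogroup recall, edge enrichment at 1000
permutations), and twenty seeded 10-condition studies for the
conserved-edge significance rate. Permutation counts default to 1000
(plus-one p floor 1/1001). The demo pipeline (3 × 500 genes × 10
conditions × 3 replicates) completes in well under ten minutes on one
CPU. Ties in edge ranking break lexicographically; BH is applied within
the families stated above; all randomness flows from explicit integer
seeds and reruns are byte-identical.

## Known limitations

- The DE stand-in's FDR control is approximate (moderated t on log-CPM,
  not an NB likelihood); measured false-discovery proportion on unplanted
  genes is ~1–2% at the benchmark conditions, but heavy-tailed real data
  may behave worse.
- The orthology-shuffle null for edge enrichment is unstratified; see the
  regulator-orthology caveat above.
- JI permutation p-values are conservative for very small DEG sets
  (discreteness).
- The category → function-term lexicon is a curated stand-in for GO-based
  annotation of reference best hits and should be edited per study.
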