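# dysbiome

Case/control gut-microbiome analysis pipeline with a fully synthetic,
seeded data generator. The package implements the complete statistical
workflow of a metagenomic case/control study:

- **transforms** — closure, CLR with multiplicative zero replacement,
  per-cohort prevalence filtering (`any`/`all` modes), Blom inverse-rank
  normal transform.
- **community** — Shannon index, Bray–Curtis distances, classical PCoA
  (negative eigenvalues retained and flagged), covariate-adjusted
  PERMANOVA with sequential sums of squares and label permutation,
  Wilcoxon rank-sum and Dunn's post-hoc tests.
- **differential** — per-feature OLS of CLR+INT abundance on cohort plus
  covariates, BH-FDR, fold changes, enriched/depleted feature-set
  definition, cross-cohort replication checks.
- **scores** — Prevotella/Bacteroides ratio and the per-sample log2
  geometric-mean ratio score over enriched vs. depleted sets (dysbiosis
  index for species, function-imbalance score for pathways); sets travel
  as plain TSV so scoring an external cohort is a file-level operation.
- **associations** — residualised (partial) Spearman scans with BH-FDR
  and optional second-pass covariates, INT-linear cytokine group
  comparisons, Cochran's Q heterogeneity with Fisher-z support for
  correlations.
- **strains** — binary Jaccard distances over gene-family
  presence/absence, complete-linkage clustering cut at a fixed height
  with small-cluster exclusion, Fisher-exact cluster/cohort enrichment,
  per-gene logistic regression with an exact-test fallback under perfect
  separation, one-sided hypergeometric Pfam over-representation, and
  strain–phenotype association with indicator or abundance encoding.
- **simulate** — seeded generators for metadata, log-normal
  compositional abundance tables with planted enriched/depleted
  features, two-archetype gene-family matrices with cohort-biased strain
  membership, and cytokines with planted covariate-confounded taxon
  associations. Ground truth is returned alongside every table.

## CLI

```sh
# full synthetic run, one seed drives everything
dysbiome all --seed 1 --out results/run1

# individual, restartable stages (read/write only declared TSVs)
dysbiome simulate  --seed 1 --out results/run1
dysbiome transform --seed 1 --out results/run1
dysbiome da        --seed 1 --out results/run1
```

A YAML config can set any `PipelineConfig` field (thresholds, covariate
lists, simulation block); CLI flags override the file and the merged
effective config is written next to the outputs. All outputs are TSV
with `#`-prefixed provenance headers (config hash, seed, version — no
timestamps), so reruns with the same config and seed are byte-identical.

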