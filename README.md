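# mirisk

Statistical analysis toolkit for miRNA expression profiling with survival
endpoints, built around a myeloma-style study design: probe-by-sample
expression matrices, clinical annotations with cytogenetic flags and
EFS/OS outcomes, and miRNA-target prediction tables.

Components:

- **datamodel** — TSV readers/writers and validated containers for
  expression matrices (`#scale=` tagged), clinical annotations, and
  gene-by-tool prediction tables.
- **preprocess** — constant scaling + log2 transform (smallest value maps
  to 1), rank-invariant normalization to a frozen reference profile with a
  monotone piecewise-linear per-sample mapping. Models serialize to JSON so
  a frozen reference can be shipped with a signature.
- **diffexpr** — probe-wise two-group linear models, empirical-Bayes
  moderated t-statistics (method-of-moments hyperparameters on log
  variances), Benjamini–Hochberg FDR, and signed fold-change reporting
  (`2^logFC` up, `-2^(-logFC)` down, rounded half-away-from-zero).
- **survival_stats** — Cox proportional hazards (Efron ties, Newton with
  step-halving), two-group log-rank test, and maximally selected rank
  statistics with the Lausen–Schumacher improved-Bonferroni adjustment.
- **signature** — PCA risk signatures: project samples onto the first two
  principal axes, fit bivariate Cox models for EFS and OS, score samples
  with the averaged coefficient pair, dichotomize at a maxstat-selected
  cutoff. Frozen signatures transfer to independent cohorts by
  documentation-by-value (frozen normalization reference, centers,
  loadings, coefficients, cutoff — no refitting). Target-gene risk scores
  reuse the same algorithm on predicted-target mRNA rows.
- **association_targets** — variance filter (keep the top fraction by
  variance), all-pairs Pearson miRNA–mRNA screen with BH control and a
  leave-one-out influence flag, ≥k-of-n tool consensus target filter,
  permutation global association test, Wilcoxon / Fisher group tests.
- **cluster_report** — centered-Pearson dissimilarity, average-linkage
  (UPGMA) dendrograms with newick export, per-group branch-purity reports.
- **synthetic_data** — cohort generator with planted differential probes,
  a latent prognostic factor driving exponential-hazard survival,
  miRNA→mRNA correlation links, aberration subgroups, risk indices, and a
  shifted independent validation cohort; ground truth is returned for
  recovery tests.

## CLI

```sh
mirisk simulate --outdir fixtures --seed 1            # synthetic fixture set
mirisk run-all --fixture-dir fixtures --outdir results --seed 1
mirisk de --matrix fixtures/mirna.tsv --annotations fixtures/annotations.tsv \
          --contrast MM,BMPC --out de.tsv
mirisk survive --matrix fixtures/mirna.tsv --annotations fixtures/annotations.tsv \
          --endpoint efs --out survival.tsv
mirisk signature-build --matrix fixtures/mirna.tsv \
          --annotations fixtures/annotations.tsv \
          --features mir-sim-001,mir-sim-002 --out signature.json
mirisk signature-apply --signature signature.json \
          --matrix fixtures/validation_mirna.tsv --out scores.tsv
mirisk correlate --mirna fixtures/mirna.tsv --mrna fixtures/mrna.tsv --out hits.tsv
mirisk cluster --matrix fixtures/mirna.tsv \
          --annotations fixtures/annotations.tsv --out cluster.txt
```

`run-all` executes the full workflow (differential expression for the main
contrasts, the per-probe Cox survival screen, signature construction and
transfer to the validation cohort, the correlation screen, clustering) and
writes a manifest plus a plain-text summary. Runs are deterministic for a
given seed; rerunning reproduces byte-identical outputs.

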