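# smrkit

Summary-data Mendelian randomization (SMR) for multi-omics integration:
screen GWAS loci for trait associations mediated by gene expression or DNA
methylation, using only per-SNP summary statistics from non-overlapping
samples.

For each molecular probe, the top cis SNP (smallest QTL p within a window
around the probe, below an instrument threshold) acts as the instrument; the
effect of the molecular phenotype on the trait is the Wald ratio
`b_zy / b_zx`, tested with the combined statistic
`T = z_zy² z_zx² / (z_zy² + z_zx²)` against chi-square(1). Downstream stages
intersect significant genes between analyses (e.g. cohorts or ancestries)
and cross-reference significant SNPs against methylation-QTL evidence.

## Modules

| module | what it does |
|---|---|
| `smrkit.sumstats_io` | read/write GWAS and QTL flat files (configurable column dialects, gzip-transparent), write/read result reports |
| `smrkit.harmonize` | rsID intersection and effect-allele alignment (swap detection, strand-ambiguity policy, rejection tally) |
| `smrkit.smr_core` | cis instrument selection, Wald-ratio estimate, delta-method SE, the chi-square(1) test, thresholding policies |
| `smrkit.multiomics` | gene-set overlap, SNP de-duplication with provenance, mQTL cross-reference (SMR or nominal-lookup mode), per-source mQTL eligibility filters |
| `smrkit.synthetic_data` | linked GWAS/eQTL/mQTL summary-statistic generator with known ground truth (null / causal / pleiotropy architectures) |
| `smrkit.pipeline_cli` | end-to-end orchestration, YAML run configs, JSON-lines run log, `smrkit` CLI |

## CLI

Generate a deterministic synthetic fixture (two GWAS cohorts sharing one
QTL truth, plus linked methylation probes):

```sh
smrkit simulate --seed 42 --out fixture/ --n-probes 8 --n-cohorts 2 \
    --n-mqtl-linked 8 --n-mqtl-effects 5
```

Run the full analysis from a config file:

```sh
smrkit run-all --config run.yaml
```

with `run.yaml` like:

```yaml
gwas:
  - {path: fixture/gwas_cohort1.tsv, label: cohort1, trait: stroke}
  - {path: fixture/gwas_cohort2.tsv, label: cohort2, trait: stroke}
eqtl_path: fixture/eqtl.tsv
mqtl_path: fixture/mqtl.tsv
mqtl_mode: lookup          # or "smr"
out_dir: run1
smr: {window_bp: 1000000, p_qtl_max: 5.0e-8, alpha_policy: bonferroni}
```

The run directory contains one `<label>.smr.tsv` report per GWAS input
(SNP / P-value / Gene plus estimate, SE, statistic, probe id), a
`<label>.significant.tsv` subset, pairwise `overlap.*.tsv` gene reports, an
`mqtl_xref.tsv` cross-reference, and a `runlog.jsonl` machine-readable log
(row counts, rejection tallies, resolved thresholds, version). Reruns are
byte-identical.

Single stages are also exposed: `smrkit smr`, `smrkit read-check`,
`smrkit mqtl-xref`. Real consortium files are read by naming a column
dialect (`--gwas-dialect megastroke`) or supplying a custom mapping in code.

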