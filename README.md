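# cardioqtl

Statistical procedures for a case/control cardiac transcriptome-genetics
study, re-implemented as a tested Python package: differential expression and
exon usage, cis and condition-specific eQTL mapping, an exon-by-genotype
interaction splicing-QTL model, allelic-imbalance analysis, LD-block GWA
enrichment, SNP functional-annotation enrichment, and a multilocus genetic
risk score. A synthetic cohort generator reproduces the statistical structure
the analyses assume, so the full pipeline runs end-to-end without any patient
data.

## Layout

| Module | Contents |
| --- | --- |
| `cardioqtl.synthetic` | cohort generator (HWE genotypes, NB counts, binomial exon inclusion, allele counts, planted effects of every class), GWA summary simulator |
| `cardioqtl.prep` | quantile-based count scaling, RPKM, expression filters, quantile normalization, rank-inverse-normal transform, covariate adjustment, fibroblast score, genotype utilities (rare-homozygote folding, concordance, PCs) |
| `cardioqtl.differential` | Wilcoxon–Mann–Whitney differential expression with the log(1.2) fold gate, PSI-based differential exon usage (nested F test, 0.1 effect gate), negative-binomial fitting, and the sensitivity/FDR simulation study |
| `cardioqtl.qtl` | cis-pair construction (1 Mb window), matrix eQTL scan, group-specific eQTL test with slope CIs, Cochran–Armitage trend test, sQTL interaction model, Storey q-values |
| `cardioqtl.ase` | ASE site filters, per-individual expected ratios, resampled binomial imbalance test, case/control differential imbalance (FET + proportion test), LD pruning |
| `cardioqtl.enrichment` | LD blocks (connected components at r² > 0.6), block-level GWA rank-sum enrichment, causal-SNP logistic annotation model, distance bins, hexamer matching, gene-set Fisher tests, GWA↔eQTL intersection |
| `cardioqtl.riskscore` | rank-based AUC, L1-penalized logistic regression with nested CV and the 1-SE lambda rule |
| `cardioqtl.io` / `cardioqtl.pipeline` / `cardioqtl.cli` | TSV/VCF/BED readers and writers, stage orchestration, CLI |

## CLI

Each analysis stage is a subcommand; `run-all` chains them:

```sh
cardioqtl run-all --seed 1 --outdir results/
cardioqtl simulate --config config.yaml
cardioqtl eqtl --seed 2 --outdir results/
```

Configuration is a YAML file mirroring `cardioqtl.pipeline.PipelineConfig`
(cohort sizes, planted effects, thresholds, windows, PC counts, seed).
Outputs are TSV tables with a provenance header (`# cardioqtl=<version>
config=<hash> seed=<seed>`); reruns with the same config and seed are
byte-identical.

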