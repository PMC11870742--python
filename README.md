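# antigenome

A reusable Python implementation of a phage-display autoantigen
screening pipeline: simulation of large-fragment cDNA phage libraries
and serological screens, in-silico two-plasmid ORF filtering with
library QC, count normalization and binary selection calls, a
Kruskal-Wallis / Benjamini-Hochberg differential-selection cascade with
split-set reproducibility, sequence-property enrichment (Chou-Fasman,
Emini, Parker, GRAVY, pI) via a GSEA-style running sum, and L1-penalized
logistic biomarker models with nested cross-validation and Shapley
attribution.

Because the underlying serological data are not publicly deposited, the
package ships a first-class synthetic-data module
(`antigenome.synthetic_data`) that generates proteomes, fragment pools,
serum reactivity profiles, and multinomial sequencing counts with known
ground truth; all calibration and recovery tests run against it.

## Layout

| module | contents |
| --- | --- |
| `synthetic_data` | proteome / fragment-library / serum-cohort / count simulation, dataset emission |
| `library_build` | ORF read-through screen, clone validation stats, library complexity and coverage QC |
| `profiles` | count matrices, CPM + log normalization, batch factors, selection calls, replicate QC |
| `differential` | KW test, BH FDR, prevalence-filtered cascade, split-set reproducibility, overlap algebra, longitudinal pairing |
| `seqfeatures` | residue scales, Emini surface probability, Chou-Fasman fractions, pI, running-sum enrichment |
| `predictor` | lasso-logistic paths, nested CV, AUC, effect shares, linear SHAP |
| `workbench` | YAML config validation, seeded pipeline orchestration, CLI backing |

## CLI

```sh
antigenome run --config config.yaml --seed 1 --out runs/demo
antigenome simulate --out runs/simonly           # single stages also work
antigenome diff --inputs runs/demo/data --out runs/diff
```

An empty (or missing) config file means "all defaults": a 2,000-protein
simulated screen with 102 case donors in four subgroups, 43 healthy
controls, three time points, planted disease antigens, and every stage
enabled. `antigenome run` writes TSV/JSON artifacts plus a config hash;
rerunning with the same config and seed reproduces every artifact
byte-for-byte.

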