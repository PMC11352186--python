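# pairomics

Matched-pair multi-omics analysis pipeline for LC-MS metabolomics/lipidomics
and processed proteomics tables: preprocessing, paired differential
statistics with robust fold changes, multi-omics signature selection,
clustering/classification evaluation, and probabilistic-network
integration. A synthetic study generator with planted ground truth makes
every stage testable end to end.

## Components

| module | what it does |
| --- | --- |
| `pairomics.datamodel` | `OmicsDataset` / `MatchedDesign` / `KnowledgeGraph` / `ConsensusNetwork` with validated invariants |
| `pairomics.io` | TSV/CSV readers and writers, GraphML/SIF/TSV network export |
| `pairomics.synthetic` | matched case–control generator: planted effects, injection-order drift, MNAR missingness, internal standards, planted interaction network |
| `pairomics.preprocess` | lipid line consolidation, group presence filter, QC random-forest drift correction, feature-wise knn imputation, multi-internal-standard normalization, QC CV reporting |
| `pairomics.diffstats` | paired t / Wilcoxon signed-rank / sign tests, per-layer BH adjustment, signed one-step Tukey-biweight fold change |
| `pairomics.signature` | \|tFC\| threshold selection and elastic-net leave-one-out stability selection (own JIT-compiled path solver) |
| `pairomics.evaluate` | UPGMA clustering + Fisher exact association, PCA+SVM leave-one-out classification, rank AUC with bootstrap CI |
| `pairomics.network` | hill-climbing Gaussian-BIC structure learning, bootstrap model averaging, knowledge-based strength modification, L1-CDF significance threshold, subnetwork extraction |

A reference table of published differential-abundance results for 109
molecules (three omics layers) is bundled (`pairomics/data/differential_reference.tsv`) and
loadable via `pairomics.reference`.

## CLI

```bash
pairomics --seed 3 --out-dir run1 --config config.yaml run-all
```

Subcommands `simulate`, `preprocess`, `diff`, `signature`, `evaluate`,
`network` run individual stages against the files in `--out-dir`. The
YAML config mirrors the option dataclasses in `pairomics.config`
(sections `simulate`, `preprocess`, `diff`, `signature`, `evaluate`,
`network`), e.g.:

```yaml
simulate:
  n_pairs: 15
  n_features: {metabolite: 219, lipid: 161, protein: 100}
preprocess:
  presence_rule: either
  n_trees: 500
signature:
  fc_cutoff: 1.5
network:
  n_bootstrap: 1000
  knowledge_weight: 0.3
```

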