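# connfact

Latent connectivity-factor modelling of functional connectomes.
`connfact` decomposes whole-brain functional-connectivity data into K
co-expressed latent factors with a from-scratch variational-Bayes LDA,
predicts factor expression in unseen individuals, quantifies
factor–symptom associations with permutation-tested CCA (site-aware,
BH-FDR corrected), and scores individual-level profile overlap with a
Dice statistic — all exercisable on synthetic cohorts with planted
ground truth.

## Layout

| module | role |
| --- | --- |
| `connfact.synthetic` | cohort generator: sparse signed factor profiles in network blocks, Dirichlet subject mixtures, coupled phenotypes, pre/post treatment pairs |
| `connfact.connectome` | Pearson FC matrices, half-vectorization, control-referenced deviation (w-)scores, signed count encoding, network-block summaries |
| `connfact.lda` | batch variational EM for LDA, out-of-sample inference, factor matching, subject-bootstrap profile CIs, ELBO, K-scan |
| `connfact.association` | residualization, scalar-side CCA with within-site permutation p, BH-FDR, rank-sum group/longitudinal tests, Spearman change coupling |
| `connfact.similarity` | top-fraction / paired-altered edge sets, Dice coefficient, region contribution ranking |
| `connfact.cli` + `connfact.config` | YAML-configured end-to-end pipeline |

## CLI

Every stage reads one YAML config (unknown keys rejected; all
randomness derives from one root seed):

```sh
connfact simulate  --config run.yaml     # synthetic cohort + ground truth
connfact fit       --config run.yaml     # LDA fit + bootstrap profile CIs
connfact infer     --config run.yaml     # loadings for unseen subjects
connfact associate --config run.yaml     # permutation-tested CCA tables
connfact dice      --config run.yaml     # per-subject profile overlap
connfact report    <out_dir>             # markdown summary
```

Minimal config:

```yaml
seed: 7
paths: {out_dir: run1}
simulate: {n_patients: 60, n_controls: 30, k: 3, n_regions: 32}
model: {k: 3, n_restarts: 4}
stats: {n_perm: 1000, n_boot: 50, covariate_columns: [cov1]}
```

Inputs for real data are plain text: one `R x R` CSV connectivity
matrix per subject, a `subjects.csv` manifest (`subject_id`, `group`,
optional `site` and `cov*` columns), a parcellation TSV
(`region_id`, `region_name`, `network`) and a phenotype CSV with a
`scales.json` manifest mapping scale names to item columns.

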