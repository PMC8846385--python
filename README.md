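# m6apattern

Analysis toolkit for **N6-methyladenosine (m6A) regulator patterns in breast-cancer
transcriptomes**. m6A is the most common reversible mRNA modification, installed by
*writer* methyltransferases, removed by *eraser* demethylases, and bound by *reader*
proteins. The expression of the 23 canonical regulators stratifies breast tumors into
modification patterns that differ in prognosis, immune-cell infiltration and mutation
burden. `m6apattern` implements that analysis end-to-end as a tested, reusable
library and CLI:

1. **Consensus subtyping** — Monti-style resampled consensus clustering of samples
   on the 23-regulator expression profile (and, later, on the subtype-related gene
   space), with PAC and delta-area k selection.
2. **Single-sample enrichment** — the ssGSEA rank-weighted running-sum statistic and
   a GSVA-like ECDF variant, for tumor-microenvironment cell abundance and pathway
   activity, plus hypergeometric over-representation with Benjamini–Hochberg FDR.
3. **Differential expression** — empirical-Bayes moderated *t* between clusters
   (gene variances shrunk toward a prior estimated by digamma/trigamma moment
   matching), DEG gate |log2FC| > 1 and p < 0.05, and the cross-contrast overlap.
4. **The m6Ascore** — univariate Cox filtering of the overlap DEGs, z-scoring, PCA
   by SVD, and the per-patient score

   `m6Ascore = PC1 projection + PC2 projection = Σᵢ (v1ᵢ + v2ᵢ) · zᵢ`

   summing each signature gene *i*'s standardized expression weighted by the first
   two component loadings (the Genomic-Grade-Index-style construction).
5. **Survival statistics** — Kaplan–Meier, multi-group log-rank, Cox proportional
   hazards (Efron ties; a vectorized univariate screen for thousands of genes), and
   the survminer-style maximally selected cutpoint: the threshold maximizing the
   absolute standardized two-group log-rank statistic inside a minprop quantile
   window.
6. **Genomic associations** — tumor mutational burden from MAF records
   (maftools nonsynonymous classes), per-group mutation frequencies, copy-number
   gain/loss frequencies, and score–TMB / score–IPS association tests.

Because the original cohorts (TCGA-BRCA plus GEO series GSE21653, GSE24450,
GSE42568, GSE45255, GSE51783 and GSE61304 — see
`m6apattern.cohort_manifest()`) must be downloaded by the user, the package ships a
first-class **synthetic cohort generator** with planted ground truth: regulator-driven
sample clusters, cluster-specific DEGs and immune-set activity, exponential survival
tied to a latent per-sample score, Poisson mutation burden anti-correlated with that
score, and planted regulator copy-number events. Every pipeline stage is therefore
testable offline, and recovery of the planted structure is part of the test suite.

## Worked example

Run the full pipeline on a synthetic 300-patient cohort:

```python
from m6apattern.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo_run", seed=7,
                     simulate={"n_samples": 300}, reps=100)
summary = run_pipeline(cfg)
st = summary["stages"]
print(st["m6a_clusters"]["chosen_k"], st["m6a_clusters"]["cluster_sizes"])
print(st["diffexp"]["n_overlap_degs"], st["signature"]["n_signature_genes"])
print(st["signature"]["cutpoint"], st["signature"]["logrank_p"])
print(st["genomics"]["tmb_spearman"])
```

prints (seed 7):

```
3 {1: 100, 2: 100, 3: 100}
252 166
-8.742048481343645 5.871622073671337e-10
{'rho': -0.37248806779313903, 'p': 2.6256928867846268e-11}
```

Reading: consensus clustering selects k = 3 and recovers the three planted
modification patterns (100 patients each; adjusted Rand index 1.0 against truth).
The three one-vs-rest contrasts share 252 overlap DEGs, of which 166 are prognostic
(univariate Cox p < 0.05) and form the PCA signature. The survival-optimal cutpoint
(−8.74 on the score scale) splits the cohort into arms whose survival differs at
log-rank p ≈ 6e-10 (median 1196 vs 417 days), and the m6Ascore is negatively
correlated with tumor mutational burden (Spearman ρ ≈ −0.37, p ≈ 3e-11) — the
planted directional structure, recovered by the full analysis chain.

The same run is available from the shell:

```sh
m6apattern simulate --seed 7 --outdir cohort/
m6apattern run --config pipeline.yml --seed 7
```

Each stage also exists as a standalone subcommand (`cluster`, `enrich`, `deg`,
`score`, `survival`, `mutation`) operating on TSV/GMT/MAF files; all outputs are
TSV plus a JSON run summary, and every writer emits a sidecar manifest with input
hashes and parameters.

## Layout

```
src/m6apattern/
  data_model.py   containers, TSV/GMT/MAF readers+writers, regulator catalog
  synthetic.py    planted-truth cohort generator
  clustering.py   consensus clustering, PAC / delta-area k selection
  enrichment.py   ssGSEA, GSVA-like scores, pathway differential, ORA
  diffexp.py      moderated t, DEG selection, overlap
  survival.py     KM, log-rank, Cox, optimal cutpoint
  scoring.py      signature PCA, m6Ascore, stratification, associations
  genomics.py     TMB, mutation frequency, CNV frequency
  pipeline.py     stage orchestration and run summary
  cli.py          click CLI (`m6apattern`)
```

See `docs/methods.md` for the statistical methods, generator assumptions, numerical
conventions and known limitations.
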