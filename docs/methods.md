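# Methods

This note documents the statistical procedures implemented in `m6apattern`, the
assumptions behind the synthetic cohort generator, the numerical conventions, and
the limitations a user should keep in mind before applying the pipeline to real
cohorts.

## The regulator catalog

The built-in catalog holds the 23 canonical m6A regulators: 8 writers (METTL3,
METTL14, WTAP, VIRMA, RBM15, RBM15B, ZC3H13, CBLL1), 2 erasers (FTO, ALKBH5) and
13 readers (YTHDC1/2, YTHDF1/2/3, HNRNPC, HNRNPA2B1, FMR1, LRPPRC, RBMX,
IGF2BP1/2/3). Symbol canonicalization is uppercase-and-strip plus a small alias
table (KIAA1429 → VIRMA; the common misspelling LRPPPRC → LRPPRC), because the
literature uses both spellings. A user-supplied catalog that disagrees with the
23-gene enumeration is flagged rather than silently remapped.

## Consensus clustering

Samples are clustered on a feature list (regulators for the m6A clusters; the
overlap DEGs for the gene clusters) with Monti-style consensus clustering: `reps`
resamples (default 1000; features are never subsampled) each draw 80% of samples
without replacement, an inner clustering partitions each resample, and consensus
entry (i, j) is the number of resamples in which i and j co-clustered divided by
the number in which both were drawn. Pairs never co-sampled get consensus 0 with a
warning. The inner algorithm is average-linkage hierarchical clustering on
1 − Pearson correlation between samples (k-means on z-scored features is available);
final per-k labels come from average-linkage clustering of 1 − consensus as a
distance, renumbered by descending cluster size (ties by lexicographically smallest
member id) so "cluster 1" is always the largest.

Two k-selection rules are exposed. PAC (proportion of ambiguous clustering,
CDF(0.9) − CDF(0.1) of the off-diagonal consensus entries; argmin, ties to the
smallest k) and the Monti delta-area elbow (the largest k whose relative increase
in consensus-CDF area still exceeds 10%). **Delta-area is the default**: on a
cleanly separated k-cluster cohort the consensus matrix is perfectly binary not
only at the true k but also at smaller k (two true clusters merge identically in
every resample), so PAC ties at zero and its tie rule would systematically return
k = 2. The delta-area curve flattens exactly after the true k. The chosen k can be
overridden (`forced_k`) to honor an external choice such as the three-pattern
breast-cancer solution.

Everything is deterministic given the seed; small instances can return every
resample's assignments so the consensus matrix is verifiable against direct
recomputation (the test suite holds this to 1e-12).

## Single-sample enrichment

`ssgsea_scores` follows the original single-sample GSEA statistic: per sample,
genes are ranked by expression (descending; ties get average ranks); walking down
the ranked list, in-set genes advance the running sum proportionally to
rank^alpha (normalized to total 1, alpha = 0.25, the method's published default)
while out-of-set genes decrement uniformly; the enrichment score is the sum of the
running-sum deviations. Scores depend only on within-sample ranks, hence are
invariant under any strictly monotone transform of a sample's expression — this is
checked exactly in the tests. With `normalize=True` (default) all scores are
divided by the matrix-wide max − min.

`gsva_like_scores` is a lighter variant of GSVA: each gene's expression is replaced
by its centered cross-sample ECDF rank (requiring ≥ 3 samples), and the per-sample
running statistic weights in-set genes by |z|^tau; the score is the maximum
positive deviation plus the minimum negative deviation. The full GSVA
kernel-density CDF estimation and phenotype-permutation p-values are out of scope.

Sets are intersected with the expression matrix; sets with fewer than `min_size`
(default 2) surviving members are dropped with a warning. Over-representation of a
gene list uses the one-sided hypergeometric tail P[X ≥ overlap] with BH FDR.

## Moderated-t differential expression

For each contrast (three one-vs-rest contrasts by default; "overlap DEGs" is the
intersection of the per-contrast DEG lists, matching the Venn-core reading;
pairwise contrasts are available) the per-gene log fold change is the group mean
difference on the log2 scale, and the pooled residual variance s² has
d = n1 + n2 − 2 degrees of freedom. Empirical-Bayes shrinkage estimates a prior
(d0, s0²) by moment matching of log s²: the excess of Var(log s²) over
trigamma(d/2) identifies d0 through trigamma inversion (Newton, tolerance 1e-8);
no excess dispersion means d0 = ∞ (complete shrinkage). The posterior variance is
(d0·s0² + d·s²)/(d0 + d) and the moderated t = logFC/(s_post·c) is referred to a t
distribution with d0 + d df. Zero-variance genes are handled through the prior;
an all-zero-variance matrix is an error, and with fewer than 10 genes the prior is
inestimable and the fit falls back to the ordinary t with a warning. The DEG gate
is the raw-p rule |logFC| > 1 and p < 0.05 with strict inequalities (an FDR column
is always emitted; the gate can use it instead).

## Survival statistics

*Kaplan–Meier* is the product-limit estimator on the observed time grid; censored
times shrink the risk set without steps. *Log-rank* uses the standard
observed-minus-expected statistic over the pooled event grid (χ² with groups − 1
df); the two-group standardized form z = (O − E)/√V with the hypergeometric
variance V drives the cutpoint scan. *Cox* models use the Efron tie approximation
throughout: multivariate fits delegate to lifelines (Newton–Raphson on the partial
likelihood), while the univariate many-gene screen is an in-package Newton solver
vectorized across features (each feature an independent univariate model;
convergence |Δloglik| < 1e-9, 50 iterations max, steps clipped at ±2 to damp
monotone-likelihood blow-up; non-convergent or constant features are flagged, not
raised). The two routes agree to ~1e-6 in the tests when lifelines is run at
tight precision.

*Maximally selected cutpoint*: all distinct score values inside the
[minprop, 1 − minprop] quantile window (minprop = 0.1) are scanned; the cutpoint
maximizes |z|, ties resolve to the smaller value, and "high" means strictly
greater than the cutpoint. The selected-maximum p-value is *not* corrected for the
multiple looks by default (the report carries the statistic and scan table); an
optional permutation p (score permuted against outcome) is provided and controls
the selection optimism — the null calibration test shows the naive rejection rate
is inflated while the permutation rate stays near nominal.

## The m6Ascore

Overlap DEGs are screened by univariate Cox (keep p < 0.05 by default), z-scored
gene-wise (population sd — correlation-scale PCA, so merged cohorts with different
dynamic ranges contribute equally), and decomposed by SVD. The per-sample score is
the projection onto PC1 plus the projection onto PC2. The sum-over-genes formula
Σᵢ(PC1ᵢ + PC2ᵢ) is interpreted per sample — each projection is itself the sum over
signature genes of loading × standardized expression — consistent with the
Genomic-Grade-Index-style construction it cites; the literal alternative (summing
loadings only) would be a cohort constant and carries no information. SVD sign
ambiguity is removed deterministically: each component is flipped so its loading
sum is ≥ 0 (exact zero: the lexicographically first gene's loading is ≥ 0). A
training matrix of effective rank 1 yields a zero PC2 with a degeneracy flag.
Scoring a cohort requires all signature genes; missing genes raise with their
names. Scoring the training cohort gives mean 0 by construction.

Because the score's sign is a convention, association analyses against planted
truth align orientation by the sign of the score–latent correlation before
asserting directions.

## Genomic summaries

TMB counts MAF records in the maftools nonsynonymous classes (Missense, Nonsense,
Frame_Shift_Del/Ins, In_Frame_Del/Ins, Splice_Site, Translation_Start_Site,
Nonstop); silent and non-coding classes never count. Samples are counted against
an explicit universe (absent samples get 0) because a sample missing from a MAF is
otherwise ambiguous. Both the raw count (default report) and count per exome
megabase (default 38 Mb) are emitted. Mutation frequency per gene and group is
sample-level (a sample mutated twice counts once). CNV gain/loss frequency
thresholds calls at ±1 (configurable for continuous input).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
RNA-seq physics. Defaults (n = 300 samples, 2000 genes, seed-reproducible in
under a second):

- **Clusters** — 3 equal-size clusters; regulator genes shifted per cluster by
  ±2 z (a random ± pattern per cluster/regulator) on unit-variance Gaussian noise;
  expression offset to a log2-like positive scale (mean ≈ 8).
- **DEGs** — 100 genes per cluster, up `deg_effect` = 2 log2 units in their driver
  cluster and down effect/2 elsewhere, so every one-vs-rest contrast separates
  every planted gene and the cross-contrast overlap is non-degenerate.
- **Latent score** — per-sample score with cluster means +1/0/−1 (first cluster
  highest) plus N(0, 0.75) noise, standardized. 100 of the DEGs additionally load
  1.5 z per score unit ("prognostic genes"), making the score the dominant
  variance axis of the Cox-retained genes — this is what makes the planted score
  recoverable by the signature PCA (score–latent Spearman ≳ 0.8 at n = 400).
- **Survival** — exponential event times with log-hazard = log(1/1500 days⁻¹) +
  cluster effect (0 by default) − 0.8 × score, so high-score patients live longer;
  independent exponential censoring calibrated so the expected censored fraction
  equals `censoring_rate` (0.3).
- **Mutation burden** — Poisson counts with log-mean = log(20) + sign(ρ)·0.25|ρ|·
  score for target correlation ρ = −0.4; the 0.25 slope is calibrated for the
  default burden of 20 so the empirical Spearman lands near the target (≈ −0.37).
  MAF records carry realistic class frequencies plus non-counting silent records;
  ~5% of samples get one regulator missense mutation (the rare-event headline).
- **CNV** — planted amplification (30%) on VIRMA/METTL3/IGF2BP1 and deletion
  (25%) on WTAP/RBM15/ZC3H13, 2% background elsewhere.
- **Immune/pathway sets** — 6 immune sets of 15 genes (each cluster activates a
  third of them, +1.5 shift) and 4 neutral pathway sets; shipped as a GMT.

A single master seed fans out to named substreams (expression, survival, mutation,
cnv, clinical) via `SeedSequence.spawn`, so adding an output type never perturbs
the others; identical configs give byte-identical file bundles.

What the generator does **not** model: negative-binomial count noise and
library-size effects, batch effects, probe-level microarray artifacts, clonal
structure in mutations, or realistic gene–gene correlation beyond the planted
blocks. Passing the recovery tests therefore demonstrates the pipeline's
correctness and statistical calibration under its own assumptions, not performance
on real cohorts — on real data the cluster separation, DEG effect sizes and
censoring patterns are far less favorable.

## Numerical conventions and problem sizes

- Missing values are a hard error everywhere; duplicate gene symbols collapse by
  mean at load; the load step auto-log2(x+1)-transforms matrices whose maximum
  exceeds 50 (FPKM-scale detection), recording the decision in a load report.
- Consensus clustering at n = 300 on 23 features with 100 resamples takes ~1 s;
  the acceptance experiments use 100 resamples and cohorts of 300–500 samples,
  and the planted-cutpoint experiment uses 20 replicates at n = 400 with all
  events observed (maximum log-rank power). These sizes are the package's chosen
  desk-scale study conditions.
- The cutpoint scan, log-rank statistic and univariate Cox screen are vectorized
  over candidates/features; exact-oracle agreement is enforced at 1e-12 on small
  instances.

## Known limitations

- The published breast-cancer numbers (cluster sizes 685/617/498, 3429 overlap
  DEGs, score cutoff 7.795803, PIK3CA 37% vs 27%, 55/983 regulator-mutated
  samples) derive from the full TCGA + GEO cohorts; reproducing them requires the
  user to download those data and run the pipeline on them. The run summary
  deliberately reports the same headline shape (cluster sizes, DEG count,
  cutpoint, log-rank p, score–TMB ρ) to make that comparison direct.
- Immunophenoscore (IPS) is consumed as a precomputed per-sample table, and
  molecular subtype as a clinical label; computing either from expression is out
  of scope.
- Cox fitting offers Efron ties only; competing risks, time-varying covariates
  and proportional-hazards diagnostics are not implemented.
- The cutpoint's selected-maximum p-value is reported uncorrected by default;
  users quoting it should prefer the permutation option.
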