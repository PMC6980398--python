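# Methods

`brainage` reimplements, as a tested library, the analysis workflow of a
bulk brain transcriptome/proteome aging study with a 2×2 design: two
genotypes (wild type `wt` and heterozygous mutant `het`) crossed with two
ages (`young`, `aged`), three biological replicates per condition, and four
pairwise contrasts (young het vs young wt; aged het vs aged wt; aged wt vs
young wt; aged het vs young het). This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Differential expression

Genes are retained when their CPM (counts per million, raw library sizes)
exceeds 1.5 in at least 6 of the 12 libraries; the inequality is strict.
Between-sample normalisation uses trimmed-mean-of-M-values (TMM) factors:
M-values trimmed by 30%, A-values by 5%, precision weights from the
asymptotic binomial variance, reference sample chosen as the library whose
75th-percentile CPM is closest to the mean of those quantiles, and factors
rescaled so their logs sum to zero. log-CPM uses a 0.5 prior count
(`log2((c + 0.5)/(lib + 1) · 1e6)`) with TMM-effective library sizes.

One factor of unwanted variation is estimated in the RUVs style: log-CPM is
centred within replicate groups (the four biological conditions), which
removes the condition signal; the leading left-singular vector of the
centred sample×gene matrix is the batch direction `W` (unit norm, first
element non-negative). `W` enters the linear model as a covariate rather
than being regressed out of the data.

Per-gene linear models use a cell-means design (one indicator per
condition) plus `W`. Residual variances are shrunk by empirical Bayes: the
prior `(d0, s0²)` comes from the closed-form method of moments on
`log s²_g` (digamma/trigamma moment matching, the trigamma inverse solved
by Newton iteration); the posterior variance is
`(d0·s0² + d·s²_g)/(d0 + d)` and the moderated t is referred to a
t-distribution on `d0 + d` df (capped at `n_genes·d` when the moment
estimator degenerates to an infinite prior). Benjamini–Hochberg adjustment
is applied within each contrast separately. We fit ordinary least squares
on log-CPM without precision weights; this is the main reconstruction
uncertainty relative to count-level weighting, and the null simulations
(below) show the resulting p-values are calibrated at the study's depth.

## Pattern taxonomy

With FDR threshold 0.05, secondary unadjusted-p threshold 0.05 and display
threshold |log2FC| > 0.5:

- **inverted** — sign(logFC) differs between the young and aged het-vs-wt
  contrasts, with FDR < 0.05 in one and unadjusted p < 0.05 in the other
  (either orientation); a fold change of exactly 0 has no sign.
- **inappropriately down-regulated** — FDR < 0.05 with negative logFC in
  both het-aging and aged het-vs-wt.
- **failure to up-/down-regulate** — FDR < 0.05 with the appropriate sign
  in wt aging, while *failing* the (FDR, sign) criterion in aged
  het-vs-wt. "Not up-regulated" means failing the significance-and-sign
  test, not moving significantly in the opposite direction.

The groups genuinely overlap (a gene properly regulated during mutant
aging also "fails to up-regulate" under the literal rule, because aged
het-vs-wt compares genotypes, not ages); the package emits both the raw
sets and a partition by precedence inverted > inappropriately_down >
failure_up > failure_down. Display clustering uses complete-linkage
hierarchical clustering of the 4-vector of fold changes (Euclidean
distance) with deterministic leaf order.

## Rotation gene-set tests

Both tests operate on per-gene "effects": the design (contrast rotated
into the last coefficient through an orthonormal basis) is QR-decomposed
and each gene reduced to 1 contrast coordinate plus `d` residual
coordinates, whose direction is uniform on the sphere under the null.

**ROAST** draws random unit vectors shared across all sets in a comparison
(one seeded stream, so set p-values are comparable); per rotation the
moderated z (Bailey's closed-form normalising transform of the moderated
t) is recomputed with the squeezed variance, and the 'mean' set statistics
are mean(z) (directional) and mean(|z|) (mixed). Directional p-values pool
the ± rotation means (granularity 1/(2B+1)); mixed p-values have
granularity 1/(B+1). `prop_up`/`prop_down` count genes with |z| > √2. The
default is 9,999 rotations.

**FRY** standardises the effects by robust posterior residual SDs (the
largest squared coordinate left out, bias-corrected by its expected value
under rotation via 128-node Gauss–Legendre quadrature) and treats the set
mean vector as a single pseudo-gene: its t on `d` df gives the directional
p; the mixed p uses a beta approximation to the rotated quadratic form
parameterised by the set's singular-value spectrum. Single-gene sets
reduce exactly to the gene's moderated t-test. Mixed-FDR is BH across
sets.

## Co-expression networks

Signed adjacency `a_ij = ((1 + cor_ij)/2)^β` with Pearson correlation and
β = 14 (fixed, as in the study; no automatic scale-free fit). Genes whose
whole-network connectivity `k_i = Σ_j≠i a_ij` falls below the 10th
percentile (midpoint interpolation; kept when at or above, so an all-tied
network loses nothing) are dropped before module detection. The
topological overlap measure is
`TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.

Module detection is a **documented dynamic-hybrid variant**, not a port of
the reference tree cutter (whose many internal heuristics are not
reproduced; our acceptance standard is planted-structure recovery, ARI ≥
0.8 at module correlation 0.8 with 12 samples): average-linkage dendrogram
of 1−TOM; every branch of ≥ 40 genes whose *core scatter* (mean pairwise
dissimilarity among the tighter half of the branch) stays below a
deepSplit-dependent fraction of the cut height (0.64/0.73/0.82/0.91/0.95
for deepSplit 0–4; default deepSplit 1) is a candidate, and the lowest
candidates become module cores; a PAM-like stage then assigns leftover
genes to the nearest module medoid when that distance is below both the
0.90 cap and 1.25× the core's own 95th-percentile radius (the radius guard
keeps diffuse genes off tight modules at small sample sizes). Modules are
numbered by decreasing size; label 0 is unassigned (grey).

Eigengenes are first principal components of standardised module
expression, sign-aligned with the module mean profile. Module–trait
associations use the hybrid Pearson/biweight-midcorrelation (binary traits
and zero-MAD variables fall back to Pearson centring on that side) with
unadjusted Student t p-values on n−2 df. Cross-network module overlap is a
contingency table over orthologs with one-sided Fisher p-values and a
Sankey-ready serialisation.

## Module preservation

A reference-defined module is evaluated in a test network (genes matched
one-to-one through the ortholog map) with three density statistics (mean
intra-module correlation, mean signed adjacency, eigengene variance
explained) and three connectivity statistics (cross-network correlations
of intramodular connectivity, of gene–eigengene correlations, and of the
off-diagonal correlation entries). This is a fixed, documented subset of
the reference method's larger battery; published Z values from that
software are therefore not numerically comparable, and validation is by
planted-structure behaviour. The null permutes gene–module assignments in
the test network (module sizes preserved, marginal network structure
untouched; 200 permutations by default). `Z = (obs − mean)/sd` per
statistic; `Z_density` and `Z_connectivity` are medians within family and
`Z_summary` their mean, with the conventional thresholds (< 2 none, 2–10
weak-to-moderate, > 10 strong). The random-module baseline scores a
1,000-gene uniform pseudo-module exactly like a real module; between
unrelated networks it scores |Z| < 2 by construction of the null.

## Promoter motifs and over-representation

Promoters are 1500 bp upstream + 200 bp downstream of the TSS (0-based
half-open BED in, strand-aware, reverse-complemented on −, truncation at
contig edges flagged). PWMs (probability matrices; JASPAR and HOMER-style
parsers) are scanned as log2-odds against a uniform 0.25 background
(configurable) on both strands; a hit requires ≥ 90% of the motif's
maximum score by default; N bases contribute zero. Enrichment counts genes
with ≥ 1 hit, tests the one-sided hypergeometric upper tail over the
declared background universe, and Bonferroni-adjusts across motifs/terms.

## Proteomics

Peptide intensities are log2-transformed and quantile-normalised (the
reference distribution is the mean of per-sample sorted observed values on
a common quantile grid; censored entries are excluded from the reference
and stay missing). Censored entries are imputed with an
accelerated-failure-time-style censored-normal model: intensities being
already log-scale, a per-peptide intercept-only normal MLE treats missing
entries as left-censored at the sample's minimum observed intensity, and
the imputed value is the conditional expectation below the censor point
(never above it). Peptides are summarised to proteins by Tukey median
polish (NaN-aware row/column median sweeps; convergence when the total
absolute residual changes by < 1e-4 relative, at most 10 iterations;
protein profile = overall + sample effects), complete cases are retained,
and differential abundance reuses the moderated-t machinery. mRNA–protein
agreement is the gene-wise Spearman correlation over matched pairs within
an age group.

## The synthetic-study generator

The generator plants exactly the structure each stage assumes and emits
the truth separately; analysis stages never see it.

- **Counts**: NB with `var = μ + φμ²`, common φ = 0.1 (typical bulk brain
  RNA-seq), library sizes uniform in 8–12 M, gene baselines log2-normal
  (mean 4, sd 2). Pattern offsets of ±`effect_size` (default 2.0) encode
  the taxonomy: inverted (+e young-het, −e aged-het), accelerated aging
  (aging offset already in young hets), failure groups (wt-aging offset
  only), inappropriate down (−e aged-het only), aging-only (same offset in
  both genotypes, random sign). Default group sizes 80/80/80/40/60/120 in
  2,000 genes. The batch effect is rank-1 — a scalar per replicate batch
  (sd 0.3 log2) times a per-gene loading — which is precisely the k = 1
  structure RUVs removes; the real study's batch origin is unexplained, so
  this is a stand-in, not a reconstruction.
- **Modules**: each module's genes load on a standardised latent factor
  with loadings near `module_cor` (±0.1), so the realised within-module
  correlation tracks the target even at 12 samples; membership is
  scattered over gene ids so independent simulations share none. Preserved
  modules reuse the loadings in species B on a fresh factor realisation;
  non-preserved modules either stay coherent on independent factors
  (density kept, topology lost — the default) or dissolve into noise
  (`unpreserved="noise"`, the null that permutation preservation probes).
- **Promoters**: i.i.d. background at configurable base composition; each
  flagged gene receives one motif-consensus occurrence at a uniform
  position and strand (so planted occurrences score at the motif maximum
  and recovery is well-defined); sampling occurrences from the PWM is
  available but off by default.
- **Peptides**: protein log2 abundance couples to mRNA *across genes*
  through a Gaussian copula — per-sample normal scores of mRNA, loading
  `2·sin(π·ρ/6)` (the exact bivariate-normal inversion for Spearman ρ,
  default 0.4), plus a per-gene offset playing the role of translation
  efficiency — scaled to a 4-log2-unit dynamic range so peptide-level
  offsets (sd 2) do not swamp the gene-level signal after summarisation.
  Peptides add offsets and noise (sd 0.3); the lowest `censor_quantile`
  (default 10%) of global intensities is reported missing.

All randomness flows from one seed through stable named substreams, so
identical configurations are byte-identical on serialisation.

**What the synthetic data do not show.** Gaussian module expression, a
single rank-1 batch, uniform promoter background, and exactly one motif
occurrence per flagged gene are idealisations; passing the planted-recovery
tests demonstrates the algorithms recover the structure they are designed
for, not that real brain RNA-seq meets these assumptions. Library-size
composition is only approximately balanced: planted effects shift ~30% of
the aged-condition mass, and TMM removes most but not all of the resulting
null-gene bias (a residual ≈ −0.08 log2 remains), so FDR-level false calls
concentrate mildly in the down-regulated direction — visible as reduced
rule-level precision in the smallest pattern group.

## Problem sizes and defaults

The default end-to-end study uses 2,000 genes × 12 samples, 9,999
rotations, 200 preservation permutations, 1,700 bp promoters and 300
proteins; it completes in well under a minute on one CPU and is the
configuration the test suite and the acceptance script exercise. All study
constants (1.5 CPM / 6 libraries, FDR 0.05, |log2FC| 0.5, β = 14, minimum
module size 40, deepSplit 1, PAM distance 0.90, 10th-percentile
connectivity filter, 9,999 rotations, 200 permutations, 1500/200 bp, 90%
motif match, 1,000-gene random module) are configuration defaults, never
hard-coded.

## Known limitations

- Moderated fits run on log-CPM without count-level precision weights.
- The dynamic-hybrid cutter is a variant; it does not promise label parity
  with the reference implementation, and very large modules (> ~2× the
  minimum size) may split into cores that PAM reunites only partially.
- The preservation statistic battery is a documented subset; Z values are
  comparable within this package only.
- AFT imputation is intercept-only per peptide; covariate-dependent
  censoring is not modelled.
- The promoter scanner reports all positions above threshold without
  ZOOPS-style multiple-occurrence normalisation.
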