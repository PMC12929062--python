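# Methods

This package re-implements, as a tested pipeline over synthetic data, the
quantitative-genetics workflow used to dissect host control of the
rhizosphere microbiome in a crop diversity panel: heritability screening of
16S amplicon sequence variants (ASVs), mixed-model association of SNPs and
gene expression with ASV abundance, LD-based QTL/eQTL interval construction
with trans-eQTL hotspot detection, and multi-kernel genomic prediction of
mineral-nutrient (ionome) traits.

## Heritability screening

ASV count tables are filtered on two conditions — a minimum total read count
(default 10,000) and detection in at least a fraction of samples (default
80%) — then converted to relative abundance per sample and log-transformed
with a pseudocount of 1e-6 on the relative scale (the pseudocount is our
choice; zeros must be handled and 1e-6 is well below any observable relative
abundance at ~30k-read libraries).

Each ASV's plot-level trait is decomposed within one environment by the
linear mixed model

    y_ijk = mu + g_i + r_j + b_jk + e_ijk

with random genotype (g), replicate (r), block-within-replicate (b) and
residual (e) effects. Restricted maximum likelihood is computed by profiling
the residual scale out of the restricted likelihood and optimizing the three
variance ratios with Nelder-Mead (two starts, non-negativity by the log
parameterization, components below 1e-7 of the residual clamped to zero).
All linear algebra uses Woodbury identities in the random-effect dimension,
so a 175-genotype x 3-replicate fit costs a Cholesky of a ~190-dimensional
matrix per likelihood evaluation rather than a 525-dimensional one. A dense
grid evaluation of the same restricted likelihood on tiny instances serves
as the correctness oracle in the tests.

Broad-sense heritability on a genotype-mean basis is

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / R),

with R the number of replicates; ASVs with H2 > 0.15 pass the screen.
Genotype BLUEs are the generalized-least-squares genotype estimates with
genotype fixed and replicate/block random at their REML variances; in a
balanced design they coincide with genotype means (tested), and in
unbalanced designs they match a direct normal-equations solve (tested).

Expression traits are rank-normalized before eGWAS with Blom scores,
(r - 3/8)/(n + 1/4) mapped through the normal quantile; ties receive the
average score over their rank span. The offset and tie rule are our
choices among the standard variants.

## Kinship and the mixed-model engine

Genotypes are coded 0/1/2 as minor-allele counts (recoded once at load;
frequency ties keep the ALT allele; missing calls are mean-imputed per
marker and the imputed fraction recorded). The genomic kinship is the
VanRaden matrix K = ZZ'/(2 sum p(1-p)) with Z the column-centred codes. The
feature kinship for expression or ASV layers is K = MM'/c with M
column-standardized (population SD, zero-variance features dropped) and c
the mean diagonal of MM', so mean(diag K) = 1 exactly.

The single-marker model y = X beta + m a + g + e with g ~ N(0, K sigma_g^2)
and e ~ N(0, I sigma_e^2) is fitted once per trait by eigen-rotated REML:
after rotating by the eigenvectors of K the covariance is diagonal in the
variance ratio lambda = sigma_g^2/sigma_e^2, which is found by a log-grid
search (41 points over 1e-5..1e5, plus the lambda = 0 boundary) refined by
bounded Brent. The per-marker scan then holds the rotation and lambda fixed
("population parameters previously determined") and computes, by weighted
partitioned regression vectorized over markers, the effect estimate and its
Wald statistic W = a_hat^2/var(a_hat), referred to the chi-square
distribution with 1 df.

One numerical convention matters: var(a_hat) uses a residual *scale*
re-estimated per marker from the GLS residual sum of squares at the fixed
variance ratio (degrees of freedom n - p - 1). With that convention the
K = I limit of the scan reduces exactly to the squared OLS t statistic,
which is the oracle the tests check to 1e-6 relative; reusing the
null-model scale instead would differ from OLS by a factor RSS_full/RSS_null
of order 1 + W/n. This is the same choice made by the widely used
approximate mixed-model scanners.

Constant explanatory columns are reported with effect 0, W = 0, p = 1 and a
flag rather than an error, so a scan over a filtered panel never aborts.

Multiple-testing adjustment implements BH step-up and Holm step-down
directly (cumulative min/max over the sorted p-values); for Holm and
Bonferroni the first-step threshold alpha/m is reported alongside. With
alpha = 0.05 this reproduces the printed thresholds 2.09e-7 (m = 239,172)
and 1.71e-7 (m = 292,839) for the two RNA-seq SNP panels. FDR is applied
within each response trait, not pooled across ASVs; the Holm correction for
eGWAS counts the number of SNPs as the number of tests.

## Multi-kernel model and prediction

The prediction model is y = 1 mu + sum_i m_i + e with m_i ~ N(0, V_i
sigma_i^2) over up to four omics kernels. Variance components are estimated
by REML: a single kernel routes through the eigen-rotated 1-D search; k > 1
kernels use dense Nelder-Mead over log variance ratios with the scale
profiled out. A Gibbs sampler (scaled-inverse-chi-square updates, random
effects sampled in each kernel's eigenbasis where the conditional precision
is diagonal; defaults 5,000 iterations with 1,000 burn-in) is available as
an option mirroring the Bayesian estimation used in the original analysis;
REML is the default because it is deterministic and the downstream
mechanics are identical.

Held-out genotypes are predicted through the kernel cross-covariance
(BLUP): with V_tr the training-block covariance at the fitted variances,
y_hat_test = mu + sum_i sigma_i^2 V_i[test, train] V_tr^{-1}(y_train - mu).
Kernels are built once on the full panel; only training rows enter the fit.

Cross-validation uses 5 folds repeated (100 by default; the calibration
experiments use 20), with the fold shuffle of repeat r drawn from the seed
pair (seed, r) so results are reproducible regardless of execution order.
Accuracy is the Pearson correlation between observed and predicted values
computed *within each held-out fold and averaged*. A single pooled
correlation would carry a negative bias of up to ~0.17 under a null trait,
because fold-specific training means anti-correlate with the held-out
values; the per-fold average is free of that artifact and is a standard
reporting convention in genomic prediction.

Scenarios are all non-empty subsets of the available kernels, ordered by
(size, lexicographic): 15 scenarios from four layers, 7 from three.

## LD, QTL intervals, eQTL classes and hotspots

LD is the squared Pearson correlation of genotype codes (composite LD). The
decay profile averages r^2 in physical-distance bins over all
intra-chromosomal pairs within 500 kb; the decay distance is the first bin
midpoint at which the cumulative-minimum-smoothed mean falls below 0.1
(the smoothing makes "first crossing" robust to non-monotone bins).

Each significant SNP's interval runs outward to the last marker before LD
with the focal SNP first drops below 0.1 — a one-pass scan that does not
re-enter after the first sub-threshold marker, the literal reading of
"first dropped below". Intervals that overlap, or whose peak SNPs lie
strictly less than 50 kb apart, are merged by single linkage (exact
union-find over pairs; significant-SNP sets are small) into independent QTL
regions led by their most significant SNP (ties broken by smaller
position). An eQTL is local when it lies on the eGene's chromosome and
overlaps or sits within 50 kb (inclusive) of the gene interval; otherwise
distant. The asymmetry — strict < for peak merging, inclusive <= for the
local window — follows the two rules' respective wording.

Hotspot detection replaces the published scan tool, whose internal
statistic we do not reproduce, with a windowed Poisson scan honouring the
same window (100 kb) and significance (0.01) parameters: windows advance by
half a window; each window's distant-eQTL event count (lead-eSNP positions)
is tested against a genome-wide uniform Poisson background; p-values are BH
adjusted across windows and overlapping significant windows merge into
maximal regions. Under a uniform null this flags anything in well under 5%
of simulations, and a window holding ten times the background rate is
detected essentially always.

## Covariation and network assembly

The Mantel statistic correlates the upper off-diagonal triangles of two
distance matrices (Pearson by default, Spearman as an option); significance
comes from jointly permuting rows and columns of the second matrix with the
one-sided upper-tail estimate p = (1 + #{r_perm >= r_obs})/(1 + B), B =
1,999 by default, so identical matrices give p = 0.0005 exactly. The
regulated-ASV network is a deduplicated edge list over four node kinds —
ASV-QTL edges from significant GWAS, ASV-gene edges from significant TWAS,
gene-hotspot edges for eGenes whose distant eQTL lead SNP falls inside a
hotspot — with a degree table and GraphML export.

## The synthetic cohort

The generator emulates a replicated two-environment field study of a
~175-accession diversity panel. Its defaults (175 genotypes, 3 replicates x
3 blocks, 5 chromosomes of 10 Mb, 5,000 LD-blocked SNPs with MAF >= 0.05 by
construction, 300 ASVs half of which are heritable with targets in
0.15-0.6, 1,000 genes with a 50-target trans hub, 12 kernel-driven ionome
traits) mirror the study scale while running end to end in minutes.

Genotypes follow a founder mosaic: each accession anchors on one of 6
founders; per LD block each haplotype copies the primary founder with
probability `founder_fidelity` (default 0.95) or a uniformly random founder
otherwise. Two regimes of the same generator are used deliberately:

* the **structured default** (fidelity 0.95) produces the tight
  ancestral-group kinship typical of ecotype-structured crop panels. It is
  the condition for the prediction experiments: with a kernel-generated
  trait at h2 = 0.5 and n = 175, cross-validated accuracy approaches
  sqrt(h2) ~ 0.7 because held-out genotypes have close relatives in
  training. This deliberately reproduces the regime where multi-omics
  prediction is informative; accuracy in the real panel is driven by a
  mixture of relatedness and marker LD that a 5,000-marker simulation
  cannot represent marker-for-marker.
* the **panmictic variant** (`panmictic_config`, fidelity = 1/founders)
  redraws lineages uniformly at every block, confining LD to blocks
  (within-block mean r^2 exceeds between-block by well over 5x at the
  default sizes) and making markers nearly exchangeable. It is the
  condition for LD-decay behaviour, mapping-power and type-I calibration
  experiments: a trans-hub locus must segregate within the population for
  its effects to survive the kinship correction, and under the structured
  default a randomly placed hub is often fully confounded with the group
  structure that the Q+K model (correctly) removes.

ASV counts are drawn multinomially per sample from soft-maxed latent
log-abundances (log-normal library sizes around 30,000 reads), so the
table carries real compositional coupling: genetic signal in abundant ASVs
leaks into every ASV's relative abundance. The per-ASV heritability target
refers to the analyzed trait (log relative abundance): the log-sum-exp
closure term is shared within a sample and behaves as extra plot-level
residual variance (~0.1-0.3 under the defaults), so the genetic scale is
calibrated against sigma_e^2 + var(log-sum-exp) in one correction pass.
Without that correction, realized H2 under-shoots the target by ~0.03-0.06.

Expression assigns each gene to a random anchor SNP (a `cis_fraction` of
genes load on it) and gives hub-target genes a shared effect from the hub
SNP, preferentially drawn on other chromosomes so the planted events are
unambiguously distant. Ionome traits are sums of kernel-driven genetic
values u_i ~ N(0, V_i) plus Gaussian noise, with realized variance
fractions recorded as ground truth.

Every generator is a pure function of (config, seed); identical inputs give
bitwise-identical outputs.

What passing tests on this cohort do **not** show about real data: the
generator has no sequencing-error or chimera model, no taxonomic structure,
no genotype-by-environment interaction, Gaussian expression rather than
count-based noise, and far fewer markers than a resequenced panel — so the
calibrations demonstrate correctness of the statistical machinery under the
study's assumed model, not field-data effect sizes.

## Problem sizes in the calibration battery

The acceptance experiments use: 50 ASVs at n = 200 genotypes for H2
recovery; 10,000 markers at n = 175 for type-I error and genomic inflation;
200-marker instances for the OLS-equivalence oracle and 1,000 random
vectors for the adjustment oracles; 25 full-pipeline runs (1,200 markers,
250 genes) for hotspot power and 100 event-level scans for the hotspot
null; 20 CV repeats at n = 175 for prediction; 500 simulations for Mantel
null uniformity. These sizes were chosen so the whole battery completes in
a few minutes on one core while leaving Monte-Carlo error well inside each
acceptance band.

## Known limitations

* Per-marker full REML is available only as a validation mode; the default
  scan is P3D throughout, whose p-values are anti-conservative by a factor
  vanishing in n (chi-square reference for a squared t statistic).
* The plot-model REML uses a general-purpose simplex optimizer; pathological
  variance surfaces (e.g. near-confounded replicate and block labels) may
  end on a local boundary optimum. The multistart covers the common cases.
* The hotspot scan's Poisson background assumes events are uniform within a
  chromosome under the null; clustered marker maps violate this mildly.
* Mean imputation of missing genotype calls attenuates effect estimates at
  markers with substantial missingness; the study's own pipeline imputed
  with a haplotype model, which is out of scope here.
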