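# Methods

## Problem setting

The package targets small diversity panels (tens of accessions, tens of
thousands of chip SNPs) in which predefined groups — crop landraces — are
real but weakly expressed genome-wide, and in which an environmental
gradient (altitude) is partially confounded with group identity. The goal is
a small marker panel that assigns samples to groups, together with an
explicit separation of group-informative from altitude-associated markers.

## Genotype model and I/O

Genotypes are diploid biallelic dosages 0/1/2 counting copies of `allele_b`,
with NaN for missing calls. `allele_b` is canonically the lexicographically
larger of the two observed alleles, which makes the coding stable across
files and lets two datasets merge on their marker intersection without a
reference panel. A marker with a single observed allele is stored as
(`allele_a` = that allele, `allele_b` = '0') with dosage 0; an all-missing
marker as ('N', '0'). PED text alone cannot fix the dosage orientation of a
marker whose second allele is unobserved in a given file, so the writer
emits a marker TSV with the allele pair and `read_dataset` restores the
exact coding — write→read is then the identity, which the tests assert.

Merging never auto-resolves strand flips: conflicting allele pairs are an
error, with an explicit per-marker allele-remap table as the escape hatch.
Missingness filters are boundary-inclusive ("at most x" is kept), applied
to the current registry, and commute for disjoint criteria. The Illumina
GenTrain quality filter is optional and requires populated scores.

## Per-SNP differentiation

Two estimators over a k-group partition, computed per marker from observed
per-group allele frequencies (missing calls dropped per marker per group):

* **Weir–Cockerham (1984) θ** — the variance-components estimator with
  per-group sample sizes n_i, frequencies p_i and heterozygote fractions
  h_i; a = n̄/n_c [s² − (p̄(1−p̄) − (r−1)/r·s² − h̄/4)/(n̄−1)],
  b = n̄/(n̄−1) [p̄(1−p̄) − (r−1)/r·s² − (2n̄−1)/(4n̄)·h̄], c = h̄/2,
  θ = a/(a+b+c). Values can be slightly negative; monomorphic loci, loci
  where a group has no data, and single-individual groups are undefined
  (NaN) and excluded from quantiles. The default, because it corrects for
  the small per-group sample sizes this setting has.
* **Nei G_ST** — 1 − H_S/H_T with unweighted group means; always in [0,1],
  0 for monomorphic loci.

Both are vectorized over markers and verified to 1e-12 against scalar
single-locus oracles coded separately. Fixed opposite alleles give exactly 1
under either.

Quantile subsetting uses the empirical (1−q) order-statistic threshold and
keeps every marker at or above it, so ties can push the realized count past
⌈qN⌉ — the behaviour implied by published panel counts exceeding the
nominal percentage. The realized threshold and count are recorded in the
set's provenance.

## PCA and the cluster-number scan

Missing dosages are mean-imputed per marker (the standard reference-free
choice for SNP PCA), the matrix centered (optionally unit-scaled; off by
default since dosages share units) and decomposed by SVD. Component signs
are fixed by making the largest-magnitude loading positive.

The cluster scan runs k-means on the first d principal-component scores for
each k in [k_min, k_max] and scores solutions with

    BIC(k) = n·ln(W_k/n) + κ(k)·ln(n),

W_k the total within-cluster sum of squares, κ(k) = k by default (one
parameter per cluster, the convention of the DAPC literature's
cluster-finding step; a κ = k·d variant is available). d defaults to the
number of components covering ≥ 90% of the variance. Multistart k-means is
seeded and deterministic; increasing `n_starts` can only lower W_k.

A caveat established while validating: the global min-SS bipartition of a
point set need not be Voronoi-consistent (moving a point between clusters
changes SS with n/(n±1) factors), so Lloyd's algorithm — any k-means —
cannot always reach it, and scikit-learn's greedy k-means++ explores only a
subset of point-pair initializations. The exactness tests therefore compare
the scan against an independently coded Lloyd iteration run from *every*
distinct point-pair initialization, plus a lower-bound check against the
unrestricted exhaustive bipartition minimum.

## DAPC

`DAPC(gm, grouping, n_pca, n_disc).fit()` retains `n_pca` PC scores and
solves the generalized symmetric eigenproblem B·a = λ·W·a with B the
between-group and W the pooled within-group covariance of the scores;
eigenvectors are normalized to unit within-group variance (aᵀWa = 1) and at
most min(n_pca, k−1) discriminant functions are kept. When W is singular —
likely when n_pca approaches n − k, as with 8–14 samples per group — a
ridge of 1e-8·trace(W)/d is added and recorded on the results object.

Membership posteriors use equal priors and unit isotropic covariance in
discriminant space, P(g) ∝ exp(−½‖z − c_g‖²): assignment by proximity to
centroids, matching reference DAPC behaviour. Accuracy is
self-classification on the training set by default (the number reported in
assignment-plot style figures); classifying a held-out matrix goes through
the training imputation/centering and projection.

Marker coefficients are the discriminant eigenvectors back-projected
through the PCA loadings (`var_coeff = loadings · eigvec`); contributions
are their squares normalized to sum to 1 per function, invariant to marker
order and to any rescaling of the eigenvector columns. Each function is
oriented so its largest-|coefficient| marker is positive. Panel-selection
rules: `top_fraction(q)` and `top_count(m)` (ties at the cut included) and
`mean_plus_sd(t)` (strict inequality, so a flat profile selects nothing).
The per-analysis panel is the union of per-function selections; an
eigenvalue-weighted combined profile is also available.

## Pipeline defaults

Landrace analysis: Weir–Cockerham, q = 0.01, scans for k = 1…5, DAPC with
n_pca = 4 and n_disc = 2, top-2% contributors per function. Altitude
analysis: samples dichotomized at 750 masl (low = [0, 750], high above),
n_pca = 1 and n_disc = 1. The confound report partitions the two panels
into shared / landrace-only / altitude-only (SNP-level only; gene-level
sharing needs external annotation and is carried as free-text notes). Every
run logs one line per stage with dimensions and realized thresholds,
writes deterministic TSV/JSON outputs, and stores its resolved
configuration.

## Synthetic cohorts

The generator draws, per locus, an ancestral frequency p ~ U(0.05, 0.95)
and per group a Balding–Nichols frequency
p_g ~ Beta(p(1−F)/F, (1−p)(1−F)/F); F equals the expected F_ST of the
locus class, making calibration targets analytic. Defaults emulate a
five-landrace chip panel: 50 samples in groups of 12/8/9/11/10; 2,000
background loci at F = 0.056; 40 landrace-class and 20 shared loci at
F = 0.4; 40 altitude-class loci whose per-sample frequency shifts on the
logit scale by 2.0 per km of altitude (centred at 1 km); group-specific
altitude bands with one group entirely below 750 masl; locus-level
admixture (20% between the two highest-altitude groups, 10% between two
mid-altitude groups); a 1.5× drift multiplier for the isolated group; 2%
missing calls. Dosages are Binomial(2, p) per sample and locus. The truth
table records each marker's class (background/landrace/altitude/shared).

What the generator does *not* emulate: linkage disequilibrium (loci are
independent), pedigree-level admixture (mixing acts per locus), genotyping
batch effects, and departures from Hardy–Weinberg within groups. Passing
recovery tests therefore demonstrate the ranking behaviour of the method
under idealized exchangeable loci, not its performance on linked chip data.

A consequence of the Balding–Nichols model worth stating: with only five
group-frequency draws per locus, the *realized* differentiation of a locus
scatters widely around its class F (at F = 0.4 the Beta is U-shaped), so a
fraction of planted high-F loci realize near-background differentiation and
are unrecoverable in principle. Ranking loci by the generator's true group
frequencies recalls only ~65–85% of planted landrace-class loci at an
oracle-sized panel; estimated rankings at n = 50 recall ~40–60%. The
recovery benchmark (`aimsel.benchmark`) is accordingly designed as recall
at an oracle-sized panel — subset quantile q = 0.05 (the planted share),
DAPC with 10 retained PCs, and a top-m panel with m equal to the planted
class size on combined contributions — and its numbers should be read
against that ceiling. The shared-panel hypergeometric enrichment and the
cluster-number contrast (k = 1 on all loci, k ≥ 2 on the top-1% subset) are
robust across seeds.

## Problem sizes and runtimes

Unit tests run on a 20 × 500 cohort and hand-sized toys; the benchmark and
acceptance script use the 50 × 2,100 default cohort (seconds on one CPU).
A `paper_scale` fixture profile (50 × 35,909) is provided for chip-scale
runs; the full pipeline on it completes in well under two minutes.
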