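# Methods

This note documents the models behind `cfcomp`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer should know about. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Analytic coverage model

A single paired-end fragment (insert *L*, reads of length *r*) from a
genome of *n* bases contributes coverage to a base with a two-point
distribution. For *L* < 2*r* (the cfDNA regime) the two reads overlap
and the model assigns the covered state the concentrated value 2r/L with
probability L/n; for *L* > 2*r* the covered state is 1 with probability
2r/n. Both kinds share the expectation 2r/n; the variances differ by
(2r/n)(2r/L − 1), strictly positive below the *L* = 2*r* boundary.

Assumptions and known stylization: the short-insert model spreads the
2r sequenced bases uniformly over the fragment as a constant per-base
value 2r/L, although true per-base depth inside an overlapped fragment
is 1 or 2. We implement the stylized model verbatim; the fragment-level
simulator (below) uses the exact 1-or-2 geometry, so the two components
bracket the idealization. The model is derived for a single fragment
(*k* = 1); `k` is carried in the parameter set and larger values raise
`NotImplementedError` rather than silently extending the model. At
exactly *L* = 2*r* both PMFs coincide (support {0, 1}) and either
library kind is accepted; elsewhere a kind/insert mismatch is an error.
All formula evaluation is double precision; analytic equalities are
asserted at 1e-12 absolute.

## Library simulator

Fragments are placed uniformly; lengths are truncated normal
(short-insert mean 170 bp, sd 15; long-insert mean 350 bp, sd 60; read
length 100 bp — the DNBSEQ-style paired-end 100 geometry). PCR
duplication gives each unique fragment 1 + Poisson(λ) copies; λ tunes
the duplication rate 1 − unique/copies continuously from 0, with
defaults λ = 0.229 (short) and λ = 0.0115 (long) chosen so the expected
rates λ/(1+λ) ≈ 18.6% and 1.1% match typical low-input plasma versus
sheared gDNA libraries. Duplicate marking keys on (start, length) —
the simulator has no strand, so this matches coordinate-based duplicate
semantics. Region-dependent placement loss multiplies a retention
probability, evaluated at the fragment midpoint (unambiguous for
boundary-straddling fragments), emulating short-read alignment failure
in repetitive sequence rather than modelling alignment itself.

Depth is exact: each copy contributes reads [start, start+r) and
[start+len−r, start+len); overlapped bases count twice, and fragments
shorter than r truncate both reads, so total depth equals
2·min(r, len)·copies per fragment, a conservation law the tests assert
exactly. Coordinates are 0-based half-open throughout; bedGraph output
is run-length encoded.

Depth matching follows the two-round design of a paired study: both
libraries are sampled at the same raw (copy-counted) depth, duplicates
are removed — costing the high-λ library most of its excess — and the
deeper deduplicated library is thinned binomially to the shallower one's
effective depth (each unit retained with probability target/current;
round 1 operates on copies, round 2 on unique fragments).

## Default genome

One synthetic chromosome of 2 Mb stands in for a genome at desk scale
(multi-chromosome inputs are supported through concatenated coordinates).
Real short-read data never reaches 100% coverage at 1×: a few percent of
the genome (centromeric satellite, other repeats, assembly gaps) is
effectively unalignable, and more so for short fragments. The default
genome therefore reserves 5% centromere (fragment retention 0.05
short-insert / 0.30 long-insert), 3% difficult (0.60 / 0.85) and 1% gap
(0 for both). These multipliers are configuration, not claims about any
particular genome; they were chosen once to put coverage at 1× in the
realistic 95–99% band and to make the below-/above-mean coverage
ordering measurable. On an all-normal genome coverage at low thresholds
saturates and the ordering at 1×/10× degenerates to sign noise.
The default raw target depth is 46.73×, the first-round matched raw
depth of a paired cfDNA/gDNA design; after deduplication and the second
matching round the tracks sit near 35×.

## Cohort, observation and trait generators

True genotypes are Binomial(2, AF) per individual (Hardy–Weinberg
proportions) with allele frequencies uniform on [0.001, 0.5] by default.
Population structure is modelled as discrete ancestry groups with
Gaussian per-variant AF offsets — sufficient to test PCA-agreement
machinery, though real structure is clinal. SNP ref/alt pairs are drawn
with transition probability 2/3 so site-level Ti/Tv sits near the ~2.0
expected genome-wide; 15% of variants are 1-bp indels and 6% carry a
multiallelic flag (kept as flagged records, not split).

Observation converts truth into one called dataset per library kind:
each variant is dropped with a region-label-dependent probability
(default higher for the short-insert library in difficult/centromeric
sequence, emulating the variant-detection gap of short fragments);
retained genotypes are set missing with rate *m*, else perturbed with
rate *e*, moving uniformly to one of the two other dosages. The
symmetric error model is the simplest one producing ~2% cross-library
discordance at *e* = 0.01 per dataset: two independently perturbed
copies agree with probability (1−e)² + e²/2. Its known limitation is
that the error rate does not depend on allele frequency, whereas real
genotyping error concentrates in rare, low-depth sites; consequently
dosage correlations of *common* variants (MAF-bin R², GWAS beta
agreement) are attenuated by var(x)/(var(x)+var(e)) per SNP and plateau
around R² ≈ 0.85–0.93 rather than the near-unity values real common
SNPs show. Tests assert the enumerated attenuation, and passing them
demonstrates correctness of the statistics, not that real cfDNA would
show those particular R² values.

Phenotypes are y = Σβ·dosage + noise with the noise orthogonalized to
the genetic score and rescaled so the sample genetic-variance fraction
equals the target heritability exactly. Expression plants cis effects
(β·dosage of a SNP within ±1 Mb of the gene's TSS, plus Gaussian noise)
for a configurable fraction of genes; causal variants are drawn from
SNPs only, since the cis scan tests SNP dosages. Age/sex-like covariates
are generated signal-free so the association design matrix has a
realistic shape.

## Window outlier rule

Windows are fixed-origin 10 000-bp tiles from coordinate 0 (the trailing
window is averaged over its actual length; window-mean × length sums
conserve total depth exactly). The flag rule is two-sided on the signed
per-window difference (short − long): |d − mean| > 3·SD, with mean and
SD over all windows, outliers included — the plain reading of a 3-SD
screen; a `robust` option (median/MAD, scale 1.4826) exists but is off
by default. Sidedness is not specified by convention, and the two-sided
choice is the conservative one. SD = 0 flags nothing. Mean/SD are
genome-wide by default (per-chromosome available by running the rule per
chromosome's table). Annotation labels a flagged window by the region
containing its *start* coordinate; when tracks overlap, the most
specific label wins (centromere > gap > difficult), and windows matching
no interval are "uncategorized".

## Genotype comparison statistics

All statistics use pairwise-complete observations. Concordance is the
per-individual fraction of shared sites with identical dosage; MAF-bin
R² bins shared SNPs by the long-insert dataset's MAF (width 0.01,
configurable to the other dataset or their mean) and averages the
per-SNP squared Pearson correlation of dosage vectors, skipping SNPs
monomorphic in either dataset (counted, excluded from means; empty bins
do not enter the overall mean). Ti/Tv is counted per site over biallelic
SNPs with at least one non-reference call; Het/Hom is per individual and
undefined (NaN) without homozygous-alternate calls. PCA comparison
standardizes dosages as (g − 2p)/√(2p(1−p)) over shared variants with
MAF > 0.05 in both datasets, takes top-PC scores from each dataset's
SVD, and aligns one to the other by orthogonal Procrustes, making the
displacement invariant to per-PC sign flips and rotations.

## Association analyses

The quantitative-trait "GLM" is ordinary least squares with t-tests on a
rank-based inverse-normal transformed phenotype (Blom offsets
(rank − 3/8)/(n + 1/4), ties by average rank), with covariates
standardized to unit variance: user covariates plus the top five
principal components of the same genotype matrix being tested.
Pre-association QC keeps biallelic SNPs with MAF > 0.05, exact
Hardy–Weinberg P > 1e-5 and missingness < 10%. The exact HWE test is
the conditional test of the heterozygote count given allele counts,
evaluated in log space and summing configurations no more probable than
the observed one.

The per-variant scan residualizes the phenotype and dosages on the
covariates (QR) and recovers the full-design dosage coefficient, SE and
t-test via the Frisch–Waugh–Lovell identity — exact, and fast enough to
drive permutations; statsmodels OLS is the independent oracle in the
tests. SNPs with per-SNP missingness drop those individuals only.

cis-eQTL mapping tests SNPs with MAF ≥ 0.01 within ±1 Mb of the TSS per
gene, on inverse-normal expression. Latent expression confounders are
adjusted with the top 5 expression principal components (a deliberate
substitution for PEER factors, which serve the same role); genotype
structure with 2 genotype PCs. The gene-level empirical P is
(1 + #{permutations with max |association| ≥ observed})/(1 + B),
permuting the residualized expression vector (the common approximation
to re-residualizing each permutation); missing dosages are mean-imputed
for this scan. B defaults to 1000 at desk scale and is configurable
upward. FDR is Benjamini–Hochberg across genes — chosen over Storey's
q-value for determinism — with eGenes at q ≤ 0.05. Direct permutations
only; no beta-approximated permutation scheme is implemented.

Agreement joins two association summaries on the exact variant key,
harmonizing allele-swapped records by flipping the effect sign
(counted in the report), and computes squared Pearson correlations of
−log₁₀ P and of beta over the overlap, plus unique-variant tables for
mirrored-Manhattan output.

## Pipeline and reproducibility

`run_pipeline` executes the stages in workflow order and writes
TSV/JSON/BED/VCF/bedGraph outputs stamped with the config SHA-256 digest
and master seed. Per-stage seeds are CRC32(stage label) XOR master seed,
so inserting a stage never perturbs the randomness of the others; the
same config and seed reproduce the bundle byte-for-byte. Any stage
failure aborts with a stage-named error, preserving earlier outputs.

## Problem sizes

Defaults are desk scale, chosen for a single CPU: 2 Mb genome, 200
individuals, 3000 variants, 40 genes, 1000 permutations; the full
pipeline runs in well under a minute, and the Monte-Carlo and
replicate-based property checks use 10⁶ draws and 20 seeded replicates.
Statistical conclusions at this scale are about the correctness and
calibration of the machinery; data-specific magnitudes from real
cohorts (exact outlier-window counts, variant totals, R² of real
traits) are not reproduction targets.

## Known limitations

No linkage disequilibrium, GC or fragmentomic end-motif structure, no
read-level alignment or base-quality model, binary ancestry groups
rather than clines, uniform (MAF-independent) genotype error, direct
permutations only, and quantitative traits only (no logistic GWAS or
mixed models).
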