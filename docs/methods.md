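# Methods

`anosurv` implements the downstream analysis of a mosquito
genomic-surveillance study: per-sample copy-number inference from
windowed read depth, cohort diversity and structure statistics, H12
selection scans with bioassay phenotype contrasts, resistance-allele
frequency tables with Fisher exact association, and diplotype
clustering. A built-in simulator generates cohorts with the statistical
structure these analyses assume, so every stage is validated end to end
without sequencing data. This note records the models, the defaults and
why they are what they are, and what the synthetic validation does and
does not demonstrate.

## Sample QC and cohorts

Samples enter the analysis when their sequencing metadata clears three
strict bounds: median genome coverage above 10x, genome-wide
missingness below 20%, and estimated cross-sample contamination below
4.5%. All three are strict inequalities in the passing direction;
records with unpopulated QC fields fail with an explicit reason.

Analysis cohorts are the cross-classification of location, collection
year, insecticide and bioassay outcome (alive/dead at a diagnostic
dose; samples never exposed are "untested"). Two thresholds gate what a
cohort may be used for: diversity statistics require at least ten
individuals; alive/dead association tests require at least five per
arm. Both are configurable, and the defaults match standard practice
for these estimators' variance.

## Copy-number inference (Gaussian HMM)

Read counts over fixed 300 bp windows are converted to copy-number
units as `ploidy * count / median(count)`, the median taken over the
sample's autosomal windows (ploidy 2; 1 for the male X). Integer copy
number 0..12 is decoded by Viterbi under:

* **Emissions** Normal(mean = k, variance = sigma0^2 + k * sigma1^2) for
  state k. Noise grows with copy number because read counts do. The
  spread is fit per sample — one moment equation in two unknowns — by
  splitting the robust baseline variance v equally: sigma0^2 = v/2,
  sigma1^2 = v/(2*ploidy), so the baseline state's variance equals v and
  variance rises linearly with state. v is the squared scaled MAD
  (1.4826 * MAD) of the normalized values: robust to the minority of CNV
  windows and free of the truncation bias a hard "windows near baseline"
  cut would introduce (that cut underestimates sigma and inflates false
  calls). A floor of 1e-4 keeps noiseless input finite.
* **Transitions** self-probability 1 − 1e-4 per window, remainder
  uniform over the other states. CNVs are rare and kilobase-scale, so a
  single-window excursion cannot pay the two off-diagonal transitions
  unless its emission evidence is overwhelming. The initial distribution
  puts the same 1 − 1e-4 on the baseline state.
* **Values above the top state** are clamped to 12 for emission
  evaluation only.

An amplification call is a maximal run of at least five consecutive
windows decoded above ploidy whose likelihood ratio against the
forced-baseline state over the run's windows exceeds 1000
(delta log-likelihood > ln 1000 ≈ 6.91; transitions inside a constant
run cancel). Deletions are decoded but not emitted as calls — the
surveillance frequency analysis concerns amplifications. Samples whose
normalized coverage variance (diploid scale) exceeds 0.35 are removed
before decoding; exactly 0.35 is retained.

**Shared window bias.** Median scaling removes per-sample depth but not
per-window structure (mappability, GC). An optional bias track divides
it out; when no external track is supplied, `estimate_window_bias`
estimates one as a low across-sample quantile (25th percentile) of
median-scaled counts per window. The low quantile keeps the track clean
while fewer than ~75% of samples are amplified at a window, and the
track is clamped to [2/3, 1.5] because genuine mappability bias is
bounded — without the clamp, a CNV at fixation in the cohort would be
absorbed into the track and silently erased. For loci where an
amplification may be at or near fixation, the honest configurations are
an externally derived track or no correction at all; the caller is
validated in both modes.

Per-gene CNV frequency is the carrier fraction of the cohort, a carrier
being any sample with a retained call overlapping the gene footprint by
at least one window. Rows at or below 5% are flagged out of the report
but kept in the full table.

## Diversity and structure statistics

For a cohort of n haplotypes over a region of accessible length L:

* **pi** — mean pairwise Hamming distance per bp, computed site-wise as
  `sum_s 2 c_s (n − c_s) / (n(n−1)) / L`. L is supplied by the caller;
  the package does not guess an accessible-genome denominator.
* **Watterson's theta** — `S / a_n / L`, `a_n = sum_{i<n} 1/i`.
* **Tajima's D** — `(pi_total − S/a1) / sqrt(e1 S + e2 S(S−1))` with the
  standard constants computed from n. Undefined at S = 0 and reported
  as missing, never coerced to zero.
* **Hudson's FST** — per-site numerator
  `(p1−p2)^2 − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)` and denominator
  `p1(1−p2) + p2(1−p1)`, combined as a ratio of sums (ratio of
  averages), the low-bias choice for genome-scale data. Sites with
  fewer than two sampled alleles in either cohort are excluded;
  per-site components are retained for windowed output. The numerator
  is grouped so `fst(A,B) == fst(B,A)` bit-exactly.
* **PCA** — on allele dosages filtered to complete, segregating sites
  with minor allele frequency above 0.2 (the frequency reading of the
  threshold; a fractional allele *count* is not meaningful), thinned
  evenly by index to 100,000 sites when more qualify, mean-centred, and
  decomposed by SVD. Component signs follow the convention that each
  component's largest-magnitude loading is positive, making coordinates
  deterministic.

## H12 selection scan

For a window of phased haplotypes with distinct-haplotype frequencies
p1 ≥ p2 ≥ ..., `H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2`. Pooling the top
two classes keeps the statistic sensitive to soft sweeps (two sweeping
haplotypes) as well as hard ones. Windows are consecutive,
non-overlapping blocks of w SNPs; a ragged terminal block is dropped
when shorter than w/2. Scans default to chromosomes 2 and 3 (the X is
excluded as divergent in this system).

**Window-size calibration.** For each candidate w in a grid, the
genome-wide H12 distribution is computed and its 95th percentile taken
(nearest rank). The chosen w is the *largest* whose 95th percentile
falls below 0.1 — the widest window that still keeps the neutral
background quiet; when none qualifies the smallest is used and flagged.
The default grid (100..2000 SNPs in steps of 100) assumes real
chromosomes; the simulated-genome studies use (100, 150) because a
300 kb region supports far fewer windows.

**Phenotype contrast.** Delta-H12 = H12(alive) − H12(dead) on identical
window definitions, enforced by recomputing both profiles on the shared
SNP set. Peaks are maximal runs of windows above a threshold (default:
the profile's own 99th percentile — a reporting convention), merged
across single-window gaps and annotated with overlapping gene models.

## Amino-acid substitutions and association

For each biallelic SNP inside a transcript's CDS, the reference codon
is rebuilt in transcription order (reverse-complemented for minus-strand
genes), the alternate base substituted, and both codons translated with
the standard genetic code; only residue-changing records are kept,
labelled like `L995F` ('*' denotes stop, so stop-gains label as e.g.
`E762*`). Codon numbers count from the transcript start. Cohort
frequency is pooled alt-allele count over called alleles, with distinct
nucleotide variants encoding the same residue change pooled into one
row; variants sharing a codon are computed independently against the
reference codon and flagged (haplotype-aware codon reconstruction is
out of scope). Rows at or below 5% are excluded from the report,
retained in full output.

Association with bioassay outcome uses the two-sided Fisher exact test
under the probability-ordering definition: the sum of hypergeometric
probabilities of all tables sharing the observed margins whose point
probability does not exceed the observed one. The comparison uses exact
integer weights (binomial coefficients), so ties are handled exactly
rather than to floating-point tolerance. SNP tests use allele counts
(alt/ref x alive/dead); CNV tests collapse to carrier status
(carrier/non-carrier x alive/dead) because a "distribution of CNV
counts" is not a single defined statistic — a secondary
permutation test over the full copy-number class distribution
(`cnv_class_association`, chi-square ordering with a simulated null)
is provided for users who want to retain the classes. A zero margin returns p = 1, flagged. Raw p-values are
reported; a Benjamini-Hochberg column is emitted alongside for the
reader, not applied to any decision in the pipeline.

## Diplotype clustering

Dosage vectors (0/1/2 per site) over a gene region are compared with
city-block distance `d(a,b) = sum_s |a_s − b_s|` and clustered by
complete linkage (inter-cluster distance = maximum member pairwise
distance). The agglomeration is implemented directly with a
deterministic smallest-index tie-break — library implementations
resolve distance ties differently, which changes dendrograms on tied
integer distances — and emits a scipy-format merge table so standard
cutting and plotting tools apply. Missing dosages are imputed to the
per-site mode for distance purposes only, with the imputed fraction
reported.

The dendrogram cut defaults to 0.001 x (site count) in distance units
and is always reported alongside results, since no principled universal
cut exists. Clusters at or above 5% cohort frequency are summarized:
size, frequency, mean heterozygosity (fraction of dosage-1 sites),
sites fixed non-reference within the cluster and the subset exclusive
to it, and mean region copy number when calls are supplied. A common
cluster with low heterozygosity — below the 25th percentile of
per-sample heterozygosity by default — is flagged as a selection
candidate: a haplotype rising under selection is increasingly found
homozygous.

## The synthetic cohort generator

The generator's defaults are the study conditions under which the
package is validated.

**Forward Wright-Fisher.** Diploid, discrete generations: parents
sampled with replacement proportional to fitness (1, 1+hs, 1+s at the
sweep locus), each gamete formed with Poisson(rL) crossovers and
Poisson(muL) new mutations at uniform integer positions under an
infinite-sites rule (positions no longer segregating are recycled, so
finite L never exhausts). Migration swaps individuals symmetrically
between demes, preserving sizes. Everything is reproducible from the
config seed.

Named configurations:

* `default_config` — two demes of N=100, 30 sampled each, 50 kb,
  mu=1.25e-5, r=1e-5, migration 0.25/generation, 800 generations:
  weakly differentiated cohorts (Hudson FST of order 0.001-0.01) like
  neighbouring field populations.
* `neutral_config` — one deme, N=50, 20 sampled, 20 kb at 4Nmu=0.005
  per bp, burn-in 20N generations. A 10N burn-in from the monomorphic
  start still shows a small negative Tajima's D (residual excess of
  rare variants); 20N centres it.
* `sweep_config` — the end-to-end scenario. Standing variation for
  N=1000 diploids over 300 kb (mu=1.5e-6, r=4e-6) is initialized from a
  neutral coalescent (msprime) — a 10N-generation forward burn-in at
  this size is not a desk-scale computation, and only the selective
  phase needs forward dynamics. A single-origin protective allele
  (s=0.1, h=0.5) is injected established at 40%: carriers receive the
  founder haplotype over an interval around the locus with
  exponentially-distributed extents of scale 1/(r * 30 generations) per
  side, emulating recombination during the unsimulated establishment
  phase (copying the founder's whole genome would leave an unrealistic
  genome-wide identical-haplotype relic). The forward phase runs until
  the allele reaches 75%, and 120 diploids are sampled mid-sweep — a
  fixed allele cannot associate with a bioassay outcome.

The scaled-down genome forces three choices a real chromosome would
not: recombination is set so neutral scan windows contain many
genealogies (per-window population rho ≈ 40-70) while the sweep core
(~1/(r t) ≈ ±8 kb) still spans whole windows; the 300 kb length keeps
the sweep footprint under ~5% of scan windows so it cannot contaminate
the 95th-percentile calibration statistic; and the selective phase is
kept to ~40 generations so the rescaled per-lineage mutation load on a
scan window stays well below one. Localization is therefore scored at
window granularity: a scan "finds" the sweep when its maximum falls
within one window of the window containing the locus, since the core's
homozygosity footprint physically spans several consecutive SNP windows
and window boundaries are arbitrary relative to the locus.

**Balding-Nichols genotypes.** Per site and deme, an allele frequency
is drawn from Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequency
p, and genotypes are Binomial(2, frequency) — the standard
structured-population model parameterized directly by FST, used to
verify the Hudson estimator recovers F (±0.03 at F=0.1, 1000 sites,
50 diploids per deme, 20 replicates).

**Coverage.** Window counts are negative binomial with mean
`depth * b_w * c / 2` (depth 30, dispersion 100) where c is the true
copy number and b_w a lognormal per-window bias (sd 0.1) shared across
samples, mimicking mappability/GC structure so that scalar
normalization is genuinely insufficient and the bias hook is exercised.
The negative binomial (not Poisson) makes coverage-variance QC failures
simulable (dispersion ~3 puts a sample past the 0.35 cutoff).

**Bioassay.** P(alive) = logistic(b0 + sum beta_l * dosage_l), dosage
being alt-allele count (or copy number minus ploidy). The sweep
scenario uses b0 = −3.0 and beta = +2 per allele, giving roughly
balanced ~60/60 arms at the sampled allele frequency of 0.75.

## What the synthetic validation shows — and does not

Passing studies demonstrate that the estimators are implemented exactly
(brute-force oracle agreement), that they recover known generator
parameters at the stated tolerances, and that the full pipeline
localizes a strong recent sweep and its phenotype association under
idealized conditions: phased error-free genotypes, a panmictic cohort,
a single selected locus, no inversions or other structural variation,
no batch effects, and coverage bias that is exactly shared across
samples. Real data violate all of these to some degree; in particular
the generator does not emulate realistic *Anopheles* demography,
polymorphic inversions (which the real analysis sidesteps by choosing
regions free of them), phasing or genotyping error, or GC-dependent
coverage beyond a static shared bias. Results on real cohorts therefore
depend on upstream QC that these simulations do not test.

## Numerical conventions

Internal coordinates are 0-based half-open; VCF/GFF I/O converts at the
boundary. Multiallelic records are dropped, not split. Missing
genotypes are excluded site-wise from allele counts. Percentiles use
the nearest-rank method. All reporting thresholds are strict in the
stated direction (frequency > 5% reported; variance > 0.35 removed;
likelihood ratio > 1000 retained). Tajima's D at S=0, FST with a zero
denominator, and Fisher tests with a zero margin return flagged
missing/convention values rather than silent zeros. Replicate counts in
the validation studies (50 neutral replicates, 20 sweep replicates, 20
Balding-Nichols replicates, 1000 null association tests) were chosen so
that each study's Monte-Carlo standard error is small relative to the
tolerance it checks.
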