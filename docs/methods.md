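# Methods

This note documents the models, conventions, numerical choices and
limitations of `circseam`, in the order data flows through the pipeline.

## Coordinates and identifiers

All intervals are 0-based half-open on the forward genomic axis. CIRI2
tables and GTF annotation (1-based inclusive) are converted exactly once at
parse time; no internal object ever carries 1-based values. The circRNA
identifier string `chrom:start-end:strand` keeps the *external* 1-based
start so ids match detector output; it is a pure function of the
coordinates, and identity across samples and detectors is coordinate
identity (an optional 0–2 nt slack exists for cross-detector matching,
since detectors can disagree on junction bases; default 0).

**BSJ extremity convention.** The two extremities of a back-splicing
junction are named in transcript orientation: `five_prime_ss` is the
transcript-5' boundary of the circularized span (genomic start on `+`,
genomic end on `-`) and `three_prime_ss` the transcript-3' boundary.
Region labels follow the same orientation: `Ex_A` is the first exon of the
span in transcript order, `Ex_Z` the last, with `Intr_A`/`Intr_M`/`Intr_Z`
between them. A bi-exonic circRNA has a single intron, which is proximal to
both extremities; it is labelled `Intr_A`. Window offsets are
strand-relative: negative offsets are upstream in transcript orientation,
and the offset of a window is the position of its 5'-most (transcript
orientation) base relative to the extremity.

## Count matrices

Each BSJ contributes a circular feature (junction-spanning reads) and a
linear partner (reads mapping linearly over the same two splice sites,
already summed over both sites by the upstream detector). `complete_counts`
builds a dense matrix over the union of BSJs across samples: a sample
lacking a BSJ gets a circular count of 0 and whatever linear-junction count
it reported (rows with zero junction reads model the realignment rerun that
recovers linear reads at junctions detected only in other samples), else 0.

The expression filter keeps features with ≥ `min_count` (default 2) reads
in ≥ `min_samples` (default 3) samples, applied to circular and linear
features independently; it is idempotent. A stricter linear-only threshold
(≥5 in ≥3, per condition) can be reproduced with the same function by
changing the parameters and the sample subset. Library sizes are sums over
the junction universe itself (circular + linear features), not
whole-transcriptome totals — CPM values are therefore comparable within
this universe only. CPM uses TMM-effective library sizes by default
(`library size x factor`); plain library sizes are a flag away.

`top_expressed` ranks circRNAs by mean CPM and keeps the top fraction
(default 20%), ties broken by identifier. `high_confidence` intersects the
calls of three detectors.

## TMM normalization

`tmm_factors` implements the trimmed mean of M-values: the reference sample
is the one whose 0.75-quantile of counts/library-size is closest to the
mean of those quantiles; for each sample vs the reference, features with a
zero in either sample are excluded, M-values (log2 ratio of library-scaled
counts) are trimmed by 30% on both tails and A-values (mean log2 abundance)
by 5%, and the factor is 2 to the inverse-asymptotic-variance weighted mean
of the surviving M-values. Factors are rescaled to geometric mean 1.
The implementation was validated during development against the reference
Bioconductor implementation on fixed toy matrices (agreement to ~1e-8;
frozen in the test suite at 1e-4).

TMM assumes most features are unaltered. When a large one-sided fraction of
the junction universe is deregulated the asymmetric trimming leaves a
residual bias (the planted-null log2FC shifts away from 0); the synthetic
defaults below respect the majority-invariant assumption for this reason.

## Negative-binomial LRT

Counts are modelled NB with mean `mu_ij = s_j * q_i` (offsets `s_j` =
TMM-effective library sizes) and variance `mu + phi * mu^2`. Per feature,
the rate `q` is fitted by Fisher scoring on `log q` under the null (one
rate) and the two-group alternative (one rate per group); the likelihood
ratio is referred to χ²(1). Features that are all-zero in both groups are
excluded (the expression filter normally removes them first). Group levels
sort alphabetically (or are supplied explicitly); `log2fc` is the second
level vs the first, computed on CPM-scale normalized group means with a 0.5
pseudo-count guard against zero groups. Significance is the raw p < α
(default 0.05); a BH-FDR column is emitted but unused by default.

Dispersion is either a fixed value or (default) a single common value
chosen on a 200-point log grid from 1e-4 to 4 by maximizing the Cox–Reid
adjusted profile likelihood (the fitted-mean profile likelihood minus half
the log determinant of the per-group Fisher information). The adjustment
matters: at 3+3 samples the unadjusted profile MLE is biased low (≈0.06 for
a true 0.1), which inflates the type-I error to ~0.11; the adjusted
estimate is near-unbiased and the realized type-I error is ~0.05. Tagwise
or trended dispersion shrinkage is out of scope; an externally computed
dispersion can be injected.

Numerical details: Fisher scoring runs at most 60 damped steps (step
clipped to ±5 in log space) with a 1e-10 convergence tolerance;
dispersions below 1e-8 use the Poisson log-likelihood directly (the NB form
suffers catastrophic cancellation in `gammaln` at 1/φ ≳ 1e10); the LR
statistic is clipped at 0.

## Pair classification and summary statistics

A circ/linear pair is **Concordant** when both isoforms are significant
with the same fold-change sign; **DiscordantCirc** when the circular is
significant and the linear is unaltered or significant with the opposite
sign; **DiscordantLin** when only the linear is significant; **Unaltered**
otherwise. The four categories partition all tested pairs.

The circular-to-linear ratio (CLR) is computed per condition on mean CPM,
excluding pairs whose linear CPM is zero; CLR distributions are compared
with the two-sample KS test (asymptotic two-sided p; appropriate for the
hundreds-to-thousands of pairs the analysis targets). Proportion and
overlap comparisons use two-tailed Fisher exact tests; reported odds ratios
apply a Haldane–Anscombe 0.5 correction when a cell is zero (the p-value is
always the uncorrected exact one). Overlap percentages default to the
Jaccard convention |A∩B|/|A∪B| with `setA`/`setB` denominators available,
since a single printed percentage for a two-set Venn does not identify its
denominator. `binding_by_cutoff` reports the interactor fraction among
significant circRNAs per p-cutoff and fold-change direction, with NA (not
0) for empty strata.

## Meta-BSJ binding enrichment

The representative transcript of a circRNA is chosen among its host gene's
isoforms by lexicographic priority: (1) transcript biotype equal to the
gene biotype, (2) both BSJ boundaries coincident with annotated exon
junctions, (3) fewest exons within the circularized span, (4) lowest number
of the first included exon, then lowest transcript id. Exon count and the
region labels derive from this transcript; only circRNAs whose boundaries
lie on exon junctions are labelable.

Windows are 100 nt wide and slide in 10-nt steps from −1000 to +1000 nt
around each extremity: offsets −1000 … +900, i.e. 191 windows per
extremity. Windows that would leave the chromosome are dropped with a
warning. Each window carries annotation properties measured against the
representative transcript (% of nucleotides in exons, 5'UTR, CDS, 3'UTR)
plus the host biotype and the exon class (1/2/3/4+).

For each target window, 2 control windows are selected from invariant
circRNAs (default: p ≥ 0.05 in the contrast, expression-filtered) at the
same extremity and offset: the pool is restricted to the same host biotype
and exon class, candidates are ranked by Euclidean distance on the four
percentage properties (ties by circ id), and the best k are taken without
replacement within a target (reuse across targets is allowed). Scarce
pools relax exon class, then biotype, logging each relaxation; a target
window with no pool at all is excluded from testing. `balance_check`
verifies target/control comparability: continuous properties are
dichotomized at the pooled median and tested by Fisher, categorical ones
category-vs-rest.

Peak containment (≥1 nt overlap, after within-replicate longest-peak
merging) is compared target-vs-control in a 2×2 Fisher test per
(extremity, offset), separately per RIP replicate — replicates are never
pooled. Region-level enrichment runs the same test per (exon-class group ∈
{2, 3, 4+}, region label) between downregulated and invariant circRNAs.
A circRNA is a binding interactor when its genomic span overlaps ≥1 peak in
≥2 replicates.

Note one geometric subtlety: for circRNAs shorter than the ±1000 nt window
range, the two extremities' window sets overlap, so planted binding at the
5' extremity legitimately produces significant bins at `three_prime_ss`
offsets ≈ −span. Localization checks therefore measure distance to the
planted extremity through each circRNA's span rather than reading the
per-extremity offset alone.

## Structure profiling

Within a replicate, overlapping peaks are reduced to the longest (ties:
lowest start). Each surviving peak contributes a 500-nt window with the
summit at offset 0 (offsets −250 … +249; the summit occupies index 250),
oriented to the strand of the associated circRNA (minus-strand windows are
reverse-complemented). For every position, the 151-nt subsequence (75 nt
up- and downstream, center included; the flank is configurable) is scored
for GC fraction (N bases excluded from numerator and denominator) and
folding ΔG; the profile reports per-offset means over windows.

The builtin folding backend computes the optimal nested secondary structure
under a simplified energy model — pair energies GC −3, AU −2, GU −1
kcal/mol, minimum hairpin loop 3 nt, no pseudoknots — by an O(L³) dynamic
program (numba-compiled with a pure-Python fallback). It is exact for its
own model (verified against exhaustive structure enumeration up to 18 nt)
and monotone (adding a closing G…C pair never raises ΔG), but its absolute
values are not thermodynamic free energies: the scientific claim a profile
supports is its *shape* (a center minimum in ΔG, a center peak in GC), not
kcal/mol magnitudes. The `external` backend shells out to the RNAfold
binary in batch for thermodynamic MFE values when those are wanted.

## Synthetic data

The generator emits a toy genome, Ensembl-dialect GTF, per-sample
CIRI2-style tables, three narrowPeak replicates and a truth table; a
(seed, config) pair is fully deterministic, with one pseudo-random stream
per output file (master seed + fixed label) so regenerating one file never
shifts the others.

Default study conditions (each a config key): 60 genes on 2 chromosomes,
3–6 exons of 150–300 nt, introns 400–900 nt, 3 kb intergenic spacing, 20%
lncRNA hosts, one circRNA per gene with boundaries on exon junctions and
1–4 exons; 3 control vs 3 knock-down samples; NB counts with dispersion 0.1
around baseline means of 100 (circular) and 400 (linear); planted log2 fold
change −2 on deregulated isoforms. Category fractions default to
Concordant 4% / DiscordantCirc 10% / DiscordantLin 6% / Unaltered 80%,
mirroring the deregulation rates of the knock-down contrasts the pipeline
targets (roughly 10–17% of tested circRNAs deregulated, mostly down and
discordant) and respecting TMM's majority-invariant assumption. 15% of
circRNAs are "dropout" species detected in only one condition (half still
report linear-junction reads in the undetected samples, half are absent
entirely), exercising cross-sample count completion; dropout circRNAs are
excluded when scoring category recovery since their planted category is not
identifiable from one-sided detection.

Peak placement: under `near_bsj`, every target circRNA (downregulated
discordant) receives, in 2–3 of 3 replicates, a 50–100 nt peak whose summit
is within 50 nt of the 5' extremity and which always covers the extremity
(guaranteeing interactor recall 1 by construction), plus 10 uniform
background peaks per replicate; under `uniform`, 120 peaks per replicate
are scattered uniformly. Summits carry a GC-rich motif (GC 0.9, length 30
by default) written into the genome; profile-shape checks use a motif
length of 151 = the folding context, which makes offset 0 the unique
profile optimum instead of a plateau.

What the generator does *not* emulate: read-level artifacts (no FASTQ, no
mapping ambiguity), multi-isoform host genes (one transcript per gene;
isoform selection logic is tested on hand-built annotations), overlapping
genes, GC-dependent coverage bias, and correlated replicate structure.
Passing tests on this data therefore demonstrate the statistical machinery
and geometry of the pipeline, not robustness to alignment artifacts of real
libraries.

## Problem sizes used by the acceptance script

The acceptance script measures category recovery on a 200-circRNA scenario
(~180 scorable pairs after dropout exclusion, chosen so the binomial noise
of the recovery estimate is small), calibration on a 2000-feature null,
window-enrichment calibration on three 120-circRNA uniform-peak scenarios,
and metaprofiles over 15 summit windows (7,500 folding calls); the whole
script completes in about half a minute.

## Known limitations

* The NB testing stage reproduces the statistical contract (TMM, NB GLM,
  χ²(1) LRT, common dispersion) of the standard count-based DE stack, not
  the exact numerics of any particular release of it.
* Fisher p-values use the exact two-tailed convention of summing
  hypergeometric probabilities ≤ the observed table's; other two-tailed
  conventions (doubling) give different values for asymmetric margins.
* The builtin ΔG scale is model-specific (see above).
* The matched-control design assumes invariant circRNAs exist with
  comparable annotation composition; heavily relaxed matches are logged
  but still used.
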