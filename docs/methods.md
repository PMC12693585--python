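# Methods

## Scope and model

`promevol` quantifies promoter sequence evolution for a tissue-specific
gene set against control gene sets, and relates it to expression
divergence between species and between the two parental alleles of
interspecies hybrids. It consumes pre-aligned promoter alignments,
TSS annotations, per-base signal tracks and count/expression tables; it
does not compute multiple alignments, align reads, or fit moderated
differential-expression models.

## Coordinates

All genomic coordinates are 0-based half-open. TSS-relative positions are
signed offsets with the TSS base at 0 and upstream negative; the analysis
window is offsets [−1000, +300). On minus-strand genes tracks are
reversed (`track_to_offsets`) so offsets always increase downstream —
one convention for every stage. bedGraph is the canonical track format
(text, diff-able); uncovered bases take a configurable fill value
(default 0 for both CAGE and conservation; coverage handling is a
package choice).

## Gene-set selection (τ)

τ = Σᵢ (1 − xᵢ/x_max)/(N − 1) on untransformed non-negative expression
values (a log2(x+1) transform is available behind a flag, off by
default). An all-zero profile has no defined τ and is returned as NaN,
never 0. Selection requires both τ ≥ τ_min (default 0.9, the
conventional tissue-specificity threshold) and the row maximum in the
target tissue — τ alone does not identify *which* tissue dominates. The
second-tissue control set ranks qualifying genes by τ (descending, ties
by gene id) and truncates to k = 50. The random control set samples k
genes from the universe minus the focal set, reproducibly per seed.

## Dominant TSS (f)

f at a candidate TSS is the CAGE signal summed over a 9-nt window
*centered* on the candidate (symmetric with respect to CAGE peak-position
inaccuracy, which is the score's purpose), truncated — not discarded — at
track boundaries. The annotated candidate with the highest f is dominant;
exact ties go to the most 5′ candidate on the gene's strand, which is
reproducible and favours the annotated primary start. De novo peak
calling is out of scope: only annotated candidates are ranked.

## Event coding

Alignments are trimmed to reference offsets [−1000, +300), counted in
reference (non-gap) bases; columns gapped in the reference between
retained bases are kept, and a reference shorter than the window yields a
truncated window with a warning. Each non-reference species is coded
against the reference (never all-pairs):

- **base** mode: 1 where both rows carry nucleotides that differ;
- **indel** mode: 1 at every reference base aligned to a gap in the
  other row (deletion), and a single 1 at the reference base immediately
  5′ of an insertion (insertions carry no reference base of their own;
  an insertion before the first reference base anchors to the first
  offset with a warning);
- **all** mode: the elementwise OR.

`N` is treated as conserved (assembly artifacts should not inflate d) and
columns gapped in both rows carry no information and are skipped. Multi-
base deletions mark every affected base in the per-offset vectors
(matching per-nucleotide 0/1 coding); for positional analyses
`event_positions_5prime` instead collapses each contiguous indel to one
event at the 5′ site of its start. Tallies sum vectors across species
pairs and genes sharing mode and offset range.

## Hotspot scores (Se, d, d^P)

Se is the event count summed over a centered 5-base window, truncated at
the ends. The control baseline Se^C is the *global* mean of all control
Se values within the promoter region — a single scalar, matching its use
as one group-level reference. The promoter region defaults to offsets
[−380, −31]: 350 nt immediately upstream of a TATA box placed at the
canonical −30; the exact TATA estimate is open, so the region is
configurable.

d = 100 × n_exceeding/N over the region, where by default n_exceeding
counts *events* (weighted by per-position counts in tallies) whose Se
strictly exceeds Se^C; this keeps d in [0, 100]. An alternative
interpretation counting all positions with Se > Se^C is available via
`d_mode="positions"`. A region without events yields d = 0 flagged
undefined. d^P replaces events with per-base conservation values:
100 × #{positions with p < p^C}/#positions, with NaN positions excluded
from both counts. Both comparisons use strict inequality ("exceeding",
"below").

Group tests: unpaired Student t-tests on per-gene means, and 2×2
chi-squared tests without continuity correction on
[exceeding, not-exceeding] × [group, control]. Bonferroni correction is
applied within the d/d^P family; Benjamini–Hochberg within the
expression-fraction family.

d discriminates between groups only when Se^C exceeds 1 — for a single
species pair every isolated event (Se ≥ 1) trivially exceeds a
sub-unit baseline — so group-level d is computed on concatenated tallies
across genes and species pairs, which is also how the score is exercised
in the tests.

## Positional hotspots (G function)

For n ≥ 2 unique sorted event positions x₁ < … < xₙ (0-based alignment
columns; events at one site must be pre-merged) in an alignment of
length L, G_k = k/n − (x_k + 1)/L. The test statistic is the maximal
climb max_{i<j} (G_j − G_i), with ties broken by smaller i then smaller
j (indices are 0-based in the API). The null distribution draws n sites
uniformly without replacement from [0, L) — 100,000 resamples by
default, computed in fixed-size chunks to bound memory — and the
empirical p-value is (1 + b)/(1 + B), never exactly 0. If the maximal
climb is significant at α, its events are masked and the remaining
events are retested against a null re-simulated at the reduced n; calls
are reported as half-open column spans sorted by start. Events fed to
this stage are the collapsed 5′-start events, pooled across species by
default. The per-consecutive-pair ΔG values are exposed on the `GSeries`
for the alternative reading of the statistic, but the maximal climb is
the tested quantity.

## Expression divergence

TPM divides counts by gene length in kb and rescales each sample to 10⁶
(no effective-length modelling). log₂ fold changes use a pseudocount of
1 TPM on both means (the choice is open; 1 TPM is small against the
simulated means of ~200 counts). Two significance presets exist:
`divergent` (|log₂FC| ≥ 0.5 *and* adjusted p ≤ 0.05, both boundaries
inclusive; missing p never qualifies) and the fold-change-only
`large_change` rule (|log₂FC| > 1, strict) used for tertile enrichment.
Externally fitted per-gene log₂FC/adjusted-p tables are the intended
input; `welch_de_table` provides a plain per-gene Welch t-test on
log-TPM with BH correction as a clearly labelled self-contained
stand-in, not a moderated model.

Hybrid allele tables (rows = gene × allele, one count column per
replicate) are filtered by removing genes on excluded chromosomes
(default X, by label — no genome knowledge baked in) and genes detected
in fewer than 4 of the pooled allele × replicate columns, the guard
against mono-allelic expression inherited from one parent. Pooled-column
counting is the implemented reading of the detection rule; the threshold
and pooling are configurable.

Densitometry: per-allele signal is Σ intensity/fragment-length over that
allele's bands (digested fragments are length-normalised), and the
allele log₂FC is the log-ratio; zero signal on either side is an error,
never ±∞. The hybrid/non-hybrid normalisation is
log₂FC_hybrid / log₂FC_non-hybrid, undefined at a zero denominator.

## Synthetic data

The generator writes events directly on the reference coordinate frame
and emits the alignment with explicit gaps, so its truth records are an
exact oracle for the event-coding stage — no aligner sits in the loop,
and misalignment noise is deliberately not modelled. Consequences: a
deletion never starts immediately after a deleted base (adjacent
deletions would merge in the alignment and blur the truth), insertions
never occur before the first reference base, and each junction carries
at most one insertion per species.

Defaults, chosen once as realistic for closely related fly species and
not tuned afterwards: base substitution rate 0.05/site and indel rate
0.01/site (split evenly between insertions and deletions), scaled per
species by the divergence ladder (0.4, 0.5, 1.0, 1.2) so the closest
pair diverges at ~2% of sites; geometric indel lengths with mean 3;
hotspot region [−380, −31] at multiplier 4. Conservation tracks are
Gaussian (mean 1.0, sd 0.5) minus a depression of 1.5 at event
positions. CAGE tracks place Poisson-jittered peaks (height 20–60) at
candidate TSSs with one candidate scaled 5×. Counts are negative
binomial with mean 200 and dispersion 0.1 (variance μ + 0.1μ²),
n = 3 replicates; per-gene log₂FC ~ Normal(0, 1); hybrid allele means
either keep the species ratio (cis-maintained) or fix one allele at
2² × the other (dominant_A/B); 15% of genes are labelled X.

What the generator does not emulate: alignment errors, phylogenetic
substitution models (HKY/GTR, rate heterogeneity), shared ancestry
between the non-reference species (each is drawn independently from the
reference), library-size variation, and read-level artifacts. Passing
tests therefore demonstrate correctness of the scoring machinery and
sensible behaviour under the assumed generative structure, not
robustness to real-data noise.

## Problem sizes and numerical choices

The test suite and acceptance script exercise the Monte Carlo machinery
at n = 25 events, L = 1300 columns and 2,000 resamples — 500 null
replicates for calibration (exact binomial 99% interval around
α = 0.05) and 200 planted-cluster replicates for power — sizes chosen so
the full suite runs in well under a minute while the binomial intervals
remain tight. The production default of 100,000 resamples matches the
intended use on real alignments. Oracle-equivalence checks (G function,
d score) run 1,000 random instances each and require exact (G) or
floating-point-close (d) agreement with direct brute-force evaluation.

## Known limitations

- The τ formula is applied to whatever expression units are supplied;
  FPKM vs raw intensities change τ values.
- The TATA-box position is assumed at −30 rather than estimated.
- The package reports hybrid allele fold changes from supplied or
  simulated counts; inference of cis vs trans architecture beyond the
  maintained/dominant dichotomy is out of scope.
- Interface: the package is a library — the importable API plus the
  `examples/` scripts are the supported entry points; there is no shell
  command.
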