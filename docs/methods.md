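# Methods

## The measurement model

The package analyzes clonal reproduction in a triploid parthenogen. Because
sperm triggers embryogenesis without contributing a genome, an offspring is
genetically its mother's clone plus the mutations of one generation; a
heterozygous single-copy variant therefore sits at true allele fraction
1/3 (or 2/3 when two of the three genome copies carry it). Every analysis
operates on per-site, per-sample read counts — a pileup table — rather than
on alignments: the calling criteria are all expressible as counts, coverage
and mean mapping quality, which keeps the pipeline aligner-independent and
desk-scale. BAM-level processing (realignment, base-quality recalibration)
is deliberately out of scope.

Four variant classes structure the analysis:

* **germline-shared** — carried by every animal in the cohort; used for
  ploidy inference.
* **lineage-specific** — pre-existing variants private to one family
  (a parent and its descendants); used for pedigree assignment.
* **de-novo-clonal** — private to one offspring, present in all its cells
  at AF ≈ 1/3; the per-generation mutation load.
* **subclonal** — confined to a fraction *c* of an animal's cells at
  AF = *c*/3; the signature of mosaicism in regenerated animals.

## Calling

One count-based caller serves both detection modes. `call_unique` emits a
sample-private call when the permissive scan passes (alt fraction ≥
`min_sample_freq` = 0.15 in the candidate, depth ≥ `cov_limit` = 20, every
other sample ≥ `min_other_ref_freq` = 0.9 reference) and the postfilter
holds (≥ `min_support` = 7 supporting reads, ≤ `max_other_alt` = 1 read of
the allele in any other sample, candidate depth within 25–130× inclusive,
mean MQ ≥ 40). Boundary behavior is fixed as inclusive everywhere and every
threshold is configurable. A comparator sample with zero depth fails the
reference check — absence of evidence is not evidence of reference. The
coverage window applies to the candidate sample only (a flag widens it to
all samples). `call_shared` applies the same allele-fraction threshold to
≥ 2 carriers and the same contamination bound to the rest.

At ~50× and a per-base error rate of 0.002 the per-variant recall of a
clonal (AF 1/3) variant is ≈ 99%: the dominant loss modes are a binomial
draw below 7 supporting reads (P ≈ 1e-3) and ≥ 2 error reads of the same
allele in one of the comparators (P ≈ 5e-4 per comparator). Specificity is
effectively perfect: a false positive needs ≥ 7 error reads of one allele
at per-allele rate e/3, with tail probability ~1e-14 per cell. Both numbers
are verified in the test suite against binomial-tail oracles.

## Pedigree

Lineage-specific variants shared exclusively within a family accumulate in
a pairwise sharing matrix (variants carried by all samples contribute to no
pair; family-mode counting credits every carrier pair, because regenerants
sit between parent and offspring and share trunk variants with both).
Offspring and regenerants are assigned to the argmax parent; an assignment
must beat the runner-up by a configurable margin (default 3 variants) or it
is flagged ambiguous rather than silently chosen. The three-generation star
topology (parent → regenerant → offspring) is the only model; no general
phylogenetic inference is attempted.

## Rates, mappability and burden

The per-generation rate is μ = *k* / (*n*·*L*): total mappable de novo
calls over offspring, divided by offspring count times the uniquely
mappable haploid length. Each heterozygous event is counted once per
surveyed haploid position; the per-allele variant (÷ ploidy) is available
behind `per_allele=True` but is not the default, as the position-based
normalization is the one under which the worked-example rates are
arithmetically self-consistent. Displayed rates keep three significant
digits by truncation toward zero, not rounding (`display_rate`), the rule
under which 1.316e-8 prints as 1.31e-08 and 1.727e-8 as 1.72e-08.

Mappability is computed as exact k-mer uniqueness (default k = 50,
canonical = lexicographic min of k-mer and reverse complement), replacing
the aligner-based mask a real study would derive; external BED masks are
accepted for real data. The burden comparison uses Welch's unequal-variance
two-sided t-test (pooled-variance available), with sample SDs on the n−1
denominator; the two-proportion test is Pearson's χ² without continuity
correction (correction available).

## Spectra and CpG

SNVs are collapsed to the pyrimidine strand: 6 substitution channels, or 96
when resolved by trinucleotide context (COSMIC channel order). The collapse
is an exact 2-to-1 map of the 192 strand-resolved (context, substitution)
pairs, verified exhaustively. Spectrum comparisons use Pearson correlation
of normalized channel vectors; the default resolution is 6 channels because
cohort-scale de novo sets (~20–50 mutations) leave 96 channels sparse.
Genome triplet frequencies are counted on the forward strand (N windows
skipped) with a strand-collapsed 32-triplet view derived from the same
pass. The CpG-depletion probe compares mean frequencies of CpG-containing
vs composition-matched non-CpG triplets within each G/C-count stratum; a
ratio near 1 is the signature of an unmethylated genome.

## Ploidy and mosaicism

Ploidy comes from the histogram of germline-variant allele fractions (2%
bins, 3-bin moving average). Peaks are local maxima above half the global
maximum with a prominence and 3-bin-separation requirement — integer read
counts at near-constant depth leave comb artifacts in the histogram that
plain local-maximum detection mistakes for modes — and each peak is refined
as the mean AF of the observations nearest to it. The lowest peak fixes the
ploidy (round(1/peak)); remaining peaks are checked against multiples of
1/ploidy. On matched simulations ploidies 2, 3 and 4 are recovered in 100
of 100 seeded runs each.

Subclonal support of a filial clonal variant in an ancestor requires ≥ 2
alt reads and a one-sided binomial test against the per-allele error rate
(e/3) at α = 0.05 — an explicit, configurable stand-in for a judgment the
original workflow made by inspection, consistent with an observed AF floor
of ~1% at 50–90×. Cell fraction = min(1, ploidy × AF) for single-copy
heterozygous variants; because planted subclonal variants are
single-haplotype within their subclone, the conversion is exact on
noiseless input. Deep amplicon sequencing is modeled as a second binomial
readout of the same true site fractions at fixed high depth
(`amplicon_resample`); primers, read merging and realignment are not
simulated. Quantifying sub-2% fractions needs that deep readout: at 50× a
3%-cell-fraction subclone (AF 1%) yields a median of zero alt reads, so
WGS-scale counts can detect but not quantify the smallest subclones — the
parameter-recovery test therefore detects at 50× and quantifies at 2000×.

## Haplotig purging and synteny

A self-alignment counts as duplication evidence only if it is
reciprocal-best between its two scaffolds (each scaffold's best partner by
summed matched bases is the other), its secondary/primary chain-score ratio
is ≤ 0.5, divergence ≤ 60%, mapq ≥ 60, and no single repeat interval covers
> 40% of the aligned length on either side (the per-element reading, not
cumulative repeat coverage). For each retained alignment the aligned region
on the shorter scaffold is excised, overlapping removals are merged first,
and scaffolds left under 1 kb are dropped. Alignments whose coordinates no
longer fit the current scaffolds (stale evidence from a previous pass) are
skipped, which makes purging idempotent; alignments naming unknown
scaffolds are errors.

Synteny links classify each scaffold by the set of partner scaffolds its
filtered gene anchors map to (filters: masked < 10% of length, mapped
length > 300 bp, not nested, one-to-one homology — all strict). A break
site between consecutive anchor runs of different partners requires ≥ 2
genes on both sides. Classification formalizes a previously manual
judgment: both runs within 50 kb of their partner-scaffold ends (or named
by user-supplied adjacency evidence) → partner-end adjacency; both runs
strand-consistent with monotone partner coordinates → rearrangement;
otherwise → poor scaffolding.

## The synthetic generator and what it does not emulate

`SimConfig` defaults are the study conditions: 50× mean coverage (Poisson
per sample and site), error rate 0.002 split evenly among the three non-
reference bases, triploid genomes at GC 0.32 with 10% repeats built by
copying a 500 bp master unit (guaranteeing non-unique k-mers), germline
heterozygosity 1 site / 5 kb (a free parameter — the real density is not
established) with a 50/50 split between one- and two-haplotype sites, four
parents per arm with offspring counts (1, 1, 0, 2), planted per-offspring
clonal SNV counts (2, 4, 5, 9) control and (11, 13, 13, 17) regenerated
(integer tuples consistent with group summaries of 5 ± 2.94 and
13.5 ± 2.52), indel counts (0, 0, 2, 3) and (1, 1, 2, 2), and one
18%-cell-fraction, 5-variant subclone per regenerant (AF 6%, the maximum
the analysis converts to cell fraction). De novo spectra default to a
broad shape for control/germline — (0.20, 0.10, 0.25, 0.10, 0.20, 0.15)
over C>A, C>G, C>T, T>A, T>C, T>G — and a transition-enriched one
(0.05, 0.04, 0.38, 0.04, 0.44, 0.05) for the regenerated arm; the exact
weights are this package's choice, with magnitudes that make the
germline-resembles-control correlation ordering reproducible at realistic
mutation counts.

Pileups are simulated only at variant sites plus a configurable number of
invariant sites (default 3000): simulating the full genome would add
nothing, since the caller touches only sites with non-reference reads or
planted variants, and the false-positive analysis is handled analytically.
Reads are never simulated; binomial count sampling at the pileup level
captures everything the caller consumes. Mean mapping quality is 60 outside
repeats and uniform in [10, 35] inside, so the MQ filter excludes
repeat-region sites the way multi-mapping reads would.

Features of real data deliberately not emulated: recombination and
occasional sex (the species is assumed stably triploid and clonal),
indel sequencing noise (aligner-specific), context-dependent error rates,
mapping artifacts beyond the MQ proxy, and embryonic lineage structure.
Passing tests therefore demonstrate the correctness of the statistical
machinery under the stated model, not robustness to alignment artifacts in
real sequencing data.

One interaction deserves emphasis: if regenerant subclones are *linked* to
their offspring's clonal variants (the germ-lineage scenario, available via
`subclone_shared_fraction > 0`), the caller's ≤ 1-alt-read-in-any-other-
sample postfilter censors exactly the filial calls that have genuine
subclonal support in the regenerant (AF 4% ≈ 2 reads at 50×). The default
replica therefore plants regenerant subclones at independent sites, which
keeps planted-count recovery exact; analyses of linked designs should
exempt direct ancestors from the contamination check (the caller's
`max_other_alt` applies to all comparators uniformly, so this is a known
limitation, not a switch).

## Determinism and numerics

All randomness flows from one root seed through named, CRC-hashed
substreams per stage (`stage_rng`), so any stage can be rerun in isolation
and a rerun of the replica with the same seed is byte-identical (JSON with
sorted keys). Variant-position collisions are resampled against a global
occupied set. The k-mer mask packs canonical k-mers into one or two 64-bit
words (k ≤ 31 or ≤ 62) and finds duplicates by lexicographic sort — exact,
no hashing collisions. Ties in pedigree argmax resolve alphabetically but
any tie within the margin is reported as ambiguous. Degenerate inputs
(empty call sets, zero-depth cells, all-N windows, empty masks) return
empty results or raise typed errors as documented per function.

## Problem sizes

Default test and acceptance scales: 5 Mb genomes for the study replica
(seconds per run), 2 Mb / 8 samples / 20 000 invariant sites for the
specificity check, 20 kb for brute-force oracle comparisons, 2000 AF
observations for ploidy inference, 100 seeded runs for recovery-rate
statements. These sizes make every property testable in seconds while
keeping all per-site statistics identical to genome-scale runs (the
analyses are per-site; only the number of sites shrinks).
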