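# Methods

`rilmap` builds genetic linkage maps for recombinant inbred line (RIL)
populations from genotype call matrices and compares them with a physical
genome assembly. This note documents the models, estimators, numerical
choices and their limitations.

## Population model and simulator

A biparental RIL population starts from a fully heterozygous F1 and is
advanced by single-seed descent (one offspring per line per generation,
no outcrossing) to generation g. Residual heterozygosity halves each
generation; at F7 the expected heterozygote fraction is (1/2)^6 =
1.5625 %.

The simulator realises meiosis as a Markov process along each
chromosome: a gamete starts on one of the two parental haplotypes with
probability 1/2 and switches haplotype independently in each adjacent
marker interval with probability r = inverse-Kosambi(Δd). Using the
inverse of the same map function the mapping stage uses makes
distance-recovery experiments self-consistent; no interference beyond
what the Kosambi function encodes is modelled, and crossovers are only
realised at marker-interval resolution.

Transmission distortion is modelled as gametic viability: a gamete
carrying the disfavoured allele at a distortion locus survives with
probability w per generation (rejection sampling). This reproduces
localized allele-frequency skews without asserting a specific biological
mechanism (meiotic drive, gametic or zygotic selection all produce
similar marker-level signatures in a selfing design).

Observation noise is a separate, seeded step: each call is masked with
probability `missing_rate`, then each surviving homozygous call is
flipped A↔B with probability `error_rate`. Heterozygous calls are never
flipped — array genotyping errors overwhelmingly confuse homozygote
clusters, and downstream mapping treats H as missing anyway.

What the simulator does *not* emulate: read-level data (depth, allele
dropout, reference bias), correlated missingness (real RAD libraries
lose whole restriction sites per line, not independent calls),
position-dependent marker density, and interference-aware crossover
placement. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated statistical model, not robustness to
every artefact of real sequencing data.

## Filters

Two marker-filter profiles mirror the two screening stages of a RAD-seq
workflow: `rad` (missing ≤ 0.66, het ≤ 0.10, allele frequency within
[0.2, 0.8]) and `map` (missing ≤ 0.30, same otherwise), plus line-level
filters (het > 0.10 removed, optionally missing > 0.25 removed — the
`map` stage default). Allele frequency is nA/(nA+nB) over homozygous
calls only; in a RIL, heterozygosity is transient and the 0.2–0.8 band
targets parental allele balance among fixed lines. "More than" is read
as strict inequality, "up to" as inclusive.

## Imputation and binning

Within a scaffold (markers ordered by bp), a maximal run of missing
calls whose nearest non-missing calls on both sides are identical is
filled with that call — the assumption being that no recombination
occurred across the run. Imputation never alters a non-missing call and
never crosses scaffold boundaries. Its only failure mode is a double
crossover entirely inside a masked run; at study-like marker spacing the
measured mismatch rate against simulation truth is ~0.1–0.5 %, reported
by the acceptance script.

Markers with *exactly* identical call vectors (including missing
positions) collapse into recombination bins; requiring exact equality
rather than compatibility ensures binning never imputes silently. The
representative is the member with the fewest missing calls (ties: lowest
bp, then lexicographic id). Binning runs after imputation, genome-wide
by default with a within-scaffold option.

## Grouping, ordering, distances

Pairwise recombination fractions are estimated as opposite-homozygote
fractions over lines homozygous at both markers; pairs with fewer than
`min_informative` (default 20) informative lines are treated as
undefined — a guard that replaces tool-internal quality scores of
legacy mapping software with a transparent sample-size threshold.
Linkage groups are single-linkage connected components at r ≤ 0.2.
Groups are labelled by the majority physical chromosome of their markers
when known, else LG1, LG2, … by size.

Ordering minimises COUNT: the total number of transitions between
consecutive non-missing homozygous calls along the order, summed over
lines (the RECORD objective; H counts as missing). The search is greedy
sequential insertion — markers added in random order, each at the
COUNT-minimising position — repeated from 30 seeded random starts,
followed by rippling: every window of 5 consecutive markers is permuted
exhaustively, permutations are accepted only when they strictly lower
COUNT, and sweeps repeat until none improves. For groups of ≤ 8 markers
an oversized window degrades to exhaustive permutation of the whole
group, which is also the brute-force oracle used in tests. Orientation
is canonicalised (first marker id lexicographically ≤ last).

Map construction is two-round. After round-1 ordering, singletons
(interior calls contradicting two agreeing flanking calls — apparent
double recombinants) are replaced by the flank consensus, and missing
calls are re-imputed from flanks along the map order; round 2 re-orders
the corrected matrix, and per group the candidate order with the
shortest total Kosambi length is kept. Boundary markers are never
corrected. Note that an error adjacent to a true junction merely shifts
the junction and is undetectable by any flank-based rule; such errors
(plus boundary errors) bound the achievable correction rate, which is
why the error-reversion experiments run at the study-like 0.5 cM
spacing.

**Adjacent distances.** After imputation, naive adjacent-pair estimates
are biased: flank-filling imputes exactly the concordant runs, so the
lines still missing at a marker are enriched for recombinants, and
complete-case estimation hides their junctions. Adjacent r is therefore
estimated with the same skip semantics as COUNT: per line, each pair of
consecutive non-missing homozygous calls spans one or more adjacent
intervals; a junction contributes 1/k recombinant weight to each of the
k spanned intervals and the line contributes one observation to each.
Summed over intervals this preserves the total junction count exactly.
Estimates are capped at 0.4999 so the Kosambi transform
d = ¼·ln((1+2r)/(1−2r)) stays finite; intervals with no spanning line
get r = 0.

**RIL map expansion.** The observed recombinant fraction R between
homozygous RILs accumulates recombination over generations and at
fixation approaches 2r/(1+2r) — roughly doubling map lengths if used
directly. By default `rilmap` reports distances from raw R, matching the
convention of the classical mapping tools this pipeline emulates. Two
corrections are available: the fixation-limit inversion r = R/(2−2R),
and an exact finite-generation inversion that propagates the two-locus
diplotype Markov chain of selfing to F_g and inverts the resulting
monotone map numerically (Brent's method). The exact form matters: an
F7 population sits ~9 % below the fixation limit, a visible bias when
comparing estimated maps against simulation truth, which is why all
truth-recovery experiments use `ril_correction=True, generations=7`.

## Diagnostics

Mean adjacent-marker spacing is total length / total markers — the
convention under which 653 cM over 1,336 markers prints as 0.5 cM.
Genome length is estimated by Chakravarti's method 4, scaling each
group's length by (m+1)/(m−1); coverage is observed / estimated
(Sekino–Hara ratio). Per-group application is the default; a global
single-factor mode is exposed since the two differ visibly for few,
marker-dense groups (98.2 % vs 99.9 % on the packaged published table).

Segregation distortion is a χ² goodness-of-fit test of nA:nB against
1:1 (df = 1, H and U excluded — the Mendelian 1:1 expectation applies
to fixed lines). A marker is called distorted when p < α (default 0.05)
*and* freq(A) falls outside the open interval (0.4, 0.6); no
multiple-testing correction by default (a Bonferroni flag exists).
Segregation distortion regions are maximal runs of ≥ 2 consecutive
mapped markers distorted toward the same parent; interleaved
non-distorted markers are tolerated only up to `max_gap_markers`
(default 0), and opposite-direction markers always split a region.

## Genome comparison and recombination landscape

Physical positions are an input (marker metadata), not computed by
alignment. Each mapped marker is classified exactly once: syntenic
(physical chromosome equals its group's majority chromosome),
non-syntenic (runs of ≥ 2 sharing a chromosome are reported as
clusters), unplaced-scaffold (anchored to the group and cM interval of
its markers), or no-physical-hit. Since linkage-map orientation is
arbitrary, each group is flipped when its Spearman ρ (map rank vs bp,
syntenic markers only, ≥ 3 required) is negative, and reported ρ values
are post-orientation.

Local inversions: a window (default 10) of consecutive syntenic markers
slides along each group; windows with local ρ ≤ −0.8 are flagged and
overlapping flags merge into maximal segments reported with cM and bp
extents and segment-wide ρ. Reversed blocks ≥ 1.5× the window are
detected with no false segments on collinear fixtures; blocks shorter
than the window are not detectable by construction.

Recombination rates: each adjacent syntenic pair contributes
ΔcM/(Δbp/10⁶); intervals whose physical coordinates run backwards are
skipped and logged. Classes: hot > 20 cM/Mb, moderate 10 ≤ rate < 20,
cold exactly 0, else normal. Chromosome-level rates use marker-flanked
spans, and the chromosome rate equals the Δbp-weighted mean of its
interval rates. Gene membership in an interval uses the gene-midpoint
rule (no double counting); GC is computed over unambiguous bases of the
interval sequence and reported as unavailable without a FASTA.
Coordinates are 0-based half-open internally; GFF3 input (1-based
closed) is converted on read, and outputs are labelled.

## Problem sizes and seeds

Simulation-backed tests and the acceptance script run at the study's
scale: 92 lines, F7, chromosomes of ~80 cM. The parameter-recovery
experiment uses 2 chromosomes × 100 markers with 20 % missing calls and
0.5 % genotyping error; ordering-oracle checks use 7-marker groups so
all 5,040 permutations can be enumerated; calibration checks use
independent loci (one marker per unlinked chromosome) so binomial error
bars apply. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
outputs, including the run manifest.

A caveat on length recovery: the realized junction count of a 92-line
F7 population has ~9 % sampling SD per 80 cM chromosome, so estimated
group lengths scatter accordingly around the generative truth — an
irreducible property of the population size, not estimator noise.

## Known limitations

- Only codominant A/B/H/U calls are supported; dominant marker patterns
  must be excluded upstream.
- Grouping is single linkage; a chain of borderline pairs can bridge
  distinct chromosomes at liberal cutoffs (an optional split at adjacent
  gaps > 30 cM is provided).
- The greedy-insertion + rippling search is a heuristic; global COUNT
  optimality is only guaranteed where enumeration is feasible (≤ 8
  markers), though it is attained in practice far beyond that.
- The distortion test assumes independent lines; SDR calls inherit the
  marker order and flag clusters, not causal loci.
- The landscape analysis trusts the input physical positions; assembly
  errors appear as inversions/non-syntenic clusters by design rather
  than being corrected.
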