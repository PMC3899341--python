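# Methods

## Reference index

The reference is concatenated contig-by-contig with single `N` separators
and indexed as a Burrows–Wheeler transform with an FM-index (checkpointed
ranks every 64 symbols) and a suffix array sampled at rate 8 (positions
recovered by LF-walking to the nearest sampled row). The suffix array is
built by numpy prefix doubling — O(n log n) with sorted-key passes — which
handles the desk-scale genomes this package targets (a 10-Mb genome
indexes in about half a minute); the per-read hot loops (backward search,
locate, seed enumeration) are numba kernels. `N` is excluded from the
searchable alphabet: a pattern containing it matches nothing, and because
contigs are separated by `N`, no seed can straddle a contig boundary.

MEM seeds are found by exact backward search of every length-`min_mem_len`
window of the (oriented) read, locating each occurrence and extending it
on the text to its maximal exact match; every MEM of length ≥
`min_mem_len` contains at least one such window, so the enumeration is
exact (verified against a quadratic brute-force enumerator in the tests).
Windows with more than `max_occ` occurrences contribute only the first
`max_occ` rows in suffix-array order — a deterministic cap on repeat
blow-up. k-mer seeds use the same search on non-overlapping tiles at
offsets 0, k, 2k, … of each strand.

## Alignment kernels

Local (Smith–Waterman) and semi-global alignments use affine gap scoring:
match +1, mismatch −3, gap of length L costs −5 − 2L. The match reward is
deliberately smaller than the penalties so that runs of errors depress
local scores — which is what makes the semi-global rescue path
informative. The matrix fill and traceback are delegated to Biopython's C
`PairwiseAligner` (semi-global = global mode with free reference end
gaps); this module owns CIGAR construction, identity and edit-distance
bookkeeping, and is checked against an independent full-matrix DP oracle
in the tests. Identity is computed over aligned read bases (M+I columns).
`N` never scores as a match, not even against `N`.

Qualification: a local alignment is accepted at identity ≥ 90% and
aligned-base fraction ≥ 0.80; a semi-global alignment at identity ≥ 65%
and the same coverage gate (all thresholds configurable).

## Pipelines

Single-end: MEM seeds → per-seed mapping region (the implied full-read
placement widened by ⌈0.1·L⌉+10 bp, clamped to the contig) → seeds ranked
by their region's Smith–Waterman score, deduplicated per (region, strand)
→ top 20 extended with traceback until 10 qualified alignments are found
→ if none qualified, the best local alignment becomes a variable-length
seed for one semi-global attempt → if still nothing, the read is
re-seeded once with k-mer tiles (merged with the MEMs) and the cascade
repeats → otherwise unaligned. Reported alignments are ranked by score,
then edit distance, then leftmost coordinate; the first is primary, the
rest secondary.

Paired-end: both ends are seeded and ranked as above; seeds with score
≥ 30 are paired under the orientation and insert-window constraints
(mean ± 4σ) into a max-heap keyed by w = (q1+q2)/(m·(L1+L2)). While the
heap is empty and an end remains un-reseeded, the end with fewer
high-quality seeds is k-mer re-seeded, its seed list merged and
re-ranked. Popped pairs are extended end-wise (local with semi-global
fallback); qualified pairs are ranked by recomputed weight then
edit-distance sum. If no pair forms, mate rescuing anchors on single-end
alignments with MAPQ ≥ 20 (best anchors first, bounded by 100) and
DP-aligns the mate inside the implied window; reads that remain unpaired
are reported through their best single-end alignments.

Insert-size estimation aligns a sample of pairs single-end and keeps
pairs where both ends have a unique qualified alignment in the proper
orientation on one contig; outliers beyond 3×IQR are discarded before
taking mean and standard deviation. At least 100 usable pairs are
required, otherwise the caller must supply the distribution.

## MAPQ

The tool's mapping quality is a score-gap rule over the ranked placements
of a read: ambiguous co-optimal placements → 0; a unique alignment with
no runner-up → 60; otherwise round(60·(s₁−s₂)/s₁) clamped to [0, 60].
All reported alignments of one read carry the primary's MAPQ. This is a
deliberately simple, monotone surrogate for a full posterior computation;
its ROC behaviour is evaluated but not calibrated to PHRED error
probabilities.

## Color space

Colors encode di-base transitions (the XOR of 2-bit base codes; any pair
touching `N` gives `.`). The genome is color-encoded per contig and the
standard pipelines run on color strings; the reverse-strand transform in
color space is plain reversal. The primer base and its adjacent color are
stripped before seeding (SOLiD convention), leaving L−1 transition colors
for an L-base read. A qualified color alignment is translated to bases by
a 4-state-per-position dynamic program: a transition inconsistent with
its observed color costs 1 (missing colors are free), emitting a base
different from the aligned reference base costs 1, with ties resolved
toward the reference base then alphabetically. With these costs an
isolated color error resolves to a single color correction instead of
cascading through every downstream base (verified against exhaustive
search over all base strings at small L). The translated read is then
re-aligned in base space in the same mode as its color parent. Base
qualities for translated reads are the minimum of the two adjacent color
qualities. Mate pairs are FF-oriented by default.

## Simulator and evaluator

The simulator draws i.i.d. genomes at a chosen GC, uniform fragment loci,
normal insert sizes, random fragment strands, and per-base (or per-color)
substitution errors; truth (contig, leftmost forward-strand position,
strand) is recorded per end before errors are injected. An optional
per-read deletion mode exercises the semi-global rescue path. It does
**not** model coverage or GC bias, position-dependent quality decay,
sequencing indels, adapter contamination, or genuine genomic repeats —
so passing benchmarks on these data show the pipeline's behaviour under
idealized error processes on repeat-poor sequence, not performance on
real libraries or real genomes.

The evaluator scores an alignment correct when it lands on the true
contig and strand within 10 bp of the true leftmost position (clipped
start; opposite-strand hits are incorrect). Sensitivity = aligned/total;
recall is computed both over all reported alignments and over the first
occurrence per read. The TPR curve is monotone in the MAPQ threshold by
construction; the FPR, a ratio of two threshold-dependent counts, is not
mathematically guaranteed monotone and is only bounds-checked.

## Defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| `min_mem_len` | clamp(⌈log₄ n⌉+3, 13, 17) | n = genome length; 15 at 10 Mb |
| `k` (tile length) | 13 | 7 tiles per 100-bp read and strand |
| `max_occ` | 1000 | per seed pattern, suffix-array order |
| match / mismatch / gap | +1 / −3 / −5−2L | mismatch and gaps outweigh a match |
| local / global identity | 90% / 65% | percent of aligned read bases |
| aligned fraction | 0.80 | non-soft-clipped read bases / read length |
| seed score floor (PE) | 30 | scaled by the match score if m ≠ 1 |
| insert window | mean ± 4σ | configurable `--insert-nsd` |
| rescue MAPQ gate | 20 | anchors below it do not rescue |
| top seeds / extensions | 100 / 20 | rescue anchors; seeds extended per stage |
| reported alignments | 10 | one primary + up to 9 secondary |

## Benchmark problem sizes

The packaged benchmarks (`scripts/acceptance.py`) use a 10-Mb
uniform-random genome with 12,500 simulated pairs (25,000 reads) per
error rate; the in-suite version (`tests/test_acceptance.py`) uses a
400-kb genome with 1,200 pairs. At these sizes the binomial sampling
noise on the reported percentages is a few hundredths to a tenth of a
point — small against the margins being tested. A repeat-free random
genome is an easier target than a real mammalian genome: published
full-scale figures are treated as lower bounds, never matched exactly.

## Known limitations

* The suffix-array builder and in-memory FM-index target desk-scale
  genomes (tens of Mb), not 3-Gb references; no succinct structures.
* Single gap-affine scoring scheme per run; no quality-aware scoring.
* No split/chimeric alignments; one insert-size population; FR and FF
  layouts only (no RF).
* SAM output only (no BAM/CRAM); SAM/BAM is not accepted as read input.
* The MAPQ rule is a surrogate; downstream tools needing calibrated
  error probabilities should recalibrate.
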