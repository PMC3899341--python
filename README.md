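# hybridaln

A sensitive short-read aligner for base-space (Illumina-like) and SOLiD
color-space reads, built around **hybrid seeding**: three complementary
seed types feed one seed-and-extend pipeline, so reads that defeat any
single seeding strategy still find their locus.

* **MEM seeds** — maximal exact matches between read and genome, found by
  backward search on a BWT/FM-index of the reference (both strands).
* **Exact-match k-mer seeds** — the read's non-overlapping k-mer tiles
  (default k = 13), used to re-seed reads whose MEMs all fail; at 6% base
  error a read of 100 bp still carries an error-free tile with high
  probability even when no long exact match survives.
* **Variable-length seeds** — a read's best *local* alignment, recycled as
  the anchor for a *semi-global* re-alignment. Long mismatch runs and gaps
  depress Smith–Waterman scores below the local acceptance bar
  (identity ≥ 90%, aligned fraction ≥ 0.8); re-aligning the whole read
  end-to-end against the recentred region under a laxer identity bar
  (≥ 65%) recovers those placements.

For paired-end data the aligner adds three techniques. High-quality seeds
(local score q ≥ 30) from the two ends are enumerated as candidate pairs,
filtered by orientation (FR for Illumina, FF for SOLiD mate pairs) and the
insert-size window, and ranked on a max-heap by the pair weight

    w = (q1 + q2) / (m · (|S1| + |S2|))

where q_i is end i's optimal local alignment score against its candidate
region and m the match score — w = 1 means two perfect ends. Extended
**alignment pairs** are re-ranked by recomputed weight, ties broken by the
smaller edit-distance sum. When seed pairing fails, **read-mate rescuing**
takes a confident alignment of one end (MAPQ ≥ 20) and aligns the mate by
dynamic programming inside the window the insert-size distribution
implies. Color-space reads run the same pipelines on the color-encoded
genome; qualified color alignments are translated to nucleotides by a
4-state dynamic program guided by the aligned reference bases, then
re-aligned in base space.

The package also ships a simulator (random genomes; Illumina-like PE reads
with substitution errors and N(μ, σ) inserts; SOLiD-like color mate
pairs) and an evaluator for the standard benchmark metrics: sensitivity
(aligned/total), recall (an alignment within 10 bp of the true locus,
over all reported alignments or the first occurrence only), and a
MAPQ-ordered TPR/FPR curve.

## Worked example

```sh
hybridaln simulate -o demo --length 1000000 --n-pairs 2000 \
    --err-rate 0.06 --insert-mean 500 --insert-sd 50 --seed 42
hybridaln index -r demo.fa -o demo.idx
hybridaln align -r demo.idx -q demo_1.fq -Q demo_2.fq -o demo.sam
hybridaln evaluate -s demo.sam -t demo.truth.tsv
```

On this 1-Mb genome with 2,000 read pairs at 6% base error the run prints

```
estimated insert size: 497.3 +/- 50.9
{
  "n_reads": 4000,
  "n_aligned": 4000,
  "sensitivity": 100.0,
  "recall_all": 99.2,
  "recall_first": 99.2
}
```

All 4,000 reads received an alignment (the pipeline auto-estimated the
insert distribution from uniquely aligned sample pairs, close to the
simulated N(500, 50)); 99.2% landed within 10 bp of their true locus —
the remainder are high-error reads whose best-scoring placement is a
near-repeat elsewhere.

The same operations are available as library calls (`build_index`,
`align_single`, `align_pair`, `align_color_read`, `simulate_pe_reads`,
`evaluate`, …) returning plain dataclasses.

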