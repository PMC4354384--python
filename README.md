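# rdprep

Read preparation and GC-corrected read-depth signals for copy-number
variation (CNV) analysis.

Read-depth (RD) CNV methods count aligned reads in fixed, non-overlapping
genomic windows: under uniform sequencing the count in a window is
Poisson with mean proportional to the local copy number, so duplicated
regions stand out as persistently high depth and deletions as low depth.
That inference is only as good as the two preparatory stages feeding it,
which most CNV callers leave to ad-hoc tool chains. `rdprep` implements
them as one library + CLI:

* **Read cleanup** — Illumina quality-encoding detection (offsets 33/64,
  Solexa scores from −5) and decoding; removal of reads whose share of
  low-quality bases (Phred < threshold) exceeds an allowance; masking of
  low-quality bases with `N`; minimal 3′ adapter trimming.
* **Alignment-free duplicate removal** — PCR duplicates inflate window
  counts and fake gains. Reads are clustered by identical length-*k*
  prefix using base-5 integer keys (A=0, C=1, G=2, T=3, N=4; injective up
  to *k* = 27 in 64 bits since 5²⁷ < 2⁶⁴), then suffixes are compared in
  19-digit decimal chunk codes whose numeric difference localizes the
  leftmost mismatch by its order of magnitude; each cluster is greedily
  collapsed onto consensus representatives allowing up to *m* suffix
  mismatches (no indels — Illumina's indel rate is negligible while its
  substitution rate grows with base position, which is why a clean prefix
  is a sound cluster key).
* **Alignment post-filtering** — drop unmapped/low-MAPQ records, then
  resolve multi-mapped reads by unique-best or seeded random-best
  selection.
* **RD signal** — per-window GC percentage from the reference, raw RD by
  read-center window assignment, and GC correction

  RD′ᵂᵢ = (R̄D / R̄D_GCᵂᵢ) · RDᵂᵢ

  where R̄D is the mean raw RD over valid windows and R̄D_GCᵂᵢ the mean
  over windows sharing window *i*'s GC bin — after which every GC bin
  averages to the global mean.
* **Synthetic data** — seeded generators for GC-structured references,
  error-bearing libraries with exact low-quality quotas and adapter
  contamination, bounded-divergence duplicate injection, and an
  ideal-aligner SAM — so every stage ships with its own ground truth.

CNV segmentation and copy-number estimation (the downstream half of the
pipeline) are out of scope, as is running an aligner: the pipeline
consumes any aligner's SAM between its read side and alignment side.

## Worked example

Plant a known 30 % of near-duplicate reads (identical first 25 bp, one
substitution in the suffix) and remove them without any alignment
(`examples/03_duplicate_removal.py`):

```text
library: 42857 reads, 12857 constructed duplicates (30.0%)
allowing 1 suffix mismatch(es): removed 12888 reads (30.07%) across 29283 prefix clusters
allowing 0 suffix mismatch(es): removed 12 reads (0.03%) across 29283 prefix clusters
with 1 mismatch every planted copy collapses onto its source; with 0 the copies' single suffix error protects them
```

At *m* = 1 every planted copy collapses onto its source (the 31 extra
removals are natural duplicates: reads that happened to be sampled from
the same position with few errors); at *m* = 0 the copies' single suffix
error protects them, so essentially nothing is removed. The other
examples cover quality filtering/masking (`01`), adapter trimming (`02`),
SAM filtering (`04`), the GC-corrected RD track (`05`) and the composed
pipeline (`06`); each prints the numbers it computes and what they mean.

The same stages are available from the shell:

```sh
rdprep filter in.fastq out.fastq --min-qual 20 --min-good-pct 90
rdprep dedup in.fastq out.fastq -D 1 -p 25
rdprep samfilter in.sam out.sam --min-mapq 10 --multimap random --seed 7
rdprep rdsignal ref.fa out.sam track.tsv --window 100
rdprep pipeline --config pipeline.yaml
```

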