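# Methods

This note records the models implemented by `rdprep`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic generators do and do not emulate.

## Quality model

FASTQ quality characters are ASCII codes; the decoded score is
`ascii - offset` with the offset fixed by the Illumina pipeline version
(64 for Solexa/1.0 and 1.3–1.7, 33 from 1.8). The legal ranges overlap
above ASCII 64, so detection uses the only available discriminator, the
minimum code over a sample (first 10,000 reads by default): a code below
59 forces offset 33; 59–63 forces Solexa; otherwise the file is taken as
illumina-1.3. A file written with offset 33 whose qualities never dip
below ASCII 64 is genuinely ambiguous and will be classified as 1.3;
the CLI `--encoding` flag overrides detection for such files. Solexa
scores are used as plain offset-64 integers (no odds-to-Phred
transformation) and compared directly against the user's threshold.

A base is *low quality* when its score is strictly below the threshold
(default 20). A read is removed when its low-quality percentage strictly
exceeds `100 - min_good_pct` (default allowance 10 %): a read exactly at
the allowance is kept. Percentages run over the full read length,
including `N` bases, which carry their own scores. In paired mode a pair
is dropped when either mate fails, keeping mate files synchronized.
Masking rewrites sub-threshold bases as `N` and nothing else, so it is
idempotent and commutes with the filter.

## Duplicate removal

The algorithm assumes substitution-only divergence between duplicates
(no indels) with errors concentrated toward the 3′ end, which is the
Illumina error profile; the 5′ prefix is therefore the cluster key.

Two integer encodings over the alphabet A=0, C=1, G=2, T=3, N=4 drive
it, both bounded by the unsigned 64-bit range:

* prefix keys are base-5 positional values — injective and strictly
  order-preserving up to k = 27 (5²⁷ < 2⁶⁴ < 5²⁸);
* suffix chunks are the same digits concatenated in decimal — any 19
  digits fit (10¹⁹ < 2⁶⁴ < 10²⁰).

The decimal form exists for mismatch localization: with digits ≤ 4 the
leading disagreement at place p contributes at least 10^p to the code
difference while the tail contributes under 0.45·10^p. The digit count
of |Δ| therefore pins the leftmost mismatch to within one position; the
read-off is one too far right exactly when the leading digits differ by
1 and the tail opposes (e.g. digit strings `10` vs `04`, Δ = 6), so the
implementation confirms against the digit one place left, making the
locator exact. Counting proceeds per chunk: locate, count, truncate both
codes below the mismatch (`mod 10^p`), repeat; abort as soon as the
count exceeds the allowance m. The result equals the Hamming distance
whenever that distance is ≤ m.

Clustering sorts (key, original index) pairs — stable, so ties keep
input order — and takes maximal equal-key runs. Collapse is greedy: the
lowest-index remaining member is the seed; equal-length members within m
suffix mismatches of the *seed* (never of the evolving consensus) are
condensed with it into a per-position majority consensus (ties →
seed's base; id and quality string from the seed), and the loop repeats
on the remainder. Reads shorter than k bypass deduplication and are
always written out; reads of unequal length are never duplicates.
Output order is ascending original seed index, making the stage
byte-deterministic. Greedy collapse is not provably monotone in m for
adversarial inputs; on the synthetic libraries tested, removal counts
are monotone, and the suite checks them on seeded instances only.

The whole library's key table is held in memory (two machine words per
read), which is comfortable for tens of millions of reads on ordinary
hardware. Paired-end duplicate marking is not supported.

## Adapter trimming

A minimal mismatch-only 3′ trimmer: the leftmost read suffix matching a
prefix of the adapter with overlap ≥ `min_overlap` (default 3) and
mismatch fraction ≤ `max_error_rate` (default 0.1) is removed; reads
left shorter than `min_length` are discarded. Adapter tails shorter than
the minimum overlap are undetectable by construction. Indel-tolerant or
multi-adapter trimming is deliberately out of scope; run a dedicated
trimmer upstream when needed.

## Alignment post-filtering

Unmapped records are dropped; mapped records pass an inclusive MAPQ
threshold. Multi-mapper resolution groups records by read name (first
seen order preserved), ranks by alignment score (`AS` tag) falling back
to MAPQ per record, and either refuses ties (`unique`) or picks one tied
best with `random.Random(seed)` (`random`), so output is a deterministic
function of input order and seed. Secondary/supplementary records
compete in their read's candidate set.

## RD signal and GC correction

Windows tile each chromosome half-open `[iL, (i+1)L)`; the last window
may be short. GC per window is `round(100·(G+C)/(A+C+G+T))` over non-N
bases, rounded half-up to integer bins; a window whose informative bases
cover less than half of *its own span* (so short terminal windows are
judged on their own length) is invalid: it keeps its raw count, is
excluded from all means, and is never rescaled. Alignments are assigned
by the center of their reference footprint (`floor((2·pos + span−1)/2)`
in 1-based coordinates) or by their start; output coordinates are
0-based half-open, converted at assignment.

The correction `RD′ = (R̄D / R̄D_GC) · RD` uses means over valid windows.
Consequences used as invariants: the count sum is conserved through
assignment; after correction every occupied GC bin's mean equals R̄D (to
1e−9 relative, pure floating error); zero-count windows stay zero; the
map is homogeneous of degree 1. Statistics run per chromosome by
default — appropriate when chromosomes may differ in ploidy — with a
genome-wide switch for small or homogeneous references where bins would
otherwise be thin.

## Synthetic generators

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; reruns are bit-identical.

* **Reference**: bases drawn independently with a per-region GC
  fraction; no repeats, so distinct-origin reads essentially never share
  a 25 bp prefix.
* **Library**: reads sampled uniformly (length-weighted across
  chromosomes). Per-base substitution probability
  `p(i) = A·exp(shape·i/read_len)` with shape 3 and A fixed so the mean
  equals the configured 2 % — an exponential-decay-style curve rising
  toward the 3′ end; the exact shape constant is this package's choice.
  Fragment lengths are Normal(150, 50) (own choice; ≈16 % of 100 bp
  reads contaminated); a fragment shorter than the read puts the adapter
  (then random bases) at its 3′ end and erases errors there.
* **Quality quotas are exact, not expected**: the generator first
  assigns each designated low-quality read the minimum failing count
  (11 of 100 at the default rule), then distributes the remaining base
  budget over passing reads by multivariate hypergeometric draws capped
  at the passing maximum (10), raising a config error when the quotas
  are jointly infeasible. Error positions are preferentially the
  low-scored ones. Low scores are uniform on [0, 20), high on [31, 40],
  written Phred+33.
* **Duplicates**: copies form the configured fraction of the *final*
  library (`n_dup = f/(1−f)·n_src`); sources are drawn without
  replacement when possible so every copy is within the mismatch
  allowance of its cluster seed; each copy matches its source over the
  protected prefix (25 bp) and carries 1..max (default exactly 1) suffix
  substitutions — bounded divergence, not Binomial error, so that a
  1-mismatch deduplication recovers the constructed fraction exactly and
  a 0-mismatch run removes none of the copies. The combined library is
  shuffled.
* **Ideal SAM**: `round(coverage·len/read_len)` reads per chromosome,
  uniform starts, one perfect full-length primary record each (MAPQ 60).
  Window counts are then Poisson-like with mean `coverage·L/read_len`;
  the first/last window of a chromosome is undercounted because read
  centers cannot fall near the edges, so dispersion checks use interior
  windows.

What passing tests on these libraries does *not* show: real data have
non-uniform coverage, repeat-induced prefix collisions, indels, optical
duplicate structure and quality-score correlations none of which the
generators emulate. The generators validate the machinery and its exact
bookkeeping, not caller performance on real genomes.

## Problem sizes and tolerances

The shipped suite runs the quality/dedup experiments at 100,000 reads of
100 bp over a 1 Mb reference and the RD suite at 30x over 1 Mb with
100 bp windows — sizes chosen so the full suite completes in well under
a minute per experiment while keeping binomial fluctuations far inside
the asserted bands. Exact-quota assertions use exact equality (the
generator enforces the quota, not its expectation); the GC bin-mean
property is asserted at 1e−9 relative; the Poisson dispersion band is
[0.8, 1.2] on ~10,000 interior windows.

## Known limitations

* Duplicate removal is single-end only.
* Encoding detection cannot distinguish offset-33 from offset-64 files
  whose codes never drop below ASCII 64 (inherent FASTQ ambiguity).
* The pipeline stages materialize each library in memory; at the
  intended desk scale (≤ tens of millions of short reads) this is the
  simpler and faster choice.
* The trimmer is mismatch-only; indel-bearing adapters escape it.
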