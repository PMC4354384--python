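"""Filter low-quality reads and mask low-quality bases.

Builds a small synthetic library whose quality structure is known exactly
(3% of bases and 9% of reads below Phred 20), then applies the standard
read-depth preprocessing rule: drop a read when more than 10% of its
bases score below 20, and mask surviving low-quality bases with N.
"""

from rdprep import (
    FilterPolicy,
    SimConfig,
    filter_low_quality,
    mask_low_quality,
    quality_report,
    simulate_reads_s1,
    simulate_reference,
)

ref, _ = simulate_reference(n_chroms=1, lengths=[200_000], gc_profile=0.45, seed=1)
reads, truth = simulate_reads_s1(ref, SimConfig(seed=1, n_reads=20_000))

policy = FilterPolicy(qual_threshold=20, min_good_pct=90.0)
report = quality_report(reads, policy)
print(f"library: {report.n_reads} reads, {report.n_bases} bases")
print(f"low-quality bases: {report.pct_lowq_bases:.2f}%  (generator target 3%)")
print(f"low-quality reads: {report.pct_lowq_reads:.2f}%  (generator target 9%)")

result = filter_low_quality(reads, policy)
print(f"filter removed {result.removed} reads = {result.pct_removed:.2f}% "
      "(every read whose low-quality share exceeds 10%)")

masked = list(mask_low_quality(result.kept, 20))
n_masked = sum(b == "N" for r in masked for b in r.seq)
print(f"masking turned {n_masked} surviving low-quality bases into N; "
      "window-level GC and depth statistics now ignore them")
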