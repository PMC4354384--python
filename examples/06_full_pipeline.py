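"""Run the composed preprocessing pipeline from a config.

Simulates every input, then executes filter -> dedup on the read side and
samfilter -> rdsignal on the alignment side, producing the GC-corrected
read-depth track and a machine-readable run report.  (Alignment itself is
an explicit gap: any aligner's SAM slots in between the two sides.)
"""

import json
from pathlib import Path
import tempfile

from rdprep import PipelineConfig, SimConfig, run_pipeline, write_fastq
from rdprep.simulate import ideal_alignment_sam, simulate_reads_s1, simulate_reference

workdir = Path(tempfile.mkdtemp())
ref, _ = simulate_reference(1, [200_000], 0.45, seed=5, out_fasta=workdir / "ref.fa")
reads, _ = simulate_reads_s1(ref, SimConfig(seed=5, n_reads=10_000))
write_fastq(reads, workdir / "reads.fastq")
ideal_alignment_sam(ref, 10, 100, 5, workdir / "ideal.sam")

config = PipelineConfig(
    stages=[
        {"stage": "filter", "input": str(workdir / "reads.fastq"),
         "min_qual": 20, "min_good_pct": 90},
        {"stage": "dedup", "prefix_len": 25, "max_mismatches": 1},
        {"stage": "samfilter", "input": str(workdir / "ideal.sam"),
         "min_mapq": 10, "multimap": "random"},
        {"stage": "rdsignal", "reference": str(workdir / "ref.fa"), "window": 100},
    ],
    seed=5,
    outdir=workdir / "out",
)
report = run_pipeline(config)
for stage in report["stages"]:
    print(f"{stage['stage']:<10} {stage['counts']}")
print(f"outputs in {config.outdir}: "
      f"{sorted(p.name for p in config.outdir.iterdir())}")
print("rd_track.tsv holds chrom/start/end/gc_pct/raw_rd/corrected_rd/valid "
      "per window; run_report.json records parameters, seed and counts")
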