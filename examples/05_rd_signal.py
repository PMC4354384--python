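"""Build a GC-corrected windowed read-depth signal.

A reference with a GC-poor and a GC-rich half is covered at 30x by an
ideal aligner (unique, error-free placements).  The raw per-window depth
is Poisson-like around coverage * window / read_len = 30; the GC
correction RD' = (RDbar / RDbar_GC) * RD flattens any depth-vs-GC trend
so that every GC bin averages to the global mean.
"""

from pathlib import Path
import tempfile

from rdprep import gc_correct, gc_signal, grid_from_reference, make_track, raw_rd
from rdprep.alignfilter import read_sam
from rdprep.simulate import ideal_alignment_sam, simulate_reference

workdir = Path(tempfile.mkdtemp())
ref, _ = simulate_reference(
    1, [1_000_000], [[(500_000, 0.35), (500_000, 0.55)]], seed=4,
    out_fasta=workdir / "ref.fa",
)
sam = workdir / "ideal.sam"
n = ideal_alignment_sam(ref, coverage=30, read_len=100, seed=4, out_sam=sam)

L = 100
grid = grid_from_reference(ref, L)
gc = gc_signal(ref, L)
_, records = read_sam(sam)
counts, skipped = raw_rd(records, grid, rule="center")
track = gc_correct(make_track(grid, gc, counts))

valid = track[track["valid"]]
print(f"{n} alignments -> {len(track)} windows of {L} bp "
      f"(sum of window counts = {int(track['raw_rd'].sum())}, conservation)")
print(f"mean raw depth {valid['raw_rd'].mean():.2f} "
      f"(expected coverage*L/read_len = 30), "
      f"variance/mean {valid['raw_rd'].var(ddof=1) / valid['raw_rd'].mean():.3f} "
      "(Poisson ~ 1)")
bin_means = valid.groupby("gc_pct")["corrected_rd"].mean()
print(f"after GC correction every occupied GC bin (n={len(bin_means)}) has mean "
      f"{bin_means.min():.6f}..{bin_means.max():.6f} — all equal to the "
      f"global mean {valid['raw_rd'].mean():.6f}")
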