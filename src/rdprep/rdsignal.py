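"""Windowed read-depth (RD) signal construction and GC-bias correction.

Each chromosome is tiled with non-overlapping windows of a user-chosen
length ``L`` (the last window may be short).  The raw RD of a window is
the number of filtered alignments assigned to it — by default via the
center of the alignment's reference footprint.  Because sequencing depth
varies systematically with local GC content, the raw signal is rescaled
per GC percentage bin:

    RD'_wi = (RDbar / RDbar_GCwi) * RD_wi

where ``RDbar`` is the mean raw RD over valid windows and ``RDbar_GCwi``
the mean over valid windows sharing window ``i``'s GC bin.  After
correction every occupied GC bin has mean corrected RD equal to
``RDbar`` — the flattening the downstream segmentation relies on.
Averages run per chromosome by default; a genome-wide switch is offered
because the right span depends on the experiment.

Windows with fewer than half their span in informative (non-N) bases are
flagged invalid: they keep their raw value, are excluded from all means,
and are left uncorrected.

Tracks are plain :class:`pandas.DataFrame` objects with BED-style
0-based half-open coordinates (SAM input is 1-based; the conversion
happens inside :func:`assign_window`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignfilter import AlignmentRecord
from .fastq import PathLike, _open_text

TRACK_COLUMNS = ["chrom", "start", "end", "gc_pct", "raw_rd", "corrected_rd", "valid"]

#: GC-bin sentinel for windows with too few informative bases.
INVALID_GC = -1

Reference = Union[PathLike, Mapping[str, str]]


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of each chromosome with length-L windows."""

    chrom_lengths: Tuple[Tuple[str, int], ...]
    window_len: int

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int], window_len: int) -> "WindowGrid":
        if window_len < 1:
            raise ValueError("window_len must be >= 1")
        return cls(tuple(lengths.items()), window_len)

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self.chrom_lengths)

    def n_windows(self, chrom: str) -> int:
        return math.ceil(self.lengths[chrom] / self.window_len)


def _iter_reference(reference: Reference) -> Iterable[Tuple[str, str]]:
    if isinstance(reference, Mapping):
        yield from reference.items()
    else:
        for rec in SeqIO.parse(str(reference), "fasta"):
            yield rec.id, str(rec.seq).upper()


def grid_from_reference(reference: Reference, window_len: int) -> WindowGrid:
    lengths = {name: len(seq) for name, seq in _iter_reference(reference)}
    return WindowGrid.from_lengths(lengths, window_len)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def gc_signal(
    reference: Reference,
    window_len: int,
    min_informative_frac: float = 0.5,
) -> Dict[str, np.ndarray]:
    """Per-window GC percentage for every sequence in ``reference``.

    ``gc_pct = round(100 * (G+C) / (A+C+G+T))`` over the window
    (half-up rounding); windows whose informative (non-N) bases cover
    less than ``min_informative_frac`` of their span get :data:`INVALID_GC`.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    out: Dict[str, np.ndarray] = {}
    for name, seq in _iter_reference(reference):
        n = len(seq)
        if n == 0:
            out[name] = np.empty(0, dtype=int)
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_info = is_gc | (arr == ord("A")) | (arr == ord("T"))
        starts = np.arange(0, n, window_len)
        gc_counts = np.add.reduceat(is_gc, starts)
        info_counts = np.add.reduceat(is_info, starts)
        spans = np.minimum(starts + window_len, n) - starts
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = _round_half_up(100.0 * gc_counts / info_counts)
        invalid = info_counts < min_informative_frac * spans
        pct[invalid | (info_counts == 0)] = INVALID_GC
        out[name] = pct
    return out


def assign_window(
    aln: AlignmentRecord, grid: WindowGrid, rule: str = "center"
) -> int:
    """Window index of a mapped alignment under the ``center`` or ``start`` rule.

    Center rule: the 1-based midpoint of the reference footprint,
    ``floor((pos + pos + span - 1) / 2)``, converted to 0-based and
    divided by the window length.
    """
    L = grid.window_len
    if rule == "center":
        center = (aln.pos + aln.pos + aln.aln_span - 1) // 2  # 1-based
        return (center - 1) // L
    if rule == "start":
        return (aln.pos - 1) // L
    raise ValueError(f"unknown assignment rule {rule!r}")


def raw_rd(
    alignments: Iterable[AlignmentRecord],
    grid: WindowGrid,
    rule: str = "center",
) -> Tuple[Dict[str, np.ndarray], int]:
    """Count alignments per window; returns ``(counts, skipped)``.

    ``skipped`` counts alignments on references absent from the grid (or
    with out-of-range window indices).  Conservation holds by
    construction: the counts sum to the number of assigned alignments.
    """
    lengths = grid.lengths
    counts = {
        chrom: np.zeros(grid.n_windows(chrom), dtype=np.int64) for chrom in lengths
    }
    skipped = 0
    for aln in alignments:
        if not aln.mapped_flag or aln.refname not in counts:
            skipped += 1
            continue
        w = assign_window(aln, grid, rule)
        track = counts[aln.refname]
        if 0 <= w < len(track):
            track[w] += 1
        else:
            skipped += 1
    return counts, skipped


def make_track(
    grid: WindowGrid,
    gc: Mapping[str, np.ndarray],
    counts: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Assemble the per-window RD track (corrected_rd starts as NaN)."""
    frames = []
    for chrom, length in grid.chrom_lengths:
        n = grid.n_windows(chrom)
        starts = np.arange(n) * grid.window_len
        ends = np.minimum(starts + grid.window_len, length)
        gc_arr = np.asarray(gc[chrom]) if chrom in gc else np.full(n, INVALID_GC)
        cnt = np.asarray(counts[chrom]) if chrom in counts else np.zeros(n, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc_pct": gc_arr,
                    "raw_rd": cnt,
                    "corrected_rd": np.nan,
                    "valid": gc_arr != INVALID_GC,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRACK_COLUMNS]


@dataclass
class GCProfile:
    """Mean raw RD per scope and per (scope, GC bin) over valid windows.

    ``scope`` is a chromosome name, or ``"*"`` when statistics are pooled
    genome-wide.
    """

    means: Dict[str, float]
    bin_means: Dict[Tuple[str, int], float]
    per_chromosome: bool = True


def gc_profile(track: pd.DataFrame, per_chromosome: bool = True) -> GCProfile:
    """Compute RDbar and the per-GC-bin means from a track's valid windows."""
    valid = track[track["valid"]]
    if per_chromosome:
        means = valid.groupby("chrom")["raw_rd"].mean().to_dict()
        bins = valid.groupby(["chrom", "gc_pct"])["raw_rd"].mean()
        bin_means = {(c, int(g)): v for (c, g), v in bins.items()}
    else:
        mean = float(valid["raw_rd"].mean()) if len(valid) else float("nan")
        means = {"*": mean}
        bins = valid.groupby("gc_pct")["raw_rd"].mean()
        bin_means = {("*", int(g)): v for g, v in bins.items()}
    return GCProfile(means, bin_means, per_chromosome)


def gc_correct(
    track: pd.DataFrame, profile: Optional[GCProfile] = None, per_chromosome: bool = True
) -> pd.DataFrame:
    """GC-correct a raw RD track: ``RD' = (RDbar / RDbar_GC) * RD``.

    Valid windows are rescaled by their GC bin; zero-count windows stay
    zero; invalid windows keep their raw value uncorrected.  Returns a
    new DataFrame.
    """
    if profile is None:
        profile = gc_profile(track, per_chromosome=per_chromosome)
    out = track.copy()
    corrected = out["raw_rd"].astype(float).to_numpy()
    valid = out["valid"].to_numpy()
    chroms = out["chrom"].to_numpy()
    gcs = out["gc_pct"].to_numpy()
    raws = out["raw_rd"].to_numpy()
    for i in np.flatnonzero(valid):
        scope = chroms[i] if profile.per_chromosome else "*"
        bin_mean = profile.bin_means.get((scope, int(gcs[i])))
        if raws[i] == 0:
            corrected[i] = 0.0
            continue
        if bin_mean is None or bin_mean == 0:
            # a window's own count contributes to its bin, so a positive
            # count in a zero-mean bin means profile and track disagree
            raise AssertionError(
                f"window {i} (scope {scope}, GC {gcs[i]}) has raw RD {raws[i]} "
                "but its GC bin mean is zero or missing"
            )
        corrected[i] = profile.means[scope] / bin_mean * raws[i]
    out["corrected_rd"] = corrected
    return out


def write_track(track: pd.DataFrame, path: PathLike) -> None:
    """TSV export (0-based half-open coordinates; valid as 0/1)."""
    out = track.copy()
    out["valid"] = out["valid"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_track(path: PathLike) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t")
    track["valid"] = track["valid"].astype(bool)
    return track[TRACK_COLUMNS]


def write_bedgraph(
    track: pd.DataFrame, path: PathLike, column: str = "corrected_rd"
) -> None:
    """bedGraph export of one signal column, one line per window."""
    with _open_text(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{column}"\n')
        for row in track.itertuples(index=False):
            value = getattr(row, column)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{value:g}\n")
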