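"""Minimal 3'-adapter trimming.

A deliberately small, mismatch-only trimmer so the pipeline runs end to
end: it looks for the leftmost read suffix matching a prefix of the
adapter with at least ``min_overlap`` bases and a mismatch fraction of at
most ``max_error_rate`` (no indels), cuts sequence and quality there, and
discards reads left shorter than ``min_length``.  Users with read-through
pairs, 5' contamination or indel-tolerant needs should run a full
trimming tool upstream instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Tuple

from .fastq import ReadRecord

#: Illumina single-end adapter 1.
ILLUMINA_SE_ADAPTER_1 = "ACACTCTTTCCCTACACGACGCTGTTCCATCT"


@dataclass(frozen=True)
class AdapterSpec:
    adapter: str = ILLUMINA_SE_ADAPTER_1
    max_error_rate: float = 0.1
    min_overlap: int = 3
    min_length: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if not self.adapter:
            raise ValueError("adapter sequence must be non-empty")


def _match_at(seq: str, adapter: str, start: int, max_errors: int) -> bool:
    errors = 0
    overlap = min(len(seq) - start, len(adapter))
    for i in range(overlap):
        if seq[start + i] != adapter[i]:
            errors += 1
            if errors > max_errors:
                return False
    return True


def trim_3prime(read: ReadRecord, spec: AdapterSpec) -> Optional[ReadRecord]:
    """Trim the adapter from the 3' end; ``None`` means the read is discarded.

    Among candidate start positions meeting the error bound, the leftmost
    (longest trim) wins.  An untouched read is returned unchanged.
    """
    seq = read.seq
    for start in range(0, len(seq) - spec.min_overlap + 1):
        overlap = min(len(seq) - start, len(spec.adapter))
        max_errors = int(spec.max_error_rate * overlap)
        if _match_at(seq, spec.adapter, start, max_errors):
            if start < spec.min_length:
                return None
            return replace(
                read,
                seq=seq[:start],
                qual=read.qual[:start],
                scores=read.scores[:start] if read.scores is not None else None,
            )
    if len(seq) < spec.min_length:
        return None
    return read


@dataclass
class TrimStats:
    total: int = 0
    trimmed: int = 0
    discarded: int = 0


def trim_library(
    reads: Iterable[ReadRecord], spec: AdapterSpec
) -> Tuple[List[ReadRecord], TrimStats]:
    """Trim every read; discarded reads are dropped from the output."""
    stats = TrimStats()
    out: List[ReadRecord] = []
    for read in reads:
        stats.total += 1
        trimmed = trim_3prime(read, spec)
        if trimmed is None:
            stats.discarded += 1
        else:
            if len(trimmed) != len(read):
                stats.trimmed += 1
            out.append(trimmed)
    return out, stats
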