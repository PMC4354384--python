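"""SAM alignment post-filtering: MAPQ threshold and multi-mapper resolution.

Read-depth analysis needs at most one confidently placed alignment per
read.  Two passes provide that: :func:`filter_mapq` drops unmapped
records and records below an inclusive MAPQ threshold, and
:func:`resolve_multimappers` reduces each read's candidate set to its
best-scoring alignments, emitting the single best (``unique`` strategy:
nothing on a tie) or one tied best chosen by a seeded RNG (``random``
strategy, reproducible for a fixed input order and seed).

Records flow through :class:`AlignmentRecord`, a minimal view of a SAM
row; when reading from a SAM file the underlying :mod:`pysam` segment is
carried along so filtered files can be rewritten without loss.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Any, Dict, Iterable, List, Optional, Tuple

import pysam

from .fastq import PathLike

logger = logging.getLogger(__name__)


@dataclass
class AlignmentRecord:
    """Minimal SAM-derived record; ``pos`` is the 1-based leftmost coordinate."""

    qname: str
    refname: Optional[str]
    pos: int
    mapq: int
    aln_span: int
    score: Optional[int] = None
    mapped_flag: bool = True
    source: Any = field(default=None, repr=False, compare=False)

    @classmethod
    def from_pysam(cls, seg: "pysam.AlignedSegment") -> "AlignmentRecord":
        if seg.is_unmapped:
            return cls(seg.query_name or "", None, 0, seg.mapping_quality, 0,
                       mapped_flag=False, source=seg)
        score = seg.get_tag("AS") if seg.has_tag("AS") else None
        return cls(
            qname=seg.query_name or "",
            refname=seg.reference_name,
            pos=seg.reference_start + 1,
            mapq=seg.mapping_quality,
            aln_span=seg.reference_length or 0,
            score=score,
            mapped_flag=True,
            source=seg,
        )


def read_sam(path: PathLike) -> Tuple[Any, List[AlignmentRecord]]:
    """Read a SAM/BAM file into (header, records)."""
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header = fh.header
        for seg in fh:
            records.append(AlignmentRecord.from_pysam(seg))
    return header, records


def write_sam(header: Any, records: Iterable[AlignmentRecord], path: PathLike) -> int:
    """Write records (which must carry pysam sources) back out as SAM text."""
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for record in records:
            if record.source is None:
                raise ValueError(
                    f"record {record.qname!r} has no underlying SAM segment"
                )
            out.write(record.source)
            n += 1
    return n


@dataclass
class MapqFilterStats:
    kept: int = 0
    unmapped: int = 0
    below_threshold: int = 0
    malformed: int = 0


def filter_mapq(
    alignments: Iterable[AlignmentRecord], min_mapq: int
) -> Tuple[List[AlignmentRecord], MapqFilterStats]:
    """Keep mapped records with ``mapq >= min_mapq`` (inclusive), in order."""
    stats = MapqFilterStats()
    kept: List[AlignmentRecord] = []
    for record in alignments:
        if not record.mapped_flag:
            stats.unmapped += 1
            continue
        if record.pos < 1 or record.aln_span < 1:
            stats.malformed += 1
            logger.warning(
                "skipping malformed mapped record %r (pos=%d, span=%d)",
                record.qname, record.pos, record.aln_span,
            )
            continue
        if record.mapq >= min_mapq:
            kept.append(record)
            stats.kept += 1
        else:
            stats.below_threshold += 1
    return kept, stats


def _best_key(record: AlignmentRecord) -> int:
    return record.score if record.score is not None else record.mapq


def resolve_multimappers(
    alignments: Iterable[AlignmentRecord],
    strategy: str = "unique",
    seed: int = 0,
) -> List[AlignmentRecord]:
    """Emit at most one alignment per read.

    The best set of a read is the records maximizing the alignment score
    (falling back to MAPQ when no score is present).  ``unique`` emits
    the best record only when it is unambiguous; ``random`` picks one
    tied best uniformly with a generator seeded by ``seed``.  Output
    preserves the first-seen order of read names.
    """
    if strategy not in ("unique", "random"):
        raise ValueError(f"unknown multi-mapper strategy {strategy!r}")
    groups: Dict[str, List[AlignmentRecord]] = {}
    order: List[str] = []
    for record in alignments:
        if record.qname not in groups:
            groups[record.qname] = []
            order.append(record.qname)
        groups[record.qname].append(record)
    rng = random.Random(seed)
    out: List[AlignmentRecord] = []
    for qname in order:
        candidates = groups[qname]
        best = max(_best_key(r) for r in candidates)
        best_set = [r for r in candidates if _best_key(r) == best]
        if len(best_set) == 1:
            out.append(best_set[0])
        elif strategy == "random":
            out.append(best_set[rng.randrange(len(best_set))])
        # unique: ambiguous reads are dropped
    return out
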