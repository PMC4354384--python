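"""Quality-based read filtering and base masking.

A base is *low quality* when its decoded Phred score falls strictly below
a threshold.  A read is removed when the percentage of low-quality bases
strictly exceeds the allowance ``100 - min_good_pct`` (a read exactly at
the allowed percentage is kept).  Masking replaces low-quality bases with
``N`` while leaving identifiers, lengths and quality strings untouched,
so it is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, List, Tuple

from .fastq import ReadRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    """Low-quality read removal rule.

    ``qual_threshold``: bases scoring strictly below this are low quality.
    ``min_good_pct``: a read is kept iff its low-quality-base percentage
    does not exceed ``100 - min_good_pct``.
    """

    qual_threshold: int = 20
    min_good_pct: float = 90.0
    paired_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_good_pct <= 100.0:
            raise ValueError(f"min_good_pct must be in [0,100], got {self.min_good_pct}")

    @property
    def max_bad_pct(self) -> float:
        return 100.0 - self.min_good_pct


def _require_scores(record: ReadRecord) -> Tuple[int, ...]:
    if record.scores is None:
        raise ValueError(
            f"record '{record.id}' has no decoded quality scores; "
            "run decode_qualities first"
        )
    return record.scores


def low_quality_count(record: ReadRecord, qual_threshold: int) -> int:
    scores = _require_scores(record)
    return sum(1 for s in scores if s < qual_threshold)


def is_low_quality(record: ReadRecord, policy: FilterPolicy) -> bool:
    """True when the read violates ``policy`` (and should be removed)."""
    if len(record) == 0:
        logger.warning("record '%s' has zero length; removed", record.id)
        return True
    n_bad = low_quality_count(record, policy.qual_threshold)
    return 100.0 * n_bad / len(record) > policy.max_bad_pct


@dataclass
class FilterResult:
    kept: List[ReadRecord]
    removed: int
    total: int

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.removed / self.total if self.total else 0.0


def filter_low_quality(
    reads: Iterable[ReadRecord], policy: FilterPolicy
) -> FilterResult:
    """Drop reads violating ``policy``; order of the survivors is preserved."""
    kept: List[ReadRecord] = []
    total = 0
    for record in reads:
        total += 1
        if not is_low_quality(record, policy):
            kept.append(record)
    return FilterResult(kept, total - len(kept), total)


@dataclass
class PairFilterResult:
    kept: List[Tuple[ReadRecord, ReadRecord]]
    removed_pairs: int
    total_pairs: int

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.removed_pairs / self.total_pairs if self.total_pairs else 0.0


def filter_low_quality_pairs(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]], policy: FilterPolicy
) -> PairFilterResult:
    """Paired mode: a pair is removed when *either* mate violates the policy,
    keeping the two mate files synchronized."""
    kept: List[Tuple[ReadRecord, ReadRecord]] = []
    total = 0
    for r1, r2 in pairs:
        total += 1
        if not (is_low_quality(r1, policy) or is_low_quality(r2, policy)):
            kept.append((r1, r2))
    return PairFilterResult(kept, total - len(kept), total)


def mask_low_quality(
    reads: Iterable[ReadRecord], qual_threshold: int
) -> Iterator[ReadRecord]:
    """Replace bases scoring below ``qual_threshold`` with ``N``.

    Quality strings and scores are unchanged, so a masked ``N`` keeps its
    low score and a second pass is a no-op.
    """
    for record in reads:
        scores = _require_scores(record)
        if any(s < qual_threshold for s in scores):
            seq = "".join(
                "N" if s < qual_threshold else b for b, s in zip(record.seq, scores)
            )
            yield replace(record, seq=seq)
        else:
            yield record


@dataclass
class QualityReport:
    """Library-level totals mirroring the filter's arithmetic exactly."""

    n_reads: int
    n_bases: int
    n_lowq_bases: int
    n_lowq_reads: int

    @property
    def pct_lowq_bases(self) -> float:
        return 100.0 * self.n_lowq_bases / self.n_bases if self.n_bases else 0.0

    @property
    def pct_lowq_reads(self) -> float:
        return 100.0 * self.n_lowq_reads / self.n_reads if self.n_reads else 0.0


def quality_report(reads: Iterable[ReadRecord], policy: FilterPolicy) -> QualityReport:
    n_reads = n_bases = n_lowq_bases = n_lowq_reads = 0
    for record in reads:
        n_reads += 1
        n_bases += len(record)
        n_lowq_bases += low_quality_count(record, policy.qual_threshold)
        if is_low_quality(record, policy):
            n_lowq_reads += 1
    return QualityReport(n_reads, n_bases, n_lowq_bases, n_lowq_reads)
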