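"""Alignment-free removal of (near-)duplicate single-end reads.

PCR duplicates are near-identical copies of the same template.  On
Illumina data the substitution error rate grows with base position while
indels are vanishingly rare, so duplicates can be found without aligning:
reads sharing an identical length-``k`` prefix are clustered together as
duplicate candidates, and within a cluster suffixes are compared allowing
up to ``m`` mismatches (never indels).

Two integer encodings over the 5-symbol alphabet (A=0, C=1, G=2, T=3,
N=4) drive the method, both confined to unsigned 64-bit range:

* **cluster keys** are base-5 positional values of the prefix; since
  ``5**27 < 2**64 < 5**28`` prefixes up to **27** bases sort exactly and
  injectively;
* **suffix chunks** are the same digits concatenated in *decimal*; any
  string of up to **19** digits fits (``10**19 < 2**64``), and because
  every digit is <= 4 the order of magnitude of the difference of two
  chunk codes localizes their leftmost disagreeing position, giving a
  Hamming count that skips equal runs in O(1) each.

Each cluster is collapsed greedily: the first (lowest-index) remaining
read is the seed, every remaining read whose suffix is within ``m``
mismatches of the seed's suffix (and of equal length) is condensed with
it into a per-position majority consensus, and the loop repeats on the
remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from .fastq import PathLike, ReadRecord, read_fastq, write_fastq

logger = logging.getLogger(__name__)

_U64_MAX = 2**64 - 1

_DIGIT_TABLE = str.maketrans("ACGTN", "01234")


def _capacity(base: int) -> int:
    """Largest length L such that all base-``base`` strings of L digits
    take distinct values within unsigned 64-bit range."""
    length = 0
    while base ** (length + 1) - 1 <= _U64_MAX:
        length += 1
    return length


#: Longest prefix with injective base-5 keys in 64 bits (= 27).
MAX_PREFIX_LEN = _capacity(5)
#: Longest decimal digit-concatenation chunk guaranteed to fit (= 19).
MAX_CHUNK_LEN = _capacity(10)


class UnsupportedLengthError(ValueError):
    """Prefix/chunk length exceeds what a 64-bit code can hold."""


@dataclass(frozen=True)
class DedupPolicy:
    """Prefix length ``k``, allowed suffix mismatches ``m``, chunk length."""

    prefix_len: int = 25
    max_mismatches: int = 1
    chunk_len: int = MAX_CHUNK_LEN

    def __post_init__(self) -> None:
        if not 1 <= self.prefix_len <= MAX_PREFIX_LEN:
            raise UnsupportedLengthError(
                f"prefix_len must be in [1,{MAX_PREFIX_LEN}], got {self.prefix_len}"
            )
        if not 1 <= self.chunk_len <= MAX_CHUNK_LEN:
            raise UnsupportedLengthError(
                f"chunk_len must be in [1,{MAX_CHUNK_LEN}], got {self.chunk_len}"
            )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ChunkCode:
    """Decimal digit-concatenation code of a suffix chunk."""

    value: int
    chunk_len: int


@dataclass
class Cluster:
    """Reads sharing an identical k-prefix; members in ascending input order."""

    key: int
    members: List[int] = field(default_factory=list)


def encode_prefix(seq: str, k: int) -> int:
    """Base-5 positional value of ``seq[:k]``.

    Strictly order-preserving on lexicographic prefix order with
    A<C<G<T<N; injective for ``k <= 27``.
    """
    if k > MAX_PREFIX_LEN:
        raise UnsupportedLengthError(
            f"prefix length {k} exceeds the 64-bit base-5 limit {MAX_PREFIX_LEN}"
        )
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < prefix length {k}")
    return int(seq[:k].translate(_DIGIT_TABLE), 5)


def decode_prefix(value: int, k: int) -> str:
    """Inverse of :func:`encode_prefix` (testing aid)."""
    out = []
    for _ in range(k):
        value, d = divmod(value, 5)
        out.append("ACGTN"[d])
    return "".join(reversed(out))


def encode_chunk(sub: str) -> ChunkCode:
    """Decimal concatenation of the per-base digits of ``sub``."""
    if not 1 <= len(sub) <= MAX_CHUNK_LEN:
        raise UnsupportedLengthError(
            f"chunk length {len(sub)} outside [1,{MAX_CHUNK_LEN}]"
        )
    return ChunkCode(int(sub.translate(_DIGIT_TABLE), 10), len(sub))


def leftmost_mismatch(x: ChunkCode, y: ChunkCode) -> Optional[int]:
    """0-based position of the leftmost differing digit, or None if equal.

    The magnitude of ``|x - y|`` pins the position to within one place:
    with digits restricted to 0..4 the leading disagreement contributes
    at least ``10**p`` while the tail contributes under ``0.45 * 10**p``,
    so the digit count of the difference is either ``p + 1`` or (only
    when the leading digits differ by exactly 1 and the tail opposes)
    ``p``.  A single check of the adjacent digit resolves the ambiguity.
    """
    if x.chunk_len != y.chunk_len:
        raise ValueError(
            f"chunk length mismatch: {x.chunk_len} != {y.chunk_len}"
        )
    diff = x.value - y.value
    if diff == 0:
        return None
    c = x.chunk_len
    pos = c - len(str(abs(diff)))  # c - 1 - floor(log10 |diff|)
    if pos > 0:
        place = 10 ** (c - pos)  # one digit to the left
        if (x.value // place) % 10 != (y.value // place) % 10:
            pos -= 1
    return pos


def count_mismatches(a: str, b: str, limit: int, chunk_len: int = MAX_CHUNK_LEN) -> int:
    """Hamming distance of ``a`` and ``b``, early-stopped beyond ``limit``.

    Both strings are cut into ``chunk_len``-sized chunks (the final chunk
    may be shorter); each chunk pair is compared by repeatedly locating
    the leftmost mismatching digit from the code difference, counting it,
    truncating both codes below that position, and continuing.  Returns
    the exact Hamming distance when it is <= ``limit``; otherwise some
    value > ``limit``.
    """
    if len(a) != len(b):
        raise ValueError(
            f"cannot compare sequences of different length ({len(a)} vs {len(b)}); "
            "indels are not modelled"
        )
    mismatches = 0
    for start in range(0, len(a), chunk_len):
        x = encode_chunk(a[start : start + chunk_len])
        y = encode_chunk(b[start : start + chunk_len])
        c = x.chunk_len
        xv, yv = x.value, y.value
        while True:
            pos = leftmost_mismatch(ChunkCode(xv, c), ChunkCode(yv, c))
            if pos is None:
                break
            mismatches += 1
            if mismatches > limit:
                return mismatches
            keep = 10 ** (c - 1 - pos)  # drop digits at and left of pos
            xv %= keep
            yv %= keep
    return mismatches


def cluster_by_prefix(
    reads: Sequence[ReadRecord], k: int
) -> Tuple[List[Cluster], List[int]]:
    """Group reads by identical ``k``-prefix via a stable sort of their keys.

    Returns ``(clusters, short)`` where ``short`` holds the indices of
    reads shorter than ``k``, which bypass deduplication entirely.
    """
    keyed: List[Tuple[int, int]] = []
    short: List[int] = []
    for i, record in enumerate(reads):
        if len(record.seq) < k:
            short.append(i)
        else:
            keyed.append((encode_prefix(record.seq, k), i))
    keyed.sort()  # (key asc, original index asc)
    clusters: List[Cluster] = []
    for key, i in keyed:
        if clusters and clusters[-1].key == key:
            clusters[-1].members.append(i)
        else:
            clusters.append(Cluster(key, [i]))
    return clusters, short


def build_consensus(members: Sequence[ReadRecord]) -> ReadRecord:
    """Per-position majority base over equal-length ``members``.

    Ties resolve to the seed's (first member's) base; id and quality
    string are the seed's.
    """
    seed = members[0]
    if len(members) == 1:
        return seed
    seqs = [m.seq for m in members]
    out = []
    for pos, seed_base in enumerate(seed.seq):
        counts: dict = {}
        for s in seqs:
            b = s[pos]
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        winners = [b for b, n in counts.items() if n == best]
        out.append(seed_base if seed_base in winners or len(winners) > 1 else winners[0])
    return replace(seed, seq="".join(out), scores=seed.scores)


def collapse_cluster(
    cluster: Cluster, reads: Sequence[ReadRecord], policy: DedupPolicy
) -> Tuple[List[Tuple[int, ReadRecord]], int]:
    """Greedy condensation of one prefix cluster.

    Returns ``(representatives, removed)`` where each representative is
    ``(seed_index, record)``; ``removed`` counts the members condensed
    away.  Reads of unequal length are never duplicates of one another.
    """
    k = policy.prefix_len
    m = policy.max_mismatches
    remaining = list(cluster.members)
    representatives: List[Tuple[int, ReadRecord]] = []
    removed = 0
    while remaining:
        seed_i = remaining[0]
        seed = reads[seed_i]
        seed_suffix = seed.seq[k:]
        group = [seed]
        rest: List[int] = []
        for j in remaining[1:]:
            other = reads[j]
            if (
                len(other.seq) == len(seed.seq)
                and count_mismatches(seed_suffix, other.seq[k:], m, policy.chunk_len)
                <= m
            ):
                group.append(other)
            else:
                rest.append(j)
        representatives.append((seed_i, build_consensus(group)))
        removed += len(group) - 1
        remaining = rest
    return representatives, removed


@dataclass
class DedupStats:
    total: int
    clusters: int
    removed: int
    short_reads: int

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.removed / self.total if self.total else 0.0


def dedup_reads(
    reads: Sequence[ReadRecord], policy: DedupPolicy
) -> Tuple[List[ReadRecord], DedupStats]:
    """Deduplicate an in-memory single-end library.

    Output is every cluster representative plus the short-read
    passthroughs, ordered by ascending original (seed) index, so a given
    input and policy always reproduce the same output.
    """
    clusters, short = cluster_by_prefix(reads, policy.prefix_len)
    if short:
        logger.info(
            "%d read(s) shorter than the %d bp prefix bypass deduplication",
            len(short), policy.prefix_len,
        )
    out: List[Tuple[int, ReadRecord]] = [(i, reads[i]) for i in short]
    removed = 0
    for cluster in clusters:
        reps, n_removed = collapse_cluster(cluster, reads, policy)
        out.extend(reps)
        removed += n_removed
    out.sort(key=lambda pair: pair[0])
    stats = DedupStats(len(reads), len(clusters), removed, len(short))
    return [record for _, record in out], stats


def dedup_library(
    in_path: PathLike, out_path: PathLike, policy: DedupPolicy
) -> DedupStats:
    """File-to-file deduplication of a single-end FASTQ library."""
    reads = list(read_fastq(in_path))
    deduped, stats = dedup_reads(reads, policy)
    write_fastq(deduped, out_path)
    logger.info(
        "dedup: %d reads, %d clusters, %d removed (%.2f%%)",
        stats.total, stats.clusters, stats.removed, stats.pct_removed,
    )
    return stats
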