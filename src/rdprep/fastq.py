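"""Streaming FASTQ I/O with Illumina quality-encoding detection.

FASTQ stores one Phred quality character per base, but the ASCII offset
(and hence the decoded score) depends on the Illumina pipeline version:

* ``illumina-1.0`` (Solexa): scores -5..62, ASCII 59..126 (offset 64)
* ``illumina-1.3``: scores 0..62, ASCII 64..126 (offset 64)
* ``illumina-1.8``: scores 0..93, ASCII 33..126 (offset 33)

The ranges overlap above ASCII 64, so only the *minimum* ASCII code seen
in a file discriminates: anything below 59 can only be the offset-33
dialect, codes in 59..63 can only be Solexa, and a file whose codes never
dip below 64 is taken to be illumina-1.3.

Only the strict 4-line dialect is supported (multi-line sequence blocks
are rejected) so that parse errors can name the offending line.  Files
ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Tuple, Union

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGTN")

# upper-case, then squash any other letter to N; non-letters are a parse error
_CLEAN_TABLE = {ord(c): c for c in "ACGTN"}
_CLEAN_TABLE.update({ord(c.lower()): c for c in "ACGTN"})
for _c in range(ord("A"), ord("Z") + 1):
    _CLEAN_TABLE.setdefault(_c, "N")
    _CLEAN_TABLE.setdefault(_c + 32, "N")


class FastqParseError(ValueError):
    """Malformed FASTQ record; message carries the 1-based line number."""


class InvalidQualityError(ValueError):
    """Quality character outside the plausible ASCII range of any encoding."""


@dataclass
class ReadRecord:
    """One FASTQ read: identifier, bases over {A,C,G,T,N}, quality string.

    ``scores`` is ``None`` until :func:`decode_qualities` populates it.
    """

    id: str
    seq: str
    qual: str
    scores: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FastqParseError(
                f"record '{self.id}': sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualityEncoding:
    """An Illumina quality dialect: ASCII offset and legal ranges."""

    name: str
    ascii_offset: int
    score_min: int
    score_max: int
    ascii_min: int
    ascii_max: int = 126


ENCODINGS = {
    "illumina-1.0": QualityEncoding("illumina-1.0", 64, -5, 62, 59),
    "illumina-1.3": QualityEncoding("illumina-1.3", 64, 0, 62, 64),
    "illumina-1.8": QualityEncoding("illumina-1.8", 33, 0, 93, 33),
}

#: Lowest ASCII code any FASTQ quality character may take.
ASCII_FLOOR = 33
#: Highest ASCII code any FASTQ quality character may take.
ASCII_CEIL = 126


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _iter_records(path: PathLike) -> Iterator[ReadRecord]:
    n_cleaned = 0
    with _open_text(path, "r") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(
                    f"{path}: line {lineno}: truncated record '{header[1:]}'"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {lineno - 1}: expected '+' separator for record "
                    f"'{header[1:]}' (multi-line sequences are not supported)"
                )
            rid = header[1:]
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno}: record '{rid}': sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            if not set(seq) <= VALID_BASES:
                cleaned = seq.translate(_CLEAN_TABLE)
                if not set(cleaned) <= VALID_BASES:
                    bad = next(c for c in cleaned if c not in VALID_BASES)
                    raise FastqParseError(
                        f"{path}: line {lineno - 2}: record '{rid}': "
                        f"invalid sequence character {bad!r}"
                    )
                if cleaned != seq.upper():
                    n_cleaned += 1
                seq = cleaned
            yield ReadRecord(rid, seq, qual)
    if n_cleaned:
        logger.warning(
            "%s: %d read(s) contained non-ACGTN letters; converted to N",
            path, n_cleaned,
        )


def read_fastq(
    path: PathLike, paired_mate: Optional[PathLike] = None
) -> Iterator[Union[ReadRecord, Tuple[ReadRecord, ReadRecord]]]:
    """Stream reads from ``path``; with ``paired_mate``, yield mate pairs.

    Mate files are walked in lockstep; a record-count mismatch raises
    :class:`FastqParseError`.  The input files are never modified.
    """
    if paired_mate is None:
        yield from _iter_records(path)
        return
    sentinel = object()
    for i, (r1, r2) in enumerate(
        zip_longest(_iter_records(path), _iter_records(paired_mate), fillvalue=sentinel)
    ):
        if r1 is sentinel or r2 is sentinel:
            raise FastqParseError(
                f"mate files {path} and {paired_mate} differ in record count "
                f"(mismatch at record {i + 1})"
            )
        yield r1, r2


def detect_encoding(
    sample: Iterable[ReadRecord], max_reads: int = 10_000
) -> QualityEncoding:
    """Infer the Illumina quality encoding from up to ``max_reads`` reads.

    Precedence on the minimum ASCII code seen: <59 => illumina-1.8,
    59..63 => illumina-1.0, >=64 => illumina-1.3.  Deterministic and
    order-insensitive over the sampled set.
    """
    lo, hi = ASCII_CEIL + 1, ASCII_FLOOR - 1
    n_seen = 0
    for record in sample:
        if n_seen >= max_reads:
            break
        if not record.qual:
            continue
        codes = record.qual.encode("ascii", errors="replace")
        lo = min(lo, min(codes))
        hi = max(hi, max(codes))
        n_seen += 1
    if lo > ASCII_CEIL:
        raise InvalidQualityError("no non-empty quality strings in sample")
    if lo < ASCII_FLOOR or hi > ASCII_CEIL:
        raise InvalidQualityError(
            f"quality ASCII codes outside [{ASCII_FLOOR},{ASCII_CEIL}] "
            f"(saw min {lo}, max {hi}); not a FASTQ quality encoding"
        )
    if lo < 59:
        return ENCODINGS["illumina-1.8"]
    if lo <= 63:
        return ENCODINGS["illumina-1.0"]
    return ENCODINGS["illumina-1.3"]


def decode_qualities(record: ReadRecord, enc: QualityEncoding) -> ReadRecord:
    """Return a copy of ``record`` with ``scores[i] = ascii(qual[i]) - offset``."""
    scores = []
    for i, ch in enumerate(record.qual):
        code = ord(ch)
        if code < enc.ascii_min or code > enc.ascii_max:
            raise InvalidQualityError(
                f"record '{record.id}', position {i}: quality character {ch!r} "
                f"(ASCII {code}) outside {enc.name} range "
                f"[{enc.ascii_min},{enc.ascii_max}]"
            )
        scores.append(code - enc.ascii_offset)
    return replace(record, scores=tuple(scores))


def encode_qualities(scores: Iterable[int], enc: QualityEncoding) -> str:
    """Inverse of :func:`decode_qualities` for a score vector."""
    return "".join(chr(s + enc.ascii_offset) for s in scores)


def write_fastq(records: Iterable[ReadRecord], path: PathLike) -> int:
    """Write 4-line records to ``path``; returns the number written.

    Round-trip faithful: ``read_fastq(write_fastq(X)) == X`` on
    (id, seq, qual).
    """
    n = 0
    with _open_text(path, "w") as fh:
        for record in records:
            fh.write(f"@{record.id}\n{record.seq}\n+\n{record.qual}\n")
            n += 1
    return n
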