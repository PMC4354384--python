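"""Synthetic inputs for every pipeline stage: reference sequences,
error-bearing read libraries with exact low-quality quotas and adapter
contamination, duplicate injection, and an ideal-aligner SAM.

The read simulator emulates a single-end Illumina experiment: 100 bp
reads drawn uniformly from the reference, substitution errors whose
per-base probability follows an exponential-decay-style curve rising
with base position (``p(i) = A * exp(shape * i / read_len)``, ``A``
fixed so the mean equals the overall error rate — 2 % by default),
adapter read-through when a normally distributed fragment is shorter
than the read, and quality strings constructed so that the library
contains *exactly* the requested percentage of low-quality bases and of
low-quality reads.  Every generator is a pure function of its
configuration and seed, and each returns a truth table sufficient to
check the filtering, masking, trimming and deduplication stages without
re-deriving ground truth.

Duplicate injection appends near-copies of existing reads: each copy is
identical to its source in the first ``dup_prefix_protect`` bases and
carries between 1 and ``dup_max_suffix_mismatch`` substitutions beyond
them (0 when the allowance is 0), with no indels.  Sources are drawn
without replacement whenever the copy count allows, so the constructed
duplicate fraction is exactly the fraction a prefix-cluster
deduplication at matching settings can remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .adapters import ILLUMINA_SE_ADAPTER_1
from .fastq import PathLike, ReadRecord

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGTN")}


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation settings."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library generators.

    Defaults reproduce the reference experiment: 100 bp single-end
    reads, 2 % mean sequencing error on a position-increasing curve,
    Illumina single-end adapter 1 contamination with Normal(150, 50)
    fragment sizes, 3 % low-quality bases / 9 % low-quality reads
    (Phred < 20, read low-quality when > 10 % of its bases are), 30 %
    duplicates protected over the first 25 bp with at most one suffix
    mismatch, and 30x coverage for the ideal-aligner alignment.
    """

    seed: int = 0
    n_reads: int = 100_000
    read_len: int = 100
    error_rate: float = 0.02
    decay_shape: float = 3.0
    pct_lowq_bases: float = 3.0
    pct_lowq_reads: float = 9.0
    lowq_phred_max: int = 20
    lowq_read_pct_rule: float = 10.0
    adapter: str = ILLUMINA_SE_ADAPTER_1
    fragment_mean: float = 150.0
    fragment_sd: float = 50.0
    dup_fraction: float = 0.30
    dup_prefix_protect: int = 25
    dup_max_suffix_mismatch: int = 1
    coverage: float = 30.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "dup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("pct_lowq_bases", "pct_lowq_reads", "lowq_read_pct_rule"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise SimConfigError(f"{name} must be in [0,100], got {v}")
        if self.fragment_sd < 0:
            raise SimConfigError("fragment_sd must be >= 0")
        if self.dup_prefix_protect > self.read_len:
            raise SimConfigError("dup_prefix_protect cannot exceed read_len")
        if self.dup_max_suffix_mismatch > self.read_len - self.dup_prefix_protect:
            raise SimConfigError(
                "dup_max_suffix_mismatch exceeds the unprotected suffix length"
            )
        if self.dup_fraction >= 1.0:
            raise SimConfigError("dup_fraction must be < 1")


GCProfileSpec = Union[float, Sequence[float], Sequence[Sequence[Tuple[int, float]]]]


def _normalize_gc(
    n_chroms: int, lengths: Sequence[int], gc_profile: GCProfileSpec
) -> List[List[Tuple[int, float]]]:
    if isinstance(gc_profile, (int, float)):
        return [[(L, float(gc_profile))] for L in lengths]
    gc_profile = list(gc_profile)
    if len(gc_profile) != n_chroms:
        raise SimConfigError(
            f"gc_profile has {len(gc_profile)} entries for {n_chroms} chromosomes"
        )
    out: List[List[Tuple[int, float]]] = []
    for L, spec in zip(lengths, gc_profile):
        if isinstance(spec, (int, float)):
            out.append([(L, float(spec))])
            continue
        regions = [(int(rl), float(gc)) for rl, gc in spec]
        if sum(rl for rl, _ in regions) != L:
            raise SimConfigError(
                f"region lengths {[rl for rl, _ in regions]} do not sum to "
                f"chromosome length {L}"
            )
        out.append(regions)
    return out


def simulate_reference(
    n_chroms: int,
    lengths: Sequence[int],
    gc_profile: GCProfileSpec,
    seed: int,
    out_fasta: Optional[PathLike] = None,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random reference with controlled regional GC composition.

    ``gc_profile`` is a single GC fraction, one per chromosome, or per
    chromosome a list of ``(region_length, gc_fraction)`` tuples summing
    to the chromosome length.  Returns ``(sequences, region_table)``;
    the table records each region's true GC fraction for oracle use.
    """
    if len(lengths) != n_chroms:
        raise SimConfigError("lengths must have one entry per chromosome")
    if any(L < 1 for L in lengths):
        raise SimConfigError("chromosome lengths must be >= 1")
    regions = _normalize_gc(n_chroms, lengths, gc_profile)
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    rows = []
    for ci, (L, chrom_regions) in enumerate(zip(lengths, regions)):
        name = f"chr{ci + 1}"
        parts = []
        offset = 0
        for region_len, gc in chrom_regions:
            is_gc = rng.random(region_len) < gc
            pick = rng.integers(0, 2, region_len)  # G/C or A/T member of the pair
            codes = np.where(is_gc, np.where(pick == 0, 2, 1), np.where(pick == 0, 0, 3))
            parts.append(_BASES[codes].tobytes().decode("ascii"))
            rows.append(
                {"chrom": name, "start": offset, "end": offset + region_len, "gc": gc}
            )
            offset += region_len
        seqs[name] = "".join(parts)
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])
    if out_fasta is not None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
        ]
        SeqIO.write(records, str(out_fasta), "fasta")
    return seqs, table


def _error_curve(cfg: SimConfig) -> np.ndarray:
    i = np.arange(cfg.read_len)
    raw = np.exp(cfg.decay_shape * i / cfg.read_len)
    p = cfg.error_rate * cfg.read_len * raw / raw.sum()
    if p.max() >= 1.0:
        raise SimConfigError(
            "error curve exceeds probability 1 at the 3' end; lower "
            "error_rate or decay_shape"
        )
    return p


def _allocate_lowq_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-read low-quality-base counts hitting both quotas exactly.

    Low-quality reads get strictly more than ``lowq_read_pct_rule`` % of
    their bases low quality (the filter's removal rule); the remainder
    of the base quota is spread over the other reads below that line.
    """
    n, L = cfg.n_reads, cfg.read_len
    n_low = int(round(cfg.pct_lowq_reads / 100.0 * n))
    total = int(round(cfg.pct_lowq_bases / 100.0 * n * L))
    min_fail = int(cfg.lowq_read_pct_rule / 100.0 * L) + 1  # smallest failing count
    max_pass = min_fail - 1
    if n_low * min_fail > total:
        raise SimConfigError(
            f"pct_lowq_bases={cfg.pct_lowq_bases} cannot accommodate "
            f"{n_low} low-quality reads needing >= {min_fail} low bases each"
        )
    counts = np.zeros(n, dtype=np.int64)
    low_idx = rng.choice(n, n_low, replace=False) if n_low else np.empty(0, dtype=int)
    counts[low_idx] = min_fail
    remainder = total - n_low * min_fail
    good_idx = np.setdiff1d(np.arange(n), low_idx, assume_unique=False)
    cap_good = max_pass * len(good_idx)
    take_good = min(remainder, cap_good)
    if take_good and len(good_idx):
        extra = rng.multivariate_hypergeometric(
            np.full(len(good_idx), max_pass), take_good
        )
        counts[good_idx] += extra
    remainder -= take_good
    if remainder:
        cap_low = (L - min_fail) * n_low
        if remainder > cap_low:
            raise SimConfigError(
                "pct_lowq_bases too high for the requested pct_lowq_reads"
            )
        extra = rng.multivariate_hypergeometric(
            np.full(n_low, L - min_fail), remainder
        )
        counts[low_idx] += extra
    return counts


def _codes_to_reads(
    codes: np.ndarray, quals: np.ndarray, ids: Sequence[str]
) -> List[ReadRecord]:
    reads = []
    base_rows = _BASES[codes]
    for i, rid in enumerate(ids):
        seq = base_rows[i].tobytes().decode("ascii")
        qual = quals[i].tobytes().decode("ascii")
        scores = tuple(int(q) - 33 for q in quals[i])
        reads.append(ReadRecord(rid, seq, qual, scores))
    return reads


def simulate_reads_s1(
    reference: Union[Mapping[str, str], PathLike],
    cfg: SimConfig,
) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Error-bearing, adapter-contaminated library with exact quality quotas.

    Returns ``(reads, truth)``.  The truth table records, per read, its
    origin (chrom, 0-based start), number of surviving sequencing
    errors, adapter insertion point (-1 when uncontaminated), number of
    low-quality bases, and whether the read violates the low-quality
    read rule.  Qualities are written on the Phred+33 scale; erroneous
    bases are preferentially chosen as the low-quality ones.
    """
    if not isinstance(reference, Mapping):
        reference = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")
        }
    n, L = cfg.n_reads, cfg.read_len
    rng = np.random.default_rng(cfg.seed)
    chroms = [c for c, s in reference.items() if len(s) >= L]
    if not chroms:
        raise SimConfigError(f"no reference sequence is >= {L} bp")
    chrom_arrays = {
        c: np.frombuffer(reference[c].encode("ascii"), dtype=np.uint8) for c in chroms
    }
    code_lookup = np.zeros(256, dtype=np.uint8)
    for b, i in _CODE.items():
        code_lookup[ord(b)] = i
    weights = np.array([len(reference[c]) - L + 1 for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), n, p=weights / weights.sum())
    starts = np.empty(n, dtype=np.int64)
    codes = np.empty((n, L), dtype=np.uint8)
    for ci, chrom in enumerate(chroms):
        rows = np.flatnonzero(chrom_idx == ci)
        if not len(rows):
            continue
        s = rng.integers(0, len(reference[chrom]) - L + 1, len(rows))
        starts[rows] = s
        codes[rows] = code_lookup[
            chrom_arrays[chrom][s[:, None] + np.arange(L)[None, :]]
        ]

    # substitution errors on the position-increasing curve
    p = _error_curve(cfg)
    err_mask = rng.random((n, L)) < p[None, :]
    err_mask &= codes < 4  # never substitute an N placeholder
    shift = rng.integers(1, 4, size=(n, L))
    codes = np.where(err_mask, (codes + shift) % 4, codes)

    # adapter read-through for short fragments
    adapter_codes = np.array([_CODE[b] for b in cfg.adapter], dtype=np.uint8)
    frags = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n)).astype(int)
    frags = np.clip(frags, 0, None)
    adapter_pos = np.where(frags < L, frags, -1)
    for i in np.flatnonzero(adapter_pos >= 0):
        fpos = adapter_pos[i]
        tail_len = L - fpos
        n_ad = min(tail_len, len(adapter_codes))
        codes[i, fpos : fpos + n_ad] = adapter_codes[:n_ad]
        if tail_len > n_ad:  # fill past the adapter with random bases
            codes[i, fpos + n_ad :] = rng.integers(0, 4, tail_len - n_ad)
        err_mask[i, fpos:] = False

    # exact low-quality quotas; error positions are marked low first
    counts = _allocate_lowq_counts(cfg, rng)
    keys = rng.random((n, L)) - err_mask.astype(float)  # errors sort first
    order = np.argsort(keys, axis=1, kind="stable")
    take = np.arange(L)[None, :] < counts[:, None]
    lowq_mask = np.zeros((n, L), dtype=bool)
    lowq_mask[np.repeat(np.arange(n), L), order.ravel()] = take.ravel()

    q_high = rng.integers(cfg.lowq_phred_max + 11, cfg.lowq_phred_max + 21, size=(n, L))
    q_low = rng.integers(0, cfg.lowq_phred_max, size=(n, L))
    scores = np.where(lowq_mask, q_low, q_high)
    quals = (scores + 33).astype(np.uint8)

    min_fail = int(cfg.lowq_read_pct_rule / 100.0 * L) + 1
    ids = [f"r{i}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "chrom": [chroms[ci] for ci in chrom_idx],
            "start": starts,
            "n_errors": err_mask.sum(axis=1),
            "adapter_pos": adapter_pos,
            "n_lowq_bases": counts,
            "is_lowq_read": counts >= min_fail,
        }
    )
    return _codes_to_reads(codes, quals, ids), truth


def inject_duplicates(
    reads: Sequence[ReadRecord],
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Append near-duplicate copies so they form ``dup_fraction`` of the output.

    Each copy matches its source over the first ``dup_prefix_protect``
    bases and differs by 1..``dup_max_suffix_mismatch`` substitutions in
    the suffix (exact copies when the allowance is 0); the combined
    library is shuffled.  The truth table pairs every copy with its
    source and records its mismatch count.
    """
    if seed is None:
        seed = cfg.seed + 1
    rng = np.random.default_rng(seed)
    n_src = len(reads)
    if n_src == 0:
        raise SimConfigError("cannot inject duplicates into an empty library")
    n_dup = int(round(cfg.dup_fraction / (1.0 - cfg.dup_fraction) * n_src))
    if n_dup == 0:
        return list(reads), pd.DataFrame(
            columns=["copy_id", "source_id", "n_suffix_mismatches"]
        )
    sources = rng.choice(n_src, n_dup, replace=n_dup > n_src)
    copies: List[ReadRecord] = []
    rows = []
    for j, si in enumerate(sources):
        src = reads[int(si)]
        seq = list(src.seq)
        protect = min(cfg.dup_prefix_protect, len(seq))
        room = len(seq) - protect
        n_mm = 0
        if cfg.dup_max_suffix_mismatch > 0 and room > 0:
            n_mm = int(rng.integers(1, min(cfg.dup_max_suffix_mismatch, room) + 1))
            for pos in rng.choice(np.arange(protect, len(seq)), n_mm, replace=False):
                old = seq[pos]
                choices = [b for b in "ACGT" if b != old]
                seq[pos] = choices[int(rng.integers(0, len(choices)))]
        copy_id = f"{src.id}/dup{j}"
        copies.append(ReadRecord(copy_id, "".join(seq), src.qual, src.scores))
        rows.append(
            {"copy_id": copy_id, "source_id": src.id, "n_suffix_mismatches": n_mm}
        )
    combined = list(reads) + copies
    perm = rng.permutation(len(combined))
    shuffled = [combined[int(i)] for i in perm]
    truth = pd.DataFrame(rows, columns=["copy_id", "source_id", "n_suffix_mismatches"])
    return shuffled, truth


def ideal_alignment_sam(
    reference: Union[Mapping[str, str], PathLike],
    coverage: float,
    read_len: int,
    seed: int,
    out_sam: PathLike,
) -> int:
    """Write a SAM of uniformly placed, unique, error-free alignments.

    One primary full-length-match record per read (MAPQ 60, flag 0),
    ``round(coverage * chrom_len / read_len)`` reads per chromosome.
    Returns the number of records written.
    """
    if coverage <= 0:
        raise SimConfigError("coverage must be > 0")
    if not isinstance(reference, Mapping):
        reference = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")
        }
    lengths = {name: len(seq) for name, seq in reference.items()}
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in lengths.items()],
        }
    )
    n_written = 0
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for tid, (name, length) in enumerate(lengths.items()):
            if length < read_len:
                continue
            n_reads = int(round(coverage * length / read_len))
            starts = rng.integers(0, length - read_len + 1, n_reads)
            for i, start in enumerate(starts):
                seg = pysam.AlignedSegment(header)
                seg.query_name = f"sim-{name}-{i}"
                seg.flag = 0
                seg.reference_id = tid
                seg.reference_start = int(start)
                seg.mapping_quality = 60
                seg.cigartuples = [(0, read_len)]
                out.write(seg)
                n_written += 1
    return n_written
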