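"""Composed preprocessing pipeline with a machine-readable run report.

Stages run in the fixed preparation order — quality filter, base
masking, adapter trimming, duplicate removal on the read side; MAPQ /
multi-mapper filtering and RD-signal construction on the alignment side
— and each stage is individually skippable.  Alignment itself is an
explicit gap: the pipeline consumes a user-supplied SAM between the
read-side and alignment-side stages.  A rerun with an identical
configuration (including the global seed) reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import __version__
from .adapters import AdapterSpec, trim_library
from .alignfilter import filter_mapq, read_sam, resolve_multimappers, write_sam
from .dedup import DedupPolicy, dedup_reads
from .fastq import (
    ENCODINGS,
    PathLike,
    decode_qualities,
    detect_encoding,
    read_fastq,
    write_fastq,
)
from .quality import FilterPolicy, filter_low_quality, mask_low_quality
from .rdsignal import (
    gc_correct,
    gc_signal,
    grid_from_reference,
    make_track,
    raw_rd,
    write_bedgraph,
    write_track,
)

logger = logging.getLogger(__name__)

#: Fixed execution order of the preprocessing stages.
STAGE_ORDER = ["filter", "mask", "trim", "dedup", "samfilter", "rdsignal"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    stages: List[Dict[str, Any]]
    seed: int = 0
    outdir: Path = Path("rdprep_out")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            stages=raw.get("stages", []),
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "rdprep_out")),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def validate(self) -> None:
        if not self.stages:
            raise PipelineConfigError("no stages configured")
        last = -1
        for entry in self.stages:
            name = entry.get("stage")
            if name not in STAGE_ORDER:
                raise PipelineConfigError(
                    f"unknown stage {name!r}; valid stages: {STAGE_ORDER}"
                )
            idx = STAGE_ORDER.index(name)
            if idx <= last:
                raise PipelineConfigError(
                    f"stage {name!r} out of order; stages must follow {STAGE_ORDER}"
                )
            last = idx


def _load_decoded(path: PathLike, encoding: str = "auto") -> list:
    reads = list(read_fastq(path))
    enc = (
        detect_encoding(iter(reads))
        if encoding == "auto"
        else ENCODINGS[encoding]
    )
    return [decode_qualities(r, enc) for r in reads]


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Execute the enabled stages in order; returns (and writes) the report."""
    config.validate()
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    current_fastq: Optional[Path] = None
    current_sam: Optional[Path] = None
    try:
        for entry in config.stages:
            name = entry["stage"]
            params = {k: v for k, v in entry.items() if k != "stage"}
            stage_report: Dict[str, Any] = {"stage": name, "params": params}
            if name in ("filter", "mask", "trim", "dedup"):
                in_path = params.get("input", current_fastq)
                if in_path is None:
                    raise PipelineConfigError(f"stage {name!r} has no FASTQ input")
                out_path = config.outdir / f"{name}.fastq"
                if name == "filter":
                    reads = _load_decoded(in_path, params.get("encoding", "auto"))
                    policy = FilterPolicy(
                        qual_threshold=int(params.get("min_qual", 20)),
                        min_good_pct=float(params.get("min_good_pct", 90)),
                    )
                    result = filter_low_quality(reads, policy)
                    write_fastq(result.kept, out_path)
                    stage_report["counts"] = {
                        "total": result.total,
                        "removed": result.removed,
                        "pct_removed": result.pct_removed,
                    }
                elif name == "mask":
                    reads = _load_decoded(in_path, params.get("encoding", "auto"))
                    masked = list(
                        mask_low_quality(reads, int(params.get("min_qual", 20)))
                    )
                    write_fastq(masked, out_path)
                    n_masked = sum(
                        sum(1 for a, b in zip(x.seq, y.seq) if a != b)
                        for x, y in zip(reads, masked)
                    )
                    stage_report["counts"] = {
                        "total": len(masked),
                        "masked_bases": n_masked,
                    }
                elif name == "trim":
                    reads = list(read_fastq(in_path))
                    spec = AdapterSpec(
                        adapter=params.get("adapter", AdapterSpec().adapter),
                        max_error_rate=float(params.get("max_error_rate", 0.1)),
                        min_overlap=int(params.get("min_overlap", 3)),
                        min_length=int(params.get("min_length", 0)),
                    )
                    trimmed, tstats = trim_library(reads, spec)
                    write_fastq(trimmed, out_path)
                    stage_report["counts"] = {
                        "total": tstats.total,
                        "trimmed": tstats.trimmed,
                        "discarded": tstats.discarded,
                    }
                else:  # dedup
                    reads = list(read_fastq(in_path))
                    policy = DedupPolicy(
                        prefix_len=int(params.get("prefix_len", 25)),
                        max_mismatches=int(params.get("max_mismatches", 1)),
                    )
                    deduped, dstats = dedup_reads(reads, policy)
                    write_fastq(deduped, out_path)
                    stage_report["counts"] = {
                        "total": dstats.total,
                        "clusters": dstats.clusters,
                        "removed": dstats.removed,
                        "pct_removed": dstats.pct_removed,
                    }
                current_fastq = out_path
            elif name == "samfilter":
                in_sam = params.get("input", current_sam)
                if in_sam is None:
                    raise PipelineConfigError("samfilter stage has no SAM input")
                header, records = read_sam(in_sam)
                kept, mstats = filter_mapq(records, int(params.get("min_mapq", 0)))
                resolved = resolve_multimappers(
                    kept,
                    strategy=params.get("multimap", "unique"),
                    seed=int(params.get("seed", config.seed)),
                )
                out_path = config.outdir / "samfilter.sam"
                write_sam(header, resolved, out_path)
                stage_report["counts"] = {
                    "kept_mapq": mstats.kept,
                    "unmapped": mstats.unmapped,
                    "below_threshold": mstats.below_threshold,
                    "emitted": len(resolved),
                }
                current_sam = out_path
            else:  # rdsignal
                reference = params.get("reference")
                if reference is None:
                    raise PipelineConfigError("rdsignal stage needs a reference FASTA")
                in_sam = params.get("input", current_sam)
                if in_sam is None:
                    raise PipelineConfigError("rdsignal stage has no SAM input")
                window = int(params.get("window", 100))
                grid = grid_from_reference(reference, window)
                gc = gc_signal(reference, window)
                _, records = read_sam(in_sam)
                counts, skipped = raw_rd(
                    records, grid, rule=params.get("assign", "center")
                )
                track = make_track(grid, gc, counts)
                track = gc_correct(
                    track, per_chromosome=bool(params.get("per_chromosome", True))
                )
                track_path = config.outdir / "rd_track.tsv"
                write_track(track, track_path)
                write_bedgraph(track, config.outdir / "rd_corrected.bedgraph")
                stage_report["counts"] = {
                    "windows": len(track),
                    "assigned": int(track["raw_rd"].sum()),
                    "skipped_alignments": skipped,
                }
            report["stages"].append(stage_report)
            logger.info("stage %s done: %s", name, stage_report.get("counts"))
    finally:
        with open(config.outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
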