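"""End-to-end orchestration: simulate -> detect -> classify -> quantify.

Every stage is also runnable independently through the CLI on the
previous stage's plain-text outputs; this module wires them together
and guarantees determinism: outputs embed a hash of the configuration
plus seed, and re-running with the same hash reproduces byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gcrmap import __version__
from gcrmap.classify import ClassifyParams, classify_reads
from gcrmap.errors import DataError, StageError
from gcrmap.genome_model import (
    AnnotationSet,
    Genome,
    load_annotations,
    load_reference,
    repair_region_span,
)
from gcrmap.quantify import (
    PoolReport,
    build_report,
    write_event_table,
)
from gcrmap.splitread import (
    align_reads,
    detect_split_reads,
    parse_alignments,
    read_fastq,
    write_sam,
    write_splitread_table,
)
from gcrmap.synthetic_pool import (
    PoolTruth,
    ToyGenomeConfig,
    build_toy_genome,
    sample_pool_events,
    simulate_pool,
    write_fastq,
    write_truth_sam,
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Precedence when built through the CLI: explicit flags > config file
    > defaults.
    """

    reference: str | None = None
    annotations: str | None = None
    reads: str | None = None  # FASTQ
    alignments: str | None = None  # SAM
    outdir: str = "gcrmap_out"
    seed: int = 1
    orientation: str = "left"
    repair_chrom: str | None = None
    min_clip: int = 10
    min_mapq: int = 0
    max_mismatch: int | None = None
    tel_min_len: int = 8
    tel_min_fraction: float = 0.9
    singleton_threshold: int = 200
    merge_distance: int = 2
    bin_sizes: tuple[int, ...] = (1000, 100)
    n_clones: int = 30
    verbosity: int = 1

    def classify_params(self) -> ClassifyParams:
        return ClassifyParams(
            tel_min_len=self.tel_min_len,
            tel_min_fraction=self.tel_min_fraction,
            max_mismatch=self.max_mismatch,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"config file {path} must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "bin_sizes" in data and data["bin_sizes"] is not None:
            data["bin_sizes"] = tuple(data["bin_sizes"])
        return cls(**data)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> PoolReport:
    """Run detect -> classify -> quantify on the configured inputs and
    write all tables, the JSON report, and an audit log to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"gcrmap {__version__} config {config.config_hash()} seed {config.seed}"
    log_lines = [tag]

    try:
        if not config.reference or not config.annotations:
            raise DataError("reference and annotations are required")
        genome = load_reference(config.reference)
        annotations = load_annotations(config.annotations, genome)
        chrom = config.repair_chrom or _infer_repair_chrom(annotations)
        region = repair_region_span(annotations, chrom, config.orientation)
    except Exception as exc:
        raise StageError("configure", exc) from exc

    try:
        if config.alignments:
            anchored = parse_alignments(config.alignments, genome, region)
        elif config.reads:
            anchored = align_reads(read_fastq(config.reads), genome, region)
            write_sam(anchored, genome, outdir / "aligned.sam")
        else:
            raise DataError("either reads (FASTQ) or alignments (SAM) required")
        split = detect_split_reads(anchored, region, config.min_clip, config.min_mapq)
        log_lines.append(
            f"detect: {len(anchored)} anchored reads, {len(split)} split reads "
            f"(min_clip={config.min_clip})"
        )
        for r in anchored:
            if r.has_clip and len(r.clip_seq) < config.min_clip:
                log_lines.append(
                    f"excluded {r.read_id}: clip {len(r.clip_seq)} < min_clip"
                )
        write_splitread_table(split, region, outdir / "splitreads.tsv", tag)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("detect", exc) from exc

    try:
        read_events = classify_reads(
            split, annotations, region, genome, config.classify_params()
        )
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        report = build_report(
            read_events,
            region,
            annotations,
            bin_sizes=config.bin_sizes,
            merge_distance=config.merge_distance,
            singleton_threshold=config.singleton_threshold,
            n_clones=config.n_clones,
        )
        write_event_table(report.events, outdir / "events.tsv", tag)
        write_event_table(report.removed, outdir / "events_removed.tsv", tag)

        def dump(df, path):
            with open(path, "w") as fh:
                fh.write(f"# {tag}\n")
                df.to_csv(fh, sep="\t", index=False)

        for name, df in report.frequencies.items():
            dump(df, outdir / f"freq_{name}.tsv")
        for name, df in report.event_weighted.items():
            dump(df, outdir / f"freq_{name}_eventweighted.tsv")
        payload = report.to_json_dict()
        payload["config_hash"] = config.config_hash()
        payload["seed"] = config.seed
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        log_lines.append(
            f"quantify: {report.total_split_reads} split reads, "
            f"{len(report.events)} events retained, "
            f"{len(report.removed)} singletons removed"
        )
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise StageError("quantify", exc) from exc
    return report


def _infer_repair_chrom(annotations: AnnotationSet) -> str:
    chroms = {f.chrom for f in annotations.by_kind("HO_cut_site")}
    if len(chroms) != 1:
        raise DataError(
            "cannot infer the repair chromosome; pass repair_chrom explicitly"
        )
    return chroms.pop()


def simulate_to_dir(
    outdir: str | Path,
    seed: int,
    mixture: dict[str, float],
    n_clones: int = 30,
    depth: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.001,
    config: ToyGenomeConfig | None = None,
    truth_sam: bool = False,
) -> tuple[Genome, AnnotationSet, PoolTruth]:
    """Build a toy genome, sample a pool, simulate reads, and write
    reference.fa / annotations.tsv / reads.fastq / truth.tsv (+ truth.sam)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or ToyGenomeConfig(seed=seed)
    genome, annotations = build_toy_genome(cfg)
    truth = sample_pool_events(mixture, n_clones, genome, annotations, seed, cfg)
    clones, reads = simulate_pool(
        genome, annotations, truth, depth, read_len, error_rate, seed
    )
    genome.write(outdir / "reference.fa")
    annotations.write(outdir / "annotations.tsv")
    write_fastq(reads, outdir / "reads.fastq")
    truth.write(outdir / "truth.tsv", genome)
    if truth_sam:
        write_truth_sam(truth, genome, clones, reads, outdir / "truth.sam")
    return genome, annotations, truth
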