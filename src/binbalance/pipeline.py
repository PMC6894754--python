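"""Three-step pipeline orchestration: chunk/map -> balance -> per-region
variant discovery and VCF combination.

Rather than a cluster runtime, execution follows an explicit
independent-task contract on a local worker pool: mapper tasks are
independent over chunks, region builds are independent over regions, and all
hand-off happens through a shared work directory with atomic renames.
Results are therefore identical for any worker count and any task
completion order.

Step 1 overlaps with chunking at chunk granularity: a mapper task is
submitted as soon as its chunk becomes visible.  Step 2 runs once per
genome part, sequentially over parts, parallelising within a part.  Step 3
invokes an opaque external command per region (mark duplicates, base
recalibration, haplotype calling live behind that hook) and concatenates
the per-region VCFs under a single header.
"""
from __future__ import annotations

import json
import logging
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from ._ioutils import open_text_auto
from .chunker import ChunkSpec, iter_chunk_paths
from .errors import (
    ConfigError,
    InputError,
    InvalidArgumentError,
    RegionCommandError,
    VcfMergeError,
)
from .genome_model import DEFAULT_BIN_SIZE, ReferenceDict
from .load_balancer import BalanceConfig, RegionOutput, run_load_balancing_step
from .mapper_binning import MapperConfig, MapperTaskResult, run_mapper_task

logger = logging.getLogger("binbalance")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; mirrors the per-step configurability
    of the original framework (each step reads only its own knobs)."""

    ref_dict: str | Path  # SAM header or .fai file describing the reference
    work_dir: str | Path
    output_dir: str | Path
    # inputs: either a FASTQ pair (mapper_cmd required) or SAM files (direct mode)
    fastq_r1: str | Path | None = None
    fastq_r2: str | Path | None = None
    sam_inputs: Sequence[str | Path] = field(default_factory=tuple)
    bin_size: int = DEFAULT_BIN_SIZE
    num_parts: int = 1
    num_regions: int = 1
    workers: int = 1
    reads_per_chunk: int = 2_000_000
    mapper_cmd: str | None = None
    region_cmd: str | None = None
    ref_path: str | None = None  # passed to the mapper command template
    emit_bam: bool = False
    compression_level: int = 1
    split_at_chromosomes: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for attr in ("bin_size", "num_parts", "num_regions", "workers", "reads_per_chunk"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be positive, got {getattr(self, attr)}")
        fastq_mode = self.fastq_r1 is not None or self.fastq_r2 is not None
        if fastq_mode:
            if self.fastq_r1 is None or self.fastq_r2 is None:
                raise ConfigError("both fastq_r1 and fastq_r2 are required in FASTQ mode")
            if not self.mapper_cmd:
                raise ConfigError("FASTQ input requires a mapper_cmd template")
            for p in (self.fastq_r1, self.fastq_r2):
                if not Path(p).exists():
                    raise InputError(f"input FASTQ {p} does not exist")
        else:
            if not self.sam_inputs:
                raise ConfigError("either a FASTQ pair or sam_inputs must be given")
            for p in self.sam_inputs:
                if not Path(p).exists():
                    raise InputError(f"input SAM {p} does not exist")
        if not Path(self.ref_dict).exists():
            raise InputError(f"reference dictionary {self.ref_dict} does not exist")
        if self.region_cmd:
            _check_region_template(self.region_cmd)

    def load_reference(self) -> ReferenceDict:
        path = Path(self.ref_dict)
        if path.suffix == ".fai":
            return ReferenceDict.from_fai(path)
        return ReferenceDict.from_sam_header(path)


def _check_region_template(template: str) -> None:
    for placeholder in ("{bam}", "{bed}", "{out}"):
        if placeholder not in template:
            raise ConfigError(
                f"region command template is missing the {placeholder} placeholder"
            )


def run_region_command(
    region_bam: str | Path, region_bed: str | Path, template: str, out_path: str | Path
) -> Path:
    """Substitute {bam}/{bed}/{out} into the template, run it, verify output.

    The template is the pluggable variant-discovery hook; tests use stub
    templates (``cp``/``echo``), production wires in the real toolchain.
    """
    _check_region_template(template)
    out_path = Path(out_path)
    rendered = template.format(bam=str(region_bam), bed=str(region_bed), out=str(out_path))
    proc = subprocess.run(
        rendered, shell=True, capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise RegionCommandError(
            f"region command {rendered!r} exited with {proc.returncode}: "
            f"{proc.stderr.strip()[:2000]}"
        )
    if not out_path.exists() or out_path.stat().st_size == 0:
        raise RegionCommandError(
            f"region command {rendered!r} produced no output at {out_path}"
        )
    return out_path


def combine_vcfs(region_vcfs: Sequence[str | Path], out_path: str | Path) -> int:
    """Concatenate per-region VCFs under the first file's meta/header block.

    Regions are genome-ordered and disjoint, so concatenation in region
    order keeps the output coordinate-ordered when each input is.  Returns
    the number of data records written.
    """
    if not region_vcfs:
        raise InvalidArgumentError("need at least one VCF to combine")
    out_path = Path(out_path)
    n_records = 0
    header_cols: str | None = None
    with open(out_path, "w") as out:
        for i, path in enumerate(region_vcfs):
            with open_text_auto(path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    if line.startswith("##"):
                        if i == 0:
                            out.write(line + "\n")
                        continue
                    if line.startswith("#"):
                        if header_cols is None:
                            header_cols = line
                            out.write(line + "\n")
                        elif line != header_cols:
                            raise VcfMergeError(
                                f"{path}: column header differs from first file"
                            )
                        continue
                    out.write(line + "\n")
                    n_records += 1
    return n_records


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute chunk -> map -> balance (per part) -> region command -> combine.

    Returns the manifest: per-stage file lists and record counts.  The
    manifest is also written to ``output_dir/manifest.jsonl`` (one JSON
    object per stage event) and every stage start/end is logged.
    """
    config.validate()
    ref = config.load_reference()
    work = Path(config.work_dir)
    out = Path(config.output_dir)
    work.mkdir(parents=True, exist_ok=True)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    events: list[dict[str, Any]] = []

    def record(event: dict[str, Any]) -> None:
        events.append(event)
        with open(manifest_path, "a") as fh:
            fh.write(json.dumps(event) + "\n")
        logger.info("%s", event)

    manifest_path.write_text("")

    mapper_out = work / "mapper_out"
    mapper_cfg = MapperConfig(
        ref=ref,
        out_dir=mapper_out,
        bin_size=config.bin_size,
        num_parts=config.num_parts,
        compression_level=config.compression_level,
        mapper_cmd=config.mapper_cmd,
        ref_path=config.ref_path,
    )

    # ---- step 1: chunking overlapped with mapping -------------------------
    record({"stage": "map", "event": "start"})
    results: list[MapperTaskResult] = []
    with ThreadPoolExecutor(max_workers=config.workers) as pool:
        futures = []
        if config.fastq_r1 is not None:
            spec = ChunkSpec(
                reads_per_chunk=config.reads_per_chunk,
                output_dir=work / "chunks",
            )
            # submit each mapper task the moment its chunk is renamed into place
            for chunk_path in iter_chunk_paths(config.fastq_r1, config.fastq_r2, spec):
                futures.append(pool.submit(run_mapper_task, chunk_path, mapper_cfg))
        else:
            for sam_path in config.sam_inputs:
                futures.append(pool.submit(run_mapper_task, Path(sam_path), mapper_cfg))
        for fut in futures:
            results.append(fut.result())

    total_mapped = sum(r.mapped_count for r in results)
    total_unmapped = sum(r.unmapped_count for r in results)
    record(
        {
            "stage": "map",
            "event": "end",
            "tasks": len(results),
            "mapped_records": total_mapped,
            "unmapped_records": total_unmapped,
        }
    )

    # ---- step 2: load balancing, one pass per genome part -----------------
    balance_cfg = BalanceConfig(
        ref=ref,
        out_dir=out / "regions",
        bin_size=config.bin_size,
        num_parts=config.num_parts,
        emit_bam=config.emit_bam,
        workers=config.workers,
        split_at_chromosomes=config.split_at_chromosomes,
    )
    region_outputs: list[RegionOutput] = []
    for part in range(config.num_parts):
        record({"stage": "balance", "event": "start", "part": part})
        part_outputs = run_load_balancing_step(
            mapper_out, part, config.num_regions, balance_cfg
        )
        record(
            {
                "stage": "balance",
                "event": "end",
                "part": part,
                "regions": len(part_outputs),
                "records": sum(o.record_count for o in part_outputs),
            }
        )
        region_outputs.extend(part_outputs)

    balanced_records = sum(o.record_count for o in region_outputs)

    # ---- step 3: per-region commands + VCF combination --------------------
    combined_vcf: Path | None = None
    vcf_records = 0
    if config.region_cmd:
        record({"stage": "variant_discovery", "event": "start"})
        vcf_dir = out / "vcfs"
        vcf_dir.mkdir(exist_ok=True)

        def call(o: RegionOutput) -> Path:
            vcf = vcf_dir / f"part{o.part_id}_region{o.region_id:04d}.vcf"
            return run_region_command(o.alignment_path, o.bed_path, config.region_cmd, vcf)

        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            vcfs = list(pool.map(call, region_outputs))
        combined_vcf = out / "combined.vcf"
        vcf_records = combine_vcfs(vcfs, combined_vcf)
        record(
            {
                "stage": "variant_discovery",
                "event": "end",
                "regions": len(vcfs),
                "vcf_records": vcf_records,
            }
        )

    manifest: dict[str, Any] = {
        "events": events,
        "counts": {
            "mapped_records": total_mapped,
            "unmapped_records": total_unmapped,
            "region_records": balanced_records,
            "vcf_records": vcf_records,
        },
        "files": {
            "regions": [
                {
                    "part": o.part_id,
                    "region": o.region_id,
                    "alignment": str(o.alignment_path),
                    "bed": str(o.bed_path),
                    "records": o.record_count,
                }
                for o in region_outputs
            ],
            "combined_vcf": str(combined_vcf) if combined_vcf else None,
            "manifest": str(manifest_path),
        },
    }
    return manifest
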