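"""Mapping-side binning: group SAM records into bins, route to genome parts,
compress and emit one container per (task, part) plus a bins-info sidecar.

A *mapper task* handles one FASTQ chunk.  It either runs an external mapper
command (e.g. ``bwa mem``) and consumes SAM from its standard output, or — in
direct mode — reads an existing SAM file.  Mapped records are keyed by
:func:`~binbalance.genome_model.bin_id_for_record`; unmapped records (FLAG
0x4 or RNAME ``*``) are counted and optionally preserved, never binned.
Tasks are independent over chunks and write only files named by their
chunk id, so any worker pool may execute them concurrently.
"""
from __future__ import annotations

import gzip
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from ._ioutils import deterministic_gzip_writer
from .bin_container import (
    BinBlock,
    BinsInfo,
    DEFAULT_COMPRESSION_LEVEL,
    compress_bin,
    write_bins_info,
    write_container,
)
from .errors import (
    MalformedSAMError,
    MapperInvocationError,
    UnknownReferenceError,
)
from .genome_model import (
    BinID,
    DEFAULT_BIN_SIZE,
    GenomePartition,
    ReferenceDict,
    bin_id_for_record,
    partition_genome,
)

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class MapperConfig:
    """Per-task configuration for the mapping/binning step."""

    ref: ReferenceDict
    out_dir: Path
    bin_size: int = DEFAULT_BIN_SIZE
    num_parts: int = 1
    compression_level: int = DEFAULT_COMPRESSION_LEVEL
    mapper_cmd: str | None = None  # template with {input} and optionally {ref}
    ref_path: str | None = None  # substituted for {ref} in mapper_cmd
    exclude_secondary: bool = False  # drop 0x100/0x800 records instead of binning them
    keep_unmapped: bool = True  # write unmapped records to a sidecar file

    def partition(self) -> GenomePartition:
        return partition_genome(self.ref, self.num_parts)


@dataclass
class MapperTaskResult:
    """What one mapper task produced; counts are conserved against its input."""

    chunk_id: str
    per_part_container_paths: dict[int, Path]
    bins_info: BinsInfo
    unmapped_count: int
    bins_info_path: Path | None = None
    excluded_count: int = 0

    @property
    def mapped_count(self) -> int:
        return self.bins_info.total()


def assign_records_to_bins(
    sam_stream: Iterable[str],
    bin_size: int,
    ref: ReferenceDict,
    exclude_secondary: bool = False,
) -> tuple[dict[BinID, list[str]], list[str], int]:
    """Group SAM record lines into bins by leftmost position.

    Header lines (``@``) are skipped.  Returns ``(bins, unmapped, excluded)``
    where ``bins`` maps BinID to record lines in stream order, ``unmapped``
    collects records with FLAG 0x4 or RNAME ``*``, and ``excluded`` counts
    secondary/supplementary records dropped when ``exclude_secondary`` is set.
    """
    bins: dict[BinID, list[str]] = {}
    unmapped: list[str] = []
    excluded = 0
    for lineno, line in enumerate(sam_stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise MalformedSAMError(
                f"line {lineno}: SAM record has {len(fields)} fields, expected >= 11"
            )
        try:
            flag = int(fields[1])
            pos1 = int(fields[3])
        except ValueError as exc:
            raise MalformedSAMError(f"line {lineno}: non-integer FLAG or POS") from exc
        rname = fields[2]
        if flag & FLAG_UNMAPPED or rname == "*":
            unmapped.append(line)
            continue
        if exclude_secondary and flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            excluded += 1
            continue
        if rname not in ref:
            raise UnknownReferenceError(
                f"line {lineno}: RNAME {rname!r} not in reference dictionary"
            )
        bins.setdefault(bin_id_for_record(rname, pos1, bin_size, ref), []).append(line)
    return bins, unmapped, excluded


def route_to_parts(
    bins: dict[BinID, list[str]],
    partition: GenomePartition,
    ref: ReferenceDict,
    compression_level: int = DEFAULT_COMPRESSION_LEVEL,
) -> dict[int, list[BinBlock]]:
    """Compress each bin and place its block in the genome part owning its
    chromosome; within each part blocks ascend by BinID.  Parts with no bins
    are absent from the result."""
    per_part: dict[int, list[BinBlock]] = {}
    for bin_id in sorted(bins):
        records = bins[bin_id]
        part = partition.part_of_ordinal(bin_id.chrom_ordinal, ref)
        block = BinBlock(bin_id, len(records), compress_bin(records, compression_level))
        per_part.setdefault(part, []).append(block)
    return per_part


def _open_sam_input(path: Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _stream_mapper_command(cmd: str, chunk_path: Path, ref_path: str | None) -> Iterator[str]:
    """Run an external mapper command and yield its stdout lines as SAM."""
    rendered = cmd.format(input=str(chunk_path), ref=ref_path or "")
    proc = subprocess.Popen(
        rendered,
        shell=True,
        stdout=subprocess.PIPE,
        stderr=subprocess.PIPE,
        text=True,
    )
    assert proc.stdout is not None
    try:
        yield from proc.stdout
    finally:
        _, stderr = proc.communicate()
        if proc.returncode != 0:
            raise MapperInvocationError(
                f"mapper command {rendered!r} exited with {proc.returncode}: "
                f"{stderr.strip()[:2000]}"
            )


def run_mapper_task(
    input_path: str | Path,
    config: MapperConfig,
    chunk_id: str | None = None,
) -> MapperTaskResult:
    """Run one mapping/binning task over a FASTQ chunk or a SAM file.

    In external-mapper mode (``config.mapper_cmd`` set) the input is a FASTQ
    chunk piped through the command template; in direct mode the input is a
    SAM file.  Writes, under ``config.out_dir``:

    * ``part<p>/<chunk_id>.sgb`` for every genome part with at least one bin,
    * ``<chunk_id>.binsinfo`` with the per-bin read counts,
    * ``unmapped/<chunk_id>.sam.gz`` when unmapped records exist and are kept.
    """
    input_path = Path(input_path)
    if chunk_id is None:
        chunk_id = input_path.name.split(".")[0]
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mapper_cmd:
        stream: Iterable[str] = _stream_mapper_command(
            config.mapper_cmd, input_path, config.ref_path
        )
        bins, unmapped, excluded = assign_records_to_bins(
            stream, config.bin_size, config.ref, config.exclude_secondary
        )
    else:
        with _open_sam_input(input_path) as fh:
            bins, unmapped, excluded = assign_records_to_bins(
                fh, config.bin_size, config.ref, config.exclude_secondary
            )

    partition = config.partition()
    per_part = route_to_parts(bins, partition, config.ref, config.compression_level)

    container_paths: dict[int, Path] = {}
    for part, blocks in sorted(per_part.items()):
        part_dir = out_dir / f"part{part}"
        part_dir.mkdir(exist_ok=True)
        path = part_dir / f"{chunk_id}.sgb"
        write_container(blocks, path)
        container_paths[part] = path

    info = BinsInfo({b: len(recs) for b, recs in bins.items()})
    info_path = out_dir / f"{chunk_id}.binsinfo"
    write_bins_info(info, info_path)

    if unmapped and config.keep_unmapped:
        unmapped_dir = out_dir / "unmapped"
        unmapped_dir.mkdir(exist_ok=True)
        with deterministic_gzip_writer(unmapped_dir / f"{chunk_id}.sam.gz") as fh:
            fh.write("\n".join(unmapped) + "\n")

    return MapperTaskResult(
        chunk_id=chunk_id,
        per_part_container_paths=container_paths,
        bins_info=info,
        unmapped_count=len(unmapped),
        bins_info_path=info_path,
        excluded_count=excluded,
    )
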