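"""Read-count-balanced region construction and per-region sorted output.

The load balancer turns the per-task bin statistics into *regions*:
contiguous runs of bins sized by read count rather than base-pair length, so
that each downstream variant-discovery task gets a comparable amount of
work.  The target size is ``total reads / num_regions`` (real-valued).  A
greedy sweep in BinID order adds whole bins to the current region and closes
it as soon as its cumulative count reaches the average; because every closed
region holds at least the average, at most ``num_regions`` regions can ever
be produced.

For each region the balancer then gathers that region's compressed blocks
from all mapper containers (without decompressing), decompresses, sorts by
(chromosome ordinal, POS, QNAME, FLAG), and writes a coordinate-sorted
SAM or BAM plus the BED file that restricts downstream tools to the
region's intervals.
"""
from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .bin_container import BinsInfo, decompress_bin, parse_bins_info, read_container
from .errors import (
    ConsistencyError,
    InputError,
    InvalidArgumentError,
)
from .genome_model import (
    BinID,
    DEFAULT_BIN_SIZE,
    ReferenceDict,
    bin_span,
    partition_genome,
)


@dataclass
class RegionsMap:
    """Total assignment of observed bins to contiguous, balanced region ids."""

    region_of: dict[BinID, int]
    num_regions_requested: int
    region_summaries: dict[int, tuple[BinID, BinID, int]]  # first, last, total reads

    @property
    def num_regions(self) -> int:
        return len(self.region_summaries)

    def bins_of_region(self, region_id: int) -> list[BinID]:
        if region_id not in self.region_summaries:
            raise InvalidArgumentError(f"unknown region id {region_id}")
        return sorted(b for b, r in self.region_of.items() if r == region_id)


def aggregate_bins_info(paths: Sequence[str | Path]) -> BinsInfo:
    """Sum per-bin read counts across per-task bins-info files."""
    if not paths:
        raise InvalidArgumentError("need at least one bins-info file")
    total = BinsInfo()
    for path in paths:
        total.merge(parse_bins_info(path))
    return total


def average_reads_per_region(info: BinsInfo, num_regions: int) -> float:
    """Target region size: total reads divided by the requested region count."""
    if num_regions < 1:
        raise InvalidArgumentError(f"num_regions must be >= 1, got {num_regions}")
    if len(info) == 0:
        raise InvalidArgumentError("bins-info is empty")
    return info.total() / num_regions


def make_regions_map(
    info: BinsInfo,
    num_regions: int,
    ref: ReferenceDict | None = None,
    split_at_chromosomes: bool = False,
) -> RegionsMap:
    """Greedy sweep assigning bins (in BinID order) to balanced regions.

    A bin always joins the current region; the region closes once its
    cumulative count reaches the average, so every region except possibly
    the last holds at least ``average`` reads and fewer than ``average +
    max bin count``.  Bins are atomic and never split.  With
    ``split_at_chromosomes`` a region additionally closes at every
    chromosome boundary (for downstream tools that cannot span references);
    this may create more than ``num_regions`` regions.
    """
    avg = average_reads_per_region(info, num_regions)
    region_of: dict[BinID, int] = {}
    summaries: dict[int, tuple[BinID, BinID, int]] = {}
    region = 0
    cum = 0
    first: BinID | None = None
    prev: BinID | None = None
    for bin_id, count in info.items_sorted():
        if (
            split_at_chromosomes
            and prev is not None
            and bin_id.chrom_ordinal != prev.chrom_ordinal
            and cum > 0
        ):
            summaries[region] = (first, prev, cum)  # type: ignore[assignment]
            region += 1
            cum = 0
            first = None
        if first is None:
            first = bin_id
        region_of[bin_id] = region
        cum += count
        prev = bin_id
        if cum >= avg:
            summaries[region] = (first, bin_id, cum)
            region += 1
            cum = 0
            first = None
    if cum > 0:
        summaries[region] = (first, prev, cum)  # type: ignore[assignment]
    return RegionsMap(
        region_of=region_of,
        num_regions_requested=num_regions,
        region_summaries=summaries,
    )


def extract_region_reads(
    container_paths: Sequence[str | Path],
    regions_map: RegionsMap,
) -> dict[int, list[bytes]]:
    """Group compressed payloads by region without decompressing them.

    Payload order within a region follows (container order, block order), so
    the result is deterministic for a fixed path list.
    """
    per_region: dict[int, list[bytes]] = {}
    for path in container_paths:
        for block in read_container(path):
            try:
                region = regions_map.region_of[block.bin]
            except KeyError:
                raise ConsistencyError(
                    f"container {path} holds bin {block.bin} absent from the regions map"
                ) from None
            per_region.setdefault(region, []).append(block.payload)
    return per_region


def _sort_key(line: str, ref: ReferenceDict):
    fields = line.split("\t", 4)
    return (ref.ordinal(fields[2]), int(fields[3]), fields[0], int(fields[1]))


def sort_sam_lines(lines: Iterable[str], ref: ReferenceDict) -> list[str]:
    """Coordinate sort: (chromosome ordinal, POS), QNAME then FLAG as tie-break."""
    return sorted(lines, key=lambda l: _sort_key(l, ref))


def make_region_bed(
    region_id: int,
    regions_map: RegionsMap,
    bin_size: int,
    ref: ReferenceDict,
) -> list[tuple[str, int, int]]:
    """BED intervals (0-based half-open) covering the region's bins.

    Adjacent bin spans on the same chromosome are merged; intervals never
    cross chromosomes.  Only observed bins contribute, so unobserved genome
    stretches inside a region's range are not padded in.
    """
    rows: list[tuple[str, int, int]] = []
    for bin_id in regions_map.bins_of_region(region_id):
        start0, end0 = bin_span(bin_id, bin_size, ref)
        chrom = ref.name_of(bin_id.chrom_ordinal)
        if rows and rows[-1][0] == chrom and rows[-1][2] == start0:
            rows[-1] = (chrom, rows[-1][1], end0)
        else:
            rows.append((chrom, start0, end0))
    return rows


def write_bed(rows: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in rows:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def build_region_files(
    region_id: int,
    payloads: Sequence[bytes],
    ref: ReferenceDict,
    out_dir: str | Path,
    emit_bam: bool = False,
    regions_map: RegionsMap | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    name: str | None = None,
) -> tuple[Path, Path, int]:
    """Decompress, sort and write one region's alignment file plus its BED.

    SAM output is plain text with an ``@HD SO:coordinate`` header; BAM output
    goes through pysam with the same header.  Returns (alignment path, BED
    path, record count).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name is None:
        name = f"region{region_id:04d}"

    lines: list[str] = []
    for payload in payloads:
        lines.extend(decompress_bin(payload))
    lines = sort_sam_lines(lines, ref)

    header_lines = ref.to_sam_header_lines(sort_order="coordinate")
    if emit_bam:
        aln_path = out_dir / f"{name}.bam"
        header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
        with pysam.AlignmentFile(str(aln_path), "wb", header=header) as bam:
            for line in lines:
                bam.write(pysam.AlignedSegment.fromstring(line, header))
    else:
        aln_path = out_dir / f"{name}.sam"
        with open(aln_path, "w") as fh:
            for hline in header_lines:
                fh.write(hline + "\n")
            for line in lines:
                fh.write(line + "\n")

    bed_path = out_dir / f"{name}.bed"
    if regions_map is not None:
        write_bed(make_region_bed(region_id, regions_map, bin_size, ref), bed_path)
    else:
        bed_path.write_text("")
    return aln_path, bed_path, len(lines)


@dataclass
class BalanceConfig:
    """Configuration for one load-balancing pass (one genome part)."""

    ref: ReferenceDict
    out_dir: Path
    bin_size: int = DEFAULT_BIN_SIZE
    num_parts: int = 1
    emit_bam: bool = False
    workers: int = 1
    split_at_chromosomes: bool = False


@dataclass
class RegionOutput:
    """One region's emitted files and bookkeeping."""

    part_id: int
    region_id: int
    alignment_path: Path
    bed_path: Path
    record_count: int


def run_load_balancing_step(
    mapper_out_dir: str | Path,
    part_id: int,
    num_regions: int,
    config: BalanceConfig,
) -> list[RegionOutput]:
    """Aggregate bin stats, build the regions map and emit per-region files
    for one genome part.

    Reads every ``*.binsinfo`` under ``mapper_out_dir`` (filtering to the
    part's chromosomes) and every container under
    ``mapper_out_dir/part<part_id>/``.  Regions are built concurrently by a
    thread pool of ``config.workers``; outputs are independent files so the
    result does not depend on worker count or completion order.
    """
    mapper_out_dir = Path(mapper_out_dir)
    info_paths = sorted(mapper_out_dir.glob("*.binsinfo"))
    if not info_paths:
        raise InputError(f"no bins-info files under {mapper_out_dir}")
    container_dir = mapper_out_dir / f"part{part_id}"
    container_paths = sorted(container_dir.glob("*.sgb"))
    if not container_paths:
        raise InputError(f"no containers under {container_dir}")

    info = aggregate_bins_info(info_paths)
    partition = partition_genome(config.ref, config.num_parts)
    part_chrom_ordinals = {
        config.ref.ordinal(name)
        for name, p in partition.part_of.items()
        if p == part_id
    }
    part_info = BinsInfo(
        {
            b: n
            for b, n in info.counts.items()
            if b.chrom_ordinal in part_chrom_ordinals
        }
    )
    if len(part_info) == 0:
        return []

    regions_map = make_regions_map(
        part_info, num_regions, config.ref, config.split_at_chromosomes
    )
    per_region = extract_region_reads(container_paths, regions_map)

    def build(region_id: int) -> RegionOutput:
        aln, bed, count = build_region_files(
            region_id,
            per_region.get(region_id, []),
            config.ref,
            config.out_dir,
            emit_bam=config.emit_bam,
            regions_map=regions_map,
            bin_size=config.bin_size,
            name=f"part{part_id}_region{region_id:04d}",
        )
        return RegionOutput(part_id, region_id, aln, bed, count)

    region_ids = sorted(regions_map.region_summaries)
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            outputs = list(pool.map(build, region_ids))
    else:
        outputs = [build(r) for r in region_ids]
    return outputs
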