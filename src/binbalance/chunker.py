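"""Interleaved FASTQ chunk segmentation with an atomic-visibility hand-off.

Paired-end input arrives as two (optionally gzipped) FASTQ files, one per
mate.  The chunker rewrites them as a sequence of *interleaved* chunks —
mate-1 record then mate-2 record, pair after pair — each holding a fixed
number of records.  Chunks are the unit of mapper parallelism.

Every chunk is written under a temporary name and atomically renamed to its
final ``chunk_<index>.fastq[.gz]`` name only once complete, so a consumer
polling the output directory never observes a partial chunk and mapping can
begin while chunking is still running.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

from ._ioutils import deterministic_gzip_writer, open_text_auto
from .errors import FastqParseError, InvalidArgumentError, PairingError

DEFAULT_READS_PER_CHUNK = 2_000_000


@dataclass
class ChunkSpec:
    """How to segment: records (not pairs) per chunk, destination, compression."""

    reads_per_chunk: int = DEFAULT_READS_PER_CHUNK
    output_dir: Path = Path(".")
    compress_output: bool = True

    def __post_init__(self):
        if self.reads_per_chunk < 2 or self.reads_per_chunk % 2 != 0:
            raise InvalidArgumentError(
                f"reads_per_chunk must be an even integer >= 2, got {self.reads_per_chunk}"
            )
        self.output_dir = Path(self.output_dir)

    @property
    def pairs_per_chunk(self) -> int:
        return self.reads_per_chunk // 2

    def chunk_name(self, index: int) -> str:
        suffix = ".fastq.gz" if self.compress_output else ".fastq"
        return f"chunk_{index:05d}{suffix}"


def _read_fastq_records(fh: IO[str], label: str) -> Iterator[list[str]]:
    """Yield 4-line FASTQ records, validating the @/+ structure."""
    index = 0
    while True:
        lines = [fh.readline() for _ in range(4)]
        if not lines[0]:
            return
        if any(not l for l in lines[1:]):
            raise FastqParseError(
                f"{label}: record {index} truncated (FASTQ records are 4 lines)"
            )
        lines = [l.rstrip("\n") for l in lines]
        if not lines[0].startswith("@"):
            raise FastqParseError(
                f"{label}: record {index} header does not start with '@': {lines[0]!r}"
            )
        if not lines[2].startswith("+"):
            raise FastqParseError(
                f"{label}: record {index} separator does not start with '+'"
            )
        yield lines
        index += 1


def iter_chunk_paths(
    r1_path: str | Path, r2_path: str | Path, spec: ChunkSpec
) -> Iterator[Path]:
    """Lazily write interleaved chunks, yielding each path once it is
    complete and visible under its final name.

    This is the streaming producer: a pipeline can map chunk *k* while chunk
    *k+1* is still being written.
    """
    spec.output_dir.mkdir(parents=True, exist_ok=True)
    with open_text_auto(r1_path) as f1, open_text_auto(r2_path) as f2:
        reads1 = _read_fastq_records(f1, str(r1_path))
        reads2 = _read_fastq_records(f2, str(r2_path))
        chunk_index = 0
        pairs_in_chunk = 0
        writer: IO[str] | None = None
        tmp_path: Path | None = None
        final_path: Path | None = None

        def open_chunk() -> None:
            nonlocal writer, tmp_path, final_path
            final_path = spec.output_dir / spec.chunk_name(chunk_index)
            # temp name starts with '.' so it never matches the chunk_* pattern
            tmp_path = spec.output_dir / f".{final_path.name}.tmp"
            if spec.compress_output:
                writer = deterministic_gzip_writer(tmp_path)
            else:
                writer = open(tmp_path, "w")

        def close_chunk() -> Path:
            nonlocal writer
            assert writer is not None and tmp_path is not None and final_path is not None
            writer.close()
            writer = None
            os.replace(tmp_path, final_path)
            return final_path

        try:
            for pair_index, rec1 in enumerate(reads1):
                rec2 = next(reads2, None)
                if rec2 is None:
                    raise PairingError(
                        f"mate-2 input ended at pair {pair_index}; mate-1 has more records"
                    )
                if writer is None:
                    open_chunk()
                assert writer is not None
                writer.write("\n".join(rec1) + "\n")
                writer.write("\n".join(rec2) + "\n")
                pairs_in_chunk += 1
                if pairs_in_chunk == spec.pairs_per_chunk:
                    yield close_chunk()
                    chunk_index += 1
                    pairs_in_chunk = 0
            if next(reads2, None) is not None:
                raise PairingError(
                    "mate-1 input ended first; mate-2 has more records"
                )
            if writer is not None and pairs_in_chunk > 0:
                yield close_chunk()
        finally:
            if writer is not None:
                writer.close()
                if tmp_path is not None and tmp_path.exists():
                    tmp_path.unlink()


def chunk_paired_fastq(
    r1_path: str | Path, r2_path: str | Path, spec: ChunkSpec
) -> list[Path]:
    """Segment a FASTQ pair into interleaved chunks; returns the chunk paths
    in order.  The final chunk may hold fewer than ``reads_per_chunk`` records."""
    return list(iter_chunk_paths(r1_path, r2_path, spec))


def _base_name(header: str) -> str:
    """Read name with any mate designator removed (``/1``, ``/2`` or a
    trailing space-separated token)."""
    name = header[1:].split()[0] if len(header) > 1 else ""
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def verify_interleaving(chunk_path: str | Path) -> bool:
    """True iff records alternate mate-1 / mate-2 with matching base names."""
    try:
        with open_text_auto(chunk_path) as fh:
            records = list(_read_fastq_records(fh, str(chunk_path)))
    except (FastqParseError, OSError):
        return False
    if len(records) % 2 != 0:
        return False
    for i in range(0, len(records), 2):
        h1, h2 = records[i][0], records[i + 1][0]
        if _base_name(h1) != _base_name(h2):
            return False
        n1, n2 = h1[1:].split()[0], h2[1:].split()[0]
        if n1.endswith("/2") or n2.endswith("/1"):
            return False
    return True
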