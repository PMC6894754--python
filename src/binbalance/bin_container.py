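"""Compressed intermediate-data container (``.sgb``) and bins-info sidecar.

A container file holds, per bin, a block of DEFLATE-compressed SAM record
text together with the bin identity, its read count and the payload length,
so a later pass can route whole blocks to regions without decompressing
them.  Layout (all integers little-endian):

    magic ``SGB2`` (4 bytes) | format version (1 byte, currently 1)
    then per block:
        chrom_ordinal  u32
        bin_index      u32
        num_reads      u32
        payload_length u64
        payload        ``payload_length`` bytes (raw DEFLATE/zlib stream)

End of file terminates the block sequence.  Blocks are stored in ascending
BinID order.  The bins-info sidecar is plain text, one
``<chrom_ordinal>_<bin_index>:<num_reads>`` line per bin; it is what the
load balancer aggregates before any container is opened.
"""
from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import (
    BinsInfoParseError,
    ContainerCorruptionError,
    ContainerFormatError,
    InvalidArgumentError,
)
from .genome_model import BinID

MAGIC = b"SGB2"
FORMAT_VERSION = 1
DEFAULT_COMPRESSION_LEVEL = 1

_BLOCK_HEADER = struct.Struct("<IIIQ")


@dataclass(frozen=True)
class BinBlock:
    """One container entry: a bin's compressed SAM lines plus its read count."""

    bin: BinID
    num_reads: int
    payload: bytes

    def __post_init__(self):
        if self.num_reads < 0:
            raise InvalidArgumentError("num_reads must be >= 0")

    def decompress(self) -> list[str]:
        return decompress_bin(self.payload)


@dataclass
class BinsInfo:
    """Associative map BinID -> read count (the per-task bin statistics)."""

    counts: dict[BinID, int] = field(default_factory=dict)

    def add(self, bin: BinID, n: int) -> None:
        self.counts[bin] = self.counts.get(bin, 0) + n

    def merge(self, other: "BinsInfo") -> None:
        for b, n in other.counts.items():
            self.add(b, n)

    def total(self) -> int:
        return sum(self.counts.values())

    def items_sorted(self) -> list[tuple[BinID, int]]:
        return sorted(self.counts.items())

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, bin: BinID) -> int:
        return self.counts[bin]

    def __contains__(self, bin: BinID) -> bool:
        return bin in self.counts

    def __eq__(self, other) -> bool:
        return isinstance(other, BinsInfo) and self.counts == other.counts


def compress_bin(records: Sequence[str], level: int = DEFAULT_COMPRESSION_LEVEL) -> bytes:
    """DEFLATE-compress SAM record lines (joined by ``\\n``, trailing newline).

    Deterministic for a fixed level; the default level 1 favours speed, as
    the compression happens on the fly in the hot mapping path.
    """
    if not records:
        raise InvalidArgumentError("cannot compress an empty record list")
    if not -1 <= level <= 9:
        raise InvalidArgumentError(f"compression level {level} outside zlib range -1..9")
    raw = ("\n".join(r.rstrip("\n") for r in records) + "\n").encode()
    return zlib.compress(raw, level)


def decompress_bin(payload: bytes) -> list[str]:
    """Inverse of :func:`compress_bin`: the original lines in original order."""
    try:
        raw = zlib.decompress(payload)
    except zlib.error as exc:
        raise ContainerCorruptionError(f"undecodable payload: {exc}") from exc
    text = raw.decode()
    if not text.endswith("\n"):
        raise ContainerCorruptionError("payload does not end with a newline")
    return text[:-1].split("\n")


def write_container(blocks: Iterable[BinBlock], path: str | Path) -> int:
    """Write blocks (ascending BinID order required) to ``path``; returns the count."""
    path = Path(path)
    blocks = list(blocks)
    for prev, cur in zip(blocks, blocks[1:]):
        if not prev.bin < cur.bin:
            raise InvalidArgumentError(
                f"blocks out of order: {prev.bin} followed by {cur.bin}"
            )
    try:
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(bytes([FORMAT_VERSION]))
            for blk in blocks:
                fh.write(
                    _BLOCK_HEADER.pack(
                        blk.bin.chrom_ordinal,
                        blk.bin.bin_index,
                        blk.num_reads,
                        len(blk.payload),
                    )
                )
                fh.write(blk.payload)
    except OSError as exc:
        raise OSError(f"writing container {path}: {exc}") from exc
    return len(blocks)


def read_container(path: str | Path) -> Iterator[BinBlock]:
    """Lazily yield blocks in stored order; payloads are NOT decompressed."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(5)
        if len(head) < 5 or head[:4] != MAGIC:
            raise ContainerFormatError(f"{path}: bad magic, not an SGB2 container")
        if head[4] != FORMAT_VERSION:
            raise ContainerFormatError(
                f"{path}: unsupported format version {head[4]}"
            )
        offset = 5
        while True:
            header = fh.read(_BLOCK_HEADER.size)
            if not header:
                return
            if len(header) < _BLOCK_HEADER.size:
                raise ContainerCorruptionError(
                    f"{path}: truncated block header at byte {offset}"
                )
            chrom_ordinal, bin_index, num_reads, payload_len = _BLOCK_HEADER.unpack(header)
            payload = fh.read(payload_len)
            if len(payload) < payload_len:
                raise ContainerCorruptionError(
                    f"{path}: truncated payload at byte {offset + _BLOCK_HEADER.size} "
                    f"(expected {payload_len} bytes, got {len(payload)})"
                )
            yield BinBlock(BinID(chrom_ordinal, bin_index), num_reads, payload)
            offset += _BLOCK_HEADER.size + payload_len


def write_bins_info(info: BinsInfo, path: str | Path) -> None:
    """One ``<chrom_ordinal>_<bin_index>:<count>`` line per bin, BinID order."""
    with open(path, "w") as fh:
        for bin, count in info.items_sorted():
            fh.write(f"{bin}:{count}\n")


def parse_bins_info(path: str | Path) -> BinsInfo:
    info = BinsInfo()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            key, sep, value = line.partition(":")
            try:
                if not sep:
                    raise ValueError("missing ':' separator")
                info.add(BinID.from_string(key), int(value))
            except (ValueError, InvalidArgumentError) as exc:
                raise BinsInfoParseError(f"{path}:{lineno}: {exc}") from exc
    return info
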