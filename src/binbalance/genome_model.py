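"""Genomic coordinate model: reference dictionary, fixed-width bins, genome parts.

The unit of all downstream bookkeeping is the *bin*: a fixed-width window of
one chromosome (default width 5000 bp).  Bin indices are 1-based and defined
on 0-based positions, so with a width of 5000 bin 1 of a chromosome covers
0-based positions 0..4999 and bin 2 covers 5000..9999.  SAM POS is 1-based;
:func:`bin_id_for_record` converts with ``POS - 1`` before binning.

Chromosome *ordinals* follow the order of the reference dictionary (the SAM
header convention), not lexicographic name order.  A :class:`GenomePartition`
assigns whole chromosomes to a small number of *parts*: a coarse split used
to bound the memory of a single load-balancing pass.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    CoordinateError,
    InvalidArgumentError,
    UnknownReferenceError,
)

DEFAULT_BIN_SIZE = 5000


@dataclass(frozen=True)
class ReferenceDict:
    """Ordered chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    chromosomes:
        Sequence of ``(name, length)`` pairs in reference order.  Names must
        be unique and non-empty; lengths must be >= 1.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _ordinal: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if not chroms:
            raise InvalidArgumentError("reference dictionary must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("chromosome names must be unique")
        for name, length in chroms:
            if not name:
                raise InvalidArgumentError("chromosome names must be non-empty")
            if length < 1:
                raise InvalidArgumentError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_ordinal", {n: i for i, (n, _) in enumerate(chroms)})

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def ordinal(self, name: str) -> int:
        """0-based position of ``name`` in reference order."""
        try:
            return self._ordinal[name]
        except KeyError:
            raise UnknownReferenceError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._ordinal

    def name_of(self, ordinal: int) -> str:
        if not 0 <= ordinal < len(self.chromosomes):
            raise UnknownReferenceError(f"chromosome ordinal {ordinal} out of range")
        return self.chromosomes[ordinal][0]

    def length_of(self, name_or_ordinal: str | int) -> int:
        if isinstance(name_or_ordinal, int):
            return self.chromosomes[name_or_ordinal][1]
        return self.chromosomes[self.ordinal(name_or_ordinal)][1]

    def num_bins(self, ordinal: int, bin_size: int) -> int:
        """Number of bins tiling chromosome ``ordinal`` at width ``bin_size``."""
        length = self.length_of(ordinal)
        return -(-length // bin_size)

    # ---- construction from standard formats -------------------------------

    @classmethod
    def from_sam_header(cls, source: str | Path) -> "ReferenceDict":
        """Read ``@SQ`` lines (``SN``/``LN`` tags) from a SAM file or header text."""
        if isinstance(source, Path) or "\n" not in str(source) and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        chroms: list[tuple[str, int]] = []
        for line in text.splitlines():
            if not line.startswith("@SQ"):
                continue
            tags = dict(
                f.split(":", 1) for f in line.rstrip("\n").split("\t")[1:] if ":" in f
            )
            if "SN" not in tags or "LN" not in tags:
                raise InvalidArgumentError(f"@SQ line missing SN or LN tag: {line!r}")
            chroms.append((tags["SN"], int(tags["LN"])))
        if not chroms:
            raise InvalidArgumentError("no @SQ lines found in SAM header")
        return cls(chroms)

    @classmethod
    def from_fai(cls, path: str | Path) -> "ReferenceDict":
        """Read a FASTA index (``samtools faidx`` .fai): tab-separated name, length, ..."""
        opener = gzip.open if str(path).endswith(".gz") else open
        chroms: list[tuple[str, int]] = []
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise InvalidArgumentError(
                        f"{path}:{lineno}: expected >=2 tab-separated fields"
                    )
                chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    def to_sam_header_lines(self, sort_order: str | None = None) -> list[str]:
        """SAM header lines (``@HD`` + ``@SQ``) for this dictionary."""
        lines = []
        hd = "@HD\tVN:1.6"
        if sort_order:
            hd += f"\tSO:{sort_order}"
        lines.append(hd)
        lines.extend(f"@SQ\tSN:{n}\tLN:{l}" for n, l in self.chromosomes)
        return lines


@dataclass(frozen=True, order=True)
class BinID:
    """Key of one fixed-width genomic bin: (chromosome ordinal, 1-based bin index).

    Total order is lexicographic on ``(chrom_ordinal, bin_index)``, which is
    genome coordinate order.
    """

    chrom_ordinal: int
    bin_index: int

    def __post_init__(self):
        if self.chrom_ordinal < 0:
            raise InvalidArgumentError(f"chrom_ordinal must be >= 0, got {self.chrom_ordinal}")
        if self.bin_index < 1:
            raise InvalidArgumentError(f"bin_index must be >= 1, got {self.bin_index}")

    def __str__(self) -> str:
        return f"{self.chrom_ordinal}_{self.bin_index}"

    @classmethod
    def from_string(cls, s: str) -> "BinID":
        chrom, _, idx = s.partition("_")
        return cls(int(chrom), int(idx))


@dataclass(frozen=True)
class GenomePartition:
    """Assignment of whole chromosomes to ``num_parts`` memory parts."""

    num_parts: int
    part_of: Mapping[str, int]

    def part_of_ordinal(self, ordinal: int, ref: ReferenceDict) -> int:
        return self.part_of[ref.name_of(ordinal)]

    def chromosomes_of_part(self, part: int) -> list[str]:
        return [name for name, p in self.part_of.items() if p == part]


def bin_index(pos0: int, bin_size: int) -> int:
    """1-based bin index of a 0-based leftmost position.

    ``bin_index(5000, 5000) == 2`` and ``bin_index(4999, 5000) == 1``: bin 1
    covers 0-based positions ``0..bin_size-1``.
    """
    if bin_size < 1:
        raise InvalidArgumentError(f"bin_size must be >= 1, got {bin_size}")
    if pos0 < 0:
        raise InvalidArgumentError(f"position must be >= 0, got {pos0}")
    return pos0 // bin_size + 1


def bin_id_for_record(
    chrom_name: str, pos1: int, bin_size: int, ref: ReferenceDict
) -> BinID:
    """BinID of a SAM record from its RNAME and 1-based POS.

    SAM POS is 1-based; the bin grid is defined on 0-based positions, so the
    record is binned at ``pos1 - 1``.
    """
    ordinal = ref.ordinal(chrom_name)
    length = ref.length_of(ordinal)
    if not 1 <= pos1 <= length:
        raise CoordinateError(
            f"POS {pos1} outside chromosome {chrom_name!r} of length {length}"
        )
    return BinID(ordinal, bin_index(pos1 - 1, bin_size))


def bin_span(bin: BinID, bin_size: int, ref: ReferenceDict) -> tuple[int, int]:
    """0-based half-open interval ``[start0, end0)`` covered by ``bin``.

    The last bin of a chromosome is clipped at the chromosome length.
    """
    length = ref.length_of(bin.chrom_ordinal)
    start0 = (bin.bin_index - 1) * bin_size
    if start0 >= length:
        raise CoordinateError(
            f"bin {bin} starts at {start0}, beyond chromosome length {length}"
        )
    return start0, min(bin.bin_index * bin_size, length)


def partition_genome(ref: ReferenceDict, num_parts: int) -> GenomePartition:
    """Assign whole chromosomes to ``num_parts`` parts, balancing base-pair load.

    Greedy longest-first bin packing: chromosomes are taken in decreasing
    length (ties keep reference order) and each is placed on the currently
    lightest part (ties broken by lower part id).  Deterministic and
    independent of the input ordering of equal-length chromosomes only up to
    their reference order, which is itself fixed.
    """
    if num_parts < 1:
        raise InvalidArgumentError(f"num_parts must be >= 1, got {num_parts}")
    if num_parts > len(ref):
        raise InvalidArgumentError(
            f"num_parts={num_parts} exceeds number of chromosomes ({len(ref)})"
        )
    loads = [0] * num_parts
    part_of: dict[str, int] = {}
    by_length = sorted(ref.chromosomes, key=lambda c: -c[1])
    for name, length in by_length:
        lightest = min(range(num_parts), key=lambda p: (loads[p], p))
        part_of[name] = lightest
        loads[lightest] += length
    # preserve reference order in the mapping for readable reprs
    ordered = {name: part_of[name] for name, _ in ref.chromosomes}
    return GenomePartition(num_parts=num_parts, part_of=ordered)


def bins_of_chromosome(ordinal: int, bin_size: int, ref: ReferenceDict) -> list[BinID]:
    """All BinIDs tiling one chromosome, in order."""
    return [BinID(ordinal, i) for i in range(1, ref.num_bins(ordinal, bin_size) + 1)]
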