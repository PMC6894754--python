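"""Synthetic references, mapped reads and FASTQ pairs for end-to-end testing.

The generator emulates the one property of real resequencing data that the
balancing method exists for: *skewed* per-position coverage.  Length-based
genome partitioning assumes roughly uniform coverage; real libraries pile
reads onto hotspots, making some equal-length regions far heavier than
others.  :class:`CoverageProfile` expresses this as a base sampling weight
per bin plus hotspot multipliers.

Read content is placeholder sequence (fixed bases, uniform quality): mapping
fidelity is irrelevant to the partitioning machinery under test, which only
looks at coordinates.  CIGARs are ``<read_len>M`` and FLAGs are drawn from a
small valid set.  All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._ioutils import deterministic_gzip_writer
from .bin_container import BinsInfo
from .errors import InvalidArgumentError
from .genome_model import (
    BinID,
    DEFAULT_BIN_SIZE,
    ReferenceDict,
    bins_of_chromosome,
    bin_span,
)


@dataclass
class CoverageProfile:
    """Per-bin sampling weights: uniform ``base_rate`` plus hotspot multipliers.

    ``base_rate`` is the mean number of reads per bin a uniform library
    would give (only the *relative* weights matter for sampling; the total
    read count is set separately).  Each hotspot scales one bin's weight by
    its multiplier, concentrating coverage there.
    """

    base_rate: float = 1.0
    hotspots: Sequence[tuple[BinID, float]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if not self.base_rate > 0:
            raise InvalidArgumentError(f"base_rate must be > 0, got {self.base_rate}")
        for bin_id, mult in self.hotspots:
            if not (np.isfinite(mult) and mult >= 1):
                raise InvalidArgumentError(
                    f"hotspot multiplier for {bin_id} must be finite and >= 1, got {mult}"
                )


def make_reference(
    num_chroms: int,
    lengths: Sequence[int] | tuple[int, int] | None = None,
    seed: int = 0,
    fai_path: str | Path | None = None,
) -> ReferenceDict:
    """Build a deterministic reference dictionary named ``chr1..chrN``.

    ``lengths`` is either an explicit per-chromosome list or a
    ``(low, high)`` range sampled uniformly per chromosome; default range is
    50_000..200_000 bases, enough for a few dozen bins per chromosome.
    Optionally writes a ``.fai``-style index file.
    """
    if num_chroms < 1:
        raise InvalidArgumentError(f"num_chroms must be >= 1, got {num_chroms}")
    if lengths is None:
        lengths = (50_000, 200_000)
    if isinstance(lengths, tuple) and len(lengths) == 2 and num_chroms != 2:
        low, high = lengths
        rng = np.random.default_rng(seed)
        sizes = rng.integers(low, high + 1, size=num_chroms).tolist()
    elif len(lengths) == num_chroms:
        sizes = [int(l) for l in lengths]
    else:
        low, high = lengths  # 2 chromosomes with a 2-tuple: treat as range
        rng = np.random.default_rng(seed)
        sizes = rng.integers(low, high + 1, size=num_chroms).tolist()
    for size in sizes:
        if size < 1:
            raise InvalidArgumentError(f"chromosome lengths must be >= 1, got {size}")
    ref = ReferenceDict([(f"chr{i + 1}", sizes[i]) for i in range(num_chroms)])
    if fai_path is not None:
        with open(fai_path, "w") as fh:
            offset = 0
            for name, length in ref.chromosomes:
                # offset/linebases/linewidth are synthesized for a 60-column FASTA
                fh.write(f"{name}\t{length}\t{offset + len(name) + 2}\t60\t61\n")
                offset += len(name) + 2 + length + length // 60 + 1
    return ref


def _bin_weights(
    ref: ReferenceDict, profile: CoverageProfile, bin_size: int
) -> tuple[list[BinID], np.ndarray]:
    all_bins: list[BinID] = []
    for ordinal in range(len(ref)):
        all_bins.extend(bins_of_chromosome(ordinal, bin_size, ref))
    weights = np.full(len(all_bins), float(profile.base_rate))
    index = {b: i for i, b in enumerate(all_bins)}
    for bin_id, mult in profile.hotspots:
        if bin_id not in index:
            raise InvalidArgumentError(f"hotspot bin {bin_id} does not exist in reference")
        weights[index[bin_id]] *= mult
    return all_bins, weights


def simulate_mapped_reads(
    ref: ReferenceDict,
    profile: CoverageProfile,
    n: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    read_len: int = 100,
    n_unmapped: int = 0,
    with_header: bool = True,
) -> tuple[list[str], BinsInfo]:
    """Simulate ``n`` coordinate-mapped SAM records with bin-weighted positions.

    Each record's bin is drawn with probability proportional to the profile
    weight, then its 1-based POS uniformly within the bin (clipped to the
    chromosome).  Returns the SAM lines (header first when ``with_header``)
    and the exact realized per-bin counts as ground truth.  ``n_unmapped``
    additional unmapped records (FLAG 4, RNAME ``*``) are appended
    interleaved at the end of the stream.
    """
    if n < 0 or n_unmapped < 0:
        raise InvalidArgumentError("record counts must be >= 0")
    rng = np.random.default_rng(profile.seed)
    all_bins, weights = _bin_weights(ref, profile, bin_size)
    probs = weights / weights.sum()

    lines: list[str] = []
    if with_header:
        lines.extend(ref.to_sam_header_lines())

    truth = BinsInfo()
    seq = "A" * read_len
    qual = "I" * read_len
    cigar = f"{read_len}M"
    if n > 0:
        choices = rng.choice(len(all_bins), size=n, p=probs)
        offsets = rng.integers(0, bin_size, size=n)
        strands = rng.integers(0, 2, size=n)
        for i in range(n):
            bin_id = all_bins[int(choices[i])]
            start0, end0 = bin_span(bin_id, bin_size, ref)
            pos1 = start0 + int(offsets[i]) % (end0 - start0) + 1
            flag = 16 if strands[i] else 0
            chrom = ref.name_of(bin_id.chrom_ordinal)
            lines.append(
                f"read{i:08d}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
            )
            truth.add(bin_id, 1)
    for j in range(n_unmapped):
        lines.append(
            f"unmapped{j:06d}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}"
        )
    return lines, truth


def write_sam(lines: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return path


def simulate_fastq_pairs(
    n_pairs: int,
    read_len: int,
    seed: int,
    out_r1: str | Path,
    out_r2: str | Path,
    compress: bool = True,
) -> int:
    """Write a deterministic gzipped FASTQ mate pair; returns the pair count.

    Read names are ``pair<index>/1`` and ``pair<index>/2``; sequence bases
    are drawn uniformly so chunk payloads are not trivially compressible.
    """
    if n_pairs < 0:
        raise InvalidArgumentError(f"n_pairs must be >= 0, got {n_pairs}")
    if read_len < 1:
        raise InvalidArgumentError(f"read_len must be >= 1, got {read_len}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    qual = "I" * read_len

    def open_out(path):
        if compress:
            return deterministic_gzip_writer(path)
        return open(path, "w")

    with open_out(out_r1) as f1, open_out(out_r2) as f2:
        for i in range(n_pairs):
            s1 = "".join(bases[rng.integers(0, 4, size=read_len)])
            s2 = "".join(bases[rng.integers(0, 4, size=read_len)])
            f1.write(f"@pair{i:07d}/1\n{s1}\n+\n{qual}\n")
            f2.write(f"@pair{i:07d}/2\n{s2}\n+\n{qual}\n")
    return n_pairs
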