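# Methods

## Coordinate model

All bookkeeping is done on *bins*: fixed-width windows of one chromosome,
default width 5000 bp.  Bin indices are 1-based on a 0-based position grid:
bin *k* of a chromosome covers 0-based positions
`[(k-1)·w, k·w)`, clipped at the chromosome end.  SAM `POS` is 1-based, so a
record is binned at `POS − 1`; this conversion happens in exactly one place
(`bin_id_for_record`) and everything downstream works in 0-based half-open
coordinates (the BED convention).  A record is binned by its own `POS` only;
the mate's position never influences placement, since the downstream tools
re-pair within regions anyway.

Chromosome *ordinals* come from the order of the reference dictionary (SAM
`@SQ` order), not name sorting, so `(ordinal, bin index)` is genome
coordinate order.  The dictionary can be read from `@SQ` header lines or a
`.fai` index; no FASTA sequence is ever parsed.

The bin width default of 5000 bp balances two pressures: wide bins shrink
the bins-info sidecar (a few MB for a human genome) but coarsen the units
the balancer can move, narrow bins do the opposite.  It is configurable
everywhere (`--bin-size`).

## Container format

Intermediate mapped reads are held as per-bin DEFLATE blocks in a `.sgb`
file: magic `SGB2`, a version byte, then per block `chrom_ordinal` (u32 LE),
`bin_index` (u32 LE), `num_reads` (u32 LE), `payload_length` (u64 LE) and
the raw zlib stream of the bin's SAM lines.  Headers are interleaved with
payloads (no index footer) so the file can be produced in one streaming
pass and consumed lazily: the balancer routes whole blocks to regions
without inflating them.  Blocks within a file ascend by bin id.  Integrity
relies on the zlib checksum plus explicit length fields; truncation is
reported with the byte offset.

Compression level defaults to 1: the codec runs on the fly in the mapping
hot path, where speed matters far more than ratio, and redundant SAM text
already halves (typically much better) at the lowest level.  The level is a
parameter of the writer, and byte-determinism holds per level, so re-runs
are byte-identical.

Unmapped records (FLAG 0x4 or RNAME `*`) never enter bins.  They are
counted and, by default, preserved as gzip-compressed SAM text
(`unmapped/<chunk>.sam.gz`) rather than as container blocks — a container
block requires a genuine bin identity, which unmapped records do not have.
Secondary and supplementary alignments are binned like primary records by
default (duplicate handling belongs to the downstream tools); a switch
excludes them.

## Region construction

Let `c_1..c_B` be the aggregated per-bin read counts in genome order and
`avg = Σc / R_requested` (real division).  The greedy sweep adds bin *i* to
the current region and closes the region once its cumulative count reaches
`avg`; trailing bins form a final region even if light.  Properties, each
asserted over randomized workloads in the test suite:

* every closed region holds ≥ `avg` reads, hence at most
  `⌊Σc / avg⌋ = R_requested` closed regions can exist; with the possible
  light tail this still gives `R ≤ R_requested` (if a tail exists, the
  closed regions hold strictly less than `Σc`, so there are at most
  `R_requested − 1` of them);
* every region holds `< avg + max_i c_i` reads — an overshooting bin joins
  the *current* region rather than opening the next, which is what makes
  the upper bound and the `R ≤ R_requested` guarantee hold simultaneously;
* regions are contiguous runs in genome order, so per-region sorted outputs
  concatenate into a globally sorted stream;
* increasing `R_requested` never decreases the realized region count.

Bins with zero observed reads are absent from the statistics and belong to
no region; BED output therefore omits unobserved stretches, which is
correct for tools that only need to be told where reads exist.  Regions may
span chromosome boundaries (the BED keeps downstream tools honest);
`--split-at-chromosomes` forces closure at chromosome ends for tools that
cannot accept multi-chromosome interval lists, at the cost of possibly
exceeding the requested region count.

Sorting is by `(chromosome ordinal, POS)` with `(QNAME, FLAG)` as an
invented but fixed tie-break: the tie-break carries no semantics, it exists
solely so that independently produced outputs are byte-comparable.

## Genome parts

To bound the memory of one balancing pass, whole chromosomes can be
assigned to `num_parts` groups by greedy longest-first packing on
chromosome length (each chromosome goes to the lightest part so far; the
greedy bound `max load − min load ≤ longest chromosome` is asserted in
tests).  The mapper then writes one container per (chunk, part) and the
balancer runs once per part, seeing only that part's blocks.  Because parts
are unions of whole chromosomes and regions never mix parts, the union of
all parts' outputs is record-identical to a single-part run — verified as a
multiset equality in the acceptance suite.  Parts are processed
sequentially (that is the point: only one part's data is in flight),
regions within a part concurrently.

## Chunking and streaming hand-off

Paired FASTQ is rewritten as interleaved chunks (R1 record then R2 record)
of a fixed record count, default 2,000,000 records (1,000,000 pairs) —
large enough that an external mapper invocation amortizes its startup, small
enough for good scheduling granularity; tests use tiny values.  Each chunk
is written under a dot-prefixed temporary name and `os.replace`d into its
final `chunk_<index>.fastq.gz` name only when complete.  That rename is the
whole streaming contract: a consumer polling the directory either sees a
complete chunk or nothing, so mapping can start while chunking continues.
The pipeline exploits this by submitting each mapper task the moment its
chunk is yielded.  Gzip members are written with `mtime=0` and no embedded
filename so identical inputs produce byte-identical chunks.

## Execution model

Execution follows an explicit independent-task contract on a local thread
pool rather than a cluster runtime: mapper tasks are
independent over chunks, region builds over regions, each task writes only
files named by its own id, and all hand-off is via the work directory.
Consequently results are invariant to worker count and completion order
(asserted by comparing 1-worker and 4-worker runs).  Worker threads are
appropriate because the heavy inner loops (zlib, pysam) release the GIL or
are I/O bound; nothing in the contract precludes a process pool.

## Synthetic data

The generator emulates the single property the balancer exists for: skewed
coverage.  Bin sampling weights are uniform (`base_rate`) with hotspot
multipliers; positions are uniform within the sampled bin; the realized
per-bin counts are returned as ground truth and must agree exactly with the
binning module's output on the generated stream (a self-consistency oracle
run across seeds).  Read content is deliberately unrealistic — fixed-base
or uniform-random sequence, `<len>M` CIGARs, FLAGs limited to
{0, 16, unmapped} — because the machinery under test reads only
coordinates.  Passing tests therefore demonstrate correct partitioning,
sorting, conservation and format round-trips on coordinate-realistic data;
they say nothing about mapper behaviour, indel handling, or variant-calling
accuracy, which live behind the external command hooks.

Test problem sizes are chosen to exercise the interesting regimes while
keeping the suite quick: up to 10⁵ records end-to-end, 500 random workload
profiles of up to 5000 bins for the balance bounds, 1000 random container
round trips.

## Degenerate inputs and numerical choices

* Empty SAM input → empty containers are valid (5-byte file), zero regions.
* A single bin heavier than `avg` forms its own region (never split).
* `num_regions = 1` reproduces a global coordinate sort.
* The per-region average uses real division; integer division would
  systematically overfill early regions when `Σc` is not divisible.
* Empty regions (possible only via an inconsistent container set) still
  write header-only SAM and empty BED files rather than failing.
* VCF combination keeps the first file's meta-lines, requires identical
  column headers, and concatenates data lines in region order — regions are
  disjoint and genome-ordered, so no re-sort is needed.

## Known limitations

* No CRAM input/output; SAM validation stops at field count and coordinate
  range, trusting the mapper for the rest.
* The bins-info sidecar is per-task and re-aggregated at balance time;
  there is no incremental merge for very large task counts.
* BED emission reflects observed bins only; tools that require gap-free
  interval coverage need the region spans padded externally.
* Single-node execution only: the worker pool replaces a cluster scheduler,
  and no distributed filesystem abstraction is provided.
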