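# binbalance

Read-count-balanced scatter/gather partitioning of mapped reads for
parallel variant-calling pipelines.

## The problem

Variant discovery over a whole human genome is embarrassingly parallel *if*
the genome can be cut into pieces of comparable work.  Cutting by base-pair
length fails in practice: sequencing coverage is skewed, so equal-length
regions carry very different numbers of reads and the whole run waits on the
heaviest one.  `binbalance` implements the alternative: partition by **read
count**, measured cheaply at mapping time, so every downstream task (mark
duplicates, recalibration, haplotype calling) receives a near-equal share of
records.

The pipeline runs in three steps:

1. **Mapping & binning.**  Paired-end FASTQ is segmented into interleaved
   chunks; each chunk is mapped (by an external mapper such as `bwa mem`,
   invoked as a command template) and the resulting SAM records are grouped
   into fixed-width genomic *bins* (default 5000 bp).  With bin size *w*, a
   record with 0-based leftmost position *p* lands in bin
   ⌊*p*/*w*⌋ + 1, so bin 1 of a chromosome covers positions 0..4999 and
   bin 2 covers 5000..9999.  Each bin is DEFLATE-compressed and written as
   one block of a `.sgb` container (bin id, read count, payload length,
   payload), one container per chunk, plus a plain-text `binsinfo` sidecar of
   per-bin read counts.
2. **Load balancing & sorting.**  The sidecars are aggregated
   (`Σ` per bin across tasks), the per-region target is
   `avg = total_reads / num_regions`, and a greedy sweep in genome order
   assigns whole bins to the current region until its cumulative count
   reaches `avg`, then opens the next.  Every closed region holds ≥ `avg`
   reads, which guarantees at most `num_regions` regions.  Each region's
   blocks are then pulled from all containers (still compressed), inflated,
   coordinate-sorted, and written as a sorted SAM/BAM plus the BED file that
   restricts downstream tools to that region.
3. **Variant discovery & combination.**  An opaque per-region command
   (template with `{bam}`, `{bed}`, `{out}`) produces per-region VCFs, which
   are concatenated under a single header in genome order.

A *genome-part* switch trades memory for a little runtime: chromosomes can
be split into `num_parts` groups, step 2 then runs once per part on a
fraction of the data.  Outputs are invariant to the number of parts.

## Worked example

Simulate a skew-covered read set, bin it, and build four balanced regions:

```
$ binbalance simulate -o syn --num-reads 10000 --seed 7
syn/reads.sam: 10000 records over 99 bins
$ binbalance map syn/reads.sam --ref-dict syn/ref.fai -o mapper_out
reads: 10000 mapped in 99 bins, 0 unmapped
$ binbalance balance mapper_out --ref-dict syn/ref.fai -o regions --num-regions 4
regions/part0_region0000.sam	regions/part0_region0000.bed	2519
regions/part0_region0001.sam	regions/part0_region0001.bed	2523
regions/part0_region0002.sam	regions/part0_region0002.bed	2504
regions/part0_region0003.sam	regions/part0_region0003.bed	2454
```

The third column is each region's record count: 10000 reads split into four
regions within ~1% of the 2500-read average, even though coverage is not
uniform.  Each `.sam` is coordinate-sorted with an `@HD SO:coordinate`
header; each `.bed` lists the 0-based half-open intervals the region covers
(adjacent bins merged), e.g.

```
$ head -1 regions/part0_region0000.bed
chr1	0	125000
```

The sidecar written in the map step is what the balancer consumed:

```
$ head -3 mapper_out/reads.binsinfo
0_1:98
0_2:120
0_3:80
```

(`<chromosome ordinal>_<bin index>:<read count>` per line.)

A full run — chunking, mapping through a command template, balancing,
per-region variant calling, VCF combination — is `binbalance run`; see
`binbalance run --help` or use `binbalance.run_pipeline(PipelineConfig(...))`
from Python.

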