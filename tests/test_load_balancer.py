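"""Region construction, per-region gathering, sorting, SAM/BAM + BED output."""
import random
from pathlib import Path

import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from binbalance import (
    BinID,
    BinsInfo,
    BalanceConfig,
    MapperConfig,
    aggregate_bins_info,
    average_reads_per_region,
    build_region_files,
    extract_region_reads,
    make_region_bed,
    make_regions_map,
    run_load_balancing_step,
    run_mapper_task,
    write_bins_info,
    write_container,
)
from binbalance.bin_container import BinBlock, compress_bin
from binbalance.errors import ConsistencyError, InputError, InvalidArgumentError
from binbalance.load_balancer import sort_sam_lines
from binbalance.synthetic import CoverageProfile, simulate_mapped_reads, write_sam


def info_from_counts(counts, chrom=0):
    """BinsInfo with the given counts on consecutive bins of one chromosome."""
    return BinsInfo({BinID(chrom, i + 1): c for i, c in enumerate(counts)})


def regions_vector(rm, info):
    return [rm.region_of[b] for b, _ in info.items_sorted()]


class TestAggregateBinsInfo:
    def test_counts_summed_across_files(self, tmp_path):
        a, b = tmp_path / "a.info", tmp_path / "b.info"
        write_bins_info(BinsInfo({BinID(0, 1): 10}), a)
        write_bins_info(BinsInfo({BinID(0, 1): 15, BinID(0, 2): 2}), b)
        merged = aggregate_bins_info([a, b])
        assert merged.counts == {BinID(0, 1): 25, BinID(0, 2): 2}

    def test_single_file_identity(self, tmp_path):
        info = BinsInfo({BinID(1, 3): 7})
        path = tmp_path / "x.info"
        write_bins_info(info, path)
        assert aggregate_bins_info([path]) == info

    def test_matches_brute_force_over_many_files(self, tmp_path):
        rng = random.Random(5)
        paths, expected = [], {}
        for i in range(50):
            info = BinsInfo()
            for _ in range(rng.randrange(1, 10)):
                b = BinID(rng.randrange(2), rng.randrange(1, 20))
                n = rng.randrange(1, 100)
                info.add(b, n)
            for b, n in info.counts.items():
                expected[b] = expected.get(b, 0) + n
            path = tmp_path / f"f{i}.info"
            write_bins_info(info, path)
            paths.append(path)
        assert aggregate_bins_info(paths).counts == expected

    def test_zero_files_rejected(self):
        with pytest.raises(InvalidArgumentError):
            aggregate_bins_info([])


class TestAverageReadsPerRegion:
    @pytest.mark.parametrize(
        "counts, num_regions, expected",
        [([10, 30], 4, 10.0), ([10, 30], 1, 40.0), ([7], 2, 3.5)],
    )
    def test_real_division(self, counts, num_regions, expected):
        assert average_reads_per_region(info_from_counts(counts), num_regions) == expected

    def test_empty_info_rejected(self):
        with pytest.raises(InvalidArgumentError):
            average_reads_per_region(BinsInfo(), 2)


class TestMakeRegionsMap:
    def test_even_split(self):
        info = info_from_counts([10, 10, 10, 10])
        rm = make_regions_map(info, 2)
        assert regions_vector(rm, info) == [0, 0, 1, 1]

    def test_single_region(self):
        info = info_from_counts([5, 1, 9])
        rm = make_regions_map(info, 1)
        assert regions_vector(rm, info) == [0, 0, 0]

    def test_oversized_bin_closes_its_region(self):
        # avg = 102/3 = 34: the first bin alone exceeds it; the trailing pair never reaches it
        info = info_from_counts([100, 1, 1])
        rm = make_regions_map(info, 3)
        assert regions_vector(rm, info) == [0, 1, 1]

    def test_summaries_record_bounds_and_totals(self):
        info = info_from_counts([10, 10, 10, 10])
        rm = make_regions_map(info, 2)
        assert rm.region_summaries[0] == (BinID(0, 1), BinID(0, 2), 20)
        assert rm.region_summaries[1] == (BinID(0, 3), BinID(0, 4), 20)

    def test_split_at_chromosomes_closes_at_boundary(self):
        info = BinsInfo(
            {BinID(0, 1): 5, BinID(0, 2): 5, BinID(1, 1): 5, BinID(1, 2): 5}
        )
        rm = make_regions_map(info, 1, split_at_chromosomes=True)
        assert rm.region_of[BinID(0, 2)] != rm.region_of[BinID(1, 1)]

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=200),
        num_regions=st.integers(min_value=1, max_value=64),
    )
    def test_greedy_invariants(self, counts, num_regions):
        info = info_from_counts(counts)
        rm = make_regions_map(info, num_regions)
        vec = regions_vector(rm, info)
        # region ids 0..R-1, monotone non-decreasing, steps of at most 1
        assert vec[0] == 0
        assert all(b - a in (0, 1) for a, b in zip(vec, vec[1:]))
        R = rm.num_regions
        assert R == max(vec) + 1
        assert R <= num_regions
        avg = sum(counts) / num_regions
        totals = [t for _, _, t in rm.region_summaries.values()]
        assert all(t >= avg for t in totals[:-1])
        assert all(t < avg + max(counts) for t in totals)
        assert sum(totals) == sum(counts)

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=50),
        num_regions=st.integers(min_value=1, max_value=16),
    )
    def test_monotone_refinement(self, counts, num_regions):
        info = info_from_counts(counts)
        r_lo = make_regions_map(info, num_regions).num_regions
        r_hi = make_regions_map(info, num_regions + 1).num_regions
        assert r_hi >= r_lo


def containers_with_bins(tmp_path, bin_lines):
    """Write one container per dict of {BinID: [lines]}; return the paths."""
    paths = []
    for i, bins in enumerate(bin_lines):
        blocks = [
            BinBlock(b, len(lines), compress_bin(lines)) for b, lines in sorted(bins.items())
        ]
        path = tmp_path / f"c{i}.sgb"
        write_container(blocks, path)
        paths.append(path)
    return paths


def sam_record(qname, chrom, pos, flag=0):
    return f"{qname}\t{flag}\t{chrom}\t{pos}\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII"


class TestExtractRegionReads:
    def test_same_bin_from_two_containers(self, tmp_path):
        bins = {BinID(0, 1): [sam_record("a", "chr1", 1)]}
        paths = containers_with_bins(tmp_path, [bins, bins])
        rm = make_regions_map(BinsInfo({BinID(0, 1): 2}), 1)
        per_region = extract_region_reads(paths, rm)
        assert len(per_region[0]) == 2

    def test_empty_container_list(self):
        rm = make_regions_map(BinsInfo({BinID(0, 1): 1}), 1)
        assert extract_region_reads([], rm) == {}

    def test_payload_conservation(self, tmp_path):
        rng = random.Random(9)
        containers = []
        info = BinsInfo()
        total_blocks = 0
        for _ in range(4):
            bins = {}
            for _ in range(rng.randrange(1, 6)):
                b = BinID(0, rng.randrange(1, 15))
                bins[b] = [sam_record(f"r{rng.random()}", "chr1", 1 + (b.bin_index - 1) * 5000)]
                info.add(b, 1)
            containers.append(bins)
            total_blocks += len(bins)
        paths = containers_with_bins(tmp_path, containers)
        per_region = extract_region_reads(paths, make_regions_map(info, 3))
        assert sum(len(v) for v in per_region.values()) == total_blocks

    def test_unknown_bin_raises_consistency_error(self, tmp_path):
        bins = {BinID(0, 9): [sam_record("a", "chr1", 40001)]}
        paths = containers_with_bins(tmp_path, [bins])
        rm = make_regions_map(BinsInfo({BinID(0, 1): 1}), 1)
        with pytest.raises(ConsistencyError, match="0_9"):
            extract_region_reads(paths, rm)


class TestBuildRegionFiles:
    def test_reversed_input_is_sorted(self, small_ref, tmp_path):
        lines = [sam_record(f"r{i}", "chr1", 5000 - i * 100) for i in range(10)]
        payloads = [compress_bin(lines)]
        aln, _, count = build_region_files(0, payloads, small_ref, tmp_path)
        assert count == 10
        body = [l for l in aln.read_text().splitlines() if not l.startswith("@")]
        positions = [int(l.split("\t")[3]) for l in body]
        assert positions == sorted(positions)

    def test_tie_break_by_qname_then_flag(self, small_ref, tmp_path):
        lines = [
            sam_record("zeta", "chr1", 100, flag=0),
            sam_record("alpha", "chr1", 100, flag=16),
            sam_record("alpha", "chr1", 100, flag=0),
        ]
        aln, _, _ = build_region_files(0, [compress_bin(lines)], small_ref, tmp_path)
        body = [l for l in aln.read_text().splitlines() if not l.startswith("@")]
        assert [(l.split("\t")[0], l.split("\t")[1]) for l in body] == [
            ("alpha", "0"),
            ("alpha", "16"),
            ("zeta", "0"),
        ]

    def test_header_declares_coordinate_sort(self, small_ref, tmp_path):
        aln, _, _ = build_region_files(
            0, [compress_bin([sam_record("a", "chr1", 1)])], small_ref, tmp_path
        )
        first = aln.read_text().splitlines()[0]
        assert first.startswith("@HD") and "SO:coordinate" in first

    def test_bam_agrees_with_sam(self, small_ref, tmp_path):
        lines = [sam_record(f"r{i}", "chr2", 1 + 37 * i) for i in range(20)]
        payloads = [compress_bin(lines)]
        sam_path, _, _ = build_region_files(
            0, payloads, small_ref, tmp_path / "s", emit_bam=False
        )
        bam_path, _, n = build_region_files(
            0, payloads, small_ref, tmp_path / "b", emit_bam=True
        )
        assert n == 20
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            assert bam.header["HD"]["SO"] == "coordinate"
            from_bam = [(r.query_name, r.reference_name, r.reference_start + 1) for r in bam]
        from_sam = [
            (f[0], f[2], int(f[3]))
            for f in (l.split("\t") for l in sam_path.read_text().splitlines())
            if not f[0].startswith("@")
        ]
        assert from_bam == from_sam

    def test_empty_region_still_writes_files(self, small_ref, tmp_path):
        aln, bed, count = build_region_files(0, [], small_ref, tmp_path)
        assert count == 0
        assert aln.exists() and bed.exists()


class TestMakeRegionBed:
    def test_adjacent_bins_merge(self, small_ref):
        info = BinsInfo({BinID(0, 1): 5, BinID(0, 2): 5})
        rm = make_regions_map(info, 1)
        assert make_region_bed(0, rm, 5000, small_ref) == [("chr1", 0, 10000)]

    def test_no_cross_chromosome_merge(self, small_ref):
        info = BinsInfo({BinID(0, 20): 5, BinID(1, 1): 5})  # chr1 last bin, chr2 first
        rm = make_regions_map(info, 1)
        assert make_region_bed(0, rm, 5000, small_ref) == [
            ("chr1", 95000, 100000),
            ("chr2", 0, 5000),
        ]

    def test_gap_between_observed_bins_splits_rows(self, small_ref):
        info = BinsInfo({BinID(0, 1): 5, BinID(0, 3): 5})
        rm = make_regions_map(info, 1)
        assert make_region_bed(0, rm, 5000, small_ref) == [
            ("chr1", 0, 5000),
            ("chr1", 10000, 15000),
        ]

    def test_last_bin_clipped_at_chromosome_length(self):
        from binbalance import ReferenceDict

        ref = ReferenceDict([("chr1", 7500)])
        info = BinsInfo({BinID(0, 2): 5})
        rm = make_regions_map(info, 1)
        assert make_region_bed(0, rm, 5000, ref) == [("chr1", 5000, 7500)]

    def test_unknown_region_rejected(self, small_ref):
        rm = make_regions_map(BinsInfo({BinID(0, 1): 1}), 1)
        with pytest.raises(InvalidArgumentError):
            make_region_bed(5, rm, 5000, small_ref)


class TestRunLoadBalancingStep:
    def _map(self, small_ref, sam_path, tmp_path, num_parts=1):
        out = tmp_path / "mapper_out"
        config = MapperConfig(ref=small_ref, out_dir=out, num_parts=num_parts)
        run_mapper_task(sam_path, config)
        return out

    def test_end_to_end_conservation_and_region_bound(
        self, small_ref, skewed_sam, tmp_path
    ):
        sam_path, truth = skewed_sam
        mapper_out = self._map(small_ref, sam_path, tmp_path)
        config = BalanceConfig(ref=small_ref, out_dir=tmp_path / "regions")
        outputs = run_load_balancing_step(mapper_out, 0, 8, config)
        assert 1 <= len(outputs) <= 8
        assert sum(o.record_count for o in outputs) == truth.total()

    def test_single_region_is_genome_wide_sorted(self, small_ref, skewed_sam, tmp_path):
        sam_path, truth = skewed_sam
        mapper_out = self._map(small_ref, sam_path, tmp_path)
        config = BalanceConfig(ref=small_ref, out_dir=tmp_path / "regions")
        (only,) = run_load_balancing_step(mapper_out, 0, 1, config)
        assert only.record_count == truth.total()

    def test_global_sort_equivalence(self, small_ref, tmp_path):
        profile = CoverageProfile(seed=3, hotspots=[(BinID(0, 5), 30.0)])
        lines, _ = simulate_mapped_reads(small_ref, profile, 10_000, with_header=False)
        # two mapper tasks over two halves of the input
        p1 = write_sam(lines[:6000], tmp_path / "a.sam")
        p2 = write_sam(lines[6000:], tmp_path / "b.sam")
        mapper_out = tmp_path / "mapper_out"
        config = MapperConfig(ref=small_ref, out_dir=mapper_out)
        run_mapper_task(p1, config)
        run_mapper_task(p2, config)
        outputs = run_load_balancing_step(
            mapper_out, 0, 6, BalanceConfig(ref=small_ref, out_dir=tmp_path / "regions")
        )
        concatenated = []
        for o in sorted(outputs, key=lambda o: o.region_id):
            concatenated.extend(
                l for l in Path(o.alignment_path).read_text().splitlines()
                if not l.startswith("@")
            )
        # oracle: coordinate sort of the whole input in one go
        ordinal = {n: i for i, n in enumerate(small_ref.names)}
        expected = sorted(
            lines,
            key=lambda l: (
                ordinal[l.split("\t")[2]],
                int(l.split("\t")[3]),
                l.split("\t")[0],
                int(l.split("\t")[1]),
            ),
        )
        assert concatenated == expected

    def test_rerun_outputs_byte_identical(self, small_ref, skewed_sam, tmp_path):
        sam_path, _ = skewed_sam
        mapper_out = self._map(small_ref, sam_path, tmp_path)
        config = BalanceConfig(ref=small_ref, out_dir=tmp_path / "regions", workers=4)
        first = run_load_balancing_step(mapper_out, 0, 4, config)
        snapshot = {
            o.alignment_path: o.alignment_path.read_bytes() for o in first
        } | {o.bed_path: o.bed_path.read_bytes() for o in first}
        run_load_balancing_step(mapper_out, 0, 4, config)
        for path, data in snapshot.items():
            assert path.read_bytes() == data

    def test_missing_containers_raise_input_error(self, small_ref, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(InputError):
            run_load_balancing_step(
                tmp_path / "empty", 0, 2, BalanceConfig(ref=small_ref, out_dir=tmp_path / "r")
            )
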