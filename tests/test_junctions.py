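import pysam
import pytest
from hypothesis import given, strategies as st

from crypticex import junctions, simulate
from crypticex.junctions import (
    CigarError,
    Junction,
    SplicedAlignment,
    classify_junction,
    count_alignments,
    count_sample,
    extract_junctions,
    parse_spliced_alignment,
    passes_filters,
)
from crypticex.locus import mirror_locus
from crypticex.simulate import SampleParams, simulate_rnaseq_sample

from oracles import brute_force_count_sam


def _rec(locus, pos, cigar, mapq=255, flag=0, name="r1"):
    header = simulate.sam_header(locus)
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos - 1
    a.mapping_quality = mapq
    a.cigarstring = cigar
    qlen = a.infer_query_length()
    a.query_sequence = "A" * qlen
    return a


class TestParse:
    @pytest.mark.parametrize(
        "pos,cigar,blocks",
        [
            (1_151, "50M3800N50M", ((1_151, 1_200), (5_001, 5_050))),
            (3_079, "50M1872N50M", ((3_079, 3_128), (5_001, 5_050))),
            (100, "100M", ((100, 199),)),
            # D extends the block, I and S consume no reference
            (100, "40M2D58M", ((100, 199),)),
            (100, "5S40M3I55M", ((100, 194),)),
            # two gaps -> three blocks
            (1_151, "50M1800N30M842N20M", ((1_151, 1_200), (3_001, 3_030), (3_873, 3_892))),
        ],
    )
    def test_blocks_from_cigar(self, locus, pos, cigar, blocks):
        aln = parse_spliced_alignment(_rec(locus, pos, cigar))
        assert aln.blocks == blocks

    def test_unsupported_operator_raises(self, locus):
        rec = _rec(locus, 100, "10M")
        rec.cigartuples = [(0, 10), (6, 5), (0, 10)]  # P operator
        with pytest.raises(CigarError):
            parse_spliced_alignment(rec)

    def test_missing_cigar_raises(self, locus):
        rec = _rec(locus, 100, "10M")
        rec.cigarstring = None
        with pytest.raises(CigarError):
            parse_spliced_alignment(rec)

    def test_block_invariants_enforced(self):
        with pytest.raises(ValueError):
            SplicedAlignment("r", "chrT", ((10, 20), (21, 30)), 255, False)
        with pytest.raises(ValueError):
            SplicedAlignment("r", "chrT", ((10, 5),), 255, False)


class TestFilters:
    @pytest.mark.parametrize(
        "mapq,dup,drop,expected",
        [
            (255, False, True, True),
            (255, True, True, False),  # PCR duplicate removed
            (3, False, True, False),  # sub-unique MAPQ removed
            (255, True, False, True),  # duplicates kept on request
            (254, False, True, False),
        ],
    )
    def test_unique_and_duplicate_filter(self, mapq, dup, drop, expected):
        aln = SplicedAlignment("r", "chrT", ((1, 100),), mapq, dup)
        assert passes_filters(aln, unique_mapq=255, drop_duplicates=drop) is expected


class TestExtract:
    def test_junction_with_overhangs(self):
        aln = SplicedAlignment("r", "chrT", ((1_151, 1_200), (5_001, 5_050)), 255, False)
        (j,) = extract_junctions(aln)
        assert (j.intron_start, j.intron_end) == (1_201, 5_000)
        assert (j.left_overhang, j.right_overhang) == (50, 50)

    def test_short_overhang_discarded(self):
        # left overhang 5 < the 6-base minimum
        aln = SplicedAlignment("r", "chrT", ((1_196, 1_200), (5_001, 5_050)), 255, False)
        assert extract_junctions(aln, min_overhang=6) == []
        assert len(extract_junctions(aln, min_overhang=5)) == 1

    def test_unspliced_read_yields_nothing(self):
        aln = SplicedAlignment("r", "chrT", ((100, 199),), 255, False)
        assert extract_junctions(aln) == []

    @given(
        lengths=st.lists(st.integers(1, 60), min_size=2, max_size=5),
        gaps=st.lists(st.integers(1, 500), min_size=4, max_size=4),
        overhang_lo=st.integers(1, 10),
        delta=st.integers(0, 10),
    )
    def test_raising_overhang_never_adds_junctions(
        self, lengths, gaps, overhang_lo, delta
    ):
        blocks, pos = [], 1
        for L, g in zip(lengths, gaps + [1]):
            blocks.append((pos, pos + L - 1))
            pos += L + g
        aln = SplicedAlignment("r", "chrT", tuple(blocks), 255, False)
        lo = {
            (j.intron_start, j.intron_end)
            for j in extract_junctions(aln, overhang_lo)
        }
        hi = {
            (j.intron_start, j.intron_end)
            for j in extract_junctions(aln, overhang_lo + delta)
        }
        assert hi <= lo


class TestClassify:
    @pytest.mark.parametrize(
        "gap,name",
        [
            ((1_201, 5_000), "e20-e21"),
            ((3_129, 5_000), "e20-CE128"),
            ((3_179, 5_000), "e20-CE178"),
            ((1_201, 3_000), "CE-e21"),
            ((5_151, 7_000), "e19-e20"),
            ((1_200, 5_000), "unclassified"),  # off by one
            ((2_000, 2_500), "unclassified"),
        ],
    )
    def test_exact_interval_match(self, locus, gap, name):
        j = Junction("chrT", gap[0], gap[1], 50, 50)
        assert classify_junction(j, locus) == name

    def test_other_chromosome_unclassified(self, locus):
        j = Junction("chr9", 1_201, 5_000, 50, 50)
        assert classify_junction(j, locus) == "unclassified"


class TestCountSample:
    def test_null_sample_has_no_ce_junctions(self, locus, tmp_path):
        path = str(tmp_path / "null.sam")
        simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.0, depth=500, seed=7), out_sam=path
        )
        t = count_sample(path, locus)
        assert t.counts["e20-CE128"] == 0
        assert t.counts["e20-CE178"] == 0
        assert t.counts["CE-e21"] == 0
        assert t.counts["e20-e21"] > 0

    def test_matches_brute_force_oracle(self, locus, tmp_path):
        path = str(tmp_path / "mix.sam")
        params = SampleParams(
            psi_true=0.35,
            depth=800,
            duplicate_rate=0.1,
            nonunique_rate=0.1,
            seed=11,
        )
        simulate_rnaseq_sample(locus, params, out_sam=path)
        t = count_sample(path, locus)
        oracle = brute_force_count_sam(path, locus.exons)
        for nm in t.counts:
            assert t.counts[nm] == oracle[nm], nm
        assert t.unclassified_junctions == oracle["unclassified"]

    def test_truth_counts_equal_pipeline_counts(self, locus, tmp_path):
        path = str(tmp_path / "t.sam")
        _, truth = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.2, depth=400, seed=3), out_sam=path
        )
        t = count_sample(path, locus)
        assert t.counts == truth.junction_counts

    def test_adding_reads_never_decreases_counts(self, locus):
        recs, _ = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.3, depth=300, seed=5)
        )
        parsed = [junctions.parse_spliced_alignment(r) for r in recs]
        t_half = count_alignments(parsed[: len(parsed) // 2], locus)
        t_full = count_alignments(parsed, locus)
        for nm in t_full.counts:
            assert t_full.counts[nm] >= t_half.counts[nm]

    def test_stricter_filters_never_increase_counts(self, locus):
        recs, _ = simulate_rnaseq_sample(
            locus,
            SampleParams(psi_true=0.3, depth=300, nonunique_rate=0.2, seed=9),
        )
        parsed = [junctions.parse_spliced_alignment(r) for r in recs]
        base = count_alignments(parsed, locus, min_overhang=6, unique_mapq=3)
        harder = count_alignments(parsed, locus, min_overhang=20, unique_mapq=255)
        for nm in base.counts:
            assert harder.counts[nm] <= base.counts[nm]

    def test_strand_mirroring_gives_identical_counts(self, locus):
        # reflect the same reads and the model onto the plus strand:
        # named counts must not change
        mirrored = mirror_locus(locus)
        L = locus.chrom_length
        recs, _ = simulate_rnaseq_sample(
            locus, SampleParams(psi_true=0.25, depth=500, seed=13)
        )
        parsed = [junctions.parse_spliced_alignment(r) for r in recs]
        reflected = [
            SplicedAlignment(
                a.read_id,
                a.chrom,
                tuple(sorted((L - e + 1, L - s + 1) for s, e in a.blocks)),
                a.mapq,
                a.is_duplicate,
            )
            for a in parsed
        ]
        t = count_alignments(parsed, locus)
        t_m = count_alignments(reflected, mirrored)
        assert t.counts == t_m.counts

    def test_missing_file_and_chrom_mismatch(self, locus, tmp_path):
        with pytest.raises(FileNotFoundError):
            count_sample(str(tmp_path / "absent.sam"), locus)
        other = str(tmp_path / "other.sam")
        with open(other, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr9\tLN:1000\n")
        with pytest.raises(ValueError):
            count_sample(other, locus)

    def test_read_spanning_two_junctions_increments_both(self, locus):
        # long read: e20 overhang, whole CE128, e21 overhang
        rec = _rec(locus, 3_119, "10M", name="twojunc")
        rec.cigarstring = "10M1800N128M1872N10M"
        rec.reference_start = 1_191 - 1
        rec.query_sequence = "A" * 148
        t = count_alignments([junctions.parse_spliced_alignment(rec)], locus)
        assert t.counts["CE-e21"] == 1
        assert t.counts["e20-CE128"] == 1
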