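import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcrmap._util import revcomp, seq_to_array
from gcrmap.errors import DataError
from gcrmap.genome_model import Genome, RepairRegion
from gcrmap.splitread import (
    AnchoredRead,
    ClipTooShortError,
    KmerIndex,
    RegionAligner,
    align_reads,
    breakpoint_coordinate,
    default_max_mismatch,
    detect_split_reads,
    parse_alignments,
    read_splitread_table,
    realign_clip,
    write_sam,
    write_splitread_table,
)


def brute_force_hits(clip, genome, max_mismatch):
    """Independent oracle: sliding-window Hamming search over both strands."""
    found = []
    for strand, query in (("+", clip), ("-", revcomp(clip))):
        qarr = seq_to_array(query)
        L = len(query)
        for chrom in genome:
            seq = seq_to_array(genome[chrom])
            if len(seq) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(seq, L)
            mism = (windows != qarr).sum(axis=1)
            for start in np.nonzero(mism <= max_mismatch)[0]:
                found.append((chrom, int(start), strand, int(mism[start])))
    return sorted(found)


@pytest.fixture(scope="module")
def small_genome(toy=None):
    rng = np.random.default_rng(11)
    seqs = {
        f"c{i}": "".join(rng.choice(list("ACGT"), 4000)) for i in range(3)
    }
    return Genome(seqs)


class TestRealignClip:
    def test_unique_planted_40mer(self, small_genome):
        clip = small_genome["c1"][1000:1040]
        hits = realign_clip(clip, small_genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.chrom, h.start, h.strand, h.mismatches) == ("c1", 1000, "+", 0)
        assert h.n_equivalent == 1

    def test_reverse_complement_hit(self, small_genome):
        clip = revcomp(small_genome["c2"][500:540])
        hits = realign_clip(clip, small_genome)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 500

    def test_shared_repeat_counts_equivalents(self):
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), 60))
        pad = lambda: "".join(rng.choice(list("ACGT"), 200))
        genome = Genome(
            {
                "a": pad() + core + pad(),
                "b": pad() + core + pad() + core + pad(),
            }
        )
        hits = realign_clip(core[10:50], genome)
        assert len(hits) == 3
        assert all(h.n_equivalent == 3 for h in hits)

    def test_short_clip_raises(self, small_genome):
        with pytest.raises(ClipTooShortError):
            realign_clip("ACGTACGT", small_genome)

    def test_mismatch_budget_scales_with_length(self):
        assert default_max_mismatch(24) == 0
        assert default_max_mismatch(25) == 1
        assert default_max_mismatch(120) == 4

    def test_equals_brute_force_on_planted_mutations(self, small_genome):
        rng = np.random.default_rng(23)
        index = KmerIndex(small_genome)
        for _ in range(40):
            chrom = f"c{rng.integers(3)}"
            L = int(rng.integers(25, 80))
            start = int(rng.integers(0, 4000 - L))
            clip = list(small_genome[chrom][start : start + L])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(L))
                clip[p] = "ACGT"[rng.integers(4)]
            clip = "".join(clip)
            if rng.random() < 0.5:
                clip = revcomp(clip)
            mm = default_max_mismatch(L)
            got = sorted(
                (h.chrom, h.start, h.strand, h.mismatches)
                for h in realign_clip(clip, small_genome, index=index)
            )
            assert got == brute_force_hits(clip, small_genome, mm)


@settings(max_examples=30, deadline=None)
@given(data=st.data())
def test_realign_brute_force_property(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
    genome = Genome({"g": "".join(rng.choice(list("ACGT"), 1500))})
    L = data.draw(st.integers(12, 60))
    if data.draw(st.booleans()):
        start = data.draw(st.integers(0, 1500 - L))
        clip = genome["g"][start : start + L]
    else:
        clip = "".join(rng.choice(list("ACGT"), L))
    mm = default_max_mismatch(L)
    got = sorted(
        (h.chrom, h.start, h.strand, h.mismatches)
        for h in realign_clip(clip, genome)
    )
    assert got == brute_force_hits(clip, genome, mm)


REGION = RepairRegion("chrR", 1000, 3000)


def sam_text(records, chrom="chrR", length=4000):
    head = f"@HD\tVN:1.6\n@SQ\tSN:{chrom}\tLN:{length}\n"
    return head + "".join(records)


@pytest.fixture(scope="module")
def sam_genome():
    rng = np.random.default_rng(3)
    return Genome({"chrR": "".join(rng.choice(list("ACGT"), 4000))})


class TestParseAlignments:
    def test_full_match_has_no_clip(self, tmp_path, sam_genome):
        seq = sam_genome["chrR"][1500:1650]
        p = tmp_path / "a.sam"
        p.write_text(
            sam_text([f"r1\t0\tchrR\t1501\t60\t150M\t*\t0\t0\t{seq}\t{'I'*150}\n"])
        )
        reads = parse_alignments(p, sam_genome, REGION)
        assert len(reads) == 1
        assert not reads[0].has_clip
        assert (reads[0].anchor_start, reads[0].anchor_end) == (1500, 1650)

    def test_cigar_70m80s(self, tmp_path, sam_genome):
        anchor = sam_genome["chrR"][1500:1570]
        clip = "TG" * 40
        p = tmp_path / "a.sam"
        p.write_text(
            sam_text(
                [f"r1\t0\tchrR\t1501\t60\t70M80S\t*\t0\t0\t{anchor + clip}\t{'I'*150}\n"]
            )
        )
        r = parse_alignments(p, sam_genome, REGION)[0]
        assert r.clip_side == "right"
        assert len(r.clip_seq) == 80
        assert r.clip_seq == clip

    def test_alignment_outside_region_excluded(self, tmp_path, sam_genome):
        seq = sam_genome["chrR"][3200:3350]
        p = tmp_path / "a.sam"
        p.write_text(
            sam_text([f"r1\t0\tchrR\t3201\t60\t150M\t*\t0\t0\t{seq}\t{'I'*150}\n"])
        )
        assert parse_alignments(p, sam_genome, REGION) == []

    def test_hard_clip_skipped_with_warning(self, tmp_path, sam_genome):
        seq = sam_genome["chrR"][1500:1570]
        p = tmp_path / "a.sam"
        p.write_text(
            sam_text([f"r1\t0\tchrR\t1501\t60\t70M80H\t*\t0\t0\t{seq}\t{'I'*70}\n"])
        )
        assert parse_alignments(p, sam_genome, REGION) == []
        assert parse_alignments.last_warnings

    def test_secondary_ignored(self, tmp_path, sam_genome):
        seq = sam_genome["chrR"][1500:1650]
        p = tmp_path / "a.sam"
        p.write_text(
            sam_text([f"r1\t256\tchrR\t1501\t60\t150M\t*\t0\t0\t{seq}\t{'I'*150}\n"])
        )
        assert parse_alignments(p, sam_genome, REGION) == []

    def test_missing_file(self, sam_genome, tmp_path):
        with pytest.raises(DataError):
            parse_alignments(tmp_path / "no.sam", sam_genome, REGION)


def mk_read(anchor_start, anchor_end, clip_seq="", clip_side="none", **kw):
    return AnchoredRead(
        read_id=kw.pop("read_id", "r"),
        chrom="chrR",
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        strand="+",
        clip_seq=clip_seq,
        clip_side=clip_side,
        **kw,
    )


class TestDetectSplitReads:
    def test_threshold(self):
        short = mk_read(1500, 1640, "ACGTA", "left")
        long = mk_read(1500, 1610, "A" * 40, "left")
        kept = detect_split_reads([short, long], REGION, min_clip=10)
        assert kept == [long]

    def test_unclipped_excluded(self):
        assert detect_split_reads([mk_read(1500, 1650)], REGION) == []

    def test_wrong_side_clip_excluded(self):
        r = mk_read(1500, 1610, "A" * 40, "right")
        assert detect_split_reads([r], REGION) == []

    def test_subset_and_unique(self):
        reads = [
            mk_read(1500, 1610, "A" * 40, "left", read_id=f"r{i}") for i in range(5)
        ]
        kept = detect_split_reads(reads, REGION)
        assert set(r.read_id for r in kept) <= set(r.read_id for r in reads)
        assert len({id(r) for r in kept}) == len(kept)

    def test_min_clip_validated(self):
        with pytest.raises(DataError):
            detect_split_reads([], REGION, min_clip=0)


class TestBreakpointCoordinate:
    def test_right_clip_boundary_arithmetic(self):
        region = RepairRegion("chrIX", 41500, 61600)
        r = AnchoredRead("r", "chrIX", 44200, 44270, "+", "A" * 30, "right")
        bp = breakpoint_coordinate(r, region)
        assert bp.coordinate == 44270
        assert bp.coordinate_1based == 44271

    def test_left_clip_boundary(self):
        bp = breakpoint_coordinate(mk_read(1600, 1700, "A" * 20, "left"), REGION)
        assert bp.coordinate == 1599
        assert bp.retained_boundary == 1600

    def test_edge_breakpoint_flagged(self):
        bp = breakpoint_coordinate(mk_read(1000, 1100, "A" * 20, "left"), REGION)
        assert "at_region_edge" in bp.flags

    def test_wrong_side_flagged_not_dropped(self):
        bp = breakpoint_coordinate(mk_read(1500, 1600, "A" * 20, "right"), REGION)
        assert "clip_on_centromeric_side" in bp.flags

    def test_unclipped_read_rejected(self):
        with pytest.raises(DataError):
            breakpoint_coordinate(mk_read(1500, 1650), REGION)


class TestRegionAligner:
    def test_same_junction_reads_share_breakpoint(self, toy, analyzed_pool):
        # error-free reads covering one junction must give one coordinate
        cfg, genome, ann, region = toy
        from gcrmap.synthetic_pool import make_tg_tract, simulate_reads

        clone = revcomp(make_tg_tract(200, seed=9)) + genome["chrR"][5000:]
        reads = simulate_reads([clone], depth=20, error_rate=0.0, seed=9)
        aligner = RegionAligner(genome, region)
        boundaries = set()
        for rid, seq in reads:
            a = aligner.align(rid, seq)
            if a and a.has_clip and len(a.clip_seq) >= 10 and a.clip_side == "left":
                boundaries.add(breakpoint_coordinate(a, region).retained_boundary)
        assert len(boundaries) == 1

    def test_detect_output_subset_of_aligned(self, analyzed_pool):
        split_ids = {r.read_id for r in analyzed_pool["split"]}
        anchored_ids = {r.read_id for r in analyzed_pool["anchored"]}
        assert split_ids <= anchored_ids
        assert len(split_ids) == len(analyzed_pool["split"])


class TestTables:
    def test_splitread_table_roundtrip(self, tmp_path, analyzed_pool):
        split = analyzed_pool["split"][:20]
        region = RepairRegion("chrR", 1900, 15200)
        p = tmp_path / "sr.tsv"
        write_splitread_table(split, region, p, header_comment="test")
        back = read_splitread_table(p)
        assert [(r.read_id, r.anchor_start, r.clip_seq) for r in back] == [
            (r.read_id, r.anchor_start, r.clip_seq) for r in split
        ]

    def test_write_sam_parses_back(self, tmp_path, toy, analyzed_pool):
        _, genome, _, region = toy
        split = analyzed_pool["split"][:20]
        p = tmp_path / "x.sam"
        write_sam(split, genome, p)
        back = parse_alignments(p, genome, region)
        assert len(back) == len(split)
        assert {r.read_id for r in back} == {r.read_id for r in split}
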