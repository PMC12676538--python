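"""Read classification, mate merging, dedup and tallies."""
import pysam
import pytest
from hypothesis import given, strategies as st

from conftest import make_fragment
from umiasm.reads import (AlignmentInputError, dedup_fragments,
                          load_fragments, merge_mates, summarize_read_types,
                          _to_aligned_read)

_HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"},
           "SQ": [{"SN": "chr1", "LN": 100000}]}


def _write_sam(path, records):
    with pysam.AlignmentFile(str(path), "wh", header=_HEADER) as out:
        for rec in records:
            out.write(rec)


def _aln(qname, pos, cigar, flag=0, tags=(), mate_pos=-1, mapq=60, seq=None):
    a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(_HEADER))
    a.query_name = qname
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar
    if seq is not None:
        a.query_sequence = seq
    if flag & 0x1:
        a.next_reference_id = 0
        a.next_reference_start = mate_pos
    a.set_tags(list(tags))
    return a


class TestClassification:
    def test_ub_tag_makes_umi_read(self, tmp_path):
        sam = tmp_path / "c.sam"
        _write_sam(sam, [_aln("r1", 100, "50M", tags=[("UB", "ATTGCC")]),
                         _aln("r2", 300, "50M"),
                         _aln("r3", 500, "50M", tags=[("UB", "")])])
        frags = load_fragments(sam)
        types = {f.blocks[0][0]: f.read_type for f in frags}
        assert types == {100: "umi", 300: "internal", 500: "internal"}
        assert next(f for f in frags if f.read_type == "umi").umi == "ATTGCC"

    def test_filters_drop_secondary_supplementary_low_mapq(self, tmp_path):
        sam = tmp_path / "c.sam"
        _write_sam(sam, [_aln("ok", 100, "50M"),
                         _aln("sec", 200, "50M", flag=0x100),
                         _aln("sup", 300, "50M", flag=0x800),
                         _aln("low", 400, "50M", mapq=0)])
        assert [f.start for f in load_fragments(sam)] == [100]

    def test_unsorted_input_is_fatal(self, tmp_path):
        sam = tmp_path / "u.sam"
        header = {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": _HEADER["SQ"]}
        with pysam.AlignmentFile(str(sam), "wh", header=header) as out:
            out.write(_aln("a", 100, "50M"))
        with pytest.raises(AlignmentInputError):
            load_fragments(sam)

    def test_cigar_junctions_and_blocks(self):
        a = _aln("r", 100, "50M150N50M", seq="A" * 100)
        read = _to_aligned_read(a)
        assert read.blocks == ((100, 150), (300, 350))
        assert read.junctions == ((150, 300),)

    def test_deletions_bridge_into_one_block(self):
        read = _to_aligned_read(_aln("r", 10, "20M5D20M"))
        assert read.blocks == ((10, 55),)
        assert read.junctions == ()


class TestMateMerging:
    def test_pair_merges_blocks_and_junctions(self, tmp_path):
        sam = tmp_path / "p.sam"
        r1 = _aln("pair", 100, "50M150N50M", flag=0x1 | 0x2 | 0x40,
                  mate_pos=310)
        r2 = _aln("pair", 310, "40M", flag=0x1 | 0x2 | 0x80 | 0x10,
                  mate_pos=100)
        _write_sam(sam, [r1, r2])
        (f,) = load_fragments(sam)
        assert f.blocks == ((100, 150), (300, 350))
        assert f.junctions == ((150, 300),)

    def test_insert_gap_is_not_a_junction(self, tmp_path):
        sam = tmp_path / "g.sam"
        r1 = _aln("pair", 100, "50M", flag=0x1 | 0x2 | 0x40, mate_pos=300)
        r2 = _aln("pair", 300, "50M", flag=0x1 | 0x2 | 0x80 | 0x10,
                  mate_pos=100)
        _write_sam(sam, [r1, r2])
        (f,) = load_fragments(sam)
        assert f.blocks == ((100, 150), (300, 350))
        assert f.junctions == ()

    def test_umi_strand_follows_read1_orientation(self, tmp_path):
        sam = tmp_path / "s.sam"
        _write_sam(sam, [
            _aln("f", 100, "50M", tags=[("UB", "AAAA")]),
            _aln("r", 300, "50M", flag=0x10, tags=[("UB", "CCCC")])])
        strands = {f.start: f.strand for f in load_fragments(sam)}
        assert strands == {100: "+", 300: "-"}

    def test_internal_without_junction_has_unknown_strand(self, tmp_path):
        sam = tmp_path / "s.sam"
        _write_sam(sam, [_aln("i", 100, "50M")])
        (f,) = load_fragments(sam)
        assert f.strand == "."

    def test_xs_tag_sets_strand_of_spliced_internal_read(self, tmp_path):
        sam = tmp_path / "s.sam"
        _write_sam(sam, [_aln("i", 100, "30M100N30M", tags=[("XS", "-")])])
        (f,) = load_fragments(sam)
        assert f.strand == "-"

    def test_motif_strand_inference_from_genome(self, tmp_path):
        seq = ["A"] * 1000
        seq[150:152] = "GT"
        seq[298:300] = "AG"
        genome = {"chr1": "".join(seq)}
        sam = tmp_path / "m.sam"
        _write_sam(sam, [_aln("i", 100, "50M150N50M")])
        (f,) = load_fragments(sam, genome=genome)
        assert f.strand == "+"
        seq[150:152] = "CT"
        seq[298:300] = "AC"
        (f,) = load_fragments(sam, genome={"chr1": "".join(seq)})
        assert f.strand == "-"


class TestDedup:
    def test_identical_alignment_collapses(self):
        a = make_fragment(blocks=((100, 150),), key=("chr1", "k"))
        b = make_fragment(blocks=((100, 150),), key=("chr1", "k"))
        assert dedup_fragments([a, b]) == [a]

    def test_different_cigar_survives(self, tmp_path):
        sam = tmp_path / "d.sam"
        _write_sam(sam, [_aln("a", 100, "50M", seq="A" * 50),
                         _aln("b", 100, "48M2S", seq="A" * 50)])
        assert len(dedup_fragments(load_fragments(sam))) == 2

    def test_flagged_duplicates_removed(self):
        a = make_fragment(key=1)
        b = make_fragment(blocks=((500, 600),), key=2, duplicate_flag=True)
        assert dedup_fragments([a, b]) == [a]

    def test_n_copies_plus_m_distinct(self):
        copies = [make_fragment(key="dup") for _ in range(5)]
        distinct = [make_fragment(blocks=((i * 1000, i * 1000 + 50),), key=i)
                    for i in range(3)]
        assert len(dedup_fragments(copies + distinct)) == 4

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 3)),
                    max_size=30))
    def test_idempotent_and_order_independent(self, spec):
        frags = [make_fragment(blocks=((k * 10, k * 10 + 50),),
                               key=("chr1", k), umi="A" if tag else None)
                 for k, tag in spec]
        once = dedup_fragments(frags)
        assert dedup_fragments(once) == once
        rev = dedup_fragments(frags[::-1])
        assert {f.dedup_key for f in rev} == {f.dedup_key for f in once}


class TestSummary:
    def test_counts_partition_fragments(self):
        frags = [make_fragment(umi="A", key=1), make_fragment(umi="C", key=2),
                 make_fragment(umi="G", key=3), make_fragment(key=4)]
        st_ = summarize_read_types(frags)
        assert (st_.n_umi, st_.n_internal) == (3, 1)
        assert st_.n_umi + st_.n_internal == len(frags)

    def test_empty_input_all_zero(self):
        st_ = summarize_read_types([])
        assert st_.n_umi == st_.n_internal == 0
        assert st_.internal_fraction == 0.0

    def test_internal_proportion(self):
        frags = [make_fragment(key=("u", i), umi="A") for i in range(25)]
        frags += [make_fragment(key=("i", i)) for i in range(75)]
        assert summarize_read_types(frags).internal_fraction == 0.75

    def test_orientation_tally(self):
        fr = make_fragment(strand="+", mate1_strand="+", key=1, umi="A")
        rf = make_fragment(strand="+", mate1_strand="-", key=2, umi="C")
        unk = make_fragment(strand=".", mate1_strand="+", key=3)
        st_ = summarize_read_types([fr, rf, unk])
        assert (st_.umi_fr, st_.umi_rf, st_.internal_unknown) == (1, 1, 1)


def test_simulated_sam_round_trips(clean_dataset):
    """Simulator-written records re-load with blocks/junctions intact."""
    frags = load_fragments(clean_dataset.sam_paths["CELL00"])
    truth = clean_dataset.truth_table
    assert len(frags) == len(truth)
    by_tx = {t.transcript_id: t for t in clean_dataset.truth}
    for f in frags:
        if f.junctions:
            tx_introns = set()
            for t in by_tx.values():
                tx_introns |= set(t.introns)
            assert set(f.junctions) <= tx_introns
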