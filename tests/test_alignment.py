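"""SAM/PAF parsing, SAM→PAF conversion, flag filtering, best-mapping choice."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from transieve.alignment import (
    AlignmentParseError,
    AlignmentRecord,
    DEFAULT_EXCLUDE_MASK,
    best_per_transcript,
    filter_flags,
    parse_cigar,
    read_paf,
    read_sam,
    sam_to_paf,
    select_best,
    trim_terminal_artefacts,
    write_paf,
)
from oracles import count_matches_columnwise, random_toy_alignment

PAF_LINE = "t1\t100\t0\t100\t+\tchr1\t5000\t200\t400\t95\t100\t60\tcg:Z:50M100N50M"


class TestReadPaf:
    def test_field_mapping(self):
        (r,) = read_paf([PAF_LINE])
        assert (r.qname, r.qlen, r.qstart, r.qend) == ("t1", 100, 0, 100)
        assert (r.tname, r.tlen, r.tstart, r.tend) == ("chr1", 5000, 200, 400)
        assert (r.matches, r.block_len, r.mapq) == (95, 100, 60)
        assert r.cigar == "50M100N50M"
        assert r.flags == 0 and r.is_mapped
        r.validate()

    def test_empty_stream(self):
        assert read_paf([]) == []

    def test_too_few_columns_names_line(self):
        with pytest.raises(AlignmentParseError, match="line 2"):
            read_paf([PAF_LINE, PAF_LINE.rsplit("\t", 2)[0]])

    def test_non_integer_coordinate(self):
        bad = PAF_LINE.replace("\t200\t", "\ttwo\t")
        with pytest.raises(AlignmentParseError, match="line 1"):
            read_paf([bad])

    def test_missing_cigar_tag_gives_empty_cigar(self):
        (r,) = read_paf([PAF_LINE.rsplit("\t", 1)[0]])
        assert r.cigar == ""


class TestReadSam:
    SAM = [
        "@SQ\tSN:chr1\tLN:5000",
        "t1\t0\tchr1\t201\t60\t50M100N50M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:5",
        "t2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*",
    ]

    def test_mapped_record_keeps_sam_position(self):
        records = read_sam(self.SAM)
        r = records[0]
        assert r.is_mapped and r.tstart == 201 and r.tlen == 5000
        assert r.qlen == 100 and r.tags["NM"] == "5"

    def test_flag4_is_unmapped(self):
        assert read_sam(self.SAM)[1].is_mapped is False

    def test_headers_only(self):
        assert read_sam(["@HD\tVN:1.6", "@SQ\tSN:c\tLN:10"]) == []

    def test_missing_column_raises(self):
        with pytest.raises(AlignmentParseError, match="11 mandatory"):
            read_sam(["t1\t0\tchr1\t201\t60\t50M"])

    def test_missing_sq_header_gives_tlen_zero(self):
        (r,) = read_sam([self.SAM[1]])
        assert r.tlen == 0


class TestSamToPaf:
    def _sam(self, pos, cigar, strand_flag=0, **tags):
        return AlignmentRecord(
            qname="t", tname="chr1", tlen=100000, tstart=pos, cigar=cigar,
            flags=strand_flag, strand="-" if strand_flag & 0x10 else "+",
            tags={k: str(v) for k, v in tags.items()},
        )

    def test_coordinate_shift(self):
        p = sam_to_paf(self._sam(1, "10M", NM=0))
        assert (p.tstart, p.tend, p.qstart, p.qend) == (0, 10, 0, 10)
        assert (p.matches, p.block_len) == (10, 10)

    def test_soft_clip_offsets_query(self):
        p = sam_to_paf(self._sam(1, "5S10M"))
        assert (p.qstart, p.qend, p.qlen) == (5, 15, 15)

    def test_reverse_strand_swaps_clip_roles(self):
        p = sam_to_paf(self._sam(1, "5S10M", strand_flag=0x10))
        assert (p.qstart, p.qend) == (0, 10)

    def test_nm_recovers_matches(self):
        p = sam_to_paf(self._sam(1, "100M", NM=30))
        assert (p.matches, p.block_len) == (70, 100)

    def test_intron_excluded_from_block(self):
        p = sam_to_paf(self._sam(1, "50M100N50M", NM=0))
        assert p.block_len == 100 and p.tend - p.tstart == 200

    def test_indels_enter_block_and_nm(self):
        p = sam_to_paf(self._sam(1, "10M2I10M3D10M", NM=5))
        assert p.block_len == 35 and p.matches == 30  # NM fully explained by indels

    def test_nm_below_indels_clamps(self, caplog):
        p = sam_to_paf(self._sam(1, "10M5I10M", NM=2))
        assert p.matches == 20

    def test_no_nm_flags_approximate(self):
        p = sam_to_paf(self._sam(1, "10M"))
        assert p.matches == 10 and p.tags.get("approx_matches") == "1"

    def test_missing_cigar_rejected(self):
        with pytest.raises(ValueError):
            sam_to_paf(self._sam(1, ""))

    def test_matches_equal_columnwise_oracle(self):
        """Conversion agrees with expanding the alignment base by base."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            query, target, cigar, nm = random_toy_alignment(rng)
            p = sam_to_paf(self._sam(1, cigar, NM=nm))
            assert p.matches == count_matches_columnwise(query, target, cigar)
            p.validate()

    def test_roundtrip_through_paf_text(self):
        rng = np.random.default_rng(7)
        originals = []
        for _ in range(20):
            _, _, cigar, nm = random_toy_alignment(rng)
            originals.append(sam_to_paf(self._sam(5, cigar, NM=nm)))
        buf = io.StringIO()
        write_paf(originals, buf)
        buf.seek(0)
        for orig, back in zip(originals, read_paf(buf)):
            assert (back.qstart, back.qend, back.qlen) == \
                (orig.qstart, orig.qend, orig.qlen)
            assert (back.tstart, back.tend) == (orig.tstart, orig.tend)
            assert (back.matches, back.block_len) == (orig.matches, orig.block_len)
            assert back.cigar == orig.cigar

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_conversion_preserves_invariants(self, seed):
        rng = np.random.default_rng(seed)
        _, _, cigar, nm = random_toy_alignment(rng)
        sam_to_paf(self._sam(1, cigar, NM=nm)).validate()


class TestFilterFlags:
    def _r(self, flags):
        return AlignmentRecord(qname="t", flags=flags,
                               is_mapped=not flags & 0x4)

    @pytest.mark.parametrize("flags,kept", [
        (0, True), (256, True), (4, False), (2048, False), (16, True),
        (2048 | 256, False),
    ])
    def test_default_mask(self, flags, kept):
        out = filter_flags([self._r(flags)], DEFAULT_EXCLUDE_MASK)
        assert bool(out) is kept


class TestSelectBest:
    def _r(self, matches, flags=0, tname="c1", tstart=0, qname="t"):
        return AlignmentRecord(qname=qname, matches=matches, flags=flags,
                               tname=tname, tstart=tstart,
                               is_mapped=not flags & 0x4)

    def test_primary_beats_stronger_secondary(self):
        primary = self._r(90)
        secondary = self._r(95, flags=0x100)
        assert select_best([secondary, primary]) is primary

    def test_best_secondary_when_no_primary(self):
        a, b = self._r(80, flags=0x100), self._r(90, flags=0x100)
        assert select_best([a, b]) is b

    def test_unmapped_only_gives_none(self):
        assert select_best([self._r(0, flags=4)]) is None

    def test_deterministic_tiebreak(self):
        a = self._r(90, tname="c2", tstart=5)
        b = self._r(90, tname="c1", tstart=9)
        c = self._r(90, tname="c1", tstart=3)
        assert select_best([a, b, c]) is c

    def test_idempotent_and_member(self):
        records = [self._r(m, flags=f) for m, f in
                   [(50, 0), (70, 0x100), (60, 0)]]
        best = select_best(records)
        assert best in records
        assert select_best([best]) is best

    def test_mixed_qnames_rejected(self):
        with pytest.raises(ValueError):
            select_best([self._r(1, qname="a"), self._r(1, qname="b")])

    def test_grouping(self):
        records = [self._r(50, qname="a"), self._r(70, qname="a"),
                   self._r(10, qname="b", flags=4)]
        best = best_per_transcript(records)
        assert set(best) == {"a"} and best["a"].matches == 70


class TestTrimTerminalArtefacts:
    def _r(self, cigar, matches=None, qlen=None):
        ops = parse_cigar(cigar)
        qlen = qlen or sum(n for n, op in ops if op in "MIS=XH")
        tspan = sum(n for n, op in ops if op in "MDN=X")
        block = sum(n for n, op in ops if op in "MID=X")
        return AlignmentRecord(
            qname="t", qlen=qlen,
            qstart=ops[0][0] if ops[0][1] in "SH" else 0,
            qend=qlen - (ops[-1][0] if ops[-1][1] in "SH" else 0),
            tname="c", tlen=10 * tspan + 100, tstart=50, tend=50 + tspan,
            matches=matches if matches is not None else block,
            block_len=block, cigar=cigar,
        )

    def test_short_leading_exon_removed(self):
        out = trim_terminal_artefacts(self._r("5M100N95M"), 10)
        assert out.cigar == "5S95M"
        assert out.qstart == 5 and out.qend == 100
        assert out.tstart == 50 + 105 and out.tend == 50 + 200
        out.validate()

    def test_single_block_unchanged(self):
        r = self._r("100M")
        assert trim_terminal_artefacts(r, 10) is r

    def test_long_exons_unchanged(self):
        r = self._r("50M100N50M")
        assert trim_terminal_artefacts(r, 10) is r

    def test_both_ends_trimmed(self):
        out = trim_terminal_artefacts(self._r("3M80N50M90N4M"), 10)
        assert out.cigar == "3S50M4S"
        assert out.qstart == 3 and out.qend == 53
        out.validate()

    def test_would_empty_returns_unchanged(self):
        r = self._r("5M100N5M")
        assert trim_terminal_artefacts(r, 10) is r

    def test_matches_and_block_shrink(self):
        out = trim_terminal_artefacts(self._r("5M100N95M", matches=98), 10)
        assert out.block_len == 95 and out.matches == 93
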