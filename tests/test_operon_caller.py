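"""TU assembly, operon grouping, internal-site detection, type
classification and summary arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opterm.genome_io import FullLengthRead, Gene, SiteRecord
from opterm.operons import (
    CallerParams,
    Operon,
    build_transcription_units,
    call_operons,
    classify_operon_type,
    percent,
    round_half_away,
    summarize_operons,
)


def tss(pos, strand="+", count=10, cond="wt"):
    return SiteRecord("chr1", pos, strand, "TSS", count, cond)


def tts(pos, strand="+", count=10, cond="wt"):
    return SiteRecord("chr1", pos, strand, "TTS", count, cond)


@pytest.fixture
def two_gene_fixture():
    genes = [Gene("chr1", 100, 400, "+", "A"), Gene("chr1", 500, 900, "+", "B")]
    return genes


class TestBuildTranscriptionUnits:
    def test_read_linking_tss_and_tts_yields_one_tu(self, two_gene_fixture):
        reads = [FullLengthRead("chr1", 78, 951, "+", "r0")]
        tus = build_transcription_units(
            two_gene_fixture, [tss(80)], [tts(949)], reads,
            CallerParams(delta5=20, delta3=20, min_read_support=1))
        assert len(tus) == 1
        assert [g.locus_tag for g in tus[0].gene_list] == ["A", "B"]
        assert tus[0].supporting_reads == 1

    def test_no_reads_no_tu(self, two_gene_fixture):
        tus = build_transcription_units(
            two_gene_fixture, [tss(80)], [tts(949)], [],
            CallerParams(20, 20, 1))
        assert tus == []

    def test_strand_mismatch_gives_no_tu(self, two_gene_fixture):
        reads = [FullLengthRead("chr1", 78, 951, "+", "r0")]
        tus = build_transcription_units(
            two_gene_fixture, [tss(80, strand="-")], [tts(949)], reads,
            CallerParams(20, 20, 1))
        assert tus == []

    def test_read_support_threshold(self, two_gene_fixture):
        reads = [FullLengthRead("chr1", 78, 951, "+", "r0")]
        tus = build_transcription_units(
            two_gene_fixture, [tss(80)], [tts(949)], reads,
            CallerParams(20, 20, min_read_support=2))
        assert tus == []

    def test_partially_overlapped_gene_excluded(self):
        # gene C extends past the TTS: full containment is required
        genes = [Gene("chr1", 100, 400, "+", "A"), Gene("chr1", 500, 1100, "+", "C")]
        reads = [FullLengthRead("chr1", 80, 950, "+", "r0")]
        tus = build_transcription_units(genes, [tss(80)], [tts(949)], reads,
                                        CallerParams(20, 20, 1))
        assert len(tus) == 1
        assert [g.locus_tag for g in tus[0].gene_list] == ["A"]

    def test_minus_strand_tu_gene_order_is_five_to_three(self):
        genes = [Gene("chr1", 100, 400, "-", "A"), Gene("chr1", 500, 900, "-", "B")]
        # on '-', TSS at high coordinate, TTS at low
        reads = [FullLengthRead("chr1", 78, 951, "-", "r0")]
        tus = build_transcription_units(genes, [tss(950, "-")], [tts(79, "-")],
                                        reads, CallerParams(20, 20, 1))
        assert len(tus) == 1
        assert [g.locus_tag for g in tus[0].gene_list] == ["B", "A"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_adding_reads_never_removes_a_tu(self, data):
        genes = [Gene("chr1", 100, 400, "+", "A"), Gene("chr1", 500, 900, "+", "B"),
                 Gene("chr1", 1000, 1300, "+", "C")]
        sites5 = [tss(80), tss(480)]
        sites3 = [tts(949), tts(1349)]
        span_choices = [(78, 951), (78, 1351), (478, 951), (478, 1351)]
        base = data.draw(st.lists(st.sampled_from(span_choices), max_size=4))
        extra = data.draw(st.lists(st.sampled_from(span_choices), min_size=1,
                                   max_size=3))
        def mk(spans):
            return [FullLengthRead("chr1", s, e, "+", f"r{i}")
                    for i, (s, e) in enumerate(spans)]
        params = CallerParams(20, 20, 1)
        before = build_transcription_units(genes, sites5, sites3, mk(base), params)
        after = build_transcription_units(genes, sites5, sites3,
                                          mk(base + extra), params)
        key = lambda t: (t.tss.position, t.tts.position)
        assert {key(t) for t in before} <= {key(t) for t in after}


class TestCallOperons:
    def test_sub_tu_tts_becomes_iotts(self, two_gene_fixture):
        # a short TU ending between A and B marks an internal terminator
        sites5 = [tss(80)]
        sites3 = [tts(949), tts(430)]
        reads = [FullLengthRead("chr1", 80, 950, "+", "r0"),
                 FullLengthRead("chr1", 80, 431, "+", "r1")]
        tus = build_transcription_units(two_gene_fixture, sites5, sites3, reads,
                                        CallerParams(20, 20, 1))
        operons, singles = call_operons(tus, sites5, sites3, two_gene_fixture)
        assert len(operons) == 1 and not singles
        op = operons[0]
        assert [g.locus_tag for g in op.genes] == ["A", "B"]
        assert [s.position for s in op.internal_tts] == [430]
        assert op.type_label == "II"

    def test_operon_without_internal_sites_is_type_i(self, two_gene_fixture):
        sites5, sites3 = [tss(80)], [tts(949)]
        reads = [FullLengthRead("chr1", 80, 950, "+", "r0")]
        tus = build_transcription_units(two_gene_fixture, sites5, sites3, reads,
                                        CallerParams(20, 20, 1))
        operons, _ = call_operons(tus, sites5, sites3, two_gene_fixture)
        assert operons[0].internal_tss == [] and operons[0].internal_tts == []
        assert operons[0].type_label == "I"

    def test_tts_inside_cds_not_recorded_as_iotts(self, two_gene_fixture):
        sites5 = [tss(80)]
        sites3 = [tts(949), tts(600)]  # 600 is inside gene B
        reads = [FullLengthRead("chr1", 80, 950, "+", "r0")]
        tus = build_transcription_units(two_gene_fixture, sites5, sites3, reads,
                                        CallerParams(20, 20, 1))
        operons, _ = call_operons(tus, sites5, sites3, two_gene_fixture)
        assert operons[0].internal_tts == []

    def test_single_gene_tus_reported_separately(self):
        genes = [Gene("chr1", 100, 400, "+", "A")]
        sites5, sites3 = [tss(80)], [tts(449)]
        reads = [FullLengthRead("chr1", 80, 450, "+", "r0")]
        tus = build_transcription_units(genes, sites5, sites3, reads,
                                        CallerParams(20, 20, 1))
        operons, singles = call_operons(tus, sites5, sites3, genes)
        assert operons == [] and len(singles) == 1

    def test_every_internal_site_lies_in_an_intergenic_gap(self, noise_free_dataset):
        # construction invariant checked on a full simulated run
        truth, evidence = noise_free_dataset
        genes = truth.genes
        all_tss = [s for v in evidence.tss.values() for s in v]
        all_tts = [s for v in evidence.tts.values() for s in v]
        all_reads = [r for v in evidence.reads.values() for r in v]
        tus = build_transcription_units(genes, all_tss, all_tts, all_reads)
        operons, _ = call_operons(tus, all_tss, all_tts, genes)
        n_internal = 0
        for op in operons:
            genomic = sorted(op.genes, key=lambda g: g.start)
            gaps = [(a.end, b.start) for a, b in zip(genomic, genomic[1:])]
            lo, hi = op.span
            for s in op.internal_tss + op.internal_tts:
                n_internal += 1
                assert lo < s.position < hi - 1
                assert any(a <= s.position < b for a, b in gaps)
                assert not any(g.start <= s.position < g.end for g in genomic)
        assert n_internal > 0

    def test_strand_symmetry_mirrored_dataset(self, noise_free_dataset):
        truth, evidence = noise_free_dataset
        genes = truth.genes
        L = len(truth.sequences["chr1"])
        flip = {"+": "-", "-": "+"}
        m_genes = [Gene("chr1", L - g.end, L - g.start, flip[g.strand],
                        g.locus_tag) for g in genes]
        def m_site(s):
            return SiteRecord("chr1", L - 1 - s.position, flip[s.strand],
                              s.kind, s.count, s.condition)
        def m_read(r):
            return FullLengthRead("chr1", L - r.end, L - r.start,
                                  flip[r.strand], r.read_id)
        all_tss = [s for v in evidence.tss.values() for s in v]
        all_tts = [s for v in evidence.tts.values() for s in v]
        all_reads = [r for v in evidence.reads.values() for r in v]
        fwd_tus = build_transcription_units(genes, all_tss, all_tts, all_reads)
        fwd_ops, _ = call_operons(fwd_tus, all_tss, all_tts, genes)
        mir_tus = build_transcription_units(
            m_genes, [m_site(s) for s in all_tss], [m_site(s) for s in all_tts],
            [m_read(r) for r in all_reads])
        mir_ops, _ = call_operons(mir_tus, [m_site(s) for s in all_tss],
                                  [m_site(s) for s in all_tts], m_genes)
        key = lambda o: (sorted(g.locus_tag for g in o.genes), o.type_label)
        assert sorted(map(key, fwd_ops)) == sorted(map(key, mir_ops))


class TestClassification:
    @pytest.mark.parametrize("n_iotss,n_iotts,label", [
        (0, 0, "I"), (0, 1, "II"), (1, 0, "III"), (2, 3, "IV"), (1, 1, "IV"),
    ])
    def test_four_type_rule(self, n_iotss, n_iotts, label):
        op = _mk_operon(n_iotss, n_iotts)
        assert classify_operon_type(op) == label


def _mk_operon(n_iotss=0, n_iotts=0, length=1000):
    genes = [Gene("chr1", 100, 400, "+", f"a{id(object())}"),
             Gene("chr1", 500, 900, "+", f"b{id(object())}")]
    op = Operon("op", "chr1", "+", SiteRecord("chr1", 80, "+", "TSS", 5, "u"),
                SiteRecord("chr1", 80 + length - 1, "+", "TTS", 5, "u"),
                genes, 5)
    op.internal_tss = [SiteRecord("chr1", 450 + i, "+", "TSS", 1, "u")
                       for i in range(n_iotss)]
    op.internal_tts = [SiteRecord("chr1", 470 + i, "+", "TTS", 1, "u")
                       for i in range(n_iotts)]
    return op


class TestSummary:
    @pytest.mark.parametrize("num,den,expected", [
        (157, 410, 38), (0, 410, 0), (210, 410, 51), (1, 2, 50),
    ])
    def test_percent_rounding(self, num, den, expected):
        assert percent(num, den) == expected

    def test_round_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(3.5) == 4
        assert round_half_away(-2.5) == -3

    def test_summary_fields(self):
        operons = [_mk_operon(0, 1), _mk_operon(0, 0)]
        for i, op in enumerate(operons):
            op.type_label = classify_operon_type(op)
        s = summarize_operons(operons, [])
        assert s["n_operons"] == 2
        assert s["type_counts"]["II"] == 1
        assert s["pct_iotts_operons"] == 50
        assert s["median_operon_length_nt"] == 1000.0
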