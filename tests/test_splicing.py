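"""Junction annotation, exon catalogs and splicing-event classification."""

import pytest

from pirnascan.align import ExonChain
from pirnascan.sequence import GenomicInterval, SeqRecord
from pirnascan.splicing import (
    annotate_junctions,
    build_exon_catalog,
    classify_events,
)


def chain(tid, exons, chrom="g", strand="+"):
    return ExonChain(
        transcript_id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        identity=1.0,
        score=0.0,
    )


TOY = [SeqRecord("g", "CCGGA" + "GTAAGTTTTAG" + "TACGT")]


class TestAnnotateJunctions:
    def test_single_exon_chain_has_no_junctions(self):
        assert annotate_junctions(chain("t", [(0, 21)]), TOY) == []

    def test_toy_intron_is_canonical(self):
        (j,) = annotate_junctions(chain("t", [(0, 5), (16, 21)]), TOY)
        assert (j.donor_dinuc, j.acceptor_dinuc, j.canonical) == ("GT", "AG", True)
        assert (j.donor_pos, j.acceptor_pos) == (5, 15)

    def test_minus_strand_reads_transcribed_complement(self):
        # on '-', a genomic CT..AC intron is GT..AG on the transcribed strand
        g = [SeqRecord("g", "AAACC" + "CTTTTTTTTAC" + "GGAAA")]
        (j,) = annotate_junctions(chain("t", [(0, 5), (16, 21)], strand="-"), g)
        assert (j.donor_dinuc, j.acceptor_dinuc) == ("GT", "AG")
        assert j.canonical

    def test_all_synthetic_junctions_canonical(self, clean_dataset, aligned_chains):
        cfg, truth, transcripts, iso = clean_dataset
        genome = list(truth.genome)
        n = 0
        for t in transcripts:
            for c in aligned_chains[t.id]:
                for j in annotate_junctions(c, genome):
                    assert j.canonical
                    n += 1
        assert n > 0


class TestExonCatalog:
    def test_identical_chains_collapse(self):
        a = chain("a", [(0, 5), (16, 21)])
        cat = build_exon_catalog([a, chain("b", [(0, 5), (16, 21)])])
        assert [(e.start, e.end) for e in cat.exons] == [(0, 5), (16, 21)]

    def test_union_keeps_order_and_distinct_variants(self):
        a = chain("a", [(0, 5), (10, 14), (16, 21)])
        b = chain("b", [(0, 5), (16, 21)])
        c = chain("c", [(0, 5), (10, 12), (16, 21)])  # alt boundary variant
        cat = build_exon_catalog([a, b, c])
        assert [(e.start, e.end) for e in cat.exons] == [
            (0, 5),
            (10, 12),
            (10, 14),
            (16, 21),
        ]
        assert cat.label(GenomicInterval("g", 10, 14)) == "e3"

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            build_exon_catalog([chain("a", [(0, 5)]), chain("b", [(0, 5)], chrom="h")])


class TestClassifyEvents:
    E = [(0, 10), (20, 30), (40, 50), (60, 70)]

    def test_identical_chains_yield_nothing(self):
        a = chain("a", self.E)
        assert classify_events(a, a) == []

    def test_exon_skipping(self):
        a = chain("a", [self.E[0], self.E[2], self.E[3]])
        b = chain("b", self.E)
        (ev,) = classify_events(a, b)
        assert ev.event_type == "exon_skipping"
        assert [(iv.start, iv.end) for iv in ev.exons_b] == [(20, 30)]

    def test_alt_splice_sites_depend_on_strand(self):
        a = chain("a", [(0, 10), (20, 34), (40, 50)])
        b = chain("b", [(0, 10), (20, 30), (40, 50)])
        assert classify_events(a, b)[0].event_type == "alt_5ss"
        am = chain("a", [(0, 10), (20, 34), (40, 50)], strand="-")
        bm = chain("b", [(0, 10), (20, 30), (40, 50)], strand="-")
        assert classify_events(am, bm)[0].event_type == "alt_3ss"
        c = chain("c", [(0, 10), (16, 30), (40, 50)])
        assert classify_events(c, b)[0].event_type == "alt_3ss"

    def test_intron_retention(self):
        a = chain("a", [(0, 10), (20, 50), (60, 70)])
        b = chain("b", self.E)
        (ev,) = classify_events(a, b)
        assert ev.event_type == "intron_retention"

    def test_mutually_exclusive(self):
        a = chain("a", [self.E[0], self.E[1], self.E[3]])
        b = chain("b", [self.E[0], self.E[2], self.E[3]])
        (ev,) = classify_events(a, b)
        assert ev.event_type == "mutually_exclusive"

    def test_both_boundaries_shifted_is_complex_not_alt_site(self):
        a = chain("a", [(0, 10), (16, 34), (40, 50)])
        b = chain("b", [(0, 10), (20, 30), (40, 50)])
        (ev,) = classify_events(a, b)
        assert ev.event_type == "complex"

    def test_terminal_truncation_is_end_variation(self):
        a = chain("a", [(20, 30), (40, 50)])
        b = chain("b", [(0, 10), (20, 30), (40, 50)])
        (ev,) = classify_events(a, b)
        assert ev.event_type == "end_variation"

    def test_symmetry_swaps_roles(self):
        a = chain("a", [self.E[0], self.E[2], self.E[3]])
        b = chain("b", self.E)
        fwd = classify_events(a, b)
        rev = classify_events(b, a)
        assert [e.event_type for e in fwd] == [e.event_type for e in rev]
        assert fwd[0].exons_a == rev[0].exons_b

    def test_two_independent_events_decompose(self):
        # skipped exon next to an internal alternative donor site, with no
        # shared exon separating them
        a = chain("a", [(0, 10), (40, 54), (60, 70)])
        b = chain("b", self.E)
        types = sorted(e.event_type for e in classify_events(a, b))
        assert types == ["alt_5ss", "exon_skipping"]

    def test_terminal_boundary_shift_is_end_variation_not_alt_site(self):
        # the last exon's outer end is a transcript end, not a splice site
        a = chain("a", [(0, 10), (20, 30), (40, 50), (60, 74)])
        b = chain("b", self.E)
        (ev,) = classify_events(a, b)
        assert ev.event_type == "end_variation"

    def test_disjoint_loci_rejected(self):
        a = chain("a", [(0, 10)])
        b = chain("b", [(100, 120)])
        with pytest.raises(ValueError):
            classify_events(a, b)


class TestSyntheticEventRecovery:
    def test_planted_event_multiset_recovered(self):
        """Every planted event type — all five elementary categories plus
        complex — is recovered exactly from recovered chains, and never as
        another elementary type."""
        from pirnascan.align import align_transcripts
        from pirnascan.simulate import SynthConfig, make_genome, make_isoform_set
        from tests.conftest import SYNTH_ALIGN

        seen = set()
        for seed in range(8):
            cfg = SynthConfig(seed=seed, copy_mutation_rate=0.0, n_isoforms=13)
            truth = make_genome(cfg)
            transcripts, iso = make_isoform_set(cfg, truth)
            chains = align_transcripts(transcripts, list(truth.genome), SYNTH_ALIGN)
            c0 = truth.main_copies[0]
            at0 = {
                tid: c
                for tid, cs in chains.items()
                for c in cs
                if c.chrom == truth.chrom and c0.start <= c.start and c.end <= c0.end
            }
            catalog = build_exon_catalog(list(at0.values()))
            for ev in iso.events:
                res = classify_events(at0[ev.isoform_a], at0[ev.isoform_b], catalog)
                assert [e.event_type for e in res] == [ev.event_type], (seed, ev)
                seen.add(ev.event_type)
        assert seen == {
            "exon_skipping",
            "alt_5ss",
            "alt_3ss",
            "mutually_exclusive",
            "intron_retention",
            "complex",
        }

    def test_catalog_matches_generator_exon_master_list(self, clean_dataset, aligned_chains):
        cfg, truth, transcripts, iso = clean_dataset
        c0 = truth.main_copies[0]
        at0 = [
            c
            for cs in aligned_chains.values()
            for c in cs
            if c0.start <= c.start and c.end <= c0.end and c.chrom == truth.chrom
        ]
        cat = build_exon_catalog(at0)
        truth_exons = {
            (iv.start, iv.end)
            for tid in iso.chains
            for iv in iso.chains[tid][0]
        }
        assert {(e.start, e.end) for e in cat.exons} == truth_exons
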