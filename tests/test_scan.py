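"""Homology scanner: maximal-hit semantics, oracle agreement, dedup."""

import numpy as np
import pytest

from pirnascan.scan import (
    HomologyHit,
    ScanParams,
    classify_location,
    dedupe_unique_stretches,
    merge_hits,
    scan,
    transcript_boundaries,
)
from pirnascan.scan_oracle import scan_bruteforce
from pirnascan.sequence import SeqRecord, reverse_complement

_B = np.frombuffer(b"ACGT", np.uint8)


def rnd(rng, n):
    return bytes(_B[rng.integers(0, 4, n)]).decode()


def hit_key(h):
    return (
        h.query_id,
        h.query_start,
        h.query_end,
        h.target_id,
        h.target_start,
        h.target_end,
        h.orientation,
        h.mismatches,
    )


class TestScanSemantics:
    def test_identical_sequences_single_full_hit(self):
        q = SeqRecord("q", "ACGTTGCAGGTCAATG")
        hits = [
            h
            for h in scan([q], [SeqRecord("t", q.seq)], ScanParams.deregulated())
            if h.orientation == "+/+"
        ]
        assert len(hits) == 1
        (h,) = hits
        assert (h.length, h.mismatches, h.query_start, h.target_start) == (16, 0, 0, 0)

    def test_revcomp_hit_with_one_mismatch(self):
        rng = np.random.default_rng(5)
        q = rnd(rng, 60)
        frag = list(reverse_complement(q[20:32]))
        frag[5] = {"A": "C"}.get(frag[5], "A")
        t = rnd(rng, 25) + "".join(frag) + rnd(rng, 25)
        params = ScanParams.deregulated()
        got = scan([SeqRecord("q", q)], [SeqRecord("t", t)], params)
        want = scan_bruteforce([SeqRecord("q", q)], [SeqRecord("t", t)], params)
        assert [hit_key(h) for h in got] == [hit_key(h) for h in want]
        # the planted window is covered by a +/- hit within budget (the
        # maximal hit may extend onto matching flank bases)
        rc_hits = [h for h in got if h.orientation == "+/-" and h.mismatches <= 1]
        assert any(h.query_start <= 20 and h.query_end >= 32 for h in rc_hits)

    def test_orientation_symmetry(self):
        rng = np.random.default_rng(9)
        q, t = rnd(rng, 80), rnd(rng, 60) + rnd(rng, 12) + rnd(rng, 20)
        t = t[:30] + q[10:22] + t[42:]
        params = ScanParams.deregulated()
        fwd = scan([SeqRecord("q", q)], [SeqRecord("t", t)], params)
        mirror = scan(
            [SeqRecord("q", reverse_complement(q))], [SeqRecord("t", t)], params
        )
        L = len(q)
        flipped = {
            (L - h.query_end, L - h.query_start, h.target_start,
             "+/-" if h.orientation == "+/+" else "+/+", h.mismatches)
            for h in fwd
        }
        got = {
            (h.query_start, h.query_end, h.target_start, h.orientation, h.mismatches)
            for h in mirror
        }
        assert flipped == got

    @pytest.mark.parametrize("mode", ["deregulated", "utrdb"])
    def test_monotonicity_in_budget_and_band(self, mode):
        rng = np.random.default_rng(17)
        q = SeqRecord("q", rnd(rng, 150))
        t = SeqRecord("t", q.seq[40:90] + rnd(rng, 60))
        base = getattr(ScanParams, mode)()
        hits = scan([q], [t], base)
        looser = ScanParams(
            min_len=base.min_len,
            max_len=base.max_len,
            max_mismatch=base.max_mismatch + 1,
        )
        assert len(scan([q], [t], looser)) >= len(hits)
        # raising min_len only drops short hits; the rest are unchanged
        narrower = ScanParams(
            min_len=base.min_len + 2,
            max_len=base.max_len,
            max_mismatch=base.max_mismatch,
        )
        narrow_hits = scan([q], [t], narrower)
        assert len(narrow_hits) <= len(hits)
        assert all(h.length >= base.min_len + 2 for h in narrow_hits)
        assert all(h.length <= base.max_len for h in hits)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(min_len=0)
        with pytest.raises(ValueError):
            ScanParams(min_len=10, max_len=5)
        with pytest.raises(ValueError):
            ScanParams(max_mismatch=-1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["deregulated", "utrdb"])
    def test_random_pairs_agree_hit_for_hit(self, mode):
        """Seeded scanner equals exhaustive enumeration on random pairs."""
        rng = np.random.default_rng(123)
        params = getattr(ScanParams, mode)()
        for _ in range(40):
            q = SeqRecord("q", rnd(rng, int(rng.integers(30, 300))))
            t = SeqRecord("t", rnd(rng, int(rng.integers(30, 300))))
            assert [hit_key(h) for h in scan([q], [t], params)] == [
                hit_key(h) for h in scan_bruteforce([q], [t], params)
            ]

    def test_shared_fragment_pairs_agree(self):
        rng = np.random.default_rng(31)
        params = ScanParams.utrdb()
        for _ in range(25):
            q = rnd(rng, 200)
            s = int(rng.integers(0, 160))
            frag = list(q[s : s + 30])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, 30))
                frag[p] = "ACGT"[int(rng.integers(0, 4))]
            t = rnd(rng, 40) + "".join(frag) + rnd(rng, 40)
            qr, tr = SeqRecord("q", q), SeqRecord("t", t)
            assert [hit_key(h) for h in scan([qr], [tr], params)] == [
                hit_key(h) for h in scan_bruteforce([qr], [tr], params)
            ]


class TestLocationAndDedup:
    def _hit(self, qs, qe):
        return HomologyHit("q", qs, qe, "t", 0, qe - qs, "+/+", 0)

    def test_single_exon_transcript_is_always_exonic(self):
        assert classify_location(self._hit(5, 20), boundaries=[]) == "exonic"

    def test_junction_needs_overhang_on_both_sides(self):
        assert classify_location(self._hit(110, 126), [120]) == "junction"
        assert classify_location(self._hit(119, 121), [120], min_overhang=2) == "exonic"
        assert classify_location(self._hit(119, 121), [120], min_overhang=1) == "junction"
        # boundary touching the hit edge leaves no overhang
        assert classify_location(self._hit(110, 120), [120]) == "exonic"

    def test_boundaries_from_exon_lengths(self):
        assert transcript_boundaries([70, 55, 60]) == [70, 125]

    def test_same_stretch_in_three_utrs_counts_once(self):
        q = SeqRecord("q", "ACGTTGCAGGTCAATGTTACG")
        utrs = [SeqRecord(f"u{i}", "CCCCC" + q.seq[2:16] + "GGGGG") for i in range(3)]
        params = ScanParams.deregulated()
        import dataclasses

        hits = [
            dataclasses.replace(h, location="exonic")
            for h in merge_hits(scan([q], utrs, params))
        ]
        stretches, summary = dedupe_unique_stretches(hits, [q])
        assert summary.n_unique_stretches == 1
        assert len(stretches[0].hits) >= 3

    def test_summary_percentages(self, clean_dataset, planted_utrs):
        from pirnascan.scan import annotate_locations

        cfg, truth, transcripts, iso = clean_dataset
        utrs, planted = planted_utrs
        params = cfg.scan_params()
        bounds = {t.id: iso.boundaries(t.id) for t in transcripts}
        hits = annotate_locations(
            merge_hits(scan(transcripts, utrs, params)), bounds
        )
        _, summary = dedupe_unique_stretches(hits, transcripts)
        assert summary.n_exonic + summary.n_junction == summary.n_unique_stretches
        assert summary.pct_exonic + summary.pct_junction == pytest.approx(100.0, abs=0.01)
        assert (summary.n_exonic, summary.n_junction) == (8, 2)
        assert (summary.pct_exonic, summary.pct_junction) == (80.0, 20.0)
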