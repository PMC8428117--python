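"""Generator contracts: determinism, construction invariants, ground truth."""

import numpy as np
import pytest

from pirnascan.qpcr import livak
from pirnascan.scan import scan
from pirnascan.sequence import hamming, reverse_complement
from pirnascan.simulate import (
    ConfigError,
    CtSpec,
    PlantSpec,
    SynthConfig,
    make_ct_table,
    make_genome,
    make_isoform_set,
    plant_utr_matches,
    sample_pirna_reads,
)


class TestConfigValidation:
    def test_bad_event_mix_rejected(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SynthConfig(event_mix=(("skip", 0.5),))

    def test_short_introns_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(exon_lengths=(50, 50), intron_lengths=(20,))

    def test_pirna_range_bounds(self):
        with pytest.raises(ConfigError):
            SynthConfig(pirna_length_range=(10, 35))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(ct=CtSpec(sd_noise=-0.1))

    def test_unrecoverable_plant_rejected(self):
        cfg = SynthConfig(
            planted_hits=(PlantSpec(12, 0, "+/+", "exonic", 0),)
        )
        truth = make_genome(cfg)
        trs, iso = make_isoform_set(cfg, truth)
        with pytest.raises(ConfigError, match="maximal"):
            plant_utr_matches(cfg, trs, iso)


class TestGenome:
    def test_determinism(self):
        a = make_genome(SynthConfig(seed=4))
        b = make_genome(SynthConfig(seed=4))
        assert [r.seq for r in a.genome] == [r.seq for r in b.genome]
        assert a.copies == b.copies

    def test_copy_zero_exons_match_base_sequences(self):
        truth = make_genome(SynthConfig(seed=4, copy_mutation_rate=0.0))
        g = truth.seq(truth.chrom)
        c0 = truth.main_copies[0]
        assert tuple(g[iv.start : iv.end] for iv in c0.exons) == truth.base_exons

    def test_requested_copy_number_disjoint(self):
        truth = make_genome(SynthConfig(seed=5, n_locus_copies=5))
        copies = truth.main_copies
        assert len(copies) == 5
        for a, b in zip(copies, copies[1:]):
            assert a.end <= b.start

    def test_introns_flanked_by_gt_ag(self):
        truth = make_genome(SynthConfig(seed=6))
        for intron in truth.base_introns:
            assert intron.startswith("GT") and intron.endswith("AG")


class TestIsoforms:
    def test_all_skip_mix_removes_internal_exons(self):
        cfg = SynthConfig(
            seed=7,
            copy_mutation_rate=0.0,
            event_mix=(("skip", 1.0),),
            n_isoforms=5,
            reserved_junction=None,
        )
        truth = make_genome(cfg)
        transcripts, iso = make_isoform_set(cfg, truth)
        ref_exons = set(iso.chains[iso.reference_id][0])
        for t in transcripts[1:]:
            mine = set(iso.chains[t.id][0])
            missing = ref_exons - mine
            assert len(missing) == 1
            terminal = {min(ref_exons, key=lambda v: v.start), max(ref_exons, key=lambda v: v.start)}
            assert not (missing & terminal)

    def test_intron_retention_contains_full_intron(self):
        cfg = SynthConfig(
            seed=8, copy_mutation_rate=0.0, event_mix=(("intron_retention", 1.0),), n_isoforms=3
        )
        truth = make_genome(cfg)
        transcripts, iso = make_isoform_set(cfg, truth)
        for t in transcripts[1:]:
            assert any(i in t.seq for i in truth.base_introns)

    def test_event_inapplicable_raises(self):
        cfg = SynthConfig(
            seed=9,
            exon_lengths=(60, 60),
            intron_lengths=(60,),
            event_mix=(("mxe", 1.0),),
            n_isoforms=4,
            reserved_junction=None,
        )
        truth = make_genome(cfg)
        with pytest.raises(ConfigError):
            make_isoform_set(cfg, truth)


class TestPlants:
    def test_planted_windows_verify_against_their_spec(self, clean_dataset, planted_utrs):
        cfg, truth, transcripts, iso = clean_dataset
        utrs, planted = planted_utrs
        by_id = {t.id: t.seq for t in transcripts}
        by_utr = {u.id: u.seq for u in utrs}
        assert len(planted) == len(cfg.planted_hits)
        for h in planted:
            q = by_id[h.query_id][h.query_start : h.query_end]
            t = by_utr[h.target_id][h.target_start : h.target_end]
            probe = q if h.orientation == "+/+" else reverse_complement(q)
            assert hamming(probe, t) == h.mismatches

    def test_junction_plants_straddle_truth_boundary(self, clean_dataset, planted_utrs):
        cfg, truth, transcripts, iso = clean_dataset
        _, planted = planted_utrs
        for h in planted:
            bounds = iso.boundaries(h.query_id)
            covers = any(h.query_start + 1 <= b <= h.query_end - 1 for b in bounds)
            assert covers == (h.location == "junction")

    def test_zero_plants_leaves_only_chance_hits(self):
        cfg = SynthConfig(
            seed=10, copy_mutation_rate=0.0, planted_hits=(), clean_background=False
        )
        truth = make_genome(cfg)
        transcripts, iso = make_isoform_set(cfg, truth)
        utrs, planted = plant_utr_matches(cfg, transcripts, iso)
        assert planted == []
        hits = scan(transcripts, utrs, cfg.scan_params())
        # uniform background: chance 10-nt near-matches occur, long exact
        # stretches at the cap do not
        assert all(h.mismatches > 0 or h.length < cfg.scan_params().max_len for h in hits)


class TestReads:
    def test_lengths_within_configured_band(self, read_set, clean_dataset):
        cfg = clean_dataset[0]
        reads, rt = read_set
        lo, hi = cfg.pirna_length_range
        assert all(lo <= len(r.seq) <= hi for r in reads)

    def test_decoys_absent_from_genome_and_transcripts(self, clean_dataset, read_set):
        cfg, truth, transcripts, iso = clean_dataset
        reads, rt = read_set
        hay = [r.seq for r in truth.genome] + [t.seq for t in transcripts]
        for r in reads:
            if r.id in rt.decoy_ids:
                rc = reverse_complement(r.seq)
                assert not any(r.seq in h or rc in h for h in hay)
                assert rt.copy_counts[r.id] == 0

    def test_sampled_reads_carry_locus_copy_number(self, clean_dataset, read_set):
        cfg, truth, transcripts, iso = clean_dataset
        reads, rt = read_set
        for r in reads:
            if r.id not in rt.decoy_ids:
                assert rt.copy_counts[r.id] == cfg.n_locus_copies
                assert rt.chromosomes[r.id] == frozenset([truth.chrom])


class TestCtTable:
    def test_unit_fold_no_noise_gives_identical_groups(self):
        ct = make_ct_table(SynthConfig(seed=1, ct=CtSpec(1.0, 0.0, 3)))
        piv = ct.pivot_table(index="gene_role", columns="sample_group", values="ct")
        assert (piv["test"] == piv["control"]).all()

    def test_noise_free_fold_recovered_exactly(self):
        res = livak(make_ct_table(SynthConfig(seed=2, ct=CtSpec(1 / 3, 0.0, 4))))
        assert res.fold_change == pytest.approx(1 / 3, abs=1e-12)

    def test_mean_fold_recovery_under_noise(self):
        folds = [
            livak(
                make_ct_table(SynthConfig(seed=s, ct=CtSpec(1 / 3, 0.2, 4)))
            ).fold_change
            for s in range(200)
        ]
        assert np.mean(folds) == pytest.approx(1 / 3, rel=0.10)


class TestPurity:
    def test_generators_are_pure_functions_of_config(self):
        cfg = SynthConfig(seed=21, copy_mutation_rate=0.0)
        out = []
        for _ in range(2):
            truth = make_genome(cfg)
            transcripts, iso = make_isoform_set(cfg, truth)
            utrs, planted = plant_utr_matches(cfg, transcripts, iso)
            reads, rt = sample_pirna_reads(cfg, transcripts, truth, iso)
            out.append(
                (
                    [r.seq for r in truth.genome],
                    [t.seq for t in transcripts],
                    [u.seq for u in utrs],
                    planted,
                    [r.seq for r in reads],
                    rt.copy_counts,
                )
            )
        assert out[0] == out[1]
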