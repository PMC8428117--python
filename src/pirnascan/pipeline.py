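"""End-to-end orchestration: simulate -> align -> annotate -> scan -> map -> qPCR.

The pipeline wires the stage modules together over files, writes every
stage's table plus a machine-readable run summary, and is deterministic
given (config, seed). Results go only to files; logging goes to stderr and
a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, gffio
from .align import AlignParams, align_transcripts, assign_locus_groups
from .qpcr import livak, load_ct_table
from .scan import ScanParams, annotate_locations, dedupe_unique_stretches, merge_hits, scan
from .sequence import read_fasta
from .simulate import CtSpec, PlantSpec, SynthConfig, write_dataset
from .smallrna import PirnaParams, length_filter, map_exact, match_to_transcripts, placement_summary
from .splicing import annotate_junctions, build_exon_catalog, classify_events

log = logging.getLogger("pirnascan")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_SCAN_MODES = {
    "deregulated": dict(min_len=10, max_len=16, max_mismatch=1),
    "utrdb": dict(min_len=16, max_len=30, max_mismatch=2),
}


@dataclass
class PipelineConfig:
    output_dir: Path = Path("pirnascan_out")
    seed: int = 0
    log_level: str = "INFO"
    strict: bool = False
    target_chrom: str | None = None
    genome: Path | None = None
    transcripts: Path | None = None
    utrs: Path | None = None
    reads: Path | None = None
    ct_table: Path | None = None
    align: AlignParams = field(default_factory=AlignParams)
    scan_modes: dict = field(default_factory=lambda: {"deregulated": DEFAULT_SCAN_MODES["deregulated"]})
    pirna: PirnaParams = field(default_factory=PirnaParams)
    synth: SynthConfig = field(default_factory=SynthConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        cfg = cls()
        simple = {"seed", "log_level", "strict", "target_chrom"}
        for k in simple & raw.keys():
            setattr(cfg, k, raw[k])
        if "output_dir" in raw:
            cfg.output_dir = base / raw["output_dir"]
        for k in ("genome", "transcripts", "utrs", "reads", "ct_table"):
            if raw.get(k):
                setattr(cfg, k, base / raw[k])
        if "align" in raw:
            cfg.align = AlignParams(**raw["align"])
        if "scan_modes" in raw:
            cfg.scan_modes = dict(raw["scan_modes"])
        if "pirna" in raw:
            cfg.pirna = PirnaParams(**raw["pirna"])
        if "synth" in raw:
            s = dict(raw["synth"])
            s.setdefault("seed", cfg.seed)
            if "ct" in s:
                s["ct"] = CtSpec(**s["ct"])
            if "planted_hits" in s:
                s["planted_hits"] = tuple(PlantSpec(**p) for p in s["planted_hits"])
            for key in ("exon_lengths", "intron_lengths", "pirna_length_range"):
                if key in s:
                    s[key] = tuple(s[key])
            if "event_mix" in s:
                s["event_mix"] = tuple((k, float(v)) for k, v in s["event_mix"].items())
            cfg.synth = SynthConfig(**s)
        return cfg

    def scan_params(self, mode: str) -> ScanParams:
        return ScanParams(**self.scan_modes[mode])


def _setup_logging(cfg: PipelineConfig, outdir: Path) -> None:
    log.setLevel(cfg.log_level.upper())
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Write a synthetic dataset (with truth files) into output_dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)
    synth = cfg.synth
    if synth.seed != cfg.seed:
        synth = dataclasses.replace(synth, seed=cfg.seed)
    log.info("simulating dataset (seed=%d) into %s", cfg.seed, outdir)
    paths = write_dataset(synth, outdir)
    log.info("wrote %d files", len(paths))
    return paths


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every analysis stage available from the configured inputs.

    Returns the machine-readable run summary (also written as JSON).
    Stage failures raise :class:`PipelineError` naming the stage; outputs
    written before the failure are retained.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)
    t0 = time.time()
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "params": {
            "align": dataclasses.asdict(cfg.align),
            "scan_modes": cfg.scan_modes,
            "pirna": dataclasses.asdict(cfg.pirna),
        },
    }

    def stage(name):
        log.info("stage: %s", name)

    # --- align -----------------------------------------------------------
    chains_by_tid = {}
    transcripts = genome = None
    if cfg.genome and cfg.transcripts:
        stage("align")
        try:
            genome = read_fasta(cfg.genome)
            transcripts = read_fasta(cfg.transcripts)
            chains_by_tid = align_transcripts(transcripts, genome, cfg.align)
            all_chains = [c for cs in chains_by_tid.values() for c in cs]
            gffio.write_chains_gff3(all_chains, outdir / "chains.gff3")
            report = assign_locus_groups(chains_by_tid)
            gffio.write_tsv(report, outdir / "locus_report.tsv")
            summary["align"] = {
                "n_transcripts": len(transcripts),
                "n_placed": int((report["n_loci"] > 0).sum()),
                "n_unplaced": int((report["n_loci"] == 0).sum()),
                "n_single_locus": int(
                    report["locus_group"].str.startswith("locus").sum()
                ),
                "n_multi_locus": int((report["locus_group"] == "multi").sum()),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("align", str(e)) from e

    # --- annotate --------------------------------------------------------
    boundaries_by_tid: dict[str, list[int]] = {}
    if chains_by_tid:
        stage("annotate")
        try:
            rows = []
            n_canon = n_total = 0
            best_chains = {}
            for tid, cs in chains_by_tid.items():
                if not cs:
                    continue
                best = cs[0]
                best_chains[tid] = best
                from .scan import transcript_boundaries

                boundaries_by_tid[tid] = transcript_boundaries(best.exon_lengths)
                for j in annotate_junctions(best, genome):
                    rows.append(
                        {
                            "transcript_id": tid,
                            "intron": j.index + 1,
                            "donor": j.donor_dinuc,
                            "acceptor": j.acceptor_dinuc,
                            "canonical": int(j.canonical),
                        }
                    )
                    n_total += 1
                    n_canon += j.canonical
            gffio.write_tsv(pd.DataFrame(rows), outdir / "junctions.tsv")
            # splicing events of every isoform against the exon-richest one
            ev_rows = []
            same_locus = [
                c
                for c in best_chains.values()
            ]
            if len(same_locus) > 1:
                ref = max(same_locus, key=lambda c: (len(c.exons), -c.start))
                peers = [
                    c
                    for c in same_locus
                    if c.transcript_id != ref.transcript_id
                    and c.chrom == ref.chrom
                    and c.start < ref.end
                    and ref.start < c.end
                ]
                catalog = build_exon_catalog([ref] + peers)
                for c in peers:
                    for e in classify_events(c, ref, catalog):
                        ev_rows.append(
                            {
                                "isoform_a": e.isoform_a,
                                "isoform_b": e.isoform_b,
                                "event_type": e.event_type,
                            }
                        )
            gffio.write_tsv(
                pd.DataFrame(ev_rows, columns=["isoform_a", "isoform_b", "event_type"]),
                outdir / "events.tsv",
            )
            summary["annotate"] = {
                "n_junctions": n_total,
                "pct_canonical": round(100.0 * n_canon / n_total, 2) if n_total else 0.0,
                "n_events": len(ev_rows),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("annotate", str(e)) from e

    # --- scan ------------------------------------------------------------
    if cfg.utrs and transcripts is not None:
        stage("scan")
        try:
            utrs = read_fasta(cfg.utrs)
            summary["scan"] = {}
            for mode in cfg.scan_modes:
                params = cfg.scan_params(mode)
                hits = merge_hits(scan(transcripts, utrs, params))
                if boundaries_by_tid:
                    hits = annotate_locations(
                        hits, boundaries_by_tid, params.junction_min_overhang
                    )
                    stretches, hsum = dedupe_unique_stretches(hits, transcripts)
                    summary["scan"][mode] = {
                        "n_hits": len(hits),
                        "n_unique_stretches": hsum.n_unique_stretches,
                        "n_exonic": hsum.n_exonic,
                        "n_junction": hsum.n_junction,
                        "pct_exonic": hsum.pct_exonic,
                        "pct_junction": hsum.pct_junction,
                    }
                else:
                    summary["scan"][mode] = {"n_hits": len(hits)}
                gffio.write_hits_tsv(hits, outdir / f"hits_{mode}.tsv")
                gffio.write_hits_bed6(hits, outdir / f"hits_{mode}.bed")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("scan", str(e)) from e

    # --- map small RNAs --------------------------------------------------
    if cfg.reads and cfg.genome:
        stage("map-smallrna")
        try:
            reads = read_fasta(cfg.reads) if Path(cfg.reads).stat().st_size else []
            genome = genome or read_fasta(cfg.genome)
            kept, stats = length_filter(reads, cfg.pirna)
            placements = map_exact(kept, genome, cfg.pirna)
            target = cfg.target_chrom or (genome[0].id if genome else "")
            psum = placement_summary(placements, target)
            gffio.write_tsv(psum, outdir / "pirna_summary.tsv")
            gffio.write_placements_bed6(placements, outdir / "pirna_placements.bed")
            if transcripts is not None:
                gffio.write_tsv(
                    match_to_transcripts(kept, transcripts),
                    outdir / "pirna_transcript_matches.tsv",
                )
            n_excl = int(psum["exclusive"].sum()) if len(psum) else 0
            summary["smallrna"] = {
                **stats,
                "target_chrom": target,
                "n_placed": int((psum["copy_count"] > 0).sum()) if len(psum) else 0,
                "n_exclusive": n_excl,
                "max_copy_count": int(psum["copy_count"].max()) if len(psum) else 0,
            }
            if cfg.strict and stats["kept"] == 0:
                raise PipelineError("map-smallrna", "no reads survive length filter")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("map-smallrna", str(e)) from e

    # --- qPCR ------------------------------------------------------------
    if cfg.ct_table:
        stage("qpcr")
        try:
            res = livak(load_ct_table(cfg.ct_table))
            gffio.write_tsv(
                pd.DataFrame([res.to_dict()]), outdir / "qpcr_result.tsv"
            )
            summary["qpcr"] = res.to_dict()
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("qpcr", str(e)) from e

    summary["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info("done in %.2fs", summary["runtime_s"])
    return summary


def config_for_dataset(dataset_dir: str | Path, **overrides) -> PipelineConfig:
    """Pipeline config pointing at a directory written by :func:`simulate`.

    Alignment parameters are scaled to the synthetic genome (intercopy
    spacers separate locus copies, so max_intron must stay below the
    spacer length for copies to be reported as distinct loci).
    """
    d = Path(dataset_dir)
    cfg = PipelineConfig(
        output_dir=d / "results",
        genome=d / "genome.fa",
        transcripts=d / "transcripts.fa",
        utrs=d / "utrs.fa",
        reads=d / "reads.fa",
        ct_table=d / "ct_table.tsv",
        align=AlignParams(max_intron=2000),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
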