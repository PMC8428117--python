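"""Ground-truthed synthetic datasets emulating the study's inputs.

Generates, from one seeded configuration: a genome carrying a multi-copy
spliced ncRNA locus (plus a decoy chromosome), an isoform set spanning the
six splicing-event categories with canonical GT..AG introns, UTR sets with
planted short homology stretches (exonic and junction-spanning, both
orientations, with controlled mismatch counts), piRNA-sized reads sampled
from the transcripts plus verified decoys, and replicate qPCR Ct tables with
a configured fold change. Every generator is a pure function of the
configuration (all randomness derives from ``cfg.seed``), and every output
comes with truth objects sufficient for downstream recovery tests.

Constructions chosen for exact recoverability:

* Introns are ``GT xx GT ... AG yy AG``: the inner GT/AG pair provides
  canonical alternative donor/acceptor sites 4 nt inside the intron, so
  alternative-splice-site and "complex" isoforms keep canonical junctions.
* Each junction (in every realized isoform variant) is rejection-sampled to
  have a *unique* identity-maximal canonical boundary placement, so exon
  chains recovered by the aligner are exactly the generated truth when the
  copy mutation rate is zero.
* One junction (``reserved_junction``) is kept untouched by all splicing
  events; junction-spanning plants are placed across it so that every
  isoform carries the identical junction context and planted stretches
  deduplicate exactly.
* UTR backgrounds start uniform over {A,C,G,T} and are then repair-mutated
  until the scanner's unique-stretch summary equals the planted truth
  (chance 10-nt near-matches are dense in uniform random sequence; a clean
  background is what makes exact recovery assertable). Set
  ``clean_background=False`` for untouched uniform backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import (
    HomologyHit,
    ScanParams,
    annotate_locations,
    dedupe_unique_stretches,
    merge_hits,
    scan,
    transcript_boundaries,
)
from .sequence import GenomicInterval, SeqRecord, reverse_complement, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

EVENT_NAMES = {
    "skip": "exon_skipping",
    "alt5": "alt_5ss",
    "alt3": "alt_3ss",
    "mxe": "mutually_exclusive",
    "intron_retention": "intron_retention",
    "complex": "complex",
}

ALT_SHIFT = 4  # nt between primary and secondary splice sites inside introns
_FLANK = 12  # junction-ambiguity validation window


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantSpec:
    """One homology stretch to plant into a UTR.

    For exact recovery under a scan mode, a plant must be maximal by
    construction: either ``mismatches`` equals the mode's budget or
    ``length`` equals the mode's length cap (otherwise the scanner would
    rightfully extend it).
    """

    length: int
    mismatches: int
    orientation: str  # "+/+" | "+/-"
    location: str  # "exonic" | "junction"
    utr_index: int
    transcript_index: int | None = None


@dataclass(frozen=True)
class CtSpec:
    true_fold_change: float = 1.0 / 3.0
    sd_noise: float = 0.2
    n_replicates: int = 4


def _default_plants() -> tuple[PlantSpec, ...]:
    # 8 exonic / 2 junction, mixed lengths, orientations and mismatches:
    # emulates the reported ~81%/~19% exon vs junction split at desk scale.
    return (
        PlantSpec(16, 0, "+/+", "exonic", 0),
        PlantSpec(12, 1, "+/+", "exonic", 1),
        PlantSpec(14, 1, "+/-", "exonic", 2),
        PlantSpec(10, 1, "+/+", "exonic", 3),
        PlantSpec(16, 1, "+/-", "exonic", 4),
        PlantSpec(13, 1, "+/+", "exonic", 5),
        PlantSpec(16, 0, "+/-", "exonic", 6),
        PlantSpec(11, 1, "+/+", "exonic", 7),
        PlantSpec(12, 1, "+/+", "junction", 8),
        PlantSpec(16, 0, "+/-", "junction", 9),
    )


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    # genome / locus
    n_locus_copies: int = 3
    n_decoy_locus_copies: int = 0
    copy_mutation_rate: float = 0.01
    exon_lengths: tuple[int, ...] = (70, 55, 60, 50, 65, 75)
    intron_lengths: tuple[int, ...] = (60, 72, 55, 66, 80)
    intercopy_spacer: int = 4000
    decoy_chrom_len: int = 3000
    chrom_name: str = "chrY_syn"
    decoy_chrom_name: str = "chr1_syn"
    # isoforms
    n_isoforms: int = 8
    event_mix: tuple[tuple[str, float], ...] = (
        ("skip", 0.25),
        ("alt5", 0.15),
        ("alt3", 0.15),
        ("mxe", 0.15),
        ("intron_retention", 0.15),
        ("complex", 0.15),
    )
    reserved_junction: int | None = 1  # intron index kept intact in all isoforms
    # UTRs / plants
    n_utrs: int = 10
    utr_length: int = 150
    planted_hits: tuple[PlantSpec, ...] = field(default_factory=_default_plants)
    scan_mode: str = "deregulated"  # "deregulated" | "utrdb"
    clean_background: bool = True
    # small RNAs
    pirna_length_range: tuple[int, int] = (22, 35)
    n_pirna_reads: int = 30
    n_decoys: int = 5
    pirna_within_exon: bool = True
    # qPCR
    ct: CtSpec = field(default_factory=CtSpec)

    def __post_init__(self) -> None:
        if not self.exon_lengths or not self.intron_lengths:
            raise ConfigError("exon/intron length lists must be non-empty")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ConfigError("need exactly one intron between consecutive exons")
        if min(self.intron_lengths) < 30:
            raise ConfigError("introns must be >= 30 nt")
        if min(self.intron_lengths) < 2 * ALT_SHIFT + 30:
            raise ConfigError(
                "introns must be >= 38 nt to host secondary splice sites"
            )
        total = sum(p for _, p in self.event_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"event_mix proportions must sum to 1, got {total}")
        unknown = {n for n, _ in self.event_mix} - set(EVENT_NAMES)
        if unknown:
            raise ConfigError(f"unknown event types {sorted(unknown)}")
        lo, hi = self.pirna_length_range
        if not (18 <= lo <= hi <= 40):
            raise ConfigError("pirna_length_range must lie within [18, 40]")
        if self.ct.true_fold_change <= 0:
            raise ConfigError("true_fold_change must be > 0")
        if self.ct.sd_noise < 0:
            raise ConfigError("sd_noise must be >= 0")
        if self.ct.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per group")
        if self.n_locus_copies < 1:
            raise ConfigError("need >= 1 locus copy")
        for p in self.planted_hits:
            if p.utr_index >= self.n_utrs:
                raise ConfigError(f"plant utr_index {p.utr_index} out of range")

    def scan_params(self) -> ScanParams:
        if self.scan_mode == "deregulated":
            return ScanParams.deregulated()
        if self.scan_mode == "utrdb":
            return ScanParams.utrdb()
        raise ConfigError(f"unknown scan_mode {self.scan_mode!r}")


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class LocusCopy:
    chrom: str
    copy_index: int
    start: int
    end: int
    exons: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class GenomeTruth:
    genome: tuple[SeqRecord, ...]
    copies: tuple[LocusCopy, ...]
    base_exons: tuple[str, ...]
    base_introns: tuple[str, ...]
    chrom: str
    decoy_chrom: str

    def seq(self, chrom: str) -> str:
        for rec in self.genome:
            if rec.id == chrom:
                return rec.seq
        raise KeyError(chrom)

    @property
    def main_copies(self) -> tuple[LocusCopy, ...]:
        return tuple(c for c in self.copies if c.chrom == self.chrom)


@dataclass(frozen=True)
class TruthEvent:
    isoform_a: str
    isoform_b: str
    event_type: str  # classifier vocabulary: exon_skipping, alt_5ss, ...


@dataclass(frozen=True)
class IsoformTruth:
    reference_id: str
    # isoform id -> copy index -> exon intervals (main chromosome)
    chains: dict[str, dict[int, tuple[GenomicInterval, ...]]]
    events: tuple[TruthEvent, ...]

    def exon_lengths(self, isoform_id: str) -> tuple[int, ...]:
        return tuple(len(iv) for iv in self.chains[isoform_id][0])

    def boundaries(self, isoform_id: str) -> list[int]:
        return transcript_boundaries(self.exon_lengths(isoform_id))


@dataclass(frozen=True)
class ReadTruth:
    # read id -> (transcript id, offset, length)
    sources: dict[str, tuple[str, int, int]]
    # read id -> genomic occurrence count (palindrome-collapsed), by naive search
    copy_counts: dict[str, int]
    # read id -> set of chromosomes hit
    chromosomes: dict[str, frozenset[str]]
    decoy_ids: frozenset[str]


# ---------------------------------------------------------------------------
# helpers


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _other_base(rng: np.random.Generator, *avoid: str | None) -> str:
    pool = [b for b in "ACGT" if b not in avoid]
    return pool[int(rng.integers(0, len(pool)))]


def _unique_fill(prev_tail: str, intron: str, next_head: str) -> bool:
    """True if the identity-maximal canonical boundary placement is unique
    and equals the intended one (split at len(prev_tail))."""
    T = prev_tail + next_head
    G = prev_tail + intron + next_head
    ilen = len(intron)
    jstar = len(prev_tail)
    best = -1
    best_js: list[int] = []
    for j in range(len(T) + 1):
        if not (G[j : j + 2] == "GT" and G[j + ilen - 2 : j + ilen] == "AG"):
            continue
        m = sum(a == b for a, b in zip(T[:j], G[:j]))
        m += sum(a == b for a, b in zip(T[j:], G[j + ilen :]))
        if m > best:
            best, best_js = m, [j]
        elif m == best:
            best_js.append(j)
    return best_js == [jstar]


def _make_intron(rng: np.random.Generator, length: int) -> str:
    body = _rand_seq(rng, length - 12)
    return "GT" + _rand_seq(rng, 2) + "GT" + body + "AG" + _rand_seq(rng, 2) + "AG"


def _bad_junction_exons(exons: list[str], params) -> set[int]:
    """Exon indices whose junction context defeats exact plant recovery.

    A junction-spanning window planted into a UTR (forward or reverse
    complement) must elicit scanner hits only from its own source window;
    near-palindromic or self-similar junction neighbourhoods instead spawn
    foreign hits from other transcript regions. Checked against the spliced
    exon concatenation, the superset of content shared by all isoforms."""
    from .scan import merge_hits as _merge, scan as _scan

    S = "".join(exons)
    rec = [SeqRecord("S", S)]
    offsets = np.cumsum([0] + [len(e) for e in exons])
    bad: set[int] = set()
    W = min(16, params.max_len)
    for j in range(len(exons) - 1):
        b = int(offsets[j + 1])
        ctx_ok = 0
        n_splits = 0
        for left in range(1, W):
            qs, qe = b - left, b - left + W
            if qs < 1 or qe > len(S) - 1:
                continue
            n_splits += 1
            w = S[qs:qe]
            clean = True
            for probe in (w, reverse_complement(w)):
                t = [SeqRecord("p", probe)]
                for h in _merge(_scan(rec, t, params)):
                    if S[h.query_start : h.query_end] != w:
                        clean = False
            ctx_ok += clean
        if n_splits and ctx_ok < n_splits - 2:
            bad.update({j, j + 1})
    return bad


def _locus_parts(rng: np.random.Generator, cfg: SynthConfig) -> tuple[list[str], list[str]]:
    """Exon and intron sequences with unambiguous junctions in all variants."""
    params = cfg.scan_params()
    exons = [_rand_seq(rng, L) for L in cfg.exon_lengths]
    for _ in range(100):
        bad_e = _bad_junction_exons(exons, params)
        if not bad_e:
            break
        for j in bad_e:
            exons[j] = _rand_seq(rng, cfg.exon_lengths[j])
    else:
        raise RuntimeError("could not build clean junction contexts")
    n_i = len(cfg.intron_lengths)
    introns: list[str | None] = [None] * n_i
    for _ in range(400):
        for i in range(n_i):
            if introns[i] is None:
                introns[i] = _make_intron(rng, cfg.intron_lengths[i])
        bad: set[int] = set()
        for i in range(n_i):
            I = introns[i]
            tail = exons[i][-_FLANK:]
            head = exons[i + 1][:_FLANK]
            variants = [
                (tail, I, head),  # reference junction
                ((exons[i] + I[:ALT_SHIFT])[-_FLANK:], I[ALT_SHIFT:], head),  # alt donor
                (tail, I[:-ALT_SHIFT], (I[-ALT_SHIFT:] + exons[i + 1])[:_FLANK]),  # alt acceptor
            ]
            if not all(_unique_fill(*v) for v in variants):
                bad.add(i)
        for j in range(1, len(exons) - 1):  # skipped-exon junctions
            merged = introns[j - 1] + exons[j] + introns[j]
            if not _unique_fill(exons[j - 1][-_FLANK:], merged, exons[j + 1][:_FLANK]):
                bad.update({j - 1, j})  # either flanking intron may be at fault
        if not bad:
            return exons, [str(x) for x in introns]
        for i in bad:
            introns[i] = None
    raise RuntimeError("could not build unambiguous locus junctions")


# ---------------------------------------------------------------------------
# generators


def make_genome(cfg: SynthConfig) -> GenomeTruth:
    """Main chromosome with mutated locus copies plus a decoy chromosome."""
    rng = np.random.default_rng([cfg.seed, 1])
    exons, introns = _locus_parts(rng, cfg)
    base = "".join(
        e + i for e, i in zip(exons, list(introns) + [""])
    )
    # exon offsets within a locus copy
    offsets = []
    pos = 0
    for e, i in zip(cfg.exon_lengths, list(cfg.intron_lengths) + [0]):
        offsets.append((pos, pos + e))
        pos += e + i
    copies: list[LocusCopy] = []
    parts: list[str] = []
    cursor = 0
    for c in range(cfg.n_locus_copies):
        spacer = _rand_seq(rng, cfg.intercopy_spacer)
        parts.append(spacer)
        cursor += len(spacer)
        body = base if c == 0 else _mutate(base, cfg.copy_mutation_rate, rng)
        ivs = tuple(
            GenomicInterval(cfg.chrom_name, cursor + s, cursor + e, "+")
            for s, e in offsets
        )
        copies.append(
            LocusCopy(cfg.chrom_name, c, cursor, cursor + len(base), ivs)
        )
        parts.append(body)
        cursor += len(body)
    parts.append(_rand_seq(rng, cfg.intercopy_spacer))
    main = SeqRecord(cfg.chrom_name, "".join(parts))
    # decoy chromosome, optionally carrying extra locus copies
    dparts: list[str] = []
    dcursor = 0
    for c in range(cfg.n_decoy_locus_copies):
        spacer = _rand_seq(rng, cfg.intercopy_spacer)
        dparts.append(spacer)
        dcursor += len(spacer)
        body = _mutate(base, cfg.copy_mutation_rate, rng) if cfg.copy_mutation_rate > 0 else base
        ivs = tuple(
            GenomicInterval(cfg.decoy_chrom_name, dcursor + s, dcursor + e, "+")
            for s, e in offsets
        )
        copies.append(
            LocusCopy(cfg.decoy_chrom_name, cfg.n_locus_copies + c, dcursor, dcursor + len(base), ivs)
        )
        dparts.append(body)
        dcursor += len(body)
    dparts.append(_rand_seq(rng, cfg.decoy_chrom_len))
    decoy = SeqRecord(cfg.decoy_chrom_name, "".join(dparts))
    return GenomeTruth(
        genome=(main, decoy),
        copies=tuple(copies),
        base_exons=tuple(exons),
        base_introns=tuple(introns),
        chrom=cfg.chrom_name,
        decoy_chrom=cfg.decoy_chrom_name,
    )


def _event_choices(cfg: SynthConfig, kind: str, n: int) -> list:
    """Exon/intron indices an event may touch, honouring the reserved junction."""
    rj = cfg.reserved_junction
    internal = range(1, n - 1)

    def junction_ok(intron_idx: int) -> bool:
        return rj is None or intron_idx != rj

    if kind == "skip":
        # removing exon j breaks junctions j-1 and j
        return [j for j in internal if junction_ok(j - 1) and junction_ok(j)]
    if kind == "alt5":
        return [i for i in range(0, n - 1) if junction_ok(i)]
    if kind == "alt3":
        return [i for i in range(1, n) if junction_ok(i - 1)]
    if kind == "mxe":
        out = []
        for i in internal:
            if i + 1 not in internal:
                continue
            touched = {i - 1, i, i + 1}
            if all(junction_ok(t) for t in touched):
                out.append(i)
        return out
    if kind == "intron_retention":
        return [i for i in range(0, n - 1) if junction_ok(i)]
    if kind == "complex":
        return [
            j
            for j in internal
            if junction_ok(j - 1) and junction_ok(j)
        ]
    raise ConfigError(f"unknown event kind {kind!r}")


def make_isoform_set(
    cfg: SynthConfig, truth: GenomeTruth
) -> tuple[list[SeqRecord], IsoformTruth]:
    """Spliced isoforms of the base locus following the configured event mix.

    The first transcript is the reference isoform (all exons). Every other
    isoform realizes exactly one splicing event; a mutually-exclusive draw
    produces a partner pair. Truth events record the isoform pair they hold
    between (the partner is the reference isoform except for MXE pairs,
    where a reference containing both exons can never exhibit the relation).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    copy0 = truth.main_copies[0]
    E = list(copy0.exons)
    n = len(E)
    genome_seq = truth.seq(truth.chrom)
    names = [k for k, _ in cfg.event_mix]
    probs = np.array([p for _, p in cfg.event_mix])

    chains: dict[str, dict[int, tuple[GenomicInterval, ...]]] = {}
    events: list[TruthEvent] = []
    order: list[str] = []

    def add_isoform(iso_id: str, exon_ivs: list[GenomicInterval]) -> None:
        per_copy: dict[int, tuple[GenomicInterval, ...]] = {}
        for c in truth.main_copies:
            off = c.start - copy0.start
            per_copy[c.copy_index] = tuple(iv.shift(off) for iv in exon_ivs)
        chains[iso_id] = per_copy
        order.append(iso_id)

    ref_id = "iso000"
    add_isoform(ref_id, E)

    idx = 1
    guard = 0
    while idx < cfg.n_isoforms:
        guard += 1
        if guard > 50 * cfg.n_isoforms:
            raise ConfigError("event mix cannot be realized with this exon count")
        kind = names[int(rng.choice(len(names), p=probs))]
        if kind == "mxe" and idx + 1 >= cfg.n_isoforms:
            continue  # no room for the partner; redraw
        choices = _event_choices(cfg, kind, n)
        if not choices:
            raise ConfigError(
                f"event {kind!r} inapplicable with {n} exons and reserved junction "
                f"{cfg.reserved_junction}"
            )
        pick = int(choices[int(rng.integers(0, len(choices)))])
        if kind == "skip":
            ivs = [iv for j, iv in enumerate(E) if j != pick]
            iso = f"iso{idx:03d}"
            add_isoform(iso, ivs)
            events.append(TruthEvent(iso, ref_id, "exon_skipping"))
            idx += 1
        elif kind == "alt5":
            ivs = list(E)
            ivs[pick] = GenomicInterval(
                ivs[pick].chrom, ivs[pick].start, ivs[pick].end + ALT_SHIFT, "+"
            )
            iso = f"iso{idx:03d}"
            add_isoform(iso, ivs)
            events.append(TruthEvent(iso, ref_id, "alt_5ss"))
            idx += 1
        elif kind == "alt3":
            ivs = list(E)
            ivs[pick] = GenomicInterval(
                ivs[pick].chrom, ivs[pick].start - ALT_SHIFT, ivs[pick].end, "+"
            )
            iso = f"iso{idx:03d}"
            add_isoform(iso, ivs)
            events.append(TruthEvent(iso, ref_id, "alt_3ss"))
            idx += 1
        elif kind == "mxe":
            iso_a = f"iso{idx:03d}"
            iso_b = f"iso{idx + 1:03d}"
            add_isoform(iso_a, [iv for j, iv in enumerate(E) if j != pick + 1])
            add_isoform(iso_b, [iv for j, iv in enumerate(E) if j != pick])
            events.append(TruthEvent(iso_a, iso_b, "mutually_exclusive"))
            idx += 2
        elif kind == "intron_retention":
            ivs = (
                E[:pick]
                + [GenomicInterval(E[pick].chrom, E[pick].start, E[pick + 1].end, "+")]
                + E[pick + 2 :]
            )
            iso = f"iso{idx:03d}"
            add_isoform(iso, ivs)
            events.append(TruthEvent(iso, ref_id, "intron_retention"))
            idx += 1
        else:  # complex: both boundaries of one exon shifted
            ivs = list(E)
            ivs[pick] = GenomicInterval(
                ivs[pick].chrom, ivs[pick].start - ALT_SHIFT, ivs[pick].end + ALT_SHIFT, "+"
            )
            iso = f"iso{idx:03d}"
            add_isoform(iso, ivs)
            events.append(TruthEvent(iso, ref_id, "complex"))
            idx += 1

    transcripts = [
        SeqRecord(iso, "".join(genome_seq[iv.start : iv.end] for iv in chains[iso][0]))
        for iso in order
    ]
    return transcripts, IsoformTruth(
        reference_id=ref_id, chains=chains, events=tuple(events)
    )


def _safe_junction_indices(iso_truth: IsoformTruth) -> list[int]:
    """Reference-isoform junctions whose local context is identical in
    every isoform that shares it.

    A junction is safe for junction-spanning plants iff each isoform either
    carries both flanking exons with the same boundaries, adjacently, or
    carries no exon overlapping either flank at all — then every scanner
    hit on a plant across it has the identical query substring and
    deduplication collapses them exactly."""
    ref = iso_truth.chains[iso_truth.reference_id][0]
    safe = []
    for j in range(len(ref) - 1):
        ej, ek = ref[j], ref[j + 1]
        ok = True
        for per_copy in iso_truth.chains.values():
            chain = per_copy[0]
            pairs = list(zip(chain, chain[1:]))
            # junction-local content is fixed by the splice boundaries: the
            # upstream exon must end where ej ends and the downstream exon
            # must start where ek starts (intron retention of a *different*
            # intron may merge flanks without moving this junction)
            intact = any(
                a.end == ej.end and b.start == ek.start for a, b in pairs
            )
            touches = any(iv.overlaps(ej) or iv.overlaps(ek) for iv in chain)
            if touches and not intact:
                ok = False
                break
        if ok:
            safe.append(j)
    return safe


def _image_base(qseq: str, qs: int, qe: int, orientation: str, rel: int) -> str | None:
    """Query-strand image of the target base ``rel`` positions relative to
    the target window start (-1 = left flank, window length = right flank)."""
    if orientation == "+/+":
        qpos = qs + rel
        if 0 <= qpos < len(qseq):
            return qseq[qpos]
        return None
    qpos = qe - 1 - rel
    if 0 <= qpos < len(qseq):
        return reverse_complement(qseq[qpos])
    return None


def plant_utr_matches(
    cfg: SynthConfig,
    transcripts: list[SeqRecord],
    iso_truth: IsoformTruth,
) -> tuple[list[SeqRecord], list[HomologyHit]]:
    """Random-background UTRs with every PlantSpec realized and recoverable."""
    rng = np.random.default_rng([cfg.seed, 3])
    params = cfg.scan_params()
    for p in cfg.planted_hits:
        if not (params.min_len <= p.length <= params.max_len):
            raise ConfigError(f"plant length {p.length} outside mode band")
        if p.mismatches > params.max_mismatch:
            raise ConfigError("plant mismatches exceed mode budget")
        if p.mismatches < params.max_mismatch and p.length < params.max_len:
            raise ConfigError(
                "plant not maximal by construction: need mismatches == budget "
                "or length == cap for exact recovery"
            )
        if p.orientation not in ("+/+", "+/-"):
            raise ConfigError(f"bad orientation {p.orientation!r}")
        if p.location not in ("exonic", "junction"):
            raise ConfigError(f"bad location {p.location!r}")
    utrs = [list(_rand_seq(rng, cfg.utr_length)) for _ in range(cfg.n_utrs)]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(cfg.n_utrs)}
    planted: list[HomologyHit] = []
    used_subs: set[str] = set()
    by_id = {t.id: t for t in transcripts}

    def _foreign_in_window(utr_idx: int, lo: int, hi: int) -> bool:
        """Any hit overlapping [lo, hi) whose substring is not a plant in
        this UTR? Such hits (e.g. a chance near-reverse-complement of the
        planted content elsewhere in the transcripts) cannot be repaired
        without breaking the plant, so the placement must be rejected."""
        rec = SeqRecord(f"utr{utr_idx:02d}", "".join(utrs[utr_idx]))
        local = {
            by_id[h.query_id].seq[h.query_start : h.query_end]
            for h in planted
            if h.target_id == rec.id
        }
        for h in merge_hits(scan(transcripts, [rec], params)):
            if h.target_start < hi + 1 and lo - 1 < h.target_end:
                sub = by_id[h.query_id].seq[h.query_start : h.query_end]
                if sub not in local:
                    return True
        return False

    safe_junctions = _safe_junction_indices(iso_truth)
    if cfg.reserved_junction in safe_junctions:
        safe_junctions = [cfg.reserved_junction] + [
            j for j in safe_junctions if j != cfg.reserved_junction
        ]

    for spec in cfg.planted_hits:
        if spec.length > min(len(t) for t in transcripts):
            raise ConfigError("plant longer than shortest transcript")
        for attempt in range(300):
            # Plants are sourced from the reference isoform: its exon bodies
            # and the reserved junction are present verbatim in every isoform
            # that retains them, so the same substring (and no shifted
            # variant) is found from each — dedup then collapses them all.
            if spec.transcript_index is not None:
                tr = transcripts[spec.transcript_index]
            else:
                tr = transcripts[0]
            bounds = iso_truth.boundaries(tr.id)
            if spec.location == "exonic":
                # window strictly inside one exon, >=1 nt from each boundary
                starts = [0] + bounds
                ends = bounds + [len(tr.seq)]
                cand = [
                    (s, e)
                    for s, e in zip(starts, ends)
                    if (e - 1) - (s + 1) >= spec.length
                ]
                if not cand:
                    continue
                s, e = cand[int(rng.integers(0, len(cand)))]
                qs = int(rng.integers(s + 1, e - 1 - spec.length + 1))
            else:
                if safe_junctions:
                    # prefer the reserved junction; fall back to other safe
                    # junctions when its content rejects the plant (e.g.
                    # near-palindromic junctions spawn foreign +/- hits)
                    j = safe_junctions[(attempt // 30) % len(safe_junctions)]
                    b = bounds[j]
                elif bounds:
                    b = bounds[int(rng.integers(0, len(bounds)))]
                else:
                    continue
                left = int(rng.integers(1, spec.length))  # >=1 nt each side
                qs = b - left
                if qs < 1 or qs + spec.length > len(tr.seq) - 1:
                    continue
            qe = qs + spec.length
            q_sub = tr.seq[qs:qe]
            if q_sub in used_subs:
                continue
            # build the target window as the (possibly reverse-complemented)
            # image with exactly the requested number of substitutions
            image = q_sub if spec.orientation == "+/+" else reverse_complement(q_sub)
            tgt = list(image)
            mpos = rng.choice(spec.length, size=spec.mismatches, replace=False)
            for m in np.atleast_1d(mpos):
                tgt[int(m)] = _other_base(rng, tgt[int(m)])
            p = int(rng.integers(1, cfg.utr_length - spec.length))
            if any(
                p - 2 < oe and os < p + spec.length + 2
                for os, oe in occupied[spec.utr_index]
            ):
                continue
            u = utrs[spec.utr_index]
            saved = u[p - 1 : p + spec.length + 1]
            u[p : p + spec.length] = tgt
            # flanks must mismatch the query image so the plant is maximal
            lf = _image_base(tr.seq, qs, qe, spec.orientation, -1)
            rf = _image_base(tr.seq, qs, qe, spec.orientation, spec.length)
            u[p - 1] = _other_base(rng, lf)
            u[p + spec.length] = _other_base(rng, rf)
            planted.append(
                HomologyHit(
                    query_id=tr.id,
                    query_start=qs,
                    query_end=qe,
                    target_id=f"utr{spec.utr_index:02d}",
                    target_start=p,
                    target_end=p + spec.length,
                    orientation=spec.orientation,
                    mismatches=spec.mismatches,
                    location=spec.location,
                )
            )
            if cfg.clean_background and _foreign_in_window(
                spec.utr_index, p, p + spec.length
            ):
                planted.pop()
                u[p - 1 : p + spec.length + 1] = saved
                continue
            occupied[spec.utr_index].append((p, p + spec.length))
            used_subs.add(q_sub)
            break
        else:
            raise ConfigError(f"could not place plant {spec}")

    utr_records = lambda: [
        SeqRecord(f"utr{i:02d}", "".join(u)) for i, u in enumerate(utrs)
    ]
    if cfg.clean_background:
        planted_seqs = {
            by_id[h.query_id].seq[h.query_start : h.query_end] for h in planted
        }
        boundaries = {t.id: iso_truth.boundaries(t.id) for t in transcripts}
        protected: dict[str, list[tuple[int, int]]] = {}
        for h in planted:
            protected.setdefault(h.target_id, []).append(
                (h.target_start - 1, h.target_end + 1)
            )
        for _ in range(80):
            recs = utr_records()
            hits = merge_hits(scan(transcripts, recs, params))
            hits = annotate_locations(hits, boundaries, params.junction_min_overhang)
            stretches, _ = dedupe_unique_stretches(hits, transcripts)
            spurious = [s for s in stretches if s.sequence not in planted_seqs]
            if not spurious:
                break
            for s in spurious:
                repaired = False
                for h in s.hits:
                    ui = int(h.target_id[3:])
                    blocked = protected.get(h.target_id, [])
                    eligible = [
                        pos
                        for pos in range(h.target_start, h.target_end)
                        if not any(bs <= pos < be for bs, be in blocked)
                    ]
                    if not eligible:
                        continue
                    n_mut = min(params.max_mismatch + 1, len(eligible))
                    for pos in rng.choice(eligible, size=n_mut, replace=False):
                        utrs[ui][int(pos)] = _other_base(rng, utrs[ui][int(pos)])
                    repaired = True
                    break
                if not repaired:
                    raise RuntimeError(
                        f"unrepairable spurious stretch {s.sequence!r}"
                    )
        else:
            raise RuntimeError("background cleaning did not converge")
    return utr_records(), planted


def _count_occurrences(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def sample_pirna_reads(
    cfg: SynthConfig,
    transcripts: list[SeqRecord],
    truth: GenomeTruth,
    iso_truth: IsoformTruth | None = None,
) -> tuple[list[SeqRecord], ReadTruth]:
    """piRNA-sized substrings of transcripts plus genome-absent decoys.

    With ``pirna_within_exon`` (and exon truth available), read windows stay
    inside single exons so each read has contiguous genomic placements; reads
    allowed to straddle junctions exist only in the spliced RNA and map to
    the genome in zero copies, like junction-spanning piRNAs.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    lo, hi = cfg.pirna_length_range
    if hi > min(len(t) for t in transcripts):
        raise ConfigError("pirna_length_range exceeds shortest transcript")
    sources: dict[str, tuple[str, int, int]] = {}
    reads: list[SeqRecord] = []
    chrom_seqs = {rec.id: rec.seq for rec in truth.genome}

    spans_cache: dict[str, list[tuple[int, int]]] = {}

    def exon_spans(tid: str) -> list[tuple[int, int]]:
        if tid not in spans_cache:
            lens = iso_truth.exon_lengths(tid)
            spans, acc = [], 0
            for L in lens:
                spans.append((acc, acc + L))
                acc += L
            spans_cache[tid] = spans
        return spans_cache[tid]

    for idx in range(cfg.n_pirna_reads):
        tr = transcripts[int(rng.integers(0, len(transcripts)))]
        L = int(rng.integers(lo, hi + 1))
        if cfg.pirna_within_exon and iso_truth is not None:
            cand = [(s, e) for s, e in exon_spans(tr.id) if e - s >= L]
            if not cand:
                raise ConfigError("read length exceeds every exon")
            s, e = cand[int(rng.integers(0, len(cand)))]
            offset = int(rng.integers(s, e - L + 1))
        else:
            offset = int(rng.integers(0, len(tr.seq) - L + 1))
        rid = f"read{idx:03d}"
        reads.append(SeqRecord(rid, tr.seq[offset : offset + L]))
        sources[rid] = (tr.id, offset, L)

    decoy_ids = []
    tr_seqs = [t.seq for t in transcripts]
    for d in range(cfg.n_decoys):
        for _ in range(1000):
            L = int(rng.integers(lo, hi + 1))
            s = _rand_seq(rng, L)
            rc = reverse_complement(s)
            present = any(
                s in h or rc in h for h in list(chrom_seqs.values()) + tr_seqs
            )
            if not present:
                rid = f"decoy{d:02d}"
                reads.append(SeqRecord(rid, s))
                sources[rid] = ("", -1, L)
                decoy_ids.append(rid)
                break
        else:
            raise RuntimeError("could not sample a genome-absent decoy")

    copy_counts: dict[str, int] = {}
    chromosomes: dict[str, frozenset[str]] = {}
    for rec in reads:
        rc = reverse_complement(rec.seq)
        total = 0
        chroms = set()
        for chrom, seq in chrom_seqs.items():
            fwd = _count_occurrences(seq, rec.seq)
            rev = [] if rc == rec.seq else _count_occurrences(seq, rc)
            n = len(fwd) + len(rev)
            if n:
                chroms.add(chrom)
            total += n
        copy_counts[rec.id] = total
        chromosomes[rec.id] = frozenset(chroms)
    return reads, ReadTruth(
        sources=sources,
        copy_counts=copy_counts,
        chromosomes=chromosomes,
        decoy_ids=frozenset(decoy_ids),
    )


def make_ct_table(cfg: SynthConfig) -> pd.DataFrame:
    """Replicate Ct table with the configured true fold change.

    The target gene's Ct in the test group is shifted by ``-log2(fold)``
    relative to control (a 3-fold reduction raises Ct by log2(3) cycles);
    the reference gene is unshifted. Columns: sample_group, replicate_id,
    gene_role, ct.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    shift = -float(np.log2(cfg.ct.true_fold_change))
    base = {"target": 24.0, "reference": 20.0}
    rows = []
    for group in ("control", "test"):
        for rep in range(1, cfg.ct.n_replicates + 1):
            for role in ("target", "reference"):
                ct = base[role]
                if group == "test" and role == "target":
                    ct += shift
                ct += float(rng.normal(0.0, cfg.ct.sd_noise)) if cfg.ct.sd_noise else 0.0
                rows.append((group, f"r{rep}", role, float(ct)))
    return pd.DataFrame(rows, columns=["sample_group", "replicate_id", "gene_role", "ct"])


# ---------------------------------------------------------------------------
# dataset on disk


def write_dataset(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the study-shaped input files."""
    from . import gffio  # local import to avoid a cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_genome(cfg)
    transcripts, iso_truth = make_isoform_set(cfg, truth)
    utrs, planted = plant_utr_matches(cfg, transcripts, iso_truth)
    reads, read_truth = sample_pirna_reads(cfg, transcripts, truth, iso_truth)
    ct = make_ct_table(cfg)

    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "utrs": outdir / "utrs.fa",
        "reads": outdir / "reads.fa",
        "truth_gff3": outdir / "truth.gff3",
        "truth_hits": outdir / "truth_hits.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "ct_table": outdir / "ct_table.tsv",
    }
    write_fasta(truth.genome, paths["genome"])
    write_fasta(transcripts, paths["transcripts"])
    write_fasta(utrs, paths["utrs"])
    write_fasta(reads, paths["reads"])
    gffio.write_truth_gff3(truth, iso_truth, paths["truth_gff3"])
    gffio.write_hits_tsv(planted, paths["truth_hits"])
    rows = [
        {
            "read_id": rid,
            "source_transcript": src or ".",
            "offset": off,
            "length": L,
            "copy_count": read_truth.copy_counts[rid],
            "chromosomes": ",".join(sorted(read_truth.chromosomes[rid])) or ".",
            "is_decoy": int(rid in read_truth.decoy_ids),
        }
        for rid, (src, off, L) in read_truth.sources.items()
    ]
    gffio.write_tsv(pd.DataFrame(rows), paths["truth_reads"])
    gffio.write_tsv(
        pd.DataFrame(
            [(e.isoform_a, e.isoform_b, e.event_type) for e in iso_truth.events],
            columns=["isoform_a", "isoform_b", "event_type"],
        ),
        paths["truth_events"],
    )
    gffio.write_tsv(ct, paths["ct_table"])
    return paths
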