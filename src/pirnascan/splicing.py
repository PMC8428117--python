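"""Splice-junction annotation and splicing-event classification.

Junctions are annotated with their donor/acceptor dinucleotides read on the
transcribed strand; the canonical spliceosomal consensus is a GT donor and
an AG acceptor (often written "AG/GT" in acceptor/donor order). Event
classification compares two isoforms' exon chains and decomposes their
difference into the elementary alternative-splicing categories — exon
skipping, alternative 5'/3' splice sites, mutually exclusive exons, intron
retention — with any residual difference reported as a "complex" event.
Pure terminal truncations (no intron boundary moves) are reported as
"end_variation" notes outside the six categories, since fixed amplification
primers pin transcript ends in the kind of isoform survey this serves.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import ExonChain
from .sequence import GenomicInterval, SeqRecord, reverse_complement

ELEMENTARY = (
    "exon_skipping",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive",
    "intron_retention",
)
EVENT_TYPES = ELEMENTARY + ("complex", "end_variation")


@dataclass(frozen=True)
class SpliceJunction:
    transcript_id: str
    chrom: str
    strand: str
    index: int  # 0-based junction number in transcript order
    donor_pos: int  # first intron base, 0-based, transcribed strand
    acceptor_pos: int  # last intron base
    donor_dinuc: str
    acceptor_dinuc: str

    @property
    def canonical(self) -> bool:
        return self.donor_dinuc == "GT" and self.acceptor_dinuc == "AG"


@dataclass(frozen=True)
class SpliceEvent:
    isoform_a: str
    isoform_b: str
    event_type: str
    exons_a: tuple[GenomicInterval, ...]
    exons_b: tuple[GenomicInterval, ...]

    def swapped(self) -> "SpliceEvent":
        return SpliceEvent(
            self.isoform_b, self.isoform_a, self.event_type, self.exons_b, self.exons_a
        )


def _genome_seq(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        return genome[chrom]
    for rec in genome:
        if rec.id == chrom:
            return rec.seq
    raise KeyError(chrom)


def annotate_junctions(chain: ExonChain, genome) -> list[SpliceJunction]:
    """One junction per adjacent exon pair, dinucleotides on the transcribed
    strand; single-exon chains yield []."""
    seq = _genome_seq(genome, chain.chrom)
    if chain.exons[-1].end > len(seq):
        raise ValueError("chain exceeds chromosome bounds")
    introns = chain.introns
    if chain.strand == "-":
        introns = introns[::-1]
    out = []
    for idx, (s, e) in enumerate(introns):
        if chain.strand == "+":
            donor_pos, acceptor_pos = s, e - 1
            donor = seq[s : s + 2]
            acceptor = seq[e - 2 : e]
        else:
            donor_pos, acceptor_pos = e - 1, s
            donor = reverse_complement(seq[e - 2 : e])
            acceptor = reverse_complement(seq[s : s + 2])
        out.append(
            SpliceJunction(
                transcript_id=chain.transcript_id,
                chrom=chain.chrom,
                strand=chain.strand,
                index=idx,
                donor_pos=donor_pos,
                acceptor_pos=acceptor_pos,
                donor_dinuc=donor,
                acceptor_dinuc=acceptor,
            )
        )
    return out


@dataclass(frozen=True)
class ExonCatalog:
    """Master list of distinct exon intervals at one locus, genomic order.

    Identical intervals are merged; overlapping-but-unequal intervals stay
    distinct (they encode alternative splice sites). Labels are e1, e2, ...
    """

    chrom: str
    exons: tuple[GenomicInterval, ...]

    def label(self, iv: GenomicInterval) -> str:
        for i, e in enumerate(self.exons):
            if (e.start, e.end) == (iv.start, iv.end):
                return f"e{i + 1}"
        raise KeyError(f"interval {iv} not in catalog")

    def adjacent(self, x: GenomicInterval, y: GenomicInterval) -> bool:
        """No catalog exon lies wholly in the gap between x and y.

        Overlapping alternative-boundary variants of x or y do not break
        adjacency; only a distinct exon strictly between them does.
        """
        if x.start > y.start:
            x, y = y, x
        if x.end > y.start:
            return False
        return not any(
            x.end <= e.start and e.end <= y.start for e in self.exons
        )


def build_exon_catalog(chains: Sequence[ExonChain]) -> ExonCatalog:
    chroms = {c.chrom for c in chains}
    if len(chroms) != 1:
        raise ValueError(f"chains span multiple chromosomes: {sorted(chroms)}")
    seen = {(iv.start, iv.end) for c in chains for iv in c.exons}
    chrom = chroms.pop()
    exons = tuple(
        GenomicInterval(chrom, s, e, "+") for s, e in sorted(seen)
    )
    return ExonCatalog(chrom=chrom, exons=exons)


def _classify_region(
    A: list[GenomicInterval],
    B: list[GenomicInterval],
    a: ExonChain,
    b: ExonChain,
    catalog: ExonCatalog | None,
) -> str:
    strand = a.strand

    def is_first(iv: GenomicInterval, chain: ExonChain) -> bool:
        return (iv.start, iv.end) == (chain.exons[0].start, chain.exons[0].end)

    def is_last(iv: GenomicInterval, chain: ExonChain) -> bool:
        return (iv.start, iv.end) == (chain.exons[-1].start, chain.exons[-1].end)

    if len(A) == 1 and not B or len(B) == 1 and not A:
        x = A[0] if A else B[0]
        other = b if A else a
        if x.end <= other.exons[0].start or x.start >= other.exons[-1].end:
            return "end_variation"
        return "exon_skipping"
    if len(A) == 1 and len(B) == 1:
        x, y = A[0], B[0]
        if x.start == y.start and x.end != y.end:
            internal = not (is_last(x, a) and is_last(y, b))
            if not internal:
                return "end_variation"
            return "alt_5ss" if strand == "+" else "alt_3ss"
        if x.end == y.end and x.start != y.start:
            internal = not (is_first(x, a) and is_first(y, b))
            if not internal:
                return "end_variation"
            return "alt_3ss" if strand == "+" else "alt_5ss"
        if x.end <= y.start or y.end <= x.start:
            if catalog is None or catalog.adjacent(x, y):
                return "mutually_exclusive"
            return "complex"
        return "complex"
    for single, pair in ((A, B), (B, A)):
        if len(single) == 1 and len(pair) == 2:
            x, (y1, y2) = single[0], sorted(pair, key=lambda v: v.start)
            if x.start == y1.start and x.end == y2.end and y1.end < y2.start:
                return "intron_retention"
    return "complex"


def classify_events(
    a: ExonChain,
    b: ExonChain,
    catalog: ExonCatalog | None = None,
) -> list[SpliceEvent]:
    """Minimal decomposition of the difference between two exon chains.

    Shared exons (identical intervals) anchor the comparison; runs of
    non-shared exons between consecutive shared ones form difference
    regions, and each region is matched against the elementary event
    patterns before falling back to "complex". Identical chains yield [].
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("chains lie on different chromosomes or strands")
    if a.end <= b.start or b.end <= a.start:
        raise ValueError("chains do not overlap: different loci")
    set_a = {(iv.start, iv.end) for iv in a.exons}
    set_b = {(iv.start, iv.end) for iv in b.exons}
    matched = sorted(set_a & set_b)
    matched_ends = [e for _, e in matched]
    regions: dict[int, tuple[list[GenomicInterval], list[GenomicInterval]]] = {}
    for src, chain, shared in (("a", a, set_a), ("b", b, set_b)):
        for iv in chain.exons:
            if (iv.start, iv.end) in set_a & set_b:
                continue
            r = bisect_right(matched_ends, iv.start)
            regions.setdefault(r, ([], []))
            regions[r][0 if src == "a" else 1].append(iv)
    events = []
    for r in sorted(regions):
        A, B = regions[r]
        A.sort(key=lambda v: v.start)
        B.sort(key=lambda v: v.start)
        for cA, cB in _split_components(A, B):
            etype = _classify_region(cA, cB, a, b, catalog)
            events.append(
                SpliceEvent(
                    isoform_a=a.transcript_id,
                    isoform_b=b.transcript_id,
                    event_type=etype,
                    exons_a=tuple(cA),
                    exons_b=tuple(cB),
                )
            )
    return events


def _split_components(
    A: list[GenomicInterval], B: list[GenomicInterval]
) -> list[tuple[list[GenomicInterval], list[GenomicInterval]]]:
    """Split a difference region into independently classifiable pieces.

    Exons are grouped by genomic overlap; adjacent but non-overlapping
    pieces are independent events (e.g. a skipped exon next to an
    alternative splice site) — except for the mutually-exclusive pattern,
    one disjoint exon from each chain, which must stay together."""
    tagged = [(iv, 0) for iv in A] + [(iv, 1) for iv in B]
    tagged.sort(key=lambda t: (t[0].start, t[0].end))
    comps: list[list[tuple[GenomicInterval, int]]] = []
    cur_end = None
    for iv, src in tagged:
        if cur_end is not None and iv.start < cur_end:
            comps[-1].append((iv, src))
            cur_end = max(cur_end, iv.end)
        else:
            comps.append([(iv, src)])
            cur_end = iv.end
    if (
        len(comps) == 2
        and all(len(c) == 1 for c in comps)
        and comps[0][0][1] != comps[1][0][1]
    ):
        return [(A, B)]  # candidate mutually-exclusive pair stays whole
    return [
        (
            [iv for iv, src in comp if src == 0],
            [iv for iv, src in comp if src == 1],
        )
        for comp in comps
    ]
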