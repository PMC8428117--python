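"""Splice-aware placement of near-identical transcripts onto a genome.

Transcripts are mapped as exon chains: maximal exact anchor matches are
chained colinearly per locus, gaps between anchors are closed into exon
boundaries (preferring canonical GT..AG introns, then maximal exon
identity, then the leftmost placement), and every locus whose chain
identity reaches the threshold is reported — multi-copy placements are
first-class. The model assumes substitution-level divergence between a
transcript and its loci (no exonic indels), which matches transcripts that
are >97%-identical clones of a multi-copy locus.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .sequence import GenomicInterval, SeqRecord, reverse_complement


@dataclass(frozen=True)
class AlignParams:
    anchor_k: int = 18
    min_intron: int = 30
    max_intron: int = 50_000
    identity_threshold: float = 0.97
    boundary_window: int = 10
    intron_penalty: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.anchor_k < 4:
            raise ValueError("anchor_k must be >= 4")
        if not (0 < self.min_intron <= self.max_intron):
            raise ValueError("require 0 < min_intron <= max_intron")


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match between an oriented transcript and the genome."""

    chrom: str
    strand: str
    t_start: int  # on the oriented transcript (reverse-complemented for '-')
    g_start: int
    length: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    @property
    def g_end(self) -> int:
        return self.g_start + self.length

    @property
    def diag(self) -> int:
        return self.g_start - self.t_start


@dataclass(frozen=True)
class ExonChain:
    """A transcript's placement at one locus as ordered genomic exons."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    identity: float
    score: float

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        lens = tuple(len(iv) for iv in self.exons)
        return lens if self.strand == "+" else lens[::-1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )


class AnchorIndex:
    """k-mer index over a genome for maximal exact-match anchoring."""

    def __init__(self, genome: Sequence[SeqRecord], k: int):
        self.k = k
        self.seqs = {rec.id: rec.seq for rec in genome}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rec in genome:
            s = rec.seq
            for j in range(len(s) - k + 1):
                w = s[j : j + k]
                if "N" not in w:
                    self._index[w].append((rec.id, j))

    def _oriented_anchors(self, q: str, strand: str) -> list[Anchor]:
        k = self.k
        seeds: dict[tuple[str, int], list[int]] = defaultdict(list)
        for i in range(len(q) - k + 1):
            w = q[i : i + k]
            if "N" in w:
                continue
            for chrom, j in self._index.get(w, ()):
                seeds[(chrom, j - i)].append(i)
        anchors: set[Anchor] = set()
        for (chrom, d), positions in seeds.items():
            s = self.seqs[chrom]
            positions.sort()
            runs: list[tuple[int, int]] = []
            for i in positions:
                if runs and i <= runs[-1][1]:
                    runs[-1] = (runs[-1][0], max(runs[-1][1], i + k))
                else:
                    runs.append((i, i + k))
            for lo, hi in runs:
                while lo > 0 and 0 <= lo - 1 + d and q[lo - 1] == s[lo - 1 + d] != "N":
                    lo -= 1
                while (
                    hi < len(q)
                    and hi + d < len(s)
                    and q[hi] == s[hi + d] != "N"
                ):
                    hi += 1
                anchors.add(Anchor(chrom, strand, lo, lo + d, hi - lo))
        return sorted(anchors, key=lambda a: (a.chrom, a.g_start, a.t_start))

    def anchors(self, transcript: SeqRecord) -> list[Anchor]:
        out = self._oriented_anchors(transcript.seq, "+")
        out += self._oriented_anchors(reverse_complement(transcript.seq), "-")
        return out


def find_anchors(
    transcript: SeqRecord, genome: Sequence[SeqRecord], anchor_k: int = 18
) -> list[Anchor]:
    """All maximal exact matches of length >= anchor_k, both strands."""
    return AnchorIndex(genome, anchor_k).anchors(transcript)


def _is_canonical(seq: str, s: int, e: int, strand: str) -> bool:
    if e - s < 4:
        return False
    if strand == "+":
        return seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG"
    # '-' strand: transcribed intron is the reverse complement
    return seq[s : s + 2] == "CT" and seq[e - 2 : e] == "AC"


def _chain_dp(anchors: list[Anchor], params: AlignParams) -> list[Anchor]:
    """Highest-scoring colinear anchor chain (ties: smallest intron span)."""
    anchors = sorted(anchors, key=lambda a: (a.t_start, a.g_start))
    n = len(anchors)
    score = [float(a.length) for a in anchors]
    span = [0] * n
    prev = [-1] * n
    for i in range(n):
        B = anchors[i]
        for j in range(i):
            A = anchors[j]
            if B.t_start <= A.t_start or B.g_start <= A.g_start or B.t_end <= A.t_end:
                continue
            delta = B.diag - A.diag
            if delta != 0 and not (params.min_intron <= delta <= params.max_intron):
                continue
            overlap = max(A.t_end - B.t_start, 0)
            if overlap >= B.length:
                continue
            gain = B.length - overlap - (params.intron_penalty if delta else 0.0)
            cand = score[j] + gain
            cand_span = span[j] + delta
            if cand > score[i] + 1e-9 or (
                abs(cand - score[i]) <= 1e-9 and prev[i] != -1 and cand_span < span[i]
            ):
                score[i], span[i], prev[i] = cand, cand_span, j
    best = max(range(n), key=lambda i: (score[i], -span[i]))
    chain = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = prev[i]
    return chain[::-1]


def _fill_chain(
    chain: list[Anchor],
    T: str,
    seq: str,
    params: AlignParams,
    transcript_id: str,
) -> ExonChain:
    """Close anchor gaps into exon boundaries and score the chain."""
    strand = chain[0].strand
    chrom = chain[0].chrom
    exons: list[tuple[int, int]] = []
    first = chain[0]
    exon_start = max(first.g_start - first.t_start, 0)
    cur_t = first.g_start - exon_start  # transcript position where exon starts
    prev_a = first
    score = sum(a.length for a in chain)
    for B in chain[1:]:
        A = prev_a
        delta = B.diag - A.diag
        if delta == 0:
            prev_a = B
            continue
        score -= params.intron_penalty
        lo, hi = min(A.t_end, B.t_start), max(A.t_end, B.t_start)
        best = None  # (canonical, matches, -j)
        for j in range(lo, hi + 1):
            g_e1 = A.g_start + (j - A.t_start)
            g_e2 = B.g_start + (j - B.t_start)
            if g_e1 <= exon_start or g_e2 >= len(seq):
                continue
            m = sum(
                1
                for t in range(lo, j)
                if T[t] == seq[A.g_start + (t - A.t_start)] != "N"
            )
            m += sum(
                1
                for t in range(j, hi)
                if T[t] == seq[B.g_start + (t - B.t_start)] != "N"
            )
            canon = _is_canonical(seq, g_e1, g_e2, strand)
            key = (canon, m, -j)
            if best is None or key > best[0]:
                best = (key, j, g_e1, g_e2)
        _, j, g_e1, g_e2 = best
        exons.append((exon_start, g_e1))
        exon_start = g_e2
        prev_a = B
    last = chain[-1]
    tail = len(T) - last.t_end
    exon_end = min(last.g_end + tail, len(seq))
    exons.append((exon_start, exon_end))
    spliced = "".join(seq[s:e] for s, e in exons)
    matches = sum(
        1 for a, b in zip(T, spliced) if a == b != "N"
    )
    identity = matches / len(T)
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return ExonChain(
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=ivs,
        identity=identity,
        score=float(score),
    )


def chain_and_fill(
    anchors: Sequence[Anchor],
    transcript: SeqRecord,
    genome: Sequence[SeqRecord],
    params: AlignParams,
) -> list[ExonChain]:
    """All locus placements of one transcript at or above the identity
    threshold, best first. Transcripts with no surviving chain return []
    (reported upstream as unplaced, never dropped silently)."""
    seqs = {rec.id: rec.seq for rec in genome}
    chains: list[ExonChain] = []
    pools: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        pools[(a.chrom, a.strand)].append(a)
    for (chrom, strand), pool in sorted(pools.items()):
        T = transcript.seq if strand == "+" else reverse_complement(transcript.seq)
        remaining = list(pool)
        for _ in range(100):
            if not remaining:
                break
            chain = _chain_dp(remaining, params)
            built = _fill_chain(chain, T, seqs[chrom], params, transcript.id)
            g_lo, g_hi = built.start, built.end
            kept = [a for a in remaining if a.g_end <= g_lo or a.g_start >= g_hi]
            if len(kept) == len(remaining):
                break
            remaining = kept
            if built.identity >= params.identity_threshold:
                chains.append(built)
    chains.sort(key=lambda c: (-c.identity, -c.score, c.chrom, c.start))
    return chains


def align_transcripts(
    transcripts: Sequence[SeqRecord],
    genome: Sequence[SeqRecord],
    params: AlignParams | None = None,
) -> dict[str, list[ExonChain]]:
    """Map every transcript; the genome index is built once."""
    params = params or AlignParams()
    index = AnchorIndex(genome, params.anchor_k)
    out: dict[str, list[ExonChain]] = {}
    for tr in transcripts:
        anchors = index.anchors(tr)
        out[tr.id] = chain_and_fill(anchors, tr, genome, params) if anchors else []
    return out


def assign_locus_groups(
    chains_by_transcript: Mapping[str, Sequence[ExonChain]],
) -> pd.DataFrame:
    """Partition transcripts into shared-single-locus vs multi-locus groups.

    A transcript placing at exactly one locus joins a shared-locus group
    with every other single-locus transcript whose best placement overlaps
    it; transcripts surviving at several loci are labelled "multi", and
    transcripts with no placement "unplaced". Copy count = number of
    surviving chains.
    """
    rows = []
    singles: list[tuple[str, ExonChain]] = []
    for tid, chains in chains_by_transcript.items():
        if not chains:
            rows.append((tid, 0, float("nan"), ".", -1, -1, "unplaced"))
            continue
        best = chains[0]
        if len(chains) == 1:
            singles.append((tid, best))
        rows.append(
            (tid, len(chains), best.identity, best.chrom, best.start, best.end, None)
        )
    # connected components of overlapping best placements among singles
    group_of: dict[str, str] = {}
    parent = {tid: tid for tid, _ in singles}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (tid_a, ca) in enumerate(singles):
        for tid_b, cb in singles[i + 1 :]:
            if ca.chrom == cb.chrom and ca.start < cb.end and cb.start < ca.end:
                parent[find(tid_a)] = find(tid_b)
    roots: dict[str, int] = {}
    for tid, _ in singles:
        r = find(tid)
        if r not in roots:
            roots[r] = len(roots) + 1
        group_of[tid] = f"locus_{roots[r]}"
    out = []
    for tid, n_loci, ident, chrom, s, e, grp in rows:
        if grp is None:
            grp = group_of[tid] if tid in group_of else "multi"
        out.append((tid, n_loci, ident, chrom, s, e, grp))
    return pd.DataFrame(
        out,
        columns=[
            "transcript_id",
            "n_loci",
            "best_identity",
            "chrom",
            "start",
            "end",
            "locus_group",
        ],
    )
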