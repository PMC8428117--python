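"""Mismatch-tolerant short-homology scanning between transcripts and UTRs.

Finds every *maximal* pair of equal-length substrings (query vs target, in
+/+ or +/- orientation) whose Hamming distance is within a mismatch budget
and whose length lies in a configured band. A hit is maximal when any 1-nt
extension on either side would exceed the mismatch budget, the length cap,
or a sequence boundary.

Two parameter presets mirror the two screening regimes the pipeline serves:
"deregulated" (10-16 nt, 0-1 mismatch) for candidate-gene UTR sets, and
"utrdb" (16-30 nt, 0-2 mismatches) for database-wide screens.

The search is pigeonhole-seeded: any qualifying hit of length >= min_len
with <= k mismatches contains an exact run of at least floor(min_len/(k+1))
bases, so exact seed matches of that length locate every candidate diagonal;
maximal hits are then enumerated analytically from the mismatch positions on
each candidate diagonal. The exhaustive reference implementation lives in
:mod:`pirnascan.scan_oracle` and is kept in-tree as the correctness oracle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .sequence import SeqRecord, reverse_complement

ORIENTATIONS = ("+/+", "+/-")


@dataclass(frozen=True)
class ScanParams:
    min_len: int = 10
    max_len: int = 16
    max_mismatch: int = 1
    orientations: tuple[str, ...] = ORIENTATIONS
    junction_min_overhang: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.junction_min_overhang < 1:
            raise ValueError("junction_min_overhang must be >= 1")
        bad = set(self.orientations) - set(ORIENTATIONS)
        if bad:
            raise ValueError(f"unknown orientations {sorted(bad)}")

    @classmethod
    def deregulated(cls, **kw) -> "ScanParams":
        """10-16 nt, 0-1 mismatch: candidate-gene UTR screening."""
        return cls(min_len=10, max_len=16, max_mismatch=1, **kw)

    @classmethod
    def utrdb(cls, **kw) -> "ScanParams":
        """16-30 nt, 0-2 mismatches: whole-UTR-database screening."""
        return cls(min_len=16, max_len=30, max_mismatch=2, **kw)

    @property
    def seed_len(self) -> int:
        return max(1, self.min_len // (self.max_mismatch + 1))


@dataclass(frozen=True)
class HomologyHit:
    """One maximal homology stretch.

    ``query_start``/``query_end`` are always on the query's forward strand,
    regardless of orientation; for +/- hits the reverse complement of the
    query substring matches the target substring.
    """

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    orientation: str
    mismatches: int
    location: str | None = None  # "exonic" | "junction", set by classify_location

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    def sort_key(self):
        return (
            self.query_id,
            self.query_start,
            self.target_id,
            self.target_start,
            self.orientation,
            self.query_end,
        )


@dataclass(frozen=True)
class HitSummary:
    n_unique_stretches: int
    n_exonic: int
    n_junction: int
    pct_exonic: float
    pct_junction: float


@dataclass(frozen=True)
class UniqueStretch:
    sequence: str
    location: str
    hits: tuple[HomologyHit, ...]


def _diagonal_maximal_windows(
    q: str, t: str, q0: int, t0: int, span: int, min_len: int, max_len: int, k: int
) -> list[tuple[int, int]]:
    """Maximal windows on one diagonal, as (offset, length) pairs.

    The diagonal pairs q[q0+i] with t[t0+i] for i in [0, span). N never
    matches anything.
    """
    mism = [
        i
        for i in range(span)
        if q[q0 + i] != t[t0 + i] or q[q0 + i] == "N" or t[t0 + i] == "N"
    ]
    out: list[tuple[int, int]] = []
    # Length-capped windows: every max_len window within budget is maximal.
    if span >= max_len:
        prefix = [0]
        acc = 0
        j = 0
        for i in range(span):
            if j < len(mism) and mism[j] == i:
                acc += 1
                j += 1
            prefix.append(acc)
        for st in range(span - max_len + 1):
            if prefix[st + max_len] - prefix[st] <= k:
                out.append((st, max_len))
    # Budget-limited windows: runs bounded by the (k+1)-th mismatch (or a
    # sequence end) on each side, containing exactly k mismatches.
    bounds = [-1] + mism + [span]
    r = len(mism)
    if k > 0:
        for i in range(r - k + 1):
            st = bounds[i] + 1
            en = bounds[i + k + 1]
            length = en - st
            if min_len <= length < max_len:
                out.append((st, length))
    # Whole-diagonal windows under budget, blocked by both sequence ends.
    if r < k and min_len <= span < max_len:
        out.append((0, span))
    if k == 0:
        # 0-budget runs between consecutive mismatches / ends.
        for i in range(r + 1):
            st = bounds[i] + 1
            en = bounds[i + 1]
            length = en - st
            if min_len <= length < max_len:
                out.append((st, length))
    return out


def _maximal_hits_plus(q: str, t: str, params: ScanParams) -> list[tuple[int, int, int, int]]:
    """All maximal (q_start, t_start, length, mismatches) with q read forward."""
    s = params.seed_len
    k = params.max_mismatch
    if len(q) < params.min_len or len(t) < params.min_len:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(t) - s + 1):
        w = t[j : j + s]
        if "N" not in w:
            index[w].append(j)
    diagonals: set[int] = set()
    for i in range(len(q) - s + 1):
        w = q[i : i + s]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            diagonals.add(j - i)
    found: set[tuple[int, int, int]] = set()
    results: list[tuple[int, int, int, int]] = []
    for d in sorted(diagonals):
        q0 = max(0, -d)
        t0 = q0 + d
        span = min(len(q) - q0, len(t) - t0)
        if span < params.min_len:
            continue
        for off, length in _diagonal_maximal_windows(
            q, t, q0, t0, span, params.min_len, params.max_len, k
        ):
            qs, ts = q0 + off, t0 + off
            key = (qs, ts, length)
            if key in found:
                continue
            found.add(key)
            mm = sum(
                1
                for x, y in zip(q[qs : qs + length], t[ts : ts + length])
                if x != y or x == "N" or y == "N"
            )
            results.append((qs, ts, length, mm))
    return results


def scan(
    queries: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    params: ScanParams,
) -> list[HomologyHit]:
    """All maximal homology hits between queries and targets.

    Returns the raw maximal-hit set in deterministic order; see
    :func:`merge_hits` and :func:`dedupe_unique_stretches` for the
    collapse to unique stretches.
    """
    hits: list[HomologyHit] = []
    for q in queries:
        oriented = {}
        if "+/+" in params.orientations:
            oriented["+/+"] = q.seq
        if "+/-" in params.orientations:
            oriented["+/-"] = reverse_complement(q.seq)
        for t in targets:
            for orient, qseq in oriented.items():
                for qs, ts, length, mm in _maximal_hits_plus(qseq, t.seq, params):
                    if orient == "+/-":
                        fwd_start = len(qseq) - (qs + length)
                        fwd_end = len(qseq) - qs
                    else:
                        fwd_start, fwd_end = qs, qs + length
                    hits.append(
                        HomologyHit(
                            query_id=q.id,
                            query_start=fwd_start,
                            query_end=fwd_end,
                            target_id=t.id,
                            target_start=ts,
                            target_end=ts + length,
                            orientation=orient,
                            mismatches=mm,
                        )
                    )
    hits.sort(key=HomologyHit.sort_key)
    return hits


def classify_location(
    hit: HomologyHit,
    boundaries: Sequence[int],
    min_overhang: int = 1,
) -> str:
    """Label a hit exonic or exon-junction-spanning.

    ``boundaries`` are exon-exon boundary positions in transcript (query)
    coordinates, i.e. cumulative exon lengths excluding 0 and the total.
    A hit spans a junction when it covers a boundary with at least
    ``min_overhang`` nt on each side -- such a stretch exists only in the
    spliced RNA, not in the genome.
    """
    for b in boundaries:
        if hit.query_start + min_overhang <= b <= hit.query_end - min_overhang:
            return "junction"
    return "exonic"


def transcript_boundaries(exon_lengths: Sequence[int]) -> list[int]:
    """Exon-exon boundary positions in transcript coordinates."""
    out = []
    acc = 0
    for L in exon_lengths[:-1]:
        acc += L
        out.append(acc)
    return out


def annotate_locations(
    hits: Iterable[HomologyHit],
    boundaries_by_query: Mapping[str, Sequence[int]],
    min_overhang: int = 1,
) -> list[HomologyHit]:
    out = []
    for h in hits:
        if h.query_id not in boundaries_by_query:
            raise KeyError(f"no exon chain for query {h.query_id!r}")
        loc = classify_location(h, boundaries_by_query[h.query_id], min_overhang)
        out.append(replace(h, location=loc))
    return out


def merge_hits(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Collapse trivially shifted variants of one stretch.

    Overlapping maximal hits of the same (query, target, orientation) that
    share at least half of the shorter hit's query interval are merged,
    keeping the longest, then lowest-mismatch, then leftmost one.
    """
    groups: dict[tuple[str, str, str], list[HomologyHit]] = defaultdict(list)
    for h in hits:
        groups[(h.query_id, h.target_id, h.orientation)].append(h)
    kept: list[HomologyHit] = []
    for key in sorted(groups):
        pool = sorted(
            groups[key],
            key=lambda h: (-h.length, h.mismatches, h.query_start, h.target_start),
        )
        chosen: list[HomologyHit] = []
        for h in pool:
            absorbed = False
            for c in chosen:
                q_ov = min(h.query_end, c.query_end) - max(h.query_start, c.query_start)
                t_ov = min(h.target_end, c.target_end) - max(h.target_start, c.target_start)
                if t_ov > 0 and q_ov >= 0.5 * min(h.length, c.length):
                    absorbed = True
                    break
            if not absorbed:
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=HomologyHit.sort_key)
    return kept


def dedupe_unique_stretches(
    hits: Sequence[HomologyHit],
    queries: Sequence[SeqRecord] | Mapping[str, str],
) -> tuple[list[UniqueStretch], HitSummary]:
    """Collapse hits to unique stretches keyed by query substring sequence.

    +/- hits are canonicalized to the query strand before keying. A unique
    stretch is junction-located if any member hit spans a junction.
    """
    if not isinstance(queries, Mapping):
        queries = {r.id: r.seq for r in queries}
    by_seq: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.location is None:
            raise ValueError("hits must be location-classified before dedup")
        sub = queries[h.query_id][h.query_start : h.query_end]
        by_seq[sub].append(h)
    stretches = []
    for seq in sorted(by_seq):
        members = tuple(sorted(by_seq[seq], key=HomologyHit.sort_key))
        loc = "junction" if any(h.location == "junction" for h in members) else "exonic"
        stretches.append(UniqueStretch(sequence=seq, location=loc, hits=members))
    n = len(stretches)
    n_j = sum(1 for s in stretches if s.location == "junction")
    n_e = n - n_j
    summary = HitSummary(
        n_unique_stretches=n,
        n_exonic=n_e,
        n_junction=n_j,
        pct_exonic=round(100.0 * n_e / n, 2) if n else 0.0,
        pct_junction=round(100.0 * n_j / n, 2) if n else 0.0,
    )
    return stretches, summary
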