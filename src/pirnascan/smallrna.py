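"""Exact full-coverage mapping of piRNA-sized reads to genome and transcripts.

piRNAs are defined operationally: short (by default 22-35 nt) sequences
matching their source at 100% identity over their full length. The mapper
records every genomic occurrence of a read on either strand, counts copies
(a placement matching both strands at one position — a palindromic read —
is one physical copy, counted once; a strand-resolved count is also kept),
and flags reads exclusive to a named chromosome. Transcript matching uses
the same exact-substring criterion.

The genome search is a prefix k-mer index with full-length verification;
the synthetic-data truth counts are produced independently by naive
scanning, which keeps the two routes honest against each other.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .sequence import GenomicInterval, SeqRecord, reverse_complement


@dataclass(frozen=True)
class PirnaParams:
    min_len: int = 22
    max_len: int = 35
    require_full_coverage: bool = True
    identity: float = 1.0  # exact matching is the contract of this module

    def __post_init__(self) -> None:
        if self.identity != 1.0:
            raise ValueError("small-RNA mapping is exact: identity must be 1.0")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")


@dataclass(frozen=True)
class PirnaPlacement:
    read_id: str
    length: int
    placements: tuple[GenomicInterval, ...]
    copy_count: int  # palindrome-collapsed occurrence count
    copy_count_stranded: int  # counting both strands separately
    chromosomes: frozenset[str]

    def exclusive_to(self, chrom: str) -> bool:
        return self.copy_count >= 1 and self.chromosomes == frozenset([chrom])


def length_filter(
    reads: Sequence[SeqRecord], params: PirnaParams
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Reads within the length band, plus kept/dropped counts."""
    kept = [r for r in reads if params.min_len <= len(r.seq) <= params.max_len]
    stats = {"input": len(reads), "kept": len(kept), "dropped": len(reads) - len(kept)}
    return kept, stats


class GenomeSearchIndex:
    """Prefix k-mer index over the genome for exact read placement."""

    def __init__(self, genome: Sequence[SeqRecord], k: int):
        self.k = k
        self.seqs = {rec.id: rec.seq for rec in genome}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rec in genome:
            s = rec.seq
            for j in range(len(s) - k + 1):
                self._index[s[j : j + k]].append((rec.id, j))

    def occurrences(self, pattern: str) -> list[tuple[str, int]]:
        if len(pattern) < self.k:
            raise ValueError("pattern shorter than index k")
        out = []
        for chrom, j in self._index.get(pattern[: self.k], ()):
            if self.seqs[chrom][j : j + len(pattern)] == pattern:
                out.append((chrom, j))
        return out


def map_exact(
    reads: Sequence[SeqRecord],
    genome: Sequence[SeqRecord],
    params: PirnaParams | None = None,
    index: GenomeSearchIndex | None = None,
) -> list[PirnaPlacement]:
    """Every full-coverage genomic occurrence of each read, both strands.

    Unplaced reads are emitted with copy_count 0, never dropped.
    """
    params = params or PirnaParams()
    if index is None:
        index = GenomeSearchIndex(genome, params.min_len)
    out = []
    for r in reads:
        rc = reverse_complement(r.seq)
        fwd = index.occurrences(r.seq)
        rev = index.occurrences(rc) if rc != r.seq else []
        ivs = [
            GenomicInterval(chrom, j, j + len(r.seq), "+") for chrom, j in fwd
        ] + [GenomicInterval(chrom, j, j + len(r.seq), "-") for chrom, j in rev]
        ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
        stranded = len(fwd) + len(rev) + (len(fwd) if rc == r.seq else 0)
        out.append(
            PirnaPlacement(
                read_id=r.id,
                length=len(r.seq),
                placements=tuple(ivs),
                copy_count=len(ivs),
                copy_count_stranded=stranded,
                chromosomes=frozenset(iv.chrom for iv in ivs),
            )
        )
    return out


def match_to_transcripts(
    reads: Sequence[SeqRecord], transcripts: Sequence[SeqRecord]
) -> pd.DataFrame:
    """Exact full-length matches of reads (either strand) in transcripts.

    A read derives from the transcript set iff it has at least one match;
    junction-spanning reads match transcripts but not the genome.
    """
    rows = []
    for r in reads:
        rc = reverse_complement(r.seq)
        matched = False
        for t in transcripts:
            for strand, pat in (("+", r.seq), ("-", rc)):
                if strand == "-" and rc == r.seq:
                    continue
                start = t.seq.find(pat)
                while start != -1:
                    rows.append((r.id, t.id, start, strand))
                    matched = True
                    start = t.seq.find(pat, start + 1)
        if not matched:
            rows.append((r.id, ".", -1, "."))
    return pd.DataFrame(rows, columns=["read_id", "transcript_id", "offset", "strand"])


def placement_summary(
    placements: Sequence[PirnaPlacement], target_chrom: str
) -> pd.DataFrame:
    rows = [
        {
            "read_id": p.read_id,
            "length": p.length,
            "copy_count": p.copy_count,
            "copy_count_stranded": p.copy_count_stranded,
            "chromosomes": ",".join(sorted(p.chromosomes)) or ".",
            "exclusive": int(p.exclusive_to(target_chrom)),
        }
        for p in placements
    ]
    return pd.DataFrame(rows)
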