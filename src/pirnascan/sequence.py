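"""Alphabet-aware nucleotide sequence utilities and FASTA IO.

All other modules operate on the DNA alphabet {A, C, G, T, N}. RNA input
(containing U) is accepted and normalized to DNA on parsing; the original
molecule type is retained on each record so output can be rendered back in
the input alphabet if desired. Coordinates are 0-based half-open everywhere
internally; 1-based inclusive conversion happens only at GFF3 output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside the supported alphabet."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence, normalized to uppercase DNA.

    ``moltype`` records whether the input used the RNA alphabet (any U);
    ``seq`` is always stored with U replaced by T so that cross-comparisons
    between RNA oligos and genomic DNA are direct string comparisons.
    """

    id: str
    seq: str
    moltype: str = "DNA"  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )
        if self.moltype not in ("DNA", "RNA"):
            raise ValueError(f"moltype must be DNA or RNA, got {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def normalize(seq: str) -> tuple[str, str]:
    """Uppercase, strip whitespace, map U->T.  Returns (dna_seq, moltype)."""
    s = "".join(seq.split()).upper()
    moltype = "RNA" if "U" in s else "DNA"
    if "U" in s and "T" in s:
        raise AlphabetError("U and T co-occur in input sequence")
    s = s.replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    return s, moltype


def reverse_complement(s: str) -> str:
    """Reverse complement in the sequence's own alphabet (DNA or RNA).

    N maps to N. Mixed U/T input is rejected.
    """
    u = s.upper()
    if "U" in u:
        if "T" in u:
            raise AlphabetError("U and T co-occur")
        table = _COMPLEMENT_RNA
        alphabet = frozenset("ACGUN")
    else:
        table = _COMPLEMENT_DNA
        alphabet = DNA_ALPHABET
    bad = set(u) - alphabet
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    return u.translate(table)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings.

    N never matches anything, including another N: an ambiguous base cannot
    be claimed as evidence of homology.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into normalized records, order preserved."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, moltype = normalize(str(rec.seq))
        records.append(SeqRecord(id=rec.id, seq=seq, moltype=moltype))
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
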