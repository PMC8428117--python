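"""GFF3 / BED6 / TSV emission and read-back for pipeline artifacts.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive, BED stays 0-based half-open. Every TSV carries a ``#columns:``
schema comment that readers validate.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .align import ExonChain
from .scan import HomologyHit
from .sequence import GenomicInterval

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import GenomeTruth, IsoformTruth


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#columns: " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#columns:"):
            raise ValueError(f"{path}: missing #columns schema comment")
        declared = header[len("#columns:") :].split()
        df = pd.read_csv(fh, sep="\t")
    if list(map(str, df.columns)) != declared:
        raise ValueError(f"{path}: columns {list(df.columns)} != declared {declared}")
    return df


def _gff3_line(chrom, source, ftype, start0, end0, score, strand, attrs) -> str:
    a = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{chrom}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t{score}\t{strand}\t.\t{a}"


def write_chains_gff3(chains: Iterable[ExonChain], path: str | Path) -> None:
    """One mRNA feature per chain, exon children; 1-based inclusive."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(sorted(chains, key=lambda c: (c.transcript_id, c.chrom, c.start))):
            mid = f"{c.transcript_id}.m{i + 1}"
            fh.write(
                _gff3_line(
                    c.chrom,
                    "pirnascan",
                    "mRNA",
                    c.start,
                    c.end,
                    f"{c.identity:.4f}",
                    c.strand,
                    {"ID": mid, "transcript_id": c.transcript_id},
                )
                + "\n"
            )
            for j, iv in enumerate(c.exons):
                fh.write(
                    _gff3_line(
                        c.chrom,
                        "pirnascan",
                        "exon",
                        iv.start,
                        iv.end,
                        ".",
                        c.strand,
                        {"ID": f"{mid}.e{j + 1}", "Parent": mid},
                    )
                    + "\n"
                )


def read_chains_gff3(path: str | Path) -> list[ExonChain]:
    """Read back chains written by :func:`write_chains_gff3`."""
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, score, strand, _frame, attrs = line.split("\t")
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        if ftype == "mRNA":
            mrnas[a["ID"]] = {
                "transcript_id": a.get("transcript_id", a["ID"]),
                "chrom": chrom,
                "strand": strand,
                "identity": float(score) if score != "." else float("nan"),
                "exons": [],
            }
            order.append(a["ID"])
        elif ftype == "exon":
            mrnas[a["Parent"]]["exons"].append(
                GenomicInterval(chrom, int(start) - 1, int(end), strand)
            )
    out = []
    for mid in order:
        m = mrnas[mid]
        out.append(
            ExonChain(
                transcript_id=m["transcript_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(m["exons"], key=lambda iv: iv.start)),
                identity=m["identity"],
                score=float("nan"),
            )
        )
    return out


def write_truth_gff3(truth: "GenomeTruth", iso_truth: "IsoformTruth", path: str | Path) -> None:
    """Locus copies as gene features plus copy-0 isoform chains."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for c in truth.copies:
            gid = f"locus_copy_{c.copy_index}"
            fh.write(
                _gff3_line(
                    c.chrom, "synth", "gene", c.start, c.end, ".", "+", {"ID": gid}
                )
                + "\n"
            )
        for iso, per_copy in iso_truth.chains.items():
            exons = per_copy[0]
            mid = f"{iso}.truth"
            fh.write(
                _gff3_line(
                    exons[0].chrom,
                    "synth",
                    "mRNA",
                    exons[0].start,
                    exons[-1].end,
                    ".",
                    "+",
                    {"ID": mid, "transcript_id": iso},
                )
                + "\n"
            )
            for j, iv in enumerate(exons):
                fh.write(
                    _gff3_line(
                        iv.chrom,
                        "synth",
                        "exon",
                        iv.start,
                        iv.end,
                        ".",
                        "+",
                        {"ID": f"{mid}.e{j + 1}", "Parent": mid},
                    )
                    + "\n"
                )


def hits_frame(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "query_start": h.query_start,
                "query_end": h.query_end,
                "target_id": h.target_id,
                "target_start": h.target_start,
                "target_end": h.target_end,
                "orientation": h.orientation,
                "length": h.length,
                "mismatches": h.mismatches,
                "location": h.location or ".",
            }
            for h in hits
        ],
        columns=[
            "query_id",
            "query_start",
            "query_end",
            "target_id",
            "target_start",
            "target_end",
            "orientation",
            "length",
            "mismatches",
            "location",
        ],
    )


def write_hits_tsv(hits: Sequence[HomologyHit], path: str | Path) -> None:
    write_tsv(hits_frame(hits), path)


def read_hits_tsv(path: str | Path) -> list[HomologyHit]:
    df = read_tsv(path)
    return [
        HomologyHit(
            query_id=r.query_id,
            query_start=int(r.query_start),
            query_end=int(r.query_end),
            target_id=r.target_id,
            target_start=int(r.target_start),
            target_end=int(r.target_end),
            orientation=r.orientation,
            mismatches=int(r.mismatches),
            location=None if r.location == "." else r.location,
        )
        for r in df.itertuples()
    ]


def write_hits_bed6(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """Hits in target coordinates; name = query_id:qstart-qend:orientation:mm."""
    with Path(path).open("w") as fh:
        for h in sorted(hits, key=lambda h: (h.target_id, h.target_start)):
            name = f"{h.query_id}:{h.query_start}-{h.query_end}:{h.orientation}:{h.mismatches}"
            strand = "+" if h.orientation == "+/+" else "-"
            fh.write(
                f"{h.target_id}\t{h.target_start}\t{h.target_end}\t{name}\t"
                f"{h.length}\t{strand}\n"
            )


def write_placements_bed6(placements, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in placements:
            for iv in p.placements:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.read_id}\t"
                    f"{p.copy_count}\t{iv.strand}\n"
                )
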