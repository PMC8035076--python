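"""Readers and writers for BED, BEDPE, GFF3, bedGraph and chrom.sizes.

Internal convention is 0-based half-open. GFF3 is 1-based inclusive on disk;
the conversion (start-1, end) happens here and only here. All writers emit
tab-separated, newline-terminated records.
"""

from __future__ import annotations

import urllib.parse
from typing import Optional, Sequence

import pandas as pd

from .genome import ChromSizes, GeneModel, GenomicInterval

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
    "write_gff3",
    "read_intervals",
]


class ParseError(ValueError):
    """Malformed record; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _check_chrom(path, lineno, chrom, chrom_sizes: Optional[ChromSizes]):
    if chrom_sizes is not None and chrom not in chrom_sizes:
        raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")


def read_chrom_sizes(path) -> ChromSizes:
    items = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected two columns")
        try:
            items.append((fields[0], int(fields[1])))
        except ValueError as e:
            raise ParseError(path, lineno, str(e)) from None
    return ChromSizes(items)


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


def _interval_from_bed_fields(path, lineno, fields) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError):
        raise ParseError(path, lineno, "malformed BED coordinates") from None
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(path, lineno, f"bad score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom, start, end, strand, name, score)
    except ValueError as e:
        raise ParseError(path, lineno, str(e)) from None


def read_bed(
    path, chrom_sizes: Optional[ChromSizes] = None
) -> list[GenomicInterval]:
    out = []
    for lineno, fields in _data_lines(path):
        iv = _interval_from_bed_fields(path, lineno, fields)
        _check_chrom(path, lineno, iv.chrom, chrom_sizes)
        out.append(iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand != ".":
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedpe(
    path, chrom_sizes: Optional[ChromSizes] = None
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, "expected >= 6 BEDPE columns")
        name = fields[6] if len(fields) > 6 and fields[6] != "." else None
        score = None
        if len(fields) > 7 and fields[7] != ".":
            try:
                score = float(fields[7])
            except ValueError:
                raise ParseError(path, lineno, f"bad score {fields[7]!r}") from None
        try:
            a = GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]), name=name, score=score
            )
            b = GenomicInterval(
                fields[3], int(fields[4]), int(fields[5]), name=name, score=score
            )
        except ValueError as e:
            raise ParseError(path, lineno, str(e)) from None
        _check_chrom(path, lineno, a.chrom, chrom_sizes)
        _check_chrom(path, lineno, b.chrom, chrom_sizes)
        out.append((a, b))
    return out


def write_bedpe(
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]], path
) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fields = [
                a.chrom, str(a.start), str(a.end),
                b.chrom, str(b.start), str(b.end),
            ]
            if a.name is not None:
                fields.append(a.name)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(
    path, chrom_sizes: Optional[ChromSizes] = None
) -> list[GenomicInterval]:
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected 4 bedGraph columns")
        try:
            iv = GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]), score=float(fields[3])
            )
        except ValueError as e:
            raise ParseError(path, lineno, str(e)) from None
        _check_chrom(path, lineno, iv.chrom, chrom_sizes)
        out.append(iv)
    return out


def write_bedgraph(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k] = urllib.parse.unquote(v)
    return out


def read_gff3(path, chrom_sizes: Optional[ChromSizes] = None) -> GeneModel:
    """Read genes and transcripts (mRNA or generic *RNA features) from GFF3.

    A gene-level attribute ``housekeeping=1`` marks housekeeping genes.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    genes, transcripts = [], []
    for lineno, fields in _data_lines(path):
        if len(fields) != 9:
            raise ParseError(path, lineno, "expected 9 GFF3 columns")
        chrom, _, ftype, start, end, _, strand, _, attr_text = fields
        _check_chrom(path, lineno, chrom, chrom_sizes)
        try:
            start0, end0 = int(start) - 1, int(end)
        except ValueError:
            raise ParseError(path, lineno, "malformed GFF3 coordinates") from None
        if start0 < 0 or start0 >= end0:
            raise ParseError(path, lineno, f"invalid span {start}-{end}")
        attrs = _parse_gff3_attributes(attr_text)
        if ftype == "gene":
            genes.append(
                {
                    "gene_id": attrs.get("ID", f"gene_{lineno}"),
                    "symbol": attrs.get("Name", attrs.get("ID", "")),
                    "chrom": chrom,
                    "housekeeping": attrs.get("housekeeping", "0") == "1",
                }
            )
        elif ftype.endswith("RNA") or ftype == "transcript":
            if "Parent" not in attrs:
                raise ParseError(path, lineno, "transcript without Parent")
            transcripts.append(
                {
                    "transcript_id": attrs.get("ID", f"tx_{lineno}"),
                    "gene_id": attrs["Parent"],
                    "chrom": chrom,
                    "start": start0,
                    "end": end0,
                    "strand": strand,
                }
            )
    return GeneModel(
        pd.DataFrame(genes, columns=["gene_id", "symbol", "chrom", "housekeeping"]),
        pd.DataFrame(
            transcripts,
            columns=["transcript_id", "gene_id", "chrom", "start", "end", "strand"],
        ),
    )


def write_gff3(model: GeneModel, path) -> None:
    """Write a GeneModel as GFF3 (1-based inclusive on disk)."""
    tx_by_gene = model.transcripts.groupby("gene_id")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in model.genes.itertuples():
            try:
                txs = tx_by_gene.get_group(g.gene_id)
            except KeyError:
                continue
            gstart, gend = int(txs["start"].min()), int(txs["end"].max())
            strand = txs["strand"].iloc[0]
            hk = ";housekeeping=1" if g.housekeeping else ""
            fh.write(
                f"{g.chrom}\tdvchrom\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}{hk}\n"
            )
            for t in txs.itertuples():
                fh.write(
                    f"{t.chrom}\tdvchrom\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
                )


def read_intervals(path, format: str, chrom_sizes: Optional[ChromSizes] = None):
    """Dispatch by format name: BED, BEDPE, GFF3 or bedGraph."""
    readers = {
        "BED": read_bed,
        "BEDPE": read_bedpe,
        "GFF3": read_gff3,
        "bedGraph": read_bedgraph,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}")
    return readers[format](path, chrom_sizes)
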