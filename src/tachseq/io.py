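"""Readers and writers for the flat-file formats the pipeline exchanges.

Formats
-------
FASTA        genome sequence (via Biopython).
BED6         tags and anchors in, hotspots out. Tags require strand.
gene table   bespoke TSV: gene_id, contig, strand, tss, tts, exons
             (exons as comma-separated "start-end" pairs, may be empty).
expression   TSV: gene_id, transcripts_per_cell.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomeSequence, GenomicInterval, GeneModel, Hotspot, HotspotSet, TagLibrary

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tags_bed",
    "write_tags_bed",
    "read_intervals_bed",
    "write_hotspots_bed",
    "read_hotspots_bed",
    "write_intervals_bed",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "write_expression_table",
    "attach_expression",
]

GENE_TABLE_COLUMNS = ["gene_id", "contig", "strand", "tss", "tts", "exons"]


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Lowercase is folded to uppercase and non-ACGTN characters become N.
    Duplicate contig names or an empty file are hard errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_tags_bed(path, genome: GenomeSequence | None = None, label: str = "") -> TagLibrary:
    """Read aligned tags from BED (>= 6 columns; strand is required).

    One tag per line; records with strand '.' are rejected because the cut
    site (the 5' end) is undefined without a strand.
    """
    contigs, starts, ends, strands = [], [], [], []
    lengths = genome.lengths if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: tag BED needs >= 6 columns (strand required)"
                )
            contig, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: tag strand must be '+' or '-', got {strand!r}"
                )
            if lengths is not None:
                if contig not in lengths:
                    raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
                if end > lengths[contig]:
                    raise ValueError(f"{path}:{lineno}: tag beyond end of {contig!r}")
            contigs.append(contig)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    return TagLibrary.from_arrays(contigs, starts, ends, strands, label=label or str(path))


def write_tags_bed(library: TagLibrary, path) -> None:
    df = library.frame
    with open(path, "w") as fh:
        for i, (contig, start, end, strand) in enumerate(
            zip(df["contig"], df["start"], df["end"], df["strand"])
        ):
            fh.write(f"{contig}\t{start}\t{end}\ttag_{i + 1}\t0\t{strand}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read generic anchor/region intervals from BED3+ (strand optional)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path, name_prefix="region") -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name_prefix}_{i + 1}\t0\t{iv.strand}\n")


def write_hotspots_bed(hotspot_set: HotspotSet, path) -> None:
    """Write hotspots as BED5+: name, density (3 decimals) as score, strand '.',
    z-score in column 7, tag count in column 8; sorted by contig then start."""
    with open(path, "w") as fh:
        for i, h in enumerate(hotspot_set.hotspots):
            iv = h.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\ths_{i + 1}\t"
                f"{h.density:.3f}\t.\t{h.z_score:.4f}\t{h.tag_count}\n"
            )


def read_hotspots_bed(path, label: str = "") -> HotspotSet:
    hotspots = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 hotspot columns")
            hotspots.append(
                Hotspot(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    tag_count=int(f[7]),
                    density=float(f[4]),
                    z_score=float(f[6]),
                )
            )
    return HotspotSet(hotspots, label=label or str(path))


def _format_exons(exons: list[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str) -> list[tuple[int, int]]:
    text = text.strip()
    if not text or text == ".":
        return []
    out = []
    for block in text.split(","):
        s, e = block.split("-")
        out.append((int(s), int(e)))
    return out


def read_gene_table(path) -> list[GeneModel]:
    """Read the bespoke tab-delimited gene table.

    Multiple rows may share a ``gene_id`` (alternative TSSs). A TSS/TTS pair
    inconsistent with the strand raises (via :class:`GeneModel` validation).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                contig=row.contig,
                strand=row.strand,
                tss=int(row.tss),
                tts=int(row.tts),
                exons=_parse_exons(str(row.exons)),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig,
            "strand": g.strand,
            "tss": g.tss,
            "tts": g.tts,
            "exons": _format_exons(g.exons) or ".",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, transcripts_per_cell."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "transcripts_per_cell"} <= set(df.columns):
        raise ValueError("expression table needs gene_id and transcripts_per_cell")
    if (df["transcripts_per_cell"] < 0).any():
        raise ValueError("transcripts_per_cell must be non-negative")
    return df[["gene_id", "transcripts_per_cell"]]


def write_expression_table(df: pd.DataFrame, path) -> None:
    df[["gene_id", "transcripts_per_cell"]].to_csv(path, sep="\t", index=False)


def attach_expression(genes: list[GeneModel], expression: pd.DataFrame) -> list[GeneModel]:
    """Join expression onto genes by gene_id.

    Genes absent from the expression table keep ``transcripts_per_cell=None``
    and are treated downstream as "nd" (not detected).
    """
    lookup = dict(
        zip(expression["gene_id"], expression["transcripts_per_cell"].astype(float))
    )
    out = []
    for g in genes:
        t = lookup.get(g.gene_id)
        out.append(
            GeneModel(
                g.gene_id, g.contig, g.strand, g.tss, g.tts,
                exons=list(g.exons),
                transcripts_per_cell=None if t is None else float(t),
            )
        )
    return out
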