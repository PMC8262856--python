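"""Genome and locus-table input/output.

Coordinates are GFF3 native throughout: 1-based, inclusive on both ends.
Intergenic distances follow the survey convention of the locus table:
``start(b) - end(a) - 1``, so a negative value means the two genes overlap
and 0 means they abut.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

LOCUS_COLUMNS = [
    "kinase_id",
    "length_codons",
    "organism",
    "phylum",
    "kinase_seq",
    "distance_nt",
    "organization",
    "antitoxin_id",
    "antitoxin_len",
    "antitoxin_seq",
    "hips_seq",
    "antitoxin_domains",
    "notes",
]

KNOWN_ORGANIZATIONS = {
    "hipBA",
    "hipAB",
    "hipBST",
    "hipEB",
    "hipH_mono",
    "hipL_mono",
    "hipRF",
    "hipRG",
    "hipMP",
    "hipIN",
    "hipJS",
    "unclassified",
}


class GenomeParseError(ValueError):
    """Malformed GFF3/FASTA input."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated coding gene with its protein sequence."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.protein) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.gene_id}: invalid residues {sorted(bad)}")

    @property
    def length_codons(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class LocusRow:
    """One row of the survey locus table (one kinase gene)."""

    kinase_id: str
    length_codons: int
    organism: str
    phylum: str
    kinase_seq: str
    distance_nt: int | None
    organization: str
    antitoxin_id: str = ""
    antitoxin_len: int | None = None
    antitoxin_seq: str = ""
    hips_seq: str = ""
    antitoxin_domains: str = ""
    notes: str = ""

    @property
    def organization_known(self) -> bool:
        return self.organization in KNOWN_ORGANIZATIONS


@dataclass
class LocusTable:
    rows: list[LocusRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.kinase_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate kinase IDs in locus table")

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LocusTable) and self.rows == other.rows

    def layout_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.organization] = counts.get(row.organization, 0) + 1
        return counts

    def unknown_organizations(self) -> list[str]:
        return [r.kinase_id for r in self.rows if not r.organization_known]


def parse_genome(gff_stream: TextIO | str, fasta_stream: TextIO | str) -> list[GeneRecord]:
    """Read coding genes from GFF3 + protein FASTA.

    Returns GeneRecords sorted by (contig, start).  CDS/gene features whose
    ID has no matching FASTA record raise an error naming the gene rather
    than being silently dropped.
    """
    if isinstance(gff_stream, str):
        gff_stream = io.StringIO(gff_stream)
    if isinstance(fasta_stream, str):
        fasta_stream = io.StringIO(fasta_stream)

    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_stream, "fasta")}

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(gff_stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GenomeParseError(
                f"GFF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        contig, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype not in {"CDS", "gene"}:
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise GenomeParseError(f"GFF line {lineno}: bad coordinates") from exc
        attr_map = _parse_attributes(attrs, lineno)
        gene_id = attr_map.get("ID")
        if gene_id is None:
            raise GenomeParseError(f"GFF line {lineno}: feature without ID attribute")
        if gene_id in seen:
            raise GenomeParseError(f"duplicate gene ID {gene_id!r} (line {lineno})")
        seen.add(gene_id)
        protein = proteins.get(gene_id)
        if protein is None:
            raise GenomeParseError(
                f"gene {gene_id!r} (GFF line {lineno}) has no matching FASTA record"
            )
        records.append(
            GeneRecord(
                gene_id=gene_id,
                contig=contig,
                start=start_i,
                end=end_i,
                strand=strand,
                protein=protein,
                product=attr_map.get("product", ""),
            )
        )
    records.sort(key=lambda g: (g.contig, g.start))
    return records


def _parse_attributes(attrs: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GenomeParseError(f"GFF line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


def write_genome(genes: Sequence[GeneRecord], gff_stream: TextIO, fasta_stream: TextIO) -> None:
    """Emit GFF3 + protein FASTA for a gene set (inverse of parse_genome)."""
    gff_stream.write("##gff-version 3\n")
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        attrs = f"ID={g.gene_id}"
        if g.product:
            attrs += f";product={g.product}"
        gff_stream.write(
            f"{g.contig}\tsynth\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
        )
        fasta_stream.write(f">{g.gene_id}\n{g.protein}\n")


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Signed nucleotide gap between two genes; negative means overlap.

    Arguments may be given in either order; the gene with the smaller
    start coordinate is treated as the upstream one.
    """
    if a.contig != b.contig:
        raise ValueError(f"{a.gene_id} and {b.gene_id} are on different contigs")
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end - 1


def parse_locus_table(
    tsv_stream: TextIO | str, column_map: dict[str, str] | None = None
) -> LocusTable:
    """Read a tab-separated locus table.

    ``column_map`` maps our canonical column names to the header strings
    actually present in the file (the published supplementary table does
    not fix its header spelling).
    """
    if isinstance(tsv_stream, str):
        tsv_stream = io.StringIO(tsv_stream)
    header_line = tsv_stream.readline().rstrip("\n")
    if not header_line:
        return LocusTable()
    header = header_line.split("\t")
    column_map = column_map or {}
    positions: dict[str, int] = {}
    for canonical in LOCUS_COLUMNS:
        actual = column_map.get(canonical, canonical)
        if actual in header:
            positions[canonical] = header.index(actual)
    mandatory = ["kinase_id", "length_codons", "organism", "kinase_seq", "organization"]
    for col in mandatory:
        if col not in positions:
            raise ValueError(f"locus table missing mandatory column {col!r}")

    rows: list[LocusRow] = []
    for raw in tsv_stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")

        def get(col: str, default: str = "") -> str:
            idx = positions.get(col)
            if idx is None or idx >= len(fields):
                return default
            return fields[idx]

        dist = get("distance_nt")
        at_len = get("antitoxin_len")
        rows.append(
            LocusRow(
                kinase_id=get("kinase_id"),
                length_codons=int(get("length_codons") or 0),
                organism=get("organism"),
                phylum=get("phylum"),
                kinase_seq=get("kinase_seq"),
                distance_nt=int(dist) if dist not in ("", "NA") else None,
                organization=get("organization"),
                antitoxin_id=get("antitoxin_id"),
                antitoxin_len=int(at_len) if at_len not in ("", "NA") else None,
                antitoxin_seq=get("antitoxin_seq"),
                hips_seq=get("hips_seq"),
                antitoxin_domains=get("antitoxin_domains"),
                notes=get("notes"),
            )
        )
    return LocusTable(rows=rows)


def write_locus_table(table: LocusTable, stream: TextIO) -> None:
    stream.write("\t".join(LOCUS_COLUMNS) + "\n")
    for r in table.rows:
        fields = [
            r.kinase_id,
            str(r.length_codons),
            r.organism,
            r.phylum,
            r.kinase_seq,
            "" if r.distance_nt is None else str(r.distance_nt),
            r.organization,
            r.antitoxin_id,
            "" if r.antitoxin_len is None else str(r.antitoxin_len),
            r.antitoxin_seq,
            r.hips_seq,
            r.antitoxin_domains,
            r.notes,
        ]
        stream.write("\t".join(fields) + "\n")
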