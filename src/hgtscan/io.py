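"""Reading, writing and in-memory modelling of annotated bacterial genomes.

All coordinates are 0-based, half-open *internally*.  GFF3 (1-based,
inclusive) and BED (0-based, half-open) are converted at the I/O boundary,
so the rest of the package never handles more than one convention.

The central container is :class:`AnnotatedGenome`: one or more contig
sequences, a positionally ordered list of gene models, and the protein
translations of every gene whose CDS validates under the bacterial genetic
code (NCBI translation table 11).  Genes with an internal stop codon or a
CDS length not divisible by three are *flagged*: they keep their position
in the gene order (window-based scans are positional) but are excluded from
the proteome and from every translation-dependent statistic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_NUC_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

#: NCBI translation table used throughout (bacterial/archaeal/plant plastid).
TRANSLATION_TABLE = 11


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeRecord:
    """A single contig/chromosome: uppercase DNA over ``{A,C,G,T,N}``."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _NUC_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A protein-coding gene model on one contig.

    ``start``/``end`` are internal 0-based half-open; ``segments`` carries
    the CDS parts (also half-open) in genomic order for multi-part CDS.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})"
            )
        if not self.segments:
            self.segments = ((self.start, self.end),)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class AnnotatedGenome:
    """Genome sequence(s) plus ordered gene models and their translations.

    ``genes`` is sorted by (contig, start); this positional order is the
    one every gene-window operation uses.  ``proteome`` maps gene_id to the
    amino-acid string of each *valid* gene; ``invalid_genes`` records genes
    whose CDS failed translation, with the reason.
    """

    records: list[GenomeRecord]
    genes: list[GeneAnnotation] = field(default_factory=list)
    proteome: dict[str, str] = field(default_factory=dict)
    invalid_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)

    @property
    def record_index(self) -> dict[str, GenomeRecord]:
        return {r.id: r for r in self.records}

    def valid_genes(self) -> list[GeneAnnotation]:
        """Genes with a usable translation, in positional order."""
        return [g for g in self.genes if g.gene_id in self.proteome]

    @classmethod
    def from_files(cls, fasta_path, gff3_path) -> "AnnotatedGenome":
        records = read_fasta(fasta_path, kind="nucleotide")
        genome = cls(records=records)
        genome.genes = read_gff3(gff3_path, genome)
        genome.__post_init__()
        build_proteome(genome)
        return genome


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, kind: str = "nucleotide") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; in nucleotide mode U is mapped to T.  Protein
    mode (``kind="protein"``) validates against the amino-acid alphabet and
    returns records whose ``sequence`` is the peptide.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if kind == "nucleotide":
            seq = seq.replace("U", "T")
            bad = set(seq) - _NUC_ALPHABET
        elif kind == "protein":
            bad = set(seq) - _AA_ALPHABET
        else:
            raise ValueError(f"unknown kind {kind!r}")
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal characters {sorted(bad)!r}"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        # bypass GenomeRecord's nucleotide validation for proteins
        if kind == "protein":
            r = GenomeRecord.__new__(GenomeRecord)
            r.id, r.sequence, r.circular = rec.id, seq, False
            records.append(r)
        else:
            records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    """Write records (anything with ``.id`` and ``.sequence``) as FASTA."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_protein_fasta(path) -> dict[str, str]:
    """Protein FASTA as an id → sequence mapping (trailing ``*`` stripped)."""
    return {
        r.id: r.sequence.rstrip("*") for r in read_fasta(path, kind="protein")
    }


# ---------------------------------------------------------------------------
# GFF3

_GFF_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v for k, v in _GFF_ATTR_RE.findall(text)}


def read_gff3(path, genome: AnnotatedGenome) -> list[GeneAnnotation]:
    """Parse CDS features from a GFF3 file into gene annotations.

    One :class:`GeneAnnotation` is produced per distinct CDS ID (GFF3 allows
    a multi-segment CDS to repeat its ID; segments are concatenated in
    translation order during translation).  Coordinates are converted from
    GFF3's 1-based inclusive to the internal 0-based half-open convention.
    """
    path = Path(path)
    contigs = genome.record_index
    by_id: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("Parent")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: CDS lacks ID/Parent attribute")
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(
                    f"{path}:{lineno}: start {start_i} > end {end_i} for {gene_id!r}"
                )
            if contig not in contigs:
                raise FormatError(
                    f"{path}:{lineno}: unknown contig {contig!r} for {gene_id!r}"
                )
            if end_i > len(contigs[contig]):
                raise FormatError(
                    f"{path}:{lineno}: {gene_id!r} extends past end of {contig!r}"
                )
            seg = (start_i - 1, end_i)  # to 0-based half-open
            entry = by_id.setdefault(
                gene_id,
                {
                    "contig": contig,
                    "strand": strand,
                    "segments": [],
                    "product": attributes.get("product", ""),
                },
            )
            if entry["contig"] != contig or entry["strand"] != strand:
                raise FormatError(
                    f"{path}:{lineno}: segments of {gene_id!r} disagree on "
                    "contig/strand"
                )
            entry["segments"].append(seg)
    genes = []
    for gene_id, entry in by_id.items():
        segs = tuple(sorted(entry["segments"]))
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                contig=entry["contig"],
                start=segs[0][0],
                end=segs[-1][1],
                strand=entry["strand"],
                product=entry["product"],
                segments=segs,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Emit the genome's gene models as GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genome.records:
            fh.write(f"##sequence-region {rec.id} 1 {len(rec)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            for s, e in g.segments:
                fh.write(
                    f"{g.contig}\thgtscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Translation


def extract_cds(genome: AnnotatedGenome, gene: GeneAnnotation) -> str:
    """The coding sequence of *gene*, strand-resolved (5'→3' of the ORF)."""
    rec = genome.record_index[gene.contig]
    parts = [rec.sequence[s:e] for s, e in gene.segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def translate_cds(genome: AnnotatedGenome, gene: GeneAnnotation) -> str | None:
    """Translate a gene's CDS under NCBI table 11.

    The initial codon is rendered 'M' when it is a valid start codon of the
    table (bacterial alternative starts GTG/TTG included); the trailing stop
    is removed.  Returns ``None`` (with a logged warning) for a CDS whose
    length is not a multiple of three or that contains an internal stop —
    such genes are flagged rather than crashing the pipeline.
    """
    cds = extract_cds(genome, gene)
    if len(cds) % 3 != 0:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3; excluded",
            gene.gene_id,
            len(cds),
        )
        return None
    aa = str(Seq(cds).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("gene %s: internal stop codon; excluded", gene.gene_id)
        return None
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE]
    if aa and cds[:3] in table.start_codons:
        aa = "M" + aa[1:]
    return aa


def build_proteome(genome: AnnotatedGenome) -> None:
    """Populate ``genome.proteome`` / ``genome.invalid_genes`` in place."""
    for gene in genome.genes:
        aa = translate_cds(genome, gene)
        if aa is None:
            genome.invalid_genes[gene.gene_id] = "invalid CDS"
        elif not aa:
            genome.invalid_genes[gene.gene_id] = "empty translation"
        else:
            genome.proteome[gene.gene_id] = aa


# ---------------------------------------------------------------------------
# BED


def write_island_bed(calls, path) -> None:
    """Write island calls as BED4+score (score = mean GC × 1000, integer).

    Intervals are already 0-based half-open internally, so they are written
    verbatim.
    """
    with open(path, "w") as fh:
        for i, call in enumerate(calls, 1):
            fh.write(
                f"{call.contig}\t{call.start}\t{call.end}\t"
                f"island_{i}\t{round(call.mean_gc * 1000)}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, int]]:
    """Read a BED4+score file back into (contig, start, end, name, score)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            c, s, e, name, score = line.split("\t")[:5]
            rows.append((c, int(s), int(e), name, int(score)))
    return rows
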