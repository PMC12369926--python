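"""Coordinate-aware genome, gene and transcript models with FASTA/GTF I/O.

All internal coordinates are 0-based, half-open intervals on the forward
reference strand.  GTF input/output converts to and from the 1-based
inclusive convention of the format.  Sequence-facing operations
(:func:`spliced_sequence`, flank extraction downstream) always return
transcript-sense sequence, i.e. reverse-complemented for minus-strand
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class ValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


class GenomeSequence:
    """Mapping from chromosome name to an A/C/G/T/N nucleotide string."""

    def __init__(self, chroms: dict[str, str]):
        for name, seq in chroms.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} is empty")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValidationError(f"chromosome {name!r} has invalid characters {bad}")
        self._chroms = dict(chroms)

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self):
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._chroms == other._chroms

    def items(self):
        return self._chroms.items()

    def length(self, name: str) -> int:
        return len(self._chroms[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end); bounds-checked."""
        seq = self._chroms[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True, order=True)
class Exon:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"invalid exon interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceJunction:
    """An intron boundary pair in transcript sense.

    ``donor`` is the genomic position of the exon/intron boundary at the
    intron's 5' end, ``acceptor`` at its 3' end; on the minus strand the
    donor is therefore the genomically *rightmost* of the two.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValidationError("donor and acceptor coincide")
        if self.strand == "+" and self.donor > self.acceptor:
            raise ValidationError("plus-strand donor must precede acceptor")
        if self.strand == "-" and self.donor < self.acceptor:
            raise ValidationError("minus-strand donor must follow acceptor")

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic (start, end) of the intron, half-open."""
        return (min(self.donor, self.acceptor), max(self.donor, self.acceptor))


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Exon]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(f"transcript {self.transcript_id}: multiple chromosomes")
        strands = {e.strand for e in self.exons} | {self.strand}
        if len(strands) > 1:
            raise ValidationError(f"transcript {self.transcript_id}: mixed strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) overlap or abut (zero-length intron)"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0].start, self.exons[-1].end)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def splice_sites(self) -> list[tuple[int, str]]:
        """Internal splice-site chain in genomic order.

        Each site is (position, kind) with kind "E" for an exon-end boundary
        and "S" for an exon-start boundary; the first exon's start and the
        last exon's end are transcript termini, not splice sites, and are
        excluded.
        """
        sites: list[tuple[int, str]] = []
        for i, e in enumerate(self.exons):
            if i > 0:
                sites.append((e.start, "S"))
            if i < len(self.exons) - 1:
                sites.append((e.end, "E"))
        sites.sort()
        return sites


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for tx in self.transcripts:
            if tx.gene_id != self.gene_id:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {tx.transcript_id} "
                    f"belongs to {tx.gene_id}"
                )
        strands = {tx.strand for tx in self.transcripts}
        if len(strands) > 1:
            raise ValidationError(f"gene {self.gene_id}: transcripts on mixed strands")

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    chroms = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chroms[rec.id] = str(rec.seq).upper()
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_CORE_ATTRS = ("gene_id", "transcript_id")


def _prevalidate_gtf(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] == "exon":
                for col, name in ((3, "start"), (4, "end")):
                    if not fields[col].isdigit():
                        raise GtfParseError(
                            f"{path}: line {lineno}: non-numeric {name} {fields[col]!r}"
                        )


def read_gtf(path) -> list[GeneModel]:
    """Parse GTF exon features into gene models, grouped by gene_id.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Attributes other than gene_id/transcript_id are preserved per transcript
    (last value wins if exon lines disagree).
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[Exon]] = {}
    meta: dict[str, tuple[str, str, dict[str, str]]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: exon at {feat.seqid}:{feat.start} missing {exc} attribute"
            ) from None
        exon = Exon(feat.seqid, feat.start - 1, feat.end, feat.strand)
        exons_by_tx.setdefault(tx_id, []).append(exon)
        extra = {
            k: v[0] for k, v in feat.attributes.items() if k not in _CORE_ATTRS
        }
        if tx_id in meta and meta[tx_id][0] != gene_id:
            raise ValidationError(
                f"transcript {tx_id} assigned to genes {meta[tx_id][0]} and {gene_id}"
            )
        meta[tx_id] = (gene_id, feat.strand, {**meta.get(tx_id, ("", "", {}))[2], **extra})

    genes: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in exons_by_tx.items():
        gene_id, strand, extra = meta[tx_id]
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise ValidationError(f"transcript {tx_id} has exons on mixed strands")
        tx = TranscriptModel(tx_id, gene_id, strand, exons, extra)
        genes.setdefault(gene_id, []).append(tx)
    return [GeneModel(gid, txs) for gid, txs in genes.items()]


def _fmt_attributes(tx: TranscriptModel) -> str:
    pairs = [("gene_id", tx.gene_id), ("transcript_id", tx.transcript_id)]
    pairs += sorted(tx.attributes.items())
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(genes: list[GeneModel], path, source: str = "isoswitch") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                attrs = _fmt_attributes(tx)
                for exon in tx.exons:
                    fh.write(
                        f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature mRNA sequence of a transcript, in transcript sense (DNA alphabet)."""
    parts = [genome.fetch(e.chrom, e.start, e.end) for e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


def intron_set(tx: TranscriptModel) -> list[SpliceJunction]:
    """Splice junctions of a transcript, ordered 5'->3' in transcript sense."""
    gaps = [
        (a.end, b.start) for a, b in zip(tx.exons, tx.exons[1:])
    ]
    if tx.strand == "+":
        return [SpliceJunction(tx.chrom, d, a, "+") for d, a in gaps]
    return [SpliceJunction(tx.chrom, b, a, "-") for a, b in reversed(gaps)]
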