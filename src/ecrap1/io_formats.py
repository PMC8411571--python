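"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates inside the package are 0-based half-open (BED convention).
GFF/GTF input, which is 1-based inclusive, is converted at the boundary and
converted back on write, so interval lengths are invariant under the
round-trip.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")

#: bases a strict genome may contain
GENOME_ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes other than N, optionally normalized to N on read
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span in 0-based half-open coordinates.

    The universal currency of the pipeline: candidate regions, ChIP-seq
    peaks, motif hits and gene spans are all carried as intervals.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully inside this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with optional exon structure.

    Gene *span* (not exon union) is what the size statistics use, since the
    biology of interest concerns regulatory elements in large introns.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for exon in self.exons:
            if not self.span.contains(exon):
                raise ValueError(
                    f"exon {exon.chrom}:{exon.start}-{exon.end} outside span of "
                    f"gene {self.gene_id}"
                )


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str] = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def fetch(self, interval: GenomicInterval) -> str:
        """Return the sequence under *interval*; out of bounds is an error,
        never silent truncation."""
        if interval.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


def _validate_genome_seq(name: str, seq: str, ambiguity_to_n: bool) -> str:
    seq = seq.upper()
    bad = set(seq) - GENOME_ALPHABET
    if bad & AMBIGUITY_CODES:
        if ambiguity_to_n:
            table = str.maketrans({c: "N" for c in AMBIGUITY_CODES})
            seq = seq.translate(table)
            bad = set(seq) - GENOME_ALPHABET
        else:
            raise ValueError(
                f"sequence {name!r} contains ambiguity codes "
                f"{sorted(bad & AMBIGUITY_CODES)}; pass ambiguity_to_n=True "
                "to map them to N"
            )
    if bad:
        raise ValueError(f"sequence {name!r} contains invalid characters {sorted(bad)}")
    return seq


def read_fasta(path: str | os.PathLike, ambiguity_to_n: bool = False) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased. Characters outside {A,C,G,T,N} are rejected
    unless ``ambiguity_to_n`` maps IUPAC ambiguity codes to N. Duplicate
    record names and empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        sequences[record.id] = _validate_genome_seq(
            record.id, str(record.seq), ambiguity_to_n
        )
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# BED is parsed by hand so that malformed lines can be reported with their
# line number, which the loaders of higher-level range libraries do not do.
def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED4+ into (interval, name) pairs, order preserved.

    Missing names become ``region_<index>`` (0-based) so downstream joins
    stay deterministic.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate in {line!r}"
                ) from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            name = fields[3] if len(fields) >= 4 and fields[3] else f"region_{len(out)}"
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for interval, name in records:
            fh.write(f"{interval.chrom}\t{interval.start}\t{interval.end}\t{name}\n")


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3/GTF, converting to 0-based half-open.

    Features of type ``gene`` become spans; ``exon`` children (via Parent /
    transcript nesting) are attached. An exon outside its gene span is an
    error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        span = GenomicInterval(
            gene.seqid,
            gene.start - 1,
            gene.end,
            gene.strand if gene.strand in "+-" else ".",
        )
        exons = tuple(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end)
            for ex in db.children(gene.id, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(gene_id=gene.id, span=span, exons=exons))
    return genes


def write_gff_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            s = gene.span
            fh.write(
                f"{s.chrom}\tecrap1\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand if s.strand != '.' else '.'}\t.\tID={gene.gene_id}\n"
            )
            for i, ex in enumerate(gene.exons):
                fh.write(
                    f"{ex.chrom}\tecrap1\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{s.strand if s.strand != '.' else '.'}\t.\t"
                    f"ID={gene.gene_id}.e{i};Parent={gene.gene_id}\n"
                )


def _record_to_dict(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    return dict(record)


def write_tsv_report(records: Sequence, path: str | os.PathLike,
                     columns: Sequence[str] | None = None,
                     header_comments: Sequence[str] = ()) -> None:
    """Write records (dicts or flat dataclasses) as a TSV with a header row.

    Column order is taken from the first record (or ``columns``) and the
    output is byte-identical for identical input. An empty record list still
    produces the header row when ``columns`` is given.
    """
    dicts = [_record_to_dict(r) for r in records]
    if columns is None:
        if not dicts:
            raise ValueError("cannot infer columns from an empty record list")
        columns = list(dicts[0])
    for i, d in enumerate(dicts):
        if list(d) != list(columns) and set(d) != set(columns):
            raise ValueError(f"record {i} does not share the report schema")
    frame = pd.DataFrame(dicts, columns=list(columns))
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
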