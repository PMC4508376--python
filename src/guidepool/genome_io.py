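"""Input/output for the standard genomic formats the pipeline touches.

All coordinates inside the package are 0-based half-open. GFF3 (1-based
closed) is converted on read; BED (0-based half-open) is emitted unchanged.
Sequences are uppercased on load and any residue outside {A, C, G, T, N} is
masked to N with a logged warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A genome as a mapping of contig name to uppercase DNA string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand.

        On '-' the reverse complement of the forward-strand slice is
        returned, read 5'->3' on the minus strand.
        """
        seq = self.contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) outside contig {contig} (len {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])


@dataclass
class TranscriptModel:
    """A transcript's CDS as ordered genomic intervals.

    cds_intervals are 0-based half-open, sorted by start, non-overlapping.
    Spliced CDS position 0 is the first base of the start codon: the
    leftmost base of the first interval on '+', the rightmost base of the
    last interval on '-'.
    """

    transcript_id: str
    gene_id: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"empty CDS interval [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("CDS intervals overlap or are unsorted")
            prev_end = end
        if self.cds_length == 0:
            raise ValueError(f"transcript {self.transcript_id} has no CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def contains(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.cds_intervals)

    def spliced_index(self, position: int) -> int:
        """0-based index of a genomic position within the spliced CDS.

        Strand-aware: index 0 is the first translated base.
        Raises ValueError if the position is not in the CDS.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= position < e:
                    return offset + (position - s)
                offset += e - s
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= position < e:
                    return offset + (e - 1 - position)
                offset += e - s
        raise ValueError(
            f"position {position} not in CDS of {self.transcript_id}"
        )


@dataclass
class GeneSet:
    """Genes mapped to their CDS-bearing transcripts, with contig and strand."""

    genes: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    contig_of: dict[str, str] = field(default_factory=dict)
    strand_of: dict[str, str] = field(default_factory=dict)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class BedRecord:
    contig: str
    start: int
    end: int
    name: str
    score: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid BED interval [{self.start},{self.end})")


def read_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load a (multi-)FASTA genome.

    Residues are uppercased; characters outside ACGTN are replaced by N
    with a warning. Duplicate contig names and empty files are errors.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        if set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            logger.warning(
                "contig %s: masking %d non-ACGTN characters (%s) to N",
                record.id,
                sum(seq.count(c) for c in bad),
                ",".join(bad),
            )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def read_annotation(path: str | os.PathLike, genome: GenomeSequence) -> GeneSet:
    """Load gene models (gene/mRNA/CDS linked by ID/Parent) from GFF3.

    GFF 1-based closed coordinates are converted to 0-based half-open.
    Transcripts without CDS are dropped with a warning; genes whose
    transcripts sit on mixed strands are dropped with a warning. A CDS
    referencing an unknown transcript, or one outside its contig, is an
    error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcript_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        for parent in cds.attributes.get("Parent", []):
            if parent not in transcript_ids:
                raise ValueError(
                    f"CDS at {cds.seqid}:{cds.start}-{cds.end} references "
                    f"unknown transcript {parent!r}"
                )

    geneset = GeneSet()
    for gene in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        strands = set()
        for mrna in db.children(gene, featuretype="mRNA"):
            intervals: list[tuple[int, int]] = []
            for cds in db.children(mrna, featuretype="CDS"):
                start, end = cds.start - 1, cds.end  # GFF3 -> half-open
                if cds.seqid not in genome or end > genome.length(cds.seqid):
                    raise ValueError(
                        f"CDS {cds.seqid}:{start}-{end} outside contig bounds"
                    )
                intervals.append((start, end))
            if not intervals:
                logger.warning(
                    "transcript %s has no CDS features; dropped", mrna.id
                )
                continue
            intervals.sort()
            strands.add(mrna.strand)
            transcripts.append(
                TranscriptModel(mrna.id, gene.id, mrna.strand, intervals)
            )
        if not transcripts:
            logger.warning("gene %s has no CDS-bearing transcripts; dropped", gene.id)
            continue
        if len(strands) > 1:
            logger.warning("gene %s has transcripts on mixed strands; dropped", gene.id)
            continue
        geneset.genes[gene.id] = transcripts
        geneset.contig_of[gene.id] = gene.seqid
        geneset.strand_of[gene.id] = strands.pop()
    return geneset


def write_bed(records: list[BedRecord], path: str | os.PathLike) -> None:
    """Write 6-column tab-separated BED."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n"
            )


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    """Parse a BED6 file written by :func:`write_bed`."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end, name, score, strand = line.split("\t")[:6]
            records.append(
                BedRecord(contig, int(start), int(end), name, int(score), strand)
            )
    return records
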