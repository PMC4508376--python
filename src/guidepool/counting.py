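"""Demultiplexing and guide counting for pooled-screen amplicon reads.

Each read carries a variable-length (0-9 nt) 5' barcode before a constant
anchor, then the 20-nt guide spacer, then a second constant anchor; a fixed
6-nt barcode sits on the mate (paired mode) or after the 3' anchor (single
end). The two barcodes jointly identify the sample; the spacer is matched
exactly against the library's expressed (G-substituted) spacers.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SPACER_LEN = 20
MAX_BC1_LEN = 9
BC2_LEN = 6

NO_ANCHOR = "NO_ANCHOR"
UNASSIGNED = "UNASSIGNED"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class BarcodeSpec:
    """One sample's barcode pair: variable 0-9 nt bc1 + fixed 6 nt bc2."""

    sample_id: str
    bc1: str
    bc2: str

    def __post_init__(self) -> None:
        if not 0 <= len(self.bc1) <= MAX_BC1_LEN:
            raise ValueError(f"bc1 length {len(self.bc1)} outside [0,{MAX_BC1_LEN}]")
        if len(self.bc2) != BC2_LEN:
            raise ValueError(f"bc2 must be {BC2_LEN} nt, got {len(self.bc2)}")


@dataclass(frozen=True)
class ReadLayout:
    """Constant amplicon structure around the spacer."""

    anchor5: str
    anchor3: str
    spacer_len: int = SPACER_LEN

    def __post_init__(self) -> None:
        for name, anchor in (("anchor5", self.anchor5), ("anchor3", self.anchor3)):
            if not anchor or set(anchor) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty ACGT")


@dataclass
class CountMatrix:
    """Integer guide x sample counts plus read-fate tallies.

    The conservation identity assigned + unassigned + ambiguous + no_anchor
    == total input reads holds for every run.
    """

    counts: pd.DataFrame  # guides x samples, int
    unassigned_reads: int = 0
    ambiguous_reads: int = 0
    no_anchor_reads: int = 0
    total_reads: int = 0
    guide_to_gene: dict[str, str] = field(default_factory=dict)

    @property
    def assigned_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def check_conservation(self) -> None:
        acc = (
            self.assigned_reads
            + self.unassigned_reads
            + self.ambiguous_reads
            + self.no_anchor_reads
        )
        if acc != self.total_reads:
            raise AssertionError(
                f"read conservation violated: {acc} != {self.total_reads}"
            )


def parse_samplesheet(path) -> list[BarcodeSpec]:
    """Read a TSV sample sheet with columns sample_id, bc1, bc2.

    bc1 may be empty (0-nt insertion). Duplicate (bc1, bc2) pairs are an
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "bc1", "bc2"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    specs = [
        BarcodeSpec(row.sample_id, row.bc1, row.bc2) for row in df.itertuples()
    ]
    pairs = [(s.bc1, s.bc2) for s in specs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (bc1, bc2) pair in sample sheet")
    return specs


def _matches(a: str, b: str, max_mismatches: int) -> bool:
    if len(a) != len(b):
        return False
    if max_mismatches == 0:
        return a == b
    return sum(x != y for x, y in zip(a, b)) <= max_mismatches


def demultiplex_read(
    read1: str,
    read2: str | None,
    specs: dict[tuple[str, str], str],
    layout: ReadLayout,
    anchor_mismatches: int = 0,
    bc2_revcomp: bool = False,
) -> tuple[str, str | None]:
    """Resolve one read (pair) to (sample_id | UNASSIGNED | NO_ANCHOR, spacer).

    anchor5 is sought at offsets 0..9 of read1 (smallest offset wins); the
    prefix before it is bc1 and the spacer_len bases after it the spacer.
    bc2 is the first 6 nt of read2, or in single-end mode the 6 nt after
    anchor3 on read1.
    """
    a5 = layout.anchor5
    for off in range(MAX_BC1_LEN + 1):
        end_spacer = off + len(a5) + layout.spacer_len
        if end_spacer > len(read1):
            break
        if _matches(read1[off : off + len(a5)], a5, anchor_mismatches):
            bc1 = read1[:off]
            spacer = read1[off + len(a5) : end_spacer]
            if read2 is not None:
                if len(read2) < BC2_LEN:
                    return NO_ANCHOR, None
                bc2 = read2[:BC2_LEN]
            else:
                a3_start = end_spacer
                a3_end = a3_start + len(layout.anchor3)
                if a3_end + BC2_LEN > len(read1) or not _matches(
                    read1[a3_start:a3_end], layout.anchor3, anchor_mismatches
                ):
                    return NO_ANCHOR, None
                bc2 = read1[a3_end : a3_end + BC2_LEN]
            if bc2_revcomp:
                bc2 = bc2.translate(_COMPLEMENT)[::-1]
            sample = specs.get((bc1, bc2))
            return (sample, spacer) if sample else (UNASSIGNED, spacer)
    return NO_ANCHOR, None


def _open_fastq(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_screen(
    fastq1,
    samplesheet: list[BarcodeSpec],
    library: pd.DataFrame,
    layout: ReadLayout,
    fastq2=None,
    anchor_mismatches: int = 0,
    bc2_revcomp: bool = False,
) -> CountMatrix:
    """Count exact expressed-spacer matches per guide and sample.

    Spacers matching no library entry count as unassigned; spacers matching
    two or more entries (a post-G-substitution collision) count as ambiguous
    and are assigned to no guide.
    """
    spacer_to_guides: dict[str, list[str]] = {}
    for row in library.itertuples():
        spacer_to_guides.setdefault(row.expressed_spacer, []).append(row.guide_id)
    spec_lookup = {(s.bc1, s.bc2): s.sample_id for s in samplesheet}
    samples = [s.sample_id for s in samplesheet]
    counts = {
        sample: dict.fromkeys(library["guide_id"], 0) for sample in samples
    }
    unassigned = ambiguous = no_anchor = total = 0

    with _open_fastq(fastq1) as fh1:
        reads1 = SeqIO.parse(fh1, "fastq")
        if fastq2 is not None:
            fh2 = _open_fastq(fastq2)
            reads2 = SeqIO.parse(fh2, "fastq")
        else:
            fh2 = reads2 = None
        try:
            while True:
                try:
                    r1 = next(reads1)
                except StopIteration:
                    if reads2 is not None:
                        try:
                            next(reads2)
                        except StopIteration:
                            pass
                        else:
                            raise ValueError("R2 has more reads than R1")
                    break
                if reads2 is not None:
                    try:
                        r2 = next(reads2)
                    except StopIteration:
                        raise ValueError("R1 has more reads than R2") from None
                    read2 = str(r2.seq).upper()
                else:
                    read2 = None
                total += 1
                fate, spacer = demultiplex_read(
                    str(r1.seq).upper(), read2, spec_lookup, layout,
                    anchor_mismatches, bc2_revcomp,
                )
                if fate == NO_ANCHOR:
                    no_anchor += 1
                elif fate == UNASSIGNED:
                    unassigned += 1
                else:
                    guides = spacer_to_guides.get(spacer, [])
                    if not guides:
                        unassigned += 1
                    elif len(guides) > 1:
                        ambiguous += 1
                    else:
                        counts[fate][guides[0]] += 1
        finally:
            if fh2 is not None:
                fh2.close()

    df = pd.DataFrame(counts, columns=samples).astype(int)
    df.index.name = "guide_id"
    matrix = CountMatrix(
        counts=df,
        unassigned_reads=unassigned,
        ambiguous_reads=ambiguous,
        no_anchor_reads=no_anchor,
        total_reads=total,
        guide_to_gene=dict(zip(library["guide_id"], library["gene_id"])),
    )
    matrix.check_conservation()
    return matrix


def write_counts(matrix: CountMatrix, path) -> None:
    """Counts TSV: guide_id, gene_id, one column per sample, then summary
    rows for unassigned/ambiguous/no_anchor reads."""
    df = matrix.counts.copy()
    df.insert(0, "gene_id", [matrix.guide_to_gene.get(g, "") for g in df.index])
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t")
        samples = list(matrix.counts.columns)
        for label, value in (
            ("__unassigned__", matrix.unassigned_reads),
            ("__ambiguous__", matrix.ambiguous_reads),
            ("__no_anchor__", matrix.no_anchor_reads),
        ):
            fh.write("\t".join([label, ""] + [str(value)] + [""] * (len(samples) - 1)) + "\n")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV written by :func:`write_counts`.

    Returns (guide x sample counts with a gene_id column, summary tallies).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    summary_mask = df.index.str.startswith("__")
    summary = df.loc[summary_mask].iloc[:, 1].astype(int)
    summary.index = summary.index.str.strip("_")
    body = df.loc[~summary_mask].copy()
    for col in body.columns[1:]:
        body[col] = body[col].astype(int)
    return body, summary
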