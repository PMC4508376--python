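"""Guide enumeration, off-target elimination and library assembly.

Candidates are 20-nt protospacers followed by an NGG PAM, enumerated on both
strands within the shared CDS regions of each gene. Candidates with any
genomic near-match — an N20-(NGG|NAG) site within 3 mismatches of the
protospacer, other than the candidate's own locus — are discarded, and up to
five guides with pairwise non-overlapping protospacers are selected per gene
in order of position within the coding sequence. For synthesis, the first
protospacer base is replaced by G (efficient Pol III initiation) and common
adaptors are appended.

The off-target search uses a pigeonhole seed index: each genomic site's
20-mer is split into four disjoint 5-nt blocks; a match with <= 3 mismatches
must leave at least one block exact, so exact-block lookups followed by full
Hamming verification find every hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    BedRecord,
    GeneSet,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)
from .regions import SharedRegion, shared_regions

logger = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN
_N_BLOCKS = 4
_BLOCK_LEN = SPACER_LEN // _N_BLOCKS


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer with an NGG PAM at a genomic locus.

    start is the 5'-most genomic base of the protospacer on the forward
    strand; protospacer and pam are read 5'->3' in guide orientation.
    """

    gene_id: str
    contig: str
    start: int
    strand: str
    protospacer: str
    pam: str
    cds_offset: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != SPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if "N" in self.protospacer:
            raise ValueError("protospacer contains N")

    @property
    def end(self) -> int:
        return self.start + SPACER_LEN


@dataclass(frozen=True)
class OffTargetHit:
    contig: str
    start: int
    strand: str
    pam_class: str  # "NGG" or "NAG"
    mismatches: int


@dataclass
class LibraryRecord:
    """A selected guide with its G-substituted expressed spacer and oligo."""

    guide_id: str
    candidate: GuideCandidate
    expressed_spacer: str
    oligo: str


class SiteIndex:
    """Every genomic N20-(NGG|NAG) site on both strands, queryable for
    near-matches by pigeonhole seed lookup.

    Sites whose 20-mer contains N are excluded. Each site is keyed by
    (contig, protospacer start on the forward strand, strand, PAM class).
    """

    def __init__(self) -> None:
        self.spacers: list[str] = []
        self.meta: list[tuple[str, int, str, str]] = []
        self._blocks: list[dict[str, list[int]]] = [{} for _ in range(_N_BLOCKS)]
        self._by_locus: dict[tuple[str, int, str], list[int]] = {}

    def add(self, contig: str, start: int, strand: str, pam_class: str, spacer: str) -> None:
        idx = len(self.spacers)
        self.spacers.append(spacer)
        self.meta.append((contig, start, strand, pam_class))
        for b in range(_N_BLOCKS):
            key = spacer[b * _BLOCK_LEN : (b + 1) * _BLOCK_LEN]
            self._blocks[b].setdefault(key, []).append(idx)
        self._by_locus.setdefault((contig, start, strand), []).append(idx)

    def __len__(self) -> int:
        return len(self.spacers)

    def has_locus(self, contig: str, start: int, strand: str) -> bool:
        return (contig, start, strand) in self._by_locus

    def query(self, spacer: str, max_mismatches: int) -> list[OffTargetHit]:
        """All sites within max_mismatches Hamming distance of spacer
        (PAM not counted), sorted by (mismatches, contig, start)."""
        if len(spacer) != SPACER_LEN:
            raise ValueError("query spacer must be 20 nt")
        seen: set[int] = set()
        for b in range(_N_BLOCKS):
            key = spacer[b * _BLOCK_LEN : (b + 1) * _BLOCK_LEN]
            seen.update(self._blocks[b].get(key, ()))
        hits = []
        for idx in seen:
            mm = count_mismatches(spacer, self.spacers[idx])
            if mm <= max_mismatches:
                contig, start, strand, pam_class = self.meta[idx]
                hits.append(OffTargetHit(contig, start, strand, pam_class, mm))
        hits.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
        return hits


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between two equal-length spacers."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _forward_pam_class(pam: str) -> str | None:
    tail = pam[1:3]
    if tail == "GG":
        return "NGG"
    if tail == "AG":
        return "NAG"
    return None


def build_site_index(genome: GenomeSequence, include_nag: bool = True) -> SiteIndex:
    """Enumerate all N20-NGG (and optionally NAG) sites on both strands."""
    index = SiteIndex()
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(seq)
        if n < SITE_LEN:
            continue
        G, A, C, T = (ord(c) for c in "GACT")
        # forward: protospacer [p, p+20), PAM [p+20, p+23)
        fwd_gg = (arr[SPACER_LEN + 1 : n - 1] == G) & (arr[SPACER_LEN + 2 :] == G)
        fwd_ag = (arr[SPACER_LEN + 1 : n - 1] == A) & (arr[SPACER_LEN + 2 :] == G)
        fwd = fwd_gg | fwd_ag if include_nag else fwd_gg
        for p in np.flatnonzero(fwd):
            spacer = seq[p : p + SPACER_LEN]
            if "N" in spacer:
                continue
            pam_class = "NGG" if fwd_gg[p] else "NAG"
            index.add(contig, int(p), "+", pam_class, spacer)
        # reverse: PAM [q, q+3), protospacer [q+3, q+23); on the minus
        # strand PAM NGG reads CCN on the forward strand, NAG reads CTN
        rev_gg = (arr[: n - SITE_LEN + 1] == C) & (arr[1 : n - SITE_LEN + 2] == C)
        rev_ag = (arr[: n - SITE_LEN + 1] == C) & (arr[1 : n - SITE_LEN + 2] == T)
        rev = rev_gg | rev_ag if include_nag else rev_gg
        for q in np.flatnonzero(rev):
            spacer_fwd = seq[q + PAM_LEN : q + SITE_LEN]
            if "N" in spacer_fwd:
                continue
            pam_class = "NGG" if rev_gg[q] else "NAG"
            index.add(
                contig, int(q) + PAM_LEN, "-", pam_class,
                reverse_complement(spacer_fwd),
            )
    return index


def enumerate_candidates(
    region: SharedRegion,
    genome: GenomeSequence,
    transcripts: list[TranscriptModel],
) -> list[GuideCandidate]:
    """All N20-NGG windows (both strands) whose protospacer overlaps the
    region by >= 1 base. Windows containing N are skipped.

    The cds_offset is that of the guide's 5'-most protospacer base lying in
    at least one isoform's CDS, scanning from the guide's 5' end.
    """
    seq = genome.contigs[region.contig]
    n = len(seq)
    if not (0 <= region.start < region.end <= n):
        raise ValueError("region outside contig")
    candidates = []
    lo = max(0, region.start - SPACER_LEN + 1)
    hi = min(region.end, n - SPACER_LEN + 1)  # protospacer start range
    for p in range(lo, hi):
        # forward: PAM at [p+20, p+23)
        if p + SITE_LEN <= n:
            pam = seq[p + SPACER_LEN : p + SITE_LEN]
            if pam[1:3] == "GG":
                spacer = seq[p : p + SPACER_LEN]
                if "N" not in spacer and "N" not in pam:
                    off = _guide_cds_offset(p, "+", transcripts)
                    if off is not None:
                        candidates.append(
                            GuideCandidate(
                                region.gene_id, region.contig, p, "+", spacer, pam, off
                            )
                        )
        # reverse: PAM at [p-3, p), protospacer [p, p+20)
        if p >= PAM_LEN:
            pam_fwd = seq[p - PAM_LEN : p]
            if pam_fwd[0:2] == "CC":
                spacer = reverse_complement(seq[p : p + SPACER_LEN])
                pam = reverse_complement(pam_fwd)
                if "N" not in spacer and "N" not in pam:
                    off = _guide_cds_offset(p, "-", transcripts)
                    if off is not None:
                        candidates.append(
                            GuideCandidate(
                                region.gene_id, region.contig, p, "-", spacer, pam, off
                            )
                        )
    return candidates


def _guide_cds_offset(
    start: int, strand: str, transcripts: list[TranscriptModel]
) -> int | None:
    """cds_offset of the 5'-most in-CDS protospacer base in guide orientation."""
    positions = (
        range(start, start + SPACER_LEN)
        if strand == "+"
        else range(start + SPACER_LEN - 1, start - 1, -1)
    )
    for pos in positions:
        indices = [t.spliced_index(pos) for t in transcripts if t.contains(pos)]
        if indices:
            return min(indices)
    return None


def find_offtargets(
    candidate: GuideCandidate, index: SiteIndex, max_mismatches: int = 3
) -> list[OffTargetHit]:
    """All indexed sites within max_mismatches of the candidate's
    protospacer, excluding the candidate's own locus."""
    if not index.has_locus(candidate.contig, candidate.start, candidate.strand):
        raise ValueError(
            f"candidate locus {candidate.contig}:{candidate.start}{candidate.strand} "
            "absent from index (index built from a different genome?)"
        )
    hits = index.query(candidate.protospacer, max_mismatches)
    return [
        h
        for h in hits
        if (h.contig, h.start, h.strand)
        != (candidate.contig, candidate.start, candidate.strand)
    ]


def offtargets_bruteforce(
    candidate: GuideCandidate,
    genome: GenomeSequence,
    max_mismatches: int = 3,
    include_nag: bool = True,
) -> list[OffTargetHit]:
    """Exhaustive sliding-window off-target scan (test oracle).

    Checks every genomic N20-(NGG|NAG) site on both strands by direct
    Hamming distance, independent of the seed index.
    """
    q = np.frombuffer(candidate.protospacer.encode(), dtype=np.uint8)
    rc_q = np.frombuffer(
        reverse_complement(candidate.protospacer).encode(), dtype=np.uint8
    )
    N = ord("N")
    G, A, C, T = (ord(c) for c in "GACT")
    hits = []
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        n = len(seq)
        if n < SITE_LEN:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, SPACER_LEN)
        has_n = (windows == N).any(axis=1)
        # forward sites: spacer starts at p, PAM tail at p+21, p+22
        mm_fwd = (windows != q).sum(axis=1)
        fwd_gg = (arr[SPACER_LEN + 1 : n - 1] == G) & (arr[SPACER_LEN + 2 :] == G)
        fwd_ag = (arr[SPACER_LEN + 1 : n - 1] == A) & (arr[SPACER_LEN + 2 :] == G)
        for p in np.flatnonzero(
            (mm_fwd[: n - SITE_LEN + 1] <= max_mismatches)
            & ~has_n[: n - SITE_LEN + 1]
            & (fwd_gg | (fwd_ag if include_nag else False))
        ):
            pam_class = "NGG" if fwd_gg[p] else "NAG"
            hits.append(
                OffTargetHit(contig, int(p), "+", pam_class, int(mm_fwd[p]))
            )
        # reverse sites: forward-strand spacer window at s = q+3 must match
        # revcomp(query); PAM reads CC/CT at q, q+1 on the forward strand
        mm_rev = (windows != rc_q).sum(axis=1)
        rev_gg = (arr[: n - SITE_LEN + 1] == C) & (arr[1 : n - SITE_LEN + 2] == C)
        rev_ag = (arr[: n - SITE_LEN + 1] == C) & (arr[1 : n - SITE_LEN + 2] == T)
        spacer_start = np.arange(n - SITE_LEN + 1) + PAM_LEN
        ok = (
            (mm_rev[spacer_start] <= max_mismatches)
            & ~has_n[spacer_start]
            & (rev_gg | (rev_ag if include_nag else False))
        )
        for qpos in np.flatnonzero(ok):
            pam_class = "NGG" if rev_gg[qpos] else "NAG"
            hits.append(
                OffTargetHit(
                    contig, int(qpos) + PAM_LEN, "-", pam_class,
                    int(mm_rev[qpos + PAM_LEN]),
                )
            )
    hits = [
        h
        for h in hits
        if (h.contig, h.start, h.strand)
        != (candidate.contig, candidate.start, candidate.strand)
    ]
    hits.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
    return hits


def filter_unique(
    candidates: list[GuideCandidate], index: SiteIndex, max_mismatches: int = 3
) -> list[GuideCandidate]:
    """Keep only candidates with no off-target site within max_mismatches."""
    return [
        c for c in candidates if not find_offtargets(c, index, max_mismatches)
    ]


def select_guides(
    candidates: list[GuideCandidate], n: int = 5
) -> list[GuideCandidate]:
    """Greedy selection of up to n guides with pairwise disjoint protospacer
    intervals, in ascending cds_offset order.

    Ties in cds_offset break by (contig, start), then '+' before '-'.
    """
    ranked = sorted(
        set(candidates),
        key=lambda c: (c.cds_offset, c.contig, c.start, c.strand != "+"),
    )
    chosen: list[GuideCandidate] = []
    for c in ranked:
        if len(chosen) == n:
            break
        if all(c.end <= s.start or s.end <= c.start for s in chosen):
            chosen.append(c)
    return chosen


def assemble_oligo(
    candidate: GuideCandidate,
    guide_id: str,
    adaptor5: str = "",
    adaptor3: str = "",
) -> LibraryRecord:
    """Build the synthesis oligo: adaptor5 + G-substituted spacer + adaptor3.

    The first protospacer base is replaced by G so that transcription from a
    Pol III (U6-type) promoter initiates efficiently.
    """
    for name, adaptor in (("adaptor5", adaptor5), ("adaptor3", adaptor3)):
        if set(adaptor) - set("ACGT"):
            raise ValueError(f"{name} contains non-ACGT characters")
    expressed = "G" + candidate.protospacer[1:]
    return LibraryRecord(
        guide_id, candidate, expressed, adaptor5 + expressed + adaptor3
    )


@dataclass
class DesignReport:
    """Per-gene design outcome tallies."""

    per_gene: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes_without_designs(self) -> list[str]:
        return sorted(self.per_gene.index[self.per_gene["n_selected"] == 0])


def design_library(
    genome: GenomeSequence,
    genes: GeneSet,
    n_per_gene: int = 5,
    max_mismatches: int = 3,
    adaptor5: str = "",
    adaptor3: str = "",
    include_nag: bool = True,
) -> tuple[list[LibraryRecord], list[BedRecord], DesignReport]:
    """Full design pipeline: shared regions -> candidate enumeration ->
    off-target elimination -> per-gene selection -> oligo assembly.

    Per-gene failures are recorded in the report without aborting the run.
    """
    index = build_site_index(genome, include_nag=include_nag)
    records: list[LibraryRecord] = []
    bed: list[BedRecord] = []
    rows = []
    for gene_id in genes.gene_ids():
        transcripts = genes.genes[gene_id]
        contig = genes.contig_of[gene_id]
        try:
            regs = shared_regions(gene_id, contig, transcripts)
            cands: list[GuideCandidate] = []
            for region in regs:
                cands.extend(enumerate_candidates(region, genome, transcripts))
            cands = sorted(
                set(cands),
                key=lambda c: (c.cds_offset, c.contig, c.start, c.strand != "+"),
            )
            unique = filter_unique(cands, index, max_mismatches)
            selected = select_guides(unique, n_per_gene)
        except Exception:
            logger.exception("design failed for gene %s; skipped", gene_id)
            rows.append((gene_id, 0, 0, 0))
            continue
        for i, cand in enumerate(selected, start=1):
            rec = assemble_oligo(cand, f"{gene_id}_sg{i}", adaptor5, adaptor3)
            records.append(rec)
            bed.append(
                BedRecord(cand.contig, cand.start, cand.end, rec.guide_id, 0, cand.strand)
            )
        rows.append((gene_id, len(cands), len(unique), len(selected)))
    report = DesignReport(
        pd.DataFrame(
            rows, columns=["gene_id", "n_candidates", "n_unique", "n_selected"]
        ).set_index("gene_id")
    )
    return records, bed, report


LIBRARY_COLUMNS = [
    "guide_id", "gene_id", "contig", "start", "end", "strand",
    "protospacer", "pam", "expressed_spacer", "cds_offset", "oligo",
]


def library_table(records: list[LibraryRecord]) -> pd.DataFrame:
    """Flatten LibraryRecords into the library TSV layout."""
    rows = [
        {
            "guide_id": r.guide_id,
            "gene_id": r.candidate.gene_id,
            "contig": r.candidate.contig,
            "start": r.candidate.start,
            "end": r.candidate.end,
            "strand": r.candidate.strand,
            "protospacer": r.candidate.protospacer,
            "pam": r.candidate.pam,
            "expressed_spacer": r.expressed_spacer,
            "cds_offset": r.candidate.cds_offset,
            "oligo": r.oligo,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(records: list[LibraryRecord], path) -> None:
    library_table(records).to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "gene_id": str})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    return df


def write_oligo_fasta(records: list[LibraryRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.guide_id}\n{r.oligo}\n")
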