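"""Shared exonic (CDS) regions across transcript isoforms.

Mutating a base shared by many isoforms of a gene disrupts all of them at
once, so guides are designed inside the CDS segments covered by the maximal
number of the gene's isoforms, and ranked by how early in the spliced coding
sequence they fall (early frameshifts are the most disruptive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class SharedRegion:
    """A maximal run of CDS positions covered by the gene's peak isoform count.

    cds_offset is the minimum spliced-CDS index, over supporting isoforms, of
    the region's translation-start-proximal base.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    support: int
    cds_offset: int


def cds_coverage(
    transcripts: list[TranscriptModel],
) -> list[tuple[int, int, int]]:
    """Per-base isoform coverage over the union of CDS intervals.

    Returns disjoint segments (start, end, coverage) with coverage >= 1,
    sorted by start, computed by a boundary sweep.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    events: dict[int, int] = {}
    for t in transcripts:
        for s, e in t.cds_intervals:
            events[s] = events.get(s, 0) + 1
            events[e] = events.get(e, 0) - 1
    segments = []
    depth = 0
    prev = None
    for pos in sorted(events):
        if prev is not None and depth > 0 and pos > prev:
            segments.append((prev, pos, depth))
        depth += events[pos]
        prev = pos
    return segments


def cds_offset(position: int, transcripts: list[TranscriptModel]) -> int:
    """Earliest spliced-CDS index of a genomic position over the isoforms
    containing it (index 0 = first base of the start codon).

    Raises ValueError if no isoform's CDS contains the position.
    """
    indices = [
        t.spliced_index(position) for t in transcripts if t.contains(position)
    ]
    if not indices:
        raise ValueError(f"position {position} is in no isoform's CDS")
    return min(indices)


def shared_regions(
    gene_id: str, contig: str, transcripts: list[TranscriptModel]
) -> list[SharedRegion]:
    """Maximal runs of positions whose isoform coverage equals the gene-wide
    maximum, ordered by cds_offset ascending.

    A gene with no CDS yields an empty list with a warning.
    """
    if not transcripts:
        logger.warning("gene %s has zero CDS; no shared regions", gene_id)
        return []
    segments = cds_coverage(transcripts)
    max_cov = max(cov for _, _, cov in segments)
    # merge adjacent max-coverage segments into maximal runs
    runs: list[tuple[int, int]] = []
    for s, e, cov in segments:
        if cov != max_cov:
            continue
        if runs and runs[-1][1] == s:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))
    strand = transcripts[0].strand
    regions = []
    for s, e in runs:
        anchor = s if strand == "+" else e - 1  # translation-start-proximal base
        regions.append(
            SharedRegion(gene_id, contig, s, e, max_cov, cds_offset(anchor, transcripts))
        )
    regions.sort(key=lambda r: (r.cds_offset, r.start))
    return regions
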