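"""Synthetic test inputs: annotated genomes with controllable isoform
structure, planted off-target sites, and simulated barcoded screen reads
with a known truth table.

Everything is fully determined by the spec seeds; the genome generator also
returns the per-gene maximal-coverage CDS regions computed directly from
the constructed intervals, so downstream region extraction can be checked
against an independent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import BarcodeSpec, ReadLayout
from .genome_io import GenomeSequence

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN

_PAM_TAIL = {"NGG": "GG", "NAG": "AG"}


@dataclass
class GenomeSpec:
    """Parameters of a random annotated genome.

    Ranges are inclusive (lo, hi). Defaults give compact genes whose exons
    comfortably host many NGG windows.
    """

    n_genes: int = 10
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (1, 4)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (60, 120)
    intergenic_spacing: int = 200
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.isoforms_per_gene,
            self.exons_per_transcript,
            self.exon_length,
            self.intron_length,
        ):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive with lo <= hi")
        if self.n_genes < 1 or self.intergenic_spacing < 0:
            raise ValueError("infeasible genome spec")


@dataclass
class SyntheticGenome:
    fasta: str
    gff3: str
    genome: GenomeSequence
    # gene_id -> list of (start, end, support) maximal shared-coverage runs
    truth_regions: dict[str, list[tuple[int, int, int]]]
    gene_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def make_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Build a single-contig genome with the requested gene structure.

    Each gene gets a pool of exon slots; each isoform uses a random subset
    of them (always including the first and last used slots' natural
    order). The truth regions are maximal runs of positions covered by the
    gene's peak number of isoform CDSs, computed by an explicit per-base
    count over the constructed intervals.
    """
    rng = np.random.default_rng(spec.seed)
    contig = "chrS"
    cursor = spec.intergenic_spacing
    pieces: list[str] = [_random_dna(rng, cursor, spec.gc_fraction)]
    gff: list[str] = ["##gff-version 3"]
    truth: dict[str, list[tuple[int, int, int]]] = {}
    gene_intervals: dict[str, tuple[int, int]] = {}

    for g in range(spec.n_genes):
        gene_id = f"gene{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(spec.isoforms_per_gene[0], spec.isoforms_per_gene[1] + 1))
        max_exons = int(
            rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1)
        )
        # lay out the exon slot pool
        slots: list[tuple[int, int]] = []
        pos = cursor
        for _ in range(max_exons):
            elen = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            slots.append((pos, pos + elen))
            pos += elen + int(
                rng.integers(spec.intron_length[0], spec.intron_length[1] + 1)
            )
        transcripts: list[tuple[str, list[tuple[int, int]]]] = []
        for t in range(n_iso):
            k = int(
                rng.integers(
                    spec.exons_per_transcript[0],
                    min(spec.exons_per_transcript[1], max_exons) + 1,
                )
            )
            chosen = sorted(rng.choice(len(slots), size=min(k, len(slots)), replace=False))
            transcripts.append((f"{gene_id}.t{t + 1}", [slots[i] for i in chosen]))

        gene_start = min(iv[0][0] for _, iv in transcripts)
        gene_end = max(iv[-1][1] for _, iv in transcripts)
        gene_intervals[gene_id] = (gene_start, gene_end)
        gff.append(
            f"{contig}\tsynthetic\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tid, intervals in transcripts:
            gff.append(
                f"{contig}\tsynthetic\tmRNA\t{intervals[0][0] + 1}\t{intervals[-1][1]}"
                f"\t.\t{strand}\t.\tID={tid};Parent={gene_id}"
            )
            for s, e in intervals:
                gff.append(
                    f"{contig}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tParent={tid}"
                )

        # truth: explicit per-base count over the gene span
        span = gene_end - gene_start
        cov = np.zeros(span, dtype=int)
        for _, intervals in transcripts:
            for s, e in intervals:
                cov[s - gene_start : e - gene_start] += 1
        peak = int(cov.max())
        runs: list[tuple[int, int, int]] = []
        in_run = False
        for i in range(span + 1):
            at_peak = i < span and cov[i] == peak
            if at_peak and not in_run:
                run_start = i
                in_run = True
            elif not at_peak and in_run:
                runs.append((gene_start + run_start, gene_start + i, peak))
                in_run = False
        truth[gene_id] = runs

        pieces.append(_random_dna(rng, gene_end - cursor, spec.gc_fraction))
        cursor = gene_end
        pieces.append(_random_dna(rng, spec.intergenic_spacing, spec.gc_fraction))
        cursor += spec.intergenic_spacing

    seq = "".join(pieces)
    fasta = f">{contig}\n" + "\n".join(
        seq[i : i + 80] for i in range(0, len(seq), 80)
    ) + "\n"
    return SyntheticGenome(
        fasta=fasta,
        gff3="\n".join(gff) + "\n",
        genome=GenomeSequence({contig: seq}),
        truth_regions=truth,
        gene_intervals=gene_intervals,
    )


def plant_offtarget(
    genome: GenomeSequence,
    guide: str,
    mismatches: int,
    pam_class: str,
    contig: str,
    position: int,
    seed: int = 0,
    forbidden: list[tuple[int, int]] | None = None,
) -> GenomeSequence:
    """Return a genome carrying a forward-strand site at `position` whose
    20-mer sits at exactly `mismatches` Hamming distance from `guide`, with
    the requested PAM class.

    The caller is responsible for choosing a position free of pre-existing
    near-matches; collisions with `forbidden` intervals or the contig edge
    are errors.
    """
    if len(guide) != SPACER_LEN:
        raise ValueError("guide must be 20 nt")
    if not 0 <= mismatches <= 3:
        raise ValueError("mismatches must be 0-3")
    if pam_class not in _PAM_TAIL:
        raise ValueError(f"unknown PAM class {pam_class!r}")
    seq = genome.contigs[contig]
    if not (0 <= position and position + SITE_LEN <= len(seq)):
        raise ValueError("site would extend past the contig edge")
    for s, e in forbidden or []:
        if position < e and s < position + SITE_LEN:
            raise ValueError(f"position collides with interval [{s},{e})")
    rng = np.random.default_rng(seed)
    spacer = list(guide)
    for i in rng.choice(SPACER_LEN, size=mismatches, replace=False):
        spacer[i] = rng.choice([b for b in "ACGT" if b != spacer[i]])
    site = "".join(spacer) + rng.choice(list("ACGT")) + _PAM_TAIL[pam_class]
    mutated = seq[:position] + site + seq[position + SITE_LEN :]
    contigs = dict(genome.contigs)
    contigs[contig] = mutated
    return GenomeSequence(contigs)


@dataclass
class ScreenSpec:
    """Parameters of a simulated pooled screen readout.

    Guide abundance in a sample is baseline weight x the fold-change effect
    of the guide's gene in that sample; reads are drawn multinomially.
    """

    library: pd.DataFrame  # guide_id, gene_id, expressed_spacer
    samples: list[BarcodeSpec]
    layout: ReadLayout
    reads_per_sample: int = 1000
    baseline: dict[str, float] | None = None  # guide_id -> weight; None = uniform
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    read_length: int = 150
    paired: bool = True
    error_rate: float = 0.0
    seed: int = 0


@dataclass
class SimulatedScreen:
    r1_fastq: str
    r2_fastq: str | None
    truth: pd.DataFrame  # guide x sample drawn counts


def simulate_screen(spec: ScreenSpec) -> SimulatedScreen:
    """Draw per-guide read counts multinomially per sample and emit the
    corresponding barcoded amplicon FASTQ plus the exact truth table."""
    rng = np.random.default_rng(spec.seed)
    guides = list(spec.library["guide_id"])
    gene_of = dict(zip(spec.library["guide_id"], spec.library["gene_id"]))
    spacer_of = dict(zip(spec.library["guide_id"], spec.library["expressed_spacer"]))
    base = np.array(
        [1.0 if spec.baseline is None else spec.baseline.get(g, 0.0) for g in guides]
    )
    if (base < 0).any():
        raise ValueError("baseline weights must be >= 0")
    truth = pd.DataFrame(0, index=guides, columns=[s.sample_id for s in spec.samples])
    truth.index.name = "guide_id"
    reads: list[tuple[str, str, str | None]] = []  # (name, r1, r2)

    for sample in spec.samples:
        eff = spec.effects.get(sample.sample_id, {})
        w = base * np.array([eff.get(gene_of[g], 1.0) for g in guides])
        if w.sum() <= 0:
            raise ValueError(f"zero total weight for sample {sample.sample_id}")
        draws = rng.multinomial(spec.reads_per_sample, w / w.sum())
        truth[sample.sample_id] = draws
        for g, n in zip(guides, draws):
            for _ in range(n):
                core = (
                    sample.bc1 + spec.layout.anchor5 + spacer_of[g] + spec.layout.anchor3
                )
                if spec.paired:
                    r1 = core
                    r2 = sample.bc2
                else:
                    r1 = core + sample.bc2
                    r2 = None
                r1 = _pad(r1, spec.read_length, rng)
                if r2 is not None:
                    r2 = _pad(r2, spec.read_length, rng)
                if spec.error_rate > 0:
                    r1 = _mutate(r1, spec.error_rate, rng)
                    if r2 is not None:
                        r2 = _mutate(r2, spec.error_rate, rng)
                reads.append((f"{sample.sample_id}:{g}", r1, r2))

    rng.shuffle(reads)
    r1_out, r2_out = [], []
    for i, (name, r1, r2) in enumerate(reads):
        r1_out.append(f"@read{i}:{name}\n{r1}\n+\n{'I' * len(r1)}\n")
        if r2 is not None:
            r2_out.append(f"@read{i}:{name}\n{r2}\n+\n{'I' * len(r2)}\n")
    return SimulatedScreen(
        r1_fastq="".join(r1_out),
        r2_fastq="".join(r2_out) if spec.paired else None,
        truth=truth,
    )


def _pad(read: str, length: int, rng: np.random.Generator) -> str:
    if len(read) >= length:
        return read
    filler = "".join(rng.choice(list("ACGT"), size=length - len(read)))
    return read + filler


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(read)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)
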