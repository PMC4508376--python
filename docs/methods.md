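# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand. GFF3
(1-based closed) is converted on read; BED is emitted unchanged. Guide BED
intervals cover the 20-nt protospacer only, with the guide's strand in the
strand column — the PAM is excluded so the interval is the targeted
sequence itself. Soft-masked (lowercase) genome sequence is uppercased and
treated as ordinary sequence; residues outside ACGTN are masked to N with a
warning, and any candidate window containing N is skipped (an undefined
base can be neither synthesised nor matched).

## Shared-region extraction

A gene's CDS-bearing transcripts are swept jointly: interval boundaries
become +1/−1 events, and maximal runs of positions whose isoform coverage
equals the gene-wide maximum become the shared regions. "Maximum" rather
than "all isoforms" degrades gracefully: when no base is common to every
isoform, the regions are the best-covered runs instead of an empty set.
Non-coding transcripts are excluded throughout — only CDS-bearing isoforms
count toward coverage.

Positions are ranked by **CDS offset**: the 0-based index of the position
in the spliced coding sequence, minimised over the isoforms containing it.
The minimum is the conservative choice — it is the earliest point at which
a cut could disrupt some isoform's reading frame. For a guide, the offset
is taken at its 5′-most protospacer base in guide orientation; when that
base falls outside every isoform's CDS (possible because a protospacer
only has to overlap a shared region by one base), the first in-CDS base
scanning from the guide's 5′ end is used instead, keeping the rank defined
without discarding boundary-spanning candidates.

## Candidate enumeration and off-target elimination

On-target candidates require an NGG PAM; the off-target index contains
both NGG and NAG sites, because Cas9 tolerates NAG well enough for such
sites to matter as off-targets even though they are poor on-targets.
Mismatches are counted as Hamming distance over the 20-mer only; the PAM
must be an exact class member. The 3-mismatch radius reflects evidence
that sites beyond 3 mismatches are very unlikely to be cleaved in this
system. Off-targets are evaluated against the genomic protospacer, not the
G-substituted expressed spacer, because substitution happens at cloning,
after design.

The index partitions each site 20-mer into four disjoint 5-nt blocks
(pigeonhole-exact for ≤3 mismatches at length 20): block-exact lookup
yields a candidate set that is then verified by full Hamming distance. A
candidate's own locus — identified by exact (contig, start, strand) — is
excluded from its hit list; any other hit, including an exact duplicate of
the protospacer elsewhere, eliminates the candidate (and its duplicate,
symmetrically). An exhaustive numpy sliding-window scan
(`offtargets_bruteforce`) implements the same contract independently and
serves as the oracle in tests; the two are compared on random 10–50 kb
genomes for 0–3 mismatches, with planted NAG sites and 3-vs-4-mismatch
boundary cases.

## Guide selection and oligo assembly

Selection is greedy in ascending CDS-offset order; a candidate is accepted
if its protospacer interval is disjoint from every already-accepted
protospacer (strand-agnostic; PAM overlap is permitted — "non-overlapping"
is read as disjointness of the targeted 20-mers, the strictest common
interpretation). Ties in offset break by (contig, start) and then + before
−, making the output deterministic under any input ordering. Selection
stops at five guides (configurable) or exhaustion; genes with zero
surviving candidates are flagged in the design report rather than aborting
the run.

The expressed spacer is the protospacer with its first base replaced by G,
matching the initiation preference of Pol III U6-type promoters; the
synthesis oligo is adaptor5 + expressed spacer + adaptor3. Adaptors are
inputs (defaults empty): they are vector- and protocol-specific constant
sequences with no influence on design logic.

## Demultiplexing and counting

The amplicon layout is: variable 0–9 nt barcode (bc1) — constant anchor —
20-nt spacer — second constant anchor, with a fixed 6-nt barcode (bc2) on
the mate read in paired mode or directly after the second anchor in
single-end mode. The variable-length bc1 staggers the constant anchor
across sequencing cycles, which keeps per-cycle base composition diverse;
with 0–9 insertions and a 6-nt bc2 the scheme comfortably indexes 18
samples per run. The anchor is sought at offsets 0..9 and the smallest
matching offset wins (a collision requires bc1 to end with an anchor
prefix). Anchor matching is exact by default with an optional ≤1-mismatch
tolerance; spacer matching is always exact against the expressed spacer —
the sequence physically present in the cloned cassette. Quality scores are
ignored.

Every read receives exactly one fate — assigned, unassigned (unknown
barcode pair or unknown spacer), ambiguous (spacer matching two or more
library entries after G-substitution made them identical), or no-anchor —
and the identity assigned + unassigned + ambiguous + no_anchor = total is
asserted on every run.

## Screen statistics

Counts are normalised to counts per million (CPM) of each sample's total;
the scale is conventional and cancels in ratios. Guides are summed per
gene for genes with ≥3 guides (gene-level evidence requires multiple
independent guides agreeing), genes below 50 summed reads in the reference
library are removed (too few reads to measure change against), and log2
fold change is log2((CPM_s + pc)/(CPM_ref + pc)) with pseudocount 1.0
guarding zeros (exposed as a flag; the reference column is identically
zero). The 50-read filter applies to gene-summed counts in the reference,
matching the order of the gene-centred analysis it supports. PCA operates
on guide-level CPM without log transform by default (a `--log` flag offers
log2(CPM+1)); variables are mean-centred across samples and sample scores
and percent variance come from the SVD of the centred matrix. Differential
testing, clustering and enrichment are deliberately exports, not
reimplementations: the TSV outputs are shaped for the standard external
tools (negative-binomial testers expect the raw gene count table).

## Synthetic data

`make_genome` lays out genes on one contig separated by a fixed intergenic
spacing (default 200 nt), each with 1–3 isoforms drawn from a shared pool
of 150–300 nt exon slots separated by 60–120 nt introns, on a random
ACGT background with GC fraction 0.5. These sizes give each gene dozens of
NGG windows while keeping whole-genome off-target scans instant; at this
genome size random 20-mer near-collisions within 3 mismatches are rare, so
nearly all candidates survive the uniqueness filter and a permissive
design (five guides per gene) is the expected outcome. The generator also
returns each gene's maximal-coverage regions computed by an explicit
per-base count over the constructed intervals — an independent code path
from the sweep-line extraction it validates.

`simulate_screen` models the readout as a multinomial draw: per-sample
guide weights are baseline × the gene's fold-change effect, and the stated
reads per sample are drawn in one multinomial per sample, so the truth
table is exact by construction. Reads are padded with random filler to
150 nt (typical short-read length). There is no sequencing-error model by
default — counting is exact-match, and the optional per-base substitution
rate exists to exercise the no-anchor/unassigned paths, not to model a
sequencer.

What the simulations do **not** capture about real screens: PCR
amplification bias, cell-population dynamics (dropout is modelled as a
static fold change, not a growth process), transfection multiplicity,
chimeric reads, and sequencing error beyond uniform substitutions. Passing
tests therefore demonstrate correctness of the bookkeeping and inference
chain under the stated abundance model, not robustness to those noise
sources.

## Problem sizes and numerical choices

The test and acceptance workloads use 20-gene genomes (~50–80 kb),
40–100 random 10–50 kb genomes for the off-target oracle comparison, and
screens of 200 expected reads per guide — sizes at which every check runs
in seconds while still exercising both strands, multi-isoform genes and
all read fates. At 200 reads per guide the gene-level log2FC of a planted
4-fold depletion carries binomial noise of roughly ±0.1 and a small
positive compositional offset (~+0.06 with one of twenty genes depleted),
comfortably inside the ±0.3 tolerance used for recovery. All pipelines are
deterministic given their seeds; dict iteration is avoided or sorted
wherever output order could leak through.

## Known limitations

No on-target efficacy scoring (GC content, position-weight models), no
position-weighted off-target penalties, no bulge-tolerant search, no PAMs
beyond NGG/NAG, no UMI handling, no adapter trimming or quality filtering,
and GTF input is unsupported (GFF3 only).
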