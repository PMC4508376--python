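"""Library representation statistics, normalization, gene-level
aggregation, log2 fold change and sample PCA for pooled screens.

The analysis chain mirrors standard pooled-screen practice: per-sample
counts are scaled to counts per million (CPM) of the sample's total, guides
are summed per gene for genes carrying at least three guides, genes are
filtered on a minimum read count in the reference (plasmid) library, and
log2 ratios are taken against that reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

READ_CATEGORIES = ("0", "1", "2-5", ">5")


@dataclass
class RepresentationReport:
    """Read-count categories per guide and gene-level coverage fractions.

    Fractions use the number of genes with designs as the denominator.
    """

    category_tallies: dict[str, int]
    gene_guide_histogram: pd.Series  # cloned guides per gene -> n genes
    n_genes_designed: int
    n_genes_ge1: int
    n_genes_ge3: int

    @property
    def fraction_ge1(self) -> float:
        return self.n_genes_ge1 / self.n_genes_designed if self.n_genes_designed else 0.0

    @property
    def fraction_ge3(self) -> float:
        return self.n_genes_ge3 / self.n_genes_designed if self.n_genes_designed else 0.0


@dataclass
class GeneCountTable:
    """Gene-summed integer counts for genes with >= min_guides guides."""

    counts: pd.DataFrame  # genes x samples
    provenance: dict[str, list[str]] = field(default_factory=dict)
    min_guides: int = 3


@dataclass
class FoldChangeMatrix:
    """log2 ratios versus a designated reference sample."""

    log2fc: pd.DataFrame
    reference_sample: str
    pseudocount: float
    normalization_scale: float = 1e6


def _read_category(count: int) -> str:
    if count == 0:
        return "0"
    if count == 1:
        return "1"
    if count <= 5:
        return "2-5"
    return ">5"


def representation_report(
    counts: pd.Series, library: pd.DataFrame
) -> RepresentationReport:
    """Categorise each designed guide by its read count (0 / 1 / 2-5 / >5)
    and summarise gene coverage (genes hit by >=1 and >=3 guides)."""
    unknown = set(counts.index) - set(library["guide_id"])
    if unknown:
        raise ValueError(f"counts reference unknown guide_ids: {sorted(unknown)[:5]}")
    full = counts.reindex(library["guide_id"], fill_value=0).astype(int)
    tallies = dict.fromkeys(READ_CATEGORIES, 0)
    for c in full:
        tallies[_read_category(int(c))] += 1
    gene_of = pd.Series(library["gene_id"].values, index=library["guide_id"])
    detected = full[full >= 1]
    guides_per_gene = gene_of.loc[detected.index].value_counts()
    all_genes = library["gene_id"].unique()
    per_gene = guides_per_gene.reindex(all_genes, fill_value=0)
    return RepresentationReport(
        category_tallies=tallies,
        gene_guide_histogram=per_gene.value_counts().sort_index(),
        n_genes_designed=len(all_genes),
        n_genes_ge1=int((per_gene >= 1).sum()),
        n_genes_ge3=int((per_gene >= 3).sum()),
    )


def gene_coverage_stats(
    n_genes_designed: int, n_genes_ge1: int, n_genes_ge3: int
) -> tuple[float, float]:
    """Percent of designed genes covered by >=1 and >=3 cloned guides."""
    if n_genes_designed <= 0:
        raise ValueError("n_genes_designed must be positive")
    return (
        100.0 * n_genes_ge1 / n_genes_designed,
        100.0 * n_genes_ge3 / n_genes_designed,
    )


def coverage_fold(n_clones: float, n_designs: float) -> float:
    """Clones per designed guide (library representation fold)."""
    if n_designs == 0:
        raise ValueError("n_designs must be non-zero")
    return n_clones / n_designs


def normalize_cpm(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Scale each sample column to counts per `scale` total reads."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts / totals * scale


def aggregate_genes(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    min_guides: int = 3,
) -> GeneCountTable:
    """Sum guide counts per gene, keeping genes with >= min_guides guides
    present in the count matrix."""
    gene_of = dict(zip(library["guide_id"], library["gene_id"]))
    unknown = [g for g in counts.index if g not in gene_of]
    if unknown:
        raise ValueError(f"counts reference unknown guide_ids: {unknown[:5]}")
    genes = pd.Series([gene_of[g] for g in counts.index], index=counts.index)
    provenance = {
        gene: sorted(idx)
        for gene, idx in genes.groupby(genes).groups.items()
        if len(idx) >= min_guides
    }
    kept = sorted(provenance)
    summed = counts.groupby(genes).sum().loc[kept]
    summed.index.name = "gene_id"
    return GeneCountTable(summed, provenance, min_guides)


def filter_reference(
    table: GeneCountTable, reference_sample: str, min_reads: int = 50
) -> GeneCountTable:
    """Keep genes with >= min_reads summed counts in the reference sample."""
    if reference_sample not in table.counts.columns:
        raise ValueError(f"reference sample {reference_sample!r} absent")
    keep = table.counts[reference_sample] >= min_reads
    kept = table.counts.loc[keep]
    return GeneCountTable(
        kept,
        {g: table.provenance[g] for g in kept.index},
        table.min_guides,
    )


def log2fc(
    table: pd.DataFrame, reference_sample: str, pseudocount: float = 1.0
) -> FoldChangeMatrix:
    """log2((x_s + pc) / (x_ref + pc)) per gene and sample on a normalized
    (CPM) table. The reference column is identically zero."""
    if reference_sample not in table.columns:
        raise ValueError(f"reference sample {reference_sample!r} absent")
    ref = table[reference_sample]
    fc = np.log2(table.add(pseudocount, axis=0).div(ref + pseudocount, axis=0))
    return FoldChangeMatrix(fc, reference_sample, pseudocount)


def pca_samples(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a guide x sample value matrix.

    Guides (variables) are mean-centered across samples; sample scores come
    from the SVD of the centered sample x guide matrix, and percent variance
    per component is the eigenvalue share of the total (non-increasing,
    summing to 100).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix.to_numpy(dtype=float).T  # samples x guides
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    total = (s**2).sum()
    if total == 0:
        raise ValueError("all samples identical; no variance to decompose")
    pct = s**2 / total * 100.0
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), pct
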