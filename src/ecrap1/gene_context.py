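"""Gene-context statistics for screened regions.

Covers three questions asked of the screen's output: which genes each
candidate region falls in or near; how large those genes are compared with
a background set (composite regions tend to sit in genes with large
introns); and how dense AP-1 consensus motifs are across a gene span,
expressed as occurrences per 10 kb.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneModel, GenomicInterval, GenomeSequence
from .motif_core import AP1_MOTIF, IupacMotif, count_in_region
from .peak_annotation import overlaps

DEFAULT_NEAR_WINDOW = 10_000

RELATION_CONTAINED = "contained_in_gene"
RELATION_OVERLAPS = "overlaps_gene"
RELATION_NEAR = "near_gene"


@dataclass(frozen=True)
class GeneAssignment:
    """One (region, gene) relation; a region may have several."""

    region_name: str
    gene_id: str
    relation: str
    distance: int


@dataclass(frozen=True)
class GeneSizeStats:
    group_label: str
    n_genes: int
    mean_span: float
    median_span: float


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two non-overlapping same-chromosome intervals.

    0 for overlapping or abutting intervals; symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, b.start - a.end, a.start - b.end)


def assign_regions_to_genes(
    regions: Sequence[tuple[GenomicInterval, str]],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_NEAR_WINDOW,
) -> list[GeneAssignment]:
    """All (region, gene) pairs within *window* bp, closest-edge distance.

    Genes sharing a base with the region get distance 0 and relation
    contained_in_gene (region fully inside the span) or overlaps_gene.
    Abutting intervals count as near_gene at distance 0. Regions with no
    gene in the window yield no assignment. All qualifying genes are
    reported: nested gene arrangements make a single-winner choice lossy.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    out: list[GeneAssignment] = []
    for interval, name in regions:
        for gene in genes:
            span = gene.span
            if span.chrom != interval.chrom:
                continue
            if overlaps(interval, span):
                relation = (
                    RELATION_CONTAINED if span.contains(interval) else RELATION_OVERLAPS
                )
                out.append(GeneAssignment(name, gene.gene_id, relation, 0))
                continue
            gap = interval_gap(interval, span)
            if gap <= window:
                out.append(GeneAssignment(name, gene.gene_id, RELATION_NEAR, gap))
    return out


def gene_size_stats(
    gene_ids: Sequence[str],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    group_label: str = "",
) -> GeneSizeStats:
    """Mean and median gene-span length (bp) over *gene_ids*.

    Span length, not exon-union length, is the statistic: the comparison of
    interest is about gene extent (large introns).
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    spans = []
    for gid in gene_ids:
        if gid not in genes:
            raise KeyError(f"unknown gene id {gid!r}")
        spans.append(genes[gid].span.length())
    if not spans:
        return GeneSizeStats(group_label, 0, 0.0, 0.0)
    return GeneSizeStats(
        group_label,
        len(spans),
        float(statistics.fmean(spans)),
        float(statistics.median(spans)),
    )


def motif_density(
    gene: GeneModel,
    genome: GenomeSequence,
    motif: IupacMotif = AP1_MOTIF,
    per_bp: int = 10_000,
) -> float:
    """Motif occurrences per *per_bp* (default 10 kb) across the gene span."""
    count = count_in_region(motif, genome, gene.span)
    return count * per_bp / gene.span.length()
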