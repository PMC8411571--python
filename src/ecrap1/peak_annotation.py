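"""Classify AP-1 motif occurrences by overlap with ChIP-seq peak sets.

Each AP-1 site in a region is colored by the factors whose peaks it
touches, following the blue/red/green scheme used to diagram candidate
regions:

* **green** — the site overlaps an EcR peak;
* **red** — the site overlaps a Jun and/or Kay (Fos) peak but no EcR peak;
* **blue** — the site overlaps no EcR, Jun or Kay peak.

When a site overlaps both EcR and AP-1-subunit peaks, green wins (EcR
binding is the screen's subject); every overlapping factor is still listed
so no information is lost. Usp peaks are recorded in the factor list but
never change the category.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import GenomicInterval, GenomeSequence
from .motif_core import AP1_MOTIF, IupacMotif, MotifHit, scan_sequence

CATEGORY_GREEN = "green"
CATEGORY_RED = "red"
CATEGORY_BLUE = "blue"

#: factors that determine the category (all others are recorded only)
GREEN_FACTORS = frozenset({"EcR"})
RED_FACTORS = frozenset({"Jun", "Kay"})


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base (half-open aware)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass
class PeakSet:
    """ChIP-seq peaks for one factor, indexed for overlap queries."""

    factor: str
    peaks: list[GenomicInterval]
    source_label: str = ""
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for p in self.peaks:
            trees[p.chrom].addi(p.start, p.end)
        self._trees = dict(trees)

    def overlaps_interval(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return bool(tree is not None and tree.overlap(interval.start, interval.end))


@dataclass(frozen=True)
class AnnotatedHit:
    """A motif hit together with its peak-overlap category."""

    hit: MotifHit
    category: str
    overlapping_factors: frozenset[str]

    def as_row(self) -> dict:
        return {
            "chrom": self.hit.interval.chrom,
            "start": self.hit.interval.start,
            "end": self.hit.interval.end,
            "motif": self.hit.motif_name,
            "strand": self.hit.strand,
            "category": self.category,
            "factors": ",".join(sorted(self.overlapping_factors)) or ".",
        }


def classify_hit(hit: MotifHit, peaksets: Sequence[PeakSet]) -> AnnotatedHit:
    """Assign a category with precedence green > red > blue."""
    factors = frozenset(
        ps.factor for ps in peaksets if ps.overlaps_interval(hit.interval)
    )
    if factors & GREEN_FACTORS:
        category = CATEGORY_GREEN
    elif factors & RED_FACTORS:
        category = CATEGORY_RED
    else:
        category = CATEGORY_BLUE
    return AnnotatedHit(hit=hit, category=category, overlapping_factors=factors)


def annotate_region(
    region: GenomicInterval,
    genome: GenomeSequence,
    peaksets: Sequence[PeakSet],
    ap1_motif: IupacMotif = AP1_MOTIF,
) -> list[AnnotatedHit]:
    """One AnnotatedHit per AP-1 occurrence fully inside *region*."""
    seq = genome.fetch(region)
    if len(seq) < len(ap1_motif):
        return []
    hits = scan_sequence(ap1_motif, seq, chrom=region.chrom, origin=region.start)
    return [classify_hit(h, peaksets) for h in hits]


def category_counts(annotated: Iterable[AnnotatedHit]) -> dict[str, int]:
    counts = {CATEGORY_BLUE: 0, CATEGORY_RED: 0, CATEGORY_GREEN: 0}
    for a in annotated:
        counts[a.category] += 1
    return counts
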