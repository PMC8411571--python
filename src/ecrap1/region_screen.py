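"""The composite-element screen over candidate binding regions.

A candidate region passes when it carries at least ``min_ap1`` AP-1
consensus motifs (default 4) and no EcRE consensus site. Regions with this
composition are putative sites where the ecdysone receptor is recruited to
DNA through AP-1 rather than through a canonical EcRE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import GenomicInterval, GenomeSequence
from .motif_core import AP1_MOTIF, ECRE_MOTIF, IupacMotif, count_in_region

logger = logging.getLogger(__name__)

DEFAULT_MIN_AP1 = 4


@dataclass(frozen=True)
class RegionScreenRecord:
    """One candidate region with its motif counts and screen verdict."""

    region_name: str
    interval: GenomicInterval
    ap1_count: int
    ecre_count: int
    passes: bool

    def as_row(self) -> dict:
        return {
            "name": self.region_name,
            "chrom": self.interval.chrom,
            "start": self.interval.start,
            "end": self.interval.end,
            "ap1_count": self.ap1_count,
            "ecre_count": self.ecre_count,
            "passes": self.passes,
        }


def screen_regions(
    regions: Sequence[tuple[GenomicInterval, str]],
    genome: GenomeSequence,
    ap1_motif: IupacMotif = AP1_MOTIF,
    ecre_motif: IupacMotif = ECRE_MOTIF,
    min_ap1: int = DEFAULT_MIN_AP1,
) -> list[RegionScreenRecord]:
    """Screen regions for >= min_ap1 AP-1 motifs and zero EcRE sites.

    Returns one record per input region, order preserved. Only motif
    occurrences fully contained in a region count toward it. A region on a
    chromosome absent from the genome is an error naming the region.
    """
    if min_ap1 < 1:
        raise ValueError(f"min_ap1 must be >= 1, got {min_ap1}")
    records = []
    for interval, name in regions:
        if interval.chrom not in genome:
            raise KeyError(
                f"region {name!r} lies on unknown chromosome {interval.chrom!r}"
            )
        ap1 = count_in_region(ap1_motif, genome, interval)
        ecre = count_in_region(ecre_motif, genome, interval)
        records.append(
            RegionScreenRecord(
                region_name=name,
                interval=interval,
                ap1_count=ap1,
                ecre_count=ecre,
                passes=(ap1 >= min_ap1 and ecre == 0),
            )
        )
    n_total, n_pass, _ = screen_summary(records)
    logger.info("screened %d regions, %d pass (min_ap1=%d)", n_total, n_pass, min_ap1)
    return records


def passing(records: Sequence[RegionScreenRecord]) -> list[RegionScreenRecord]:
    """The passing subset, in input order."""
    return [r for r in records if r.passes]


def screen_summary(
    records: Sequence[RegionScreenRecord],
) -> tuple[int, int, float]:
    """(n_total, n_pass, pass_fraction); an empty input yields (0, 0, 0.0)."""
    n_total = len(records)
    n_pass = sum(r.passes for r in records)
    fraction = n_pass / n_total if n_total else 0.0
    return n_total, n_pass, fraction
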