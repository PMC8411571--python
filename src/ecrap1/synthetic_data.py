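"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its spec, seed included, so each
downstream stage can be checked against exact planted truth: motif scans
against planted site tables, the region screen against prescribed
(AP-1 count, EcRE count) compositions, peak-overlap categories against a
coverage plan, and the image quantifiers against planted pixel counts,
strip means and nuclear/cytoplasmic partitions.

One global seed expands into independent per-component streams through
numpy's ``SeedSequence(seed, spawn_key=(component,))`` derivation.

Clean-background enforcement works by local resampling: after planting,
any spurious motif occurrence is destroyed by mutating one of its
constrained positions (never inside a planted site), and the genome is
re-scanned to fixpoint, so planted counts are exact without materially
biasing base composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .image_quant import RoiPolygon, rasterize_roi
from .io_formats import GeneModel, GenomicInterval, GenomeSequence
from .motif_core import (
    AP1_MOTIF,
    DEFAULT_MOTIFS,
    ECRE_MOTIF,
    IupacMotif,
    reverse_complement,
    scan_sequence,
)
from .peak_annotation import (
    CATEGORY_BLUE,
    CATEGORY_GREEN,
    CATEGORY_RED,
    GREEN_FACTORS,
    RED_FACTORS,
    PeakSet,
)

# spawn keys for per-component child streams
_KEY_GENOME = 0
_KEY_REGIONS = 1
_KEY_PEAKS = 2
_KEY_IMAGE = 3
_KEY_GENES = 4

STANDARD_FACTORS = ("EcR", "Usp", "Jun", "Kay")


def child_rng(seed: int, component: int) -> np.random.Generator:
    """Deterministic per-component stream derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


# ---------------------------------------------------------------------------
# genomes with planted motif sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted motif occurrence, in scanner terms:
    palindromic motifs are recorded on the plus strand regardless of the
    requested orientation, matching the scanner's span-dedup rule."""

    chrom: str
    start: int
    motif_name: str
    strand: str
    matched_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass
class SyntheticGenomeSpec:
    seed: int
    lengths: Mapping[str, int]
    gc: float = 0.5
    planted: Sequence[tuple[str, int, str, str]] = ()  # (chrom, pos, motif, strand)
    clean_background: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _realize(motif: IupacMotif, rng: np.random.Generator) -> str:
    """One concrete sequence matching the consensus, ambiguous positions
    drawn uniformly from their allowed sets."""
    return "".join(rng.choice(sorted(allowed)) for allowed in motif.compiled)


def gen_genome(
    spec: SyntheticGenomeSpec,
    motifs: Mapping[str, IupacMotif] = DEFAULT_MOTIFS,
) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Random-background genome with motifs planted at known coordinates.

    With ``clean_background`` the returned truth table is exactly what
    :func:`~ecrap1.motif_core.scan_sequence` reports over the genome, for
    every motif in *motifs*. Planted sites may not overlap each other.
    """
    rng = child_rng(spec.seed, _KEY_GENOME)
    arrays = {
        name: _random_bases(rng, length, spec.gc)
        for name, length in spec.lengths.items()
    }

    truth: list[PlantedSite] = []
    occupied: dict[str, np.ndarray] = {
        name: np.zeros(length, dtype=bool) for name, length in spec.lengths.items()
    }
    for chrom, pos, motif_name, strand in spec.planted:
        if motif_name not in motifs:
            raise KeyError(f"unknown motif {motif_name!r}")
        motif = motifs[motif_name]
        if chrom not in arrays:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos + len(motif) > spec.lengths[chrom]:
            raise ValueError(
                f"planted {motif_name} at {chrom}:{pos} leaves the motif "
                "outside the chromosome"
            )
        if occupied[chrom][pos : pos + len(motif)].any():
            raise ValueError(f"planted motifs overlap at {chrom}:{pos}")
        occupied[chrom][pos : pos + len(motif)] = True
        realized = _realize(motif, rng)
        planted_seq = realized if strand == "+" else reverse_complement(realized)
        arrays[chrom][pos : pos + len(motif)] = np.frombuffer(
            planted_seq.encode(), dtype=np.uint8
        )
        reported_strand = "+" if motif.is_palindromic() else strand
        truth.append(PlantedSite(chrom, pos, motif_name, reported_strand, planted_seq))

    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    )
    if spec.clean_background:
        genome = _scrub_spurious(genome, arrays, occupied, truth, motifs, rng)
    return genome, sorted(truth, key=lambda s: (s.chrom, s.start, s.motif_name))


def _scrub_spurious(
    genome: GenomeSequence,
    arrays: dict[str, np.ndarray],
    occupied: dict[str, np.ndarray],
    truth: list[PlantedSite],
    motifs: Mapping[str, IupacMotif],
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> GenomeSequence:
    truth_keys = {(s.chrom, s.start, s.motif_name, s.strand) for s in truth}
    for _ in range(max_rounds):
        dirty = False
        for chrom, arr in arrays.items():
            seq = arr.tobytes().decode("ascii")
            for motif in motifs.values():
                for hit in scan_sequence(motif, seq, chrom=chrom):
                    key = (chrom, hit.interval.start, motif.name, hit.strand)
                    if key in truth_keys:
                        continue
                    _break_hit(arr, occupied[chrom], hit.interval.start, motif,
                               hit.strand, rng)
                    dirty = True
        if not dirty:
            return GenomeSequence(
                {name: a.tobytes().decode("ascii") for name, a in arrays.items()}
            )
    raise RuntimeError("clean-background resampling did not converge")


def _break_hit(
    arr: np.ndarray,
    occupied: np.ndarray,
    start: int,
    motif: IupacMotif,
    strand: str,
    rng: np.random.Generator,
) -> None:
    compiled = (
        motif.compiled if strand == "+" else motif.reverse_complemented().compiled
    )
    candidates = [
        j
        for j, allowed in enumerate(compiled)
        if len(allowed) < 4 and not occupied[start + j]
    ]
    if not candidates:
        raise RuntimeError(
            f"spurious {motif.name} hit at {start} lies entirely within "
            "planted sites and cannot be scrubbed"
        )
    j = int(rng.choice(candidates))
    forbidden = compiled[j]
    new_base = rng.choice(sorted(set("ACGT") - forbidden))
    arr[start + j] = ord(new_base)


# ---------------------------------------------------------------------------
# region sets with prescribed (AP-1 count, EcRE count) compositions
# ---------------------------------------------------------------------------

@dataclass
class RegionSetData:
    genome: GenomeSequence
    regions: list[tuple[GenomicInterval, str]]
    truth: list[PlantedSite]
    compositions: list[tuple[int, int]]


def gen_region_set(
    compositions: Sequence[tuple[int, int]],
    seed: int,
    region_length: int = 320,
    gap: int = 80,
    gc: float = 0.5,
    chrom: str = "chrS",
    ap1: IupacMotif = AP1_MOTIF,
    ecre: IupacMotif = ECRE_MOTIF,
) -> RegionSetData:
    """Clean-background chromosome carrying one region per composition.

    Region ``i`` contains exactly ``compositions[i] == (ap1_count,
    ecre_count)`` fully-contained motif occurrences, so the screen's output
    on this data is the prescription itself. Infeasible compositions (sites
    do not fit in ``region_length``) are an error.
    """
    rng = child_rng(seed, _KEY_REGIONS)
    max_len = max(len(ap1), len(ecre))
    planted: list[tuple[str, int, str, str]] = []
    regions: list[tuple[GenomicInterval, str]] = []
    for i, (n_ap1, n_ecre) in enumerate(compositions):
        if n_ap1 < 0 or n_ecre < 0:
            raise ValueError(f"negative composition {compositions[i]}")
        start = gap + i * (region_length + gap)
        regions.append(
            (GenomicInterval(chrom, start, start + region_length), f"region_{i}")
        )
        k = n_ap1 + n_ecre
        if k == 0:
            continue
        slot = region_length // k
        if slot < max_len + 1:
            raise ValueError(
                f"composition {compositions[i]} does not fit in a "
                f"{region_length} bp region"
            )
        names = [ap1.name] * n_ap1 + [ecre.name] * n_ecre
        for s, motif_name in enumerate(names):
            length = len(ap1) if motif_name == ap1.name else len(ecre)
            jitter = int(rng.integers(0, slot - length + 1))
            strand = str(rng.choice(["+", "-"]))
            planted.append((chrom, start + s * slot + jitter, motif_name, strand))

    total_len = gap + len(compositions) * (region_length + gap)
    spec = SyntheticGenomeSpec(
        seed=seed,
        lengths={chrom: total_len},
        gc=gc,
        planted=planted,
        clean_background=True,
    )
    genome, truth = gen_genome(spec, motifs={ap1.name: ap1, ecre.name: ecre})
    return RegionSetData(genome, regions, truth, list(compositions))


def summary_compositions(
    n_total: int, n_pass: int, min_ap1: int = 4
) -> list[tuple[int, int]]:
    """A deterministic composition list with exactly *n_pass* passing
    regions out of *n_total*, passing regions spread across the set."""
    if not 0 <= n_pass <= n_total:
        raise ValueError("need 0 <= n_pass <= n_total")
    passing_idx = {int(i * n_total / n_pass) for i in range(n_pass)} if n_pass else set()
    fail_cycle = [(min_ap1 - 1, 0), (min_ap1, 1), (0, 0), (1, 0), (min_ap1 + 2, 1)]
    pass_cycle = [(min_ap1, 0), (min_ap1 + 1, 0)]
    out: list[tuple[int, int]] = []
    n_p = n_f = 0
    for i in range(n_total):
        if i in passing_idx:
            out.append(pass_cycle[n_p % len(pass_cycle)])
            n_p += 1
        else:
            out.append(fail_cycle[n_f % len(fail_cycle)])
            n_f += 1
    return out


# ---------------------------------------------------------------------------
# ChIP-seq peak sets with planned overlap structure
# ---------------------------------------------------------------------------

def gen_peaks(
    truth: Sequence[PlantedSite],
    coverage_plan: Mapping[int, Sequence[str]],
    pad: int = 5,
    source_label: str = "synthetic",
) -> list[PeakSet]:
    """Peak sets placing one peak (site span +/- *pad*) over each planned
    planted site, per factor. Factors outside the plan get empty sets."""
    factors = list(STANDARD_FACTORS) + sorted(
        {f for fs in coverage_plan.values() for f in fs} - set(STANDARD_FACTORS)
    )
    peaks: dict[str, list[GenomicInterval]] = {f: [] for f in factors}
    for idx, site_factors in coverage_plan.items():
        if not 0 <= idx < len(truth):
            raise IndexError(f"coverage plan references unknown site {idx}")
        site = truth[idx]
        interval = GenomicInterval(site.chrom, max(0, site.start - pad), site.end + pad)
        for f in site_factors:
            peaks[f].append(interval)
    return [PeakSet(factor=f, peaks=peaks[f], source_label=source_label) for f in factors]


def expected_categories(
    truth: Sequence[PlantedSite], coverage_plan: Mapping[int, Sequence[str]]
) -> list[str]:
    """The category each planted site must receive under the plan."""
    out = []
    for i in range(len(truth)):
        factors = set(coverage_plan.get(i, ()))
        if factors & GREEN_FACTORS:
            out.append(CATEGORY_GREEN)
        elif factors & RED_FACTORS:
            out.append(CATEGORY_RED)
        else:
            out.append(CATEGORY_BLUE)
    return out


# ---------------------------------------------------------------------------
# gene models with controlled span lengths
# ---------------------------------------------------------------------------

def gen_gene_models(
    n: int,
    mean_span: float,
    seed: int,
    cv: float = 0.2,
    chrom: str = "chrG",
    gap: int = 2_000,
    prefix: str = "gene",
) -> list[GeneModel]:
    """Genes laid end to end with gamma-distributed span lengths.

    ``cv`` is the coefficient of variation of the span distribution; the
    default 0.2 gives realistically dispersed but positive lengths.
    """
    rng = child_rng(seed, _KEY_GENES)
    shape = 1.0 / cv**2
    spans = np.maximum(
        200, np.round(rng.gamma(shape, mean_span / shape, size=n))
    ).astype(int)
    genes = []
    pos = gap
    for i, span in enumerate(spans):
        genes.append(
            GeneModel(
                gene_id=f"{prefix}_{i}",
                span=GenomicInterval(chrom, pos, pos + int(span)),
            )
        )
        pos += int(span) + gap
    return genes


# ---------------------------------------------------------------------------
# fluorescence images with planted truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImageSpec:
    seed: int
    shape: tuple[int, int] = (128, 128)
    max_gray: float = 255.0
    background_mean: float = 30.0
    background_sd: float = 0.0
    # ROI pixel-fraction part
    roi: RoiPolygon | None = None
    threshold: float = 128.0
    n_signal_px: int = 0
    signal_value: float = 200.0
    # strip mean-gray-value part: parallel lists of rects and planted means
    strip_rects: Sequence[tuple[int, int, int, int]] = ()
    strip_means: Sequence[float] = ()
    strip_sd: float = 0.0
    # PLA part
    pla_partition: tuple[int, int] | None = None  # (n_nuclear, n_cytoplasmic)
    n_nuclei: int = 6
    nucleus_radius: int = 14


@dataclass
class ImageFixture:
    image: np.ndarray
    roi_mask: np.ndarray | None = None
    truth_signal_px: int | None = None
    truth_roi_area: int | None = None
    strip_truth: list[tuple[tuple[int, int, int, int], float, float]] = field(
        default_factory=list
    )  # (rect, planted_mean, realized_mean)
    nuclear_mask: np.ndarray | None = None
    pla_centroids: list[tuple[float, float]] = field(default_factory=list)
    truth_n_nuclear: int | None = None
    truth_n_cytoplasmic: int | None = None

    @property
    def truth_roi_fraction(self) -> float:
        return self.truth_signal_px / self.truth_roi_area


def gen_image(spec: SyntheticImageSpec) -> ImageFixture:
    """Grayscale image with exactly known quantification truth.

    Background pixels are kept strictly below the ROI threshold (clipped in
    noisy mode) so the planted signal-pixel count is exact in every mode;
    strip noise is unconstrained, so only noiseless strip means are exact
    and the realized mean is recorded alongside the planted one.
    """
    rng = child_rng(spec.seed, _KEY_IMAGE)
    h, w = spec.shape
    if spec.background_sd > 0:
        image = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))
    else:
        image = np.full((h, w), spec.background_mean, dtype=float)
    image = np.clip(image, 0.0, spec.max_gray)
    fixture = ImageFixture(image=image)

    if spec.roi is not None:
        if spec.signal_value < spec.threshold:
            raise ValueError("signal_value must reach the threshold")
        if spec.background_mean >= spec.threshold:
            raise ValueError("background mean must stay below the threshold")
        np.clip(image, 0.0, min(spec.max_gray, spec.threshold - 1), out=image)
        mask = rasterize_roi(spec.roi, (h, w))
        inside = np.flatnonzero(mask)
        if spec.n_signal_px > inside.size:
            raise ValueError(
                f"cannot plant {spec.n_signal_px} signal pixels in an ROI of "
                f"{inside.size} pixels"
            )
        chosen = rng.choice(inside, size=spec.n_signal_px, replace=False)
        image.flat[chosen] = spec.signal_value
        fixture.roi_mask = mask
        fixture.truth_signal_px = int(spec.n_signal_px)
        fixture.truth_roi_area = int(inside.size)

    if len(spec.strip_rects) != len(spec.strip_means):
        raise ValueError("strip_rects and strip_means must be parallel")
    for rect, mean in zip(spec.strip_rects, spec.strip_means):
        row, col, rh, rw = rect
        if row < 0 or col < 0 or row + rh > h or col + rw > w:
            raise ValueError(f"strip rect {rect} outside image")
        block = np.full((rh, rw), mean, dtype=float)
        if spec.strip_sd > 0:
            block += rng.normal(0.0, spec.strip_sd, size=(rh, rw))
        block = np.clip(block, 0.0, spec.max_gray)
        image[row : row + rh, col : col + rw] = block
        fixture.strip_truth.append((rect, float(mean), float(block.mean())))

    if spec.pla_partition is not None:
        n_nuc, n_cyt = spec.pla_partition
        nuclear_mask = _gen_nuclear_mask(rng, (h, w), spec.n_nuclei, spec.nucleus_radius)
        centroids = _sample_points(rng, nuclear_mask, n_nuc, inside=True)
        centroids += _sample_points(rng, nuclear_mask, n_cyt, inside=False)
        if spec.roi is None:  # bright puncta would corrupt a planted ROI count
            for r, c in centroids:
                image[int(r), int(c)] = spec.max_gray
        fixture.nuclear_mask = nuclear_mask
        fixture.pla_centroids = centroids
        fixture.truth_n_nuclear = n_nuc
        fixture.truth_n_cytoplasmic = n_cyt

    return fixture


def _gen_nuclear_mask(
    rng: np.random.Generator, shape: tuple[int, int], n_nuclei: int, radius: int
) -> np.ndarray:
    h, w = shape
    if 2 * radius + 2 >= min(h, w):
        raise ValueError("nucleus radius too large for image")
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_nuclei):
        cr = rng.integers(radius + 1, h - radius - 1)
        cc = rng.integers(radius + 1, w - radius - 1)
        mask |= (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    return mask


def _sample_points(
    rng: np.random.Generator, mask: np.ndarray, n: int, inside: bool
) -> list[tuple[float, float]]:
    pool = np.flatnonzero(mask if inside else ~mask)
    if n > pool.size:
        raise ValueError("not enough pixels to place the requested puncta")
    chosen = rng.choice(pool, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    return [(float(r) + 0.5, float(c) + 0.5) for r, c in zip(rows, cols)]
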