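"""Quantification of fluorescence microscopy signal.

Two transcript-signal measures on grayscale images, mirroring common
practice for in situ hybridization of flat embryonic tissues:

* **ROI pixel fraction** — a tissue region is outlined as a polygon, the
  image is thresholded, and the measure is (signal pixels inside the ROI) /
  (ROI area in pixels). Used for sheet-like tissue such as the amnioserosa.
* **strip mean gray value** — a fixed-size rectangle over a stretch of
  leading-edge epidermis; the measure is the arithmetic mean intensity.
  The rectangle size must be identical across a comparison batch.

Group comparisons use the equal-variance two-sided Student's t-test with
means +/- s.e.m. Proximity-ligation (PLA) puncta are classified as nuclear
or cytoplasmic by whether their centroid pixel falls inside a binary
nuclear mask — puncta are small relative to nuclei, so centroid membership
is the simplest auditable rule.

Thresholds are explicit parameters and, by contract, held constant within
a dataset; "signal" is every pixel with intensity >= threshold inside the
ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

MODE_ROI_FRACTION = "roi_fraction"
MODE_STRIP_MEAN = "strip_mean"


@dataclass(frozen=True)
class RoiPolygon:
    """A simple (non-self-intersecting) polygon in pixel coordinates.

    Vertices are (x, y) with x along columns and y along rows, in pixel-edge
    units: the axis-aligned square (0,0)-(w,h) covers exactly w*h pixels.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_simple or not poly.is_valid or poly.area == 0:
            raise ValueError("degenerate or self-intersecting polygon")

    @classmethod
    def from_rect(cls, x0: float, y0: float, width: float, height: float) -> "RoiPolygon":
        return cls(((x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)))

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class QuantResult:
    """One image measurement with its provenance."""

    mode: str
    value: float
    roi_area_px: int
    signal_px: int | None = None
    threshold: float | None = None


class GroupComparison(NamedTuple):
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class PlaClassification:
    """Nuclear/cytoplasmic partition of punctate signals."""

    n_total: int
    n_nuclear: int
    n_cytoplasmic: int

    @property
    def pct_cytoplasmic(self) -> float:
        return 100.0 * self.n_cytoplasmic / self.n_total


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Pixel (row r, col c) has its center at (x=c+0.5, y=r+0.5); membership is
    point-in-polygon at the centers (for the simple polygons required here
    this coincides with even-odd fill). The polygon must lie fully within
    the image.
    """
    h, w = shape
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError(
            f"ROI bounds ({minx},{miny})-({maxx},{maxy}) exceed image {w}x{h}"
        )
    c0, c1 = int(math.floor(minx)), int(math.ceil(maxx))
    r0, r1 = int(math.floor(miny)), int(math.ceil(maxy))
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(poly, cols + 0.5, rows + 0.5)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def quantify_roi_fraction(
    image: np.ndarray, roi: RoiPolygon, threshold: float
) -> QuantResult:
    """Fraction of ROI pixels at or above *threshold*.

    value = signal_px / roi_area_px, in [0, 1]. Pixels outside the ROI never
    contribute, so the result is invariant under any change to them.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    mask = rasterize_roi(roi, image.shape)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("ROI covers no pixel centers")
    signal = int(np.count_nonzero(image[mask] >= threshold))
    return QuantResult(
        mode=MODE_ROI_FRACTION,
        value=signal / area,
        roi_area_px=area,
        signal_px=signal,
        threshold=float(threshold),
    )


def quantify_strip_intensity(
    image: np.ndarray,
    rect: tuple[int, int, int, int],
    expected_size: tuple[int, int] | None = None,
) -> QuantResult:
    """Mean gray value over a rectangle (row, col, height, width).

    ``expected_size`` enforces the fixed selection size of an analysis
    batch: a differing rectangle is an error, not a silent measurement.
    """
    image = np.asarray(image)
    row, col, height, width = rect
    if height <= 0 or width <= 0:
        raise ValueError("rectangle must have positive size")
    if row < 0 or col < 0 or row + height > image.shape[0] or col + width > image.shape[1]:
        raise ValueError(f"rectangle {rect} exceeds image {image.shape}")
    if expected_size is not None and (height, width) != tuple(expected_size):
        raise ValueError(
            f"rectangle size {(height, width)} differs from the batch's "
            f"fixed size {tuple(expected_size)}"
        )
    strip = image[row : row + height, col : col + width]
    return QuantResult(
        mode=MODE_STRIP_MEAN,
        value=float(strip.mean()),
        roi_area_px=height * width,
    )


class StripBatch:
    """Enforces one fixed rectangle size across a comparison batch."""

    def __init__(self) -> None:
        self._size: tuple[int, int] | None = None

    def measure(self, image: np.ndarray, rect: tuple[int, int, int, int]) -> QuantResult:
        if self._size is None:
            self._size = (rect[2], rect[3])
        return quantify_strip_intensity(image, rect, expected_size=self._size)


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Two-sided equal-variance Student's t-test with means +/- s.e.m.

    Zero pooled variance (possible on clean synthetic data) is reported as a
    degenerate result rather than a crash: t = +/-inf with p = 0 when the
    means differ, t = 0 with p = 1 when they coincide.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if mean_a == mean_b:
            return GroupComparison(mean_a, 0.0, mean_b, 0.0, 0.0, 1.0, True)
        t = math.inf if mean_a > mean_b else -math.inf
        return GroupComparison(mean_a, 0.0, mean_b, 0.0, t, 0.0, True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(mean_a, _sem(a), mean_b, _sem(b), float(t), float(p))


def classify_pla_signals(
    centroids: Sequence[tuple[float, float]], nuclear_mask: np.ndarray
) -> PlaClassification:
    """Partition punctate signals into nuclear and cytoplasmic.

    *centroids* are (row, col) positions; a signal is nuclear iff the pixel
    containing its centroid is True in the binary nuclear mask. An empty
    centroid list is an error (the percentage is undefined).
    """
    if len(centroids) == 0:
        raise ValueError("no signals to classify")
    mask = np.asarray(nuclear_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("nuclear mask must be 2-D")
    n_nuclear = 0
    for row, col in centroids:
        r, c = int(math.floor(row)), int(math.floor(col))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            raise ValueError(f"centroid ({row}, {col}) outside image {mask.shape}")
        if mask[r, c]:
            n_nuclear += 1
    n_total = len(centroids)
    return PlaClassification(
        n_total=n_total, n_nuclear=n_nuclear, n_cytoplasmic=n_total - n_nuclear
    )
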