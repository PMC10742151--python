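"""AFM topography statistics.

Object detection on gridded height maps and the summary statistics used
to read out probe immobilization and probe–target complex formation:

* N400 — object count normalized to 400 µm² of scanned area,
  N400 = N·400/(n·S_fr) for N objects over n frames of S_fr µm² each.
* ρ(h) — the object height-distribution density, the percentage of
  detected objects per height bin: ρ(h) = N_h/N · 100%.
* The before/after comparison: complex formation on the surface shifts
  ρ(h) to the right, because a probe–target complex stands taller than
  the immobilized probe alone (h₂ > h₁).

Heights are in nm; pixel sizes in nm/pixel; frame areas in µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFractionError,
)

__all__ = [
    "TopographyImage",
    "DetectedObject",
    "HeightDistribution",
    "CountSummary",
    "ComplexFormationCall",
    "flatten_background",
    "detect_objects",
    "normalize_count",
    "height_distribution",
    "fraction_above",
    "call_complex_formation",
]


@dataclass(frozen=True)
class TopographyImage:
    """Gridded height map (nm) with pixel size (nm) and frame area S_fr (µm²)."""

    heights: np.ndarray
    pixel_size: float
    frame_area: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.size == 0:
            raise InvalidParameterError("heights must be a non-empty 2-D grid")
        if not np.all(np.isfinite(h)):
            raise InvalidParameterError("heights must be finite")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        geom_area = h.shape[0] * h.shape[1] * self.pixel_size ** 2 / 1e6
        if self.frame_area is None:
            object.__setattr__(self, "frame_area", geom_area)
        elif not np.isclose(self.frame_area, geom_area, rtol=0.01):
            raise InvalidParameterError(
                f"frame_area {self.frame_area} µm² inconsistent with "
                f"grid × pixel_size ({geom_area:.4g} µm²)")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class DetectedObject:
    """One connected object: its pixels, peak height h (nm), area (nm²),
    and compact/layered morphology."""

    pixel_set: np.ndarray  # (k, 2) row/col indices, 8-connected
    height: float
    area: float
    morphology: str  # "compact" | "layered"

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(np.asarray(self.pixel_set, dtype=float).mean(axis=0))


@dataclass(frozen=True)
class HeightDistribution:
    """Binned ρ(h) percentages plus the raw heights they were built from."""

    bin_edges: np.ndarray
    rho: np.ndarray
    total_count: int
    bin_width: float
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class CountSummary:
    """Raw and normalized object counts: N, n frames, S_fr, N400."""

    n_objects: int
    n_frames: int
    frame_area: float
    n400: float


@dataclass(frozen=True)
class ComplexFormationCall:
    """Before/after ρ(h) comparison at a height threshold."""

    before: HeightDistribution
    after: HeightDistribution
    threshold: float
    fraction_above_before: float
    fraction_above_after: float
    verdict: str  # "complex-formed" | "no-shift"


def flatten_background(image: TopographyImage,
                       background_percentile: float = 70.0) -> TopographyImage:
    """Remove the substrate plane from a topography frame.

    A least-squares plane is fitted to the pixels below the given height
    percentile — excluding objects, which sit above it — and subtracted,
    iterating mask and fit to a fixed point so the operation is
    idempotent; the output is then shifted so its median is zero. A
    constant frame degenerates to an all-zero frame.
    """
    h = image.heights
    if h.shape[0] < 4 or h.shape[1] < 4:
        raise InvalidParameterError("frame must be at least 4x4 pixels")
    if np.ptp(h) == 0.0:
        return TopographyImage(np.zeros_like(h), image.pixel_size,
                               image.frame_area, image.label)
    rows, cols = np.indices(h.shape)
    flat = h.astype(float, copy=True)
    for _ in range(20):
        mask = flat <= np.percentile(flat, background_percentile)
        design = np.column_stack([rows[mask], cols[mask], np.ones(mask.sum())])
        coef, *_ = np.linalg.lstsq(design, flat[mask], rcond=None)
        plane = coef[0] * rows + coef[1] * cols + coef[2]
        flat = flat - plane
        if np.max(np.abs(plane)) < 1e-10:
            break
    flat = flat - np.median(flat)
    return TopographyImage(flat, image.pixel_size, image.frame_area, image.label)


def _robust_roughness(flat: np.ndarray) -> float:
    """Robust RMS roughness: median absolute deviation scaled to Gaussian σ."""
    return float(np.median(np.abs(flat - np.median(flat))) * 1.4826)


def detect_objects(image: TopographyImage, k_sigma: float = 3.0,
                   min_area: float = 800.0,
                   layered_area_fraction: float = 0.05,
                   peak_filter_px: int = 3) -> list[DetectedObject]:
    """Detect objects on a flattened frame by robust thresholding.

    The detection threshold is k_sigma × robust roughness (MAD × 1.4826)
    of the raw frame, but it is applied to a ``peak_filter_px`` box-mean
    copy of the frame: the smoothing suppresses pixel noise roughly
    threefold, so at the raw-roughness threshold isolated noise clusters
    vanish (empty control frames) while genuine objects — wider than the
    filter — keep their height, and their masks are no longer pinched
    apart by single-pixel noise dips. 8-connected components with area ≥
    ``min_area`` (nm²) become objects; an object's height is the peak of
    the smoothed frame inside its component (peak above background, but
    robust to the upward bias a raw per-pixel maximum picks up from
    roughness). Components covering more than ``layered_area_fraction``
    of the frame are classified layered, the rest compact. An empty list
    is a valid result.
    """
    if k_sigma <= 0 or min_area < 0:
        raise InvalidParameterError("k_sigma must be positive, min_area >= 0")
    h = image.heights
    threshold = k_sigma * _robust_roughness(h)
    smoothed = uniform_filter(h, size=max(1, int(peak_filter_px)))
    mask = smoothed > threshold
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    frame_area_nm2 = image.frame_area * 1e6
    pixel_area = image.pixel_size ** 2
    objects: list[DetectedObject] = []
    for region in regionprops(labels):
        area_nm2 = region.area * pixel_area
        if area_nm2 < min_area:
            continue
        coords = region.coords
        height = float(smoothed[coords[:, 0], coords[:, 1]].max())
        if height <= 0:
            continue
        morphology = ("layered"
                      if area_nm2 > layered_area_fraction * frame_area_nm2
                      else "compact")
        objects.append(DetectedObject(coords, height, float(area_nm2), morphology))
    return objects


def normalize_count(n_objects: int, n_frames: int,
                    frame_area: float) -> CountSummary:
    """Normalized object count per 400 µm²: N400 = N·400/(n·S_fr)."""
    if n_frames < 1 or frame_area <= 0:
        raise InvalidParameterError("n_frames >= 1 and frame_area > 0 required")
    if n_objects < 0:
        raise InvalidParameterError("n_objects must be non-negative")
    n400 = n_objects * 400.0 / (n_frames * frame_area)
    return CountSummary(int(n_objects), int(n_frames), float(frame_area), n400)


def height_distribution(objects: list[DetectedObject],
                        bin_width: float = 0.2) -> HeightDistribution:
    """Height-distribution density ρ(h): percentage of objects per bin.

    Bins of ``bin_width`` nm cover [0, max height + bin_width). An empty
    object list yields a flagged distribution with total_count 0 and an
    all-zero ρ.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    heights = np.array([obj.height for obj in objects], dtype=float)
    if heights.size == 0:
        edges = np.array([0.0, bin_width])
        return HeightDistribution(edges, np.zeros(1), 0, bin_width, heights)
    n_bins = int(np.floor(heights.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(heights, bins=edges)
    rho = 100.0 * counts / heights.size
    return HeightDistribution(edges, rho, int(heights.size), bin_width, heights)


def fraction_above(dist: HeightDistribution, threshold: float) -> float:
    """Percentage of objects strictly taller than ``threshold`` (nm),
    computed from the raw heights, not the bins."""
    if dist.total_count == 0:
        raise UndefinedFractionError("no objects in the distribution")
    return float(100.0 * np.sum(dist.heights > threshold) / dist.total_count)


def call_complex_formation(before: HeightDistribution,
                           after: HeightDistribution,
                           threshold: float,
                           min_shift_fraction: float = 20.0) -> ComplexFormationCall:
    """Call probe–target complex formation from a before/after ρ(h) shift.

    Complex formation is called when the fraction of objects above the
    height threshold grows by at least ``min_shift_fraction`` percentage
    points after incubation — the rightward ρ(h) shift expected when
    complexes (h₂) stand taller than bare probes (h₁).
    """
    if before.total_count == 0 or after.total_count == 0:
        raise InsufficientDataError("both distributions must be non-empty")
    f_before = fraction_above(before, threshold)
    f_after = fraction_above(after, threshold)
    verdict = ("complex-formed"
               if f_after - f_before >= min_shift_fraction else "no-shift")
    return ComplexFormationCall(before, after, float(threshold),
                                f_before, f_after, verdict)
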