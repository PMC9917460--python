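"""Filter-and-threshold segmentation of mosaic disc images.

Raw channels are turned into three primary objects:

* a **disc mask** from the nuclear (DAPI) channel — Gaussian blur then a
  triangle threshold, holes filled, largest component kept;
* a **clone label map** from the clone-marker (GFP) channel — grayscale
  closing (max then min filter), Otsu/isodata threshold, despeckle, fill
  holes, restriction to the disc, and a minimum-area inclusion filter;
* an **apoptotic particle mask** from the cleaved-Dcp1 channel — radius-1
  closing and an intermodes threshold computed on within-disc pixels, so
  only high-intensity puncta survive.

All thresholds are "dark-background" variants: foreground is strictly above
the returned level; ties at the level go to background.  Threshold methods
operate on 256-level histograms and follow their published definitions, so
they can be checked against exhaustive-search oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .image import BinaryMask, LabelMap

N_LEVELS = 256

SUPPORTED_METHODS = ("triangle", "otsu", "isodata", "intermodes", "minimum")

#: Minimum separation (in 256-level units) between the two smoothed modes of
#: the particle-channel histogram before puncta are considered present.
MIN_PARTICLE_MODE_SEPARATION = 8


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied levels (e.g. constant image)."""


class ThresholdConvergenceError(RuntimeError):
    """Iterative smoothing failed to reach a bimodal histogram."""

    def __init__(self, message: str, histogram: np.ndarray | None = None):
        super().__init__(message)
        self.histogram = histogram


class EmptyMaskError(ValueError):
    """Thresholding produced no foreground where some was required."""


@dataclass
class SegmentationParams:
    """Numeric parameters of the segmentation chains.

    Filter sizes are in pixels by default, matching the image-analysis tool
    conventions the procedure was designed in; set ``sizes_in_um=True`` to
    give them in µm (converted via the image's pixel size).
    """

    dapi_blur_sigma_px: float = 4.0
    clone_filter_radius_px: float = 2.0
    particle_filter_radius_px: float = 1.0
    disc_threshold_method: str = "triangle"
    clone_threshold_method: str = "otsu"
    particle_threshold_method: str = "intermodes"
    min_clone_area_um2: float = 10.0
    despeckle: bool = True
    particle_threshold_multiplier: float = 1.0
    sizes_in_um: bool = False

    def __post_init__(self) -> None:
        for name in ("dapi_blur_sigma_px", "clone_filter_radius_px",
                     "particle_filter_radius_px", "min_clone_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("disc_threshold_method", "clone_threshold_method",
                     "particle_threshold_method"):
            method = getattr(self, name)
            if method not in SUPPORTED_METHODS:
                raise ValueError(
                    f"{name}={method!r} not in supported set {SUPPORTED_METHODS}"
                )

    def in_pixels(self, pixel_size_um: float) -> "SegmentationParams":
        """Return a copy with all filter sizes expressed in pixels."""
        if not self.sizes_in_um:
            return self
        f = 1.0 / pixel_size_um
        return replace(
            self,
            dapi_blur_sigma_px=self.dapi_blur_sigma_px * f,
            clone_filter_radius_px=self.clone_filter_radius_px * f,
            particle_filter_radius_px=self.particle_filter_radius_px * f,
            sizes_in_um=False,
        )


# ---------------------------------------------------------------------------
# Projections and histograms


def max_project(stack: np.ndarray, slice_range: tuple[int, int]) -> np.ndarray:
    """Maximum-intensity projection over an inclusive slice range.

    Emulates projecting 2–3 optical sections of an apical or basal substack.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"stack must be 3D (Z,Y,X), got shape {stack.shape}")
    lo, hi = slice_range
    if lo > hi or lo < 0 or hi >= stack.shape[0]:
        raise IndexError(
            f"slice_range {slice_range} invalid for stack of depth {stack.shape[0]}"
        )
    return stack[lo : hi + 1].max(axis=0)


def histogram256(
    image: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """256-level histogram of (masked) intensities.

    Returns ``(counts, bin_edges)`` with ``len(edges) == 257``; level ``i``
    covers ``[edges[i], edges[i+1])`` (the top bin is closed).  Intensities
    that fit the 8-bit range [0, 255] are binned on that absolute scale —
    the convention of 8-bit image tools, which keeps a low-contrast field
    from being stretched into spurious histogram structure.  Wider float
    ranges are binned min-to-max.
    """
    vals = np.asarray(image, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise DegenerateHistogramError("no pixels to histogram")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise DegenerateHistogramError(f"constant intensity {lo}: no threshold exists")
    if lo >= 0 and hi <= N_LEVELS - 1:
        edges = np.arange(N_LEVELS + 1, dtype=float) - 0.5
    else:
        edges = np.linspace(lo, hi, N_LEVELS + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def level_to_intensity(level: int, edges: np.ndarray) -> float:
    """Upper edge of the level's bin: foreground = intensity > this value."""
    return float(edges[level + 1])


# ---------------------------------------------------------------------------
# Threshold methods (histogram level space)


def threshold_level(histogram: np.ndarray, method: str) -> int:
    """Threshold level for a counts histogram, per the named method.

    Foreground ("dark background" polarity) is every level strictly above
    the returned value.

    Methods
    -------
    otsu
        Maximizes between-class variance over all candidate splits.
    isodata
        Iterates ``t <- round((mean_below + mean_above) / 2)`` to a fixed
        point (Ridler–Calvard), where *below* includes level ``t``.
    triangle
        Maximizes the perpendicular distance from the histogram to the chord
        joining the peak to the far end of the longer tail.
    intermodes
        Repeats 3-tap mean smoothing until exactly two modes remain, then
        returns ``floor((m1 + m2) / 2)``.
    minimum
        Same smoothing; returns the lowest level of minimal smoothed count
        strictly between the two modes.
    """
    counts = np.asarray(histogram, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("histogram must be a non-empty 1D array of counts")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied levels"
        )
    if method == "otsu":
        return _otsu(counts)
    if method == "isodata":
        return _isodata(counts)
    if method == "triangle":
        return _triangle(counts)
    if method == "intermodes":
        return _intermodes_minimum(counts, "intermodes")
    if method == "minimum":
        return _intermodes_minimum(counts, "minimum")
    raise ValueError(f"unknown threshold method {method!r}")


def _otsu(counts: np.ndarray) -> int:
    levels = np.arange(counts.size, dtype=float)
    w0 = np.cumsum(counts)
    total = w0[-1]
    w1 = total - w0
    s0 = np.cumsum(counts * levels)
    m0 = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    m1 = np.divide(s0[-1] - s0, w1, out=np.zeros_like(s0), where=w1 > 0)
    between = w0 * w1 * (m0 - m1) ** 2
    between[w1 == 0] = -1.0  # no valid split leaves foreground empty
    return int(np.argmax(between))


def _isodata(counts: np.ndarray) -> int:
    # Ridler–Calvard criterion t = round((mean_below + mean_above)/2);
    # several fixed points can coexist — take the lowest, the first level
    # at which the iteration can settle.
    levels = np.arange(counts.size, dtype=float)
    w0 = np.cumsum(counts)
    s0 = np.cumsum(counts * levels)
    total, stotal = w0[-1], s0[-1]
    valid = (w0 > 0) & (total - w0 > 0)
    mb = np.divide(s0, w0, out=np.zeros_like(s0), where=w0 > 0)
    ma = np.divide(stotal - s0, total - w0, out=np.zeros_like(s0),
                   where=(total - w0) > 0)
    target = np.round((mb + ma) / 2.0)
    t_all = np.arange(counts.size)
    fixed = np.flatnonzero(valid & (target == t_all))
    if fixed.size:
        return int(fixed[0])
    dev = np.where(valid, np.abs(target - t_all), np.inf)
    return int(np.argmin(dev))


def _triangle(counts: np.ndarray) -> int:
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(counts))
    flipped = (peak - first) > (last - peak)
    h = counts[::-1].copy() if flipped else counts.copy()
    if flipped:
        peak = counts.size - 1 - peak
        last = counts.size - 1 - first
    # maximize distance below the chord from (peak, h[peak]) to (last, 0)
    if last == peak:
        best = peak
    else:
        i = np.arange(peak, last + 1, dtype=float)
        dist = h[peak] * (last - i) - (last - peak) * h[peak : last + 1]
        best = peak + int(np.argmax(dist))
    if flipped:
        best = counts.size - 1 - best
    return int(best)


def _smooth3(h: np.ndarray) -> np.ndarray:
    padded = np.pad(h, 1, mode="edge")
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _modes(h: np.ndarray) -> np.ndarray:
    """Interior strict local maxima (the classical bimodality test)."""
    interior = (h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])
    return np.flatnonzero(interior) + 1


def smoothed_bimodal_modes(
    counts: np.ndarray, max_iter: int = 10000
) -> tuple[int, int, np.ndarray]:
    """Iterate 3-tap mean smoothing until exactly two modes remain.

    Returns ``(m1, m2, smoothed_histogram)``; raises
    ThresholdConvergenceError if the histogram passes straight to
    unimodality or never reaches two modes.
    """
    h = np.asarray(counts, dtype=float)
    for _ in range(max_iter):
        modes = _modes(h)
        if len(modes) == 2:
            return int(modes[0]), int(modes[1]), h
        if len(modes) < 2:
            raise ThresholdConvergenceError(
                f"histogram became unimodal before bimodality was reached "
                f"({len(modes)} modes)",
                histogram=h,
            )
        h = _smooth3(h)
    raise ThresholdConvergenceError(
        f"no bimodal histogram within {max_iter} smoothing iterations",
        histogram=h,
    )


def _intermodes_minimum(counts: np.ndarray, which: str, max_iter: int = 10000) -> int:
    h = counts.astype(float)
    for _ in range(max_iter):
        modes = _modes(h)
        if len(modes) == 2:
            m1, m2 = int(modes[0]), int(modes[1])
            if which == "intermodes":
                return (m1 + m2) // 2
            between = h[m1 : m2 + 1]
            return m1 + int(np.argmin(between))
        if len(modes) < 2:
            raise ThresholdConvergenceError(
                f"histogram became unimodal before bimodality was reached "
                f"({len(modes)} modes)",
                histogram=h,
            )
        h = _smooth3(h)
    raise ThresholdConvergenceError(
        f"no bimodal histogram within {max_iter} smoothing iterations",
        histogram=h,
    )


def threshold_intensity(
    image: np.ndarray, method: str, mask: np.ndarray | None = None
) -> float:
    """Threshold in intensity units: foreground is strictly above it."""
    counts, edges = histogram256(image, mask)
    level = threshold_level(counts, method)
    return level_to_intensity(level, edges)


# ---------------------------------------------------------------------------
# Morphological pre-processing


def _disk_footprint(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    if r <= 0:
        return np.ones((1, 1), dtype=bool)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= radius_px * radius_px


def close_then_filter(
    image: np.ndarray, radius_px: float, despeckle: bool = False
) -> np.ndarray:
    """Grayscale maximum filter then minimum filter with a disk element.

    This morphological closing removes dark specks smaller than the element;
    ``despeckle`` additionally applies a 3×3 median.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    fp = _disk_footprint(radius_px)
    out = ndi.minimum_filter(ndi.maximum_filter(img, footprint=fp), footprint=fp)
    if despeckle:
        out = ndi.median_filter(out, size=3)
    return out


def _despeckle_binary(mask: np.ndarray) -> np.ndarray:
    return ndi.median_filter(mask.astype(np.uint8), size=3) > 0


# ---------------------------------------------------------------------------
# Stage operations


def make_disc_mask(dapi: np.ndarray, params: SegmentationParams,
                   pixel_size_um: float = 1.0) -> BinaryMask:
    """Disc mask: Gaussian blur, triangle-dark threshold, fill holes,
    keep the single largest 8-connected component.

    A second component at ≥ 50 % of the largest's area indicates more than
    one disc in the field, which this pipeline does not support.
    """
    params = params.in_pixels(pixel_size_um)
    blurred = ndi.gaussian_filter(np.asarray(dapi, dtype=float),
                                  sigma=params.dapi_blur_sigma_px)
    thr = threshold_intensity(blurred, params.disc_threshold_method)
    fg = blurred > thr
    if not fg.any():
        raise EmptyMaskError("disc threshold produced an empty mask")
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg, structure=np.ones((3, 3)))
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if len(sizes) > 1 and sizes[order[1]] >= 0.5 * sizes[order[0]]:
        warnings.warn(
            "second disc-sized component found (>= 50% of largest); "
            "multi-disc fields are unsupported — keeping the largest only",
            stacklevel=2,
        )
    keep = int(order[0]) + 1
    return BinaryMask(labels == keep, pixel_size_um)


def make_clone_labels(
    gfp: np.ndarray, disc: BinaryMask, params: SegmentationParams
) -> LabelMap:
    """Clone label map from the clone-marker channel.

    Chain: max/min closing (radius 2) → dark threshold (Otsu by default) →
    despeckle → fill holes → restrict to disc → 8-connected components →
    drop components below ``min_clone_area_um2`` → consecutive relabel.
    Components touching the disc border are flagged in ``border_labels``.
    """
    psz = disc.pixel_size_um
    params = params.in_pixels(psz)
    gfp = np.asarray(gfp, dtype=float)
    if gfp.shape != disc.shape:
        raise ValueError("gfp and disc shapes differ")
    if not disc.pixels.any():
        raise EmptyMaskError("disc mask is empty")
    pre = close_then_filter(gfp, params.clone_filter_radius_px)
    thr = threshold_intensity(pre, params.clone_threshold_method)
    binary = pre > thr
    if params.despeckle:
        binary = _despeckle_binary(binary)
    binary = ndi.binary_fill_holes(binary)
    clipped = binary & disc.pixels
    labels, _ = ndi.label(clipped, structure=np.ones((3, 3)))
    min_px = params.min_clone_area_um2 / psz**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    relabel = np.zeros(counts.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1)
    out = relabel[labels]
    border = _border_touching(out, disc.pixels)
    return LabelMap(out, psz, border_labels=border)


def _border_touching(labels: np.ndarray, disc: np.ndarray) -> frozenset[int]:
    """Labels adjacent (8-conn) to outside-disc pixels or the image edge."""
    outside = ~disc
    near_out = ndi.binary_dilation(outside, structure=np.ones((3, 3)))
    edge = np.zeros_like(disc)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    touching = np.unique(labels[(near_out | edge) & (labels > 0)])
    return frozenset(int(t) for t in touching)


def detect_particles(
    cdcp1: np.ndarray, disc: BinaryMask, params: SegmentationParams
) -> BinaryMask:
    """Apoptotic particle mask from the cleaved-Dcp1 channel.

    Radius-1 closing, then an intermodes-dark threshold computed on
    within-disc pixels only — set so only high-intensity puncta are kept —
    and restriction of the binary mask to the disc.  The optional
    ``particle_threshold_multiplier`` scales the automatic threshold, the
    programmatic analogue of the manual nudge a human operator applies.
    """
    psz = disc.pixel_size_um
    params = params.in_pixels(psz)
    cdcp1 = np.asarray(cdcp1, dtype=float)
    if cdcp1.shape != disc.shape:
        raise ValueError("cdcp1 and disc shapes differ")
    pre = close_then_filter(cdcp1, params.particle_filter_radius_px)
    counts, edges = histogram256(pre, mask=disc.pixels)
    if params.particle_threshold_method in ("intermodes", "minimum"):
        # a puncta-free field smooths to a unimodal histogram, or to two
        # barely-separated noise modes; require real bimodality before
        # calling anything a particle
        try:
            m1, m2, _ = smoothed_bimodal_modes(counts)
        except ThresholdConvergenceError:
            m1 = m2 = 0
        if m2 - m1 < MIN_PARTICLE_MODE_SEPARATION:
            warnings.warn(
                f"particle histogram modes separated by only {m2 - m1} of "
                f"256 levels: treating field as particle-free",
                stacklevel=2,
            )
            return BinaryMask(np.zeros(disc.shape, dtype=bool), psz)
    try:
        level = threshold_level(counts, params.particle_threshold_method)
    except ThresholdConvergenceError as err:
        raise ThresholdConvergenceError(
            f"particle threshold did not converge: {err}", err.histogram
        ) from err
    thr = level_to_intensity(level, edges) * params.particle_threshold_multiplier
    return BinaryMask((pre > thr) & disc.pixels, psz)
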