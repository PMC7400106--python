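"""Detection of adhered cells in grayscale microscopy frames.

Mirrors the classic ImageJ workflow for counting adhered bacteria in
brightfield frames: invert the image so cells become bright, find local
maxima that stand out from their surroundings by at least a noise tolerance
(an h-maxima / prominence criterion), and count one cell per maximum.
Surface coverage is measured separately by thresholding (Otsu by default)
and reporting the covered-pixel fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .errors import ParameterError
from .kinetics import AdhesionTimeSeries

__all__ = [
    "ImageFrame",
    "DetectionParams",
    "DetectedCells",
    "find_maxima",
    "area_fraction",
    "detect_sequence",
]

_UM2_PER_CM2 = 1.0e8


@dataclass(frozen=True)
class ImageFrame:
    """One 8-bit grayscale frame with its physical pixel size and timestamp."""

    pixels: np.ndarray
    pixel_scale_um: float = 0.61
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError("pixels must be a 2D array")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            elif np.issubdtype(px.dtype, np.unsignedinteger):
                # 16-bit input: rescale linearly to 8 bits.
                warnings.warn("rescaling >8-bit frame to 8-bit", stacklevel=2)
                px = (px.astype(float) / px.max() * 255.0).astype(np.uint8) if px.max() > 0 else px.astype(np.uint8)
            else:
                raise ParameterError("pixels must be 8-bit grayscale (or unsigned int)")
            object.__setattr__(self, "pixels", px)
        if not self.pixel_scale_um > 0:
            raise ParameterError("pixel_scale_um must be > 0")

    @property
    def area_cm2(self) -> float:
        r, c = self.pixels.shape
        return r * c * self.pixel_scale_um**2 / _UM2_PER_CM2


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the maxima detector and coverage threshold.

    noise_tolerance
        Minimum prominence (in intensity units, on the inverted image) for a
        local maximum to count as a cell.
    min_separation
        Minimum distance in pixels between reported maxima; of two closer
        maxima the brighter wins (ties break to the smaller row-major index).
    smooth_sigma
        Gaussian pre-smoothing of the inverted image before maxima
        detection, in pixels.  0 disables.  The noise tolerance should sit
        well above the post-smoothing noise level (roughly
        ``noise_sd / (2 * sqrt(pi) * smooth_sigma)`` for white noise).
    coverage_smooth_sigma
        Lighter smoothing applied before the coverage threshold only.
    """

    noise_tolerance: float = 10.0
    min_separation: float = 3.0
    smooth_sigma: float = 2.0
    area_threshold_method: str = "otsu"
    fixed_threshold: float = 128.0
    coverage_smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_tolerance < 0:
            raise ParameterError("noise_tolerance must be >= 0")
        if self.min_separation < 1:
            raise ParameterError("min_separation must be >= 1")
        if self.smooth_sigma < 0 or self.coverage_smooth_sigma < 0:
            raise ParameterError("smoothing sigmas must be >= 0")
        if self.area_threshold_method not in ("otsu", "fixed"):
            raise ParameterError("area_threshold_method must be 'otsu' or 'fixed'")


@dataclass(frozen=True)
class DetectedCells:
    """Maxima positions for one frame.

    Coordinates are 0-based pixel indices with x = column, y = row and the
    origin at the top-left corner.  ``border`` flags maxima lying within
    ``min_separation`` of a field edge.
    """

    coordinates: np.ndarray  # (n, 2) columns (x_px, y_px)
    density_cells_cm2: float
    border: np.ndarray  # (n,) bool

    @property
    def count(self) -> int:
        return len(self.coordinates)


def find_maxima(frame: ImageFrame, params: DetectionParams | None = None) -> DetectedCells:
    """Detect cells as prominent local maxima of the inverted frame.

    The frame is inverted (cells dark on light background become bright),
    optionally smoothed, and maxima of prominence >= ``noise_tolerance`` are
    extracted with an h-maxima transform.  Plateau maxima are reported at the
    centroid pixel of the plateau.  Maxima closer than ``min_separation``
    pixels are merged, keeping the brighter one.
    """
    params = params or DetectionParams()
    inv = 255.0 - frame.pixels.astype(float)
    if params.smooth_sigma > 0:
        inv = ndimage.gaussian_filter(inv, params.smooth_sigma)

    h = params.noise_tolerance
    if np.ptp(inv) < h or inv.size == 0:
        empty = np.empty((0, 2), dtype=int)
        return DetectedCells(empty, 0.0, np.empty(0, dtype=bool))
    if h > 0:
        mask = morphology.h_maxima(inv, h)
    else:
        mask = morphology.local_maxima(inv)
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        empty = np.empty((0, 2), dtype=int)
        return DetectedCells(empty, 0.0, np.empty(0, dtype=bool))
    centroids = ndimage.center_of_mass(mask, labels, np.arange(1, n_lab + 1))
    peak_vals = ndimage.maximum(inv, labels, np.arange(1, n_lab + 1))

    rows = np.array([int(round(r)) for r, _ in centroids])
    cols = np.array([int(round(c)) for _, c in centroids])
    n_cols_img = frame.pixels.shape[1]
    # brighter first; ties to smaller row-major index
    order = sorted(
        range(n_lab), key=lambda i: (-peak_vals[i], rows[i] * n_cols_img + cols[i])
    )
    kept_r: list[int] = []
    kept_c: list[int] = []
    min_sep_sq = params.min_separation**2
    for i in order:
        r, c = rows[i], cols[i]
        ok = True
        for kr, kc in zip(kept_r, kept_c):
            if (kr - r) ** 2 + (kc - c) ** 2 < min_sep_sq:
                ok = False
                break
        if ok:
            kept_r.append(r)
            kept_c.append(c)
    coords = np.column_stack([np.array(kept_c), np.array(kept_r)]).astype(int)
    # stable output order: row-major
    order2 = np.lexsort((coords[:, 0], coords[:, 1]))
    coords = coords[order2]

    n_rows_img = frame.pixels.shape[0]
    m = params.min_separation
    border = (
        (coords[:, 0] < m)
        | (coords[:, 1] < m)
        | (coords[:, 0] >= n_cols_img - m)
        | (coords[:, 1] >= n_rows_img - m)
    )
    return DetectedCells(coords, len(coords) / frame.area_cm2, border)


def area_fraction(frame: ImageFrame, params: DetectionParams | None = None) -> float:
    """Percentage of the frame area covered by cells.

    The frame is inverted so cells are bright, a threshold is chosen (Otsu on
    the inverted histogram, or ``fixed_threshold``), and the fraction of
    pixels above it is returned as a percentage.  A degenerate
    single-intensity frame yields 0 with a warning.
    """
    params = params or DetectionParams()
    inv = 255.0 - frame.pixels.astype(float)
    if params.coverage_smooth_sigma > 0:
        inv = ndimage.gaussian_filter(inv, params.coverage_smooth_sigma)
    if params.area_threshold_method == "otsu":
        if np.ptp(inv) == 0:
            warnings.warn("single-intensity image: Otsu threshold undefined, coverage 0", stacklevel=2)
            return 0.0
        thr = threshold_otsu(inv)
    else:
        thr = 255.0 - params.fixed_threshold
    return float(np.mean(inv > thr)) * 100.0


def detect_sequence(
    frames: Sequence[ImageFrame], params: DetectionParams | None = None
) -> AdhesionTimeSeries:
    """Count cells in a time-ordered frame sequence.

    Returns the adhered-cell surface density (cells/cm^2) at each frame
    timestamp.  Frame timestamps must be strictly increasing.
    """
    if len(frames) == 0:
        raise ParameterError("detect_sequence requires at least one frame")
    times = np.array([f.timestamp_s for f in frames], dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ParameterError(
            f"frame timestamps must be strictly increasing; violation at index {bad[0] + 1}"
        )
    densities = np.array([find_maxima(f, params).density_cells_cm2 for f in frames])
    return AdhesionTimeSeries(times_s=times, densities=densities)
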