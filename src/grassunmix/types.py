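"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Map coordinates: x increases east, y increases north. Pixel (row 0, col 0)
  sits at the north-west corner of the grid; ``origin_xy`` is the map
  coordinate of that corner (not of the pixel centre).
* Point-in-pixel lookup uses half-open cells: a point on a shared edge
  belongs to the cell to its south-east.
* Band and pixel indices are 0-based everywhere internally; 1-based inclusive
  ranges appear only at the configuration surface (see :mod:`.preprocess`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError

#: Scale factor used when reflectance is stored as integers on disk.
REFLECTANCE_SCALE = 10_000

#: No-data sentinel in scaled-integer storage units (sentinel / scale in
#: unscaled reflectance).
NODATA_SENTINEL = -9999


@dataclass
class SpectralCube:
    """A hyperspectral reflectance cube with validity masks and georeferencing.

    Parameters
    ----------
    reflectance : ndarray, shape (rows, cols, bands)
        Unitless surface reflectance on a 0-1 scale (already unscaled).
    wavelengths_nm : ndarray, shape (bands,)
        Strictly increasing band-centre wavelengths.
    band_valid : ndarray of bool, shape (bands,)
        False for bands excluded from analysis (water absorption, noise).
    pixel_valid : ndarray of bool, shape (rows, cols)
        False for no-data / invalid-reflectance / clipped-out pixels.
    pixel_size_m : float
        Ground sampling distance; 1.0 for NEON-like scenes.
    origin_xy : tuple of float
        Map coordinate of the outer north-west corner of pixel (0, 0).
    crs_label : str
        Free-text coordinate-system tag.
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    band_valid: np.ndarray = None
    pixel_valid: np.ndarray = None
    pixel_size_m: float = 1.0
    origin_xy: tuple = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise DataError("reflectance must be a rows x cols x bands array")
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        rows, cols, bands = self.reflectance.shape
        if self.wavelengths_nm.shape != (bands,):
            raise DataError(
                f"wavelength count {self.wavelengths_nm.size} does not match "
                f"band dimension {bands}"
            )
        if bands > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DataError("wavelengths must be strictly increasing")
        if self.band_valid is None:
            self.band_valid = np.ones(bands, dtype=bool)
        else:
            self.band_valid = np.asarray(self.band_valid, dtype=bool).reshape(bands)
        if self.pixel_valid is None:
            self.pixel_valid = np.ones((rows, cols), dtype=bool)
        else:
            self.pixel_valid = np.asarray(self.pixel_valid, dtype=bool)
            if self.pixel_valid.shape != (rows, cols):
                raise DataError("pixel_valid shape does not match cube")
        if not self.pixel_size_m > 0:
            raise DataError("pixel_size_m must be positive")

    @property
    def shape(self):
        return self.reflectance.shape

    @property
    def n_rows(self):
        return self.reflectance.shape[0]

    @property
    def n_cols(self):
        return self.reflectance.shape[1]

    @property
    def n_bands(self):
        return self.reflectance.shape[2]

    def copy(self) -> "SpectralCube":
        return SpectralCube(
            reflectance=self.reflectance.copy(),
            wavelengths_nm=self.wavelengths_nm.copy(),
            band_valid=self.band_valid.copy(),
            pixel_valid=self.pixel_valid.copy(),
            pixel_size_m=self.pixel_size_m,
            origin_xy=tuple(self.origin_xy),
            crs_label=self.crs_label,
        )

    def pixel_center_xy(self, row, col):
        """Map coordinates of a pixel centre (scalar or array indices)."""
        x0, y0 = self.origin_xy
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size_m
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size_m
        return x, y

    def rowcol_of_xy(self, x, y):
        """Half-open point-to-pixel lookup (edge points go south-east)."""
        x0, y0 = self.origin_xy
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.pixel_size_m)
        row = np.floor((y0 - np.asarray(y, dtype=float)) / self.pixel_size_m)
        return row.astype(int), col.astype(int)


@dataclass
class EndmemberLibrary:
    """K class mean spectra on a shared wavelength axis.

    ``provenance`` optionally carries, per class, the ROI identifier, the
    number of contributing pixels, and the per-band standard deviation.
    """

    spectra: np.ndarray  # (K, B)
    class_names: Sequence[str]
    wavelengths_nm: np.ndarray  # (B,)
    band_valid: np.ndarray = None  # (B,) bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.class_names = list(self.class_names)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        k, b = self.spectra.shape
        if len(self.class_names) != k:
            raise DataError("class_names length does not match spectra rows")
        if len(set(self.class_names)) != k:
            raise DataError("class names must be unique")
        if self.wavelengths_nm.shape != (b,):
            raise DataError("wavelength axis does not match spectra columns")
        if self.band_valid is None:
            self.band_valid = np.ones(b, dtype=bool)
        else:
            self.band_valid = np.asarray(self.band_valid, dtype=bool).reshape(b)

    @property
    def n_classes(self):
        return self.spectra.shape[0]

    @property
    def n_bands(self):
        return self.spectra.shape[1]


@dataclass
class FractionStack:
    """Per-pixel fractional abundances for K classes plus residual RMSE.

    ``mode`` records the constraint regime the fractions were solved under:
    ``"ols"`` (unconstrained), ``"sto"`` (sum-to-one), ``"nnls"``
    (non-negative), or ``"fcls"`` (both).
    """

    fractions: np.ndarray  # (K, rows, cols)
    class_names: Sequence[str]
    residual_rmse: np.ndarray = None  # (rows, cols)
    mode: str = "fcls"
    pixel_valid: np.ndarray = None  # (rows, cols) bool
    pixel_size_m: float = 1.0
    origin_xy: tuple = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.ndim != 3:
            raise DataError("fractions must be a K x rows x cols array")
        self.class_names = list(self.class_names)
        k, rows, cols = self.fractions.shape
        if len(self.class_names) != k:
            raise DataError("class_names length does not match fraction layers")
        if self.pixel_valid is None:
            self.pixel_valid = np.ones((rows, cols), dtype=bool)
        else:
            self.pixel_valid = np.asarray(self.pixel_valid, dtype=bool)
            if self.pixel_valid.shape != (rows, cols):
                raise DataError("pixel_valid shape does not match fractions")
        if self.residual_rmse is None:
            self.residual_rmse = np.zeros((rows, cols))
        else:
            self.residual_rmse = np.asarray(self.residual_rmse, dtype=np.float64)
            if self.residual_rmse.shape != (rows, cols):
                raise DataError("residual_rmse shape does not match fractions")

    @property
    def n_classes(self):
        return self.fractions.shape[0]

    @property
    def shape(self):
        return self.fractions.shape[1:]

    def layer(self, class_name: str) -> np.ndarray:
        return self.fractions[self.class_names.index(class_name)]

    def rowcol_of_xy(self, x, y):
        x0, y0 = self.origin_xy
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.pixel_size_m)
        row = np.floor((y0 - np.asarray(y, dtype=float)) / self.pixel_size_m)
        return row.astype(int), col.astype(int)


@dataclass
class RegionSet:
    """Labelled polygons in map coordinates (shapely geometries)."""

    polygons: list
    labels: list

    def __post_init__(self):
        if len(self.polygons) != len(self.labels):
            raise DataError("polygons and labels must have equal length")
        for i, (poly, label) in enumerate(zip(self.polygons, self.labels)):
            if not label:
                raise DataError(f"empty label for polygon {i}")
            coords = list(poly.exterior.coords)
            if len(set(coords)) < 3:
                raise DataError(f"polygon {i} has fewer than 3 distinct vertices")

    def __len__(self):
        return len(self.polygons)


@dataclass
class ReferencePoints:
    """Class-labelled validation points in map coordinates."""

    x: np.ndarray
    y: np.ndarray
    labels: list
    class_list: list = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.labels = list(self.labels)
        if not (self.x.size == self.y.size == len(self.labels)):
            raise DataError("x, y and labels must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError("point coordinates must be finite")
        if self.class_list is not None:
            bad = [
                (i, lab)
                for i, lab in enumerate(self.labels)
                if lab not in self.class_list
            ]
            if bad:
                i, lab = bad[0]
                raise DataError(
                    f"label {lab!r} at row {i} is not in the declared class list"
                )

    def __len__(self):
        return len(self.labels)


@dataclass
class TrendRaster:
    """Per-pixel rate of fractional-abundance change between two years."""

    slope: np.ndarray  # (rows, cols), fraction units per year
    year_pair: tuple  # (t1, t2)
    class_name: str = ""
    pixel_valid: np.ndarray = None
    categories: np.ndarray = None  # optional per-pixel int labels

    def __post_init__(self):
        self.slope = np.asarray(self.slope, dtype=np.float64)
        if self.pixel_valid is None:
            self.pixel_valid = np.isfinite(self.slope)
        else:
            self.pixel_valid = np.asarray(self.pixel_valid, dtype=bool)


@dataclass
class HistogramSummary:
    """Equal-width histogram of a fraction map plus summary statistics.

    Carries both the median of the pixel fractions (``median_fraction``) and
    the median of the per-bin tallies (``median_of_counts``); the two are
    easily conflated in published summaries and must stay distinct.
    """

    bin_edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,) ints
    n_valid: int
    mean: float
    sd: float
    median_fraction: float
    median_of_counts: float
    class_name: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)


@dataclass
class ConfusionMatrix:
    """K x K reference-vs-predicted counts (rows = reference class).

    ``n_reference_total`` optionally records the declared size of the
    reference sample when it differs from the cell sum (published matrices
    occasionally print cells that do not tally to the stated sample);
    overall accuracy is computed against it when present.
    """

    counts: np.ndarray  # (K, K) ints
    class_order: list
    n_unclassified: int = 0
    n_reference_total: int = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise DataError("confusion counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TestResult:
    """Outcome of a statistical test (Wilcoxon V or Shapiro-Wilk W)."""

    statistic_name: str  # "V" or "W"
    statistic: float
    p_two_sided: float
    n_effective: int
    method: str  # "exact" or "approximate"
    notes: str = ""
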