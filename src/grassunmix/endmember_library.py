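"""Endmember construction from labelled regions of interest.

Endmembers are supervised ROI means: the per-band arithmetic mean
reflectance over the valid pixels of manually delineated, spectrally
homogeneous polygons — one spectrum per cover class, pooling multiple
regions that share a label. Separability between classes is quantified by
the spectral angle (arccos of the normalised inner product over valid
bands), reported without enforcing a threshold: it is a diagnostic the
analyst inspects, not a gate.
"""

from __future__ import annotations

import numpy as np
import shapely

from .errors import DataError, NumericalError
from .types import EndmemberLibrary, RegionSet, SpectralCube

__all__ = [
    "extract_mean_spectrum",
    "build_library",
    "spectral_angle",
    "separability_matrix",
    "region_pixel_mask",
]


def region_pixel_mask(cube: SpectralCube, polygon) -> np.ndarray:
    """Boolean mask of cube pixels whose centres fall inside a polygon."""
    rr, cc = np.meshgrid(
        np.arange(cube.n_rows), np.arange(cube.n_cols), indexing="ij"
    )
    x, y = cube.pixel_center_xy(rr.ravel(), cc.ravel())
    return shapely.contains_xy(polygon, x, y).reshape(cube.n_rows, cube.n_cols)


def extract_mean_spectrum(cube: SpectralCube, region):
    """Per-band mean reflectance over the valid pixels of a region.

    ``region`` is either a shapely polygon or a boolean pixel mask.
    Returns ``(spectrum, n_pixels, per_band_sd)`` for the provenance
    record; the sd uses the population convention (ddof=0) and is 0 for a
    single-pixel region.
    """
    if isinstance(region, np.ndarray):
        mask = region.astype(bool)
        if mask.shape != (cube.n_rows, cube.n_cols):
            raise DataError("region mask shape does not match the cube")
    else:
        mask = region_pixel_mask(cube, region)
    mask = mask & cube.pixel_valid
    n = int(mask.sum())
    if n == 0:
        raise DataError("region contains no valid pixels")
    pixels = cube.reflectance[mask]  # (n, B)
    return pixels.mean(axis=0), n, pixels.std(axis=0, ddof=0)


def build_library(
    cube: SpectralCube, regions: RegionSet, class_order=None
) -> EndmemberLibrary:
    """One mean spectrum per label; regions sharing a label are pooled.

    Pooling happens at the pixel level (all pixels of all same-label
    regions enter one mean), which equals the pixel-count-weighted mean of
    the individual region means. Library rows follow ``class_order`` if
    given, else first appearance order.
    """
    if class_order is None:
        class_order = list(dict.fromkeys(regions.labels))
    else:
        class_order = list(class_order)
        unknown = set(regions.labels) - set(class_order)
        if unknown:
            raise DataError(f"labels {sorted(unknown)} missing from class_order")
    if len(class_order) < 2:
        raise DataError("need at least 2 distinct labels to build a library")

    spectra, provenance = [], {}
    for label in class_order:
        mask = np.zeros((cube.n_rows, cube.n_cols), dtype=bool)
        region_ids = []
        for i, (poly, lab) in enumerate(zip(regions.polygons, regions.labels)):
            if lab == label:
                mask |= region_pixel_mask(cube, poly)
                region_ids.append(i)
        if not region_ids:
            raise DataError(f"no region carries label {label!r}")
        try:
            mean, n, sd = extract_mean_spectrum(cube, mask)
        except DataError:
            raise DataError(f"label {label!r} has zero valid pixels after masking")
        spectra.append(mean)
        provenance[label] = {"roi_ids": region_ids, "n_pixels": n, "band_sd": sd}
    return EndmemberLibrary(
        spectra=np.vstack(spectra),
        class_names=class_order,
        wavelengths_nm=cube.wavelengths_nm.copy(),
        band_valid=cube.band_valid.copy(),
        provenance=provenance,
    )


def spectral_angle(s1, s2, band_valid=None) -> float:
    """Angle between two spectra over the shared valid bands, in radians.

    Scale-invariant; lies in [0, pi/2] for non-negative spectra.
    """
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    if band_valid is not None:
        valid = np.asarray(band_valid, dtype=bool)
        s1, s2 = s1[valid], s2[valid]
    n1, n2 = np.linalg.norm(s1), np.linalg.norm(s2)
    if n1 == 0 or n2 == 0:
        raise NumericalError("spectral angle undefined for a zero-norm spectrum")
    return float(np.arccos(np.clip(s1 @ s2 / (n1 * n2), -1.0, 1.0)))


def separability_matrix(lib: EndmemberLibrary) -> np.ndarray:
    """Symmetric K x K matrix of pairwise spectral angles (zero diagonal)."""
    k = lib.n_classes
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = spectral_angle(
                lib.spectra[i], lib.spectra[j], lib.band_valid
            )
    return out
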