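"""Masking, band exclusion and AOI clipping for reflectance cubes.

Preprocessing never alters reflectance values — it only flips validity
flags — so the operations are idempotent and commute. Band indices at this
surface are 1-based inclusive, matching how band ranges are quoted in the
hyperspectral literature; they are converted to 0-based half-open
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import DataError
from .types import RegionSet, SpectralCube, NODATA_SENTINEL, REFLECTANCE_SCALE

__all__ = [
    "WATER_BAND_PRESETS",
    "mask_invalid",
    "exclude_bands",
    "clip_to_polygon",
]

#: Named water-absorption window presets (1-based inclusive band ranges).
#: "default" is the band-selection variant; "alternate" the unmixing-stage
#: variant quoted elsewhere in the source study.
WATER_BAND_PRESETS = {
    "default": ((192, 212), (282, 314)),
    "alternate": ((190, 211), (281, 314)),
}


@dataclass
class MaskReport:
    """Outcome of a masking step."""

    cube: SpectralCube
    n_newly_masked: int = 0
    n_valid_bands: int = None
    area_ha: float = None


def mask_invalid(
    cube: SpectralCube,
    sentinel: float = NODATA_SENTINEL,
    min_valid: float = 0.0,
) -> MaskReport:
    """Flag pixels containing the no-data sentinel or sub-threshold values.

    ``sentinel`` is given in scaled-integer storage units (default -9999)
    and compared against the unscaled reflectance; any band strictly below
    ``min_valid`` (default 0: negative reflectance is physically invalid)
    also invalidates its pixel. Only currently valid bands are examined —
    garbage in an already-excluded water-absorption band must not condemn
    the pixel — so exclude noisy bands before masking. Reflectance data
    are untouched.
    """
    out = cube.copy()
    sentinel_reflectance = sentinel / REFLECTANCE_SCALE
    data = out.reflectance[:, :, out.band_valid]
    hit_sentinel = np.isclose(data, sentinel_reflectance, atol=0.5 / REFLECTANCE_SCALE)
    below = data < min_valid
    bad_pixel = np.any(hit_sentinel | below, axis=2)
    newly = int(np.count_nonzero(bad_pixel & out.pixel_valid))
    out.pixel_valid &= ~bad_pixel
    return MaskReport(cube=out, n_newly_masked=newly)


def _ranges_to_mask(ranges, n_bands):
    mask = np.zeros(n_bands, dtype=bool)
    for lo, hi in ranges:
        if not (1 <= lo <= hi <= n_bands):
            raise DataError(
                f"band range ({lo}, {hi}) outside the valid span 1..{n_bands}"
            )
        mask[lo - 1 : hi] = True  # 1-based inclusive -> 0-based half-open
    return mask


def exclude_bands(cube: SpectralCube, ranges) -> MaskReport:
    """Invalidate bands in the given 1-based inclusive index ranges.

    Bands are masked, not deleted: the wavelength axis is unchanged.
    Raises if the exclusions would leave no valid band.
    """
    out = cube.copy()
    excluded = _ranges_to_mask(ranges, out.n_bands)
    out.band_valid &= ~excluded
    n_valid = int(out.band_valid.sum())
    if n_valid == 0:
        raise DataError("all bands excluded")
    return MaskReport(cube=out, n_valid_bands=n_valid)


def clip_to_polygon(
    cube: SpectralCube, aoi: RegionSet, crop: bool = False
) -> MaskReport:
    """Keep only pixels whose centres fall inside the AOI polygon.

    Containment is tested at pixel centres (strict interior). With
    ``crop=True`` the cube is additionally cropped to the bounding window
    of the surviving pixels. The retained area is reported in hectares.
    """
    if len(aoi) != 1:
        raise DataError("clip_to_polygon expects exactly one AOI polygon")
    poly = aoi.polygons[0]
    out = cube.copy()
    rows, cols = out.n_rows, out.n_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = out.pixel_center_xy(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(poly, x, y).reshape(rows, cols)
    if not inside.any():
        raise DataError("AOI polygon does not overlap the cube extent")
    out.pixel_valid &= inside
    if crop:
        keep_r = np.flatnonzero(inside.any(axis=1))
        keep_c = np.flatnonzero(inside.any(axis=0))
        r0, r1 = keep_r[0], keep_r[-1] + 1
        c0, c1 = keep_c[0], keep_c[-1] + 1
        out = SpectralCube(
            reflectance=out.reflectance[r0:r1, c0:c1],
            wavelengths_nm=out.wavelengths_nm,
            band_valid=out.band_valid,
            pixel_valid=out.pixel_valid[r0:r1, c0:c1],
            pixel_size_m=out.pixel_size_m,
            origin_xy=(
                out.origin_xy[0] + c0 * out.pixel_size_m,
                out.origin_xy[1] - r0 * out.pixel_size_m,
            ),
            crs_label=out.crs_label,
        )
    area_ha = float(out.pixel_valid.sum()) * out.pixel_size_m**2 / 10_000.0
    return MaskReport(cube=out, area_ha=area_ha)
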