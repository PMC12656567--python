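"""Two-date per-pixel trend analysis of fractional abundance.

With exactly two acquisition years the least-squares slope through the two
points reduces exactly to the difference quotient (f2 - f1) / (t2 - t1),
in fraction units per year. The default category breaks
(-0.085, -0.036, 0.037) partition the slope axis into decline / moderate
decline / moderate gain / gain bands used for trend mapping of
2018-to-2022 change (denominator 4 years, so slopes lie in +/-0.25 for
fractions in [0, 1]).
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .types import TrendRaster

__all__ = ["DEFAULT_TREND_BREAKS", "DEFAULT_TREND_LABELS", "slope_map",
           "classify_trend", "trend_summary"]

DEFAULT_TREND_BREAKS = (-0.085, -0.036, 0.037)
DEFAULT_TREND_LABELS = ("decline", "moderate_decline", "moderate_gain", "gain")


def slope_map(f1, f2, t1: int, t2: int, pixel_valid=None, class_name="") -> TrendRaster:
    """Per-pixel slope (f2 - f1) / (t2 - t1) between two co-registered maps."""
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise DataError("fraction maps are not co-registered (shape mismatch)")
    if not t2 > t1:
        raise DataError("t2 must be later than t1")
    valid = np.isfinite(f1) & np.isfinite(f2)
    if pixel_valid is not None:
        valid &= np.asarray(pixel_valid, dtype=bool)
    slope = np.full(f1.shape, np.nan)
    slope[valid] = (f2[valid] - f1[valid]) / float(t2 - t1)
    return TrendRaster(
        slope=slope,
        year_pair=(t1, t2),
        class_name=class_name,
        pixel_valid=valid,
    )


def classify_trend(
    trend: TrendRaster,
    breaks=DEFAULT_TREND_BREAKS,
    labels=DEFAULT_TREND_LABELS,
):
    """Assign each valid pixel to a slope category (lower-inclusive).

    ``breaks`` are strictly increasing thresholds defining len(breaks)+1
    half-open intervals covering the whole real line; a slope exactly at a
    break belongs to the upper interval. Returns ``(category_raster,
    counts)`` where the raster holds interval indices (-1 for invalid) and
    counts maps label -> pixel tally.
    """
    breaks = np.asarray(breaks, dtype=np.float64)
    if np.any(np.diff(breaks) <= 0):
        raise DataError("breaks must be strictly increasing")
    if len(labels) != breaks.size + 1:
        raise DataError("need exactly one label more than breaks")
    cat = np.full(trend.slope.shape, -1, dtype=np.int64)
    valid = trend.pixel_valid
    cat[valid] = np.searchsorted(breaks, trend.slope[valid], side="right")
    counts = {lab: int(np.count_nonzero(cat == i)) for i, lab in enumerate(labels)}
    return cat, counts


def trend_summary(trend: TrendRaster, ddof: int = 1):
    """Mean and standard deviation of slope over valid pixels.

    ``ddof=1`` (sample sd) by default; pass 0 for the population
    convention.
    """
    vals = trend.slope[trend.pixel_valid]
    if vals.size == 0:
        raise DataError("no valid pixels in trend raster")
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    return float(vals.mean()), sd
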