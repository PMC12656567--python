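"""Histogram, category and hectare summaries of fraction maps.

All binning is lower-inclusive: a fraction exactly on a bin edge or
category break belongs to the upper interval (except 1.0, which closes the
last histogram bin). For a sum-to-one fraction stack the per-class
weighted areas obey an exact conservation law — they sum to the total
valid area — which downstream checks rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .types import FractionStack, HistogramSummary

__all__ = [
    "DEFAULT_CATEGORY_BREAKS",
    "ABUNDANCE_CATEGORY_LABELS",
    "histogram_counts",
    "median_of_counts",
    "categorize_abundance",
    "weighted_area_ha",
    "stack_area_report",
    "histogram_table",
]

#: Low / medium / high abundance categories: low [0, 0.3), medium
#: [0.3, 0.6), high [0.6, 1].
DEFAULT_CATEGORY_BREAKS = (0.3, 0.6)
ABUNDANCE_CATEGORY_LABELS = ("low", "medium", "high")


def _valid_fractions(frac_map, pixel_valid):
    frac_map = np.asarray(frac_map, dtype=np.float64)
    if pixel_valid is None:
        valid = np.isfinite(frac_map)
    else:
        valid = np.asarray(pixel_valid, dtype=bool) & np.isfinite(frac_map)
    return frac_map[valid]


def histogram_counts(
    frac_map, n_bins: int = 10, pixel_valid=None, class_name: str = ""
) -> HistogramSummary:
    """Equal-width histogram of a fraction map over [0, 1].

    Bins are left-closed right-open except the last, which is closed at 1.
    Invalid pixels are excluded; values outside [0, 1] raise.
    """
    if n_bins < 1:
        raise DataError("n_bins must be at least 1")
    vals = _valid_fractions(frac_map, pixel_valid)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise DataError("fraction values outside [0, 1]")
    idx = np.minimum(np.floor(vals * n_bins).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return HistogramSummary(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        counts=counts,
        n_valid=int(vals.size),
        mean=float(vals.mean()) if vals.size else float("nan"),
        sd=float(vals.std(ddof=0)) if vals.size else float("nan"),
        median_fraction=float(np.median(vals)) if vals.size else float("nan"),
        median_of_counts=float(np.median(counts)),
        class_name=class_name,
    )


def median_of_counts(hist: HistogramSummary, integer: bool = False):
    """Median of the per-bin tallies (NOT of the pixel fractions).

    With an even number of bins the median is the mean of the two central
    tallies; when ``integer`` is requested, half-integers round half away
    from zero.
    """
    if hist.counts.size < 1:
        raise DataError("histogram has no bins")
    med = float(np.median(hist.counts))
    if integer:
        return int(np.floor(med + 0.5)) if med >= 0 else int(np.ceil(med - 0.5))
    return med


def categorize_abundance(
    frac_map,
    breaks=DEFAULT_CATEGORY_BREAKS,
    labels=ABUNDANCE_CATEGORY_LABELS,
    pixel_valid=None,
):
    """Assign each valid pixel to an abundance category (lower-inclusive).

    Returns ``(category_raster, counts)``; the raster holds interval
    indices (-1 for invalid pixels).
    """
    breaks = np.asarray(breaks, dtype=np.float64)
    if np.any(np.diff(breaks) <= 0):
        raise DataError("breaks must be strictly increasing")
    if np.any(breaks <= 0) or np.any(breaks >= 1):
        raise DataError("category breaks must lie strictly inside (0, 1)")
    if len(labels) != breaks.size + 1:
        raise DataError("need exactly one label more than breaks")
    frac_map = np.asarray(frac_map, dtype=np.float64)
    valid = (
        np.isfinite(frac_map)
        if pixel_valid is None
        else np.asarray(pixel_valid, bool) & np.isfinite(frac_map)
    )
    cat = np.full(frac_map.shape, -1, dtype=np.int64)
    cat[valid] = np.searchsorted(breaks, frac_map[valid], side="right")
    counts = {lab: int(np.count_nonzero(cat == i)) for i, lab in enumerate(labels)}
    return cat, counts


def weighted_area_ha(frac_map, pixel_area_m2: float = 1.0, pixel_valid=None) -> float:
    """Fraction-weighted area in hectares: sum(fraction) * pixel area / 1e4."""
    if not pixel_area_m2 > 0:
        raise DataError("pixel_area_m2 must be positive")
    vals = _valid_fractions(frac_map, pixel_valid)
    return float(vals.sum() * pixel_area_m2 / 10_000.0)


def stack_area_report(stack: FractionStack) -> pd.DataFrame:
    """Per-class weighted areas (ha) of a fraction stack.

    For sum-to-one stacks the class areas sum to the total valid area.
    """
    pixel_area = stack.pixel_size_m**2
    rows = [
        {
            "class": name,
            "area_ha": weighted_area_ha(
                stack.fractions[i], pixel_area, stack.pixel_valid
            ),
        }
        for i, name in enumerate(stack.class_names)
    ]
    return pd.DataFrame(rows)


def histogram_table(histograms) -> pd.DataFrame:
    """Wide CSV-ready table: bins as rows, one count column per histogram.

    Appends a ``median_of_counts`` row mirroring published bin-count
    summaries. All histograms must share a bin structure.
    """
    if not histograms:
        raise DataError("no histograms given")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if not np.allclose(h.bin_edges, edges):
            raise DataError("histograms have mismatched bin structure")
    table = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
        }
    )
    for h in histograms:
        table[h.class_name or f"hist_{histograms.index(h)}"] = h.counts
    med = {"bin_low": np.nan, "bin_high": np.nan}
    for h in histograms:
        med[h.class_name or f"hist_{histograms.index(h)}"] = median_of_counts(h)
    return pd.concat([table, pd.DataFrame([med])], ignore_index=True)
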