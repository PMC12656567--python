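"""Packaged reference tables from the original rangeland field study.

Small CSV fixtures shipped with the package:

* ``abundance_bin_counts.csv`` — per-bin pixel tallies (ten equal-width
  fractional-abundance bins, 0 to 1) for herbaceous, mixed-forb and
  bare-soil cover in 2018 and 2022 at a semi-arid Oklahoma rangeland site.
* ``confusion_threshold50.csv`` / ``confusion_threshold75.csv`` — published
  reference-vs-predicted confusion matrices from the UAV-based validation of
  the 2022 unmixing map, thresholded at 50% and 75% fractional abundance.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from ..types import ConfusionMatrix, HistogramSummary

__all__ = [
    "load_abundance_bin_counts",
    "bin_count_histogram",
    "load_reference_confusion",
    "COVER_CLASSES",
    "YEARS",
]

COVER_CLASSES = ("herbaceous", "forbs", "bare_soil")
YEARS = (2018, 2022)


def _data_path(name: str):
    return files(__package__).joinpath(name)


def load_abundance_bin_counts() -> pd.DataFrame:
    """Per-bin pixel counts, one column per cover class and year."""
    with _data_path("abundance_bin_counts.csv").open() as fh:
        return pd.read_csv(fh)


def bin_count_histogram(cover_class: str, year: int) -> HistogramSummary:
    """The packaged bin counts for one class-year as a HistogramSummary.

    Pixel-level mean/sd/median are not recoverable from bin tallies alone
    and are reported as NaN; only the counts and bin structure are real.
    """
    table = load_abundance_bin_counts()
    column = f"{cover_class}_{year}"
    if column not in table.columns:
        raise KeyError(f"no packaged column {column!r}")
    counts = table[column].to_numpy(dtype=np.int64)
    edges = np.concatenate([table["bin_low"].to_numpy(), [table["bin_high"].iloc[-1]]])
    med_counts = float(np.median(counts))
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        n_valid=int(counts.sum()),
        mean=float("nan"),
        sd=float("nan"),
        median_fraction=float("nan"),
        median_of_counts=med_counts,
        class_name=f"{cover_class}_{year}",
    )


def load_reference_confusion(threshold: float) -> ConfusionMatrix:
    """Published confusion matrix for the 50% or 75% abundance threshold.

    The validation campaign declared 150 reference points (50 per class);
    the 75%-threshold matrix's printed cells sum to 154, so the declared
    total is carried explicitly and overall accuracy is computed against
    it, matching the published percentages.
    """
    name = {0.5: "confusion_threshold50.csv", 0.75: "confusion_threshold75.csv"}
    if threshold not in name:
        raise KeyError("packaged confusion matrices exist for thresholds 0.5 and 0.75")
    with _data_path(name[threshold]).open() as fh:
        table = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(
        counts=table.to_numpy(dtype=np.int64),
        class_order=list(table.columns),
        n_reference_total=150,
    )
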