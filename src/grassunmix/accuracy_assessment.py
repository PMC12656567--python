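"""Threshold-based accuracy assessment of fraction maps.

A reference point is predicted as the class whose fraction at the point's
pixel reaches the presence threshold tau (commonly 0.5 or 0.75); if no
class qualifies the point is "unclassified" and excluded from the
confusion matrix (counted separately). Metrics follow the row/column
convention of the source study's published tables by default — user's
accuracy = diagonal / reference-row total, producer's = diagonal /
predicted-column total — which is the reverse of the textbook assignment;
``convention="standard"`` swaps them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .types import ConfusionMatrix, FractionStack, ReferencePoints

__all__ = [
    "UNCLASSIFIED",
    "predicted_class_at_points",
    "confusion_matrix",
    "accuracy_metrics",
    "confusion_table",
]

UNCLASSIFIED = "unclassified"


def predicted_class_at_points(
    stack: FractionStack, points: ReferencePoints, tau: float
) -> list:
    """Predicted label at each reference point under threshold tau.

    The prediction is the class whose fraction at the point's pixel is
    >= tau; if several qualify (possible for tau < 0.5 or in
    non-sum-to-one modes), the largest fraction wins with a lexicographic
    tie-break on the class name. Points where no class qualifies map to
    ``UNCLASSIFIED``.
    """
    if not 0 < tau < 1:
        raise DataError("tau must lie in (0, 1)")
    rows, cols = stack.rowcol_of_xy(points.x, points.y)
    h, w = stack.shape
    outside = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if outside.any():
        raise DataError(
            f"point(s) at index {np.flatnonzero(outside).tolist()} fall outside "
            "the raster extent"
        )
    labels = []
    names = stack.class_names
    for r, c in zip(rows, cols):
        if not stack.pixel_valid[r, c]:
            labels.append(UNCLASSIFIED)
            continue
        frac = stack.fractions[:, r, c]
        qualifying = [i for i in range(len(names)) if frac[i] >= tau]
        if not qualifying:
            labels.append(UNCLASSIFIED)
        else:
            # max fraction, then lexicographically smallest name
            best = min(qualifying, key=lambda i: (-frac[i], names[i]))
            labels.append(names[best])
    return labels


def confusion_matrix(reference, predicted, class_order) -> ConfusionMatrix:
    """K x K counts of reference (rows) vs predicted (columns) labels.

    ``UNCLASSIFIED`` predictions are tallied in ``n_unclassified`` and
    excluded from the cells.
    """
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted):
        raise DataError("reference and predicted label sequences differ in length")
    class_order = list(class_order)
    index = {name: i for i, name in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    n_unclassified = 0
    for ref, pred in zip(reference, predicted):
        if ref not in index:
            raise DataError(f"unknown reference label {ref!r}")
        if pred == UNCLASSIFIED:
            n_unclassified += 1
            continue
        if pred not in index:
            raise DataError(f"unknown predicted label {pred!r}")
        counts[index[ref], index[pred]] += 1
    return ConfusionMatrix(
        counts=counts, class_order=class_order, n_unclassified=n_unclassified
    )


def accuracy_metrics(cm: ConfusionMatrix, convention: str = "study"):
    """Overall, user's and producer's accuracy from a confusion matrix.

    Returns ``(overall, users, producers)`` with the per-class values as
    dicts keyed by class name, unrounded. Classes with an empty row or
    column are absent from the corresponding dict rather than reported as
    0. ``convention="study"`` assigns user's = diagonal/row-total and
    producer's = diagonal/column-total (matching the source tables, where
    rows carry the reference points); ``"standard"`` swaps the two.
    """
    if convention not in ("study", "standard"):
        raise DataError("convention must be 'study' or 'standard'")
    total = cm.total
    if total == 0:
        raise DataError("confusion matrix is empty")
    diag = np.diag(cm.counts)
    overall = float(diag.sum() / (cm.n_reference_total or total))
    row_tot = cm.counts.sum(axis=1)
    col_tot = cm.counts.sum(axis=0)
    by_row = {
        name: float(diag[i] / row_tot[i])
        for i, name in enumerate(cm.class_order)
        if row_tot[i] > 0
    }
    by_col = {
        name: float(diag[i] / col_tot[i])
        for i, name in enumerate(cm.class_order)
        if col_tot[i] > 0
    }
    if convention == "study":
        return overall, by_row, by_col
    return overall, by_col, by_row


def confusion_table(cm: ConfusionMatrix, convention: str = "study") -> pd.DataFrame:
    """Confusion matrix as a publishable table with totals and accuracies."""
    overall, users, producers = accuracy_metrics(cm, convention)
    k = len(cm.class_order)
    table = pd.DataFrame(
        cm.counts, index=cm.class_order, columns=cm.class_order
    )
    table["Total"] = cm.counts.sum(axis=1)
    table["UsersAccuracy"] = [users.get(c, np.nan) for c in cm.class_order]
    table["ProducersAccuracy"] = [producers.get(c, np.nan) for c in cm.class_order]
    total_row = {c: int(cm.counts[:, i].sum()) for i, c in enumerate(cm.class_order)}
    total_row.update(
        {"Total": cm.total, "UsersAccuracy": np.nan, "ProducersAccuracy": np.nan}
    )
    table = pd.concat([table, pd.DataFrame([total_row], index=["Total"])])
    table.attrs["overall_accuracy"] = overall
    table.attrs["n_unclassified"] = cm.n_unclassified
    return table
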