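"""Accuracy assessment and area validation.

Map accuracy follows the standard confusion-matrix quartet — user accuracy
(column-wise), producer accuracy (row-wise), overall accuracy (trace) and
Cohen's kappa (chance-corrected, with expected agreement p_e from the
marginals).  Area validation counts maize cells on an equal-area grid and
compares mapped against yearbook areas with the coefficient of
determination R² = 1 - SS_res / SS_tot (the yearbook record is the
reference variable; the squared Pearson correlation is available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .constants import CLASSES, CLASS_CODES
from .types import LabelRaster

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "AreaRecord",
    "confusion_matrix",
    "accuracy_metrics",
    "metrics_from_counts",
    "cross_year_evaluation",
    "cross_year_mean",
    "area_from_map",
    "r_squared",
    "inventory_total",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.845 -> 0.85), as report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are the reference class, columns the prediction."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts must be ({c}, {c}); got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="reference"),
            columns=pd.Index(self.classes, name="predicted"),
        )


@dataclass
class AccuracyReport:
    """The reported quartet for one evaluation (target class: maize)."""

    user_accuracy: float
    producer_accuracy: float
    overall_accuracy: float
    kappa: float
    per_class: dict[str, dict[str, float]] | None = None


def confusion_matrix(reference, predicted, classes=CLASSES) -> ConfusionMatrix:
    """Count reference-vs-predicted labels in the fixed class order."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.size == 0:
        raise ValueError("cannot evaluate empty label lists")
    if reference.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {reference.shape} reference vs "
            f"{predicted.shape} predicted"
        )
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(reference.ravel(), predicted.ravel()):
        if r not in index or p not in index:
            bad = r if r not in index else p
            raise ValueError(f"unknown class label {bad!r}")
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def metrics_from_counts(counts: np.ndarray, target_index: int = 0) -> dict:
    """Vectorized UA/PA/OA/kappa over a stack of matrices shaped (..., C, C).

    Degenerate denominators (empty matrix, empty target row/column, p_e = 1)
    yield NaN for the affected metric.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        trace = np.trace(counts, axis1=-2, axis2=-1)
        oa = np.where(total > 0, trace / np.where(total > 0, total, 1), np.nan)
        rowsum = counts.sum(axis=-1)
        colsum = counts.sum(axis=-2)
        pe = np.where(
            total > 0,
            (rowsum * colsum).sum(axis=-1) / np.where(total > 0, total, 1) ** 2,
            np.nan,
        )
        denom = 1.0 - pe
        kappa = np.where(
            np.abs(denom) > 1e-15, (oa - pe) / np.where(denom != 0, denom, 1), np.nan
        )
        t = target_index
        diag = counts[..., t, t]
        ua = np.where(colsum[..., t] > 0,
                      diag / np.where(colsum[..., t] > 0, colsum[..., t], 1),
                      np.nan)
        pa = np.where(rowsum[..., t] > 0,
                      diag / np.where(rowsum[..., t] > 0, rowsum[..., t], 1),
                      np.nan)
    return {"ua": ua, "pa": pa, "oa": oa, "kappa": kappa, "pe": pe}


def accuracy_metrics(
    cm: ConfusionMatrix, target_class: str = "maize", verbose: bool = False
) -> AccuracyReport:
    """UA/PA (for the target class), OA and kappa from one matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    t = cm.classes.index(target_class)
    m = metrics_from_counts(cm.counts, target_index=t)
    per_class = None
    if verbose:
        per_class = {}
        for i, c in enumerate(cm.classes):
            mi = metrics_from_counts(cm.counts, target_index=i)
            per_class[c] = {
                "user_accuracy": float(mi["ua"]),
                "producer_accuracy": float(mi["pa"]),
            }
    return AccuracyReport(
        user_accuracy=float(m["ua"]),
        producer_accuracy=float(m["pa"]),
        overall_accuracy=float(m["oa"]),
        kappa=float(m["kappa"]),
        per_class=per_class,
    )


def cross_year_evaluation(
    scenarios: dict[int, "object"],
    trainer,
    pairs: list[tuple[int, int]],
) -> pd.DataFrame:
    """Train on one year's samples, test on another's, per ordered pair.

    ``scenarios`` maps year -> Scenario; ``trainer`` maps a record list to
    a fitted zone model (see :mod:`maizemap.classifiers`).  Returns one row
    per pair with the overall accuracy on the *full* test-year sample set.
    """
    from .classifiers import predict_pixels
    from .preprocessing import SequenceFeaturizer
    from .synthetic import generate_sample_set

    if len(pairs) == 0:
        raise ValueError("no train/test year pairs requested")
    for tr, te in pairs:
        if tr == te:
            raise ValueError("train and test years must differ")
        for year in (tr, te):
            if year not in scenarios:
                raise ValueError(f"no scenario for year {year}")
    feats = SequenceFeaturizer(flatten=False)
    samples = {y: generate_sample_set(s) for y, s in scenarios.items()}
    models = {}
    rows = []
    for tr, te in pairs:
        if tr not in models:
            models[tr] = trainer(samples[tr])
        X = feats.transform([series for _, series in samples[te]])
        y_true = np.array([rec.class_label for rec, _ in samples[te]])
        labels, _ = predict_pixels(models[tr], X)
        rows.append(
            {
                "train_year": tr,
                "test_year": te,
                "overall_accuracy": float(np.mean(labels == y_true)),
            }
        )
    return pd.DataFrame(rows)


def cross_year_mean(table: pd.DataFrame, ndigits: int = 2) -> float:
    """Arithmetic mean of the pairwise OAs, half-up rounded for reporting."""
    return round_half_up(float(table["overall_accuracy"].mean()), ndigits)


def area_from_map(raster: LabelRaster, class_label: str = "maize") -> float:
    """Mapped class area in km² (cell count x cell area).

    Emits a warning (and proceeds) when the raster is not flagged as being
    on an equal-area grid.
    """
    import warnings

    if not raster.equal_area:
        warnings.warn(
            "raster is not flagged equal-area; cell-count areas may be biased",
            stacklevel=2,
        )
    n = int(np.count_nonzero(raster.data == CLASS_CODES[class_label]))
    return n * raster.cell_size**2 / 1e6


@dataclass(frozen=True)
class AreaRecord:
    """One province-year mapped-vs-yearbook area pair (km²)."""

    name: str
    year: int
    predicted_area_km2: float
    yearbook_area_km2: float

    def __post_init__(self) -> None:
        if self.predicted_area_km2 < 0 or self.yearbook_area_km2 < 0:
            raise ValueError("areas must be non-negative")


def r_squared(predicted, reference, method: str = "determination") -> float:
    """Agreement of mapped areas with the yearbook reference.

    ``determination``: R² = 1 - SS_res / SS_tot about the reference mean
    (can be negative for poor agreement).  ``pearson``: squared Pearson
    correlation.  NaN when the reference is constant.  Also accepts a list
    of :class:`AreaRecord`.
    """
    if len(predicted) and isinstance(predicted[0], AreaRecord):
        records = predicted
        reference = np.array([r.yearbook_area_km2 for r in records], dtype=float)
        predicted = np.array([r.predicted_area_km2 for r in records], dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D")
    if predicted.size < 3:
        raise ValueError("need at least 3 records for R²")
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    if method == "determination":
        ss_res = float(np.sum((reference - predicted) ** 2))
        return 1.0 - ss_res / ss_tot
    if method == "pearson":
        return float(np.corrcoef(predicted, reference)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")


def inventory_total(inventory: pd.DataFrame) -> int:
    """Sum of all per-zone/year/class/method sample counts (0 when empty)."""
    if len(inventory) == 0:
        return 0
    return int(inventory["count"].sum())
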