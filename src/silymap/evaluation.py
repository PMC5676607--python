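"""Accuracy assessment and model introspection reports.

Provides the validation-set confusion matrix with row percentages (per actual
class, as in the field's standard accuracy-assessment tables), the overall
accuracy, a Hinton-style table of signed first-layer weights, and the
per-feature relevance report pairing each input feature's decay
hyperparameter alpha with its weight-group norm.

Feature display order in reports is Texture, NIR, Red, Green — the reverse of
the storage order — because the texture and NIR features are the scientific
headline; the mapping is explicit in every report header.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ard import HyperparameterSet, MLPARDModel, WeightGroups, forward, group_penalty
from .features import FEATURE_NAMES

__all__ = [
    "ConfusionResult",
    "RelevanceReport",
    "HintonTable",
    "predict_labels",
    "confusion_matrix",
    "overall_accuracy",
    "hinton_export",
    "relevance_report",
    "DISPLAY_ORDER",
]

# report display order (storage order is green, red, nir, texture)
DISPLAY_ORDER = ("texture", "nir", "red", "green")

CLASS_NAMES = {1: "S. marianum", 0: "other vegetation"}


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals, so 99.545... prints as 99.55."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def predict_labels(model: MLPARDModel, features: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels from network outputs; y exactly at threshold goes to class 1.

    ``features`` must already be standardized with the training parameters.
    """
    y = np.atleast_1d(forward(model, features))
    return (y >= threshold).astype(np.int8)


@dataclass(frozen=True)
class ConfusionResult:
    """2x2 actual-by-predicted counts with row percentages.

    Row order and column order are (target weed, other); percentages are
    normalized per actual class ("estimated on actual observation sums") and
    reported half-up to 2 decimals alongside the exact fractions.
    """

    counts: np.ndarray  # (2, 2) int, rows = actual (1, 0), cols = predicted (1, 0)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2 matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def support(self) -> tuple[int, int]:
        """Per-actual-class sample counts (target, other)."""
        return int(self.counts[0].sum()), int(self.counts[1].sum())

    def row_fractions(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(sums > 0, self.counts / sums, 0.0)
        return frac

    def row_percentages(self) -> np.ndarray:
        """Row-normalized percentages, half-up to 2 decimals."""
        return np.vectorize(_round2)(100.0 * self.row_fractions())

    def accuracy_fraction(self) -> float:
        if self.n == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts)) / self.n

    def to_frame(self) -> pd.DataFrame:
        pct = self.row_percentages()
        idx = [CLASS_NAMES[1], CLASS_NAMES[0]]
        df = pd.DataFrame(self.counts, index=idx, columns=[f"pred {c}" for c in idx])
        for j, c in enumerate(idx):
            df[f"pred {c} (%)"] = pct[:, j]
        return df

    def to_text(self) -> str:
        pct = self.row_percentages()
        sup = self.support
        lines = [
            "Confusion matrix (rows = actual, columns = network prediction;",
            "percentages estimated on actual observation sums)",
            f"{'':<20}{CLASS_NAMES[1]:>18}{CLASS_NAMES[0]:>20}",
            f"{CLASS_NAMES[1] + f' ({sup[0]} px)':<24}{pct[0, 0]:>12.2f} %{pct[0, 1]:>16.2f} %",
            f"{CLASS_NAMES[0] + f' ({sup[1]} px)':<24}{pct[1, 0]:>12.2f} %{pct[1, 1]:>16.2f} %",
        ]
        return "\n".join(lines)


def confusion_matrix(actual: np.ndarray, predicted: np.ndarray) -> ConfusionResult:
    """Counts by (actual, predicted) for binary {0, 1} labels.

    Row/column order puts the target weed (t=1) first, matching the layout of
    accuracy tables that list the class of interest on top.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if not (np.isin(actual, (0, 1)).all() and np.isin(predicted, (0, 1)).all()):
        raise ValueError("labels must be binary {0, 1}")
    counts = np.empty((2, 2), dtype=np.int64)
    for i, a in enumerate((1, 0)):
        for j, p in enumerate((1, 0)):
            counts[i, j] = int(np.sum((actual == a) & (predicted == p)))
    return ConfusionResult(counts=counts)


def overall_accuracy(confusion: ConfusionResult) -> float:
    """Overall accuracy percent (diagonal / N), half-up to 2 decimals."""
    return _round2(100.0 * confusion.accuracy_fraction())


@dataclass(frozen=True)
class HintonTable:
    """Signed first-layer weights, rows = input features, columns = hidden units."""

    weights: np.ndarray  # (n, hidden_count)
    feature_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights,
            index=list(self.feature_names),
            columns=[f"h{j}" for j in range(self.weights.shape[1])],
        )

    def to_text(self, width: int = 6) -> str:
        """Text rendering: sign by character (+/-), magnitude by bar length."""
        mags = np.abs(self.weights)
        vmax = mags.max() if mags.size and mags.max() > 0 else 1.0
        lines = ["Hinton table (rows = features, columns = hidden neurons; '+' excitatory, '-' inhibitory)"]
        for name, row in zip(self.feature_names, self.weights):
            cells = []
            for wgt in row:
                nchar = int(round(width * abs(wgt) / vmax))
                sym = "+" if wgt >= 0 else "-"
                cells.append((sym * nchar).ljust(width) or " " * width)
            lines.append(f"{name:>8} | " + " ".join(cells))
        return "\n".join(lines)


def hinton_export(model: MLPARDModel, feature_names=FEATURE_NAMES) -> HintonTable:
    """First-layer weight matrix transposed to feature-major orientation."""
    return HintonTable(weights=model.u.T.copy(), feature_names=tuple(feature_names[: model.n]))


@dataclass(frozen=True)
class RelevanceReport:
    """Per input feature: decay hyperparameter alpha, weight norm, relevance rank.

    alpha and the norm come from the same model snapshot, so the report shows
    the inverse alpha-norm relation directly: suppressed (irrelevant)
    features have large alpha and small group norm. Rank 1 = smallest alpha
    (most relevant); ties are broken by display order.
    """

    table: pd.DataFrame  # index = feature in display order; columns alpha, weight_norm, rank

    def to_text(self) -> str:
        lines = [
            "Feature relevance (display order Texture, NIR, Red, Green;",
            "storage order in the feature stack is green, red, nir, texture)",
            self.table.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)


def relevance_report(
    model: MLPARDModel,
    hyperparameters: HyperparameterSet,
    feature_names=FEATURE_NAMES,
    display_order=DISPLAY_ORDER,
) -> RelevanceReport:
    """Pair each input feature's alpha with its group weight norm (2 E_w)^1/2."""
    groups = WeightGroups.for_network(model.n, model.hidden_count)
    feature_names = tuple(feature_names[: model.n])
    rows = {}
    for k, name in enumerate(feature_names):
        e_w = group_penalty(model, groups, k)
        rows[name] = {
            "alpha": float(hyperparameters.alphas[k]),
            "weight_norm": float(np.sqrt(2.0 * e_w)),
        }
    order = [f for f in display_order if f in rows] + [f for f in feature_names if f not in display_order]
    df = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    # stable sort: ties in alpha resolve by display order
    df["rank"] = df["alpha"].rank(method="first").astype(int)
    return RelevanceReport(table=df)
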