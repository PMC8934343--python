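"""Multiclass evaluation: confusion matrices, macro-averaged performance
measures, and higher-taxon generalization rates.

The four summary measures follow the Sokolova–Lapalme multiclass definitions,
with overall accuracy (trace over total) in place of average accuracy:

    overall accuracy = sum_i tp_i / (tp_i + tn_i + fp_i + fn_i)  = trace / N
    Precision_M      = mean_i tp_i / (tp_i + fp_i)
    Recall_M         = mean_i tp_i / (tp_i + fn_i)
    F-score_M        = (b^2 + 1) P_M R_M / (b^2 P_M + R_M)       (b = 1)

Note the F-score is the harmonic mean of the *macro averages*, not the mean of
per-class F1 values.  A class with an empty prediction (or truth) column
contributes 0 to the macro mean.

Higher-taxon rates score a model trained on a fixed species list against
samples of species it never saw: the fraction of samples whose predicted
species shares the true species' genus (resp. family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "MetricCounts",
    "TaxonTable",
    "confusion",
    "counts_from_confusion",
    "overall_accuracy",
    "macro_precision",
    "macro_recall",
    "f_score",
    "higher_taxon_rates",
    "metrics_report",
]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""

    counts: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Per-true-class accuracy fractions (rows summing to 1; empty rows 0)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        return np.divide(self.counts, sums, out=np.zeros(self.counts.shape), where=sums > 0)

    def to_csv(self, path: str | Path) -> None:
        labels = self.labels or [str(i) for i in range(self.n_classes)]
        pd.DataFrame(self.counts, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), labels=list(df.index.astype(str)))


@dataclass
class MetricCounts:
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


def confusion(true_labels, predicted_labels, n_classes: int,
              labels: list[str] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    counts = _sk_confusion(t, p, labels=np.arange(n_classes))
    return ConfusionMatrix(counts, labels=labels)


def counts_from_confusion(cm: ConfusionMatrix) -> MetricCounts:
    c = cm.counts
    tp = np.diag(c).astype(np.int64)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = cm.total - tp - fn - fp
    return MetricCounts(tp, tn, fp, fn)


def overall_accuracy(mc: MetricCounts) -> float:
    n = mc.total
    if n == 0:
        raise ValueError("no evaluated samples")
    return float(np.sum(mc.tp / (mc.tp + mc.tn + mc.fp + mc.fn)))


def _macro_ratio(num: np.ndarray, denom: np.ndarray) -> float:
    ratios = np.divide(num, denom, out=np.zeros(len(num), dtype=float), where=denom > 0)
    return float(ratios.mean())


def macro_precision(mc: MetricCounts) -> float:
    return _macro_ratio(mc.tp, mc.tp + mc.fp)


def macro_recall(mc: MetricCounts) -> float:
    return _macro_ratio(mc.tp, mc.tp + mc.fn)


def f_score(precision_m: float, recall_m: float, beta: float = 1.0) -> float:
    if precision_m < 0 or recall_m < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision_m == 0 and recall_m == 0:
        warnings.warn("precision and recall both zero; F-score defined as 0")
        return 0.0
    b2 = beta * beta
    return (b2 + 1.0) * precision_m * recall_m / (b2 * precision_m + recall_m)


class TaxonTable:
    """Species -> genus -> family lookup from a 3-column table."""

    def __init__(self, df: pd.DataFrame) -> None:
        cols = ["species", "genus", "family"]
        if not all(c in df.columns for c in cols):
            raise ValueError(f"taxonomy table needs columns {cols}")
        if df[cols].isna().any().any() or (df[cols].astype(str) == "").any().any():
            raise ValueError("taxonomy names must be non-empty")
        self._df = df.set_index("species")[["genus", "family"]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonTable":
        return cls(pd.read_csv(path, sep="\t"))

    def genus(self, species: str) -> str:
        return self._lookup(species, "genus")

    def family(self, species: str) -> str:
        return self._lookup(species, "family")

    def _lookup(self, species: str, rank: str) -> str:
        try:
            return str(self._df.loc[species, rank])
        except KeyError:
            raise KeyError(f"species {species!r} not found in taxonomy table") from None


def higher_taxon_rates(
    predicted_species: list[str],
    true_species: list[str],
    taxa: TaxonTable,
) -> tuple[float, float]:
    """Fractions of samples whose predicted species shares the true species'
    genus and family.  Same-genus <= same-family whenever genera nest in
    families.  Unknown species raise KeyError naming the species."""
    if len(predicted_species) != len(true_species):
        raise ValueError("prediction/truth lengths differ")
    if not predicted_species:
        raise ValueError("no samples")
    genus_hits = sum(
        taxa.genus(p) == taxa.genus(t) for p, t in zip(predicted_species, true_species)
    )
    family_hits = sum(
        taxa.family(p) == taxa.family(t) for p, t in zip(predicted_species, true_species)
    )
    n = len(true_species)
    return genus_hits / n, family_hits / n


def metrics_report(cm: ConfusionMatrix, beta: float = 1.0) -> dict:
    """All four summary measures from one confusion matrix."""
    mc = counts_from_confusion(cm)
    p, r = macro_precision(mc), macro_recall(mc)
    return {
        "overall_accuracy": overall_accuracy(mc),
        "macro_precision": p,
        "macro_recall": r,
        "f_score": f_score(p, r, beta),
        "n_samples": cm.total,
        "n_classes": cm.n_classes,
    }
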