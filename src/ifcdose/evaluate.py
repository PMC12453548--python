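"""Statistical evaluation of dose estimates and the 2 Gy triage layer.

Dose-estimation accuracy is summarized by the root mean squared error
RMSE = sqrt(mean((D_hat_i - D_i)^2)), overall and within true-dose bins,
and by tolerance coverage: the fraction of estimates within +/-0.5 Gy and
+/-1 Gy of the delivered dose (boundaries inclusive).

For population triage, estimates are dichotomized at a threshold (2 Gy by
default, boundary inclusive: an estimate of exactly 2 Gy is positive) and
compared with the same rule applied to the delivered doses, yielding a
confusion matrix with per-class precision and recall and overall accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "ConfusionReport",
    "DEFAULT_BIN_EDGES",
    "rmse",
    "tolerance_coverage",
    "rmse_by_bin",
    "triage_classify",
    "confusion_metrics",
    "evaluate_estimates",
]

#: Default true-dose bins for per-range RMSE reporting (Gy); the last bin is
#: closed at 10 Gy.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)


def _check_pair(estimates, truths):
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape or e.ndim != 1:
        raise ValueError(f"estimates and truths must be equal-length 1-D; got {e.shape} vs {t.shape}")
    if e.size == 0:
        raise ValueError("need at least one estimate")
    return e, t


def rmse(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Root mean squared error of the dose estimates, in Gy."""
    e, t = _check_pair(estimates, truths)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def tolerance_coverage(
    estimates: Sequence[float],
    truths: Sequence[float],
    tolerances: Sequence[float] = (0.5, 1.0),
) -> dict[float, tuple[int, float]]:
    """Per tolerance t: (count, fraction) of |D_hat - D| <= t.

    The boundary counts as within: an estimate exactly 0.5 Gy off is inside
    the +/-0.5 Gy range.
    """
    e, t = _check_pair(estimates, truths)
    out = {}
    for tol in tolerances:
        n_within = int(np.sum(np.abs(e - t) <= tol))
        out[float(tol)] = (n_within, n_within / e.size)
    return out


def rmse_by_bin(
    estimates: Sequence[float],
    truths: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """RMSE within true-dose bins [e0,e1), [e1,e2), ..., [e_{m-1}, e_m].

    Bins with no samples are absent from the table (never reported as zero
    error).  A truth outside every bin is an error.
    """
    e, t = _check_pair(estimates, truths)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    if t.min() < edges[0] or t.max() > edges[-1]:
        raise ValueError(f"true dose outside the binned range [{edges[0]}, {edges[-1]}]")
    # right edge of the last bin is inclusive
    which = np.clip(np.digitize(t, edges, right=False) - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(sel.sum()),
                "rmse": float(np.sqrt(np.mean((e[sel] - t[sel]) ** 2))),
            }
        )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n", "rmse"])


def triage_classify(estimates: Sequence[float], threshold_gy: float = 2.0) -> list[str]:
    """Dichotomize dose estimates for triage: positive iff D_hat >= threshold
    (2 Gy or greater -> further cytogenetic workup)."""
    e = np.asarray(estimates, dtype=float)
    if (e < 0).any():
        raise ValueError("estimates must be >= 0 Gy")
    return ["positive" if x >= threshold_gy else "negative" for x in e]


@dataclass(frozen=True)
class ConfusionReport:
    """Binary triage confusion matrix with per-class precision/recall.

    Counts follow the radiation-triage convention: positive = dose at or
    above the threshold.  A recall is NaN when its class is absent from the
    truth (undefined, never coerced to 0); precision likewise when the class
    is never predicted.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    threshold_gy: float

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def accuracy(self) -> float:
        return (self.tn + self.tp) / self.n

    @property
    def precision_pos(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan

    @property
    def precision_neg(self) -> float:
        denom = self.tn + self.fn
        return self.tn / denom if denom else math.nan

    @property
    def recall_pos(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def recall_neg(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan

    def as_dict(self) -> dict:
        return {
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "tp": self.tp,
            "n": self.n,
            "accuracy": self.accuracy,
            "precision_pos": self.precision_pos,
            "precision_neg": self.precision_neg,
            "recall_pos": self.recall_pos,
            "recall_neg": self.recall_neg,
            "threshold_gy": self.threshold_gy,
        }


def confusion_metrics(
    pred_labels: Sequence[str],
    true_labels: Sequence[str],
    threshold_gy: float = 2.0,
) -> ConfusionReport:
    """Count the confusion matrix from predicted and true triage labels."""
    if len(pred_labels) != len(true_labels):
        raise ValueError("label sequences must have equal length")
    valid = {"positive", "negative"}
    if not set(pred_labels) <= valid or not set(true_labels) <= valid:
        raise ValueError("labels must be 'positive' or 'negative'")
    tn = fp = fn = tp = 0
    for p, t in zip(pred_labels, true_labels):
        if t == "negative":
            if p == "negative":
                tn += 1
            else:
                fp += 1
        else:
            if p == "positive":
                tp += 1
            else:
                fn += 1
    return ConfusionReport(tn=tn, fp=fp, fn=fn, tp=tp, threshold_gy=threshold_gy)


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation of one set of dose estimates against delivered doses."""

    rmse_overall: float
    rmse_table: pd.DataFrame
    coverage: dict[float, tuple[int, float]]
    confusion: ConfusionReport
    n: int
    method: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "rmse_overall": self.rmse_overall,
            "rmse_by_bin": self.rmse_table.to_dict(orient="records"),
            "coverage": {str(t): {"count": c, "fraction": f} for t, (c, f) in self.coverage.items()},
            "confusion": self.confusion.as_dict(),
        }


def evaluate_estimates(
    estimates: Sequence[float],
    truths: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    tolerances: Sequence[float] = (0.5, 1.0),
    threshold_gy: float = 2.0,
    method: str = "",
) -> EvaluationReport:
    """One-call evaluation: RMSE (overall and binned), tolerance coverage,
    and the 2 Gy triage confusion matrix (truth labelled by the same rule)."""
    e, t = _check_pair(estimates, truths)
    pred = triage_classify(e, threshold_gy)
    true = triage_classify(t, threshold_gy)
    return EvaluationReport(
        rmse_overall=rmse(e, t),
        rmse_table=rmse_by_bin(e, t, bin_edges),
        coverage=tolerance_coverage(e, t, tolerances),
        confusion=confusion_metrics(pred, true, threshold_gy),
        n=e.size,
        method=method,
    )
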