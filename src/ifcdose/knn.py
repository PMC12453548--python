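"""Non-parametric K-nearest-neighbors dose regression.

Instead of inverting a fitted curve, the estimator places the query's
endpoint vector (MFI, mean spot count, mean spot area) among the calibration
samples' vectors and averages the delivered doses of its k nearest
neighbours under Euclidean distance:

    D_hat = (1/k) * sum of the k nearest calibration doses.

Columns are standardized with the calibration set's own center/scale before
distances are taken (raw MFI is orders of magnitude larger than spot counts
and would otherwise dominate the metric); queries are always transformed
with the frozen calibration statistics, never their own.  Confidence
intervals come from a percentile bootstrap over calibration rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import DoseEstimate

__all__ = [
    "CalibrationDataset",
    "KnnConfig",
    "standardize",
    "knn_estimate",
    "tune_k",
    "bootstrap_ci",
    "estimate_batch",
]

FEATURE_NAMES = ("mfi", "spot_count", "spot_area")


@dataclass(frozen=True)
class CalibrationDataset:
    """The calibration dose-response matrix.

    ``X`` holds one row per calibration sample with the m = 3 endpoint means;
    ``doses`` the delivered doses in Gy.  ``center``/``scale`` are set once
    by :func:`standardize` and reused verbatim for every query.
    """

    X: np.ndarray
    doses: np.ndarray
    donor_ids: tuple[str, ...] = ()
    feature_names: tuple[str, ...] = FEATURE_NAMES
    center: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.doses.shape[0]:
            raise ValueError("X rows must match the number of doses")
        if self.donor_ids and len(self.donor_ids) != self.X.shape[0]:
            raise ValueError("donor_ids must match the number of rows")
        if self.scale is not None and np.any(np.asarray(self.scale) <= 0):
            raise ValueError("scale must be > 0 per column")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def is_standardized(self) -> bool:
        return self.center is not None and self.scale is not None

    def transform_query(self, query: np.ndarray) -> np.ndarray:
        """Map a raw query vector into the calibration's standardized space."""
        q = np.asarray(query, dtype=float)
        if not self.is_standardized:
            return q
        return (q - self.center) / self.scale

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "CalibrationDataset":
        """Build from a per-sample table with mfi/spot_count/spot_area columns."""
        X = df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
        donors = tuple(df["donor_id"].astype(str)) if "donor_id" in df else ()
        return CalibrationDataset(X=X, doses=df["dose_gy"].to_numpy(dtype=float), donor_ids=donors)


@dataclass(frozen=True)
class KnnConfig:
    """Estimator settings: neighborhood size k (default 7), standardization,
    bootstrap replicate count B, and confidence level."""

    k: int = 7
    standardize: bool = True
    bootstrap_B: int = 2000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


def standardize(cal: CalibrationDataset) -> CalibrationDataset:
    """Center and unit-scale each endpoint column, storing the statistics for
    transforming queries.  Idempotent: standardizing a standardized dataset
    leaves it unchanged (up to numerical tolerance)."""
    if cal.n < 2:
        raise ValueError("standardize needs n >= 2 rows")
    center = cal.X.mean(axis=0)
    scale = cal.X.std(axis=0, ddof=0)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        names = [cal.feature_names[i] for i in bad]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (cal.X - center) / scale
    # compose with any prior transform so query mapping stays a single affine step
    if cal.is_standardized:
        new_center = cal.center + center * cal.scale
        new_scale = cal.scale * scale
    else:
        new_center, new_scale = center, scale
    return replace(cal, X=Z, center=new_center, scale=new_scale)


def _prepared(cal: CalibrationDataset, cfg: KnnConfig) -> CalibrationDataset:
    if cfg.standardize and not cal.is_standardized:
        return standardize(cal)
    return cal


def _neighbor_order(dists: np.ndarray) -> np.ndarray:
    """Ascending distance, ties broken deterministically by row index."""
    return np.lexsort((np.arange(dists.size), dists))


def knn_estimate(
    query: Sequence[float],
    cal: CalibrationDataset,
    cfg: Optional[KnnConfig] = None,
) -> DoseEstimate:
    """Point estimate: mean delivered dose of the k nearest calibration rows.

    The interval fields are degenerate ([D_hat, D_hat]); use
    :func:`bootstrap_ci` or :func:`estimate_batch` for bootstrap intervals.
    """
    cfg = KnnConfig() if cfg is None else cfg
    cal = _prepared(cal, cfg)
    if cfg.k > cal.n:
        raise ValueError(f"k={cfg.k} exceeds the {cal.n} calibration rows")
    if np.shape(np.asarray(query, dtype=float)) != (cal.m,):
        raise ValueError(f"query must have {cal.m} features, got shape {np.shape(query)}")
    q = cal.transform_query(query)
    dists = np.linalg.norm(cal.X - q, axis=1)
    order = _neighbor_order(dists)[: cfg.k]
    dose_hat = float(cal.doses[order].mean())
    return DoseEstimate(
        dose_hat=dose_hat,
        ci_low=dose_hat,
        ci_high=dose_hat,
        method="KNN",
        diagnostics={"neighbors": order.tolist(), "k": cfg.k},
    )


def bootstrap_ci(
    query: Sequence[float],
    cal: CalibrationDataset,
    cfg: Optional[KnnConfig] = None,
    stream: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for one query.

    Calibration rows are resampled with replacement B times and the K-NN
    estimate recomputed per replicate (distances are invariant under
    resampling, so each replicate reuses the precomputed distance vector).
    Standardization statistics stay frozen at their full-calibration values.
    Replicates with fewer than k distinct rows are redrawn; the redraw count
    is available via the returned interval's provenance in estimate_batch.
    """
    cfg = KnnConfig() if cfg is None else cfg
    stream = np.random.default_rng(cfg.seed) if stream is None else stream
    cal = _prepared(cal, cfg)
    if cfg.k > cal.n:
        raise ValueError(f"k={cfg.k} exceeds the {cal.n} calibration rows")
    q = cal.transform_query(query)
    dists = np.linalg.norm(cal.X - q, axis=1)
    # lexicographic key (distance, row index) keeps tie-breaking identical to
    # the point estimator inside every replicate
    order_key = dists + np.arange(cal.n) * 1e-12 * max(1.0, dists.max())
    estimates = np.empty(cfg.bootstrap_B)
    b = 0
    redraws = 0
    while b < cfg.bootstrap_B:
        idx = stream.integers(0, cal.n, cal.n)
        if np.unique(idx).size < cfg.k:
            redraws += 1
            continue
        kk = np.argpartition(order_key[idx], cfg.k - 1)[: cfg.k]
        estimates[b] = cal.doses[idx[kk]].mean()
        b += 1
    alpha = 1.0 - cfg.ci_level
    lo, hi = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def estimate_batch(
    queries,
    cal: CalibrationDataset,
    cfg: Optional[KnnConfig] = None,
    stream: Optional[np.random.Generator] = None,
    with_ci: bool = True,
) -> list[DoseEstimate]:
    """Estimate a batch of queries (array-like of shape (q, m) or a table
    with mfi/spot_count/spot_area columns), with per-query bootstrap CIs."""
    cfg = KnnConfig() if cfg is None else cfg
    stream = np.random.default_rng(cfg.seed) if stream is None else stream
    if isinstance(queries, pd.DataFrame):
        Q = queries.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        Q = np.atleast_2d(np.asarray(queries, dtype=float))
    cal = _prepared(cal, cfg)
    out: list[DoseEstimate] = []
    for q in Q:
        est = knn_estimate(q, cal, cfg)
        if with_ci:
            lo, hi = bootstrap_ci(q, cal, cfg, stream)
            lo, hi = min(lo, est.dose_hat), max(hi, est.dose_hat)
            est = DoseEstimate(est.dose_hat, lo, hi, "KNN", est.diagnostics)
        out.append(est)
    return out


def tune_k(
    cal: CalibrationDataset,
    cfg: Optional[KnnConfig] = None,
    split_fraction: float = 0.7,
    k_grid: Optional[Sequence[int]] = None,
    stream: Optional[np.random.Generator] = None,
) -> tuple[int, pd.DataFrame]:
    """Select k by a seeded 70:30 train/test split.

    Every test-row dose is estimated from the training rows for each k in
    ``k_grid`` (default 1..15); returns the RMSE-minimising k (ties go to
    the smaller k) and the full RMSE-vs-k table.
    """
    cfg = KnnConfig() if cfg is None else cfg
    stream = np.random.default_rng(cfg.seed) if stream is None else stream
    k_grid = list(range(1, 16)) if k_grid is None else sorted(k_grid)
    perm = stream.permutation(cal.n)
    n_train = int(round(split_fraction * cal.n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split leaves an empty subset; need more calibration rows")
    if max(k_grid) > len(train_idx):
        raise ValueError(f"k_grid maximum {max(k_grid)} exceeds the {len(train_idx)} training rows")

    train = CalibrationDataset(X=cal.X[train_idx], doses=cal.doses[train_idx])
    if cfg.standardize:
        train = standardize(train)
    test_X = cal.X[test_idx]
    test_D = cal.doses[test_idx]

    rows = []
    for k in k_grid:
        k_cfg = replace(cfg, k=k)
        preds = np.array([knn_estimate(q, train, k_cfg).dose_hat for q in test_X])
        rows.append((k, float(np.sqrt(np.mean((preds - test_D) ** 2)))))
    table = pd.DataFrame(rows, columns=["k", "rmse"])
    best_k = int(table.loc[table["rmse"].idxmin(), "k"])  # idxmin takes the first (smallest k) on ties
    return best_k, table
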