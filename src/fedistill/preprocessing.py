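"""Preprocessing chain for the tabular cohort.

Steps, in pipeline order: univariate IQR outlier flagging, multivariate
local-outlier-factor flagging (union removed, with a data-quality ceiling),
clinical binning of glucose and insulin, z-score normalisation fitted on
training rows only, and per-shard SMOTE class balancing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

from fedistill.synthetic_cohort import Cohort, FEATURE_COLUMNS


class DataQualityWarning(UserWarning):
    """Raised-as-warning when a cleaning step is unusually aggressive."""


@dataclass
class PreprocessConfig:
    """Tunables for the cleaning chain.

    ``glucose_bin_edges`` default to the standard clinical cut points for
    impaired fasting tolerance and diabetes (140 and 200 mg/dL); insulin
    edges, when None, are the training-data quartiles.
    """

    iqr_multiplier: float = 1.5
    lof_neighbors: int = 20
    lof_threshold: float = 1.5
    glucose_bin_edges: tuple[float, ...] = (140.0, 200.0)
    insulin_bin_edges: tuple[float, ...] | None = None
    smote_k: int = 5
    removal_ceiling: float = 0.10

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")
        if self.lof_neighbors < 1 or self.smote_k < 1:
            raise ValueError("counts must be >= 1")
        for edges in (self.glucose_bin_edges, self.insulin_bin_edges):
            if edges is not None and list(edges) != sorted(set(edges)):
                raise ValueError("bin edges must be strictly ascending")

    def to_dict(self) -> dict:
        return asdict(self)


def flag_outliers_iqr(column: np.ndarray | pd.Series, multiplier: float = 1.5) -> np.ndarray:
    """Tukey-fence mask: value outside [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use linear interpolation.  A constant column has zero IQR
    and an empty fence violation set, so no flags are raised.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 4:
        raise ValueError("column must have at least 4 values")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - multiplier * iqr) | (x > q3 + multiplier * iqr)


def flag_outliers_lof(features: np.ndarray | pd.DataFrame, k: int = 20,
                      threshold: float = 1.5) -> np.ndarray:
    """Local-outlier-factor mask (Euclidean metric).

    A point is flagged when the ratio of its k-neighbour average local
    reachability density to its own exceeds ``threshold``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k >= len(X):
        raise ValueError("k must be smaller than the number of rows")
    lof = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    lof.fit(X)
    scores = -lof.negative_outlier_factor_
    return scores > threshold


def remove_outliers(cohort: Cohort, config: PreprocessConfig) -> tuple[Cohort, np.ndarray]:
    """Drop rows flagged by the union of per-column IQR and multivariate LOF.

    Returns the cleaned cohort and the boolean kept-mask over the input.
    Exceeding ``removal_ceiling`` emits a :class:`DataQualityWarning`
    (rows are still removed; the ceiling is advisory).
    """
    mask = np.zeros(cohort.n, dtype=bool)
    for col in FEATURE_COLUMNS:
        mask |= flag_outliers_iqr(cohort.features[col].to_numpy(), config.iqr_multiplier)
    if cohort.n > config.lof_neighbors:
        mask |= flag_outliers_lof(cohort.features.to_numpy(), config.lof_neighbors,
                                  config.lof_threshold)
    frac = mask.mean()
    if frac > config.removal_ceiling:
        warnings.warn(
            f"outlier removal would drop {frac:.1%} of rows "
            f"(ceiling {config.removal_ceiling:.0%})", DataQualityWarning)
    kept = ~mask
    cleaned = Cohort(features=cohort.features.loc[kept].reset_index(drop=True),
                     labels=cohort.labels[kept])
    return cleaned, kept


def _bin_column(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    # left-closed intervals: value == edge falls in the upper bin
    return np.searchsorted(np.asarray(edges, dtype=float), values, side="right")


def engineer_bins(cohort: Cohort, config: PreprocessConfig,
                  fit_rows: np.ndarray | None = None) -> Cohort:
    """Append ordinal ``glucose_bin`` and ``insulin_bin`` columns.

    Glucose uses the configured clinical edges; insulin edges default to
    the quartiles of the fit rows (all rows when unspecified).  Original
    columns are untouched.
    """
    feats = cohort.features.copy()
    insulin_edges = config.insulin_bin_edges
    if insulin_edges is None:
        rows = feats["insulin"].to_numpy() if fit_rows is None \
            else feats["insulin"].to_numpy()[fit_rows]
        insulin_edges = tuple(np.percentile(rows, [25, 50, 75]))
    feats["glucose_bin"] = _bin_column(feats["glucose"].to_numpy(),
                                       config.glucose_bin_edges).astype(np.int64)
    feats["insulin_bin"] = _bin_column(feats["insulin"].to_numpy(),
                                       insulin_edges).astype(np.int64)
    return Cohort(features=feats, labels=cohort.labels.copy())


def zscore(features: np.ndarray | pd.DataFrame,
           fit_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardise columns using moments from ``fit_rows`` only.

    Returns ``(transformed, mean, sd)``.  Columns with zero spread on the
    fit rows map to all-zero (their sd is reported as 0).
    """
    X = np.asarray(features, dtype=float)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    mean = X[fit_rows].mean(axis=0)
    sd = X[fit_rows].std(axis=0, ddof=0)
    safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z, mean, sd


def apply_zscore(features: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z


def smote_balance(features: np.ndarray, labels: np.ndarray, k: int = 5,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalise class counts by synthetic minority oversampling.

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``,
    where ``x`` is a minority point and ``x_nn`` one of its ``k`` nearest
    minority neighbours (Euclidean).  Original rows are preserved verbatim
    and come first in the output.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    deficit = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) <= k:
        raise ValueError(f"minority class count ({len(Xm)}) must exceed k ({k})")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)  # +1: self is its own NN
    neighbor_idx = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=deficit)
    pick = rng.integers(0, k, size=deficit)
    u = rng.random(deficit)
    anchors = Xm[base]
    partners = Xm[neighbor_idx[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=np.int64)])
    return X_out, y_out
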