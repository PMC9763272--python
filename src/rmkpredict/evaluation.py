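"""Model evaluation panel for discrete clinical-score predictions.

Error metrics (RMSE, MAE) in score points and as percentages, the R-squared
pair, and Spearman rank correlation between therapist-assigned scores and
predictions snapped to the discrete scale, with a verbal strength rubric.

Normalization conventions
-------------------------
* ``RMSE_n = 100 * RMSE / (scale max - scale min)`` -- the fraction of the
  scale range.
* ``MAE_n`` divides by a selectable denominator: the mean of the observed
  discharge scores (default) or the scale range.  The mean-observed
  convention expresses the typical error relative to the typical score and
  is the one consistent with reporting MAE percentages well above the
  range-normalized figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .scales import MIScale, snap_scores

__all__ = [
    "rmse",
    "mae",
    "normalize_rmse",
    "normalize_mae",
    "r_squared",
    "adjusted_r_squared",
    "spearman",
    "interpret_correlation",
    "format_rmse_n",
    "ValidationReport",
    "evaluate_predictions",
]


def _pair(actual: Iterable[float], predicted: Iterable[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(list(actual), dtype=float)
    p = np.asarray(list(predicted), dtype=float)
    if a.size != p.size:
        raise ValueError("actual and predicted must have equal length")
    if a.size == 0:
        raise ValueError("empty vectors")
    return a, p


def rmse(actual: Iterable[float], predicted: Iterable[float]) -> float:
    """Root mean squared error, in score points."""
    a, p = _pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mae(actual: Iterable[float], predicted: Iterable[float]) -> float:
    """Mean absolute error, in score points.  Never exceeds the RMSE."""
    a, p = _pair(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def normalize_rmse(rmse_value: float, scale: MIScale) -> float:
    """RMSE as a percentage of the scale range (unrounded).

    The reporting layer rounds sub-item values to integers and upper-limb
    totals to one decimal; see :func:`format_rmse_n`.
    """
    rng = scale.score_range
    if rng <= 0:
        raise ValueError("scale range must be positive")
    return 100.0 * rmse_value / rng


def normalize_mae(mae_value: float, denominator: float) -> float:
    """MAE as a percentage of an explicit denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * mae_value / denominator


def r_squared(actual: Iterable[float], predicted: Iterable[float]) -> float:
    """Fraction of variance explained: 1 - SSE/SST around the observed mean.

    Computed against held-out or pooled out-of-fold predictions this may be
    negative; for a training fit it lies in [0, 1].
    """
    a, p = _pair(actual, predicted)
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0:
        raise ValueError("actual scores have zero variance; R^2 undefined")
    sse = float(np.sum((a - p) ** 2))
    return 1.0 - sse / sst


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) for p predictors."""
    if n <= p + 1:
        raise ValueError("need n > p + 1 for the adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def spearman(actual: Iterable[float], predicted: Iterable[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(r, p)``; the p-value uses the t approximation
    ``t = r * sqrt((n - 2)/(1 - r**2))``.  Raises if either vector is
    constant, in which case ranks carry no information.
    """
    a, p = _pair(actual, predicted)
    if a.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.unique(a).size < 2 or np.unique(p).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(a, p)
    return float(res.statistic), float(res.pvalue)


def interpret_correlation(r: float) -> str:
    """Verbal strength rubric on |r|.

    ``[0, 0.3]`` very weak, ``(0.3, 0.5]`` weak, ``(0.5, 0.7]`` moderate,
    ``(0.7, 1]`` strong.
    """
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValueError("|r| cannot exceed 1")
    if a <= 0.3:
        return "very weak"
    if a <= 0.5:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def format_rmse_n(value: float, scale: MIScale) -> float:
    """Reporting convention for normalized RMSE.

    Sub-item percentages are rounded half-up to integers; the upper-limb
    total, whose finer scale warrants it, to one decimal.
    """
    if scale.name == "UL":
        return math.floor(value * 10 + 0.5) / 10
    return int(math.floor(value + 0.5))


@dataclass
class ValidationReport:
    """The evaluation panel for one prediction set.

    ``rmse_n`` and ``mae_n`` are percentages; ``spearman_r`` is computed
    between the actual scores and the predictions snapped to the scale's
    discrete valid set (the raw error metrics use unsnapped predictions).
    When every snapped prediction collapses to a single class the rank
    correlation is undefined and reported as NaN.
    """

    n: int
    n_predictors: int
    rmse: float
    rmse_n: float
    mae: float
    mae_n: float
    r2: float
    r2_adj: float
    spearman_r: float
    spearman_p: float
    strength: str
    mae_n_denominator: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_predictors": self.n_predictors,
            "rmse": self.rmse,
            "rmse_n": self.rmse_n,
            "mae": self.mae,
            "mae_n": self.mae_n,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "strength": self.strength,
            "mae_n_denominator": self.mae_n_denominator,
        }


def evaluate_predictions(
    actual: Iterable[float],
    predicted: Iterable[float],
    scale: MIScale,
    n_predictors: int,
    mae_denominator: str = "mean_observed",
    snap: bool = True,
) -> ValidationReport:
    """Compute the full evaluation panel for one set of predictions.

    Parameters
    ----------
    actual, predicted:
        Therapist-assigned scores and continuous model predictions.
    scale:
        The outcome's discrete scale; supplies the RMSE normalizer and the
        valid score set for the nearest-neighbour correction.
    n_predictors:
        Number of model predictors, for the adjusted R^2.
    mae_denominator:
        ``"mean_observed"`` (default) or ``"range"``.
    snap:
        Apply the nearest-neighbour correction before the rank correlation.
    """
    a, p = _pair(actual, predicted)
    rmse_v = rmse(a, p)
    mae_v = mae(a, p)
    if mae_denominator == "mean_observed":
        den = float(np.mean(a))
        if den <= 0:
            raise ValueError("mean observed score must be positive for MAE_n")
    elif mae_denominator == "range":
        den = scale.score_range
    else:
        raise ValueError("mae_denominator must be 'mean_observed' or 'range'")

    r2 = r_squared(a, p)
    r2a = (
        adjusted_r_squared(r2, a.size, n_predictors)
        if a.size > n_predictors + 1
        else math.nan
    )
    corrected = snap_scores(p, scale) if snap else p
    try:
        r, pval = spearman(a, corrected)
        strength = interpret_correlation(r)
    except ValueError:
        r, pval, strength = math.nan, math.nan, "undefined"

    return ValidationReport(
        n=int(a.size),
        n_predictors=int(n_predictors),
        rmse=rmse_v,
        rmse_n=normalize_rmse(rmse_v, scale),
        mae=mae_v,
        mae_n=normalize_mae(mae_v, den),
        r2=r2,
        r2_adj=r2a,
        spearman_r=r,
        spearman_p=pval,
        strength=strength,
        mae_n_denominator=den,
    )
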