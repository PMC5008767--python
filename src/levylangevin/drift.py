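"""Recovery of the deterministic drift g(x) from activity time series.

The observed increments dx(t) = x(t+1) - x(t) decompose into a deterministic
drift plus noise.  Because the noise has zero (median-)location, the drift is
the conditional expectation E[dx | x], estimated here by binning x and
averaging dx within bins, then fitted by a weighted straight line

    g(x) = -k (x - x*) ,

the linear relaxation model: activity decays exponentially to the
equilibrium x* with characteristic time tau = 1/k (in sampling steps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "DriftCurve",
    "DriftModel",
    "DriftEstimationError",
    "increments",
    "estimate_drift_curve",
    "fit_linear_drift",
    "deterministic_solution",
    "LinearDriftEstimator",
]


class DriftEstimationError(RuntimeError):
    """Raised when too few populated bins remain to estimate the drift."""


@dataclass
class DriftCurve:
    """Binned conditional-mean increments: the nonparametric drift estimate."""

    bin_centers: np.ndarray
    conditional_means: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.conditional_means = np.asarray(self.conditional_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if not np.all(np.diff(self.bin_centers) >= 0):
            raise ValueError("bin_centers must be ordered")

    def to_dict(self) -> dict:
        return {
            "bin_centers": self.bin_centers.tolist(),
            "conditional_means": self.conditional_means.tolist(),
            "bin_counts": self.bin_counts.tolist(),
        }


@dataclass
class DriftModel:
    """Linear relaxation drift g(x) = -k (x - x*)."""

    k: float
    x_star: float
    slope_se: float = math.nan
    r_squared: float = math.nan
    non_relaxing: bool = False
    n_points: int = 0

    @property
    def tau(self) -> float:
        """Characteristic relaxation time 1/k, in sampling steps."""
        return 1.0 / self.k if self.k > 0 else math.inf

    def g(self, x):
        """Evaluate the drift at activity level x."""
        return -self.k * (np.asarray(x, dtype=float) - self.x_star)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "x_star": self.x_star,
            "tau": self.tau,
            "slope_se": self.slope_se,
            "r_squared": self.r_squared,
            "non_relaxing": self.non_relaxing,
            "n_points": self.n_points,
        }


def increments(values) -> tuple[np.ndarray, np.ndarray]:
    """Return (x_t, dx_t) pairs with dx_t = x(t+1) - x(t)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to form increments")
    return v[:-1], np.diff(v)


def _as_pairs(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept a TimeSeries, a 1-D array, or an (x, dx) pair."""
    if hasattr(data, "values") and not isinstance(data, tuple):
        return increments(data.values)
    if isinstance(data, tuple) and len(data) == 2:
        x, dx = (np.asarray(a, dtype=float) for a in data)
        if x.shape != dx.shape:
            raise ValueError("x and dx must have matching shapes")
        return x, dx
    return increments(np.asarray(data, dtype=float))


def estimate_drift_curve(
    data,
    n_bins: int = 50,
    min_count: int = 20,
    aggregator: str = "mean",
    trim: tuple[float, float] = (0.01, 0.99),
) -> DriftCurve:
    """Bin x into equal-occupancy bins and aggregate dx within each bin.

    Parameters
    ----------
    data : TimeSeries, 1-D array of activities, or an ``(x, dx)`` pair of
        pooled increments.
    n_bins : target number of equal-occupancy bins (quantile edges), robust
        to heavy-tailed marginals where equal-width bins starve.
    min_count : bins with fewer samples are dropped.
    aggregator : ``"mean"`` (default, the conditional expectation) or
        ``"median"`` (robust option for heavy-tailed noise, alpha <= 1).
    trim : drop pairs whose x lies outside these marginal quantiles, to
        remove leverage from rare excursions.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    x, dx = _as_pairs(data)
    lo, hi = np.quantile(x, trim)
    keep = (x >= lo) & (x <= hi)
    x, dx = x[keep], dx[keep]
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)))
    # digitize: values == last edge fall into the final bin
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)
    # the bin center uses the same location statistic as the aggregator:
    # pairing a mean center with a median aggregate biases the slope in
    # skewed (heavy-tailed) bins
    agg = np.mean if aggregator == "mean" else np.median
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < min_count:
            continue
        centers.append(float(agg(x[sel])))
        means.append(float(agg(dx[sel])))
        counts.append(n)
    if len(centers) < 3:
        raise DriftEstimationError(
            f"only {len(centers)} bins with >= {min_count} samples; "
            "cannot estimate a drift curve (need >= 3)"
        )
    order = np.argsort(centers)
    return DriftCurve(
        np.asarray(centers)[order], np.asarray(means)[order], np.asarray(counts)[order]
    )


def fit_linear_drift(curve: DriftCurve) -> DriftModel:
    """Weighted least-squares line through the drift curve.

    Weights are the bin occupancies.  The slope gives -k; the equilibrium is
    the zero crossing x* = intercept / k.  A non-negative slope (no
    relaxation) sets a warning flag rather than raising; x* is then reported
    as the occupancy-weighted mean activity, by convention.
    """
    if curve.bin_centers.size < 3:
        raise DriftEstimationError("need at least 3 bins to fit a line")
    X = sm.add_constant(curve.bin_centers)
    res = sm.WLS(curve.conditional_means, X, weights=curve.bin_counts).fit()
    intercept, slope = res.params
    n_pts = int(curve.bin_counts.sum())
    if slope >= 0:
        warnings.warn(
            "drift curve slope is non-negative: no relaxation towards an "
            "equilibrium; model flagged",
            stacklevel=2,
        )
        x_star = float(np.average(curve.bin_centers, weights=curve.bin_counts))
        return DriftModel(
            k=max(-slope, 0.0),
            x_star=x_star,
            slope_se=float(res.bse[1]),
            r_squared=float(res.rsquared),
            non_relaxing=True,
            n_points=n_pts,
        )
    k = -float(slope)
    return DriftModel(
        k=k,
        x_star=float(intercept) / k,
        slope_se=float(res.bse[1]),
        r_squared=float(res.rsquared),
        non_relaxing=False,
        n_points=n_pts,
    )


def deterministic_solution(model: DriftModel, x0: float, t) -> np.ndarray | float:
    """Noise-free mean path <x(t)> = x* + (x0 - x*) exp(-t / tau).

    ``t`` is measured in sampling steps and may be an array.
    """
    if model.k <= 0:
        raise ValueError("deterministic solution requires k > 0")
    t = np.asarray(t, dtype=float)
    out = model.x_star + (x0 - model.x_star) * np.exp(-t / model.tau)
    return float(out) if out.ndim == 0 else out


class LinearDriftEstimator(BaseEstimator):
    """Estimator recovering the linear relaxation drift from a 1-D series.

    Follows the scikit-learn protocol: hyperparameters in ``__init__``,
    fitted quantities with trailing underscores, ``fit`` returns ``self``.

    Parameters
    ----------
    n_bins, min_count, aggregator, trim : see :func:`estimate_drift_curve`.

    Attributes
    ----------
    curve_ : DriftCurve of binned conditional mean increments.
    model_ : fitted DriftModel.
    k_, x_star_, tau_ : convenience copies of the model parameters.
    """

    def __init__(self, n_bins=50, min_count=20, aggregator="mean", trim=(0.01, 0.99)):
        self.n_bins = n_bins
        self.min_count = min_count
        self.aggregator = aggregator
        self.trim = trim

    def fit(self, X, y=None):
        """Fit from a TimeSeries, a 1-D activity array, or an (x, dx) pair."""
        self.curve_ = estimate_drift_curve(
            X,
            n_bins=self.n_bins,
            min_count=self.min_count,
            aggregator=self.aggregator,
            trim=self.trim,
        )
        self.model_ = fit_linear_drift(self.curve_)
        self.k_ = self.model_.k
        self.x_star_ = self.model_.x_star
        self.tau_ = self.model_.tau
        return self

    def predict(self, X):
        """Drift g(x) = -k (x - x*) at activity levels X."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return self.model_.g(np.asarray(X, dtype=float))
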