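"""Characterization of the stochastic residuals of the Langevin model.

Residuals are recovered by inverting the Euler-Maruyama step,

    xi(t) = dx(t) - g(x(t)) = dx(t) + k (x(t) - x*),

and then characterized two ways, each on its natural input:

* the signed residuals feed a full four-parameter stable fit by regression
  on the empirical characteristic function (McCulloch quantile
  initialization, then the Koutrouvelis regression-type method);
* the magnitudes |xi| feed the empirical survival function, whose log-log
  tail is linear with slope -alpha when the law is stable with alpha < 2.
  A Hill estimator on the same tail serves as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator

from .drift import DriftModel, increments
from .stable import ALPHA_ONE_BAND, StableParams

__all__ = [
    "ResidualSet",
    "SurvivalCurve",
    "TailFit",
    "extract_residuals",
    "pool_residuals",
    "mcculloch_initial",
    "StableECFEstimator",
    "estimate_stable_params",
    "empirical_ccdf",
    "tail_slope",
    "TailSlopeEstimator",
]


class EstimationError(RuntimeError):
    """Raised when a stable fit cannot be attempted on the given residuals."""


# ---------------------------------------------------------------------------
# residual extraction
# ---------------------------------------------------------------------------

@dataclass
class ResidualSet:
    """Signed noise realizations and their magnitudes, with provenance."""

    xi: np.ndarray
    subject_id: str = ""
    network_id: str = ""

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if not np.all(np.isfinite(self.xi)):
            raise ValueError("residuals contain non-finite values")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.xi)

    def __len__(self) -> int:
        return int(self.xi.size)


def extract_residuals(series, model: DriftModel) -> ResidualSet:
    """xi(t) = dx(t) - g(x(t)); one fewer residual than series samples."""
    x, dx = increments(series.values if hasattr(series, "values") else series)
    xi = dx - model.g(x)
    return ResidualSet(
        xi,
        subject_id=getattr(series, "subject_id", ""),
        network_id=getattr(series, "network_id", ""),
    )


def pool_residuals(sets: list[ResidualSet]) -> ResidualSet:
    """Concatenate residuals across subjects within a network."""
    if not sets:
        raise ValueError("no residual sets to pool")
    nets = {s.network_id for s in sets}
    return ResidualSet(
        np.concatenate([s.xi for s in sets]),
        subject_id="pooled",
        network_id=nets.pop() if len(nets) == 1 else "mixed",
    )


# ---------------------------------------------------------------------------
# McCulloch quantile initialization
# ---------------------------------------------------------------------------

# Lookup tables mapping the quantile ratios
#   nu_a = (q95 - q05) / (q75 - q25),  nu_b = (q95 + q05 - 2 q50)/(q95 - q05)
# to (alpha, beta).  Standard tabulation of the quantile method.
_NU_A = np.array(
    [2.439, 2.5, 2.6, 2.7, 2.8, 3.0, 3.2, 3.5, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 25.0]
)
_NU_B = np.array([0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0])

_PSI_1 = np.array(
    [
        [2.000, 2.000, 2.000, 2.000, 2.000, 2.000, 2.000],
        [1.916, 1.924, 1.924, 1.924, 1.924, 1.924, 1.924],
        [1.808, 1.813, 1.829, 1.829, 1.829, 1.829, 1.829],
        [1.729, 1.730, 1.737, 1.745, 1.745, 1.745, 1.745],
        [1.664, 1.663, 1.663, 1.668, 1.676, 1.676, 1.676],
        [1.563, 1.560, 1.553, 1.548, 1.547, 1.547, 1.547],
        [1.484, 1.480, 1.471, 1.460, 1.448, 1.438, 1.438],
        [1.391, 1.386, 1.378, 1.364, 1.337, 1.318, 1.318],
        [1.279, 1.273, 1.266, 1.250, 1.210, 1.184, 1.150],
        [1.128, 1.121, 1.114, 1.101, 1.067, 1.027, 0.973],
        [1.029, 1.021, 1.014, 1.004, 0.974, 0.935, 0.874],
        [0.896, 0.892, 0.887, 0.883, 0.855, 0.823, 0.769],
        [0.818, 0.812, 0.806, 0.801, 0.780, 0.756, 0.691],
        [0.698, 0.695, 0.692, 0.689, 0.676, 0.656, 0.595],
        [0.593, 0.590, 0.588, 0.586, 0.579, 0.563, 0.513],
    ]
)

_PSI_2 = np.array(
    [
        [0.0, 2.160, 1.000, 1.000, 1.000, 1.000, 1.000],
        [0.0, 1.592, 3.390, 1.000, 1.000, 1.000, 1.000],
        [0.0, 0.759, 1.800, 1.000, 1.000, 1.000, 1.000],
        [0.0, 0.482, 1.048, 1.694, 1.000, 1.000, 1.000],
        [0.0, 0.360, 0.760, 1.232, 2.229, 1.000, 1.000],
        [0.0, 0.253, 0.518, 0.823, 1.575, 1.000, 1.000],
        [0.0, 0.203, 0.410, 0.632, 1.244, 1.906, 1.000],
        [0.0, 0.165, 0.332, 0.499, 0.943, 1.560, 1.000],
        [0.0, 0.136, 0.271, 0.404, 0.689, 1.230, 2.195],
        [0.0, 0.109, 0.216, 0.323, 0.539, 0.827, 1.917],
        [0.0, 0.096, 0.190, 0.284, 0.472, 0.693, 1.759],
        [0.0, 0.082, 0.163, 0.243, 0.412, 0.601, 1.596],
        [0.0, 0.074, 0.147, 0.220, 0.377, 0.546, 1.482],
        [0.0, 0.064, 0.128, 0.191, 0.330, 0.478, 1.362],
        [0.0, 0.056, 0.112, 0.167, 0.285, 0.428, 1.274],
    ]
)

_ALPHA_INTERP = RegularGridInterpolator(
    (_NU_A, _NU_B), _PSI_1, bounds_error=False, fill_value=None
)
_BETA_INTERP = RegularGridInterpolator(
    (_NU_A, _NU_B), _PSI_2, bounds_error=False, fill_value=None
)


def mcculloch_initial(x: np.ndarray) -> tuple[float, float, float, float]:
    """Quantile-based starting values (alpha, beta, gamma, delta).

    alpha and beta come from the standard quantile-ratio tables; the scale
    and location seeds are IQR/2 and the median, which is enough because the
    ECF regression re-estimates both at every iteration.
    """
    q05, q25, q50, q75, q95 = np.quantile(x, [0.05, 0.25, 0.50, 0.75, 0.95])
    iqr = q75 - q25
    span = q95 - q05
    if iqr <= 0 or span <= 0:
        raise EstimationError("degenerate sample: zero interquantile range")
    nu_a = min(max(span / iqr, _NU_A[0]), _NU_A[-1])
    nu_b = (q95 + q05 - 2.0 * q50) / span
    sgn = 1.0 if nu_b >= 0 else -1.0
    nu_b_c = min(abs(nu_b), _NU_B[-1])
    alpha = float(np.clip(_ALPHA_INTERP((nu_a, nu_b_c)), 0.1, 2.0))
    beta = float(np.clip(sgn * _BETA_INTERP((nu_a, nu_b_c)), -1.0, 1.0))
    return alpha, beta, float(iqr / 2.0), float(q50)


# ---------------------------------------------------------------------------
# Koutrouvelis regression on the empirical characteristic function
# ---------------------------------------------------------------------------

# Optimal numbers of CF evaluation points for the modulus (K) and argument
# (L) regressions, indexed by alpha (rows) and sample size (columns);
# standard tabulation for the regression-type estimator.
_TAB_ALPHA = np.array([1.9, 1.5, 1.3, 1.1, 0.9, 0.7, 0.5, 0.3])
_TAB_N = np.array([200.0, 800.0, 1600.0])
_TAB_K = np.array(
    [
        [9, 9, 9],
        [11, 11, 11],
        [22, 16, 14],
        [24, 18, 15],
        [28, 22, 18],
        [30, 24, 20],
        [86, 68, 56],
        [134, 124, 118],
    ],
    dtype=float,
)
_TAB_L = np.array(
    [
        [9, 10, 11],
        [12, 14, 15],
        [16, 18, 17],
        [14, 14, 14],
        [24, 16, 16],
        [20, 16, 16],
        [61, 38, 30],
        [70, 68, 67],
    ],
    dtype=float,
)

_K_INTERP = RegularGridInterpolator(
    (_TAB_ALPHA[::-1], _TAB_N), _TAB_K[::-1], bounds_error=False, fill_value=None
)
_L_INTERP = RegularGridInterpolator(
    (_TAB_ALPHA[::-1], _TAB_N), _TAB_L[::-1], bounds_error=False, fill_value=None
)


def _n_points(alpha: float, n: int) -> tuple[int, int]:
    a = float(np.clip(alpha, _TAB_ALPHA[-1], _TAB_ALPHA[0]))
    m = float(np.clip(n, _TAB_N[0], _TAB_N[-1]))
    return int(round(float(_K_INTERP((a, m))))), int(round(float(_L_INTERP((a, m)))))


def _ecf(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.exp(1j * np.outer(t, x)).mean(axis=1)


class StableECFEstimator(BaseEstimator):
    """Four-parameter stable fit by regression on the empirical CF.

    The modulus of the CF obeys ``-log|phi(t)|^2 = 2 (gamma |t|)^alpha``, a
    straight line in log-log coordinates giving alpha and gamma; the
    argument obeys ``arg phi(t) = delta t + beta gamma^alpha tan(pi alpha/2)
    sign(t) |t|^alpha``, a two-regressor linear model giving delta and beta.
    The sample is re-standardized and the two regressions alternated until
    alpha and gamma stabilize.  Estimates are reported in the S1 form.

    Parameters
    ----------
    max_iter : maximum regression sweeps (convergence is typically 2-4).
    tol : stop when |d alpha| < tol and the scale update is within tol of 1.
    min_samples : refuse to fit fewer residuals than this floor.

    Attributes
    ----------
    alpha_, beta_, gamma_, delta_ : fitted S1 parameters; alpha_ clamped to
        (0, 2], beta_ to [-1, 1].
    params_ : the same as a :class:`~levylangevin.stable.StableParams`.
    n_iter_, converged_ : iteration diagnostics.
    """

    def __init__(self, max_iter: int = 8, tol: float = 1e-3, min_samples: int = 200):
        self.max_iter = max_iter
        self.tol = tol
        self.min_samples = min_samples

    def fit(self, X, y=None):
        x = np.asarray(X.xi if isinstance(X, ResidualSet) else X, dtype=float).ravel()
        if x.size < self.min_samples:
            raise EstimationError(
                f"need >= {self.min_samples} residuals, got {x.size}"
            )
        if np.ptp(x) == 0:
            raise EstimationError("degenerate (all-equal) residuals")
        n = x.size
        alpha, beta, g_acc, d_acc = mcculloch_initial(x)
        s = (x - d_acc) / g_acc
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            K, L = _n_points(alpha, n)
            # --- modulus regression: alpha and the residual scale of s ----
            t = np.pi * np.arange(1, K + 1) / 25.0
            phi = _ecf(t, s)
            mod2 = np.clip(np.abs(phi) ** 2, 1e-12, 1.0 - 1e-12)
            yk = np.log(-np.log(mod2))
            wk = np.log(t)
            slope, icept = np.polyfit(wk, yk, 1)
            alpha_new = float(np.clip(slope, 0.1, 2.0))
            g_hat = float((math.exp(icept) / 2.0) ** (1.0 / alpha_new))
            s = s / g_hat
            g_acc *= g_hat
            # --- argument regression: beta and the residual location ------
            u = np.pi * np.arange(1, L + 1) / 50.0
            phi_u = _ecf(u, s)
            z = np.unwrap(np.arctan2(phi_u.imag, phi_u.real))
            if abs(alpha_new - 1.0) < 0.02:
                reg = -(2.0 / math.pi) * u * np.log(u)
                design = np.column_stack([u, reg])
                coef, *_ = np.linalg.lstsq(design, z, rcond=None)
                d_hat, b_hat = float(coef[0]), float(coef[1])
            else:
                ta = math.tan(math.pi * alpha_new / 2.0)
                if abs(ta) < 1e-8:  # alpha at 2: skew unidentifiable
                    coef, *_ = np.linalg.lstsq(u[:, None], z, rcond=None)
                    d_hat, b_hat = float(coef[0]), 0.0
                else:
                    design = np.column_stack([u, ta * np.abs(u) ** alpha_new * np.sign(u)])
                    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
                    d_hat, b_hat = float(coef[0]), float(coef[1])
            s = s - d_hat
            d_acc += d_hat * g_acc
            da = abs(alpha_new - alpha)
            alpha = alpha_new
            beta = float(np.clip(b_hat, -1.0, 1.0))
            if da < self.tol and abs(g_hat - 1.0) < self.tol:
                converged = True
                break
        if alpha > 2.0 - 1e-9:
            alpha, beta = 2.0, 0.0
        self.alpha_ = alpha
        self.beta_ = beta
        self.gamma_ = g_acc
        self.delta_ = d_acc
        self.n_iter_ = it
        self.converged_ = converged
        self.params_ = StableParams(alpha, beta, g_acc, d_acc, parameterization="S1")
        return self


def estimate_stable_params(residuals, **kwargs) -> StableParams:
    """Thin functional wrapper over :class:`StableECFEstimator`."""
    return StableECFEstimator(**kwargs).fit(residuals).params_


# ---------------------------------------------------------------------------
# survival function and tail slope
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Empirical survival function of residual magnitudes.

    Survival at the i-th largest magnitude is i/n; ties share the higher
    value, so every survival value is strictly positive and log-transforms
    are always defined.
    """

    magnitudes: np.ndarray  # sorted ascending
    survival: np.ndarray
    tail_threshold: float = math.nan

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"magnitude": self.magnitudes, "survival": self.survival}
        )


def empirical_ccdf(magnitudes) -> SurvivalCurve:
    """Survival curve F_bar(m) = P(|xi| >= m) evaluated at the sample points."""
    m = np.asarray(magnitudes, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("empty magnitude sample")
    if np.any(m < 0):
        raise ValueError("magnitudes must be nonnegative")
    srt = np.sort(m)
    n = srt.size
    # count of points >= value; ties share the higher survival value
    surv = 1.0 - np.searchsorted(srt, srt, side="left") / n
    return SurvivalCurve(srt, surv)


@dataclass
class TailFit:
    """Tail exponent from the log-log survival slope, with diagnostics."""

    alpha_tail: float
    slope_se: float
    r_squared: float
    hill_alpha: float
    n_tail: int
    threshold: float
    power_law: bool

    def to_dict(self) -> dict:
        return {
            "alpha_tail": self.alpha_tail,
            "slope_se": self.slope_se,
            "r_squared": self.r_squared,
            "hill_alpha": self.hill_alpha,
            "n_tail": self.n_tail,
            "threshold": self.threshold,
            "power_law": self.power_law,
        }


def tail_slope(
    curve: SurvivalCurve, tail_fraction: float = 0.1, min_tail: int = 50
) -> TailFit:
    """OLS slope of log F_bar vs log |xi| over the upper tail.

    Returns alpha_tail = -slope with its standard error, plus a Hill
    estimator on the same tail as a cross-check.  ``power_law`` is False
    when the estimate exceeds 2 or the log-log fit is visibly curved
    (R^2 < 0.95), as happens for exponential (Gaussian-like) tails.
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5]")
    mags, surv = curve.magnitudes, curve.survival
    pos = mags > 0
    mags, surv = mags[pos], surv[pos]
    n_tail = int(math.floor(tail_fraction * mags.size))
    if n_tail < min_tail:
        raise ValueError(
            f"tail has {n_tail} points, below the floor of {min_tail}"
        )
    tm, ts = mags[-n_tail:], surv[-n_tail:]
    threshold = float(tm[0])
    X = sm.add_constant(np.log(tm))
    res = sm.OLS(np.log(ts), X).fit()
    slope = float(res.params[1])
    alpha_tail = -slope
    # Hill estimator over exceedances of the same threshold
    exceed = mags[mags >= threshold]
    logs = np.log(exceed / threshold)
    logs = logs[logs > 0]
    hill = float(1.0 / logs.mean()) if logs.size else math.nan
    r2 = float(res.rsquared)
    curve.tail_threshold = threshold
    return TailFit(
        alpha_tail=alpha_tail,
        slope_se=float(res.bse[1]),
        r_squared=r2,
        hill_alpha=hill,
        n_tail=n_tail,
        threshold=threshold,
        power_law=bool(alpha_tail <= 2.0 and r2 >= 0.95),
    )


class TailSlopeEstimator(BaseEstimator):
    """Tail-exponent estimator on raw magnitudes (survival-slope + Hill)."""

    def __init__(self, tail_fraction: float = 0.1, min_tail: int = 50):
        self.tail_fraction = tail_fraction
        self.min_tail = min_tail

    def fit(self, X, y=None):
        mags = np.abs(
            np.asarray(X.xi if isinstance(X, ResidualSet) else X, dtype=float).ravel()
        )
        self.curve_ = empirical_ccdf(mags)
        fitres = tail_slope(self.curve_, self.tail_fraction, self.min_tail)
        self.fit_ = fitres
        self.alpha_tail_ = fitres.alpha_tail
        self.slope_se_ = fitres.slope_se
        self.r_squared_ = fitres.r_squared
        self.hill_alpha_ = fitres.hill_alpha
        self.power_law_ = fitres.power_law
        return self
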