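"""Numerics for the four-parameter alpha-stable family.

The family ``f(x; alpha, beta, gamma, delta)`` is closed under addition and
has a closed-form density only in three special cases (normal, Cauchy and
Levy).  Everything here is therefore built on the characteristic function:
direct evaluation, Chambers--Mallows--Stuck sampling, and Fourier inversion
for the density and distribution function, with Pareto-tail asymptotics
taking over far from the mode.

Two standard parameterizations are supported:

* ``S1`` -- the classical (Samorodnitsky--Taqqu) form in which results are
  reported; the location enters the characteristic function as ``i*delta*t``.
* ``S0`` -- Nolan's continuous-in-alpha variant, used internally for the
  numerical work because it behaves smoothly as alpha crosses 1.

Parameters
----------
alpha : characteristic exponent, 0 < alpha <= 2.  Controls the tail weight:
    alpha = 2 is Gaussian, alpha < 2 gives power-law tails ~ |x|^(-1-alpha).
beta : skewness in [-1, 1].
gamma : scale > 0, in signal units.
delta : location, in signal units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "StableParams",
    "ParameterError",
    "NumericsError",
    "stable_cf",
    "stable_sample",
    "stable_pdf",
    "stable_cdf",
    "stable_ccdf",
]

#: parameters with |alpha - 1| below this band snap to the alpha = 1 branch
ALPHA_ONE_BAND = 1e-3

#: |x - delta| / gamma beyond which the Pareto asymptotic series replaces
#: quadrature (configurable per call)
TAIL_SWITCH = 25.0


class ParameterError(ValueError):
    """Raised when (alpha, beta, gamma, delta) leave the stable domain."""


class NumericsError(RuntimeError):
    """Raised when CF inversion fails to converge."""


def _is_one(alpha: float) -> bool:
    return abs(alpha - 1.0) < ALPHA_ONE_BAND


@dataclass(frozen=True)
class StableParams:
    """A point in the alpha-stable family, tagged with its parameterization."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    parameterization: str = "S1"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 2.0):
            raise ParameterError(f"alpha must be in (0, 2], got {self.alpha}")
        if not (-1.0 <= self.beta <= 1.0):
            raise ParameterError(f"beta must be in [-1, 1], got {self.beta}")
        if not (self.gamma > 0.0 and math.isfinite(self.gamma)):
            raise ParameterError(f"gamma must be positive finite, got {self.gamma}")
        if not math.isfinite(self.delta):
            raise ParameterError(f"delta must be finite, got {self.delta}")
        if self.parameterization not in ("S0", "S1"):
            raise ParameterError(
                f"parameterization must be 'S0' or 'S1', got {self.parameterization!r}"
            )

    # -- parameterization changes -------------------------------------------------
    def _shift(self) -> float:
        """delta_S0 - delta_S1 for these (alpha, beta, gamma)."""
        if _is_one(self.alpha):
            return self.beta * (2.0 / math.pi) * self.gamma * math.log(self.gamma)
        return self.beta * self.gamma * math.tan(math.pi * self.alpha / 2.0)

    def to_s0(self) -> "StableParams":
        if self.parameterization == "S0":
            return self
        return replace(self, delta=self.delta + self._shift(), parameterization="S0")

    def to_s1(self) -> "StableParams":
        if self.parameterization == "S1":
            return self
        return replace(self, delta=self.delta - self._shift(), parameterization="S1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.delta)


# ---------------------------------------------------------------------------
# characteristic function
# ---------------------------------------------------------------------------

def stable_cf(t, params: StableParams):
    """Characteristic function E[exp(i t X)] in the S1 form.

    S0 inputs are converted internally.  Vectorized over ``t``.
    """
    p = params.to_s1()
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    a, b, g, d = p.alpha, p.beta, p.gamma, p.delta
    at = np.abs(t)
    sg = np.sign(t)
    if _is_one(a):
        # exp(i d t - g|t| [1 + i b (2/pi) sign(t) ln|t|])
        with np.errstate(divide="ignore", invalid="ignore"):
            tlog = np.where(at > 0, at * np.log(at), 0.0)
        psi = -g * at - 1j * g * b * (2.0 / math.pi) * sg * tlog + 1j * d * t
    else:
        psi = (
            -((g * at) ** a) * (1.0 - 1j * b * sg * math.tan(math.pi * a / 2.0))
            + 1j * d * t
        )
    out = np.exp(psi)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# sampling (Chambers-Mallows-Stuck)
# ---------------------------------------------------------------------------

def stable_sample(params: StableParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. variates via the Chambers--Mallows--Stuck transform.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The alpha = 1
    branch is implemented separately (the general formula is singular there).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    p = params.to_s1()
    a, b, g, d = p.alpha, p.beta, p.gamma, p.delta
    if n == 0:
        return np.empty(0)
    u = rng.uniform(-math.pi / 2.0, math.pi / 2.0, size=n)
    w = rng.exponential(1.0, size=n)
    if _is_one(a):
        half = math.pi / 2.0
        x = (1.0 / half) * (
            (half + b * u) * np.tan(u)
            - b * np.log((half * w * np.cos(u)) / (half + b * u))
        )
        return g * x + (2.0 / math.pi) * b * g * math.log(g) + d
    ta = math.tan(math.pi * a / 2.0)
    bab = math.atan(b * ta) / a
    s = (1.0 + (b * ta) ** 2) ** (1.0 / (2.0 * a))
    x = (
        s
        * np.sin(a * (u + bab))
        / np.cos(u) ** (1.0 / a)
        * (np.cos(u - a * (u + bab)) / w) ** ((1.0 - a) / a)
    )
    return g * x + d


# ---------------------------------------------------------------------------
# density / distribution by CF inversion
# ---------------------------------------------------------------------------

def _std_cf_s0(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Standardized (gamma=1, delta_S0=0) S0 characteristic function."""
    at = np.abs(t)
    sg = np.sign(t)
    if _is_one(alpha):
        with np.errstate(divide="ignore", invalid="ignore"):
            lt = np.where(at > 0, np.log(at), 0.0)
        psi = -at * (1.0 + 1j * beta * (2.0 / math.pi) * sg * lt)
    else:
        ta = math.tan(math.pi * alpha / 2.0)
        psi = -(at**alpha) * (1.0 + 1j * beta * ta * sg * (at ** (1.0 - alpha) - 1.0))
    return np.exp(psi)


def _tail_coeff(alpha: float) -> float:
    """C_alpha = sin(pi alpha / 2) Gamma(alpha) / pi of the Pareto tail."""
    return math.sin(math.pi * alpha / 2.0) * math.gamma(alpha) / math.pi


def _tail_start(alpha: float, tail_switch: float, rel_tol: float = 5e-4) -> float:
    """Where the first-order Pareto series is trusted.

    The relative error of the leading term is O(z^-alpha), so the switch
    additionally requires z^-alpha < rel_tol; below that point the
    oscillatory quadrature is used instead (it stays accurate at large z).
    ``tail_switch`` acts as a floor.  The density uses a looser rel_tol than
    the distribution function: far out the density is so small that the
    quadrature's absolute error floor dominates instead.
    """
    return max(tail_switch, min(rel_tol ** (-1.0 / alpha), 1e8))


def _phase_split(alpha: float, beta: float):
    """Decompose exp(-itz) * phi_S0(t) = A(t) * exp(-i(w0 + z) t + i g(t)).

    Returns (w_shift, A, g): the linear phase shift w0 so that the
    oscillation frequency is w = z + w0, the smooth amplitude A(t) =
    |phi(t)| and the sublinear residual phase g(t).  This lets the Fourier
    integrals be computed with oscillatory (QAWO) quadrature, which plain
    adaptive quadrature cannot manage for small alpha where the CF decays
    slowly.
    """
    if _is_one(alpha):
        def A(t):
            return np.exp(-t)

        def g(t):
            return -beta * (2.0 / math.pi) * t * np.log(t) if t > 0 else 0.0

        return 0.0, A, g
    tau = math.tan(math.pi * alpha / 2.0)

    def A(t):
        return np.exp(-(t**alpha))

    def g(t):
        return beta * tau * t**alpha

    return beta * tau, A, g


def _integration_cutoff(alpha: float) -> float:
    """t beyond which |phi(t)| = exp(-t^alpha) < 1e-14."""
    return min(32.3 ** (1.0 / alpha), 1e6)


_QUAD_OPTS = dict(limit=400, epsabs=1e-10, epsrel=1e-9)


def _pdf_integral(z: float, alpha: float, beta: float) -> float:
    """Integral over (0, inf) of Re[exp(-itz) phi_S0(t)].

    cos(wt - g) = cos(wt)cos(g) + sin(wt)sin(g): the rest functions
    A cos(g), A sin(g) are smooth, so cos/sin-weighted (QAWO) quadrature
    against the dominant linear phase w stays accurate at any frequency.
    """
    w0, A, g = _phase_split(alpha, beta)
    w = z + w0
    T = _integration_cutoff(alpha)
    if abs(w) < 1e-9:
        val, _ = integrate.quad(
            lambda t: A(t) * math.cos(g(t)), 0.0, T, **_QUAD_OPTS
        )
        if beta != 0.0:
            v, _ = integrate.quad(
                lambda t: A(t) * math.sin(g(t)), 0.0, T, weight="sin", wvar=w,
                **_QUAD_OPTS,
            )
            val += v
        return val
    total = 0.0
    v, _ = integrate.quad(
        lambda t: A(t) * math.cos(g(t)), 0.0, T, weight="cos", wvar=w, **_QUAD_OPTS
    )
    total += v
    if beta != 0.0:
        v, _ = integrate.quad(
            lambda t: A(t) * math.sin(g(t)), 0.0, T, weight="sin", wvar=w,
            **_QUAD_OPTS,
        )
        total += v
    if not math.isfinite(total):
        raise NumericsError(
            f"pdf CF inversion failed at z={z} (alpha={alpha}, beta={beta})"
        )
    return total


def _gil_pelaez_integral(z: float, alpha: float, beta: float) -> float:
    """Integral over (0, inf) of Im[exp(-itz) phi_S0(t)] / t.

    The 1/t factor is integrably singular at 0; a short leading segment
    (covering a bounded number of oscillation cycles) is integrated
    directly and the remainder by weighted quadrature.
    """
    w0, A, g = _phase_split(alpha, beta)
    w = z + w0
    T = _integration_cutoff(alpha)
    c = min(1.0, T, 30.0 / max(abs(w), 1.0))
    total, _ = integrate.quad(
        lambda t: -A(t) * math.sin(w * t - g(t)) / t, 0.0, c, **_QUAD_OPTS
    )
    if T > c:
        # -sin(wt - g)/t = -sin(wt) cos(g)/t + cos(wt) sin(g)/t
        v, _ = integrate.quad(
            lambda t: -A(t) * math.cos(g(t)) / t, c, T, weight="sin", wvar=w,
            **_QUAD_OPTS,
        )
        total += v
        if beta != 0.0:
            v, _ = integrate.quad(
                lambda t: A(t) * math.sin(g(t)) / t, c, T, weight="cos", wvar=w,
                **_QUAD_OPTS,
            )
            total += v
    if not math.isfinite(total):
        raise NumericsError(
            f"cdf CF inversion failed at z={z} (alpha={alpha}, beta={beta})"
        )
    return total


def _pdf_std(z: float, alpha: float, beta: float, tail_switch: float) -> float:
    """Standardized S0 density by CF inversion with a Pareto tail branch."""
    if z < 0:  # reflect so the tail branch only ever sees the upper tail
        return _pdf_std(-z, alpha, -beta, tail_switch)
    if alpha < 2.0 and z > _tail_start(alpha, tail_switch, rel_tol=1e-2):
        coef = alpha * _tail_coeff(alpha) * (1.0 + beta)
        if coef > 0:
            return coef * z ** (-alpha - 1.0)
        # beta = -1: this tail is lighter than any power law (or outside the
        # support entirely for alpha < 1); it is zero to double precision here
        return 0.0
    return max(_pdf_integral(z, alpha, beta) / math.pi, 0.0)


def _cdf_std(z: float, alpha: float, beta: float, tail_switch: float) -> float:
    """Standardized S0 CDF via the Gil-Pelaez inversion formula."""
    if alpha < 2.0 and abs(z) > _tail_start(alpha, tail_switch):
        coef = _tail_coeff(alpha) * (1.0 + (beta if z > 0 else -beta))
        tail = coef * abs(z) ** (-alpha)
        if coef > 0:
            return 1.0 - tail if z > 0 else tail
        return 1.0 if z > 0 else 0.0
    im_int = _gil_pelaez_integral(z, alpha, beta)
    return min(max(0.5 - im_int / math.pi, 0.0), 1.0)


def _closed_form(params: StableParams):
    """Return a frozen scipy distribution when a closed form exists."""
    p1 = params.to_s1()
    a, b, g, d = p1.alpha, p1.beta, p1.gamma, p1.delta
    if a == 2.0:
        return stats.norm(loc=d, scale=g * math.sqrt(2.0))
    if _is_one(a) and b == 0.0:
        return stats.cauchy(loc=d, scale=g)
    if a == 0.5 and b == 1.0:
        return stats.levy(loc=d, scale=g)
    if a == 0.5 and b == -1.0:
        return stats.levy_l(loc=d, scale=g)
    return None


def stable_pdf(x, params: StableParams, tail_switch: float = TAIL_SWITCH):
    """Density of the stable law, vectorized over ``x``.

    Closed forms are used for the normal, Cauchy and Levy cases; otherwise
    the CF is inverted by adaptive quadrature, switching to the Pareto
    asymptotic branch for ``|x - delta| > tail_switch * gamma``.
    """
    frozen = _closed_form(params)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    if frozen is not None:
        out = frozen.pdf(xv)
    else:
        p0 = params.to_s0()
        z = (xv - p0.delta) / p0.gamma
        out = np.array(
            [_pdf_std(zi, p0.alpha, p0.beta, tail_switch) for zi in z]
        ) / p0.gamma
    return float(out[0]) if scalar else out


def stable_cdf(x, params: StableParams, tail_switch: float = TAIL_SWITCH):
    """Cumulative distribution function, vectorized over ``x``."""
    frozen = _closed_form(params)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    if frozen is not None:
        out = frozen.cdf(xv)
    else:
        p0 = params.to_s0()
        z = (xv - p0.delta) / p0.gamma
        out = np.array([_cdf_std(zi, p0.alpha, p0.beta, tail_switch) for zi in z])
    return float(out[0]) if scalar else out


def stable_ccdf(x, params: StableParams, tail_switch: float = TAIL_SWITCH):
    """Survival function 1 - F(x); asymptotically ~ x^(-alpha) for alpha < 2."""
    frozen = _closed_form(params)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    if frozen is not None:
        out = frozen.sf(xv)
    else:
        p0 = params.to_s0()
        z = (xv - p0.delta) / p0.gamma
        out = np.array(
            [1.0 - _cdf_std(zi, p0.alpha, p0.beta, tail_switch) for zi in z]
        )
    return float(out[0]) if scalar else out


def abs_ccdf(m, params: StableParams, tail_switch: float = TAIL_SWITCH):
    """P(|X| > m) for X stable -- the survival law of noise magnitudes."""
    m = np.asarray(m, dtype=float)
    return stable_ccdf(m, params, tail_switch) + stable_cdf(-m, params, tail_switch)
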