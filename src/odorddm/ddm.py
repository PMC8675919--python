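"""Closed-form drift-diffusion quantities.

All formulas refer to a Wiener process ``dx/dt = A + xi`` with
``E[xi(t) xi(t')] = c^2 delta(t - t')``, absorbing bounds at ``+theta``
("report present") and ``-theta`` ("report absent"), and start point
``m * theta``.  The dimensionless combination ``r = 2 A theta / c^2``
controls both the choice probability and the decision-time moments.

Everything here is deterministic, vectorized where it pays, and written
to stay finite for the extreme parameter values an optimizer will visit
(log-space / ``expm1`` forms for large ``|r|``, explicit limit branches
for ``r -> 0``).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import log_ndtr

from .params import DDMParameters, ParameterDomainError

__all__ = [
    "scaled_drift",
    "choice_probability",
    "mean_decision_time",
    "g_factor",
    "choice_probability_derivatives",
    "mean_dt_derivative_c2",
    "fpt_defective_cdf",
    "fpt_quantile",
    "UndefinedDerivativeError",
]

#: below this |r| the explicit r -> 0 limit branches are used
R_LIMIT = 1e-6


class UndefinedDerivativeError(ValueError):
    """Derivative requested at r = 0 where the printed form is 0/0."""


def scaled_drift(params: DDMParameters) -> float:
    """Dimensionless drift r = 2 A theta / c^2 (may be zero)."""
    return 2.0 * params.drift * params.threshold / params.diffusion_var


def choice_probability(params: DDMParameters) -> float:
    """Probability p of absorption at +theta ("report present").

    p = [exp(r) - exp(-r m)] / [2 sinh(r)]  for r != 0, with the
    continuous limit (1 + m) / 2 at r = 0.  Evaluated through an
    equivalent ``expm1`` ratio that never overflows for r > 0; r < 0 is
    mapped through the reflection p(A, m) = 1 - p(-A, -m).
    """
    r = scaled_drift(params)
    m = params.start_bias
    return _choice_probability_rm(r, m)


def _choice_probability_rm(r: float, m: float) -> float:
    if abs(r) < R_LIMIT:
        # limit branch with its first-order term, smooth to ~1e-12
        return 0.5 * (1.0 + m) + 0.25 * r * (1.0 - m * m)
    if r <= -30.0:
        # p = e^{r(1-m)} up to a relative error of e^{2r}; evaluating
        # directly keeps full precision for vanishing probabilities
        # (the reflection 1 - p(-r,-m) would saturate at ~1e-16)
        return math.exp(r * (1.0 - m))
    # multiply numerator and denominator of Eq. p by exp(-r):
    # p = (1 - e^{-r(1+m)}) / (1 - e^{-2r}); exact for either sign of r
    # and overflow-free on (-30, inf)
    return math.expm1(-r * (1.0 + m)) / math.expm1(-2.0 * r)


def mean_decision_time(params: DDMParameters) -> float:
    """Mean decision time E[DT] (seconds, Ter not included).

    E[DT] = theta [cosh(r) - m sinh(r) - exp(-r m)] / [A sinh(r)]
    with the pure-diffusion limit theta^2 (1 - m^2) / c^2 at r = 0.
    The reflection symmetry E[DT](A, m) = E[DT](-A, -m) reduces the
    evaluation to r >= 0 where all exponents are non-positive.
    """
    theta = params.threshold
    c2 = params.diffusion_var
    r = scaled_drift(params)
    m = params.start_bias
    if r < 0.0:
        r, m = -r, -m
    if r < R_LIMIT:
        return theta * theta * (1.0 - m * m) / c2 * (1.0 - r * m / 3.0)
    A = r * c2 / (2.0 * theta)  # |drift| after reflection
    # bracket = coth(r) - m - exp(-r m)/sinh(r), written overflow-free
    bracket = (
        1.0 / math.tanh(r)
        - m
        - 2.0 * math.exp(-r * (1.0 + m)) / (-math.expm1(-2.0 * r))
    )
    return theta / A * bracket


def g_factor(r: float, m: float) -> float:
    """g(r) = exp(-r m) [cosh(r) + m sinh(r)] - 1.

    Strictly positive for r != 0 and m in (-1, 1); g(0) = 0.  This
    factor carries the sign structure of every sensitivity below.
    """
    if not -1.0 < m < 1.0:
        raise ParameterDomainError(f"start bias m must lie in (-1, 1), got {m}")
    return math.exp(-r * m) * (math.cosh(r) + m * math.sinh(r)) - 1.0


def _g_over_sinh2(r: float, m: float) -> float:
    """g(r) / sinh(r)^2, stable for any r != 0, m in (-1, 1)."""
    if r < 0.0:
        r, m = -r, -m
    if r < 1e-3:
        # series: g ~ (1-m^2) r^2 / 2 (1 - 2 m r / 3), sinh^2 ~ r^2
        return 0.5 * (1.0 - m * m) * (1.0 - 2.0 * m * r / 3.0)
    # multiply g and sinh^2 by 4 e^{-2r}: all exponents are <= 0
    em2r = math.exp(-2.0 * r)
    num = (
        2.0 * (1.0 + m) * math.exp(-r * (1.0 + m))
        + 2.0 * (1.0 - m) * math.exp(-r * (3.0 + m))
        - 4.0 * em2r
    )
    den = (1.0 - em2r) ** 2
    return num / den


def _require_nonzero_r(params: DDMParameters) -> float:
    r = scaled_drift(params)
    if abs(r) < 1e-12:
        raise UndefinedDerivativeError(
            "scaled drift r = 0: the printed derivative forms are 0/0; "
            "take the limit explicitly in the caller"
        )
    return r


def choice_probability_derivatives(params: DDMParameters) -> tuple[float, float]:
    """(dp/dA, dp/dc^2) for r != 0.

    dp/dA   =  theta g(r) / (c^2 sinh^2 r)          > 0 always;
    dp/dc^2 = -A theta g(r) / (c^4 sinh^2 r)        opposite sign to A.
    """
    r = _require_nonzero_r(params)
    h = _g_over_sinh2(r, params.start_bias)
    theta = params.threshold
    c2 = params.diffusion_var
    dp_dA = theta * h / c2
    dp_dc2 = -params.drift * theta * h / (c2 * c2)
    return dp_dA, dp_dc2


def mean_dt_derivative_c2(params: DDMParameters) -> float:
    """dE[DT]/dc^2 = -2 theta^2 g(r) / (c^4 sinh^2 r), strictly < 0."""
    r = _require_nonzero_r(params)
    h = _g_over_sinh2(r, params.start_bias)
    theta = params.threshold
    c2 = params.diffusion_var
    return -2.0 * theta * theta * h / (c2 * c2)


# ---------------------------------------------------------------------------
# First-passage-time defective distributions
# ---------------------------------------------------------------------------
#
# Internally the process is rescaled to unit variance on [0, a]:
#     a = 2 theta / c,   start z = (1 + m) theta / c,   drift v = A / c.
# Two exact series represent the defective CDF at the *lower* barrier
# (the upper barrier follows by reflection v -> -v, z -> a - z):
#
# large-time (spectral):
#   F0(t) = P0 - (2 pi / a^2) e^{-v z}
#           sum_k k sin(k pi z / a) e^{-(v^2 + k^2 pi^2/a^2) t / 2}
#                 / (v^2 + k^2 pi^2 / a^2)
#
# small-time (method of images, each image integrating to a shifted
# single-barrier passage-time CDF):
#   F0(t) = 1/2 sum_{k in Z} [ s(b_k) E(|b_k|) - s(bt_k) E(|bt_k|) ]
#   b_k = z + 2 k a,  bt_k = -z + 2 k a,  s = sign, and
#   E(b) = e^{v(b - z)} Phi((-v t - b)/sqrt t)
#        + e^{-v(b + z)} Phi(( v t - b)/sqrt t),
# evaluated as exp(coef + log Phi) so opposing huge/tiny factors cancel
# in log space.  The representation with fewer terms is selected per t.

_SERIES_EPS = 1e-12
_LOG_EPS = -math.log(_SERIES_EPS)  # ~27.6


def _scaled_geometry(params: DDMParameters) -> tuple[float, float, float]:
    c = math.sqrt(params.diffusion_var)
    a = 2.0 * params.threshold / c
    z = (1.0 + params.start_bias) * params.threshold / c
    v = params.drift / c
    return a, z, v


def _lower_mass(a: float, z: float, v: float) -> float:
    """P(absorb at lower barrier), unit variance, barriers 0 and a."""
    # in the +/-theta parameterization: r = v * a, m = 2 z / a - 1
    r = v * a
    m = 2.0 * z / a - 1.0
    return 1.0 - _choice_probability_rm(r, m)


def _small_time_lower_cdf(t: np.ndarray, a: float, z: float, v: float) -> np.ndarray:
    sqrt_t = np.sqrt(t)
    t_max = float(np.max(t))
    n_img = int(
        math.ceil((abs(v) * t_max + math.sqrt(2.0 * _LOG_EPS * t_max) + a) / (2.0 * a))
    )
    n_img = min(max(n_img, 1), 512)
    ks = np.arange(-n_img, n_img + 1, dtype=float)
    starts = np.concatenate([z + 2.0 * ks * a, -(-z + 2.0 * ks * a)])
    signs = np.concatenate([np.sign(z + 2.0 * ks * a), -np.sign(-z + 2.0 * ks * a)])
    b = np.abs(starts)[None, :]  # image distances, shape (1, n_terms)
    signs = signs[None, :]
    with np.errstate(divide="ignore"):
        inv_sqrt_t = np.where(t[:, None] > 0, 1.0 / sqrt_t[:, None], np.inf)
    arg1 = (-v * t[:, None] - b) * inv_sqrt_t
    arg2 = (v * t[:, None] - b) * inv_sqrt_t
    term = np.exp(v * (b - z) + log_ndtr(arg1)) + np.exp(-v * (b + z) + log_ndtr(arg2))
    out = 0.5 * np.sum(signs * term, axis=1)
    return out


def _large_time_lower_cdf(
    t: np.ndarray, a: float, z: float, v: float, mass: float
) -> np.ndarray:
    t_min = float(np.min(t))
    tau = max(t_min, 1e-300) / (a * a)
    n_terms = int(math.ceil(math.sqrt(2.0 * _LOG_EPS / (math.pi**2 * tau)))) + 1
    n_terms = min(max(n_terms, 4), 4096)
    k = np.arange(1, n_terms + 1, dtype=float)
    lam = 0.5 * (v * v + (k * math.pi / a) ** 2)  # decay rates
    coef = k * np.sin(k * math.pi * z / a) / (v * v + (k * math.pi / a) ** 2)
    log_pref = -v * z  # may be large; folded into the per-term exponent
    expo = log_pref - lam[None, :] * t[:, None]
    series = np.sum(coef[None, :] * np.exp(np.minimum(expo, 700.0)), axis=1)
    return mass - (2.0 * math.pi / (a * a)) * series


def _defective_cdf_lower(t: np.ndarray, a: float, z: float, v: float) -> np.ndarray:
    """Defective CDF at the lower barrier, vectorized over t >= 0."""
    mass = _lower_mass(a, z, v)
    out = np.zeros_like(t, dtype=float)
    pos = t > 0.0
    if not np.any(pos):
        return out
    tp = t[pos]
    # per-t series selection: compare estimated term counts, and refuse
    # the spectral form where its prefactor exponent cannot cancel safely
    with np.errstate(divide="ignore"):
        k_large = np.sqrt(2.0 * _LOG_EPS * a * a / (math.pi**2 * tp))
    k_small = (np.abs(v) * tp + np.sqrt(2.0 * _LOG_EPS * tp) + a) / (2.0 * a)
    overflow_risk = (-v * z - 0.5 * v * v * tp) > 30.0
    use_large = (k_large <= np.minimum(k_small, 64.0)) & ~overflow_risk
    vals = np.empty_like(tp)
    if np.any(use_large):
        vals[use_large] = _large_time_lower_cdf(tp[use_large], a, z, v, mass)
    if np.any(~use_large):
        vals[~use_large] = _small_time_lower_cdf(tp[~use_large], a, z, v)
    out[pos] = np.clip(vals, 0.0, mass)
    return out


def fpt_defective_cdf(params: DDMParameters, t, boundary: str):
    """P(absorbed at ``boundary`` and decision time <= t).

    ``t`` is on the decision-time scale (non-decision time excluded) and
    may be a scalar or array.  The value is nondecreasing in t and tends
    to the boundary's choice probability as t -> infinity, so the two
    boundaries' masses sum to 1.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("decision time t must be >= 0")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    a, z, v = _scaled_geometry(params)
    if boundary == "upper":
        out = _defective_cdf_lower(t_arr, a, a - z, -v)
    else:
        out = _defective_cdf_lower(t_arr, a, z, v)
    return float(out[0]) if scalar else out


def boundary_mass(params: DDMParameters, boundary: str) -> float:
    """Total defective mass at a boundary (the t -> infinity value)."""
    p_up = choice_probability(params)
    return p_up if boundary == "upper" else 1.0 - p_up


def fpt_quantile(
    params: DDMParameters, prob: float, boundary: str, tol: float = 1e-8
) -> float:
    """Invert the defective CDF by monotone bisection.

    ``prob`` must lie in (0, mass) where mass is the boundary's total
    defective probability.  Returns the decision time t with
    ``fpt_defective_cdf(params, t, boundary) = prob`` to within ``tol``
    seconds.
    """
    mass = boundary_mass(params, boundary)
    if not 0.0 < prob < mass:
        raise ValueError(f"prob must lie in (0, {mass:.6g}), got {prob}")
    hi = max(4.0 * mean_decision_time(params), 1e-3)
    while float(fpt_defective_cdf(params, hi, boundary)) < prob:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - defensive
            raise RuntimeError("quantile bracket expansion failed")
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if float(fpt_defective_cdf(params, mid, boundary)) < prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
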