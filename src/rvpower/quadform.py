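"""Tail probabilities of positive linear combinations of chi-square variables.

The variance-component tests in :mod:`rvpower.association` reduce to a
statistic ``Q`` whose null distribution is ``sum_j lambda_j * chi2_1``.  This
module computes ``P(Q > q)`` by numerical inversion of the characteristic
function (the approach introduced by Davies and Imhof), with the Liu
moment-matching approximation as a fallback when the inversion cannot reach
the requested accuracy.

The inversion evaluates Imhof's integral

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du,

    theta(u) = 0.5 * (sum_j atan(lambda_j u) - q u),
    rho(u)   = prod_j (1 + lambda_j^2 u^2)^(1/4),

by a midpoint rule.  Following Davies, the integration step is chosen from a
Chernoff bound on the tail of ``Q`` (which controls the aliasing error of the
discretisation), and the truncation point from the envelope of the integrand
combined with an integration-by-parts bound on the oscillatory tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import special, stats

__all__ = [
    "QuadFormSpec",
    "QuadFormResult",
    "davies_pvalue",
    "davies_pvalue_adaptive",
    "davies_sf_multi",
    "liu_pvalue",
    "liu_params",
    "liu_params_from_traces",
    "liu_pvalue_from_traces",
    "liu_quantile_from_traces",
    "liu_quantile",
    "quadform_pvalue",
]

#: eigenvalues below EIG_TRUNC * max(eig) are treated as numerical noise
EIG_TRUNC = 1e-10

_MAX_NODES_DEFAULT = 20_000_000


@dataclass(frozen=True)
class QuadFormSpec:
    """Observed statistic plus the chi-square-mixture weights of its null law."""

    q_obs: float
    lambdas: np.ndarray
    method: str = "davies"

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("lambdas must be a non-empty 1-d array")
        if not np.all(np.isfinite(lam)):
            raise ValueError("lambdas must be finite")
        object.__setattr__(self, "lambdas", lam)


@dataclass(frozen=True)
class QuadFormResult:
    pvalue: float
    method_used: str          # "davies" or "liu"
    converged: bool
    abs_accuracy: float


def _truncate_lambdas(lambdas: np.ndarray) -> np.ndarray:
    """Drop eigenvalues that are numerically zero (or negative round-off)."""
    lam = np.asarray(lambdas, dtype=float)
    lmax = lam.max(initial=0.0)
    if lmax <= 0:
        raise ValueError("need at least one positive eigenvalue")
    return lam[lam > EIG_TRUNC * lmax]


@njit(cache=True)
def _grid_nb(lam: np.ndarray, x_delta: float, x_trunc: float,
             acc: float) -> tuple[float, float]:
    """Integration step and truncation point (numba twin of the helpers).

    ``x_delta`` controls the aliasing bound (largest threshold served by the
    grid), ``x_trunc`` the tail-residual bound (smallest threshold).
    Returns ``(delta, upper)``; ``upper < 0`` flags failure.
    """
    k = lam.shape[0]
    # Chernoff tail point at s = 1/4 (lambdas normalised to max 1)
    log_mgf = 0.0
    for j in range(k):
        log_mgf -= 0.5 * math.log1p(-0.5 * lam[j])
    tail = 4.0 * (math.log(4.0 / acc) + log_mgf)
    spacing = tail if tail > x_delta else x_delta
    delta = 2.0 * math.pi / spacing
    # phase-monotonicity point: sum lam/(1+lam^2 u^2) <= x/2
    u = 1.0
    while True:
        s = 0.0
        for j in range(k):
            lu = lam[j] * u
            s += lam[j] / (1.0 + lu * lu)
        if s <= 0.5 * x_trunc:
            break
        u *= 2.0
        if u > 1e30:
            return delta, -1.0
    # truncation: residual after the analytic end correction below acc/4
    log_target = math.log(0.25 * acc)
    while True:
        logrho = 0.0
        for j in range(k):
            lu = lam[j] * u
            logrho += 0.25 * math.log1p(lu * lu)
        log_res = (-math.log(math.pi * u) - logrho
                   + math.log(0.5 * k + 1.5) - math.log(u)
                   - 2.0 * math.log(0.25 * x_trunc))
        if log_res <= log_target:
            break
        u *= 2.0
        if u > 1e30:
            return delta, -1.0
    return delta, u


@njit(cache=True)
def _end_correction_nb(lam: np.ndarray, x: float, u_end: float) -> float:
    theta = -0.5 * x * u_end
    dtheta = -0.5 * x
    logrho = 0.0
    for j in range(lam.shape[0]):
        lu = lam[j] * u_end
        theta += 0.5 * math.atan(lu)
        dtheta += 0.5 * lam[j] / (1.0 + lu * lu)
        logrho += 0.25 * math.log1p(lu * lu)
    g = math.exp(-logrho) / (math.pi * u_end)
    return g * math.cos(theta) / dtheta


@njit(cache=True)
def _imhof_sum(x: float, lam: np.ndarray, delta: float, n_nodes: int) -> float:
    """Midpoint-rule sum of the Imhof integrand for a single threshold."""
    total = 0.0
    for i in range(n_nodes):
        u = (i + 0.5) * delta
        theta = -0.5 * x * u
        logrho = 0.0
        for j in range(lam.shape[0]):
            lu = lam[j] * u
            theta += 0.5 * math.atan(lu)
            logrho += 0.25 * math.log1p(lu * lu)
        total += math.sin(theta) * math.exp(-logrho) / u
    return total * delta / math.pi


@njit(cache=True)
def _imhof_sum_multi(xs: np.ndarray, lam: np.ndarray, delta: float,
                     n_nodes: int, out: np.ndarray) -> None:
    """Imhof sums for several thresholds sharing one integration grid.

    The eigenvalue-dependent parts (``atan``/``log1p``) are computed once per
    node, which makes the per-threshold cost a single ``sin``.
    """
    for i in range(n_nodes):
        u = (i + 0.5) * delta
        phi = 0.0
        logrho = 0.0
        for j in range(lam.shape[0]):
            lu = lam[j] * u
            phi += 0.5 * math.atan(lu)
            logrho += 0.25 * math.log1p(lu * lu)
        env = math.exp(-logrho) / u
        for t in range(xs.shape[0]):
            out[t] += math.sin(phi - 0.5 * xs[t] * u) * env
    for t in range(xs.shape[0]):
        out[t] = out[t] * delta / math.pi


def _chernoff_tail_point(lam: np.ndarray, target: float) -> float:
    """y such that P(Q > y) <= target, via exp(-sy) * prod(1-2*lam*s)^(-1/2).

    Uses the fixed argument s = 1/(4*max(lam)); slightly conservative but
    closed-form.  ``lam`` is assumed normalised to max(lam) == 1.
    """
    log_mgf = -0.5 * np.sum(np.log1p(-0.5 * lam))
    return 4.0 * (math.log(1.0 / target) + log_mgf)


def _chernoff_lower_point(lam: np.ndarray, target: float) -> float:
    """y such that P(Q < y) <= target (0 if no positive y qualifies)."""
    # P(Q < y) <= exp(s*y) * prod(1 + 2*lam*s)^(-1/2) for s > 0, optimised
    # over a coarse grid of s values.
    best = 0.0
    for s in (0.5, 2.0, 8.0, 32.0, 128.0, 512.0, 4096.0):
        log_mgf = -0.5 * np.sum(np.log1p(2.0 * lam * s))
        y = (math.log(target) - log_mgf) / s
        best = max(best, y)
    return max(best, 0.0)


def _envelope_log(lam: np.ndarray, u: float) -> float:
    """log of the integrand envelope 1/(pi * u * rho(u))."""
    return -math.log(math.pi * u) - 0.25 * np.sum(np.log1p((lam * u) ** 2))


def davies_pvalue(q: float, lambdas: np.ndarray, acc: float = 1e-9,
                  max_nodes: int = _MAX_NODES_DEFAULT) -> float:
    """``P(sum_j lambda_j chi2_1 > q)`` by characteristic-function inversion.

    Parameters
    ----------
    q : observed value (``q <= 0`` returns 1 for positive weights).
    lambdas : positive mixture weights; near-zero entries are truncated.
    acc : requested absolute accuracy of the tail probability.
    max_nodes : abort (raise ``FloatingPointError``) beyond this grid size.
    """
    lam = _truncate_lambdas(lambdas)
    if q <= 0.0:
        return 1.0
    scale = lam.max()
    lam = lam / scale
    x = q / scale
    delta, upper = _grid_nb(lam, x, x, acc)
    if upper < 0 or upper / delta + 1 > max_nodes:
        raise FloatingPointError("quadform inversion node budget exceeded")
    n_nodes = int(upper / delta) + 1
    u_end = n_nodes * delta
    p = (0.5 + _imhof_sum(x, lam, delta, n_nodes)
         + _end_correction_nb(lam, x, u_end))
    if p < -4.0 * acc or p > 1.0 + 4.0 * acc:
        raise FloatingPointError(f"inversion out of range: p = {p}")
    return min(max(p, 0.0), 1.0)


def davies_sf_multi(qs: np.ndarray, lambdas: np.ndarray, acc: float = 1e-6,
                    max_nodes: int = _MAX_NODES_DEFAULT) -> np.ndarray:
    """Upper-tail probabilities at several thresholds for one mixture.

    Shares the eigenvalue-dependent part of the integrand across thresholds;
    thresholds in the far lower/upper tail (by Chernoff bounds) short-circuit
    to 1/0.
    """
    lam = _truncate_lambdas(lambdas)
    qs = np.asarray(qs, dtype=float)
    scale = lam.max()
    lam = lam / scale
    xs = qs / scale
    out = np.empty_like(xs)
    hi_point = _chernoff_tail_point(lam, acc / 4.0)
    lo_point = _chernoff_lower_point(lam, acc / 4.0)
    trivial_lo = xs <= max(lo_point, 1e-12)
    trivial_hi = xs >= hi_point
    out[trivial_lo] = 1.0
    out[trivial_hi] = 0.0
    mid = ~(trivial_lo | trivial_hi)
    if np.any(mid):
        xm = xs[mid]
        delta, upper = _grid_nb(lam, float(xm.max()), float(xm.min()), acc)
        if upper < 0 or upper / delta + 1 > max_nodes:
            raise FloatingPointError("quadform inversion node budget exceeded")
        n_nodes = int(upper / delta) + 1
        buf = np.zeros(xm.size)
        _imhof_sum_multi(xm, lam, delta, n_nodes, buf)
        u_end = n_nodes * delta
        corr = np.array([_end_correction_nb(lam, float(x), u_end) for x in xm])
        out[mid] = np.clip(0.5 + buf + corr, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Liu et al. moment-matching approximation (modified form)


def liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matching parameters ``(mu_Q, sigma_Q, df, ncp)``.

    Matches the skewness (and where possible the kurtosis) of the mixture to
    a non-central chi-square reference distribution.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam2 = lam * lam
    return liu_params_from_traces(float(lam.sum()), float(lam2.sum()),
                                  float((lam2 * lam).sum()),
                                  float((lam2 * lam2).sum()))


def liu_params_from_traces(c1: float, c2: float, c3: float, c4: float
                           ) -> tuple[float, float, float, float]:
    """Moment parameters from the power sums ``c_j = sum lambda^j``.

    The power sums equal ``tr(A^j)`` for the mixture's kernel matrix, so the
    approximation never needs an eigendecomposition.
    """
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * d
    else:
        df = 1.0 / s2
        d = 0.0
    mu_q = c1
    sigma_q = math.sqrt(2.0 * c2)
    return mu_q, sigma_q, df, d


def _liu_pvalue_params(q, mu_q, sigma_q, df, d) -> float:
    mu_x = df + d
    sigma_x = math.sqrt(2.0 * (df + 2.0 * d))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if d > 0:
        return float(stats.ncx2.sf(x, df, d))
    if x <= 0:
        return 1.0
    return float(special.chdtrc(df, x))


def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Upper-tail probability from the moment-matched chi-square reference."""
    return _liu_pvalue_params(q, *liu_params(lambdas))


def liu_pvalue_from_traces(q: float, c1: float, c2: float, c3: float,
                           c4: float) -> float:
    """Moment-matched upper tail from kernel power-sums (no eigenvalues)."""
    return _liu_pvalue_params(q, *liu_params_from_traces(c1, c2, c3, c4))


def _liu_quantile_params(p_upper, mu_q, sigma_q, df) -> float:
    q_ref = special.chdtri(df, p_upper)
    return float((q_ref - df) / math.sqrt(2.0 * df) * sigma_q + mu_q)


def liu_quantile(p_upper: float, lambdas: np.ndarray) -> float:
    """Threshold q with moment-matched upper-tail probability ``p_upper``.

    Used to convert a minimum p-value over a family of mixtures back to
    per-mixture thresholds (the central-reference form, df only).
    """
    mu_q, sigma_q, df, _ = liu_params(lambdas)
    return _liu_quantile_params(p_upper, mu_q, sigma_q, df)


def liu_quantile_from_traces(p_upper: float, c1: float, c2: float, c3: float,
                             c4: float) -> float:
    """Moment-matched upper-tail quantile from kernel power-sums."""
    mu_q, sigma_q, df, _ = liu_params_from_traces(c1, c2, c3, c4)
    return _liu_quantile_params(p_upper, mu_q, sigma_q, df)


def davies_pvalue_adaptive(q: float, lambdas: np.ndarray, *,
                           rel: float = 5e-3, floor: float = 1e-8,
                           cap: float = 1e-3,
                           max_nodes: int = 400_000) -> tuple[float, str]:
    """Inversion with accuracy targeted relative to the p-value's size.

    A Liu pre-estimate sets the absolute accuracy to ``rel`` times the
    p-value (clipped to ``[floor, cap]``), so large p-values use coarse cheap
    grids while deep-tail p-values are resolved to ``floor``.  Falls back to
    the Liu value when the inversion exceeds its node budget (which happens
    only far in the lower tail, where the upper-tail probability is near 1
    and the moment approximation is adequate for any decision rule).
    """
    p0 = liu_pvalue(q, lambdas)
    acc = min(cap, max(floor, rel * p0))
    try:
        return davies_pvalue(q, lambdas, acc=acc, max_nodes=max_nodes), \
            "davies"
    except FloatingPointError:
        return p0, "liu"


# ---------------------------------------------------------------------------


def quadform_pvalue(spec: QuadFormSpec, acc: float = 1e-9,
                    max_nodes: int = _MAX_NODES_DEFAULT) -> QuadFormResult:
    """Tail probability for a quadratic-form statistic with fallback logic.

    Tries the characteristic-function inversion first; if it cannot reach the
    requested accuracy (node budget exceeded or out-of-range result) the Liu
    approximation is used and flagged in ``method_used``.
    """
    lam = _truncate_lambdas(spec.lambdas)
    if spec.q_obs < 0:
        raise ValueError("q_obs must be non-negative")
    if spec.method == "liu":
        return QuadFormResult(liu_pvalue(spec.q_obs, lam), "liu", True, math.nan)
    try:
        p = davies_pvalue(spec.q_obs, lam, acc=acc, max_nodes=max_nodes)
        return QuadFormResult(p, "davies", True, acc)
    except FloatingPointError:
        return QuadFormResult(liu_pvalue(spec.q_obs, lam), "liu", False, math.nan)
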