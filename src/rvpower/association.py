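"""Gene-level association tests for quantitative traits.

Four tests of the same causal locus (a gene with ``k`` SNVs):

* **single-marker test (SMT)** — per-SNV Wald-type t-test from the OLS fit
  ``y ~ 1 + x1 + x2 + g_i`` (residual df ``n - 4``), combined to a gene-level
  decision through the minP rule after Bonferroni or Benjamini-Hochberg
  adjustment of the ``k`` per-SNV p-values;
* **burden test** — Wald t-test of the unweighted minor-allele sum
  ``y ~ 1 + x1 + x2 + sum_i g_i``;
* **SKAT** — variance-component score test with the linear weighted kernel,
  weights the Beta(1, 25) density of each SNV's MAF, p-value from the
  chi-square-mixture inversion in :mod:`rvpower.quadform`;
* **SKAT-O** — optimal convex combination of SKAT and the weighted burden
  score statistic over a grid of mixing parameters rho, with the
  one-dimensional-integration correction for searching the grid.

All tests can include every SNV of the gene or only the rare ones
(MAF <= 0.03), applied identically so that the tests remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .quadform import (QuadFormSpec, QuadFormResult, davies_pvalue_adaptive,
                       davies_sf_multi, liu_pvalue, liu_pvalue_from_traces,
                       liu_quantile_from_traces, EIG_TRUNC)

__all__ = [
    "RARE_MAF_THRESHOLD",
    "DEFAULT_RHO_GRID",
    "SingleMarkerFit",
    "GeneTestResult",
    "smt_fit",
    "smt_fit_all",
    "adjust_pvalues",
    "gene_level_smt",
    "burden_test",
    "skat_weights",
    "skat_test",
    "skato_test",
    "run_gene_tests",
]

#: MAF cutoff below which a variant counts as rare
RARE_MAF_THRESHOLD = 0.03

#: default rho grid of the optimal combined test
DEFAULT_RHO_GRID = (0.0, 0.1 ** 2, 0.2 ** 2, 0.3 ** 2, 0.4 ** 2,
                    0.5 ** 2, 0.5, 1.0)

# relative tolerance declaring a genotype column collinear with covariates
_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class SingleMarkerFit:
    """Per-SNV OLS fits of ``y ~ 1 + x1 + x2 + g`` (arrays over SNVs)."""

    beta_hat: np.ndarray      # (k,) SNV effect estimates
    se_hat: np.ndarray        # (k,) standard errors
    t_stat: np.ndarray        # (k,) beta_hat / se_hat
    df: int                   # residual degrees of freedom, n - 4
    p_raw: np.ndarray         # (k,) two-sided p from t_df
    gamma_hat: np.ndarray     # (k, 3) intercept/covariate coefficients
    sigma2_hat: np.ndarray    # (k,) unbiased residual-variance estimates
    valid: np.ndarray         # (k,) False where g is collinear with design


@dataclass(frozen=True)
class GeneTestResult:
    """Per-replicate p-values of all four tests under one inclusion mode."""

    inclusion: str
    site_index: np.ndarray        # indices into the gene's site list
    smt_p_raw: np.ndarray
    smt_p_adj_bh: np.ndarray
    smt_p_adj_bonf: np.ndarray
    smt_min_p_bh: float
    smt_min_p_bonf: float
    burden_p: float
    skat_p: float
    skato_p: float
    smt_fit: SingleMarkerFit | None = None


class _NullDesign:
    """Shared pre-computation: covariate design and residualisation.

    ``X`` is the full covariate design including the intercept column; the
    simulation-study path uses ``[1, x1, x2]`` so that single-marker fits
    carry ``n - 4`` residual degrees of freedom.
    """

    def __init__(self, y: np.ndarray, x1: np.ndarray = None,
                 x2: np.ndarray = None, *, X: np.ndarray | None = None):
        n = y.shape[0]
        if X is None:
            X = np.column_stack([np.ones(n), x1, x2])
        XtX = X.T @ X
        self.X = X
        self.n = n
        self._chol = np.linalg.cholesky(XtX)
        self.gamma_null = self.solve(X.T @ y)
        self.resid_y = y - X @ self.gamma_null
        self.yty = float(self.resid_y @ self.resid_y)
        self.sigma2_ml = self.yty / n          # score-test variance
        if self.sigma2_ml <= 0:
            raise ValueError("response is collinear with the covariates")

    def solve(self, b: np.ndarray) -> np.ndarray:
        z = np.linalg.solve(self._chol, b)
        return np.linalg.solve(self._chol.T, z)

    def residualize(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (G - X (X'X)^-1 X' G, the projection coefficients)."""
        C = self.solve(self.X.T @ G)
        return G - self.X @ C, C


def _as_matrix(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    return g[:, None] if g.ndim == 1 else g


def smt_fit_all(y, x1, x2, G, *, design: _NullDesign | None = None
                ) -> SingleMarkerFit:
    """Vectorised per-SNV OLS over all columns of ``G``.

    Uses the Frisch-Waugh-Lovell residualisation: each SNV effect (and its
    standard error) from the 4-column fit equals the simple regression of the
    covariate-residualised trait on the covariate-residualised genotype, with
    the residual degrees of freedom of the full model (``n - 4``).
    """
    G = _as_matrix(G)
    d = design if design is not None else _NullDesign(np.asarray(y, float),
                                                      np.asarray(x1, float),
                                                      np.asarray(x2, float))
    n, k = G.shape
    n_covar = d.X.shape[1]
    if n <= n_covar + 1:
        raise ValueError("need more observations than fitted coefficients")
    Gt, C = d.residualize(G)
    gg = np.einsum("ij,ij->j", Gt, Gt)
    col_norm = np.einsum("ij,ij->j", G, G)
    valid = gg > _COLLINEAR_TOL * np.maximum(col_norm, 1.0)
    gg_safe = np.where(valid, gg, np.nan)
    gy = Gt.T @ d.resid_y
    beta = gy / gg_safe
    df = n - n_covar - 1
    sse = d.yty - beta * gy
    sigma2 = sse / df
    se = np.sqrt(sigma2 / gg_safe)
    t = beta / se
    p = 2.0 * special.stdtr(df, -np.abs(t))
    gamma = d.gamma_null[None, :] - (C * beta[None, :]).T
    return SingleMarkerFit(beta_hat=beta, se_hat=se, t_stat=t, df=df,
                           p_raw=p, gamma_hat=gamma, sigma2_hat=sigma2,
                           valid=valid)


def smt_fit(pheno, g) -> SingleMarkerFit:
    """Single-SNV convenience wrapper around :func:`smt_fit_all`."""
    return smt_fit_all(pheno.y, pheno.x1, pheno.x2, np.asarray(g, float))


def adjust_pvalues(p_raw, method: str = "bh") -> np.ndarray:
    """Multiplicity-adjusted p-values, input order preserved.

    ``bonferroni``: ``min(1, k * p)``.  ``bh``: Benjamini-Hochberg step-up
    adjusted values (monotone, capped at 1).
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if method == "bonferroni":
        return np.minimum(1.0, k * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * k / np.arange(1, k + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(k)
        out[order] = np.minimum(adj, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


def gene_level_smt(result: GeneTestResult, alpha: float,
                   correction: str = "bh") -> bool:
    """minP decision: gene significant iff smallest adjusted p <= alpha."""
    min_p = (result.smt_min_p_bh if correction == "bh"
             else result.smt_min_p_bonf)
    if not np.isfinite(min_p):
        raise ValueError("no fitted SNV available for the gene-level rule")
    return bool(min_p <= alpha)


def _burden_arrays(y, x1, x2, G, *, design: _NullDesign | None = None) -> float:
    """Wald t-test p-value of the unweighted minor-allele sum score."""
    G = _as_matrix(G)
    score = G.sum(axis=1)
    fit = smt_fit_all(y, x1, x2, score[:, None], design=design)
    if not fit.valid[0]:
        return math.nan
    return float(fit.p_raw[0])


def skat_weights(mafs, a1: float = 1.0, a2: float = 25.0) -> np.ndarray:
    """Beta-density weights of the linear weighted kernel."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    log_w = ((a1 - 1.0) * np.log(mafs) + (a2 - 1.0) * np.log1p(-mafs)
             - special.betaln(a1, a2))
    return np.exp(log_w)


def _skat_arrays(y, x1, x2, G, weights, *, design: _NullDesign | None = None,
                 acc: float = 1e-6) -> tuple[float, QuadFormSpec, QuadFormResult]:
    """Variance-component score test with a weighted linear kernel.

    ``Q = r' G W^2 G' r / sigma^2`` with ``r`` the covariate-only residuals
    and ML variance ``sigma^2``; the null law is the chi-square mixture with
    weights the eigenvalues of ``W G~' G~ W / sigma^2`` (``G~`` the
    covariate-residualised genotypes).
    """
    G = _as_matrix(G)
    d = design if design is not None else _NullDesign(np.asarray(y, float),
                                                      np.asarray(x1, float),
                                                      np.asarray(x2, float))
    w = np.asarray(weights, dtype=float)
    s = G.T @ d.resid_y
    q_obs = float(np.sum((w * s) ** 2) / d.sigma2_ml)
    Gt, _ = d.residualize(G)
    Zw = Gt * w[None, :]
    # E[Q] under the null equals tr(W G~' G~ W), so the mixture weights are
    # the eigenvalues of that matrix (unscaled)
    B = Zw.T @ Zw
    lam = np.linalg.eigvalsh(B)
    lam = lam[lam > EIG_TRUNC * lam.max()] if lam.max() > 0 else lam[:0]
    if lam.size == 0:
        # all weighted genotypes vanish: no signal by convention
        spec = QuadFormSpec(q_obs, np.array([1.0]))
        return 1.0, spec, QuadFormResult(1.0, "degenerate", True, 0.0)
    spec = QuadFormSpec(q_obs, lam)
    p, method = davies_pvalue_adaptive(q_obs, lam, floor=acc)
    return p, spec, QuadFormResult(p, method, method == "davies", acc)


def _rho_sqrt_matrix(k: int, rho: float) -> np.ndarray:
    """Symmetric square root of ``(1-rho) I + rho 1 1'``."""
    a = math.sqrt(1.0 - rho)
    b = math.sqrt(1.0 - rho + k * rho)
    M = np.full((k, k), (b - a) / k)
    M[np.diag_indices(k)] += a
    return M


# Gauss-Legendre rule on (0, sqrt(40)) reused across calls for the
# mixing-parameter search (substitution x = t^2 in the chi2_1 integral)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_GL_T = 0.5 * math.sqrt(40.0) * (_GL_NODES + 1.0)
_GL_X = _GL_T ** 2
# combined quadrature weight including the chi2_1 density mass 2*phi(t)
_GL_MASS = (0.5 * math.sqrt(40.0) * _GL_WEIGHTS
            * 2.0 * np.exp(-0.5 * _GL_T ** 2) / math.sqrt(2.0 * math.pi))


def _skato_arrays(y, x1, x2, G, weights, rho_grid=DEFAULT_RHO_GRID, *,
                  design: _NullDesign | None = None, acc: float = 1e-6) -> float:
    """Optimal combined burden/variance-component test over a rho grid.

    For each rho the statistic ``Q_rho = (1-rho) Q_SKAT + rho Q_burden`` (in
    the weighted-score form) is referred to its own chi-square mixture; the
    minimum p-value over the grid is then corrected for the search by the
    one-dimensional integration over the common burden-direction component.
    Mixing parameters at 1 are capped at 0.999 so every mixture keeps full
    rank, as in the published construction.
    """
    G = _as_matrix(G)
    d = design if design is not None else _NullDesign(np.asarray(y, float),
                                                      np.asarray(x1, float),
                                                      np.asarray(x2, float))
    w = np.asarray(weights, dtype=float)
    k = G.shape[1]
    rho_list = [min(float(r), 0.999) for r in rho_grid]

    Gt, _ = d.residualize(G)
    sigma = math.sqrt(d.sigma2_ml)
    Z1 = (Gt * w[None, :]) / sigma                  # n x k, Var(Z1' eps) = B
    u = (G.T @ d.resid_y) * w / d.sigma2_ml         # scores on the Z1 scale
    B = Z1.T @ Z1

    if len(rho_list) == 1:
        rho = rho_list[0]
        return _single_rho_pvalue(u, B, rho, rho_grid[0], acc)

    # Per-rho p-values and mixture quantiles at the minimum p.  The mixture
    # moments equal the power-sum traces tr((B R_rho)^j), which a rank-one
    # update plus one matrix product delivers without any
    # eigendecomposition; the Liu approximation built on them screens the
    # grid, and only candidates near the minimum (where the decision can
    # change) are refined with the exact inversion.
    n_rho = len(rho_list)
    p_each = np.empty(n_rho)
    q_each = np.empty(n_rho)
    traces = np.empty((n_rho, 4))
    sum_u2 = float(np.sum(u ** 2))
    sum_u = float(np.sum(u))
    b_vec = B.sum(axis=1)
    for i, rho in enumerate(rho_list):
        q_each[i] = (1.0 - rho) * sum_u2 + rho * sum_u ** 2
        N = (1.0 - rho) * B + rho * np.outer(b_vec, np.ones(k))
        N2 = N @ N
        c1 = float(np.trace(N))
        c2 = float(np.trace(N2))
        c3 = float(np.sum(N2 * N.T))
        c4 = float(np.sum(N2 * N2.T))
        traces[i] = (c1, c2, c3, c4)
        p_each[i] = liu_pvalue_from_traces(q_each[i], c1, c2, c3, c4)
    screen = p_each <= min(0.15, max(4.0 * p_each.min(),
                                     p_each.min() + 1e-3))
    for i in np.flatnonzero(screen):
        Rh = _rho_sqrt_matrix(k, rho_list[i])
        lam = np.linalg.eigvalsh(Rh @ B @ Rh)
        lam = lam[lam > EIG_TRUNC * lam.max()]
        p_each[i], _ = davies_pvalue_adaptive(q_each[i], lam, floor=acc)
    p_min = float(p_each.min())
    if p_min >= 1.0:
        return 1.0
    qmin = np.array([liu_quantile_from_traces(p_min, *traces[i])
                     for i in range(n_rho)])

    # moment decomposition along the common (burden) direction
    z_mean = Z1.mean(axis=1)
    zbar2 = float(z_mean @ z_mean)
    if zbar2 <= 0:
        return p_min * len(rho_list)
    cof1 = (z_mean @ Z1) / zbar2
    Zi1 = np.outer(z_mean, cof1)
    Zi2 = Z1 - Zi1
    K2 = Zi2.T @ Zi2
    lam_rem = np.linalg.eigvalsh(K2)
    lam_rem = lam_rem[lam_rem > EIG_TRUNC * max(lam_rem.max(), 0.0)] \
        if lam_rem.max() > 0 else lam_rem[:0]
    if lam_rem.size == 0:
        return p_min * len(rho_list)
    var_remain = 4.0 * float(np.sum((Zi1.T @ Zi1) * K2))
    mu_q = float(lam_rem.sum())
    var_q = 2.0 * float(np.sum(lam_rem ** 2)) + var_remain
    sd_ratio = math.sqrt(max(var_q - var_remain, 0.0) / var_q)
    tau = np.array([(k ** 2 * rho + (1.0 - rho) * float(np.sum(cof1 ** 2)))
                    * zbar2 for rho in rho_list])

    # integrate over the chi2_1 burden component, substitution x = t^2
    thresh = np.min((qmin[:, None] - tau[:, None] * _GL_X[None, :])
                    / (1.0 - np.asarray(rho_list))[:, None], axis=0)
    pos = thresh > 0
    cdf_vals = np.zeros_like(thresh)          # F_kappa at the thresholds
    if np.any(pos):
        adj = (thresh[pos] - mu_q) * sd_ratio + mu_q
        adj = np.maximum(adj, 0.0)
        try:
            sf = davies_sf_multi(adj, lam_rem, acc=max(acc, 1e-6))
        except FloatingPointError:
            sf = np.array([liu_pvalue(float(a), lam_rem) for a in adj])
        cdf_vals[pos] = 1.0 - sf
    p_value = 1.0 - float(np.sum(_GL_MASS * cdf_vals))

    # guard against integration round-off; the searched minimum provides a
    # Bonferroni-style ceiling
    p_value = min(p_value, p_min * len(rho_list), 1.0)
    if p_value <= 0.0:
        p_value = p_min * len(rho_list)
    return float(min(p_value, 1.0))


def _single_rho_pvalue(u, B, rho, rho_requested, acc) -> float:
    """Degenerate one-point grids reduce to the plain score tests."""
    k = B.shape[0]
    if rho_requested >= 1.0:
        q = float(np.sum(u)) ** 2
        lam = np.array([float(np.ones(k) @ B @ np.ones(k))])
        if lam[0] <= 0:
            return 1.0
        return float(stats.chi2.sf(q / lam[0], 1))
    q = (1.0 - rho) * float(np.sum(u ** 2)) + rho * float(np.sum(u)) ** 2
    Rh = _rho_sqrt_matrix(k, rho)
    lam = np.linalg.eigvalsh(Rh @ B @ Rh)
    lam = lam[lam > EIG_TRUNC * lam.max()]
    return davies_pvalue_adaptive(q, lam, floor=acc)[0]


ALL_METHODS = ("smt", "burden", "skat", "skato")


def run_gene_tests(pheno, gene, inclusion: str = "all_snvs", *,
                   methods=ALL_METHODS,
                   weight_params: tuple[float, float] = (1.0, 25.0),
                   rho_grid=DEFAULT_RHO_GRID, acc: float = 1e-6,
                   keep_fit: bool = False,
                   rare_threshold: float = RARE_MAF_THRESHOLD
                   ) -> GeneTestResult:
    """Run the requested tests on one gene replicate under one inclusion mode."""
    if inclusion == "all_snvs":
        idx = np.arange(gene.genotypes.shape[1])
    elif inclusion == "rare_only":
        idx = np.flatnonzero(gene.mafs <= rare_threshold)
    else:
        raise ValueError(f"unknown inclusion mode {inclusion!r}")
    if idx.size == 0:
        raise ValueError("no SNVs left after inclusion filtering")
    G = gene.genotypes[:, idx].astype(float)
    mafs = gene.mafs[idx]
    y = np.asarray(pheno.y, float)
    x1 = np.asarray(pheno.x1, float)
    x2 = np.asarray(pheno.x2, float)
    design = _NullDesign(y, x1, x2)

    fit = None
    adj_bh = np.full(idx.size, np.nan)
    adj_bonf = np.full(idx.size, np.nan)
    min_bh = min_bonf = math.nan
    if "smt" in methods:
        fit = smt_fit_all(y, x1, x2, G, design=design)
        p_raw = fit.p_raw[fit.valid]
        if p_raw.size:
            adj_bh_v = adjust_pvalues(p_raw, "bh")
            adj_bonf_v = adjust_pvalues(p_raw, "bonferroni")
            adj_bh[fit.valid] = adj_bh_v
            adj_bonf[fit.valid] = adj_bonf_v
            min_bh = float(adj_bh_v.min())
            min_bonf = float(adj_bonf_v.min())

    skat_p = skato_p = burden_p = math.nan
    if "skat" in methods or "skato" in methods:
        w = skat_weights(mafs, *weight_params)
        if "skat" in methods:
            skat_p, _, _ = _skat_arrays(y, x1, x2, G, w, design=design,
                                        acc=acc)
        if "skato" in methods:
            skato_p = _skato_arrays(y, x1, x2, G, w, rho_grid, design=design,
                                    acc=acc)
    if "burden" in methods:
        burden_p = _burden_arrays(y, x1, x2, G, design=design)

    return GeneTestResult(
        inclusion=inclusion, site_index=idx,
        smt_p_raw=fit.p_raw if fit is not None else np.full(idx.size, np.nan),
        smt_p_adj_bh=adj_bh, smt_p_adj_bonf=adj_bonf,
        smt_min_p_bh=min_bh, smt_min_p_bonf=min_bonf,
        burden_p=burden_p, skat_p=skat_p, skato_p=skato_p,
        smt_fit=fit if keep_fit else None)

# ---------------------------------------------------------------------------
# PhenotypeSet/GeneReplicate wrappers


def _included_columns(gene, inclusion: str, rare_threshold: float):
    if inclusion == "all_snvs":
        idx = np.arange(gene.genotypes.shape[1])
    elif inclusion == "rare_only":
        idx = np.flatnonzero(gene.mafs <= rare_threshold)
    else:
        raise ValueError(f"unknown inclusion mode {inclusion!r}")
    if idx.size == 0:
        raise ValueError("no SNVs left after inclusion filtering")
    return idx, gene.genotypes[:, idx].astype(float), gene.mafs[idx]


def burden_test(pheno, gene, inclusion: str = "all_snvs", *,
                rare_threshold: float = RARE_MAF_THRESHOLD) -> float:
    """Burden-test p-value for one gene replicate."""
    _, G, _ = _included_columns(gene, inclusion, rare_threshold)
    return _burden_arrays(np.asarray(pheno.y, float),
                          np.asarray(pheno.x1, float),
                          np.asarray(pheno.x2, float), G)


def skat_test(pheno, gene, weights=None, inclusion: str = "all_snvs", *,
              acc: float = 1e-6, rare_threshold: float = RARE_MAF_THRESHOLD
              ) -> tuple[float, QuadFormSpec]:
    """SKAT p-value and the quadratic-form spec of its null distribution."""
    _, G, mafs = _included_columns(gene, inclusion, rare_threshold)
    w = skat_weights(mafs) if weights is None else np.asarray(weights, float)
    p, spec, _ = _skat_arrays(np.asarray(pheno.y, float),
                              np.asarray(pheno.x1, float),
                              np.asarray(pheno.x2, float), G, w, acc=acc)
    return p, spec


def skato_test(pheno, gene, weights=None, rho_grid=DEFAULT_RHO_GRID,
               inclusion: str = "all_snvs", *, acc: float = 1e-6,
               rare_threshold: float = RARE_MAF_THRESHOLD) -> float:
    """SKAT-O p-value for one gene replicate."""
    _, G, mafs = _included_columns(gene, inclusion, rare_threshold)
    w = skat_weights(mafs) if weights is None else np.asarray(weights, float)
    return _skato_arrays(np.asarray(pheno.y, float),
                         np.asarray(pheno.x1, float),
                         np.asarray(pheno.x2, float), G, w, rho_grid, acc=acc)
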