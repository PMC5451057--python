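"""Single-marker, burden, SKAT and SKAT-O tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import rvpower as rv
from rvpower.association import (_NullDesign, _skat_arrays, _burden_arrays,
                                 smt_fit_all, adjust_pvalues, skat_weights,
                                 DEFAULT_RHO_GRID)
from conftest import make_pheno


# --- fixed tiny dataset for the normal-equations oracle --------------------

N8_Y = np.array([1.2, -0.3, 0.8, 2.1, -1.0, 0.4, 1.7, -0.6])
N8_X1 = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
N8_X2 = np.array([0.5, -1.2, 0.3, 1.8, -0.7, 0.0, 0.9, -1.5])
N8_G = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 1.0, 1.0, 0.0])


def _ols_oracle(y, X):
    """Brute-force normal equations with unbiased sigma^2."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = y.size - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.diag(XtX_inv))
    return beta, se, s2, df


class _P:
    def __init__(self, y, x1, x2):
        self.y, self.x1, self.x2 = y, x1, x2


def test_smt_matches_normal_equations_oracle():
    X = np.column_stack([np.ones(8), N8_X1, N8_X2, N8_G])
    beta, se, s2, df = _ols_oracle(N8_Y, X)
    fit = rv.smt_fit(_P(N8_Y, N8_X1, N8_X2), N8_G)
    assert fit.df == 4 == df
    assert fit.beta_hat[0] == pytest.approx(beta[3], rel=1e-10)
    assert fit.se_hat[0] == pytest.approx(se[3], rel=1e-10)
    assert fit.sigma2_hat[0] == pytest.approx(s2, rel=1e-10)
    assert fit.gamma_hat[0] == pytest.approx(beta[:3], rel=1e-9)
    t = beta[3] / se[3]
    assert fit.p_raw[0] == pytest.approx(2 * stats.t.sf(abs(t), df),
                                         rel=1e-9)


def test_smt_perfect_fit_recovers_exact_coefficients():
    y = 0.5 * N8_X1 + 0.5 * N8_X2 + 2.0 * N8_G
    fit = rv.smt_fit(_P(y, N8_X1, N8_X2), N8_G)
    assert fit.beta_hat[0] == pytest.approx(2.0, abs=1e-10)
    assert fit.sigma2_hat[0] == pytest.approx(0.0, abs=1e-12)


def test_smt_collinear_column_flagged(mini_gene):
    ph = make_pheno(mini_gene, seed=1)
    G = np.column_stack([ph.x1, mini_gene.genotypes[:, 0]])
    fit = smt_fit_all(ph.y, ph.x1, ph.x2, G)
    assert not fit.valid[0] and fit.valid[1]
    assert np.isnan(fit.p_raw[0])


def test_smt_vectorised_equals_per_column(mini_gene):
    ph = make_pheno(mini_gene, seed=2)
    G = mini_gene.genotypes[:, :6].astype(float)
    fit_all = smt_fit_all(ph.y, ph.x1, ph.x2, G)
    for j in range(6):
        fit_j = rv.smt_fit(ph, G[:, j])
        assert fit_all.beta_hat[j] == pytest.approx(fit_j.beta_hat[0],
                                                    rel=1e-12)
        assert fit_all.p_raw[j] == pytest.approx(fit_j.p_raw[0], rel=1e-12)


# --- multiplicity adjustment ----------------------------------------------

def test_bh_hand_example():
    assert np.allclose(adjust_pvalues([0.01, 0.02, 0.04], "bh"),
                       [0.03, 0.03, 0.04])


def test_bonferroni_hand_example():
    assert np.allclose(adjust_pvalues([0.03, 0.5], "bonferroni"),
                       [0.06, 1.0])


def test_single_p_unchanged_by_both_methods():
    for method in ("bh", "bonferroni"):
        assert adjust_pvalues([0.123], method)[0] == pytest.approx(0.123)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_adjustment_matches_statsmodels_oracle(ps):
    ps = np.asarray(ps)
    for ours, theirs in (("bh", "fdr_bh"), ("bonferroni", "bonferroni")):
        got = adjust_pvalues(ps, ours)
        want = multipletests(ps, method=theirs)[1]
        assert np.allclose(got, want, atol=1e-12)
        assert np.all(got >= ps - 1e-15)        # adjusted >= raw


def test_adjustment_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        adjust_pvalues([1.2])
    with pytest.raises(ValueError):
        adjust_pvalues([])


def test_gene_level_minp_rule(mini_gene):
    ph = make_pheno(mini_gene, seed=3)
    res = rv.run_gene_tests(ph, mini_gene)
    for alpha in (1e-6, 0.05, 0.5, 1.0):
        assert rv.gene_level_smt(res, alpha) == (res.smt_min_p_bh <= alpha)
        assert (rv.gene_level_smt(res, alpha, "bonferroni")
                == (res.smt_min_p_bonf <= alpha))
    # Bonferroni can never reject when BH does not (adjusted bonf >= bh)
    assert res.smt_min_p_bonf >= res.smt_min_p_bh - 1e-15


# --- burden ----------------------------------------------------------------

def test_burden_single_snv_equals_smt(mini_gene):
    ph = make_pheno(mini_gene, seed=4)
    g = mini_gene.genotypes[:, [0]]
    single = rv.GeneReplicate(genotypes=g, macs=mini_gene.macs[:1],
                              mafs=mini_gene.mafs[:1],
                              site_positions=mini_gene.site_positions[:1])
    burden_p = rv.burden_test(ph, single)
    smt_p = rv.smt_fit(ph, g[:, 0].astype(float)).p_raw[0]
    assert burden_p == pytest.approx(smt_p, rel=1e-12)


def test_burden_scale_invariance(mini_gene):
    ph = make_pheno(mini_gene, seed=5)
    G = mini_gene.genotypes.astype(float)
    p1 = _burden_arrays(ph.y, ph.x1, ph.x2, G)
    p2 = _burden_arrays(ph.y, ph.x1, ph.x2, np.hstack([G, G]))
    assert p2 == pytest.approx(p1, rel=1e-10)


def test_burden_matches_ols_oracle(mini_gene):
    ph = make_pheno(mini_gene, seed=6)
    score = mini_gene.genotypes.sum(axis=1).astype(float)
    X = np.column_stack([np.ones(score.size), ph.x1, ph.x2, score])
    beta, se, _, df = _ols_oracle(ph.y, X)
    want = 2 * stats.t.sf(abs(beta[3] / se[3]), df)
    assert rv.burden_test(ph, mini_gene) == pytest.approx(want, rel=1e-9)


def test_burden_constant_score_reported_missing():
    n = 50
    rng = np.random.default_rng(0)
    g = np.ones((n, 1))
    p = _burden_arrays(rng.normal(size=n), rng.integers(0, 2, n),
                       rng.normal(size=n), g)
    assert math.isnan(p)


# --- SKAT weights ----------------------------------------------------------

def test_flat_weights_for_uniform_beta():
    assert np.allclose(skat_weights([0.1, 0.3, 0.5], 1.0, 1.0), 1.0)


def test_weight_density_value():
    assert skat_weights([0.01])[0] == pytest.approx(25 * 0.99 ** 24,
                                                    rel=1e-12)


def test_weights_decreasing_in_maf():
    w = skat_weights(np.linspace(0.001, 0.5, 50))
    assert np.all(np.diff(w) < 0)


def test_weights_reject_zero_maf():
    with pytest.raises(ValueError):
        skat_weights([0.0, 0.01])


# --- SKAT ------------------------------------------------------------------

def _dense_skat_oracle(y, x1, x2, G, w):
    """Explicit projection-matrix construction of Q and the mixture."""
    n = y.size
    X = np.column_stack([np.ones(n), x1, x2])
    P = np.eye(n) - X @ np.linalg.inv(X.T @ X) @ X.T
    r = P @ y
    s2 = float(r @ r) / n
    W = np.diag(w)
    q = float(r @ G @ W @ W @ G.T @ r) / s2
    M = W @ G.T @ P @ G @ W
    lam = np.linalg.eigvalsh(M)
    return q, lam[lam > 1e-10 * lam.max()]


def test_skat_matches_dense_matrix_oracle():
    rng = np.random.default_rng(8)
    n, k = 50, 3
    G = rng.binomial(2, 0.2, size=(n, k)).astype(float)
    y = rng.normal(size=n)
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(size=n)
    w = np.array([1.0, 2.0, 0.5])
    q_o, lam_o = _dense_skat_oracle(y, x1, x2, G, w)
    p, spec, _ = _skat_arrays(y, x1, x2, G, w)
    assert spec.q_obs == pytest.approx(q_o, rel=1e-10)
    assert np.allclose(np.sort(spec.lambdas), np.sort(lam_o), rtol=1e-8)
    from rvpower.quadform import davies_pvalue
    assert p == pytest.approx(davies_pvalue(q_o, lam_o, acc=1e-9), abs=2e-3)


def test_skat_single_snv_reduces_to_score_chi2(mini_gene):
    ph = make_pheno(mini_gene, seed=9)
    g = mini_gene.genotypes[:, [5]].astype(float)
    p, spec, _ = _skat_arrays(ph.y, ph.x1, ph.x2, g, np.array([1.0]))
    assert spec.lambdas.size == 1
    chi2_p = stats.chi2.sf(spec.q_obs / spec.lambdas[0], 1)
    # the returned p uses the accuracy-adapted inversion; the full-accuracy
    # inversion of the same spec is exact against the chi2 closed form
    assert p == pytest.approx(chi2_p, abs=2e-3)
    from rvpower.quadform import davies_pvalue
    assert davies_pvalue(spec.q_obs, spec.lambdas, acc=1e-9) \
        == pytest.approx(chi2_p, abs=1e-6)
    # and asymptotically the squared-score chi2 equals the SMT t^2 p-value
    smt_p = rv.smt_fit(ph, g[:, 0]).p_raw[0]
    assert p == pytest.approx(smt_p, abs=0.01)


def test_skat_zero_weights_gives_p_one(mini_gene):
    ph = make_pheno(mini_gene, seed=10)
    G = mini_gene.genotypes[:, :4].astype(float)
    p, _, res = _skat_arrays(ph.y, ph.x1, ph.x2, G, np.zeros(4))
    assert p == 1.0 and res.method_used == "degenerate"


def test_skat_invariant_to_column_order_and_allele_flip(mini_gene):
    ph = make_pheno(mini_gene, seed=11)
    G = mini_gene.genotypes[:, :5].astype(float)
    mafs = mini_gene.mafs[:5]
    w = skat_weights(mafs)
    p_ref, _, _ = _skat_arrays(ph.y, ph.x1, ph.x2, G, w)
    perm = np.array([3, 1, 4, 0, 2])
    p_perm, _, _ = _skat_arrays(ph.y, ph.x1, ph.x2, G[:, perm], w[perm])
    assert p_perm == pytest.approx(p_ref, abs=1e-6)
    # relabel major/minor at one site; the sample MAF (hence weight) is
    # unchanged and the score only flips sign
    G2 = G.copy()
    G2[:, 0] = 2.0 - G2[:, 0]
    p_flip, _, _ = _skat_arrays(ph.y, ph.x1, ph.x2, G2, w)
    assert p_flip == pytest.approx(p_ref, abs=1e-6)


def test_skat_pheno_wrapper_inclusion_modes(mini_gene):
    ph = make_pheno(mini_gene, seed=12)
    p_all, _ = rv.skat_test(ph, mini_gene, inclusion="all_snvs")
    p_rare, _ = rv.skat_test(ph, mini_gene, inclusion="rare_only")
    rare = mini_gene.mafs <= 0.03
    G = mini_gene.genotypes[:, rare].astype(float)
    p_manual, _, _ = _skat_arrays(ph.y, ph.x1, ph.x2, G,
                                  skat_weights(mini_gene.mafs[rare]))
    assert p_rare == pytest.approx(p_manual, abs=1e-9)
    assert p_all != p_rare


# --- SKAT-O ----------------------------------------------------------------

def test_skato_degenerate_grid_zero_equals_skat(mini_gene):
    ph = make_pheno(mini_gene, seed=13)
    p_skat, _ = rv.skat_test(ph, mini_gene)
    p_o = rv.skato_test(ph, mini_gene, rho_grid=(0.0,))
    assert p_o == pytest.approx(p_skat, abs=1e-9)


def test_skato_degenerate_grid_one_equals_weighted_burden(mini_gene):
    """rho = 1 collapses to the weighted-sum score test (exact chi2_1)."""
    ph = make_pheno(mini_gene, seed=14)
    p_o = rv.skato_test(ph, mini_gene, rho_grid=(1.0,))
    w = skat_weights(mini_gene.mafs)
    score = (mini_gene.genotypes.astype(float) * w).sum(axis=1)
    d = _NullDesign(ph.y, ph.x1, ph.x2)
    st_, _ = d.residualize(score[:, None])
    u = float(score @ d.resid_y) / d.sigma2_ml
    lam = float(st_[:, 0] @ st_[:, 0]) / d.sigma2_ml
    want = stats.chi2.sf(u ** 2 / lam, 1)
    assert p_o == pytest.approx(want, rel=1e-8)


def test_skato_respects_grid_minimum_bound(mini_gene):
    """The combined p never beats the Bonferroni bound of the grid search."""
    for seed in range(6):
        ph = make_pheno(mini_gene, seed=100 + seed)
        p_o = rv.skato_test(ph, mini_gene)
        per_rho = [rv.skato_test(ph, mini_gene, rho_grid=(r,))
                   for r in DEFAULT_RHO_GRID]
        p_min = min(per_rho)
        assert p_o <= len(DEFAULT_RHO_GRID) * p_min + 1e-6
        assert p_o >= p_min - 0.01      # search correction costs power
        assert 0.0 <= p_o <= 1.0


def test_skato_tracks_best_component_under_signal(mini_pool):
    """With a strong one-directional signal SKAT-O approaches the best rho."""
    rng = np.random.default_rng(3)
    gene, _ = rv.sample_gene_replicate(mini_pool, 500, seed=rng)
    cfg = rv.ScenarioConfig(causal_fraction=0.5, c=0.6, n=500, m=1)
    causal = rv.select_causal_variants(gene, cfg, 1)
    eff = rv.assign_effect_sizes(gene.mafs[causal], cfg, 1,
                                 causal_indices=causal)
    ph = rv.generate_quantitative_trait(gene, eff, cfg, 1)
    p_o = rv.skato_test(ph, gene)
    p_skat, _ = rv.skat_test(ph, gene)
    assert p_o <= 10 * p_skat + 1e-12   # combined test keeps the signal


# --- null calibration (small scale) ----------------------------------------

def test_null_smt_pvalues_uniform(mini_pool):
    """One raw SMT p per replicate is U(0,1) under the null (KS check)."""
    cfg = rv.ScenarioConfig(causal_fraction=0.0, c=0.0, n=500, m=300,
                            seed=21)
    res = rv.run_scenario(cfg, mini_pool, methods=("smt",), collect_snv=True)
    rng = np.random.default_rng(0)
    one_per_rep = res.snv.groupby("replicate")["p_raw"] \
        .apply(lambda s: s.sample(1, random_state=7).iloc[0]).to_numpy()
    ks = stats.kstest(one_per_rep, "uniform")
    assert ks.pvalue > 1e-3


def test_null_singleton_tstats_follow_t_distribution(mini_pool):
    cfg = rv.ScenarioConfig(causal_fraction=0.0, c=0.0, n=500, m=400,
                            seed=22)
    res = rv.run_scenario(cfg, mini_pool, methods=("smt",), collect_snv=True)
    t = res.snv.loc[res.snv["mac"] == 1, "t_stat"].to_numpy()
    t = t[np.isfinite(t)]
    assert t.size > 1000
    ks = stats.kstest(t, "t", args=(500 - 4,))
    assert ks.pvalue > 1e-4
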