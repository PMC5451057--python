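"""Phenotype generation conditional on genotypes and covariates.

The quantitative trait follows the additive model

    Y = 0.5 * x1 + 0.5 * x2 + sum_i beta_i g_i + eps,

with ``x1 ~ Bin(0.5)``, ``x2 ~ N(0, 1)`` and ``eps ~ N(0, 1)`` by default.
Causal variants are drawn among the rare SNVs (MAF <= 0.03) of a gene; a
causal variant's effect magnitude is ``c * |log10(MAF)|`` so that rarer
variants carry larger effects, with the sign split between positive and
negative effects controlled per scenario.  A misspecification arm replaces
the error distribution by t4, t8 or a centred standard log-normal, and a
binary-trait arm thresholds a logistic model instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml
from scipy import optimize, special

__all__ = [
    "ScenarioConfig",
    "EffectAssignment",
    "PhenotypeSet",
    "scenario_grid",
    "round_half_up",
    "select_causal_variants",
    "assign_effect_sizes",
    "generate_quantitative_trait",
    "generate_binary_trait",
    "explained_variance",
    "NoEligibleSitesError",
]

_ERROR_DISTS = ("normal", "t4", "t8", "lognormal")


class NoEligibleSitesError(RuntimeError):
    """An alternative scenario found no rare site to make causal."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One row of the simulation grid."""

    causal_fraction: float
    c: float
    positive_fraction: float = 1.0
    rare_threshold: float = 0.03
    error_dist: str = "normal"
    trait: str = "quantitative"
    n: int = 1000
    m: int = 10_000
    seed: int = 0
    scenario_id: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.causal_fraction <= 0.5:
            raise ValueError("causal_fraction must lie in [0, 0.5]")
        if self.c < 0:
            raise ValueError("effect-size constant c must be non-negative")
        if self.positive_fraction not in (0.5, 0.8, 1.0):
            raise ValueError("positive_fraction must be 0.5, 0.8 or 1.0")
        if self.error_dist not in _ERROR_DISTS:
            raise ValueError(f"error_dist must be one of {_ERROR_DISTS}")
        if self.trait not in ("quantitative", "binary"):
            raise ValueError("trait must be 'quantitative' or 'binary'")

    @property
    def is_null(self) -> bool:
        return self.causal_fraction == 0.0 or self.c == 0.0


@dataclass(frozen=True)
class EffectAssignment:
    """Causal site indices and their signed effects."""

    causal_indices: np.ndarray   # indices into the gene's site list
    betas: np.ndarray            # signed per-site effects, same length


@dataclass(frozen=True)
class PhenotypeSet:
    """Trait values and the two non-genetic covariates.

    For binary traits drawn by case-control rejection sampling the record
    also stores which genotype rows of the source gene were kept
    (``genotype_rows``); quantitative traits keep the original row order.
    """

    y: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    error_dist: str = "normal"
    genotype_rows: np.ndarray | None = None


def scenario_grid(**overrides) -> dict[int, ScenarioConfig]:
    """The shipped scenario table as ``{scenario_id: ScenarioConfig}``.

    Keyword overrides (e.g. ``m=2000``) are applied to every scenario.
    """
    text = resources.files("rvpower").joinpath("data/scenarios.yaml") \
        .read_text()
    raw = yaml.safe_load(text)
    defaults = raw["defaults"]
    grid = {}
    for row in raw["scenarios"]:
        merged = {**defaults, **row}
        sid = merged.pop("id")
        cfg = ScenarioConfig(scenario_id=sid, **merged)
        grid[sid] = replace(cfg, **overrides) if overrides else cfg
    return grid


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (toward +inf)."""
    return int(math.floor(round(x, 9) + 0.5))


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def select_causal_variants(gene, cfg: ScenarioConfig, seed=None) -> np.ndarray:
    """Uniformly draw the causal subset of the gene's rare sites.

    The number of causal sites is ``max(1, round_half_up(fraction * n_rare))``
    under an alternative scenario (at least one rare variant per gene is
    causal); the null scenario returns an empty set.
    """
    if cfg.causal_fraction == 0.0:
        return np.empty(0, dtype=np.intp)
    rare = np.flatnonzero(gene.mafs <= cfg.rare_threshold)
    if rare.size == 0:
        raise NoEligibleSitesError("gene has no rare site to make causal")
    n_causal = max(1, round_half_up(cfg.causal_fraction * rare.size))
    rng = _rng_from(seed)
    chosen = rng.choice(rare, size=n_causal, replace=False)
    return np.sort(chosen)


def assign_effect_sizes(mafs, cfg: ScenarioConfig, seed=None,
                        causal_indices=None) -> EffectAssignment:
    """Signed effects ``+-c * |log10(MAF)|`` with the scenario's sign split.

    ``round_half_up(positive_fraction * n_causal)`` sites, chosen uniformly,
    receive a positive sign; the rest are negative.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0):
        raise ValueError("causal MAFs must be positive")
    if np.any(mafs > cfg.rare_threshold):
        raise ValueError("causal MAFs must not exceed the rare threshold")
    magnitude = cfg.c * np.abs(np.log10(mafs))
    n_causal = mafs.size
    n_pos = round_half_up(cfg.positive_fraction * n_causal)
    signs = np.full(n_causal, -1.0)
    rng = _rng_from(seed)
    pos = rng.choice(n_causal, size=min(n_pos, n_causal), replace=False)
    signs[pos] = 1.0
    if causal_indices is None:
        causal_indices = np.arange(n_causal, dtype=np.intp)
    return EffectAssignment(causal_indices=np.asarray(causal_indices,
                                                      dtype=np.intp),
                            betas=magnitude * signs)


def _draw_errors(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal(n)
    if dist == "t4":
        return rng.standard_t(4, n)
    if dist == "t8":
        return rng.standard_t(8, n)
    if dist == "lognormal":
        # standard log-normal, centred so the null intercept stays 0
        return rng.lognormal(0.0, 1.0, n) - math.exp(0.5)
    raise ValueError(f"unknown error distribution {dist!r}")


def generate_quantitative_trait(gene, eff: EffectAssignment,
                                cfg: ScenarioConfig, seed=None
                                ) -> PhenotypeSet:
    """Draw covariates, errors and the additive quantitative trait."""
    rng = _rng_from(seed)
    n = gene.n_individuals
    x1 = rng.binomial(1, 0.5, n).astype(float)
    x2 = rng.standard_normal(n)
    eps = _draw_errors(rng, n, cfg.error_dist)
    y = 0.5 * x1 + 0.5 * x2 + eps
    if eff.causal_indices.size:
        y = y + gene.genotypes[:, eff.causal_indices].astype(float) @ eff.betas
    return PhenotypeSet(y=y, x1=x1, x2=x2, error_dist=cfg.error_dist)


def explained_variance(gene, eff: EffectAssignment, var_y: float) -> float:
    """Additive heritability of the gene: sum 2 MAF (1-MAF) beta^2 / Var(Y)."""
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    if eff.causal_indices.size == 0:
        return 0.0
    maf = gene.mafs[eff.causal_indices]
    return float(np.sum(2.0 * maf * (1.0 - maf) * eff.betas ** 2) / var_y)


def _solve_logistic_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept gamma0 with mean(expit(gamma0 + eta)) == prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")

    def deficit(g0):
        return float(np.mean(special.expit(g0 + eta))) - prevalence

    return float(optimize.brentq(deficit, -50.0, 50.0, xtol=1e-10))


def generate_binary_trait(gene, eff: EffectAssignment, cfg: ScenarioConfig,
                          seed=None, prevalence: float = 0.1,
                          max_rounds: int = 10_000) -> PhenotypeSet:
    """Balanced case-control sample from a logistic model on the same scale.

    The linear predictor reuses the quantitative model's covariate and
    genetic terms; the intercept is solved numerically so the *population*
    prevalence equals ``prevalence``, and cases/controls are accumulated by
    rejection sampling until n/2 of each are collected.
    """
    rng = _rng_from(seed)
    n = gene.n_individuals
    n_cases = n // 2
    n_controls = n - n_cases

    def draw_batch(size):
        x1 = rng.binomial(1, 0.5, size).astype(float)
        x2 = rng.standard_normal(size)
        idx = rng.integers(0, n, size)         # genotype vectors re-drawn
        gterm = np.zeros(size)
        if eff.causal_indices.size:
            gterm = gene.genotypes[np.ix_(idx, eff.causal_indices)] \
                .astype(float) @ eff.betas
        return x1, x2, idx, 0.5 * x1 + 0.5 * x2 + gterm

    # calibrate the intercept on a large population draw
    _, _, _, eta_pop = draw_batch(max(20 * n, 10_000))
    gamma0 = _solve_logistic_intercept(eta_pop, prevalence)

    kept_y, kept_x1, kept_x2, kept_idx = [], [], [], []
    need_case, need_control = n_cases, n_controls
    for _ in range(max_rounds):
        if need_case <= 0 and need_control <= 0:
            break
        x1, x2, idx, eta = draw_batch(4 * n)
        case = rng.random(eta.size) < special.expit(gamma0 + eta)
        for want_case in (True, False):
            need = need_case if want_case else need_control
            if need <= 0:
                continue
            sel = np.flatnonzero(case == want_case)[:need]
            kept_y.append(np.full(sel.size, 1.0 if want_case else 0.0))
            kept_x1.append(x1[sel])
            kept_x2.append(x2[sel])
            kept_idx.append(idx[sel])
            if want_case:
                need_case -= sel.size
            else:
                need_control -= sel.size
    if need_case > 0 or need_control > 0:
        raise RuntimeError("case-control rejection sampling did not fill the "
                           "requested sample; prevalence may be too extreme")
    return PhenotypeSet(y=np.concatenate(kept_y),
                        x1=np.concatenate(kept_x1),
                        x2=np.concatenate(kept_x2),
                        error_dist="binary",
                        genotype_rows=np.concatenate(kept_idx))
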