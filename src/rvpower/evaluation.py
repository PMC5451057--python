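"""Monte-Carlo orchestration: scenario runs and power/type-I summaries.

A scenario run draws ``m`` independent gene replicates from the haplotype
pool, generates a phenotype under the scenario's effect model, applies the
requested association tests and returns the per-replicate p-values (plus
optional per-SNV records).  Replicate ``i`` of a run with root seed ``s``
uses the RNG stream ``SeedSequence([s, i])``, so results do not depend on
execution order and a run is bit-reproducible from its root seed.

Degenerate replicates (windows without polymorphic sites, or — under an
alternative scenario — genes without a rare site) are resampled so that the
power denominator stays at exactly ``m``; every resample is counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import traits as tr
from .haplotypes import (HaplotypePool, GeneReplicate, EmptyGeneError,
                         sample_gene_region, pair_haplotypes,
                         DEFAULT_GENE_LENGTH)

__all__ = [
    "PowerEstimate",
    "ScenarioResults",
    "run_scenario",
    "estimate_gene_power",
    "estimate_snv_power",
    "classify_mac",
    "summarize_experiment",
    "write_results_tsv",
    "plot_power_by_scenario",
    "MAF_CLASSES",
]

logger = logging.getLogger(__name__)

#: MAF strata used for SNV-level summaries (closed on the right)
MAF_CLASSES = ("singleton", "doubleton", "(0.001,0.005]", "(0.005,0.01]",
               "(0.01,0.03]", ">0.03")


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion with its binomial Monte-Carlo standard error."""

    level: str                 # "gene" or "snv"
    alpha: float
    method: str                # e.g. "smt_bh" / "skat", plus inclusion tag
    estimate: float
    mc_se: float
    denominator: int
    inclusion: str = "all_snvs"
    maf_class: str | None = None
    scenario_id: int | None = None


@dataclass
class ScenarioResults:
    """Raw per-replicate output of one scenario run."""

    cfg: tr.ScenarioConfig
    inclusions: tuple[str, ...]
    methods: tuple[str, ...]
    # {inclusion: {column: array of length m}}
    gene_p: dict[str, dict[str, np.ndarray]]
    explained_var: np.ndarray
    n_resampled: int
    # per-SNV records pooled over replicates (all-SNV inclusion)
    snv: pd.DataFrame | None = None

    @property
    def m(self) -> int:
        return self.explained_var.shape[0]


_GENE_COLUMNS = {"smt": ("smt_bh", "smt_bonf"), "burden": ("burden",),
                 "skat": ("skat",), "skato": ("skato",)}


def _result_columns(methods) -> list[str]:
    cols: list[str] = []
    for meth in methods:
        cols.extend(_GENE_COLUMNS[meth])
    return cols


def _replicate_rng(root_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([root_seed, index]))


def _resample_gene_rows(gene, rows, eff):
    """Rebuild a gene after case-control row resampling (binary arm).

    The retrospective sample repeats/drops individuals, so MAFs change and
    sites can go monomorphic; the genotype matrix is re-oriented and
    filtered, and causal indices are remapped.  Returns ``None`` when no
    polymorphic site survives.
    """
    geno = gene.genotypes[rows].copy()
    n2 = 2 * geno.shape[0]
    counts = geno.sum(axis=0, dtype=np.int64)
    flip = counts * 2 > n2
    if np.any(flip):
        geno[:, flip] = 2 - geno[:, flip]
        counts[flip] = n2 - counts[flip]
    keep = counts > 0
    if not np.any(keep):
        return None
    keep_idx = np.flatnonzero(keep)
    remap = {old: new for new, old in enumerate(keep_idx)}
    causal_new = [remap[i] for i in eff.causal_indices if i in remap]
    betas_new = [b for i, b in zip(eff.causal_indices, eff.betas)
                 if i in remap]
    new_gene = GeneReplicate(genotypes=np.ascontiguousarray(geno[:, keep]),
                             macs=counts[keep], mafs=counts[keep] / n2,
                             site_positions=gene.site_positions[keep_idx])
    new_eff = tr.EffectAssignment(np.asarray(causal_new, dtype=np.intp),
                                  np.asarray(betas_new, dtype=float))
    return new_gene, new_eff


def run_scenario(cfg: tr.ScenarioConfig, pool: HaplotypePool, *,
                 methods=assoc.ALL_METHODS, inclusions=("all_snvs",),
                 gene_length: float = DEFAULT_GENE_LENGTH,
                 collect_snv: bool = False, acc: float = 1e-6,
                 max_attempts: int = 1000) -> ScenarioResults:
    """Run one scenario of the simulation grid for ``cfg.m`` replicates."""
    methods = tuple(methods)
    inclusions = tuple(inclusions)
    logger.info("run_scenario: %r methods=%s inclusions=%s", cfg, methods,
                inclusions)
    cols = _result_columns(methods)
    gene_p = {inc: {c: np.full(cfg.m, np.nan) for c in cols}
              for inc in inclusions}
    explained = np.full(cfg.m, np.nan)
    n_resampled = 0
    snv_rows: list[pd.DataFrame] = []

    for rep in range(cfg.m):
        rng = _replicate_rng(cfg.seed, rep)
        gene = pheno = eff = None
        for _ in range(max_attempts):
            window = sample_gene_region(pool, gene_length, rng)
            try:
                cand = pair_haplotypes(pool, window, cfg.n, rng)
            except EmptyGeneError:
                n_resampled += 1
                continue
            if not cfg.is_null and not np.any(cand.mafs <= cfg.rare_threshold):
                n_resampled += 1
                continue
            if cfg.is_null:
                cand_eff = tr.EffectAssignment(np.empty(0, dtype=np.intp),
                                               np.empty(0))
            else:
                causal = tr.select_causal_variants(cand, cfg, rng)
                cand_eff = tr.assign_effect_sizes(cand.mafs[causal], cfg,
                                                  rng,
                                                  causal_indices=causal)
            if cfg.trait == "binary":
                cand_ph = tr.generate_binary_trait(cand, cand_eff, cfg, rng)
                resampled = _resample_gene_rows(cand,
                                                cand_ph.genotype_rows,
                                                cand_eff)
                if resampled is None:      # case-control draw lost all sites
                    n_resampled += 1
                    continue
                cand, cand_eff = resampled
            else:
                cand_ph = tr.generate_quantitative_trait(cand, cand_eff,
                                                         cfg, rng)
            gene, pheno, eff = cand, cand_ph, cand_eff
            break
        if gene is None:
            raise EmptyGeneError("could not sample a usable gene replicate")

        if cfg.trait == "binary":
            explained[rep] = np.nan        # heritability on the liability
        else:
            var_y = float(np.var(pheno.y))
            explained[rep] = tr.explained_variance(gene, eff, var_y) \
                if var_y > 0 else np.nan

        for inc in inclusions:
            res = assoc.run_gene_tests(pheno, gene, inc, methods=methods,
                                       acc=acc,
                                       rare_threshold=cfg.rare_threshold,
                                       keep_fit=collect_snv and "smt" in methods)
            g = gene_p[inc]
            if "smt" in methods:
                g["smt_bh"][rep] = res.smt_min_p_bh
                g["smt_bonf"][rep] = res.smt_min_p_bonf
            if "burden" in methods:
                g["burden"][rep] = res.burden_p
            if "skat" in methods:
                g["skat"][rep] = res.skat_p
            if "skato" in methods:
                g["skato"][rep] = res.skato_p
            if collect_snv and inc == inclusions[0] and res.smt_fit is not None:
                causal_mask = np.zeros(res.site_index.size, dtype=bool)
                causal_mask[np.isin(res.site_index, eff.causal_indices)] = True
                snv_rows.append(pd.DataFrame({
                    "replicate": rep,
                    "maf": gene.mafs[res.site_index],
                    "mac": gene.macs[res.site_index],
                    "t_stat": res.smt_fit.t_stat,
                    "beta_hat": res.smt_fit.beta_hat,
                    "se_hat": res.smt_fit.se_hat,
                    "p_raw": res.smt_p_raw,
                    "p_adj_bh": res.smt_p_adj_bh,
                    "causal": causal_mask,
                }))

    snv = pd.concat(snv_rows, ignore_index=True) if snv_rows else None
    logger.info("run_scenario finished: m=%d, %d degenerate draws resampled",
                cfg.m, n_resampled)
    return ScenarioResults(cfg=cfg, inclusions=inclusions, methods=methods,
                           gene_p=gene_p, explained_var=explained,
                           n_resampled=n_resampled, snv=snv)


def write_results_tsv(results: ScenarioResults, out_dir,
                      alphas=(0.05, 2.5e-6)) -> dict[str, Path]:
    """Write tidy TSV tables of a scenario run.

    ``gene_pvalues.tsv``: one row per replicate x method x inclusion with
    the p-value and the rejection decision at each requested alpha.
    ``snv_smt.tsv`` (when per-SNV records were collected): site-level SMT
    output (MAF, MAC, estimate, SE, raw and BH-adjusted p).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for inc in results.inclusions:
        for method, p in results.gene_p[inc].items():
            frame = pd.DataFrame({
                "replicate": np.arange(results.m),
                "method": method,
                "inclusion": inc,
                "p": p,
            })
            for a in alphas:
                frame[f"reject_at_{a:g}"] = p <= a
            rows.append(frame)
    gene_path = out_dir / "gene_pvalues.tsv"
    pd.concat(rows, ignore_index=True).to_csv(gene_path, sep="\t",
                                              index=False)
    paths = {"gene": gene_path}
    if results.snv is not None:
        snv_path = out_dir / "snv_smt.tsv"
        results.snv.to_csv(snv_path, sep="\t", index=False)
        paths["snv"] = snv_path
    return paths


def plot_power_by_scenario(summary: pd.DataFrame, out_path=None):
    """Bar panel of power per scenario and method (one panel per alpha).

    Takes the wide table from :func:`summarize_experiment`; returns the
    matplotlib figure (saved to ``out_path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = [c for c in ("smt_bh", "smt_bonf", "burden", "skat", "skato")
               if c in summary.columns]
    gene = summary[summary["level"] == "gene"]
    alphas = sorted(gene["alpha"].unique())
    fig, axes = plt.subplots(len(alphas), 1,
                             figsize=(8, 3 * len(alphas)), squeeze=False)
    for ax, alpha in zip(axes[:, 0], alphas):
        sub = gene[gene["alpha"] == alpha].set_index("scenario")
        sub[methods].plot.bar(ax=ax, width=0.8)
        ax.set_ylabel("power")
        ax.set_title(f"alpha = {alpha:g}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def _binomial_se(p_hat: float, denom: int) -> float:
    return math.sqrt(p_hat * (1.0 - p_hat) / denom) if denom else math.nan


def estimate_gene_power(results: ScenarioResults, method: str, alpha: float,
                        inclusion: str = "all_snvs") -> PowerEstimate:
    """Proportion of replicates whose gene-level test rejects at ``alpha``."""
    p = results.gene_p[inclusion][method]
    ok = np.isfinite(p)
    denom = int(ok.sum())
    if denom == 0:
        raise ValueError("no finite p-values for this method")
    est = float(np.mean(p[ok] <= alpha))
    return PowerEstimate(level="gene", alpha=alpha, method=method,
                         estimate=est, mc_se=_binomial_se(est, denom),
                         denominator=denom, inclusion=inclusion,
                         scenario_id=results.cfg.scenario_id)


def classify_mac(mac: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """MAF/MAC stratum labels used in SNV-level power reports."""
    out = np.empty(mac.shape, dtype=object)
    out[:] = ">0.03"
    out[maf <= 0.03] = "(0.01,0.03]"
    out[maf <= 0.01] = "(0.005,0.01]"
    out[maf <= 0.005] = "(0.001,0.005]"
    out[mac == 2] = "doubleton"
    out[mac == 1] = "singleton"
    return out


def estimate_snv_power(results: ScenarioResults, alpha: float,
                       maf_class: str | None = None,
                       adjusted: bool = False) -> PowerEstimate:
    """Proportion of causal-SNV p-values below ``alpha`` in one stratum.

    Pools the causal SNVs of all replicates (`l` in the denominator); the
    stratum is a MAF/MAC class label from :data:`MAF_CLASSES` or ``None``
    for all causal SNVs.  Raises if the stratum is empty.
    """
    if results.snv is None:
        raise ValueError("scenario was run without per-SNV collection")
    df = results.snv[results.snv["causal"]]
    if maf_class is not None:
        labels = classify_mac(df["mac"].to_numpy(), df["maf"].to_numpy())
        df = df[labels == maf_class]
    if df.empty:
        raise ValueError(f"empty causal stratum {maf_class!r}")
    pcol = "p_adj_bh" if adjusted else "p_raw"
    est = float((df[pcol] <= alpha).mean())
    denom = int(df.shape[0])
    return PowerEstimate(level="snv", alpha=alpha,
                         method="smt_adj" if adjusted else "smt",
                         estimate=est, mc_se=_binomial_se(est, denom),
                         denominator=denom, maf_class=maf_class,
                         scenario_id=results.cfg.scenario_id)


def summarize_experiment(estimates, explained=None) -> pd.DataFrame:
    """Wide table of estimates per scenario x method x alpha x inclusion.

    ``explained`` may map scenario ids to per-replicate explained-variance
    arrays; the summary then appends the median and median absolute
    deviation (in percent) for each scenario.
    """
    rows = []
    for est in estimates:
        rows.append({
            "scenario": est.scenario_id, "level": est.level,
            "method": est.method, "inclusion": est.inclusion,
            "alpha": est.alpha, "maf_class": est.maf_class,
            "estimate": est.estimate, "mc_se": est.mc_se,
            "denominator": est.denominator,
        })
    if not rows:
        raise ValueError("no estimates to summarise")
    df = pd.DataFrame(rows)
    wide = df.pivot_table(index=["scenario", "level", "inclusion", "alpha",
                                 "maf_class"],
                          columns="method", values="estimate",
                          dropna=False, observed=True).reset_index()
    if explained:
        ev_rows = []
        for sid, arr in explained.items():
            arr = np.asarray(arr, dtype=float)
            arr = arr[np.isfinite(arr)]
            med = float(np.median(arr)) if arr.size else math.nan
            mad = float(np.median(np.abs(arr - med))) if arr.size else math.nan
            ev_rows.append({"scenario": sid,
                            "explained_var_median_pct": 100 * med,
                            "explained_var_mad_pct": 100 * mad})
        wide = wide.merge(pd.DataFrame(ev_rows), on="scenario", how="left")
    return wide
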