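"""Medication adjustment of blood pressure and gene-level testing on VCFs.

Antihypertensive treatment lowers observed systolic blood pressure (SBP)
below the untreated value the genetic analysis is about, so treated
individuals are right-censored: their true SBP is only known to exceed the
observed one.  The adjustment stage

1. fits a censored (Tobit-type) linear regression of observed SBP on age,
   sex and smoking with medication use as the censoring indicator,
2. defines the adjusted phenotype ``SBP_adj`` as observed minus fitted SBP
   for untreated individuals, and as the conditional expectation of true SBP
   given ``T > observed`` minus fitted SBP (sigma times the inverse Mills
   ratio of the standardised censor point) for treated individuals,
3. collects genotypes per gene region (gene body plus a flank) from a VCF,
   drops SNVs with more than ``max_missing`` missing calls, mean-imputes the
   remaining missing genotypes and codes minor-allele counts,
4. runs the four association tests of :mod:`rvpower.association` on
   ``SBP_adj`` per gene.

A fully synthetic cohort generator writes VCF/phenotype/gene-table fixtures
so the pipeline can be exercised end to end without any external data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import optimize, stats

from . import association as assoc
from .association import _NullDesign, _burden_arrays, _skat_arrays, \
    _skato_arrays, adjust_pvalues, skat_weights, smt_fit_all

__all__ = [
    "CensoredRegressionFit",
    "AdjustedPhenotype",
    "fit_censored_regression",
    "adjust_phenotype",
    "define_gene_regions",
    "qc_filter_snvs",
    "RegionGenotypes",
    "gene_level_scan",
    "write_synthetic_cohort",
]

COVARIATE_NAMES = ("age", "sex", "smoking")


@dataclass(frozen=True)
class CensoredRegressionFit:
    """Maximum-likelihood Tobit fit with right-censoring at observed SBP."""

    coefficients: pd.Series     # intercept + covariate effects (mmHg/unit)
    se: pd.Series               # asymptotic standard errors (incl. sigma)
    sigma: float                # residual scale, mmHg
    loglik: float
    n_censored: int
    converged: bool
    covariate_names: tuple[str, ...]

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(covariates, self.covariate_names)
        return X @ self.coefficients.to_numpy()


@dataclass(frozen=True)
class AdjustedPhenotype:
    sbp_adj: np.ndarray
    treated: np.ndarray
    sbp_obs: np.ndarray


def _design_matrix(covariates, names) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        X = covariates.loc[:, list(names)].to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
    return np.column_stack([np.ones(X.shape[0]), X])


def _tobit_negll(params, X, y, censored):
    beta, log_sigma = params[:-1], params[-1]
    sigma = math.exp(log_sigma)
    z = (y - X @ beta) / sigma
    ll_unc = stats.norm.logpdf(z[~censored]).sum() - (~censored).sum() \
        * log_sigma
    ll_cen = stats.norm.logsf(z[censored]).sum()
    return -(ll_unc + ll_cen)


def fit_censored_regression(sbp_obs, covariates, treated,
                            covariate_names=COVARIATE_NAMES
                            ) -> CensoredRegressionFit:
    """Tobit-type ML fit of SBP on covariates with right-censored treated.

    Treated individuals contribute ``P(T > observed)`` to the likelihood;
    untreated contribute the normal density.  Starts from the OLS solution
    (which it reduces to exactly when nobody is treated).
    """
    y = np.asarray(sbp_obs, dtype=float)
    censored = np.asarray(treated, dtype=bool)
    X = _design_matrix(covariates, covariate_names)
    if censored.all():
        raise ValueError("need at least one uncensored observation")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    sigma0 = max(float(np.std(resid)), 1e-6)
    x0 = np.append(beta_ols, math.log(sigma0))

    if not censored.any():
        # exact closed form: the ML solution is the OLS fit
        n = y.size
        sigma_ml = math.sqrt(float(resid @ resid) / n)
        ll = -_tobit_negll(np.append(beta_ols, math.log(sigma_ml)), X, y,
                           censored)
        cov = _tobit_covariance(np.append(beta_ols, math.log(sigma_ml)),
                                X, y, censored)
        return _pack_fit(beta_ols, sigma_ml, ll, cov, censored,
                         covariate_names, True)

    res = optimize.minimize(_tobit_negll, x0, args=(X, y, censored),
                            method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    if not res.success:
        # polish with Nelder-Mead before giving up
        res = optimize.minimize(_tobit_negll, res.x, args=(X, y, censored),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 5000})
    beta = res.x[:-1]
    sigma = math.exp(res.x[-1])
    cov = _tobit_covariance(res.x, X, y, censored)
    return _pack_fit(beta, sigma, -res.fun, cov, censored, covariate_names,
                     bool(res.success))


def _tobit_covariance(params, X, y, censored) -> np.ndarray:
    """Inverse numerical Hessian of the negative log-likelihood."""
    k = params.size
    h = 1e-5 * np.maximum(np.abs(params), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (
                _tobit_negll(pp, X, y, censored)
                - _tobit_negll(pm, X, y, censored)
                - _tobit_negll(mp, X, y, censored)
                + _tobit_negll(mm, X, y, censored)) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


def _pack_fit(beta, sigma, loglik, cov, censored, names, converged):
    index = ["intercept", *names]
    se_beta = np.sqrt(np.diag(cov)[:-1])
    # delta method: SE(sigma) = sigma * SE(log sigma)
    se_sigma = sigma * math.sqrt(cov[-1, -1]) if np.isfinite(cov[-1, -1]) \
        else math.nan
    return CensoredRegressionFit(
        coefficients=pd.Series(beta, index=index),
        se=pd.Series(np.append(se_beta, se_sigma), index=index + ["sigma"]),
        sigma=float(sigma), loglik=float(loglik),
        n_censored=int(censored.sum()), converged=converged,
        covariate_names=tuple(names))


def adjust_phenotype(fit: CensoredRegressionFit, sbp_obs, covariates,
                     treated) -> AdjustedPhenotype:
    """Adjusted SBP: residuals for untreated, conditional-mean shift treated.

    For a treated individual with censor point ``c`` and linear predictor
    ``mu``:  ``sbp_adj = E[T | T > c] - mu = sigma * phi(z)/(1 - Phi(z))``
    with ``z = (c - mu)/sigma`` (computed on the log scale, so extreme censor
    points degrade gracefully into the asymptotic ``z + 1/z`` regime).
    """
    y = np.asarray(sbp_obs, dtype=float)
    censored = np.asarray(treated, dtype=bool)
    mu = fit.linear_predictor(covariates) if isinstance(covariates,
                                                        pd.DataFrame) \
        else _design_matrix(covariates, fit.covariate_names) \
        @ fit.coefficients.to_numpy()
    z = (y - mu) / fit.sigma
    adj = y - mu
    if censored.any():
        zc = z[censored]
        inv_mills = np.exp(stats.norm.logpdf(zc) - stats.norm.logsf(zc))
        adj = adj.copy()
        adj[censored] = fit.sigma * inv_mills
    return AdjustedPhenotype(sbp_adj=adj, treated=censored, sbp_obs=y)


def define_gene_regions(gene_table: pd.DataFrame,
                        flank: float = 5000) -> pd.DataFrame:
    """Flanked gene regions (1-based inclusive), floored at position 1.

    Overlapping regions are allowed: a SNV may belong to several genes.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(gene_table.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    if (gene_table["start"] > gene_table["end"]).any():
        raise ValueError("gene start must not exceed gene end")
    out = gene_table.copy()
    out["region_start"] = np.maximum(out["start"] - flank, 1).astype(int)
    out["region_end"] = (out["end"] + flank).astype(int)
    return out


@dataclass(frozen=True)
class RegionGenotypes:
    """QC-passed genotypes of one gene region (minor-allele dosages)."""

    gene: str
    genotypes: np.ndarray       # (n, k) float, mean-imputed where missing
    mafs: np.ndarray
    macs: np.ndarray
    site_positions: np.ndarray
    samples: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


def _read_vcf_matrix(vcf_path):
    """All biallelic records of a VCF as dosage rows (multi-allelic skipped)."""
    vcf = VCF(str(vcf_path))
    samples = tuple(vcf.samples)
    chroms, positions, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at "
                          f"{var.CHROM}:{var.POS}")
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        dose = gts.sum(axis=1).astype(float)
        dose[(gts < 0).any(axis=1)] = np.nan
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dose)
    vcf.close()
    if not rows:
        return samples, pd.DataFrame(), np.empty((0, len(samples)))
    meta = pd.DataFrame({"chrom": chroms, "pos": positions})
    return samples, meta, np.vstack(rows)


def qc_filter_snvs(vcf_path, regions: pd.DataFrame,
                   max_missing: float = 0.05,
                   rare_threshold: float = assoc.RARE_MAF_THRESHOLD,
                   inclusion: str = "all_snvs") -> list[RegionGenotypes]:
    """Per-region genotype matrices after missingness QC and recoding.

    A SNV is excluded when its missing-call fraction is *strictly greater*
    than ``max_missing``.  Kept genotypes are oriented to count the sample
    minor allele (frequency from called genotypes), missing calls are imputed
    with the per-SNV mean dosage, and the inclusion mode keeps all SNVs or
    only the rare (MAF <= ``rare_threshold``) ones.  Regions left without
    SNVs yield an empty entry.
    """
    samples, meta, dose = _read_vcf_matrix(vcf_path)
    out = []
    for _, row in regions.iterrows():
        if meta.empty:
            sel = np.empty(0, dtype=bool)
        else:
            sel = ((meta["chrom"] == str(row["chrom"]))
                   & (meta["pos"] >= row["region_start"])
                   & (meta["pos"] <= row["region_end"])).to_numpy()
        D = dose[sel]                      # k x n
        pos = meta.loc[sel, "pos"].to_numpy() if sel.any() \
            else np.empty(0, dtype=int)
        keep_rows, mafs, macs, cols = [], [], [], []
        for i in range(D.shape[0]):
            d = D[i]
            miss = np.isnan(d)
            if miss.mean() > max_missing:
                continue
            called = d[~miss]
            ac = called.sum()
            an = 2 * called.size
            if ac * 2 > an:                # orient to minor allele
                d = 2.0 - d
                ac = an - ac
            if ac <= 0 or ac >= an:
                continue                   # monomorphic among called
            maf = ac / an
            if inclusion == "rare_only" and maf > rare_threshold:
                continue
            d = d.copy()
            d[np.isnan(d)] = np.nanmean(d)
            keep_rows.append(d)
            mafs.append(maf)
            macs.append(int(round(ac)))
            cols.append(pos[i])
        geno = np.column_stack(keep_rows) if keep_rows \
            else np.empty((len(samples), 0))
        out.append(RegionGenotypes(gene=row["gene"], genotypes=geno,
                                   mafs=np.asarray(mafs),
                                   macs=np.asarray(macs),
                                   site_positions=np.asarray(cols),
                                   samples=samples))
    return out


def gene_level_scan(vcf_path, phenotypes: pd.DataFrame,
                    gene_table: pd.DataFrame, *, flank: float = 5000,
                    max_missing: float = 0.05,
                    inclusions=("all_snvs", "rare_only"),
                    acc: float = 1e-6) -> pd.DataFrame:
    """The full application stage: adjust SBP, then test each gene region.

    ``phenotypes`` needs columns id, sbp, age, sex, smoking, medication; the
    VCF sample names must match the id column.  Returns one row per gene and
    inclusion mode with the p-values of all four tests (SMT as the minimum
    BH-adjusted p-value).
    """
    fit = fit_censored_regression(phenotypes["sbp"],
                                  phenotypes[list(COVARIATE_NAMES)],
                                  phenotypes["medication"])
    adj = adjust_phenotype(fit, phenotypes["sbp"],
                           phenotypes[list(COVARIATE_NAMES)],
                           phenotypes["medication"])
    regions = define_gene_regions(gene_table, flank)
    rows = []
    ids = phenotypes["id"].astype(str).tolist()
    for inclusion in inclusions:
        for reg in qc_filter_snvs(vcf_path, regions, max_missing,
                                  inclusion=inclusion):
            if reg.n_sites == 0:
                rows.append({"gene": reg.gene, "inclusion": inclusion,
                             "n_snvs": 0, "smt": np.nan, "skat": np.nan,
                             "skato": np.nan, "burden": np.nan})
                continue
            order = [reg.samples.index(i) for i in ids]
            G = reg.genotypes[order]
            y = adj.sbp_adj
            n = y.size
            design = _NullDesign(y, X=np.ones((n, 1)))
            fit_s = smt_fit_all(y, None, None, G, design=design)
            p_raw = fit_s.p_raw[fit_s.valid]
            smt_p = float(adjust_pvalues(p_raw, "bh").min()) if p_raw.size \
                else np.nan
            w = skat_weights(reg.mafs)
            skat_p, _, _ = _skat_arrays(y, None, None, G, w, design=design,
                                        acc=acc)
            skato_p = _skato_arrays(y, None, None, G, w, design=design,
                                    acc=acc)
            burden_p = _burden_arrays(y, None, None, G, design=design)
            rows.append({"gene": reg.gene, "inclusion": inclusion,
                         "n_snvs": reg.n_sites, "smt": smt_p,
                         "skat": skat_p, "skato": skato_p,
                         "burden": burden_p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic end-to-end fixture


def write_synthetic_cohort(out_dir, n_individuals: int = 100,
                           n_genes: int = 9, seed: int = 0,
                           missing_rate: float = 0.01,
                           n_high_missing: int = 3) -> dict[str, Path]:
    """Write a synthetic VCF + phenotype table + gene table cohort.

    Purely simulated stand-in for an access-restricted sequencing study:
    binomial genotypes at mixed MAFs inside ``n_genes`` gene regions on one
    chromosome, an SBP phenotype driven by age/sex/smoking with ~30%
    medicated (right-censored) individuals, sprinkled missing genotype calls
    and ``n_high_missing`` SNVs whose missingness exceeds the QC threshold.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = n_individuals
    ids = [f"IND{i:04d}" for i in range(n)]

    # phenotypes: true SBP from covariates, treated observed below true
    age = rng.integers(30, 75, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    smoking = rng.integers(0, 2, n).astype(float)
    true_sbp = 95.0 + 0.45 * age + 4.0 * sex + 3.0 * smoking \
        + rng.normal(0.0, 12.0, n)
    treated = rng.random(n) < 0.3
    sbp = true_sbp.copy()
    sbp[treated] -= rng.uniform(5.0, 20.0, int(treated.sum()))
    pheno = pd.DataFrame({"id": ids, "sbp": np.round(sbp, 1), "age": age,
                          "sex": sex, "smoking": smoking,
                          "medication": treated.astype(int)})
    pheno_path = out_dir / "phenotypes.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)

    # gene table: evenly spaced genes on chromosome 19
    starts = 100_000 + 40_000 * np.arange(n_genes)
    genes = pd.DataFrame({"gene": [f"GENE{i + 1}" for i in range(n_genes)],
                          "chrom": "19", "start": starts,
                          "end": starts + 12_000})
    gene_path = out_dir / "genes.tsv"
    genes.to_csv(gene_path, sep="\t", index=False)

    # genotypes: binomial dosages at a rare-heavy MAF spectrum
    vcf_path = out_dir / "cohort.vcf"
    records = []
    high_missing_left = n_high_missing
    for _, g in genes.iterrows():
        k = int(rng.integers(12, 25))
        pos = np.sort(rng.choice(
            np.arange(g["start"] - 4000, g["end"] + 4000), k, replace=False))
        for p in pos:
            maf = float(rng.choice(
                [0.005, 0.01, 0.02, 0.05, 0.1, 0.25],
                p=[0.3, 0.25, 0.2, 0.1, 0.1, 0.05]))
            dose = rng.binomial(2, maf, n).astype(float)
            if dose.sum() == 0:
                dose[rng.integers(0, n)] = 1.0       # keep site polymorphic
            miss = rng.random(n) < missing_rate
            if high_missing_left > 0 and rng.random() < 0.05:
                miss = rng.random(n) < 0.10
                high_missing_left -= 1
            dose[miss] = np.nan
            records.append(("19", int(p), dose))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=19>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for chrom, p, dose in sorted(records, key=lambda r: r[1]):
            cells = ["./." if np.isnan(d) else gt_map[int(d)] for d in dose]
            fh.write(f"{chrom}\t{p}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")
    return {"vcf": vcf_path, "phenotypes": pheno_path, "genes": gene_path}
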