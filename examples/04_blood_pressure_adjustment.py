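"""Medication-adjusted blood-pressure association on a synthetic cohort.

Writes a fully synthetic VCF + phenotype + gene-table cohort (~100
individuals, 9 gene regions), fits the censored regression that corrects
observed SBP for antihypertensive treatment, and runs the gene-level tests
on the adjusted phenotype under both SNV-inclusion modes.
"""

import pandas as pd

from rvpower.adjust import (adjust_phenotype, fit_censored_regression,
                            gene_level_scan, write_synthetic_cohort)

paths = write_synthetic_cohort("scratch/example_cohort", seed=5)
pheno = pd.read_csv(paths["phenotypes"], sep="\t")
genes = pd.read_csv(paths["genes"], sep="\t")

fit = fit_censored_regression(pheno["sbp"],
                              pheno[["age", "sex", "smoking"]],
                              pheno["medication"])
print("censored-regression fit (treated observations right-censored):")
print(fit.coefficients.round(3).to_string())
print(f"sigma = {fit.sigma:.2f} mmHg, {fit.n_censored} treated of "
      f"{len(pheno)}")

adj = adjust_phenotype(fit, pheno["sbp"], pheno[["age", "sex", "smoking"]],
                       pheno["medication"])
print(f"mean adjustment for treated individuals: "
      f"+{adj.sbp_adj[adj.treated].mean():.1f} mmHg above the censor point")

table = gene_level_scan(paths["vcf"], pheno, genes)
print("\ngene-level p-values (SMT = min BH-adjusted per-SNV p):")
print(table.round(3).to_string(index=False))

# Treated individuals' true untreated SBP is only known to exceed the
# observed value; the Tobit fit recovers the covariate effects and the
# inverse-Mills term imputes the conditional mean before the genetic tests.
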