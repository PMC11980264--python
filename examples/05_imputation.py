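"""Covariate missingness: exclusion rule plus predictive mean matching.

Masks covariates completely at random, applies the >30% per-subject
exclusion rule, then fills the remaining holes by single PMM imputation
(5 donors) so imputed values are always observed values.
"""

import thermolag as tl
from thermolag.imputation import drop_high_missing, pmm_impute

cohort, _ = tl.simulate_cohort(2000, tl.null_truth(), seed=5)
covs = ["sex", "edu", "parity", "deprivation", "ndvi", "age_test_months"]
masked = tl.inject_missingness(
    cohort, {"edu": 0.15, "deprivation": 0.10, "age_test_months": 0.05}, seed=5
)

kept, report = drop_high_missing(masked, covs)
print(f"dropped {len(report.subjects_dropped)} subject(s) with >30% missing covariates")
print("per-covariate missing fractions after exclusion:")
for cov, frac in report.covariate_missing.items():
    if frac > 0:
        print(f"  {cov}: {frac:.1%}")

filled = pmm_impute(
    kept, ["edu", "deprivation", "age_test_months"], covs + ["y"], seed=5
)
print(f"remaining missing cells: {filled[covs].isna().sum().sum()}")
print(f"imputed edu levels are legal: "
      f"{set(filled['edu'].unique()) <= set(cohort['edu'].unique())}")

# PMM guarantees every imputed cell holds a value some other subject actually
# has, so category levels stay legal and continuous values stay in range.
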