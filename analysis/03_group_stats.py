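"""Group comparisons and feature-covariate correlation analysis.

Applies the Shapiro–Wilk gate per feature, runs ANOVA+Tukey or
Kruskal–Wallis+Mann–Whitney against the control group, and correlates
each fitted model feature with each clinical covariate (Pearson or
Spearman by normality), flagging significance at the modified-Bonferroni
level 0.05/8.  Writes results/group_comparisons.csv and
results/correlations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from frorfot.fitting import FEATURE_COLUMNS
from frorfot.io import read_feature_table
from frorfot.stats import (
    comparison_table,
    correlation_table,
    corrected_alpha,
    effective_independent_correlations,
    format_alpha,
)

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

features = read_feature_table(args.out / "features.csv")
covariates = pd.read_csv(args.out / "covariates.csv")

comp = comparison_table(features, FEATURE_COLUMNS)
comp.to_csv(args.out / "group_comparisons.csv", index=False)
level = corrected_alpha(effective_independent_correlations(2, 4))
corr = correlation_table(features, covariates, FEATURE_COLUMNS)
corr.to_csv(args.out / "correlations.csv", index=False)

print(f"corrected significance level for correlations: {format_alpha(level)} (0.05/8)")
print("group comparison stars vs control:")
for _, row in comp.iterrows():
    print(f"  {row['feature']:>5} [{row['gate']:>13}]  "
          f"NE {row['stars_normal_exam'] or 'ns':>3}  "
          f"AE {row['stars_abnormal_exam'] or 'ns':>3}")
sig = corr[corr["significant"]]
print(f"{len(sig)}/{len(corr)} correlations significant after correction; strongest:")
for _, row in sig.reindex(sig["R"].abs().sort_values(ascending=False).index).head(5).iterrows():
    print(f"  {row['feature']} ~ {row['covariate']}: R = {row['R']:+.2f} "
          f"({row['method']}, {row['strength']})")
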