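"""Clinical decision support: six classifiers, LOOCV, subset search.

Evaluates all six classifier families on the seven fitted model features
by leave-one-out cross-validation for both contrasts, then runs the
exhaustive 127-subset feature search for the kernel/instance-based kinds
(the boosted and forest ensembles are evaluated on all features only —
their subset search is available through `frorfot cdss --search` when
a longer run is acceptable).  Also checks whether appending the 21
pairwise cross products changes the best achievable accuracy.
Writes results/cdss_<contrast>_{all,search}.csv.
"""

import argparse
from pathlib import Path

from frorfot.cdss import ClassifierSpec, cross_product_expand, evaluation_table, loocv_evaluate
from frorfot.fitting import FEATURE_COLUMNS
from frorfot.io import read_feature_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

features = read_feature_table(args.out / "features.csv")
CONTRASTS = {"control_vs_NE": "normal_exam", "control_vs_AE": "abnormal_exam"}
SEARCH_KINDS = ("SVML", "SVMR", "1-NN", "PARZEN")

for contrast, patient_group in CONTRASTS.items():
    sub = features[features["group"].isin(["control", patient_group])]
    x, y = sub[FEATURE_COLUMNS], sub["label"].to_numpy()

    all_feats = evaluation_table(x, y, seed=args.seed)
    all_feats.to_csv(args.out / f"cdss_{contrast}_all.csv")
    print(f"\n{contrast}: all seven features (LOOCV)")
    print(all_feats.to_string())

    searched = evaluation_table(x, y, seed=args.seed, kinds=SEARCH_KINDS, search=True)
    searched.to_csv(args.out / f"cdss_{contrast}_search.csv")
    print(f"{contrast}: exhaustive subset search")
    print(searched.to_string())

# cross products: does the interaction expansion help the linear margin?
sub = features[features["group"].isin(["control", "normal_exam"])]
x, y = sub[FEATURE_COLUMNS], sub["label"].to_numpy()
spec = ClassifierSpec(kind="SVML", seed=args.seed)
plain = loocv_evaluate(x, y, spec).auc
expanded = loocv_evaluate(cross_product_expand(x), y, spec).auc
print(f"\ncross products (control_vs_NE, SVML): AUC {plain:.3f} -> {expanded:.3f} "
      f"with {cross_product_expand(x).shape[1] - len(FEATURE_COLUMNS)} product columns")
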