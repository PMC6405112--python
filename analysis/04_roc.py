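"""Single-parameter diagnostic accuracy: ROC, Youden cutoffs, LOOCV, DeLong.

For each contrast (control vs NE, control vs AE) computes per-feature
AUC, the optimal cutoff with its criterion direction, Se/Sp at the
cutoff, the accuracy class, and the leave-one-out cross-validated AUC.
Also compares the best tissue feature (eta) against the weakest (FrC)
with DeLong's paired test.  Writes results/roc_<contrast>.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from frorfot.fitting import FEATURE_COLUMNS
from frorfot.io import read_feature_table
from frorfot.roc import accuracy_class, compare_aucs_paired, loocv_threshold_roc, roc_analysis

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

features = read_feature_table(args.out / "features.csv")
CONTRASTS = {"control_vs_NE": "normal_exam", "control_vs_AE": "abnormal_exam"}

for contrast, patient_group in CONTRASTS.items():
    sub = features[features["group"].isin(["control", patient_group])]
    labels = sub["label"].to_numpy()
    rows = []
    for feat in FEATURE_COLUMNS:
        scores = sub[feat].to_numpy(dtype=float)
        res = roc_analysis(scores, labels)
        cls, adequate = accuracy_class(res.auc)
        rows.append({
            "feature": feat, "auc": round(res.auc, 3),
            "se_pct": round(res.se_at_cutoff, 1), "sp_pct": round(res.sp_at_cutoff, 1),
            "criterion": res.criterion, "class": cls, "adequate": adequate,
            "loocv_auc": round(loocv_threshold_roc(scores, labels).auc, 3),
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / f"roc_{contrast}.csv", index=False)
    print(f"\n{contrast} (n = {len(sub)}):")
    print(table.to_string(index=False))
    # beta and eta are a strictly monotone pair: identical rows expected
    b, e = table.set_index("feature").loc["beta"], table.set_index("feature").loc["eta"]
    assert b["auc"] == e["auc"] and b["se_pct"] == e["se_pct"]
    cmp = compare_aucs_paired(sub["eta"].to_numpy(), sub["FrC"].to_numpy(), labels)
    print(f"DeLong eta vs FrC: delta AUC = {cmp.delta:+.3f}, p = {cmp.p:.4f}")
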