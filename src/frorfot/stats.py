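"""Normality-gated group comparisons and correlation analysis.

The comparison protocol: Shapiro–Wilk decides, per feature, between the
parametric route (one-way ANOVA with Tukey's HSD) and the nonparametric
route (Kruskal–Wallis with pairwise Mann–Whitney U against the control
group).  Pairwise significance against control is annotated with the
conventional star scheme (* p<0.05, ** p<0.01, *** p<0.001).

Correlations use Pearson when both variables pass Shapiro–Wilk and
Spearman otherwise, are labelled with the standard strength classes, and
are tested against a modified-Bonferroni level obtained by dividing 0.05
by the effective number of independent correlations (two FOT families
crossed with the exam's variable families).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "normality_gate",
    "compare_groups",
    "correlate",
    "corrected_alpha",
    "format_alpha",
    "effective_independent_correlations",
    "classify_strength",
    "stars",
    "comparison_table",
    "correlation_table",
]

STRENGTH_CLASSES = (
    "small or no",
    "reasonable",
    "moderate to good",
    "very good to excellent",
)


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    gate: str  # "parametric" | "nonparametric"
    omnibus_test: str
    omnibus_p: float
    pairwise_p: dict[str, float]  # patient group name -> p vs control
    stars: dict[str, str]


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    method: str  # "pearson" | "spearman"
    R: float
    p: float
    significant_after_correction: bool
    strength_class: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.R <= 1.0 + 1e-12:
            raise ValueError(f"R out of range: {self.R}")


def _shapiro_normal(values: np.ndarray, alpha: float) -> bool:
    """True when Shapiro–Wilk does not reject normality.

    Zero-variance samples are degenerate for the test and routed to the
    nonparametric branch (returns False).
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False
    return sps.shapiro(values).pvalue > alpha


def normality_gate(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """"parametric" iff every group passes Shapiro–Wilk at ``alpha``."""
    for name, vals in values_by_group.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has < 3 values")
    ok = all(_shapiro_normal(v, alpha) for v in values_by_group.values())
    return "parametric" if ok else "nonparametric"


def stars(p: float) -> str:
    """Conventional significance annotation for a pairwise p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    control: str = "control",
    feature: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Omnibus + pairwise-vs-control comparison with a normality gate.

    Parametric route: one-way ANOVA, pairwise Tukey HSD p-values vs the
    control group.  Nonparametric route: Kruskal–Wallis, pairwise
    two-sided Mann–Whitney U vs control (uncorrected, reported as-is).
    Groups with literally identical pooled values short-circuit to "no
    difference" (omnibus p = 1, no stars).
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least two groups")
    if control not in values_by_group:
        raise ValueError(f"control group {control!r} missing")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    others = [k for k in groups if k != control]

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        pairwise = {k: 1.0 for k in others}
        return ComparisonResult(
            feature, "nonparametric", "kruskal-wallis", 1.0, pairwise,
            {k: "" for k in others},
        )

    gate = normality_gate(groups, alpha)
    names = list(groups)
    samples = [groups[k] for k in names]
    if gate == "parametric":
        omnibus_name = "anova"
        omnibus_p = float(sps.f_oneway(*samples).pvalue)
        tukey = sps.tukey_hsd(*samples)
        ci = names.index(control)
        pairwise = {
            k: float(tukey.pvalue[ci, names.index(k)]) for k in others
        }
    else:
        omnibus_name = "kruskal-wallis"
        omnibus_p = float(sps.kruskal(*samples).pvalue)
        pairwise = {
            k: float(
                sps.mannwhitneyu(groups[control], groups[k], alternative="two-sided").pvalue
            )
            for k in others
        }
    return ComparisonResult(
        feature, gate, omnibus_name, omnibus_p, pairwise,
        {k: stars(p) for k, p in pairwise.items()},
    )


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
    corrected_level: float = 0.05,
    gate_alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson (both variables normal by Shapiro–Wilk) or Spearman correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 5")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")

    if _shapiro_normal(x, gate_alpha) and _shapiro_normal(y, gate_alpha):
        method = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = sps.spearmanr(x, y)
    r, p = float(r), float(p)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        method=method,
        R=r,
        p=p,
        significant_after_correction=bool(p <= corrected_level),
        strength_class=classify_strength(r),
    )


def effective_independent_correlations(n_fot_families: int, n_exam_families: int) -> int:
    """Effective number of independent correlations: product of the family counts.

    FOT contributes its resistive and reactive families (2); a typical
    companion exam contributes about four independent variables, giving
    2 x 4 = 8 independent correlations.
    """
    if n_fot_families < 1 or n_exam_families < 1:
        raise ValueError("family counts must be >= 1")
    return int(n_fot_families) * int(n_exam_families)


def corrected_alpha(n_independent: int) -> float:
    """Modified-Bonferroni significance level 0.05 / n_independent."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return 0.05 / n_independent


def format_alpha(level: float) -> str:
    """Display form: rounded half-away-from-zero to 4 decimals (0.00625 -> '0.0063')."""
    return str(Decimal(repr(level)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def classify_strength(r: float) -> str:
    """Standard correlation strength classes on |R| (boundaries to the lower class)."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|R| must be <= 1, got {r}")
    if a <= 0.25:
        return STRENGTH_CLASSES[0]
    if a <= 0.50:
        return STRENGTH_CLASSES[1]
    if a <= 0.75:
        return STRENGTH_CLASSES[2]
    return STRENGTH_CLASSES[3]


def comparison_table(
    features: pd.DataFrame,
    feature_columns: list[str],
    group_column: str = "group",
    control: str = "control",
) -> pd.DataFrame:
    """Star-annotated group-comparison table, one row per feature."""
    rows = []
    for feat in feature_columns:
        grouped = {
            name: sub[feat].to_numpy(dtype=float)
            for name, sub in features.groupby(group_column, sort=False)
        }
        res = compare_groups(grouped, control=control, feature=feat)
        row = {
            "feature": feat,
            "gate": res.gate,
            "omnibus_test": res.omnibus_test,
            "omnibus_p": res.omnibus_p,
        }
        for g, p in res.pairwise_p.items():
            row[f"p_{g}_vs_{control}"] = p
            row[f"stars_{g}"] = res.stars[g]
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    feature_columns: list[str],
    corrected_level: float | None = None,
) -> pd.DataFrame:
    """All feature-by-covariate correlations with strength and significance flags.

    ``corrected_level`` defaults to the modified-Bonferroni level for
    2 x 4 = 8 independent correlations.
    """
    if corrected_level is None:
        corrected_level = corrected_alpha(effective_independent_correlations(2, 4))
    cov_cols = [c for c in covariates.columns if c != "subject_id"]
    overlap = [c for c in cov_cols if c in features.columns]
    merged = features.drop(columns=overlap).merge(covariates, on="subject_id")
    rows = []
    for feat in feature_columns:
        for cov in cov_cols:
            res = correlate(
                merged[feat].to_numpy(dtype=float),
                merged[cov].to_numpy(dtype=float),
                x_name=feat,
                y_name=cov,
                corrected_level=corrected_level,
            )
            rows.append(
                {
                    "feature": feat,
                    "covariate": cov,
                    "method": res.method,
                    "R": res.R,
                    "p": res.p,
                    "significant": res.significant_after_correction,
                    "strength": res.strength_class,
                }
            )
    return pd.DataFrame(rows)
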