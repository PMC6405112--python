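"""ROC-based diagnostic accuracy: AUC, Youden cutoff, paired tests, power.

AUC is the Mann–Whitney pair-counting probability that a randomly chosen
patient scores on the patient side of a randomly chosen control, with
ties credited 1/2.  The score orientation (whether high or low values
indicate disease) is chosen automatically so that AUC >= 0.5 and is
reported in the criterion string ("> x" for higher-is-positive, "<= x"
for lower-is-positive).  The optimal cutoff maximises the Youden index
J = Se + Sp - 1 over thresholds placed at observed score values, breaking
ties toward the more specific threshold.

Also provided: the accuracy-class bins (low / moderate / high, with 0.75
as the minimum adequate AUC), DeLong's paired test for correlated ROC
curves, a leave-one-out cross-validated threshold ROC, and the
Hanley–McNeil sample-size computation for detecting an AUC above a null
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "AUCComparison",
    "auc_mann_whitney",
    "roc_analysis",
    "accuracy_class",
    "compare_aucs_paired",
    "loocv_threshold_roc",
    "hanley_mcneil_n",
]


@dataclass(frozen=True)
class ROCResult:
    """Operating points plus the Youden-optimal summary of one score."""

    thresholds: np.ndarray
    se: np.ndarray  # sensitivity per threshold, fraction
    sp: np.ndarray  # specificity per threshold, fraction
    auc: float
    orientation: str  # "higher" | "lower" is positive
    cutoff: float
    criterion: str  # e.g. "> 0.137" or "<= 0.623"
    se_at_cutoff: float  # percent
    sp_at_cutoff: float  # percent
    cutoff_defined: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 subjects in each class")
    return scores, labels


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5*P(tie), higher-is-positive convention."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _operating_points(
    scores: np.ndarray, labels: np.ndarray, orientation: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Se/Sp at every observed threshold under the given orientation.

    "higher": predict positive when score > t; "lower": when score <= t.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    thresholds = np.unique(scores)
    if orientation == "higher":
        se = np.array([(pos > t).mean() for t in thresholds])
        sp = np.array([(neg <= t).mean() for t in thresholds])
    else:
        se = np.array([(pos <= t).mean() for t in thresholds])
        sp = np.array([(neg > t).mean() for t in thresholds])
    return thresholds, se, sp


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray, orientation: str | None = None
) -> ROCResult:
    """Full ROC analysis of one continuous score against binary labels.

    ``orientation=None`` (default) auto-orients so that AUC >= 0.5;
    passing "higher" or "lower" fixes the disease direction, in which
    case the reported AUC may fall below 0.5 (e.g. for classifier scores
    whose class-1 meaning is not up for reinterpretation).
    """
    scores, labels = _check_labels(scores, labels)
    auc_high = auc_mann_whitney(scores, labels)
    if orientation is None:
        orientation = "higher" if auc_high >= 0.5 else "lower"
    elif orientation not in ("higher", "lower"):
        raise ValueError(f"orientation must be 'higher' or 'lower', got {orientation!r}")
    # recount on negated scores (rather than 1 - auc) so that a strictly
    # decreasing transform of the scores yields the bit-identical AUC
    auc = auc_high if orientation == "higher" else auc_mann_whitney(-scores, labels)

    if np.ptp(scores) == 0:
        # all scores tied: no informative threshold exists
        return ROCResult(
            thresholds=np.array([scores[0]]),
            se=np.array([0.0]),
            sp=np.array([1.0]),
            auc=0.5,
            orientation=orientation,
            cutoff=float("nan"),
            criterion="undefined",
            se_at_cutoff=float("nan"),
            sp_at_cutoff=float("nan"),
            cutoff_defined=False,
        )

    thresholds, se, sp = _operating_points(scores, labels, orientation)
    j = se + sp - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    # tie-break toward higher specificity, then (still tied) larger J index order
    best_idx = candidates[np.argmax(sp[candidates])]
    cutoff = float(thresholds[best_idx])
    op = "> " if orientation == "higher" else "<= "
    return ROCResult(
        thresholds=thresholds,
        se=se,
        sp=sp,
        auc=auc,
        orientation=orientation,
        cutoff=cutoff,
        criterion=f"{op}{cutoff:g}",
        se_at_cutoff=float(se[best_idx] * 100.0),
        sp_at_cutoff=float(sp[best_idx] * 100.0),
    )


def accuracy_class(auc: float) -> tuple[str, bool]:
    """Diagnostic-accuracy class of an (oriented) AUC plus the adequacy flag.

    Bins are upper-inclusive: (0.5, 0.7] low, (0.7, 0.9] moderate,
    (0.9, 1.0] high; AUC >= 0.75 counts as adequate for clinical use.
    """
    if not 0.5 <= auc <= 1.0:
        raise ValueError(f"oriented AUC must lie in [0.5, 1], got {auc}")
    if auc <= 0.7:
        cls = "low"
    elif auc <= 0.9:
        cls = "moderate"
    else:
        cls = "high"
    return cls, bool(auc >= 0.75)


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-positive (V10) and per-negative (V01) placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # psi(x, y) = 1 if x > y, 0.5 if x == y, else 0
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp_matrix.mean())
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    return auc, v10, v01


def compare_aucs_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> AUCComparison:
    """DeLong's z-test for two correlated (same-subject) ROC curves.

    Each score is auto-oriented (sign-flipped when its plain AUC < 0.5)
    before comparison so that both AUCs are on the >= 0.5 scale.  When the
    estimated variance of the AUC difference is zero — e.g. the two scores
    are rank-identical — delta is reported with p = 1.
    """
    scores_a, labels = _check_labels(scores_a, labels)
    scores_b, _ = _check_labels(scores_b, labels)

    oriented = []
    for s in (scores_a, scores_b):
        oriented.append(s if auc_mann_whitney(s, labels) >= 0.5 else -s)
    sa, sb = oriented

    auc_a, v10_a, v01_a = _delong_placements(sa, labels)
    auc_b, v10_b, v01_b = _delong_placements(sb, labels)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        return AUCComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=0.0, p=1.0)
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, delta=delta, z=float(z), p=min(p, 1.0))


def loocv_threshold_roc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Leave-one-out cross-validated threshold ROC for a single score.

    Each fold learns the orientation and Youden cutoff on the remaining
    n-1 subjects; the held-out subject is assigned the signed distance of
    its score to that cutoff (positive side = patient side), yielding a
    continuous cross-validated score vector whose ROC summarises held-out
    performance.
    """
    scores, labels = _check_labels(scores, labels)
    n = scores.size
    if n < 10:
        raise ValueError(f"LOOCV needs n >= 10, got {n}")
    cv_scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        if len(np.unique(train_labels)) < 2:
            raise ValueError("training fold contains a single class")
        fold = roc_analysis(scores[mask], train_labels)
        if not fold.cutoff_defined:
            cv_scores[i] = 0.0
        elif fold.orientation == "higher":
            cv_scores[i] = scores[i] - fold.cutoff
        else:
            cv_scores[i] = fold.cutoff - scores[i]
    # the cross-validated score already encodes the disease direction, so
    # the final ROC must not re-learn the orientation from held-out data
    return roc_analysis(cv_scores, labels, orientation="higher")


def _hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil exponential-model variance of an empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def hanley_mcneil_n(
    auc_alt: float,
    auc_null: float = 0.5,
    type1: float = 0.10,
    type2: float = 0.10,
    max_n: int = 10000,
) -> int:
    """Smallest equal group size to detect ``auc_alt`` against ``auc_null``.

    Normal-approximation power condition with the Hanley–McNeil variance
    (Q1 = A/(2-A), Q2 = 2A^2/(1+A)) evaluated under both hypotheses:

        z_{alpha/2} * SE(auc_null) + z_{beta} * SE(auc_alt) <= auc_alt - auc_null

    with a two-sided type I error and one-sided power, the usual
    convention of ROC sample-size calculators.
    """
    if not 0.5 <= auc_null < auc_alt < 1.0:
        raise ValueError("need 0.5 <= auc_null < auc_alt < 1")
    if not (0 < type1 < 0.5 and 0 < type2 < 0.5):
        raise ValueError("error rates must lie in (0, 0.5)")
    z_a = sps.norm.ppf(1.0 - type1 / 2.0)
    z_b = sps.norm.ppf(1.0 - type2)
    delta = auc_alt - auc_null
    for n in range(2, max_n + 1):
        se0 = np.sqrt(_hanley_mcneil_variance(auc_null, n, n))
        se1 = np.sqrt(_hanley_mcneil_variance(auc_alt, n, n))
        if z_a * se0 + z_b * se1 <= delta:
            return n
    raise ValueError("no feasible group size below max_n")
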