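"""Clinical decision support stage: classifiers, LOOCV, feature search.

Six classifier families are evaluated by leave-one-out cross-validation
(LOOCV) on the seven model-derived features: linear-kernel SVM (SVML),
RBF-kernel SVM (SVMR), AdaBoost over decision stumps (ADAB), 1-nearest
neighbour (1-NN), random forest (RF) and a Parzen-window kernel-density
classifier (PARZEN).  Every fold standardises the features using
training-fold statistics only, trains on the remaining n-1 subjects and
records a continuous class-1 score for the held-out subject; AUC is
computed from the held-out scores and Se/Sp at their Youden cutoff.

An exhaustive subset search evaluates every nonempty subset of the
candidate features by LOOCV and returns the best-AUC subset (ties broken
toward smaller, lexicographically-first subsets).  Pairwise cross
products of features can be appended to probe interaction terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.special import logsumexp
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .roc import roc_analysis

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "EvalResult",
    "SearchResult",
    "loocv_evaluate",
    "parzen_score",
    "exhaustive_search",
    "cross_product_expand",
    "evaluation_table",
]

CLASSIFIER_KINDS = ("SVML", "SVMR", "ADAB", "1-NN", "RF", "PARZEN")

#: guard against combinatorial blow-up in the exhaustive search
MAX_SEARCH_FEATURES = 12


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six classifier kinds with its hyperparameters.

    Defaults: margin penalty C = 1 for both SVMs, RBF width from the
    median pairwise-distance heuristic, 50 depth-1 boosted stumps, a
    100-tree random forest, and a Parzen bandwidth chosen per training
    fold by maximising the pooled leave-one-out log-likelihood over a log
    grid.  ``seed`` fixes every stochastic component.
    """

    kind: str
    seed: int = 0
    svm_c: float = 1.0
    adaboost_stumps: int = 50
    rf_trees: int = 100
    parzen_bandwidth: float | None = None  # None -> per-fold LOO selection
    parzen_grid: tuple[float, ...] = tuple(np.geomspace(0.05, 3.0, 12))

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")
        if self.parzen_bandwidth is not None and self.parzen_bandwidth <= 0:
            raise ValueError("parzen bandwidth must be positive")


@dataclass(frozen=True)
class EvalResult:
    """LOOCV evaluation summary for one classifier on one feature set."""

    auc: float
    se_pct: float
    sp_pct: float
    scores: np.ndarray
    spec: ClassifierSpec
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")


@dataclass(frozen=True)
class SearchResult:
    best_features: tuple[str, ...]
    best: EvalResult
    ranking: pd.DataFrame  # one row per evaluated subset


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets using training statistics only (fold hygiene)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _median_heuristic_gamma(x: np.ndarray) -> float:
    d = pdist(x)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    sigma = np.median(d)
    return float(1.0 / (2.0 * sigma**2))


def parzen_score(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Class-1 posterior of a Parzen-window classifier.

    Class-conditional densities are Gaussian product-kernel estimates
    with a single shared bandwidth; the posterior combines them with
    training-prevalence priors.
    """
    if bandwidth <= 0 or not np.isfinite(bandwidth):
        raise ValueError(f"degenerate bandwidth {bandwidth}")
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ValueError("both classes must be present in training data")

    log_prior = {c: np.log((train_y == c).mean()) for c in (0, 1)}
    d = train_x.shape[1]
    log_norm = -0.5 * d * np.log(2 * np.pi * bandwidth**2)
    log_joint = {}
    for c in (0, 1):
        pts = train_x[train_y == c]
        sq = ((test_x[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        log_dens = logsumexp(-0.5 * sq / bandwidth**2, axis=1) - np.log(pts.shape[0]) + log_norm
        log_joint[c] = log_prior[c] + log_dens
    denom = np.logaddexp(log_joint[0], log_joint[1])
    return np.exp(log_joint[1] - denom)


def _select_parzen_bandwidth(x: np.ndarray, grid: tuple[float, ...]) -> float:
    """Bandwidth maximising the pooled leave-one-out log-likelihood."""
    n, d = x.shape
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(sq, np.inf)  # leave-one-out: exclude self kernel
    best_h, best_ll = grid[0], -np.inf
    for h in grid:
        log_norm = -0.5 * d * np.log(2 * np.pi * h**2)
        ll = float(
            np.sum(logsumexp(-0.5 * sq / h**2, axis=1) - np.log(n - 1) + log_norm)
        )
        if ll > best_ll:
            best_h, best_ll = h, ll
    return best_h


def _fold_score(
    spec: ClassifierSpec, train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> float:
    """Continuous class-1 score of the held-out point for one trained fold."""
    kind = spec.kind
    if kind == "SVML":
        clf = SVC(kernel="linear", C=spec.svm_c)
        clf.fit(train_x, train_y)
        return float(clf.decision_function(test_x)[0])
    if kind == "SVMR":
        clf = SVC(kernel="rbf", C=spec.svm_c, gamma=_median_heuristic_gamma(train_x))
        clf.fit(train_x, train_y)
        return float(clf.decision_function(test_x)[0])
    if kind == "ADAB":
        clf = AdaBoostClassifier(n_estimators=spec.adaboost_stumps, random_state=spec.seed)
        clf.fit(train_x, train_y)
        return float(clf.decision_function(test_x)[0])
    if kind == "RF":
        clf = RandomForestClassifier(n_estimators=spec.rf_trees, random_state=spec.seed)
        clf.fit(train_x, train_y)
        return float(clf.predict_proba(test_x)[0, list(clf.classes_).index(1)])
    if kind == "1-NN":
        # continuous score: relative distance to the nearest point of each class
        d = {}
        for c in (0, 1):
            nn = NearestNeighbors(n_neighbors=1).fit(train_x[train_y == c])
            d[c] = float(nn.kneighbors(test_x)[0][0, 0])
        total = d[0] + d[1]
        return 0.5 if total == 0 else d[0] / total
    if kind == "PARZEN":
        h = spec.parzen_bandwidth or _select_parzen_bandwidth(train_x, spec.parzen_grid)
        return float(parzen_score(train_x, train_y, test_x, h)[0])
    raise AssertionError(kind)


def loocv_evaluate(
    features: pd.DataFrame,
    labels: np.ndarray,
    spec: ClassifierSpec,
    test_features: pd.DataFrame | None = None,
) -> EvalResult:
    """Leave-one-out evaluation of one classifier.

    ``test_features`` defaults to ``features``; passing a modified copy
    scores altered held-out rows against the unaltered training folds,
    which is how fold hygiene (no leakage of the held-out subject into
    standardisation or training) can be audited.
    """
    x = features.to_numpy(dtype=float)
    x_test = x if test_features is None else test_features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n = x.shape[0]
    if x_test.shape != x.shape:
        raise ValueError("test_features must match features in shape")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(x_test))):
        raise ValueError("missing or non-finite feature values")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 rows per class")

    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("training fold contains a single class")
        train_s, test_s = _standardize(x[mask], x_test[i : i + 1])
        scores[i] = _fold_score(spec, train_s, y[mask], test_s)

    # class-1 scores have a fixed meaning: keep the higher-is-positive scale
    roc = roc_analysis(scores, y, orientation="higher")
    return EvalResult(
        auc=float(roc.auc),
        se_pct=roc.se_at_cutoff,
        sp_pct=roc.sp_at_cutoff,
        scores=scores,
        spec=spec,
        features=tuple(features.columns),
    )


def exhaustive_search(
    features: pd.DataFrame, labels: np.ndarray, spec: ClassifierSpec
) -> SearchResult:
    """LOOCV-evaluate every nonempty feature subset; return the best by AUC.

    Subsets are enumerated by increasing size and lexicographic order of
    the (sorted) feature names, and the first subset attaining the
    maximum AUC wins — i.e. ties break toward the smallest, then
    lexicographically-first subset.
    """
    names = sorted(features.columns)
    k = len(names)
    if not 1 <= k <= MAX_SEARCH_FEATURES:
        raise ValueError(
            f"exhaustive search supports 1..{MAX_SEARCH_FEATURES} candidate features "
            f"(2^k - 1 LOOCV runs); got {k}. Pre-select a smaller candidate set."
        )
    best: tuple[tuple[str, ...], EvalResult] | None = None
    rows = []
    for size in range(1, k + 1):
        for subset in itertools.combinations(names, size):
            res = loocv_evaluate(features[list(subset)], labels, spec)
            rows.append(
                {"features": ",".join(subset), "n_features": size, "auc": res.auc,
                 "se_pct": res.se_pct, "sp_pct": res.sp_pct}
            )
            if best is None or res.auc > best[1].auc:
                best = (subset, res)
    ranking = pd.DataFrame(rows).sort_values(
        ["auc", "n_features", "features"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return SearchResult(best_features=best[0], best=best[1], ranking=ranking)


def cross_product_expand(features: pd.DataFrame) -> pd.DataFrame:
    """Append all pairwise products ``a*b`` (column name "a*b"), keeping originals."""
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValueError("need at least two features to form cross products")
    out = features.copy()
    for a, b in itertools.combinations(cols, 2):
        name = f"{a}*{b}"
        if name in out.columns:
            raise ValueError(f"cross-product column name collision: {name!r}")
        out[name] = features[a] * features[b]
    return out


def evaluation_table(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    search: bool = False,
) -> pd.DataFrame:
    """AUC/Se/Sp rows by classifier columns; optionally with subset search.

    Mirrors the conventional presentation: one column per classifier,
    rows AUC, Se (%), Sp (%) and — in search mode — the chosen features.
    """
    table: dict[str, dict[str, object]] = {}
    for kind in kinds:
        spec = ClassifierSpec(kind=kind, seed=seed)
        if search:
            sr = exhaustive_search(features, labels, spec)
            res, chosen = sr.best, ",".join(sr.best_features)
        else:
            res, chosen = loocv_evaluate(features, labels, spec), ",".join(features.columns)
        col = {"AUC": round(res.auc, 4), "Se_pct": round(res.se_pct, 1),
               "Sp_pct": round(res.sp_pct, 1)}
        if search:
            col["features"] = chosen
        table[kind] = col
    return pd.DataFrame(table)
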