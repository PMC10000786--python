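"""Binary Dll4-high/low classification, pair selection and metrics.

The unit of evaluation is a *group pair*: one Dll4-high strain group
against one Dll4-low group. Each pair is scored by repeated stratified
75/25 splits, inner cross-validated hyperparameter tuning on the training
part, and a full confusion-matrix metric panel on the held-out part. The
headline score is

    A_score = (accuracy + sensitivity + specificity) / 3

and congenic pairs are ranked by the separation score against the
parental strains,

    S_score(CG+|CG-) = (A(Dll4+|CG-) + A(CG+|Dll4-) + 2 A(CG+|CG-)) / 4.

Pair selection is two-staged: all-feature S_scores filter pairs (> 0.80),
then survivors are re-evaluated with their two best recursive-feature-
elimination (RFE) features and must reach A_score >= 0.70; the argmax
wins. Neural networks are deliberately out of scope; the model suite is
nearest neighbors, linear/RBF SVM, decision tree, naive Bayes and
logistic regression. The positive class is always Dll4-high.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import InvalidArgumentError, SelectionError

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "high"

MODEL_NAMES = (
    "knn",
    "linear_svm",
    "rbf_svm",
    "decision_tree",
    "naive_bayes",
    "logistic_regression",
)

#: small fixed hyperparameter grids (reproducibility over exhaustiveness)
PARAM_GRIDS = {
    "knn": {"clf__n_neighbors": [1, 3, 5]},
    "linear_svm": {"clf__C": [0.1, 1.0, 10.0]},
    "rbf_svm": {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale", 0.1]},
    "decision_tree": {"clf__max_depth": [2, 3, 5, None]},
    "naive_bayes": {},
    "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
}


def make_model(name: str, seed: int = 0) -> Pipeline:
    """A standardized-input pipeline for one of the supported models.

    Models that support it use balanced class weights: group sizes differ
    up to 28 vs 12, and the headline A_score averages accuracy with both
    class-conditional rates, so unweighted fits would systematically
    sacrifice the smaller strain group.
    """
    if name == "knn":
        clf = KNeighborsClassifier()
    elif name == "linear_svm":
        clf = SVC(kernel="linear", class_weight="balanced", random_state=seed)
    elif name == "rbf_svm":
        clf = SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    elif name == "decision_tree":
        clf = DecisionTreeClassifier(class_weight="balanced", random_state=seed)
    elif name == "naive_bayes":
        clf = GaussianNB()
    elif name == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed)
    else:
        raise InvalidArgumentError(f"unknown model '{name}'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricPanel:
    """The full confusion-matrix metric panel of one evaluation."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    fpr: float
    fdr: float
    fnr: float
    accuracy: float
    f1: float
    mcc: float
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int, auc: float = float("nan")) -> MetricPanel:
    """All ten standard metrics from a confusion matrix.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any marginal is zero.
    """
    for v in (tp, fn, fp, tn):
        if v < 0 or int(v) != v:
            raise InvalidArgumentError("confusion counts must be nonnegative integers")
    total = tp + fn + fp + tn
    if total == 0:
        raise InvalidArgumentError("all-zero confusion matrix")
    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, tn + fp)
    prec = _safe_ratio(tp, tp + fp)
    npv = _safe_ratio(tn, tn + fn)
    acc = (tp + tn) / total
    f1 = _safe_ratio(2 * prec * sens, prec + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricPanel(
        tp=int(tp),
        fn=int(fn),
        fp=int(fp),
        tn=int(tn),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        npv=npv,
        fpr=_safe_ratio(fp, fp + tn),
        fdr=_safe_ratio(fp, fp + tp),
        fnr=_safe_ratio(fn, fn + tp),
        accuracy=acc,
        f1=f1,
        mcc=mcc,
        auc=auc,
    )


def a_score(accuracy: float, sensitivity: float, specificity: float) -> float:
    """Average of accuracy, sensitivity and specificity."""
    for v in (accuracy, sensitivity, specificity):
        if not 0 <= v <= 1:
            raise InvalidArgumentError("metrics must be in [0, 1]")
    return (accuracy + sensitivity + specificity) / 3.0


def s_score(a_parental_high_vs_cg_low: float, a_cg_high_vs_parental_low: float, a_cg_high_vs_cg_low: float) -> float:
    """Separation score of one congenic pair against the parental strains."""
    for v in (a_parental_high_vs_cg_low, a_cg_high_vs_parental_low, a_cg_high_vs_cg_low):
        if not 0 <= v <= 1:
            raise InvalidArgumentError("A_scores must be in [0, 1]")
    return (
        a_parental_high_vs_cg_low
        + a_cg_high_vs_parental_low
        + 2.0 * a_cg_high_vs_cg_low
    ) / 4.0


def confusion_from_rates(
    sensitivity: float,
    specificity: float,
    precision: float,
    npv: float,
    accuracy: float,
    max_total: int = 200,
) -> tuple[int, int, int, int]:
    """Smallest integer confusion matrix consistent with printed rates.

    Exhaustively searches (TP, FN, FP, TN) with total <= ``max_total``
    whose rates round to the given values at 4 decimal places; returns the
    smallest-total solution. Scale-invariant metrics (F1, MCC) are the
    same for every consistent solution.
    """
    rates = (sensitivity, specificity, precision, npv, accuracy)
    if any(not 0 <= r <= 1 for r in rates):
        raise InvalidArgumentError("rates must be in [0, 1]")

    def matches(value: float, target: float) -> bool:
        return abs(round(value, 4) - round(target, 4)) < 1e-9

    pos_candidates = [
        (tp, pos - tp)
        for pos in range(1, max_total)
        for tp in range(pos + 1)
        if matches(tp / pos, sensitivity)
    ]
    neg_candidates = [
        (neg - tn, tn)
        for neg in range(1, max_total)
        for tn in range(neg + 1)
        if matches(tn / neg, specificity)
    ]
    best = None
    for (tp, fn), (fp, tn) in itertools.product(pos_candidates, neg_candidates):
        total = tp + fn + fp + tn
        if total > max_total or (best is not None and total >= best[0]):
            continue
        if (tp + fp) and not matches(tp / (tp + fp), precision):
            continue
        if (tp + fp) == 0 and precision != 0:
            continue
        if (tn + fn) and not matches(tn / (tn + fn), npv):
            continue
        if (tn + fn) == 0 and npv != 0:
            continue
        if not matches((tp + tn) / total, accuracy):
            continue
        best = (total, (tp, fn, fp, tn))
    if best is None:
        raise InvalidArgumentError("no integer confusion matrix matches the rates")
    return best[1]


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated stratified hold-out evaluation with inner CV tuning."""

    test_fraction: float = 0.25
    n_repeats: int = 20
    inner_cv_folds: int = 10
    stratified: bool = True
    base_seed: int = 0
    report_mode: str = "best"  # or "mean"

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise InvalidArgumentError("test_fraction must be in (0, 1)")
        if self.inner_cv_folds < 2:
            raise InvalidArgumentError("inner_cv_folds must be >= 2")
        if self.report_mode not in ("best", "mean"):
            raise InvalidArgumentError("report_mode must be 'best' or 'mean'")


@dataclass
class PairEvaluation:
    """Outcome of evaluating one (high, low) group pair."""

    group_high: str
    group_low: str
    a_score: float
    a_score_sd: float
    a_score_mean: float
    a_score_best: float
    best_model: str
    best_features: list
    panels: dict = field(default_factory=dict)  # model -> list[MetricPanel]


def _param_candidates(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*grid.values())]


def _cv_a_score(model, params: dict, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    """A_score of pooled out-of-fold predictions under stratified CV."""
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return float("nan")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fn = fp = tn = 0
    for train_idx, val_idx in skf.split(X, y):
        est = clone(model).set_params(**params)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
        truth = y[val_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
    panel = metrics_from_confusion(tp, fn, fp, tn)
    return a_score(panel.accuracy, panel.sensitivity, panel.specificity)


def _tune(model, grid: dict, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int):
    """Pick grid hyperparameters by inner-CV A_score; fit on all of X."""
    candidates = _param_candidates(grid)
    if len(candidates) > 1:
        scores = [
            _cv_a_score(model, params, X, y, n_folds, seed) for params in candidates
        ]
        best = candidates[int(np.nanargmax(scores))]
    else:
        best = candidates[0]
    est = clone(model).set_params(**best)
    est.fit(X, y)
    return est, best


def _decision_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    proba = est.predict_proba(X)
    return np.asarray(proba[:, 1], dtype=float)


def _pair_arrays(
    features_table: pd.DataFrame,
    group_high: str,
    group_low: str,
    feature_subset=None,
) -> tuple[np.ndarray, np.ndarray, list]:
    cols = feature_columns(features_table) if feature_subset is None else list(feature_subset)
    sub = features_table[features_table["group"].isin([group_high, group_low])]
    sub = sub.dropna(subset=cols)
    y = (sub["group"] == group_high).astype(int).to_numpy()
    X = sub.loc[:, cols].to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise InvalidArgumentError(
            f"both groups need >= 2 usable members ({group_high} vs {group_low})"
        )
    return X, y, cols


def feature_columns(features_table: pd.DataFrame) -> list:
    """All feature columns of a table (everything but the id/label columns)."""
    meta = {"animal_id", "group", "dll4_label"}
    return [c for c in features_table.columns if c not in meta]


def evaluate_pair(
    features_table: pd.DataFrame,
    group_high: str,
    group_low: str,
    models=("linear_svm", "decision_tree"),
    protocol: EvalProtocol | None = None,
    feature_subset=None,
) -> PairEvaluation:
    """Repeated hold-out evaluation of one high-vs-low group pair.

    For each repeat: stratified 75/25 split, inner-CV tuning on the
    training part, a metric panel on the held-out part. Reports the best
    and the mean A_score across repeats (which one is headline depends on
    ``protocol.report_mode``). Fully reproducible from ``base_seed``.
    """
    protocol = protocol or EvalProtocol()
    X, y, cols = _pair_arrays(features_table, group_high, group_low, feature_subset)
    panels: dict[str, list[MetricPanel]] = {name: [] for name in models}
    for name in models:
        model = make_model(name, seed=protocol.base_seed)
        grid = PARAM_GRIDS[name]
        for rep in range(protocol.n_repeats):
            seed = protocol.base_seed + rep
            for attempt in range(5):
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X,
                    y,
                    test_size=protocol.test_fraction,
                    random_state=seed + 1000 * attempt,
                    stratify=y if protocol.stratified else None,
                )
                if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
                    break
                logger.warning("single-class split at seed %d; resampling", seed)
            est, _ = _tune(model, grid, X_tr, y_tr, protocol.inner_cv_folds, seed)
            pred = est.predict(X_te)
            tp = int(((pred == 1) & (y_te == 1)).sum())
            fn = int(((pred == 0) & (y_te == 1)).sum())
            fp = int(((pred == 1) & (y_te == 0)).sum())
            tn = int(((pred == 0) & (y_te == 0)).sum())
            scores = _decision_scores(est, X_te)
            if np.ptp(scores) > 0:
                fpr_c, tpr_c, _ = roc_curve(y_te, scores)
                auc_val = float(_trapezoid_auc(fpr_c, tpr_c))
            else:
                auc_val = 0.5
            panels[name].append(metrics_from_confusion(tp, fn, fp, tn, auc=auc_val))

    def _a(p: MetricPanel) -> float:
        return a_score(p.accuracy, p.sensitivity, p.specificity)

    summary = {
        name: (
            float(np.mean([_a(p) for p in ps])),
            float(np.std([_a(p) for p in ps])),
            float(np.max([_a(p) for p in ps])),
        )
        for name, ps in panels.items()
    }
    key = 2 if protocol.report_mode == "best" else 0
    best_model = max(summary, key=lambda nm: summary[nm][key])
    mean_a, sd_a, best_a = summary[best_model]
    return PairEvaluation(
        group_high=group_high,
        group_low=group_low,
        a_score=best_a if protocol.report_mode == "best" else mean_a,
        a_score_sd=sd_a,
        a_score_mean=mean_a,
        a_score_best=best_a,
        best_model=best_model,
        best_features=cols,
        panels=panels,
    )


# ---------------------------------------------------------------------------
# pair enumeration and selection
# ---------------------------------------------------------------------------


def enumerate_eligible_pairs(cohort_table: pd.DataFrame, min_n: int = 5) -> list[tuple[str, str]]:
    """All (high, low) group pairs where both groups have n > ``min_n``.

    ``cohort_table`` needs ``group`` and ``dll4_label`` columns, either one
    row per animal or per group with an ``n`` column.
    """
    if "n" in cohort_table.columns:
        grouped = cohort_table.set_index("group")[["dll4_label", "n"]]
        counts = grouped["n"]
        labels = grouped["dll4_label"]
    else:
        counts = cohort_table.groupby("group").size()
        labels = cohort_table.groupby("group")["dll4_label"].first()
    high = sorted(g for g in counts.index if labels[g] == "high" and counts[g] > min_n)
    low = sorted(g for g in counts.index if labels[g] == "low" and counts[g] > min_n)
    return [(h, l) for h in high for l in low]


def rfe_select(
    features_table: pd.DataFrame,
    pair: tuple[str, str],
    model_name: str = "linear_svm",
    n_final: int = 2,
    protocol: EvalProtocol | None = None,
) -> tuple[list, float]:
    """Recursive feature elimination down to ``n_final`` features.

    One feature is dropped per iteration, ranked by coefficient magnitude
    (linear models), impurity importance (trees) or permutation importance
    (nearest neighbors / naive Bayes). Constant columns are dropped first
    with a log entry. Returns the surviving names and their
    cross-validated A_score.
    """
    protocol = protocol or EvalProtocol()
    group_high, group_low = pair
    X, y, cols = _pair_arrays(features_table, group_high, group_low)
    if n_final >= len(cols):
        est0 = make_model(model_name, protocol.base_seed)
        est0.fit(X, y)
        score0 = _cv_a_score(
            make_model(model_name, protocol.base_seed),
            {},
            X,
            y,
            protocol.inner_cv_folds,
            protocol.base_seed,
        )
        return cols, score0

    n_constant = sum(np.ptp(X[:, i]) == 0 for i in range(X.shape[1]))
    if n_constant:
        logger.warning("dropping %d constant feature columns before RFE", n_constant)
    rng_seed = protocol.base_seed
    keep = _rfe_rank(X, y, model_name, n_final, rng_seed)
    names = [cols[i] for i in keep]
    final_score = _cv_a_score(
        make_model(model_name, rng_seed),
        {},
        X[:, keep],
        y,
        protocol.inner_cv_folds,
        rng_seed,
    )
    return names, final_score


def _rfe_rank(X: np.ndarray, y: np.ndarray, model_name: str, n_final: int, seed: int) -> np.ndarray:
    """Indices of the ``n_final`` surviving features after RFE.

    Features are eliminated one or more at a time: 30% of the remainder
    per iteration while more than 10 survive, then one at a time.
    """
    keep = np.array([i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0])
    while len(keep) > n_final:
        est = make_model(model_name, seed)
        est.fit(X[:, keep], y)
        clf = est.named_steps["clf"]
        if hasattr(clf, "coef_"):
            importance = np.abs(np.asarray(clf.coef_)).ravel()
        elif hasattr(clf, "feature_importances_"):
            importance = np.asarray(clf.feature_importances_)
        else:
            res = permutation_importance(est, X[:, keep], y, n_repeats=5, random_state=seed)
            importance = res.importances_mean
        n_drop = max(1, round(0.3 * len(keep))) if len(keep) > 10 else 1
        n_drop = min(n_drop, len(keep) - n_final)
        drop = np.argsort(importance)[:n_drop]
        keep = np.delete(keep, drop)
    return keep


def evaluate_pair_nested_rfe(
    features_table: pd.DataFrame,
    pair: tuple[str, str],
    models=("linear_svm", "decision_tree"),
    protocol: EvalProtocol | None = None,
    rfe_model: str = "linear_svm",
    n_features: int = 2,
    cv_folds: int = 6,
    cv_repetitions: int = 6,
) -> PairEvaluation:
    """Cross-validated evaluation of a pair with RFE nested in every fold.

    Stratified k-fold CV (k capped at the smaller class count) repeated
    with different fold shuffles; RFE sees only each fold's training part,
    so the pooled out-of-fold A_score is free of selection optimism, and
    every animal is tested exactly once per repetition (low variance even
    for small groups). Used to rank survivors in stage-2 pair selection.
    """
    protocol = protocol or EvalProtocol()
    X, y, cols = _pair_arrays(features_table, *pair)
    k = min(cv_folds, int(np.bincount(y).min()))
    panels: dict[str, list[MetricPanel]] = {name: [] for name in models}
    for rep in range(cv_repetitions):
        seed = protocol.base_seed + rep
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        counts = {name: np.zeros(4, dtype=int) for name in models}
        for tr_idx, te_idx in skf.split(X, y):
            keep = _rfe_rank(X[tr_idx], y[tr_idx], rfe_model, n_features, seed)
            for name in models:
                est, _ = _tune(
                    make_model(name, seed),
                    PARAM_GRIDS[name],
                    X[np.ix_(tr_idx, keep)],
                    y[tr_idx],
                    protocol.inner_cv_folds,
                    seed,
                )
                pred = est.predict(X[np.ix_(te_idx, keep)])
                truth = y[te_idx]
                counts[name] += np.array(
                    [
                        int(((pred == 1) & (truth == 1)).sum()),
                        int(((pred == 0) & (truth == 1)).sum()),
                        int(((pred == 1) & (truth == 0)).sum()),
                        int(((pred == 0) & (truth == 0)).sum()),
                    ]
                )
        for name in models:
            panels[name].append(metrics_from_confusion(*counts[name]))

    def _a(p: MetricPanel) -> float:
        return a_score(p.accuracy, p.sensitivity, p.specificity)

    summary = {
        name: (
            float(np.mean([_a(p) for p in ps])),
            float(np.std([_a(p) for p in ps])),
            float(np.max([_a(p) for p in ps])),
        )
        for name, ps in panels.items()
    }
    best_model = max(summary, key=lambda nm: summary[nm][0])
    mean_a, sd_a, best_a = summary[best_model]
    return PairEvaluation(
        group_high=pair[0],
        group_low=pair[1],
        a_score=mean_a,
        a_score_sd=sd_a,
        a_score_mean=mean_a,
        a_score_best=best_a,
        best_model=best_model,
        best_features=cols,
        panels=panels,
    )


def select_final_features(
    features_table: pd.DataFrame,
    selected_pair: tuple[str, str],
    parental_high: str = "Dll4+",
    parental_low: str = "Dll4-",
    model_name: str = "linear_svm",
    n_final: int = 2,
    protocol: EvalProtocol | None = None,
) -> tuple[list, float]:
    """Final feature pair from the pooled parental + selected congenic groups.

    The final classifier's features are refined on the combination of the
    parental strains and the selected congenic pair (high: parental-high +
    CG-high; low: parental-low + CG-low): pooling the strongest-contrast
    groups selects features that carry the class axis itself rather than
    pair-specific quirks.
    """
    cg_high, cg_low = selected_pair
    sub = features_table[
        features_table["group"].isin([parental_high, parental_low, cg_high, cg_low])
    ].copy()
    sub["group"] = np.where(
        sub["group"].isin([parental_high, cg_high]), "__high__", "__low__"
    )
    return rfe_select(sub, ("__high__", "__low__"), model_name, n_final, protocol)


@dataclass
class SelectionResult:
    selected_pair: tuple[str, str] | None
    selected_features: list
    stage1: pd.DataFrame
    stage2: pd.DataFrame


def compute_s_scores(
    features_table: pd.DataFrame,
    congenic_pairs: list,
    parental_high: str = "Dll4+",
    parental_low: str = "Dll4-",
    models=("linear_svm", "decision_tree"),
    protocol: EvalProtocol | None = None,
) -> pd.DataFrame:
    """S_score of each congenic pair, caching the shared pair evaluations."""
    protocol = protocol or EvalProtocol()
    cache: dict[tuple[str, str], PairEvaluation] = {}

    def _eval(high: str, low: str) -> PairEvaluation:
        key = (high, low)
        if key not in cache:
            cache[key] = evaluate_pair(
                features_table, high, low, models=models, protocol=protocol
            )
        return cache[key]

    rows = []
    for cg_high, cg_low in congenic_pairs:
        a1 = _eval(parental_high, cg_low).a_score
        a2 = _eval(cg_high, parental_low).a_score
        a3 = _eval(cg_high, cg_low).a_score
        rows.append(
            {
                "group_high": cg_high,
                "group_low": cg_low,
                "a_parental_high_vs_cg_low": a1,
                "a_cg_high_vs_parental_low": a2,
                "a_cg_pair": a3,
                "s_score": s_score(a1, a2, a3),
            }
        )
    return pd.DataFrame(rows)


def select_congenic_pair(
    features_table: pd.DataFrame,
    cohort_table: pd.DataFrame | None = None,
    protocol: EvalProtocol | None = None,
    models=("linear_svm", "decision_tree"),
    parental_high: str = "Dll4+",
    parental_low: str = "Dll4-",
    s_threshold: float = 0.80,
    a_threshold: float = 0.70,
    rfe_model: str = "linear_svm",
    n_features: int = 2,
) -> SelectionResult:
    """Two-stage congenic pair selection with a full audit trail.

    Stage 1 computes all-feature S_scores for every eligible congenic pair
    and keeps those above ``s_threshold``. Stage 2 re-evaluates survivors
    with their two best RFE features (mean A_score across repeats) and
    keeps those at/above ``a_threshold``; the argmax wins, ties broken by
    lexicographic pair name (logged).
    """
    protocol = protocol or EvalProtocol()
    if cohort_table is None:
        cohort_table = features_table[["group", "dll4_label"]]
    pairs = enumerate_eligible_pairs(cohort_table)
    congenic = [
        (h, l) for h, l in pairs if h not in (parental_high,) and l not in (parental_low,)
    ]
    if not congenic:
        raise SelectionError("no eligible congenic pairs")

    stage1 = compute_s_scores(
        features_table, congenic, parental_high, parental_low, models, protocol
    )
    survivors = stage1[stage1["s_score"] > s_threshold]
    if survivors.empty:
        raise SelectionError("no pair with S_score above threshold", audit=stage1)

    stage2_protocol = EvalProtocol(
        test_fraction=protocol.test_fraction,
        n_repeats=max(protocol.n_repeats, 20),
        inner_cv_folds=protocol.inner_cv_folds,
        stratified=protocol.stratified,
        base_seed=protocol.base_seed,
        report_mode="mean",
    )
    rows = []
    for _, r in survivors.iterrows():
        pair = (r["group_high"], r["group_low"])
        ev = evaluate_pair_nested_rfe(
            features_table,
            pair,
            models=models,
            protocol=stage2_protocol,
            rfe_model=rfe_model,
            n_features=n_features,
        )
        # the reported feature pair comes from RFE on the pair's full data;
        # the score above is the nested (selection-bias-free) estimate
        feats, _rfe_score = rfe_select(
            features_table, pair, rfe_model, n_features, protocol
        )
        rows.append(
            {
                "group_high": pair[0],
                "group_low": pair[1],
                "features": tuple(feats),
                "a_score": ev.a_score_mean,
                "a_score_sd": ev.a_score_sd,
                "best_model": ev.best_model,
            }
        )
    stage2 = pd.DataFrame(rows)
    passed = stage2[stage2["a_score"] >= a_threshold]
    if passed.empty:
        raise SelectionError(
            "no surviving pair reached the A_score threshold",
            audit={"stage1": stage1, "stage2": stage2},
        )
    ranked = passed.sort_values(
        by=["a_score", "group_high", "group_low"], ascending=[False, True, True]
    )
    top = ranked.iloc[0]
    n_tied = int((passed["a_score"] == top["a_score"]).sum())
    if n_tied > 1:
        logger.info(
            "A_score tie among %d pairs; lexicographic tie-break selected %s|%s",
            n_tied,
            top["group_high"],
            top["group_low"],
        )
    return SelectionResult(
        selected_pair=(top["group_high"], top["group_low"]),
        selected_features=list(top["features"]),
        stage1=stage1,
        stage2=stage2,
    )


# ---------------------------------------------------------------------------
# final evaluation
# ---------------------------------------------------------------------------


@dataclass
class FinalEvaluation:
    model: str
    train_panel: MetricPanel
    test_panel: MetricPanel
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float


def final_evaluation(
    features_table: pd.DataFrame,
    train_groups,
    selected_features,
    models=("linear_svm", "knn"),
    protocol: EvalProtocol | None = None,
    report_path=None,
    roc_path=None,
) -> dict:
    """Train/test the selected features on the held-back group set.

    Pools the animals of ``train_groups``, labels them Dll4-high vs -low,
    makes one stratified hold-out split, tunes each model by inner CV and
    reports the confusion-matrix panel, ROC curve (score-threshold sweep)
    and trapezoidal AUC on both parts. Optionally writes a JSON report and
    ROC coordinates CSV.
    """
    protocol = protocol or EvalProtocol()
    missing = [f for f in selected_features if f not in features_table.columns]
    if missing:
        raise InvalidArgumentError(f"selected features missing from table: {missing}")
    sub = features_table[features_table["group"].isin(list(train_groups))]
    sub = sub.dropna(subset=list(selected_features))
    y = (sub["dll4_label"] == POSITIVE_LABEL).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training set contains a single class")
    X = sub.loc[:, list(selected_features)].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=protocol.test_fraction,
        random_state=protocol.base_seed,
        stratify=y if protocol.stratified else None,
    )
    results = {}
    for name in models:
        est, _ = _tune(
            make_model(name, protocol.base_seed),
            PARAM_GRIDS[name],
            X_tr,
            y_tr,
            protocol.inner_cv_folds,
            protocol.base_seed,
        )

        def _panel(Xs, ys) -> MetricPanel:
            pred = est.predict(Xs)
            tp = int(((pred == 1) & (ys == 1)).sum())
            fn = int(((pred == 0) & (ys == 1)).sum())
            fp = int(((pred == 1) & (ys == 0)).sum())
            tn = int(((pred == 0) & (ys == 0)).sum())
            return metrics_from_confusion(tp, fn, fp, tn)

        scores = _decision_scores(est, X_te)
        if np.ptp(scores) > 0:
            fpr_c, tpr_c, thresh = roc_curve(y_te, scores)
            auc_val = float(_trapezoid_auc(fpr_c, tpr_c))
        else:
            fpr_c, tpr_c, thresh = (
                np.array([0.0, 1.0]),
                np.array([0.0, 1.0]),
                np.array([np.inf, -np.inf]),
            )
            auc_val = 0.5
        roc_df = pd.DataFrame({"fpr": fpr_c, "tpr": tpr_c, "threshold": thresh})
        test_panel = _panel(X_te, y_te)
        results[name] = FinalEvaluation(
            model=name,
            train_panel=_panel(X_tr, y_tr),
            test_panel=metrics_from_confusion(
                test_panel.tp, test_panel.fn, test_panel.fp, test_panel.tn, auc=auc_val
            ),
            roc=roc_df,
            auc=auc_val,
        )

    if report_path is not None:
        payload = {
            name: {
                "train": res.train_panel.as_dict(),
                "test": res.test_panel.as_dict(),
                "auc": res.auc,
            }
            for name, res in results.items()
        }
        with open(report_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    if roc_path is not None:
        pd.concat(
            [res.roc.assign(model=name) for name, res in results.items()]
        ).to_csv(roc_path, index=False)
    return results
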