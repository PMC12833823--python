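"""Feature-based prediction of MTSR status (radiomics-arm surrogate).

The chain mirrors a standard radiomics workflow: screen features for
test-retest reproducibility by ICC(2,1), z-score the survivors, pick the
ten most informative by minimum-redundancy-maximum-relevance (mRMR, FCD
variant: F-statistic relevance minus mean absolute-correlation
redundancy), fit a random forest over an exhaustive hyperparameter grid
(trees 5-150, depth 1-10, split 2-10, leaf 1-6) chosen by cross-validated
AUC, and report the full metric panel with a bootstrap AUC interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split

from .quantification import icc_2_1

_GRID_BOUNDS = {"n_estimators": (5, 150), "max_depth": (1, 10),
                "min_samples_split": (2, 10), "min_samples_leaf": (1, 6)}


def zscore(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score normalization (population sd)."""
    sd = features.std(ddof=0).replace(0, 1.0)
    return (features - features.mean()) / sd


def icc_screen(
    repeat_a: pd.DataFrame, repeat_b: pd.DataFrame, threshold: float = 0.75
) -> tuple[list[str], pd.Series]:
    """Per-feature ICC(2,1) across two repeated measurements.

    Features with ICC at or above the threshold are retained.
    """
    if list(repeat_a.columns) != list(repeat_b.columns):
        raise ValueError("the two repeats must share the same feature columns")
    iccs = {}
    for col in repeat_a.columns:
        iccs[col], _ = icc_2_1(repeat_a[col].to_numpy(), repeat_b[col].to_numpy())
    icc_series = pd.Series(iccs)
    retained = [c for c in repeat_a.columns if icc_series[c] >= threshold]
    return retained, icc_series


@dataclass
class MRMRSelection:
    selected: list[str]
    relevance: pd.Series  # F-statistic of each feature vs. the label
    steps: list[dict] = field(default_factory=list)  # per-step score breakdown


def mrmr_select(features: pd.DataFrame, labels: np.ndarray, k: int = 10) -> MRMRSelection:
    """Greedy mRMR (FCD): maximize relevance minus mean redundancy.

    Relevance is the one-way ANOVA F-statistic of the feature against the
    binary label, mapped to the explained-variance scale
    R^2 = F / (F + n - 2) so that it is commensurable with the redundancy
    term (mean absolute Pearson correlation with the already-selected
    set). The mapping is strictly monotone in F, so the first pick is
    always the most relevant feature; ties break by column order.
    """
    if k > features.shape[1]:
        raise ValueError(f"k={k} exceeds the {features.shape[1]} available features")
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    raw_f, _ = f_classif(x, y)
    raw_f = np.nan_to_num(raw_f, nan=0.0)
    f_stat = raw_f / (raw_f + len(y) - 2)
    cols = list(features.columns)
    corr = np.abs(np.corrcoef(x, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    selected: list[int] = []
    steps = []
    remaining = list(range(len(cols)))
    for _ in range(k):
        if not selected:
            scores = f_stat[remaining]
            red = np.zeros(len(remaining))
        else:
            red = corr[np.ix_(remaining, selected)].mean(axis=1)
            scores = f_stat[remaining] - red
        best_pos = int(np.argmax(scores))  # argmax keeps the earliest on ties
        best = remaining[best_pos]
        steps.append(
            {"feature": cols[best], "relevance": float(f_stat[best]),
             "redundancy": float(red[best_pos]), "score": float(scores[best_pos])}
        )
        selected.append(best)
        remaining.remove(best)
    return MRMRSelection(
        selected=[cols[i] for i in selected],
        relevance=pd.Series(f_stat, index=cols),
        steps=steps,
    )


@dataclass(frozen=True)
class GridSearchSpec:
    """Hyperparameter grid; values must stay inside the canonical bounds."""

    n_estimators: tuple[int, ...] = (5, 13, 25, 50, 100, 150)
    max_depth: tuple[int, ...] = (1, 2, 4, 6, 10)
    min_samples_split: tuple[int, ...] = (2, 5, 10)
    min_samples_leaf: tuple[int, ...] = (1, 3, 6)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _GRID_BOUNDS.items():
            vals = getattr(self, name)
            if not vals or any(not lo <= v <= hi for v in vals):
                raise ValueError(f"{name} values must lie in [{lo}, {hi}]")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


def grid_search_forest(
    features: pd.DataFrame, labels: np.ndarray, spec: GridSearchSpec = GridSearchSpec()
) -> tuple[dict, RandomForestClassifier, pd.DataFrame]:
    """Exhaustive CV grid search maximizing mean AUC.

    Ties prefer fewer trees, then shallower depth. Returns the best
    parameters, the forest refit on all data, and the full CV table.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    splits = list(cv.split(x, y))
    grid = ParameterGrid(
        {"n_estimators": spec.n_estimators, "max_depth": spec.max_depth,
         "min_samples_split": spec.min_samples_split,
         "min_samples_leaf": spec.min_samples_leaf}
    )
    rows = []
    for params in grid:
        aucs = []
        for tr, te in splits:
            clf = RandomForestClassifier(random_state=spec.seed, **params)
            clf.fit(x[tr], y[tr])
            prob = clf.predict_proba(x[te])[:, 1]
            aucs.append(roc_auc_score(y[te], prob))
        rows.append({**params, "mean_auc": float(np.mean(aucs))})
    table = pd.DataFrame(rows)
    best_row = table.sort_values(
        by=["mean_auc", "n_estimators", "max_depth"], ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    best = {k: int(best_row[k]) for k in
            ("n_estimators", "max_depth", "min_samples_split", "min_samples_leaf")}
    final = RandomForestClassifier(random_state=spec.seed, **best)
    final.fit(x, y)
    return best, final, table


@dataclass(frozen=True)
class ClassifierMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    auc_ci: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int
    probabilities: np.ndarray


def classification_metrics(
    truth: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassifierMetrics:
    """Confusion-based panel at a probability threshold plus rank AUC.

    The AUC equals the Mann-Whitney concordance of the probabilities; its
    95% CI comes from a stratified bootstrap over samples.
    """
    y = np.asarray(truth).astype(int)
    p = np.asarray(probabilities, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)

    def _safe(a: float, b: float) -> float:
        return a / b if b > 0 else np.nan

    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else np.nan
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        boots.append(roc_auc_score(y[idx], p[idx]))
    ci = (
        (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        if boots else (np.nan, np.nan)
    )
    return ClassifierMetrics(
        accuracy=_safe(tp + tn, n),
        sensitivity=_safe(tp, tp + fn),
        specificity=_safe(tn, tn + fp),
        ppv=_safe(tp, tp + fp),
        npv=_safe(tn, tn + fn),
        auc=auc,
        auc_ci=ci,
        tp=tp, fp=fp, tn=tn, fn=fn,
        probabilities=p,
    )


def split_train_validation(
    features: pd.DataFrame, labels: np.ndarray, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified 7:3 train/validation split with a fixed seed."""
    xtr, xva, ytr, yva = train_test_split(
        features, labels, train_size=ratio, stratify=labels, random_state=seed
    )
    return xtr, xva, ytr, yva
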