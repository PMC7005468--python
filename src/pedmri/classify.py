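"""Cross-validated tumour classification.

Implements the study protocol: stratified 3-fold cross-validation over two
tasks (binary grade, three-way tumour type), with either PCA (95% variance,
capped at N_min - 1 components where N_min is the smallest group) or
fold-wise univariate feature selection; five classifier families (AdaBoost
of stumps, random forest, RBF support-vector machine, k-nearest neighbours
with k = round(sqrt(n_train)), and a single-hidden-layer neural network);
optional minority oversampling of the training folds (replication or
SMOTE, +100% ependymoma by default); and inner-loop hyperparameter tuning
that maximises training-set AUC.

Everything that learns from data — scaling, PCA loadings, feature
selection, oversampling, hyperparameters — is fitted strictly on the
training rows of each fold; test rows are only ever transformed and
predicted.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS, VOLUME_COLUMN, grade_of
from .stats import univariate_battery

__all__ = [
    "ExperimentConfig",
    "CVReport",
    "grade_task_labels",
    "stratified_kfold",
    "pca_reduce",
    "univariate_select",
    "oversample",
    "knn_k",
    "train_and_evaluate",
    "perturbation_analysis",
]

log = logging.getLogger(__name__)

TASKS = ("grade", "type")
FEATURE_SETS = ("all", "roi", "wb")
REDUCTIONS = ("pca", "univariate", "none")
CLASSIFIERS = ("adaboost", "random_forest", "svm", "knn", "neural_net")
OVERSAMPLING = ("none", "replicate", "smote")

#: learners that need z-scored inputs (distance / gradient based)
_SCALED = {"svm", "knn", "neural_net"}


@dataclass
class ExperimentConfig:
    """One classification experiment."""

    task: str = "type"
    feature_set: str = "all"
    reduction: str = "pca"
    classifier: str = "adaboost"
    oversampling: str = "none"
    oversample_class: str = "ependymoma"
    oversample_amount: float = 1.0       # +100%
    n_folds: int = 3
    seed: int = 0
    hyperopt_budget: int = 6
    variance_target: float = 0.95
    cap_before_oversampling: bool = False
    max_selected_features: int | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.oversampling not in OVERSAMPLING:
            raise ValueError(f"unknown oversampling {self.oversampling!r}")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class CVReport:
    """Pooled cross-validation result."""

    bar: float                       # balanced accuracy rate, %
    f_stat: float                    # macro-averaged F1
    precision_macro: float           # between-group average precision, %
    per_class: dict[str, dict[str, float]]
    confusion: pd.DataFrame
    fold_details: list[dict] = field(default_factory=list)
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None


def grade_task_labels(labels) -> np.ndarray:
    """Collapse tumour types to the grade dichotomy (PA low, MB/EP high)."""
    return np.array([grade_of(lab) for lab in np.asarray(labels)])


def feature_columns_for(feature_set: str) -> list[str]:
    if feature_set == "all":
        return list(FEATURE_COLUMNS)
    region = "ROI" if feature_set == "roi" else "WB"
    cols = [c for c in FEATURE_COLUMNS if f"_{region}_" in c]
    if feature_set == "roi":
        cols.append(VOLUME_COLUMN)  # volume is a tumour-ROI measurement
    return cols


def stratified_kfold(labels, k: int = 3, seed: int = 0):
    """Stratified fold assignment: per class, fold counts differ by <= 1.

    Returns a list of (train_idx, test_idx) pairs forming a partition.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < k:
            raise ValueError(f"class {cls!r} has only {n} members (< k={k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def pca_reduce(
    X_train: np.ndarray,
    X_test: np.ndarray,
    train_labels,
    variance_target: float = 0.95,
    cap: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Standardise on training statistics, then project both sets onto the
    leading principal components: the smallest m reaching the variance
    target, capped at ``N_min - 1`` where N_min is the smallest group among
    ``train_labels`` (or at an explicit ``cap``)."""
    if X_train.shape[1] < 1:
        raise ValueError("no features to reduce")
    if cap is None:
        _, counts = np.unique(np.asarray(train_labels), return_counts=True)
        cap = int(counts.min()) - 1
    cap = max(1, min(cap, X_train.shape[1], X_train.shape[0]))
    scaler = StandardScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Xte = scaler.transform(X_test)
    pca = PCA(n_components=min(Xtr.shape), svd_solver="full").fit(Xtr)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m_var = int(np.searchsorted(cum, variance_target) + 1)
    m = min(m_var, cap)
    return pca.transform(Xtr)[:, :m], pca.transform(Xte)[:, :m], m


def univariate_select(
    train_table: pd.DataFrame,
    train_labels,
    feature_columns: list[str],
    max_features: int | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Fold-wise univariate feature selection on the training rows only.

    Runs the univariate battery (normality-gated omnibus tests, Bonferroni
    over the candidate features, pairwise Mann–Whitney AUCs), keeps the
    Bonferroni-significant features ranked by their best pairwise
    discrimination max|AUC - 0.5|, and falls back to the single best-AUC
    feature when nothing reaches significance."""
    df = train_table[feature_columns].copy()
    df["__label__"] = np.asarray(train_labels)
    battery = univariate_battery(df, feature_columns, label_column="__label__",
                                 alpha=alpha, posthoc=False)
    ranked = battery.sort_values("max_auc_distance", ascending=False)
    selected = ranked.index[ranked["significant_bonferroni"]].tolist()
    if not selected:
        selected = [ranked.index[0]]
        log.info("no feature passed Bonferroni; falling back to best-AUC "
                 "feature %s", selected[0])
    if max_features is not None:
        selected = selected[:max_features]
    return selected


def _smote(X_min: np.ndarray, n_new: int, rng: np.random.Generator) -> np.ndarray:
    """Minimal SMOTE: each synthetic point lies uniformly on the segment
    between a minority point and one of its k nearest minority neighbours
    (k = min(5, n_minority - 1))."""
    n_min = X_min.shape[0]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(5, n_min - 1)
    d = np.linalg.norm(X_min[:, None, :] - X_min[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbours = np.argsort(d, axis=1)[:, :k]
    base = rng.integers(0, n_min, size=n_new)
    pick = neighbours[base, rng.integers(0, k, size=n_new)]
    lam = rng.uniform(0.0, 1.0, size=(n_new, 1))
    return X_min[base] + lam * (X_min[pick] - X_min[base])


def oversample(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "none",
    target_class: str = "ependymoma",
    amount: float = 1.0,
    rng: np.random.Generator | int | None = None,
):
    """Augment the *training* rows of ``target_class`` by ``amount`` (1.0 =
    +100%, doubling the class).  ``replicate`` duplicates existing rows;
    ``smote`` interpolates between minority neighbours.  Rows of other
    classes are untouched and test folds never pass through here."""
    if method == "none":
        return X, y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = np.nonzero(y == target_class)[0]
    if idx.size == 0:
        log.info("oversampling target %r absent from training fold; no-op",
                 target_class)
        return X, y
    n_new = int(round(amount * idx.size))
    if n_new == 0:
        return X, y
    if method == "replicate":
        extra_idx = np.tile(idx, int(np.ceil(n_new / idx.size)))[:n_new]
        X_new = X[extra_idx]
    elif method == "smote":
        X_new = _smote(X[idx], n_new, rng)
    else:
        raise ValueError(f"unknown oversampling method {method!r}")
    y_new = np.full(n_new, target_class, dtype=y.dtype)
    return np.vstack([X, X_new]), np.concatenate([y, y_new])


def knn_k(n_train: int) -> int:
    """k = round(sqrt(n_train)), minimum 1 (vote ties broken by sklearn's
    neighbour ordering)."""
    return max(1, int(round(np.sqrt(n_train))))


def _param_grid(classifier: str) -> list[dict]:
    if classifier == "adaboost":
        return [{"n_estimators": n} for n in (25, 50, 100)]
    if classifier == "random_forest":
        return [{"n_estimators": 100, "max_depth": d} for d in (None, 3, 6)]
    if classifier == "svm":
        return [{"C": c} for c in (0.5, 2.0, 8.0)]
    if classifier == "knn":
        return [{}]  # k is fixed by the sqrt(n_train) rule
    if classifier == "neural_net":
        return [{"hidden_layer_sizes": (h,)} for h in (8, 16, 32)]
    raise ValueError(classifier)


def _make_classifier(name: str, params: dict, seed: int, n_train: int):
    if name == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed, **params,
        )
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", probability=True,
                   random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=min(knn_k(n_train), n_train),
                                    **params)
    if name == "neural_net":
        return MLPClassifier(max_iter=1000, random_state=seed, **params)
    raise ValueError(name)


def _train_auc(model, X, y, seed: int) -> float:
    """Inner-CV macro one-vs-rest AUC on the training fold (the tuning
    objective)."""
    classes = np.unique(y)
    n_min = np.bincount(pd.factorize(y)[0]).min()
    n_splits = min(3, n_min)
    if n_splits < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        m = clone(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[tr], y[tr])
            proba = m.predict_proba(X[va])
        # align probability columns to the global class order
        full = np.zeros((len(va), classes.size))
        for j, c in enumerate(m.classes_):
            full[:, np.searchsorted(classes, c)] = proba[:, j]
        try:
            if classes.size == 2:
                aucs.append(roc_auc_score((y[va] == classes[1]).astype(int),
                                          full[:, 1]))
            else:
                aucs.append(roc_auc_score(y[va], full, multi_class="ovr",
                                          average="macro", labels=classes))
        except ValueError:
            continue  # a validation split missing a class
    return float(np.mean(aucs)) if aucs else 0.5


def _tune(name: str, X, y, seed: int, budget: int):
    grid = _param_grid(name)[:budget]
    if len(grid) == 1:
        return grid[0]
    best, best_auc = grid[0], -np.inf
    for params in grid:
        model = _make_classifier(name, params, seed, n_train=len(y))
        auc = _train_auc(model, X, y, seed)
        if auc > best_auc:
            best, best_auc = params, auc
    return best


def _hash_rows(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X, dtype=float).tobytes()).hexdigest()


def train_and_evaluate(
    table: pd.DataFrame,
    config: ExperimentConfig,
    columns: list[str] | None = None,
) -> CVReport:
    """Run the full stratified-CV experiment and pool test predictions.

    Reports BAR (mean per-class recall, %), macro F1 ("F-statistic"),
    between-group average precision (%), per-class precision/recall/F1 and
    the pooled confusion matrix.  ``columns`` overrides the configured
    feature set (used by the perturbation analysis).
    """
    cols = columns if columns is not None else feature_columns_for(config.feature_set)
    y_all = (
        grade_task_labels(table["label"]) if config.task == "grade"
        else table["label"].to_numpy()
    )
    X_all = table[cols]

    folds = stratified_kfold(y_all, k=config.n_folds, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    y_true_parts, y_pred_parts, details = [], [], []
    for fold_no, (tr, te) in enumerate(folds):
        Xtr_df, Xte_df = X_all.iloc[tr], X_all.iloc[te]
        ytr, yte = y_all[tr], y_all[te]
        test_hash = _hash_rows(Xte_df.to_numpy())

        cap_labels_pre = ytr.copy()
        Xtr, ytr_os = oversample(
            Xtr_df.to_numpy(dtype=float), ytr, method=config.oversampling,
            target_class=config.oversample_class,
            amount=config.oversample_amount, rng=rng,
        )
        Xte = Xte_df.to_numpy(dtype=float)

        selected: list[str] | None = None
        if config.reduction == "pca":
            cap_labels = cap_labels_pre if config.cap_before_oversampling else ytr_os
            Xtr, Xte, m = pca_reduce(
                Xtr, Xte, cap_labels, variance_target=config.variance_target
            )
            detail = {"fold": fold_no, "n_components": m}
        elif config.reduction == "univariate":
            train_df = pd.DataFrame(Xtr, columns=cols)
            selected = univariate_select(
                train_df, ytr_os, cols,
                max_features=config.max_selected_features,
            )
            keep = [cols.index(c) for c in selected]
            Xtr, Xte = Xtr[:, keep], Xte[:, keep]
            detail = {"fold": fold_no, "selected_features": selected}
        else:
            detail = {"fold": fold_no}

        if config.classifier in _SCALED and config.reduction != "pca":
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)

        params = _tune(config.classifier, Xtr, ytr_os, config.seed,
                       config.hyperopt_budget)
        model = _make_classifier(config.classifier, params, config.seed,
                                 n_train=len(ytr_os))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr_os)
            y_pred = model.predict(Xte)

        assert _hash_rows(Xte_df.to_numpy()) == test_hash, \
            "test rows were modified during training"

        detail.update({"hyperparameters": params, "n_train": len(ytr_os),
                       "seed": config.seed})
        details.append(detail)
        y_true_parts.append(yte)
        y_pred_parts.append(y_pred)

    y_true = np.concatenate(y_true_parts)
    y_pred = np.concatenate(y_pred_parts)
    classes = np.unique(y_all)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bar = balanced_accuracy_score(y_true, y_pred) * 100.0
        f_macro = f1_score(y_true, y_pred, average="macro", labels=classes,
                           zero_division=0)
        prec_macro = precision_score(y_true, y_pred, average="macro",
                                     labels=classes, zero_division=0) * 100.0
        prec = precision_score(y_true, y_pred, average=None, labels=classes,
                               zero_division=0) * 100.0
        rec = recall_score(y_true, y_pred, average=None, labels=classes,
                           zero_division=0) * 100.0
        f1 = f1_score(y_true, y_pred, average=None, labels=classes,
                      zero_division=0)
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(classes, prec, rec, f1)
    }
    confusion = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    return CVReport(
        bar=float(bar), f_stat=float(f_macro), precision_macro=float(prec_macro),
        per_class=per_class, confusion=confusion, fold_details=details,
        y_true=y_true, y_pred=y_pred,
    )


def perturbation_analysis(
    table: pd.DataFrame,
    config: ExperimentConfig,
    base_feature: str = "ADC_ROI_mean",
    family: str = "roi",
) -> pd.DataFrame:
    """Pair every other feature of the family with the base feature (ADC
    ROI mean by default), run the CV experiment on each two-feature set, and
    rank the partners by the resulting between-group average precision."""
    if base_feature not in table.columns:
        raise ValueError(f"base feature {base_feature!r} not in table")
    candidates = [c for c in feature_columns_for(family) if c != base_feature]
    cfg = replace(config, reduction="none", feature_set=family)
    rows = []
    for feat in candidates:
        report = train_and_evaluate(table, cfg, columns=[base_feature, feat])
        rows.append({"paired_feature": feat, "precision": report.precision_macro,
                     "bar": report.bar, "f_stat": report.f_stat})
    return (
        pd.DataFrame(rows)
        .sort_values("precision", ascending=False)
        .set_index("paired_feature")
    )
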