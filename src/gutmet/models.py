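"""Cross-validated random-forest classification, metrics, sweeps, kNN baseline.

The classification protocol throughout is a 200-tree random forest evaluated
by stratified 5-fold cross-validation, summarized by the median per-fold
balanced accuracy (BAC). The metric suite is BAC, AUC, PPV, TPR, FPR, F1 and
MCC; AUC uses the rank (Mann-Whitney) formulation with midranks for ties, so
it equals the probability that a random positive outscores a random negative.

Two sweeps mirror the model-selection procedure: over the number of top-scored
enzymes encoded per instance, and over kernel-PCA reductions (five kernels,
power-of-two component grids) fitted inside each training fold. The baseline
is a k-nearest-neighbour classifier on a combined chemical/enzymatic
similarity: each training instance is placed at (tanimoto, cosine) and ranked
by Euclidean distance from the ideal point (1, 1).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import KernelPCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .chem import Fingerprint, tanimoto
from .encoders import cosine_similarity

KPCA_KERNELS = ("cosine", "polynomial", "rbf", "sigmoid", "linear")
DEFAULT_ENZYME_COUNTS = (5, 10, 15, 20, 40, 60, 80, 100, 120)


@dataclass(frozen=True)
class MetricSet:
    bac: float
    auc: float
    ppv: float
    tpr: float
    fpr: float
    f1: float
    mcc: float


@dataclass
class CVResult:
    per_fold: list[MetricSet]
    median_bac: float
    fold_assignment: np.ndarray
    seed: int


@dataclass
class SweepResult:
    """One row per setting: (setting, per-fold BACs, median BAC)."""

    rows: list[tuple[object, list[float], float]] = field(default_factory=list)

    def add(self, setting, fold_bacs: Sequence[float]) -> None:
        self.rows.append((setting, list(fold_bacs), statistics.median(fold_bacs)))

    def best(self) -> tuple[object, list[float], float]:
        return max(self.rows, key=lambda row: row[2])


# ---------------------------------------------------------------------------
# Metrics


def bac_from_rates(tpr: float, fpr: float) -> float:
    """Balanced accuracy from sensitivity and false-positive rate."""
    return (tpr + (1.0 - fpr)) / 2.0


def f1_from(ppv: float, tpr: float) -> float:
    """F1 as the harmonic mean of precision and recall."""
    if ppv + tpr == 0:
        return float("nan")
    return 2.0 * ppv * tpr / (ppv + tpr)


def auc_score(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC by the rank formulation with midranks for tied scores."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(y_score)  # midranks
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """Full metric set from true labels and positive-class scores.

    Hard labels are positive iff score > threshold (a score exactly at the
    threshold classifies negative). PPV and F1 are NaN when no instance is
    predicted positive; MCC is 0 when its denominator vanishes.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score must have equal length")
    y_pred = (y_score > threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both classes must be present in y_true")
    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    f1 = f1_from(ppv, tpr) if (tp + fp) > 0 else float("nan")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return MetricSet(
        bac=bac_from_rates(tpr, fpr),
        auc=auc_score(y_true, y_score),
        ppv=ppv,
        tpr=tpr,
        fpr=fpr,
        f1=f1,
        mcc=float(mcc),
    )


# ---------------------------------------------------------------------------
# Cross-validation


def stratified_folds(labels: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Fold id per instance; per-fold positive counts differ by at most one."""
    labels = np.asarray(labels, dtype=int)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    assignment = np.empty(labels.size, dtype=int)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def train_rf_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 200,
    n_folds: int = 5,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """Stratified cross-validated random forest with the full metric suite.

    Per fold, a fresh forest is fitted on the training split and scores the
    test split with the fraction of trees voting positive. ``fold_assignment``
    lets sweeps reuse one partition across settings for comparability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if fold_assignment is None:
        fold_assignment = stratified_folds(y, n_folds, seed)
    per_fold = []
    for fold in range(int(fold_assignment.max()) + 1):
        test = fold_assignment == fold
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        clf.fit(X[~test], y[~test])
        positive_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores = clf.predict_proba(X[test])[:, positive_col]
        per_fold.append(compute_metrics(y[test], scores))
    return CVResult(
        per_fold=per_fold,
        median_bac=statistics.median(m.bac for m in per_fold),
        fold_assignment=fold_assignment,
        seed=seed,
    )


def enzyme_count_sweep(
    matrix_builder: Callable[[int], np.ndarray],
    y: np.ndarray,
    counts: Sequence[int] = DEFAULT_ENZYME_COUNTS,
    n_trees: int = 200,
    n_folds: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Cross-validate once per enzyme count k, reusing one fold partition.

    ``matrix_builder(k)`` must return the feature matrix for the same instance
    list in the same order for every k.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, n_folds, seed)
    result = SweepResult()
    for k in counts:
        cv = train_rf_cv(matrix_builder(k), y, n_trees, n_folds, seed, fold_assignment=folds)
        result.add(k, [m.bac for m in cv.per_fold])
    return result


# ---------------------------------------------------------------------------
# Kernel PCA


def kpca_reduce(
    X_train: np.ndarray,
    X_apply: np.ndarray,
    kernel: str,
    n_components: int,
    params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered kernel-matrix eigendecomposition fitted on train, applied to both.

    ``n_components`` may not exceed min(n_train_samples, n_features). Kernel
    defaults: polynomial degree 3 with coef0 1; rbf/sigmoid gamma 1/n_features.
    Component signs follow the convention that the largest-magnitude dual
    coefficient of each component is positive.
    """
    if kernel not in KPCA_KERNELS:
        raise ValueError(f"kernel must be one of {KPCA_KERNELS}")
    X_train = np.asarray(X_train, dtype=float)
    X_apply = np.asarray(X_apply, dtype=float)
    cap = min(X_train.shape)
    if n_components > cap:
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, features)={cap}"
        )
    params = dict(params or {})
    sk_kernel = "poly" if kernel == "polynomial" else kernel
    kpca = KernelPCA(
        n_components=n_components,
        kernel=sk_kernel,
        degree=params.get("degree", 3),
        coef0=params.get("coef0", 1.0),
        gamma=params.get("gamma"),  # sklearn default: 1/n_features
    )
    Z_train = kpca.fit_transform(X_train)
    if X_apply.shape[0]:
        Z_apply = kpca.transform(X_apply)
    else:
        Z_apply = np.empty((0, n_components))
    # Fix component signs: largest-|alpha| dual coefficient positive.
    alphas = kpca.eigenvectors_
    signs = np.sign(alphas[np.abs(alphas).argmax(axis=0), np.arange(alphas.shape[1])])
    signs[signs == 0] = 1.0
    return Z_train * signs, Z_apply * signs


def kpca_sweep(
    X: np.ndarray,
    y: np.ndarray,
    kernels: Sequence[str] = KPCA_KERNELS,
    component_grid: Sequence[int] = (8, 16, 32, 64, 128, 256, 512, 1024),
    n_trees: int = 200,
    n_folds: int = 5,
    seed: int = 0,
    params: dict | None = None,
    global_fit: bool = False,
) -> SweepResult:
    """Grid over (kernel, n_components), reducing inside each CV fold.

    Reduction is fitted on the training split only (no test leakage);
    ``global_fit=True`` reproduces the fit-once-on-all-data variant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, n_folds, seed)
    min_train = min(int((folds != f).sum()) for f in range(n_folds))
    cap = min(min_train, X.shape[1]) if not global_fit else min(X.shape)
    result = SweepResult()
    for kernel in kernels:
        for n_components in component_grid:
            if n_components > cap:
                raise ValueError(
                    f"n_components={n_components} exceeds fold cap {cap}"
                )
            fold_bacs = []
            if global_fit:
                Z, _ = kpca_reduce(X, X[:0], kernel, n_components, params)
                cv = train_rf_cv(Z, y, n_trees, n_folds, seed, fold_assignment=folds)
                fold_bacs = [m.bac for m in cv.per_fold]
            else:
                for fold in range(n_folds):
                    test = folds == fold
                    Z_train, Z_test = kpca_reduce(
                        X[~test], X[test], kernel, n_components, params
                    )
                    clf = RandomForestClassifier(
                        n_estimators=n_trees, random_state=seed, n_jobs=1
                    )
                    clf.fit(Z_train, y[~test])
                    positive_col = int(np.flatnonzero(clf.classes_ == 1)[0])
                    scores = clf.predict_proba(Z_test)[:, positive_col]
                    fold_bacs.append(compute_metrics(y[test], scores).bac)
            result.add((kernel, n_components), fold_bacs)
    return result


# ---------------------------------------------------------------------------
# Dual-similarity kNN baseline


def knn_rank_neighbors(
    query_fp: Fingerprint,
    query_enzyme: np.ndarray,
    train_fps: Sequence[Fingerprint],
    train_enzymes: np.ndarray,
) -> list[tuple[float, int]]:
    """All training instances sorted by combined distance, ties by index.

    For each training instance, t = Tanimoto similarity of the metabolite
    fingerprints and c = cosine similarity of the enzyme encodings; the
    combined distance is the Euclidean distance from (t, c) to the ideal
    point (1, 1): d = sqrt((1-t)^2 + (1-c)^2).
    """
    ranked = []
    for i, (fp, enz) in enumerate(zip(train_fps, train_enzymes)):
        t = tanimoto(query_fp, fp)
        c = cosine_similarity(query_enzyme, enz)
        ranked.append((float(np.hypot(1.0 - t, 1.0 - c)), i))
    ranked.sort()
    return ranked


def knn_classify(
    fingerprints: Sequence[Fingerprint],
    enzyme_encodings: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated majority-vote kNN on the combined similarity.

    Scores are the neighbour vote fraction for the positive class; with odd k
    and binary labels no vote tie can occur.
    """
    y = np.asarray(y, dtype=int)
    enzyme_encodings = np.asarray(enzyme_encodings, dtype=float)
    if fold_assignment is None:
        fold_assignment = stratified_folds(y, n_folds, seed)
    per_fold = []
    for fold in range(int(fold_assignment.max()) + 1):
        test_idx = np.flatnonzero(fold_assignment == fold)
        train_idx = np.flatnonzero(fold_assignment != fold)
        if k_neighbors >= train_idx.size:
            raise ValueError("k_neighbors must be smaller than the training split")
        train_fps = [fingerprints[i] for i in train_idx]
        train_enz = enzyme_encodings[train_idx]
        scores = np.empty(test_idx.size)
        for j, qi in enumerate(test_idx):
            ranked = knn_rank_neighbors(
                fingerprints[qi], enzyme_encodings[qi], train_fps, train_enz
            )
            votes = [y[train_idx[i]] for _, i in ranked[:k_neighbors]]
            scores[j] = float(np.mean(votes))
        per_fold.append(compute_metrics(y[test_idx], scores))
    return CVResult(
        per_fold=per_fold,
        median_bac=statistics.median(m.bac for m in per_fold),
        fold_assignment=fold_assignment,
        seed=seed,
    )
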