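"""Evaluation harness: repeated stratified k-fold CV with labeled-size
sweeps, AUC/accuracy/F1 metrics, paired Win/Tie/Loss method comparison, and
feature-recovery checks on simulated data.

The sweep mirrors the benchmark design: per fold, 80% of the samples form
the training pool from which K labeled samples are drawn stratified; the
rest of the pool is unlabeled; metrics are computed on the held-out fold.
Supervised baselines see only the K labeled samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .model import HiRANDClassifier, ImportanceScores

__all__ = [
    "ExperimentRecord",
    "ComparisonCall",
    "compute_metrics",
    "labeled_size_grid",
    "run_sweep",
    "compare_methods",
    "win_tie_loss_table",
    "feature_recovery_eval",
    "select_stable_genes",
]

#: methods trained on the K labeled samples only
BASELINES = ("mlp", "knn", "svm", "rf")
#: methods that additionally see the unlabeled training pool
SEMI_SUPERVISED = ("hirand", "hirand_noaug")


@dataclass
class ExperimentRecord:
    dataset_id: str
    method: str
    labeled_size: int
    repeat: int
    fold: int
    auc: float
    accuracy: float
    f1: float
    seed: int


@dataclass
class ComparisonCall:
    method_pair: tuple
    metric: str
    verdict: str  # Win / Tie / Loss, from the first method's viewpoint
    p_value: float
    mean_diff: float
    n_pairs: int


def compute_metrics(y_true, scores, threshold: float = 0.5):
    """(AUC, accuracy, F1) for binary labels against class-1 scores.

    AUC is the pairwise concordance probability (ties count 1/2); accuracy
    and F1 use ``scores >= threshold``.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    auc = roc_auc_score(y_true, scores)
    pred = (scores >= threshold).astype(int)
    return float(auc), float(accuracy_score(y_true, pred)), float(f1_score(y_true, pred))


def labeled_size_grid() -> list[int]:
    """The benchmark's labeled-sample-size grid: {2..20} plus {30..210 step 30}."""
    return list(range(2, 21)) + list(range(30, 211, 30))


def _stratified_labeled_subset(y_pool: np.ndarray, K: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Pick K labeled positions from the pool, guaranteeing both classes."""
    classes, counts = np.unique(y_pool, return_counts=True)
    if classes.size < 2:
        raise ValueError("training pool must contain both classes")
    if K < classes.size:
        raise ValueError(f"K={K} too small to cover {classes.size} classes")
    # proportional allocation with at least one per class
    alloc = np.maximum(1, np.round(K * counts / counts.sum()).astype(int))
    while alloc.sum() > K:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < K:
        alloc[np.argmin(alloc / counts)] += 1
    chosen = []
    for cls, k_c in zip(classes, alloc):
        pos = np.flatnonzero(y_pool == cls)
        chosen.append(rng.choice(pos, size=min(k_c, pos.size), replace=False))
    return np.sort(np.concatenate(chosen))


def _fit_predict_baseline(method: str, X_lab, y_lab, X_test, seed: int) -> np.ndarray:
    """Train a supervised baseline on the labeled samples; return class-1 scores."""
    if method == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(128,), max_iter=500,
                            random_state=seed)
    elif method == "knn":
        clf = KNeighborsClassifier(n_neighbors=min(5, len(y_lab)))
    elif method == "svm":
        clf = SVC(kernel="linear", random_state=seed)
    elif method == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown baseline {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny labeled sets trip convergence warnings
        clf.fit(X_lab, y_lab)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X_test)[:, 1]
    # linear SVM: squash the margin so thresholding at 0.5 matches predict()
    from scipy.special import expit
    return expit(clf.decision_function(X_test))


def _fit_predict_hirand(method: str, X, y_semi, X_test, seed: int,
                        hirand_params: dict | None) -> tuple[np.ndarray, object]:
    kwargs = dict(hirand_params or {})
    if method == "hirand_noaug":
        kwargs["augmentation"] = False
        kwargs.setdefault("lam", 0.0)  # one view: nothing to be consistent across
    clf = HiRANDClassifier(random_state=seed, **kwargs)
    clf.fit(X, y_semi)
    return clf.predict_proba(X_test)[:, 1], clf


def run_sweep(X, y, methods=("hirand", "mlp", "knn", "svm", "rf"),
              grid=None, n_repeats: int = 5, n_folds: int = 5, seed: int = 0,
              dataset_id: str = "dataset", hirand_params: dict | None = None,
              collect_importance: bool = False):
    """Repeated stratified k-fold CV over a labeled-size grid.

    For each (repeat, fold, K, method): the training pool is the 1-1/n_folds
    share of samples outside the held-out fold; K labeled samples are drawn
    stratified from the pool; semi-supervised methods see the rest of the
    pool unlabeled, supervised baselines only the K labeled samples; AUC,
    accuracy and F1 are computed on the held-out fold.

    Returns a list of :class:`ExperimentRecord` (plus, when
    ``collect_importance`` is set, a parallel list of importance-score
    vectors for the hirand runs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if grid is None:
        grid = labeled_size_grid()
    records: list[ExperimentRecord] = []
    importances: list[ImportanceScores] = []
    for repeat in range(n_repeats):
        rep_seed = seed * 1000 + repeat
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            y_pool = y[train_idx]
            for K in grid:
                if K >= train_idx.size:
                    warnings.warn(
                        f"K={K} >= training pool size {train_idx.size}; skipped")
                    continue
                rng = np.random.default_rng(rep_seed * 100 + fold * 10 + K)
                lab_pos = _stratified_labeled_subset(y_pool, K, rng)
                run_seed = (rep_seed * 97 + fold * 13 + K) % (2**31 - 1)
                for method in methods:
                    if method in SEMI_SUPERVISED:
                        y_semi = np.full(train_idx.size, -1, dtype=int)
                        y_semi[lab_pos] = y_pool[lab_pos]
                        scores, clf = _fit_predict_hirand(
                            method, X[train_idx], y_semi, X[test_idx],
                            run_seed, hirand_params)
                        if collect_importance and method == "hirand":
                            importances.append(clf.importance_)
                    elif method in BASELINES:
                        lab_global = train_idx[lab_pos]
                        scores = _fit_predict_baseline(
                            method, X[lab_global], y[lab_global], X[test_idx],
                            run_seed)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    auc, acc, f1 = compute_metrics(y[test_idx], scores)
                    records.append(ExperimentRecord(
                        dataset_id, method, K, repeat, fold, auc, acc, f1,
                        run_seed))
    if collect_importance:
        return records, importances
    return records


def _paired_metric(records_a, records_b, metric: str):
    key = lambda r: (r.labeled_size, r.repeat, r.fold)
    da = {key(r): getattr(r, metric) for r in records_a}
    db = {key(r): getattr(r, metric) for r in records_b}
    if set(da) != set(db):
        raise ValueError("records are not matched on (labeled_size, repeat, fold)")
    keys = sorted(da)
    return (np.array([da[k] for k in keys]), np.array([db[k] for k in keys]))


def compare_methods(records_a, records_b, metric: str = "auc",
                    alpha: float = 0.05) -> ComparisonCall:
    """Paired Win/Tie/Loss call for method A vs method B on matched folds.

    Two-sided Wilcoxon signed-rank on the per-fold metric differences (paired
    t-test fallback below 5 informative pairs).  Win: mean difference > 0 and
    p < alpha; Loss: mean difference < 0 and p < alpha; otherwise Tie.
    """
    a, b = _paired_metric(records_a, records_b, metric)
    diffs = a - b
    mean_diff = float(diffs.mean())
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        p = 1.0
    elif nonzero.size < 5:
        p = float(stats.ttest_rel(a, b).pvalue)
        if np.isnan(p):  # zero-variance nonzero differences
            p = 0.0
    else:
        p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    if p < alpha and mean_diff > 0:
        verdict = "Win"
    elif p < alpha and mean_diff < 0:
        verdict = "Loss"
    else:
        verdict = "Tie"
    pair = (records_a[0].method, records_b[0].method)
    return ComparisonCall(pair, metric, verdict, p, mean_diff, diffs.size)


def win_tie_loss_table(records, reference: str = "hirand",
                       metrics=("auc", "f1", "accuracy"), alpha: float = 0.05):
    """Tally Win/Tie/Loss of the reference method against every other method.

    One comparison per (method, metric, labeled_size); returns a nested dict
    ``{metric: {method: {"Win": int, "Tie": int, "Loss": int}}}``.
    """
    methods = sorted({r.method for r in records} - {reference})
    sizes = sorted({r.labeled_size for r in records})
    ref = [r for r in records if r.method == reference]
    table: dict = {}
    for metric in metrics:
        table[metric] = {}
        for method in methods:
            tally = {"Win": 0, "Tie": 0, "Loss": 0}
            other = [r for r in records if r.method == method]
            for K in sizes:
                call = compare_methods(
                    [r for r in ref if r.labeled_size == K],
                    [r for r in other if r.labeled_size == K],
                    metric, alpha)
                tally[call.verdict] += 1
            table[metric][method] = tally
    return table


def feature_recovery_eval(importance, true_idx):
    """How well importance scores recover the planted predictors.

    Returns (one-sided rank-sum p for true > non-true, precision among the
    top-|true_idx| ranked features).
    """
    scores = importance.scores if isinstance(importance, ImportanceScores) \
        else np.asarray(importance, dtype=float)
    true_idx = np.asarray(true_idx, dtype=int)
    if true_idx.size == 0:
        raise ValueError("true_idx is empty")
    mask = np.zeros(scores.size, dtype=bool)
    mask[true_idx] = True
    p = float(stats.mannwhitneyu(scores[mask], scores[~mask],
                                 alternative="greater").pvalue)
    top = np.argsort(-scores, kind="stable")[:true_idx.size]
    precision = float(np.isin(top, true_idx).mean())
    return p, precision


def select_stable_genes(importance_runs, top_n: int = 50) -> set:
    """Genes in the top-``top_n`` importance ranks of every repeated run."""
    if len(importance_runs) < 2:
        raise ValueError("need at least two runs")
    sets = []
    universe = None
    for run in importance_runs:
        if isinstance(run, ImportanceScores):
            ids = run.gene_ids if run.gene_ids is not None else list(range(run.scores.size))
            scores = run.scores
        else:
            scores = np.asarray(run, dtype=float)
            ids = list(range(scores.size))
        if universe is None:
            universe = list(ids)
        elif set(ids) != set(universe):
            raise ValueError("importance runs cover different gene universes")
        order = np.argsort(-scores, kind="stable")[:top_n]
        sets.append({ids[i] for i in order})
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out
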