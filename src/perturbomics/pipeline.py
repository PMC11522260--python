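"""Leakage-safe cross-validated SVM benchmarking.

Per stratified fold the training rows flow through: Spearman redundancy
filter -> resampling (balancing or augmentation, training patients only)
-> relevance selector -> z-scoring -> linear SVM. Test rows are scored
with the frozen fold model; no statistic is ever recomputed on them, and
perturbation variants of test patients never enter the fold. The
robustness screen runs once on the whole cohort before cross-validation.

Method comparison follows the two-track convention: if the fold-wise
differences look Gaussian (Shapiro-Wilk), a repeated-measures ANOVA with
paired-t post hocs; otherwise a Friedman omnibus with Dunn post hocs.
Pairwise p-values are Holm-adjusted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .features import META_COLUMNS
from .resampling import ResamplingPlan, apply_plan
from .selection import SelectionError, SelectionModel, fit_selector, redundancy_filter

__all__ = [
    "FoldMetrics",
    "ComparisonReport",
    "compute_metrics",
    "run_cv",
    "compare_methods",
    "summarize_folds",
]

logger = logging.getLogger(__name__)

SVM_C = 1.0  # linear kernel, uniform class weights — resampling handles imbalance


@dataclass
class FoldMetrics:
    fold_id: int
    sensitivity: float = np.nan
    specificity: float = np.nan
    balanced_accuracy: float = np.nan
    f1: float = np.nan
    auc: float = np.nan
    n_test: int = 0
    test_patients: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    model_hash: str = ""
    failed: bool = False
    reason: str = ""


@dataclass
class ComparisonReport:
    metric: str
    means: dict[str, float]
    sds: dict[str, float]
    omnibus_test: str
    omnibus_p: float
    posthoc: pd.DataFrame  # columns: pair, p_raw, p_adj


def compute_metrics(y_true, y_pred, scores, positive_class) -> dict[str, float]:
    """Sensitivity, specificity, balanced accuracy, f1 and rank-based AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("y_true must contain both classes")
    pred_pos = y_pred == positive_class
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    # AUC as the normalized Mann-Whitney U statistic of the scores
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 * (sens + spec),
        "f1": f1,
        "auc": float(auc),
    }


def _hash_model(parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p, dtype=np.float64).tobytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def run_cv(
    features: pd.DataFrame,
    plan: ResamplingPlan,
    selector: str,
    corr_threshold: float = 0.95,
    folds: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
    variant_features: pd.DataFrame | None = None,
    robust_features: list[str] | None = None,
) -> list[FoldMetrics]:
    """Stratified k-fold benchmark of one (selector, resampling) arm.

    ``features`` holds one original row per patient; ``variant_features``
    the precomputed augmentation-entity rows (required for perturbation
    resampling). ``robust_features`` restricts the candidate pool (output
    of the robustness screen); None uses all feature columns. Fully
    deterministic for a fixed seed.
    """
    originals = features[features["variant"] == "original"].reset_index(drop=True)
    if originals["patient_id"].duplicated().any():
        raise ValueError("duplicate original rows per patient")
    pool = robust_features if robust_features is not None else _feature_columns(originals)
    missing = [f for f in pool if f not in originals.columns]
    if missing:
        raise ValueError(f"robust features absent from table: {missing[:5]}")
    table = originals[META_COLUMNS + list(pool)]
    labels = table["label"].to_numpy()
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need two classes, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    var_table = None
    if variant_features is not None:
        var_table = variant_features[META_COLUMNS + list(pool)]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    out: list[FoldMetrics] = []
    for fold_id, (tr_idx, te_idx) in enumerate(skf.split(table, labels)):
        train = table.iloc[tr_idx].reset_index(drop=True)
        test = table.iloc[te_idx].reset_index(drop=True)
        fold_seed = (seed * 9973 + 7919 * fold_id + 1) % (2**31)
        try:
            fm = _run_fold(
                fold_id, train, test, plan, selector, corr_threshold,
                fold_seed, positive_class, var_table,
            )
        except (SelectionError, ValueError) as exc:
            logger.warning("fold %d failed: %s", fold_id, exc)
            fm = FoldMetrics(fold_id=fold_id, failed=True, reason=str(exc), n_test=len(te_idx))
        fm.test_patients = list(test["patient_id"])
        out.append(fm)
    return out


def _run_fold(
    fold_id: int,
    train: pd.DataFrame,
    test: pd.DataFrame,
    plan: ResamplingPlan,
    selector: str,
    corr_threshold: float,
    fold_seed: int,
    positive_class: str,
    variant_features: pd.DataFrame | None,
) -> FoldMetrics:
    train_patients = set(train["patient_id"])
    assert train_patients.isdisjoint(set(test["patient_id"]))
    # 1. redundancy filter on the training originals
    kept = redundancy_filter(train, threshold=corr_threshold)
    train_k = train[META_COLUMNS + kept]
    test_k = test[META_COLUMNS + kept]
    # 2. resampling — perturbation variants restricted to training patients
    var_k = None
    if variant_features is not None:
        var_k = variant_features[
            variant_features["patient_id"].isin(train_patients)
        ][META_COLUMNS + kept]
    resampled = apply_plan(train_k, plan, seed=fold_seed, variant_features=var_k)
    assert set(resampled["patient_id"]) <= train_patients
    # 3. relevance selection on the resampled training rows
    model: SelectionModel = fit_selector(selector, resampled, seed=fold_seed)
    Xtr = model.transform(resampled)
    Xte = model.transform(test_k)
    # 4. z-score with training statistics, then the SVM
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    ytr = (resampled["label"] == positive_class).to_numpy()
    clf = SVC(kernel="linear", C=SVM_C)
    clf.fit(Xtr, ytr)
    scores = clf.decision_function(Xte)
    negative_class = _other(resampled["label"], positive_class)
    y_pred = np.where(clf.predict(Xte), positive_class, negative_class)
    metrics = compute_metrics(test_k["label"].to_numpy(), y_pred, scores, positive_class)
    selected = model.selected_names if model.selected_names else [
        f"PC{i+1}" for i in range(model.n_outputs)
    ]
    model_hash = _hash_model(
        [kept, selected, model.components, model.means, model.scales,
         mu, sd, clf.coef_, clf.intercept_]
    )
    return FoldMetrics(
        fold_id=fold_id, n_test=len(test_k), selected=list(selected),
        model_hash=model_hash, **metrics,
    )


def _other(labels: pd.Series, positive_class: str) -> str:
    rest = [c for c in pd.unique(labels) if c != positive_class]
    return rest[0] if rest else positive_class


def summarize_folds(fold_metrics: list[FoldMetrics]) -> dict[str, float]:
    """Mean metrics over the non-failed folds (failed folds are reported
    separately, never silently averaged in)."""
    ok = [f for f in fold_metrics if not f.failed]
    if not ok:
        raise ValueError("all folds failed")
    out = {}
    for m in ("sensitivity", "specificity", "balanced_accuracy", "f1", "auc"):
        out[m] = float(np.mean([getattr(f, m) for f in ok]))
    out["n_failed"] = len(fold_metrics) - len(ok)
    return out


def _dunn_posthoc(M: np.ndarray, names: list[str]) -> list[tuple[str, float]]:
    """Dunn's multiple-comparison z tests on within-block (fold) ranks."""
    n, k = M.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, M)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z))
            out.append((f"{names[i]} vs {names[j]}", float(p)))
    return out


def compare_methods(
    metrics_by_method: dict[str, list[float]], metric: str = "balanced_accuracy"
) -> ComparisonReport:
    """Omnibus + post-hoc comparison of per-fold metric vectors.

    All methods must be evaluated on the same folds (equal-length vectors,
    fold-aligned).
    """
    names = list(metrics_by_method)
    vecs = [np.asarray(metrics_by_method[m], dtype=np.float64) for m in names]
    n = len(vecs[0])
    if any(len(v) != n for v in vecs):
        raise ValueError("all methods must share the same folds")
    M = np.column_stack(vecs)
    means = {m: float(v.mean()) for m, v in zip(names, vecs)}
    sds = {m: float(v.std(ddof=1)) for m, v in zip(names, vecs)}

    if len(names) < 3:
        logger.warning("fewer than 3 methods; pairwise test only")
        d = vecs[0] - vecs[1]
        normal = _diffs_normal([d])
        if normal:
            test, p = "paired t-test", float(stats.ttest_rel(vecs[0], vecs[1]).pvalue)
        else:
            test, p = "Wilcoxon signed-rank", float(stats.wilcoxon(vecs[0], vecs[1]).pvalue)
        posthoc = pd.DataFrame(
            {"pair": [f"{names[0]} vs {names[1]}"], "p_raw": [p], "p_adj": [p]}
        )
        return ComparisonReport(metric, means, sds, test, p, posthoc)

    diffs = [M[:, i] - M[:, j] for i in range(len(names)) for j in range(i + 1, len(names))]
    if all(np.ptp(d) == 0 for d in diffs):
        # methods are literally identical on every fold
        posthoc = pd.DataFrame(
            {
                "pair": [f"{a} vs {b}" for i, a in enumerate(names) for b in names[i + 1:]],
                "p_raw": 1.0,
                "p_adj": 1.0,
            }
        )
        return ComparisonReport(metric, means, sds, "degenerate (identical)", 1.0, posthoc)

    if _diffs_normal(diffs):
        long = pd.DataFrame(
            {
                "fold": np.repeat(np.arange(n), len(names)),
                "method": names * n,
                "value": M.ravel(),
            }
        )
        res = AnovaRM(long, depvar="value", subject="fold", within=["method"]).fit()
        omnibus_p = float(res.anova_table["Pr > F"].iloc[0])
        test = "repeated-measures ANOVA"
        raw = [
            (f"{names[i]} vs {names[j]}", float(stats.ttest_rel(M[:, i], M[:, j]).pvalue))
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    else:
        statv, omnibus_p = stats.friedmanchisquare(*[M[:, i] for i in range(len(names))])
        omnibus_p = float(omnibus_p)
        test = "Friedman"
        raw = _dunn_posthoc(M, names)
    if not np.isfinite(omnibus_p):
        omnibus_p = 1.0
    pairs = [r[0] for r in raw]
    p_raw = np.array([min(1.0, r[1]) if np.isfinite(r[1]) else 1.0 for r in raw])
    p_adj = multipletests(p_raw, method="holm")[1]
    posthoc = pd.DataFrame({"pair": pairs, "p_raw": p_raw, "p_adj": p_adj})
    return ComparisonReport(metric, means, sds, test, omnibus_p, posthoc)


def _diffs_normal(diffs: list[np.ndarray], alpha: float = 0.05) -> bool:
    for d in diffs:
        if np.ptp(d) == 0:
            continue  # constant difference: no evidence against normality
        try:
            if stats.shapiro(d).pvalue < alpha:
                return False
        except ValueError:
            continue
    return True
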