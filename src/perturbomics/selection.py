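"""Redundancy filtering and the five relevance selectors.

Redundancy: pairwise Spearman correlation with greedy elimination — while
any pair exceeds the threshold, the currently worst pair is taken and the
member with the higher mean |rho| against all remaining features is
dropped.

Relevance: Mann-Whitney p-value screening, L1-penalized logistic
regression (LASSO, lambda by inner 5-fold CV with the one-standard-error
rule), PCA with Kaiser retention (eigenvalue > 1), and the semi-supervised
variants that run LASSO/PCA on the Mann-Whitney survivors. Every selector
fits on training rows only; the fitted :class:`SelectionModel` replays the
stored transform on test rows without recomputing statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import META_COLUMNS

__all__ = [
    "SelectionError",
    "SelectionModel",
    "redundancy_filter",
    "select_pvalue",
    "select_lasso",
    "select_pca",
    "select_semisupervised",
    "fit_selector",
    "SELECTOR_NAMES",
    "PVALUE_ALPHA",
]

logger = logging.getLogger(__name__)

PVALUE_ALPHA = 0.05  # two-sided, unadjusted
SELECTOR_NAMES = ("pvalue", "lasso", "sslasso", "pca", "sspca")


class SelectionError(RuntimeError):
    """Explicit 'no features selected' failure state."""


@dataclass
class SelectionModel:
    """A fitted relevance selector.

    Sparse methods (pvalue, lasso, sslasso) store the selected feature
    names and transform by column subset. Projection methods (pca, sspca)
    store the training means/scales and orthonormal loadings and transform
    by standardize-then-project, so test rows never touch test statistics.
    """

    method: str
    feature_names_in: list[str]
    selected_names: list[str] = field(default_factory=list)
    components: np.ndarray | None = None  # (n_components, n_features_in)
    means: np.ndarray | None = None
    scales: np.ndarray | None = None

    @property
    def n_outputs(self) -> int:
        if self.components is not None:
            return self.components.shape[0]
        return len(self.selected_names)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if self.components is not None:
            X = table[self.feature_names_in].to_numpy(dtype=np.float64)
            return (X - self.means) / self.scales @ self.components.T
        return table[self.selected_names].to_numpy(dtype=np.float64)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def redundancy_filter(table: pd.DataFrame, threshold: float = 0.95) -> list[str]:
    """Greedy Spearman-redundancy elimination; order of output preserved.

    A constant feature has undefined rank correlation; it is treated as
    rho = 0 against everything (and logged), so it always survives this
    stage.
    """
    feats = _feature_columns(table)
    if len(feats) < 2:
        return list(feats)
    X = table[feats].to_numpy(dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("redundancy filtering needs >= 3 samples")
    # pairwise Spearman via pandas: robust to constant columns, which get
    # undefined (NaN) correlations
    rho = table[feats].corr(method="spearman").to_numpy()
    const = [f for i, f in enumerate(feats) if np.ptp(X[:, i]) == 0]
    if const:
        logger.warning("constant features treated as rho=0: %s", const)
    C = np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(C, 0.0)
    alive = list(range(len(feats)))
    while True:
        sub = C[np.ix_(alive, alive)]
        if sub.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)  # worst pair, first by order on ties
        i, j = alive[a], alive[b]
        others = [k for k in alive]
        mean_i = C[i, others].sum() / max(1, len(others) - 1)
        mean_j = C[j, others].sum() / max(1, len(others) - 1)
        # drop the member with the higher mean |rho|; registry order wins ties
        drop = j if mean_j >= mean_i else i
        if mean_i == mean_j:
            drop = max(i, j)
        alive.remove(drop)
        if len(alive) == 1:
            break
    return [feats[i] for i in alive]


def _class_split(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = table["label"].to_numpy()
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    feats = _feature_columns(table)
    return labels, np.asarray(classes), feats


def select_pvalue(table: pd.DataFrame, alpha: float = PVALUE_ALPHA) -> list[str]:
    """Features with a two-sided Mann-Whitney U p-value below alpha."""
    labels, classes, feats = _class_split(table)
    out = []
    for f in feats:
        x = table.loc[labels == classes[0], f].to_numpy()
        y = table.loc[labels == classes[1], f].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        p = mannwhitneyu(x, y, alternative="two-sided").pvalue
        if p < alpha:
            out.append(f)
    return out


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    return (X - means) / scales, means, scales


def select_lasso(
    table: pd.DataFrame, seed: int = 0, cv_folds: int = 5
) -> list[str]:
    """L1-logistic selection at the one-standard-error lambda.

    The penalty path is scanned by stratified inner CV on the training
    rows; the strongest penalty whose mean log-loss is within one standard
    error of the best is kept, and the nonzero coefficients of the final
    fit are the selected features.
    """
    labels, classes, feats = _class_split(table)
    X, _, _ = _standardize(table[feats].to_numpy(dtype=np.float64))
    y = (labels == classes[1]).astype(int)
    Cs = np.logspace(-3, 2, 20)
    n_min = min((y == 0).sum(), (y == 1).sum())
    folds = min(cv_folds, n_min)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    losses = np.zeros((len(Cs), folds))
    for f_idx, (tr, va) in enumerate(skf.split(X, y)):
        for c_idx, C in enumerate(Cs):
            clf = LogisticRegression(
                penalty="l1", C=C, solver="liblinear", max_iter=2000, random_state=0
            )
            clf.fit(X[tr], y[tr])
            p = np.clip(clf.predict_proba(X[va])[:, 1], 1e-12, 1 - 1e-12)
            losses[c_idx, f_idx] = -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
    mean_loss = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_loss))
    # smallest C (strongest penalty) within one SE of the best
    ok = np.flatnonzero(mean_loss <= mean_loss[best] + se[best])
    chosen = Cs[ok[0]]
    clf = LogisticRegression(
        penalty="l1", C=chosen, solver="liblinear", max_iter=2000, random_state=0
    )
    clf.fit(X, y)
    selected = [f for f, c in zip(feats, clf.coef_.ravel()) if c != 0.0]
    if not selected:
        raise SelectionError("LASSO selected no features at the 1-SE penalty")
    return selected


def select_pca(table: pd.DataFrame, kaiser_threshold: float = 1.0) -> SelectionModel:
    """PCA on standardized training features, Kaiser retention.

    Components with an eigenvalue of the training correlation matrix above
    1 are kept (always at least one). The returned model stores training
    means/scales and loadings for leakage-free test projection.
    """
    feats = _feature_columns(table)
    X = table[feats].to_numpy(dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Z, means, scales = _standardize(X)
    # eigenvalues of the correlation matrix (population normalization)
    cov = Z.T @ Z / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    n_keep = max(1, int(np.sum(eigval > kaiser_threshold)))
    return SelectionModel(
        method="pca",
        feature_names_in=feats,
        components=eigvec[:, :n_keep].T,
        means=means,
        scales=scales,
    )


def select_semisupervised(table: pd.DataFrame, inner: str, seed: int = 0) -> SelectionModel:
    """Mann-Whitney prefilter (p < 0.05), then LASSO or PCA on survivors."""
    if inner not in ("lasso", "pca"):
        raise ValueError("inner must be 'lasso' or 'pca'")
    survivors = select_pvalue(table)
    if not survivors:
        raise SelectionError("Mann-Whitney prefilter left no features")
    sub = table[META_COLUMNS + survivors]
    if inner == "lasso":
        names = select_lasso(sub, seed=seed)
        return SelectionModel(method="sslasso", feature_names_in=survivors, selected_names=names)
    model = select_pca(sub)
    model.method = "sspca"
    return model


def fit_selector(method: str, table: pd.DataFrame, seed: int = 0) -> SelectionModel:
    """Uniform entry point: fit any of the five selectors on training rows."""
    if method == "pvalue":
        names = select_pvalue(table)
        if not names:
            raise SelectionError("no feature passed the Mann-Whitney test")
        return SelectionModel(
            method="pvalue", feature_names_in=_feature_columns(table), selected_names=names
        )
    if method == "lasso":
        names = select_lasso(table, seed=seed)
        return SelectionModel(
            method="lasso", feature_names_in=_feature_columns(table), selected_names=names
        )
    if method == "pca":
        return select_pca(table)
    if method == "sslasso":
        return select_semisupervised(table, "lasso", seed=seed)
    if method == "sspca":
        return select_semisupervised(table, "pca", seed=seed)
    raise ValueError(f"unknown selector {method!r}; choose from {SELECTOR_NAMES}")
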