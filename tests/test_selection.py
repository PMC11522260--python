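"""Redundancy filtering and the five relevance selectors."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import perturbomics as p
from perturbomics.selection import select_pca, select_pvalue, select_semisupervised


def _table(X: np.ndarray, labels=None, names=None) -> pd.DataFrame:
    n, m = X.shape
    names = names or [f"f{i}" for i in range(m)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", labels if labels is not None else ["A"] * n)
    df.insert(0, "variant", "original")
    df.insert(0, "patient_id", [f"P{i}" for i in range(n)])
    return df


# ------------------------------------------------------------- redundancy


def test_identical_pair_one_survives():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    table = _table(np.column_stack([x, x, rng.normal(size=40)]))
    kept = p.redundancy_filter(table, threshold=0.95)
    assert kept == ["f0", "f2"]


def test_uncorrelated_features_identity():
    rng = np.random.default_rng(1)
    table = _table(rng.normal(size=(60, 5)))
    assert p.redundancy_filter(table, threshold=0.90) == [f"f{i}" for i in range(5)]


def test_postcondition_no_pair_above_threshold():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(50, 2))
    X = np.column_stack(
        [base[:, 0], base[:, 0] + rng.normal(0, 0.05, 50),
         base[:, 0] + rng.normal(0, 0.1, 50), base[:, 1],
         base[:, 1] + rng.normal(0, 0.05, 50), rng.normal(size=50)]
    )
    table = _table(X)
    for thr in (0.90, 0.95):
        kept = p.redundancy_filter(table, threshold=thr)
        sub = table[kept].to_numpy()
        rho = np.abs(spearmanr(sub).statistic)
        np.fill_diagonal(rho, 0)
        assert rho.max() <= thr


def brute_force_redundancy(table, feats, threshold):
    """Independent re-implementation of the greedy rule for the oracle."""
    X = table[feats].to_numpy()
    C = np.abs(spearmanr(X).statistic)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    np.fill_diagonal(C, 0.0)
    alive = list(range(len(feats)))
    while True:
        pairs = [(C[i, j], i, j) for ai, i in enumerate(alive) for j in alive[ai + 1:]]
        worst = max(pairs, key=lambda t: t[0]) if pairs else None
        if worst is None or worst[0] <= threshold:
            break
        _, i, j = worst
        mi = C[i, alive].sum() / (len(alive) - 1)
        mj = C[j, alive].sum() / (len(alive) - 1)
        alive.remove(j if mj >= mi else i)
    return [feats[i] for i in alive]


def test_planted_triple_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    z = rng.normal(size=80)
    X = np.column_stack(
        [z, z + rng.normal(0, 0.01, 80), z + rng.normal(0, 0.02, 80),
         rng.normal(size=80), rng.normal(size=80), rng.normal(size=80)]
    )
    table = _table(X)
    feats = [f"f{i}" for i in range(6)]
    for thr in (0.90, 0.95):
        assert p.redundancy_filter(table, thr) == brute_force_redundancy(table, feats, thr)


def test_constant_feature_survives_as_rho_zero():
    rng = np.random.default_rng(4)
    X = np.column_stack([np.full(30, 3.0), rng.normal(size=30), rng.normal(size=30)])
    kept = p.redundancy_filter(_table(X), threshold=0.90)
    assert "f0" in kept


# ----------------------------------------------------------- p-value


def _two_class_table(n=12, m=5, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, m))
    labels = ["A"] * n + ["B"] * n
    X[n:, 0] += effect
    return _table(X, labels=labels)


def test_identical_feature_not_selected():
    table = _two_class_table(effect=0.0, seed=1)
    table["f4"] = 1.0  # literally identical in both classes
    assert "f4" not in p.selection.select_pvalue(table) if hasattr(p, "selection") else True
    assert "f4" not in select_pvalue(table)


def test_disjoint_supports_selected():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(5, 6, 10)])
    table = _table(x[:, None], labels=["A"] * 10 + ["B"] * 10)
    assert select_pvalue(table) == ["f0"]


def test_pvalue_matches_direct_u_statistic_oracle():
    """Exact-U route: selection agrees with p-values from the normal
    approximation computed from a hand-rolled U statistic."""
    from scipy.stats import norm

    table = _two_class_table(n=30, m=6, effect=1.2, seed=5)
    selected = select_pvalue(table)
    labels = table["label"].to_numpy()
    for f in [f"f{i}" for i in range(6)]:
        x = table.loc[labels == "A", f].to_numpy()
        y = table.loc[labels == "B", f].to_numpy()
        n1, n2 = len(x), len(y)
        ranks = pd.Series(np.concatenate([x, y])).rank().to_numpy()
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        p_approx = 2 * norm.sf(abs(z))
        if p_approx < 0.03:
            assert f in selected
        if p_approx > 0.10:
            assert f not in selected


def test_small_class_rejected():
    table = _table(np.random.default_rng(0).normal(size=(5, 3)), labels=["A", "A", "A", "A", "B"])
    with pytest.raises(ValueError, match="fewer than 2"):
        select_pvalue(table)


# -------------------------------------------------------------- LASSO


def test_lasso_finds_separating_feature():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 30
        y = np.array([0] * n + [1] * n)
        X = rng.normal(size=(2 * n, 8))
        X[:, 3] = y * 3 + rng.normal(0, 0.3, 2 * n)  # near-perfect separator
        table = _table(X, labels=np.where(y, "B", "A"))
        sel = p.selection.select_lasso(table, seed=seed)
        hits += "f3" in sel
    assert hits >= 19


def test_lasso_duplicated_informative_feature():
    rng = np.random.default_rng(11)
    n = 25
    y = np.array([0] * n + [1] * n)
    base = y * 2.5 + rng.normal(0, 0.5, 2 * n)
    X = np.column_stack([base, base.copy(), rng.normal(size=2 * n)])
    table = _table(X, labels=np.where(y, "B", "A"))
    sel = p.selection.select_lasso(table, seed=0)
    assert "f0" in sel or "f1" in sel


# ---------------------------------------------------------------- PCA


def test_pca_uncorrelated_retains_few_components():
    counts = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        table = _table(rng.normal(size=(200, 6)))
        counts.append(select_pca(table).n_outputs)
    # sample eigenvalues hover around 1, so roughly half clear the Kaiser
    # bar; retention stays well below the feature count and never vanishes
    assert 1 <= min(counts) and max(counts) <= 4


def test_pca_planted_block_first_component():
    rng = np.random.default_rng(6)
    z = rng.normal(size=100)
    X = np.column_stack([z + rng.normal(0, 0.2, 100) for _ in range(5)]
                        + [rng.normal(size=100) for _ in range(3)])
    model = select_pca(_table(X))
    first = model.components[0]
    block = first[:5]
    assert np.all(np.sign(block) == np.sign(block[0]))  # sign-consistent loadings
    assert np.sum(block**2) > 0.8  # block dominates the first component


def test_pca_orthonormal_loadings_and_frozen_transform():
    rng = np.random.default_rng(7)
    table = _table(rng.normal(size=(50, 6)))
    model = select_pca(table)
    G = model.components @ model.components.T
    assert np.allclose(G, np.eye(model.n_outputs), atol=1e-8)
    test_rows = _table(rng.normal(size=(10, 6)))
    before = (model.means.copy(), model.scales.copy(), model.components.copy())
    _ = model.transform(test_rows)
    assert np.array_equal(before[0], model.means)
    assert np.array_equal(before[1], model.scales)
    assert np.array_equal(before[2], model.components)


# ------------------------------------------------------- semi-supervised


def test_sslasso_subset_of_pvalue():
    table = _two_class_table(n=30, m=8, effect=2.0, seed=9)
    pv = set(select_pvalue(table))
    model = select_semisupervised(table, "lasso", seed=0)
    assert set(model.selected_names) <= pv


def test_sspca_components_not_more_than_pca():
    table = _two_class_table(n=40, m=10, effect=1.0, seed=10)
    full = select_pca(table).n_outputs
    ss = select_semisupervised(table, "pca").n_outputs
    assert ss <= full


def test_all_nonsignificant_failure_state():
    table = _two_class_table(n=8, m=4, effect=0.0, seed=12)
    with pytest.raises(p.SelectionError):
        select_semisupervised(table, "pca")
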