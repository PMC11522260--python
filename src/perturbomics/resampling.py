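"""Training-fold resampling: ROS, SMOTE, ADASYN and perturbation-based
balancing/augmentation.

The feature-space oversamplers follow their canonical algorithms: ROS
duplicates rows with replacement; SMOTE interpolates uniformly along the
segment to one of the k nearest within-class neighbours; ADASYN allocates
the generation budget across minority samples proportionally to the
fraction of other-class samples in their k-neighbourhood (learning
difficulty) before SMOTE-style interpolation. Neighbour searches use
Euclidean distance on features z-scored with training-fold statistics.

The perturbation-based methods do not synthesize in feature space at all:
they add rows extracted from the eroded, dilated or contour-randomized
ROI of training patients, looked up from a variant feature table computed
once before cross-validation.

`balance` mode equalizes the class counts; `augment` mode quadruples each
class (the original rows plus three synthetic rows per instance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import META_COLUMNS

__all__ = [
    "ResamplingPlan",
    "ros",
    "smote",
    "adasyn",
    "perturb_balance",
    "perturb_augment",
    "apply_plan",
    "AUGMENTATION_KINDS",
    "RESAMPLING_METHODS",
]

logger = logging.getLogger(__name__)

AUGMENTATION_KINDS = ("erode", "dilate", "randomize")
RESAMPLING_METHODS = ("none", "ros", "smote", "adasyn", "perturbation")
AUGMENT_FACTOR = 4  # original + 3 synthetic rows per instance


@dataclass
class ResamplingPlan:
    """What to do to each training fold."""

    method: str = "none"
    mode: str = "balance"  # balance | augment
    k_neighbors: int = 5
    augment_factor: int = AUGMENT_FACTOR

    def __post_init__(self) -> None:
        if self.method not in RESAMPLING_METHODS:
            raise ValueError(f"method must be one of {RESAMPLING_METHODS}")
        if self.mode not in ("balance", "augment"):
            raise ValueError("mode must be 'balance' or 'augment'")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.mode == "augment" and self.augment_factor != AUGMENT_FACTOR:
            raise ValueError(f"augment mode uses a fixed factor of {AUGMENT_FACTOR}")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _class_counts(table: pd.DataFrame) -> pd.Series:
    counts = table["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("resampling needs two classes in the training rows")
    return counts


def _targets(table: pd.DataFrame, mode: str) -> dict[str, int]:
    """Rows to ADD per class."""
    counts = _class_counts(table)
    if mode == "balance":
        majority = int(counts.max())
        return {c: majority - int(n) for c, n in counts.items()}
    return {c: (AUGMENT_FACTOR - 1) * int(n) for c, n in counts.items()}


def ros(table: pd.DataFrame, seed: int = 0, mode: str = "balance") -> pd.DataFrame:
    """Random oversampling: duplicate class rows with replacement."""
    rng = np.random.default_rng(seed)
    added = []
    for cls, n_add in _targets(table, mode).items():
        if n_add == 0:
            continue
        pool = table[table["label"] == cls]
        picks = rng.integers(0, len(pool), size=n_add)
        dup = pool.iloc[picks].copy()
        dup["variant"] = [f"ros{i}" for i in range(n_add)]
        added.append(dup)
    return pd.concat([table, *added], ignore_index=True) if added else table.copy()


def _zscore_space(table: pd.DataFrame, feats: list[str]) -> np.ndarray:
    X = table[feats].to_numpy(dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _interpolate(
    base_rows: pd.DataFrame,
    feats: list[str],
    base_idx: np.ndarray,
    nn_idx: np.ndarray,
    u: np.ndarray,
    tag: str,
) -> pd.DataFrame:
    X = base_rows[feats].to_numpy(dtype=np.float64)
    synth = X[base_idx] + u[:, None] * (X[nn_idx] - X[base_idx])
    out = pd.DataFrame(synth, columns=feats)
    out.insert(0, "label", base_rows["label"].iloc[0])
    out.insert(0, "variant", [f"{tag}{i}" for i in range(len(base_idx))])
    out.insert(0, "patient_id", base_rows["patient_id"].to_numpy()[base_idx])
    return out


def _effective_k(k: int, pool_size: int) -> int:
    if pool_size < 2:
        raise ValueError("need at least 2 samples in the class to interpolate")
    if pool_size <= k:
        logger.warning("class of %d too small for k=%d; using k=%d", pool_size, k, pool_size - 1)
        return pool_size - 1
    return k


def smote(
    table: pd.DataFrame, k: int = 5, seed: int = 0, mode: str = "balance"
) -> pd.DataFrame:
    """SMOTE: convex combinations with k nearest within-class neighbours."""
    rng = np.random.default_rng(seed)
    feats = _feature_columns(table)
    Z = _zscore_space(table, feats)
    added = []
    for cls, n_add in _targets(table, mode).items():
        if n_add == 0:
            continue
        in_cls = np.flatnonzero((table["label"] == cls).to_numpy())
        kk = _effective_k(k, len(in_cls))
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(Z[in_cls])
        _, neigh = nn.kneighbors(Z[in_cls])  # col 0 is self
        base = rng.integers(0, len(in_cls), size=n_add)
        pick = neigh[base, rng.integers(1, kk + 1, size=n_add)]
        u = rng.uniform(0.0, 1.0, size=n_add)
        added.append(_interpolate(table.iloc[in_cls], feats, base, pick, u, "smote"))
    return pd.concat([table, *added], ignore_index=True) if added else table.copy()


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (sum exact)."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
    return base


def adasyn(
    table: pd.DataFrame, k: int = 5, seed: int = 0, mode: str = "balance"
) -> pd.DataFrame:
    """ADASYN: difficulty-weighted SMOTE.

    Each sample of the processed class gets a generation budget
    proportional to the fraction of other-class samples among its k
    nearest neighbours in the full training set; interpolation partners
    are within-class. If no neighbourhood contains the other class the
    weights degenerate to uniform (logged).
    """
    rng = np.random.default_rng(seed)
    feats = _feature_columns(table)
    Z = _zscore_space(table, feats)
    labels = table["label"].to_numpy()
    added = []
    for cls, n_add in _targets(table, mode).items():
        if n_add == 0:
            continue
        in_cls = np.flatnonzero(labels == cls)
        kk = _effective_k(k, len(in_cls))
        k_all = min(k, len(table) - 1)
        nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(Z)
        _, neigh_all = nn_all.kneighbors(Z[in_cls])
        frac_other = (labels[neigh_all[:, 1:]] != cls).mean(axis=1)
        if frac_other.sum() == 0:
            logger.warning("all %r neighbourhoods pure; uniform ADASYN weights", cls)
            weights = np.full(len(in_cls), 1.0 / len(in_cls))
        else:
            weights = frac_other / frac_other.sum()
        alloc = _largest_remainder(weights, n_add)
        nn_cls = NearestNeighbors(n_neighbors=kk + 1).fit(Z[in_cls])
        _, neigh_cls = nn_cls.kneighbors(Z[in_cls])
        base = np.repeat(np.arange(len(in_cls)), alloc)
        pick = neigh_cls[base, rng.integers(1, kk + 1, size=len(base))]
        u = rng.uniform(0.0, 1.0, size=len(base))
        added.append(_interpolate(table.iloc[in_cls], feats, base, pick, u, "adasyn"))
    return pd.concat([table, *added], ignore_index=True) if added else table.copy()


def _variant_row(
    variant_features: pd.DataFrame, patient_id: str, kind: str, feats: list[str]
) -> pd.Series:
    hit = variant_features[
        (variant_features["patient_id"] == patient_id)
        & (variant_features["variant"] == kind)
    ]
    if len(hit) == 0:
        raise ValueError(f"missing perturbation variant {kind!r} for patient {patient_id!r}")
    return hit.iloc[0]


def perturb_balance(
    table: pd.DataFrame,
    variant_features: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Balance classes with feature rows from perturbed minority ROIs.

    Minority patients are drawn without replacement until exhausted, then
    with replacement; the perturbation kind is uniform on
    {erode, dilate, randomize} and a (patient, kind) pair is used at most
    once. The deficit may not exceed 3 x the minority patient count.
    """
    rng = np.random.default_rng(seed)
    counts = _class_counts(table)
    if counts.min() == counts.max():
        return table.copy()
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    pats = list(table.loc[table["label"] == minority, "patient_id"])
    if deficit > len(AUGMENTATION_KINDS) * len(pats):
        raise ValueError(
            f"deficit {deficit} exceeds the {len(AUGMENTATION_KINDS)} variants "
            f"available per minority patient ({len(pats)} patients)"
        )
    feats = _feature_columns(table)
    used: set[tuple[str, str]] = set()
    added_rows = []
    while len(added_rows) < deficit:
        order = list(pats)
        rng.shuffle(order)
        for pid in order:
            if len(added_rows) >= deficit:
                break
            free = [kd for kd in AUGMENTATION_KINDS if (pid, kd) not in used]
            if not free:
                continue
            kind = free[rng.integers(0, len(free))]
            used.add((pid, kind))
            row = _variant_row(variant_features, pid, kind, feats)
            added_rows.append(
                {"patient_id": pid, "variant": kind, "label": minority,
                 **{f: row[f] for f in feats}}
            )
    return pd.concat([table, pd.DataFrame(added_rows)], ignore_index=True)


def perturb_augment(table: pd.DataFrame, variant_features: pd.DataFrame) -> pd.DataFrame:
    """Quadruple every training instance with its three perturbation variants."""
    feats = _feature_columns(table)
    added_rows = []
    for _, orig in table.iterrows():
        for kind in AUGMENTATION_KINDS:
            row = _variant_row(variant_features, orig["patient_id"], kind, feats)
            added_rows.append(
                {"patient_id": orig["patient_id"], "variant": kind,
                 "label": orig["label"], **{f: row[f] for f in feats}}
            )
    out = pd.concat([table, pd.DataFrame(added_rows)], ignore_index=True)
    assert len(out) == AUGMENT_FACTOR * len(table)
    return out


def apply_plan(
    table: pd.DataFrame,
    plan: ResamplingPlan,
    seed: int = 0,
    variant_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dispatch a :class:`ResamplingPlan` on one training fold."""
    if plan.method == "none":
        return table.copy()
    if plan.method == "ros":
        return ros(table, seed=seed, mode=plan.mode)
    if plan.method == "smote":
        return smote(table, k=plan.k_neighbors, seed=seed, mode=plan.mode)
    if plan.method == "adasyn":
        return adasyn(table, k=plan.k_neighbors, seed=seed, mode=plan.mode)
    if variant_features is None:
        raise ValueError("perturbation resampling needs the variant feature table")
    if plan.mode == "balance":
        return perturb_balance(table, variant_features, seed=seed)
    return perturb_augment(table, variant_features)
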