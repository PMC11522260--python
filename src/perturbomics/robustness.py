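"""ICC-based robustness screening of radiomic features.

A feature is *stable* when its one-way random-effects ICC across the
small-entity perturbation replicates {original, eroded, dilated,
contour-randomized} exceeds 0.75, and *discriminative* when its ICC across
the large-entity replicates {original, four 30% translations} falls below
0.5 — a feature that survives large displacement of the ROI is reading the
surrounding field, not the structure. Only first-order and texture
features are scored; shape features are intentionally altered by the
perturbations and bypass the screen (and the downstream pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import META_COLUMNS

__all__ = [
    "IccResult",
    "icc_oneway",
    "assess_robustness",
    "robust_filter",
    "results_to_frame",
    "STABILITY_ICC_THRESHOLD",
    "DISCRIMINATION_ICC_THRESHOLD",
    "STABILITY_VARIANTS",
    "DISCRIMINATION_VARIANTS",
]

logger = logging.getLogger(__name__)

STABILITY_ICC_THRESHOLD = 0.75  # strict >
DISCRIMINATION_ICC_THRESHOLD = 0.5  # strict <

STABILITY_VARIANTS = ("original", "erode", "dilate", "randomize")
DISCRIMINATION_VARIANTS = (
    "original",
    "translate_x_pos",
    "translate_x_neg",
    "translate_y_pos",
    "translate_y_neg",
)


@dataclass
class IccResult:
    feature_name: str
    icc_stability: float
    icc_discrimination: float
    stable: bool
    discriminative: bool


def icc_oneway(measurements: np.ndarray) -> float:
    """One-way random-effects, single-measurement ICC — ICC(1,1).

    ``measurements`` is an n-subjects x k-replicates matrix. Returns
    (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA mean squares;
    the value lies in (-1/(k-1), 1]. Zero total variance returns 1 by
    convention (perfect agreement) and is logged.
    """
    X = np.asarray(measurements, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("measurements must be a 2D (subjects x replicates) array")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 replicates, got {n} x {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("measurements must be finite")
    grand = X.mean()
    subj = X.mean(axis=1)
    ssb = k * float(np.sum((subj - grand) ** 2))
    ssw = float(np.sum((X - subj[:, None]) ** 2))
    if ssb + ssw == 0:
        logger.warning("zero total variance; ICC set to 1 by convention")
        return 1.0
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def _replicate_matrix(table: pd.DataFrame, feature: str, variants) -> np.ndarray:
    wide = table.pivot(index="patient_id", columns="variant", values=feature)
    missing = [v for v in variants if v not in wide.columns]
    if missing:
        raise ValueError(f"missing variants {missing} in feature table")
    wide = wide[list(variants)]
    bad = wide.isna()
    if bad.any().any():
        pid = wide.index[bad.any(axis=1)][0]
        var = wide.columns[bad.loc[pid]][0]
        raise ValueError(f"missing row for patient {pid!r}, variant {var!r}")
    return wide.to_numpy()


def assess_robustness(feature_table: pd.DataFrame) -> list[IccResult]:
    """Score every non-shape feature on stability and discrimination.

    ``feature_table`` holds one row per (patient, variant) and must contain
    the original, the three stability variants and the four translations
    for every patient. Subjects are patients; replicates are variants.
    """
    scored = [
        c
        for c in feature_table.columns
        if c not in META_COLUMNS and not c.startswith("shape_")
    ]
    if not scored:
        raise ValueError("no first-order/texture features to score")
    results = []
    for feat in scored:
        stab = icc_oneway(_replicate_matrix(feature_table, feat, STABILITY_VARIANTS))
        disc = icc_oneway(_replicate_matrix(feature_table, feat, DISCRIMINATION_VARIANTS))
        results.append(
            IccResult(
                feature_name=feat,
                icc_stability=stab,
                icc_discrimination=disc,
                stable=stab > STABILITY_ICC_THRESHOLD,
                discriminative=disc < DISCRIMINATION_ICC_THRESHOLD,
            )
        )
    return results


def robust_filter(results: list[IccResult]) -> list[str]:
    """Features that are both stable and discriminative, registry order."""
    return [r.feature_name for r in results if r.stable and r.discriminative]


def results_to_frame(results: list[IccResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "icc_stability": r.icc_stability,
                "icc_discrimination": r.icc_discrimination,
                "stable": r.stable,
                "discriminative": r.discriminative,
            }
            for r in results
        ]
    )
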