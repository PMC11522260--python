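"""Shared fixtures: small phantom cohorts and cached feature tables.

Everything is generated programmatically at session start; the heavier
tables are session-scoped so the CV and leakage tests can share them.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import perturbomics as p

# perturbation wrappers log expected warnings for sub-superpixel slices;
# keep test output readable
logging.getLogger("perturbomics").setLevel(logging.ERROR)


def random_blob(rng: np.random.Generator, size: int = 64, min_area: int = 60) -> np.ndarray:
    """A random connected 2D blob, for morphology oracles."""
    from scipy.ndimage import gaussian_filter, label

    while True:
        field = gaussian_filter(rng.standard_normal((size, size)), 4.0)
        blob = field > np.quantile(field, 0.85)
        lab, n = label(blob)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        best = int(np.argmax(sizes)) + 1
        out = lab == best
        # keep away from borders so dilation has room
        out[:4, :] = out[-4:, :] = out[:, :4] = out[:, -4:] = False
        from scipy.ndimage import label as _label

        lab2, n2 = _label(out)
        if n2 == 0:
            continue
        sizes2 = np.bincount(lab2.ravel())[1:]
        out = lab2 == (int(np.argmax(sizes2)) + 1)
        if out.sum() >= min_area:
            return out


@pytest.fixture(scope="session")
def fast_config() -> p.ExtractionConfig:
    """Reduced feature set: first-order + GLCM (42 features)."""
    return p.ExtractionConfig(feature_classes=("firstorder", "glcm"))


@pytest.fixture(scope="session")
def small_cohort() -> list[p.PatientRecord]:
    cfg = p.PhantomConfig(n_per_class=4, texture_effect=2.0, noise_sd=10.0, seed=11)
    return p.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tables(small_cohort, fast_config):
    """originals, augmentation-variant rows, and screen table for 8 phantoms."""
    screen_variants, aug_variants = {}, {}
    for rec in small_cohort:
        v = dict(p.make_stability_set(rec.image, rec.mask, seed=5))
        v.update(p.make_discrimination_set(rec.mask))
        screen_variants[rec.patient_id] = v
        aug_variants[rec.patient_id] = p.make_augmentation_set(rec.image, rec.mask, seed=6)
    screen_table = p.build_feature_table(small_cohort, screen_variants, fast_config)
    aug_table = p.build_feature_table(small_cohort, aug_variants, fast_config)
    originals = aug_table[aug_table["variant"] == "original"].reset_index(drop=True)
    variants = aug_table[aug_table["variant"] != "original"].reset_index(drop=True)
    return {"originals": originals, "variants": variants, "screen": screen_table}
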